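"""Morton z-order spatial indexing for voxel-located data.

Connectome rows/columns, per-voxel image stacks and located samples are
sorted along a space-filling curve so that items close in the 3D reference
space are close in storage order.  A VOI query then touches a small number
of contiguous key ranges instead of scattering reads across the store.

The curve is Morton z-order on a power-of-two padded grid: the key of a
voxel interleaves the bits of its coordinates, x least significant within
each bit triplet.

Pre-aggregation complements the index for sample-based data: per-group
(dataset, cell type, age, ...) per-region per-gene means and counts are
materialized so that any mean-expression query whose filters align with
group boundaries is answerable from the aggregate alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from atlasfuse.atlas import VOI
from atlasfuse.errors import BoundsError, FilterError
from atlasfuse.ingest import REGION_COL, ExpressionDataset

__all__ = [
    "SpatialIndex",
    "IndexedStore",
    "RangeResult",
    "PreAggregate",
    "morton_key",
    "build_index",
    "range_query",
    "preaggregate",
    "mean_from_aggregate",
]


def morton_key(x, y, z, bits: int):
    """Morton z-order key: bit-interleave (x, y, z), x least significant.

    Coordinates must satisfy ``0 <= c < 2**bits``.  Scalar or array input;
    keys fit in 64 bits for ``bits <= 21``.
    """
    if bits < 1 or bits > 21:
        raise ValueError(f"bits must be in 1..21, got {bits}")
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    z = np.asarray(z, dtype=np.int64)
    lim = np.int64(1) << bits
    for c, name in ((x, "x"), (y, "y"), (z, "z")):
        if (c < 0).any() or (c >= lim).any():
            raise BoundsError(f"{name} coordinate outside [0, 2^{bits})")
    key = np.zeros(np.broadcast(x, y, z).shape, dtype=np.int64)
    for b in range(bits):
        key |= ((x >> b) & 1) << (3 * b)
        key |= ((y >> b) & 1) << (3 * b + 1)
        key |= ((z >> b) & 1) << (3 * b + 2)
    return key if key.ndim else np.int64(key)


def grid_bits(shape) -> int:
    """Bits per axis needed to cover a grid (power-of-two padding)."""
    return max(1, int(np.ceil(np.log2(max(shape)))))


@dataclass
class SpatialIndex:
    """Item order along the Morton curve.

    ``order`` is the permutation that sorts items by key (stable: equal
    keys keep their original relative order).
    """

    ids: np.ndarray
    locations: np.ndarray  # (N, 3) voxel indices
    keys: np.ndarray  # (N,) Morton keys, aligned with ids
    order: np.ndarray  # (N,) permutation sorting by key
    grid_bits: int

    @property
    def sorted_keys(self) -> np.ndarray:
        return self.keys[self.order]


def build_index(items, bits: int | None = None) -> SpatialIndex:
    """Build a Morton index from ``(id, (x, y, z))`` pairs.

    ``bits`` defaults to the smallest power-of-two grid covering the
    locations.
    """
    ids = np.asarray([i for i, _ in items])
    locs = np.asarray([loc for _, loc in items], dtype=np.int64).reshape(-1, 3)
    if bits is None:
        bits = grid_bits((int(locs.max()) + 1 if locs.size else 2,))
    keys = morton_key(locs[:, 0], locs[:, 1], locs[:, 2], bits) if len(ids) else np.empty(0, np.int64)
    order = np.argsort(keys, kind="stable")
    return SpatialIndex(ids=ids, locations=locs, keys=np.asarray(keys), order=order, grid_bits=bits)


@dataclass
class RangeResult:
    """Items retrieved by a VOI range query plus the I/O range count."""

    ids: np.ndarray
    values: np.ndarray
    n_ranges: int


@dataclass
class IndexedStore:
    """Values stored in Morton key order for block-range retrieval."""

    index: SpatialIndex
    values: np.ndarray  # (N, ...) in ORIGINAL item order; read via the permutation
    _sorted: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape[0] != self.index.ids.shape[0]:
            raise ValueError("one value row per indexed item required")

    @property
    def sorted_values(self) -> np.ndarray:
        if "v" not in self._sorted:
            self._sorted["v"] = self.values[self.index.order]
        return self._sorted["v"]

    @property
    def sorted_ids(self) -> np.ndarray:
        if "i" not in self._sorted:
            self._sorted["i"] = self.index.ids[self.index.order]
        return self._sorted["i"]

    def to_zarr(self, path) -> None:
        import zarr

        zarr.save_group(
            str(path),
            ids=self.sorted_ids,
            keys=self.index.sorted_keys,
            locations=self.index.locations[self.index.order],
            values=self.sorted_values,
            grid_bits=np.array([self.index.grid_bits]),
        )

    @classmethod
    def from_zarr(cls, path) -> "IndexedStore":
        import zarr

        g = zarr.open_group(str(path), mode="r")
        ids = np.asarray(g["ids"])
        locs = np.asarray(g["locations"])
        keys = np.asarray(g["keys"])
        bits = int(np.asarray(g["grid_bits"])[0])
        # stored arrays are already in curve order -> identity permutation
        idx = SpatialIndex(ids=ids, locations=locs, keys=keys, order=np.arange(ids.shape[0]), grid_bits=bits)
        return cls(index=idx, values=np.asarray(g["values"]))


def _merge_runs(sorted_keys: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted unique integer keys into maximal consecutive runs [lo, hi]."""
    if sorted_keys.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(sorted_keys) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [sorted_keys.size - 1]))
    return [(int(sorted_keys[s]), int(sorted_keys[e])) for s, e in zip(starts, ends)]


def range_query(store: IndexedStore, voi: VOI) -> RangeResult:
    """Retrieve exactly the stored items located inside the VOI.

    VOI voxel keys are merged into maximal consecutive key runs; each run
    is fetched as one contiguous slice of the key-sorted store.  Because
    the Morton map is a bijection on the padded grid, a consecutive run
    contains no key outside the VOI, so the result equals a naive scan.
    """
    bits = store.index.grid_bits
    if len(voi) == 0:
        return RangeResult(ids=store.sorted_ids[:0], values=store.sorted_values[:0], n_ranges=0)
    vox = voi.voxels
    keys = np.sort(morton_key(vox[:, 0], vox[:, 1], vox[:, 2], bits))
    runs = _merge_runs(keys)

    skeys = store.index.sorted_keys
    picks = []
    for lo, hi in runs:
        a = np.searchsorted(skeys, lo, side="left")
        b = np.searchsorted(skeys, hi, side="right")
        if b > a:
            picks.append((a, b))
    if picks:
        sel = np.concatenate([np.arange(a, b) for a, b in picks])
        ids = store.sorted_ids[sel]
        values = store.sorted_values[sel]
    else:
        ids = store.sorted_ids[:0]
        values = store.sorted_values[:0]
    return RangeResult(ids=ids, values=values, n_ranges=len(runs))


@dataclass
class PreAggregate:
    """Per-group per-gene means and sample counts.

    Groups are tuples of the chosen metadata attributes plus the region
    annotation; ``means`` has genes as rows and one column per group,
    ``counts`` one entry per group.  Group counts sum to the number of
    annotated samples.
    """

    keys: tuple[str, ...]
    means: pd.DataFrame  # genes x groups (MultiIndex columns)
    counts: pd.Series  # per group

    def groups(self):
        return list(self.means.columns)


def preaggregate(ds: ExpressionDataset, keys: list[str]) -> PreAggregate:
    """Materialize per-(metadata-group, region) per-gene means and counts."""
    for attr in keys:
        if attr not in ds.sample_meta.columns:
            raise FilterError(f"unknown metadata attribute {attr!r}")
    if REGION_COL not in ds.sample_meta.columns:
        raise ValueError("dataset must be region-annotated before pre-aggregation")
    group_cols = list(keys) + [REGION_COL]
    grouped = ds.sample_meta.groupby(group_cols, observed=True).groups
    means = {}
    counts = {}
    for key, idx in grouped.items():
        key = key if isinstance(key, tuple) else (key,)
        cols = list(idx)
        means[key] = ds.values[cols].mean(axis=1)
        counts[key] = len(cols)
    means_df = pd.DataFrame(means)
    means_df.columns = pd.MultiIndex.from_tuples(means_df.columns, names=group_cols)
    counts_s = pd.Series(counts)
    counts_s.index = means_df.columns
    return PreAggregate(keys=tuple(group_cols), means=means_df, counts=counts_s)


def mean_from_aggregate(pre: PreAggregate, groups) -> pd.Series:
    """Pooled per-gene mean over a set of groups (count-weighted average).

    Equals the raw-sample mean for any selection that is a union of whole
    groups.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("no groups selected")
    w = pre.counts.loc[groups].to_numpy(dtype=float)
    m = pre.means[groups].to_numpy()
    return pd.Series(m @ w / w.sum(), index=pre.means.index)
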