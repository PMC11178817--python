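"""Voxel-level structural-connectome assembly and VOI aggregation.

A tracer experiment contributes one injection record: an injection site
with an injection volume (the voxels affected by the tracer) and a 3D
image of projection strength per target voxel.  Assembly assigns every
source voxel covered by at least one injection volume a row of target
weights; voxels covered by several injections take the per-target maximum.
To compensate for single-hemisphere injection coverage, records can be
mirrored about the mid-plane of a chosen axis before assembly, doubling
the effective number of injection sites.  Finally, weights below a noise
threshold (default 10^-4.5, a standard false-positive cutoff for tracer
projection data) are zeroed.

Functional (grayordinate) connectivity is brought into the same voxel
frame by assigning every voxel the nearest grayordinate coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from atlasfuse.atlas import Ontology, Parcellation, ReferenceSpace, VOI, region_voxels
from atlasfuse.errors import EmptySelectionError

__all__ = [
    "PROJECTION_THRESHOLD",
    "InjectionRecord",
    "Connectome",
    "GrayordinateMap",
    "assemble_structural",
    "map_grayordinates",
    "aggregate_outgoing",
    "aggregate_incoming",
    "strongest_targets",
    "region_profile",
]

#: default projection-strength noise threshold
PROJECTION_THRESHOLD = 10.0 ** -4.5


@dataclass
class InjectionRecord:
    """One tracer injection: site coordinate, injection volume, target image."""

    site: np.ndarray  # physical or voxel coordinate of the injection site
    volume: VOI  # voxels affected by the tracer
    image: np.ndarray  # projection strength per target voxel, reference shape

    def __post_init__(self):
        self.site = np.asarray(self.site, dtype=float)
        self.image = np.asarray(self.image, dtype=float)
        if len(self.volume) == 0:
            raise ValueError("injection volume is empty")
        if tuple(self.image.shape) != tuple(self.volume.shape):
            raise ValueError("target image shape differs from the reference shape")

    def mirrored(self, axis: int) -> "InjectionRecord":
        """Reflect the record about the mid-plane of ``axis`` (index -> n-1-index)."""
        shape = self.volume.shape
        vox = self.volume.voxels.copy()
        vox[:, axis] = shape[axis] - 1 - vox[:, axis]
        site = self.site.copy()
        site[axis] = shape[axis] - 1 - site[axis]
        return InjectionRecord(
            site=site,
            volume=VOI.from_voxels(shape, vox, provenance=self.volume.provenance),
            image=np.flip(self.image, axis=axis).copy(),
        )


@dataclass
class Connectome:
    """Dense source-voxel x target-voxel weights.

    ``sources`` are the linear indices of covered source voxels; targets
    are all voxels of the reference grid in linear order, so each weight
    row reshapes to a target volume.
    """

    shape: tuple[int, int, int]
    sources: np.ndarray  # (Ns,) linear voxel indices, sorted
    weights: np.ndarray  # (Ns, prod(shape)) nonnegative
    directed: bool = True
    provenance: str = "assembled"
    n_injection_sites: int = 0
    threshold: float = PROJECTION_THRESHOLD
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.sources.size, int(np.prod(self.shape))):
            raise ValueError("weights shape inconsistent with sources/grid")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    def row(self, source_linear: int) -> np.ndarray:
        i = np.searchsorted(self.sources, source_linear)
        if i >= self.sources.size or self.sources[i] != source_linear:
            raise KeyError(f"no connectivity row for source voxel {source_linear}")
        return self.weights[i]


def assemble_structural(
    records: list[InjectionRecord],
    threshold: float = PROJECTION_THRESHOLD,
    mirror: int | None = None,
) -> Connectome:
    """Assemble a voxel-level structural connectome from injection records.

    Every source voxel covered by at least one injection volume receives
    a row; overlapping coverage is resolved by the per-target maximum.
    With ``mirror`` set, each record is duplicated reflected about the
    mid-plane of that axis before assembly (the mirrored copies are
    combined by the same max rule).  Weights strictly below ``threshold``
    are set to zero afterwards.
    """
    if not records:
        raise ValueError("empty record list")
    if mirror is not None and mirror not in (0, 1, 2):
        raise ValueError(f"mirror axis must be 0, 1 or 2, got {mirror}")
    shape = records[0].volume.shape
    for r in records:
        if r.volume.shape != shape:
            raise ValueError("records do not share a reference space")

    effective = list(records)
    if mirror is not None:
        effective += [r.mirrored(mirror) for r in records]

    n_targets = int(np.prod(shape))
    covered = np.unique(np.concatenate([r.volume.linear for r in effective]))
    pos = {int(v): i for i, v in enumerate(covered)}
    weights = np.zeros((covered.size, n_targets), dtype=float)
    for rec in effective:
        img = rec.image.ravel()
        for v in rec.volume.linear:
            i = pos[int(v)]
            np.maximum(weights[i], img, out=weights[i])

    weights[weights < threshold] = 0.0
    return Connectome(
        shape=shape,
        sources=covered,
        weights=weights,
        n_injection_sites=len(effective),
        threshold=threshold,
        attrs={"mirrored": mirror is not None, "input_records": len(records)},
    )


@dataclass
class GrayordinateMap:
    """Grayordinate coordinates: (index, physical coordinate, vertex|voxel)."""

    indices: np.ndarray  # (N,) grayordinate indices
    coords: np.ndarray  # (N, 3) physical coordinates in mm
    kinds: np.ndarray  # (N,) 'vertex' or 'voxel'

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.kinds = np.asarray(self.kinds)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.indices.size == 0:
            raise ValueError("grayordinate map is empty")


def map_grayordinates(gmap: GrayordinateMap, space: ReferenceSpace, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Assign every (in-brain) voxel the nearest grayordinate index.

    Distance is Euclidean between voxel centers and grayordinate
    coordinates; exact ties resolve to the lowest grayordinate index.
    Returns a volume of grayordinate indices (-1 outside the mask).
    """
    centers = np.stack(
        np.meshgrid(space.centers(0), space.centers(1), space.centers(2), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    if brain_mask is not None:
        flat_mask = np.asarray(brain_mask, dtype=bool).ravel()
    else:
        flat_mask = np.ones(centers.shape[0], dtype=bool)

    tree = cKDTree(gmap.coords)
    dist, nearest = tree.query(centers[flat_mask])
    # resolve ties deterministically: among all entries at the minimal
    # distance (within exact fp equality) pick the lowest grayordinate index
    out_idx = gmap.indices[nearest].copy()
    for i, (d, _) in enumerate(zip(dist, nearest)):
        cands = tree.query_ball_point(centers[flat_mask][i], d * (1 + 1e-12) if d > 0 else 1e-12)
        if len(cands) > 1:
            dists = np.linalg.norm(gmap.coords[cands] - centers[flat_mask][i], axis=1)
            best = [c for c, dd in zip(cands, dists) if dd == dists.min()]
            out_idx[i] = gmap.indices[best].min()

    volume = np.full(centers.shape[0], -1, dtype=np.int64)
    volume[flat_mask] = out_idx
    return volume.reshape(space.shape)


def aggregate_outgoing(conn: Connectome, voi: VOI, stat: str = "mean") -> np.ndarray:
    """Per-target aggregate of the rows of source voxels inside the VOI.

    Source voxels without connectivity data are excluded from the
    aggregate; ``stat`` is ``'mean'`` (default) or ``'max'``.
    """
    if voi.shape != conn.shape:
        raise ValueError("VOI grid does not match the connectome grid")
    pos = np.searchsorted(conn.sources, voi.linear)
    valid = pos < conn.sources.size
    valid[valid] = conn.sources[pos[valid]] == voi.linear[valid]
    idx = pos[valid]
    if idx.size == 0:
        raise EmptySelectionError("VOI covers no source voxel with connectivity data")
    rows = conn.weights[idx]
    agg = rows.mean(axis=0) if stat == "mean" else rows.max(axis=0)
    return agg.reshape(conn.shape)


def aggregate_incoming(conn: Connectome, voi: VOI, stat: str = "mean") -> np.ndarray:
    """Per-source aggregate of the columns of target voxels inside the VOI.

    Returns a volume over the grid with values at covered source voxels
    and NaN elsewhere (voxels without connectivity rows).
    """
    if voi.shape != conn.shape:
        raise ValueError("VOI grid does not match the connectome grid")
    if len(voi) == 0:
        raise EmptySelectionError("empty VOI")
    cols = conn.weights[:, voi.linear]
    agg = cols.mean(axis=1) if stat == "mean" else cols.max(axis=1)
    out = np.full(int(np.prod(conn.shape)), np.nan)
    out[conn.sources] = agg
    return out.reshape(conn.shape)


def strongest_targets(tmap: np.ndarray, k: int | float) -> VOI:
    """VOI of the k strongest (or top-fraction) positive target voxels.

    Ties at the cutoff are broken by Morton space-filling-curve key order
    (then linear index), making the result deterministic.
    """
    from atlasfuse.sfc_index import morton_key

    tmap = np.asarray(tmap, dtype=float)
    flat = tmap.ravel()
    positive = np.flatnonzero(flat > 0)
    if positive.size == 0:
        raise ValueError("target map has no positive value")
    if isinstance(k, float) and 0 < k < 1:
        n = max(1, int(np.ceil(k * positive.size)))
    else:
        n = int(k)
        if n <= 0:
            raise ValueError(f"k must be positive, got {k}")
    n = min(n, positive.size)

    coords = np.stack(np.unravel_index(positive, tmap.shape), axis=1)
    bits = max(1, int(np.ceil(np.log2(max(tmap.shape)))))
    keys = morton_key(coords[:, 0], coords[:, 1], coords[:, 2], bits)
    order = np.lexsort((keys, -flat[positive]))  # strength desc, then key asc
    chosen = positive[order[:n]]
    return VOI(tmap.shape, chosen, provenance="strongest-targets")


def region_profile(
    conn: Connectome,
    source_voi: VOI,
    regions: list[int],
    ont: Ontology,
    parc: Parcellation,
    direction: str = "outgoing",
    stat: str = "mean",
) -> np.ndarray:
    """Mean aggregated connectivity of a VOI per target (or source) region.

    Entry r is the mean of the aggregated connectivity volume over the
    voxels of region r; NaN for regions without voxels (or, for the
    incoming direction, without covered source voxels).
    """
    if not regions:
        raise ValueError("regions list is empty")
    if direction == "outgoing":
        vol = aggregate_outgoing(conn, source_voi, stat=stat)
    elif direction == "incoming":
        vol = aggregate_incoming(conn, source_voi, stat=stat)
    else:
        raise ValueError(f"direction must be 'outgoing' or 'incoming', got {direction!r}")
    flat = vol.ravel()
    profile = np.empty(len(regions))
    for i, r in enumerate(regions):
        voxels = region_voxels(parc, ont, int(r)).linear
        vals = flat[voxels]
        vals = vals[np.isfinite(vals)]
        profile[i] = vals.mean() if vals.size else np.nan
    return profile
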