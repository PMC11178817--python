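"""Hierarchical brain-region ontology, voxel parcellation and VOI construction.

A reference space is a fixed 3D voxel grid (an anatomical template such as
a mouse coordinate framework at 0.1 mm or a human MNI template at 1 mm).
A parcellation assigns every voxel a brain-region id from a hierarchical
ontology; parent regions anatomically subsume their children, so the voxel
set of a region is the union over its transitive descendants.  A volume of
interest (VOI) is an arbitrary deduplicated voxel set, built from a region,
a binary mask (brush) or a union of other VOIs.

Coordinate convention: 0-based voxel indices; the physical position of a
voxel center is ``(index + 0.5) * voxel_size`` per axis.  Label 0 is
reserved for background (outside brain) and is never a region id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from atlasfuse.errors import BoundsError, OntologyError

__all__ = [
    "RegionNode",
    "Ontology",
    "ReferenceSpace",
    "Parcellation",
    "VOI",
    "load_ontology",
    "load_ontology_json",
    "descendants",
    "region_voxels",
    "resample_nearest",
    "make_voi",
    "parcellation_from_nifti",
    "parcellation_to_nifti",
    "voi_from_nifti",
    "voi_to_nifti",
]


@dataclass(frozen=True)
class RegionNode:
    """One named region in a brain ontology."""

    id: int
    name: str
    acronym: str
    parent: int | None  # None for the root


class Ontology:
    """A tree of brain regions with unique integer ids and a single root.

    Parameters
    ----------
    nodes
        Region nodes; exactly one must have ``parent is None`` and every
        other parent id must refer to a node in the collection.

    Raises
    ------
    OntologyError
        On duplicate ids, missing/multiple roots, orphan parents or cycles.
    """

    def __init__(self, nodes: Iterable[RegionNode]):
        nodes = list(nodes)
        self._nodes: dict[int, RegionNode] = {}
        for n in nodes:
            if n.id == 0:
                raise OntologyError("region id 0 is reserved for background")
            if n.id in self._nodes:
                raise OntologyError(f"duplicate region id {n.id}")
            self._nodes[n.id] = n

        roots = [n.id for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        self.root: int = roots[0]

        self._children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent is None:
                continue
            if n.parent not in self._nodes:
                raise OntologyError(f"node {n.id} has unknown parent {n.parent}")
            self._children[n.parent].append(n.id)

        # every node must be reachable from the root (otherwise a cycle
        # detached from the tree exists)
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            r = stack.pop()
            if r in seen:
                raise OntologyError(f"cycle detected at region {r}")
            seen.add(r)
            stack.extend(self._children[r])
        if len(seen) != len(self._nodes):
            bad = sorted(set(self._nodes) - seen)
            raise OntologyError(f"regions not reachable from root (cycle): {bad}")

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes.values())

    def node(self, region_id: int) -> RegionNode:
        try:
            return self._nodes[region_id]
        except KeyError:
            raise OntologyError(f"unknown region id {region_id}") from None

    def children(self, region_id: int) -> list[int]:
        if region_id not in self._nodes:
            raise OntologyError(f"unknown region id {region_id}")
        return list(self._children[region_id])

    def by_name(self, name: str) -> RegionNode:
        for n in self._nodes.values():
            if n.name == name or n.acronym == name:
                return n
        raise OntologyError(f"no region named {name!r}")

    def leaves(self) -> list[int]:
        return [i for i, ch in self._children.items() if not ch]


def _normalize_nodes(doc) -> list[dict]:
    """Flatten an ontology document to a list of node dicts.

    Accepts a flat list of ``{id, name, acronym, parent_structure_id}``
    records (Allen structure-graph style), optionally wrapped in a dict
    under ``"msg"`` or ``"nodes"``, where entries may carry nested
    ``"children"`` lists instead of parent ids.
    """
    if isinstance(doc, Mapping):
        for key in ("msg", "nodes"):
            if key in doc:
                doc = doc[key]
                break
        else:
            raise OntologyError("ontology document has no 'msg' or 'nodes' key")
    if not isinstance(doc, Sequence):
        raise OntologyError("ontology document must be a list of nodes")

    flat: list[dict] = []

    def walk(entry: Mapping, parent: int | None):
        rec = {
            "id": entry["id"],
            "name": entry.get("name", str(entry["id"])),
            "acronym": entry.get("acronym", str(entry["id"])),
            "parent_structure_id": entry.get("parent_structure_id", parent),
        }
        flat.append(rec)
        for child in entry.get("children", []) or []:
            walk(child, entry["id"])

    for entry in doc:
        walk(entry, entry.get("parent_structure_id"))
    return flat


def load_ontology(doc) -> Ontology:
    """Build a validated :class:`Ontology` from a parsed ontology document."""
    flat = _normalize_nodes(doc)
    nodes = [
        RegionNode(
            id=int(r["id"]),
            name=str(r["name"]),
            acronym=str(r["acronym"]),
            parent=None if r["parent_structure_id"] is None else int(r["parent_structure_id"]),
        )
        for r in flat
    ]
    return Ontology(nodes)


def load_ontology_json(path) -> Ontology:
    with open(path) as fh:
        return load_ontology(json.load(fh))


def descendants(ont: Ontology, region_id: int) -> set[int]:
    """Return ``region_id`` plus all transitive children (reflexive closure)."""
    ont.node(region_id)  # raises on unknown id
    out: set[int] = set()
    stack = [region_id]
    while stack:
        r = stack.pop()
        out.add(r)
        stack.extend(ont.children(r))
    return out


@dataclass(frozen=True)
class ReferenceSpace:
    """A common voxel grid: shape in voxels and voxel size in mm per axis."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size per axis in mm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along one axis."""
        return (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]


class VOI:
    """A deduplicated set of voxel indices within a reference grid.

    Stored internally as sorted unique linear indices (C order, so the
    last axis varies fastest when flattening with numpy defaults).
    """

    def __init__(self, shape: tuple[int, int, int], linear: np.ndarray, provenance: str = "mask"):
        self.shape = tuple(int(s) for s in shape)
        lin = np.asarray(linear, dtype=np.int64).ravel()
        n = int(np.prod(self.shape))
        if lin.size and (lin.min() < 0 or lin.max() >= n):
            raise BoundsError("voxel index outside reference grid")
        self.linear = np.unique(lin)
        self.provenance = provenance

    @classmethod
    def from_voxels(cls, shape, voxels, provenance: str = "mask") -> "VOI":
        vox = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        if vox.size == 0:
            return cls(shape, np.empty(0, dtype=np.int64), provenance)
        if vox.shape[1] != 3:
            raise ValueError("voxels must be an (N, 3) array")
        if (vox < 0).any() or (vox >= np.asarray(shape)).any():
            raise BoundsError("voxel index outside reference grid")
        lin = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
        return cls(shape, lin, provenance)

    @classmethod
    def from_mask(cls, mask: np.ndarray, provenance: str = "mask") -> "VOI":
        mask = np.asarray(mask)
        return cls(mask.shape, np.flatnonzero(mask), provenance)

    @property
    def voxels(self) -> np.ndarray:
        """(N, 3) array of voxel indices, sorted by linear index."""
        return np.stack(np.unravel_index(self.linear, self.shape), axis=1)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.ravel()[self.linear] = True
        return m

    def __len__(self) -> int:
        return int(self.linear.size)

    def __contains__(self, voxel) -> bool:
        lin = int(np.ravel_multi_index(tuple(int(v) for v in voxel), self.shape))
        i = np.searchsorted(self.linear, lin)
        return bool(i < self.linear.size and self.linear[i] == lin)

    def intersects(self, other: "VOI") -> bool:
        return bool(np.intersect1d(self.linear, other.linear, assume_unique=True).size)

    def union(self, *others: "VOI") -> "VOI":
        for o in others:
            if o.shape != self.shape:
                raise ValueError("VOIs live in different grids")
        lin = np.concatenate([self.linear] + [o.linear for o in others])
        return VOI(self.shape, lin, provenance="union")

    def __repr__(self) -> str:
        return f"VOI({len(self)} voxels, shape={self.shape}, provenance={self.provenance!r})"


@dataclass
class Parcellation:
    """A 3D integer label volume binding a reference space to an ontology.

    Every nonzero label must be a region id of the bound ontology; 0 marks
    voxels outside the brain.
    """

    space: ReferenceSpace
    labels: np.ndarray
    _region_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if tuple(self.labels.shape) != self.space.shape:
            raise ValueError(
                f"label volume shape {self.labels.shape} != space shape {self.space.shape}"
            )

    def validate(self, ont: Ontology) -> None:
        present = np.unique(self.labels)
        unknown = [int(x) for x in present if x != 0 and int(x) not in ont]
        if unknown:
            raise OntologyError(f"labels not in ontology: {unknown}")


def region_voxels(parc: Parcellation, ont: Ontology, region_id: int) -> VOI:
    """Voxels labelled with ``region_id`` or any of its descendants.

    The empty VOI is a legal result (a region may have no voxels at the
    parcellation's resolution).
    """
    key = region_id
    cached = parc._region_cache.get(key)
    if cached is not None:
        return cached
    ids = descendants(ont, region_id)
    mask = np.isin(parc.labels, list(ids))
    voi = VOI(parc.space.shape, np.flatnonzero(mask), provenance=f"region:{region_id}")
    parc._region_cache[key] = voi
    return voi


def _nearest_source_indices(n_src: int, src_size: float, n_tgt: int, tgt_size: float) -> np.ndarray:
    """Per-axis nearest source voxel for each target voxel (centers compared).

    Equidistant ties go to the lower source index, which also minimizes the
    linearized source index since the mapping is separable per axis.
    """
    centers_t = (np.arange(n_tgt) + 0.5) * tgt_size
    # source center i is at (i + 0.5) * src_size; nearest i* = c/s - 0.5
    exact = centers_t / src_size - 0.5
    idx = np.ceil(exact - 0.5).astype(np.int64)  # tie at .5 -> lower index
    return np.clip(idx, 0, n_src - 1)


def resample_nearest(vol: np.ndarray, source: ReferenceSpace, target: ReferenceSpace) -> np.ndarray:
    """Resample a volume onto a target grid by nearest-neighbor interpolation.

    Both grids share the physical origin (corner of voxel (0,0,0)); each
    target voxel takes the value of the source voxel whose center is
    nearest to the target voxel center.
    """
    vol = np.asarray(vol)
    if tuple(vol.shape) != source.shape:
        raise ValueError(f"volume shape {vol.shape} != source space shape {source.shape}")
    for a in range(3):
        se, te = source.extent[a], target.extent[a]
        if min(se, te) <= 0:
            raise ValueError("non-overlapping physical extents")
    ix = _nearest_source_indices(source.shape[0], source.voxel_size[0], target.shape[0], target.voxel_size[0])
    iy = _nearest_source_indices(source.shape[1], source.voxel_size[1], target.shape[1], target.voxel_size[1])
    iz = _nearest_source_indices(source.shape[2], source.voxel_size[2], target.shape[2], target.voxel_size[2])
    return vol[np.ix_(ix, iy, iz)]


def make_voi(
    source,
    *,
    parcellation: Parcellation | None = None,
    ontology: Ontology | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VOI:
    """Build a VOI from a region id, a binary mask, or a list of VOIs.

    - integer region id: requires ``parcellation`` and ``ontology``; the
      VOI is the region's (descendant-closed) voxel set.
    - boolean mask: its true voxels (``shape`` checked against the mask).
    - list of VOI: their union.
    """
    if isinstance(source, VOI):
        return source
    if isinstance(source, (int, np.integer)):
        if parcellation is None or ontology is None:
            raise ValueError("region-id VOI requires parcellation and ontology")
        return region_voxels(parcellation, ontology, int(source))
    if isinstance(source, np.ndarray):
        if shape is not None and tuple(source.shape) != tuple(shape):
            raise ValueError(f"mask shape {source.shape} != expected {shape}")
        return VOI.from_mask(source.astype(bool))
    if isinstance(source, (list, tuple)):
        vois = [make_voi(s, parcellation=parcellation, ontology=ontology, shape=shape) for s in source]
        if not vois:
            raise ValueError("empty VOI list")
        return vois[0].union(*vois[1:]) if len(vois) > 1 else vois[0]
    raise TypeError(f"cannot build VOI from {type(source).__name__}")


# ---------------------------------------------------------------------------
# NIfTI interfaces

def _affine(space: ReferenceSpace) -> np.ndarray:
    aff = np.diag(list(space.voxel_size) + [1.0])
    return aff


def parcellation_from_nifti(path, ontology: Ontology | None = None) -> Parcellation:
    """Read an integer label volume; voxel size is taken from the header."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError("label volume contains non-integer values")
        labels = rounded.astype(np.int64)
    zooms = img.header.get_zooms()[:3]
    parc = Parcellation(ReferenceSpace(labels.shape, tuple(float(z) for z in zooms)), labels)
    if ontology is not None:
        parc.validate(ontology)
    return parc


def parcellation_to_nifti(parc: Parcellation, path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), _affine(parc.space))
    img.header.set_zooms(parc.space.voxel_size)
    nib.save(img, str(path))


def voi_from_nifti(path) -> VOI:
    img = nib.load(str(path))
    return VOI.from_mask(np.asarray(img.dataobj) > 0)


def voi_to_nifti(voi: VOI, space: ReferenceSpace, path) -> None:
    if tuple(voi.shape) != space.shape:
        raise ValueError("VOI grid does not match the reference space")
    img = nib.Nifti1Image(voi.mask().astype(np.uint8), _affine(space))
    img.header.set_zooms(space.voxel_size)
    nib.save(img, str(path))
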