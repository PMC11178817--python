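"""Deterministic synthetic fixtures with planted, known ground truth.

The generator emulates the input side of the integration pipeline:

- toy atlases: a balanced region ontology whose leaves tile a voxel grid
  as contiguous blocks;
- count matrices with lognormal noise and planted multiplicative
  cell-type / region marker fold-changes;
- injection-record connectomes with a planted source-to-target
  projection over sub-threshold background noise;
- two-species bundles sharing consensus regions and a homolog map, with
  a configurable set of genes constructed to correlate (negatively) with
  connectivity in both species, optionally embedded in inhibitory cells.

Everything is driven by ``numpy.random.default_rng(seed)``; identical
seeds give identical fixtures.  Counts are lognormal-then-rounded
(numpy's round-half-even), which keeps planted fold-changes easy to
recover; the generator makes no attempt at realistic scRNA-seq features
such as dropout or library-size gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from atlasfuse.atlas import Ontology, Parcellation, ReferenceSpace, RegionNode, VOI
from atlasfuse.connectome import PROJECTION_THRESHOLD, InjectionRecord
from atlasfuse.ingest import ExpressionDataset
from atlasfuse.xspecies import HomologMap

__all__ = [
    "Marker",
    "Projection",
    "FixtureSpec",
    "SpeciesBundle",
    "make_toy_atlas",
    "make_expression_dataset",
    "make_connectome_records",
    "make_species_pair",
]


@dataclass(frozen=True)
class Marker:
    """A planted marker: gene index, the group it marks, and its fold-change."""

    gene: int
    fold: float
    cell_type: str | None = None
    region: int | None = None  # region id in the generated ontology

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")


@dataclass(frozen=True)
class Projection:
    """A planted axonal projection between two regions with a given weight."""

    source: int  # region id
    target: int  # region id
    weight: float


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults describe a small but non-degenerate study: an 8x8x8 grid, a
    3-level ontology with fanout 2 (4 leaves), 100 genes, 20 samples per
    leaf region and cell type, two cortical cell classes, and lognormal
    count noise with sigma 0.5 (a mid-range per-sample dispersion).
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    depth: int = 3
    fanout: int = 2
    n_genes: int = 100
    n_samples: int = 20  # per leaf region per cell type
    cell_types: tuple[str, ...] = ("excitatory", "inhibitory")
    markers: tuple[Marker, ...] = ()
    projections: tuple[Projection, ...] = ()
    noise_sd: float = 0.5  # lognormal sigma of count noise
    baseline_log_mean: float = 3.0  # per-gene baseline ~ lognormal(3, 1)
    # two-species parameters (see make_species_pair)
    n_consensus_regions: int = 10
    n_conserved: int = 5
    conserved_effect: float = 2.0
    conserved_baseline_log: float = 5.0  # planted genes are well-expressed
    inhibitory_shift: float = 0.4
    pattern_noise: float = 0.5

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("ontology depth must be >= 2")
        if self.fanout < 1 or self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.pattern_noise < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.n_conserved > self.n_genes:
            raise ValueError("requested conserved genes exceed n_genes")


def make_toy_atlas(spec: FixtureSpec) -> tuple[Ontology, Parcellation]:
    """Balanced region tree whose leaves tile the grid as contiguous blocks.

    Region ids are assigned breadth-first starting from 1 (0 stays
    background).  Leaf k owns the k-th near-equal contiguous chunk of the
    flattened (C-order) grid, so labels cover every voxel exactly once.
    """
    n_leaves = spec.fanout ** (spec.depth - 1)
    n_vox = int(np.prod(spec.grid_shape))
    if n_leaves > n_vox:
        raise ValueError(f"grid of {n_vox} voxels too small for {n_leaves} leaves")

    nodes: list[RegionNode] = []
    next_id = 1
    level_ids: list[list[int]] = []
    parents: list[int | None] = [None]
    for level in range(spec.depth):
        ids_here: list[int] = []
        n_here = spec.fanout**level
        for j in range(n_here):
            parent = None if level == 0 else level_ids[level - 1][j // spec.fanout]
            rid = next_id
            next_id += 1
            nodes.append(
                RegionNode(
                    id=rid,
                    name=f"L{level}R{j}",
                    acronym=f"l{level}r{j}",
                    parent=parent,
                )
            )
            ids_here.append(rid)
        level_ids.append(ids_here)
    ont = Ontology(nodes)

    leaf_ids = level_ids[-1]
    labels = np.empty(n_vox, dtype=np.int32)
    for leaf, chunk in zip(leaf_ids, np.array_split(np.arange(n_vox), n_leaves)):
        labels[chunk] = leaf
    parc = Parcellation(ReferenceSpace(spec.grid_shape), labels.reshape(spec.grid_shape))
    parc.validate(ont)
    return ont, parc


def _gene_ids(n: int, prefix: str = "gene") -> list[str]:
    return [f"{prefix}_{i:05d}" for i in range(n)]


def make_expression_dataset(
    spec: FixtureSpec,
    ontology: Ontology,
    parcellation: Parcellation,
    *,
    rng: np.random.Generator | None = None,
    region_log_effects: np.ndarray | dict | None = None,
    baseline: np.ndarray | None = None,
    gene_prefix: str = "gene",
    name: str = "synthetic",
) -> ExpressionDataset:
    """Planted-marker count matrix annotated onto the toy atlas.

    For each leaf region and cell type, ``spec.n_samples`` samples are
    drawn; counts are ``round(baseline_g * fold(g, group) * lognormal(0,
    noise_sd))``.  Markers apply their fold-change multiplicatively to the
    matching (gene, cell type) and/or (gene, region) combinations.
    ``region_log_effects`` (genes x leaves, additive on the log scale;
    either one array for all cell types or a ``{cell_type: array}`` map)
    is the hook the two-species generator uses to plant expression-
    connectivity correlations inside a specific cell class.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    leaves = ontology.leaves()
    n_leaves = len(leaves)
    genes = _gene_ids(spec.n_genes, gene_prefix)

    for m in spec.markers:
        if not (0 <= m.gene < spec.n_genes):
            raise ValueError(f"marker gene index {m.gene} out of range")
        if m.region is not None and m.region not in ontology:
            raise ValueError(f"marker region {m.region} not in ontology")

    if region_log_effects is not None:
        if not isinstance(region_log_effects, dict):
            region_log_effects = {ct: region_log_effects for ct in spec.cell_types}
        region_log_effects = {
            ct: np.asarray(a, dtype=float) for ct, a in region_log_effects.items()
        }
        for ct, a in region_log_effects.items():
            if a.shape != (spec.n_genes, n_leaves):
                raise ValueError("region_log_effects arrays must be (n_genes, n_leaves)")

    if baseline is None:
        baseline = rng.lognormal(mean=spec.baseline_log_mean, sigma=1.0, size=spec.n_genes)
    else:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != (spec.n_genes,):
            raise ValueError("baseline must have one entry per gene")

    # per (gene, cell type) and (gene, leaf) log-fold tables from markers
    ct_logfold = {ct: np.zeros(spec.n_genes) for ct in spec.cell_types}
    region_logfold = {leaf: np.zeros(spec.n_genes) for leaf in leaves}
    for m in spec.markers:
        if m.cell_type is not None:
            if m.cell_type not in ct_logfold:
                raise ValueError(f"marker cell type {m.cell_type!r} not in spec")
            ct_logfold[m.cell_type][m.gene] += np.log(m.fold)
        if m.region is not None:
            for leaf in leaves:
                if m.region == leaf or _is_ancestor(ontology, m.region, leaf):
                    region_logfold[leaf][m.gene] += np.log(m.fold)

    columns = {}
    meta_rows = []
    sample_ids = []
    k = 0
    for li, leaf in enumerate(leaves):
        for ct in spec.cell_types:
            extra = 0.0
            if region_log_effects is not None and ct in region_log_effects:
                extra = region_log_effects[ct][:, li]
            log_mu = np.log(baseline) + ct_logfold[ct] + region_logfold[leaf] + extra
            noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
            block = np.rint(np.exp(log_mu[:, None] + noise))
            for j in range(spec.n_samples):
                sid = f"s_{k:06d}"
                sample_ids.append(sid)
                columns[sid] = block[:, j]
                meta_rows.append(
                    {
                        "cell_type": ct,
                        "age": "adult",
                        "phenotype": "control",
                        "region": ontology.node(leaf).name,
                        "region_id": leaf,
                    }
                )
                k += 1

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample"))
    return ExpressionDataset(values=values, sample_meta=meta, norm="raw", name=name)


def _is_ancestor(ont: Ontology, ancestor: int, node: int) -> bool:
    cur = ont.node(node).parent
    while cur is not None:
        if cur == ancestor:
            return True
        cur = ont.node(cur).parent
    return False


def make_connectome_records(
    spec: FixtureSpec,
    ontology: Ontology,
    parcellation: Parcellation,
    *,
    rng: np.random.Generator | None = None,
    injection_size: int = 4,
) -> list[InjectionRecord]:
    """One injection record per planted projection.

    The injection volume is a small voxel set inside the source region;
    the target image carries the projection weight (jittered a few
    percent) on the target region's voxels over uniform background noise
    drawn strictly below the detection threshold, so thresholding removes
    exactly the background.  A projection with weight 0 yields a
    background-only record.
    """
    from atlasfuse.atlas import region_voxels

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    shape = parcellation.space.shape
    records = []
    for proj in spec.projections:
        src = region_voxels(parcellation, ontology, proj.source)
        tgt = region_voxels(parcellation, ontology, proj.target)
        if len(src) == 0 or len(tgt) == 0:
            raise ValueError(f"projection regions {proj.source}->{proj.target} have no voxels")
        vol_lin = src.linear[: max(1, min(injection_size, len(src)))]
        volume = VOI(shape, vol_lin, provenance=f"injection:{proj.source}")
        image = rng.uniform(0.0, 0.99 * PROJECTION_THRESHOLD, size=shape)
        if proj.weight > 0:
            image.ravel()[tgt.linear] = proj.weight * rng.uniform(0.97, 1.03, size=len(tgt))
        site = volume.voxels.astype(float).mean(axis=0)
        records.append(InjectionRecord(site=site, volume=volume, image=image))
    if not records:
        raise ValueError("spec plants no projections")
    return records


@dataclass
class SpeciesBundle:
    """One species' synthetic atlas, annotated dataset and injection records."""

    ontology: Ontology
    parcellation: Parcellation
    dataset: ExpressionDataset
    records: list[InjectionRecord]
    source_region: int  # seed area of the planted projections
    consensus_regions: list[int]
    connectivity: pd.Series  # planted per-consensus-region projection weight
    truth: dict = field(default_factory=dict)


def make_species_pair(spec: FixtureSpec) -> tuple[SpeciesBundle, SpeciesBundle, HomologMap]:
    """Two-species fixture with shared consensus regions and a homolog map.

    Both species get a flat two-level atlas whose leaves are one seed
    (source) area plus ``spec.n_consensus_regions`` consensus regions, an
    expression dataset over excitatory/inhibitory cells, and injection
    records projecting from the seed area onto the consensus regions with
    planted per-region weights.

    Gene construction (homologs are paired by index):

    - the first ``spec.n_conserved`` genes are inhibitory-cell genes whose
      regional expression decreases monotonically with that species' own
      connectivity profile at effect ``spec.conserved_effect`` and without
      region-level pattern noise — planted conserved negative correlates;
    - the remaining inhibitory genes receive a species-independent random
      negative-shift effect ``~N(inhibitory_shift, inhibitory_shift/2)``
      plus region-level pattern noise, shifting their correlation
      distribution negative without pinning single genes to -1;
    - excitatory genes carry pattern noise only (correlations near 0).
    """
    if spec.n_consensus_regions < 3:
        raise ValueError("need at least 3 consensus regions")
    rng = np.random.default_rng(spec.seed)

    bundles = []
    for prefix in ("gA", "gB"):
        n_reg = spec.n_consensus_regions
        sub = FixtureSpec(
            seed=spec.seed,
            grid_shape=spec.grid_shape,
            depth=2,
            fanout=n_reg + 1,
            n_genes=spec.n_genes,
            n_samples=spec.n_samples,
            cell_types=("excitatory", "inhibitory"),
            noise_sd=spec.noise_sd,
            baseline_log_mean=spec.baseline_log_mean,
        )
        ont, parc = make_toy_atlas(sub)
        leaves = ont.leaves()
        source_region, consensus = leaves[0], leaves[1:]

        # planted connectivity: distinct, well-separated weights
        w = rng.permutation(np.linspace(0.1, 1.0, n_reg))
        ranks = pd.Series(w).rank().to_numpy()
        u = -(ranks - ranks.mean()) / ranks.std(ddof=0)  # high connectivity -> low u

        half = spec.n_genes // 2
        inhibitory_genes = np.arange(half)  # includes the planted conserved genes
        excitatory_genes = np.arange(half, spec.n_genes)

        # region effects on the log scale: genes x (source leaf + consensus)
        eff = np.zeros((spec.n_genes, n_reg + 1))
        beta = np.zeros(spec.n_genes)
        beta[inhibitory_genes] = rng.normal(
            spec.inhibitory_shift, spec.inhibitory_shift / 2, size=half
        ).clip(min=0.0)
        beta[: spec.n_conserved] = spec.conserved_effect
        eff[:, 1:] = beta[:, None] * u[None, :]
        noise = rng.normal(0.0, spec.pattern_noise, size=(spec.n_genes, n_reg))
        noise[: spec.n_conserved] = 0.0  # planted genes: clean monotone pattern
        eff[:, 1:] += noise

        # a gene's regional pattern lives in its own cell class, so that
        # cell-type-restricted queries see the planted correlation
        eff_inh = np.zeros_like(eff)
        eff_exc = np.zeros_like(eff)
        eff_inh[inhibitory_genes] = eff[inhibitory_genes]
        eff_exc[excitatory_genes] = eff[excitatory_genes]

        # planted genes are well-expressed, keeping their monotone regional
        # pattern clear of count-rounding at the low end
        baseline = rng.lognormal(mean=spec.baseline_log_mean, sigma=1.0, size=spec.n_genes)
        baseline[: spec.n_conserved] = np.exp(spec.conserved_baseline_log)

        ds = make_expression_dataset(
            sub,
            ont,
            parc,
            rng=rng,
            region_log_effects={"inhibitory": eff_inh, "excitatory": eff_exc},
            baseline=baseline,
            gene_prefix=prefix,
            name=f"synthetic-{prefix}",
        )
        # each gene class is enriched 4x in its own cell class
        ds = _apply_cell_class_enrichment(ds, inhibitory_genes, excitatory_genes)

        projections = tuple(
            Projection(source=source_region, target=int(c), weight=float(wi))
            for c, wi in zip(consensus, w)
        )
        rec_spec = FixtureSpec(
            seed=spec.seed,
            grid_shape=spec.grid_shape,
            depth=2,
            fanout=n_reg + 1,
            projections=projections,
        )
        records = make_connectome_records(rec_spec, ont, parc, rng=rng)

        bundles.append(
            SpeciesBundle(
                ontology=ont,
                parcellation=parc,
                dataset=ds,
                records=records,
                source_region=source_region,
                consensus_regions=list(consensus),
                connectivity=pd.Series(w, index=list(consensus)),
                truth={
                    "conserved_genes": _gene_ids(spec.n_genes, prefix)[: spec.n_conserved],
                    "inhibitory_genes": [_gene_ids(spec.n_genes, prefix)[g] for g in inhibitory_genes],
                    "excitatory_genes": [_gene_ids(spec.n_genes, prefix)[g] for g in excitatory_genes],
                },
            )
        )

    ids_a = _gene_ids(spec.n_genes, "gA")
    ids_b = _gene_ids(spec.n_genes, "gB")
    hmap = HomologMap(pd.DataFrame({"species_a": ids_a, "species_b": ids_b}))
    return bundles[0], bundles[1], hmap


def _apply_cell_class_enrichment(
    ds: ExpressionDataset,
    inhibitory_genes: np.ndarray,
    excitatory_genes: np.ndarray,
    fold: float = 4.0,
) -> ExpressionDataset:
    """Multiply each gene class up in its own cell class (marker enrichment)."""
    vals = ds.values.copy()
    inh_cols = ds.sample_meta["cell_type"] == "inhibitory"
    exc_cols = ~inh_cols
    vals.iloc[inhibitory_genes, inh_cols.to_numpy()] *= fold
    vals.iloc[excitatory_genes, exc_cols.to_numpy()] *= fold
    vals[:] = np.rint(vals.to_numpy())
    return ds.with_norm(vals, "raw")
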