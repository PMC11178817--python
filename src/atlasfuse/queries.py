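"""Volume-of-interest gene-expression queries.

Given an expression matrix M with genes G and samples S, a query is
parameterized by three sample subsets:

- ``V``: samples inside the VOI.  A region-annotated sample is in V when
  its annotation region's voxel set intersects the VOI (unweighted); a
  voxel-backed sample is in V when its voxel lies in the VOI.  Because
  membership is by intersection, querying any sub-region of the annotation
  level selects the same samples as querying the annotation level itself
  (hierarchical invariance).
- ``C``: samples of the chosen cell type(s).
- ``F``: samples passing all other metadata filters.

The four query scores per gene g are

- mean expression:        mean over V n C n F
- region specificity:     (mean over V n C n F) / (mean over C n F)
- cell-type specificity:  (mean over V n C n F) / (mean over V n F)
- enrichment:             (mean over V n C n F) / (mean over V)

Ratios with a zero denominator are undefined (NaN) and excluded from
ranking; scores are computed on whatever normalization state the dataset
carries — the query layer never re-normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from atlasfuse.atlas import Ontology, Parcellation, VOI, region_voxels
from atlasfuse.errors import FilterError
from atlasfuse.ingest import CELL_TYPE_COL, REGION_COL, VOXEL_COL, ExpressionDataset

__all__ = [
    "SampleSelection",
    "QueryResult",
    "select_samples",
    "mean_expression",
    "region_specificity",
    "cell_type_specificity",
    "enrichment",
    "gene_ranks",
    "coverage_table",
    "write_query_tsv",
]


@dataclass
class SampleSelection:
    """Sample subsets V (VOI), C (cell type) and F (metadata filters)."""

    V: pd.Index
    C: pd.Index
    F: pd.Index
    descriptor: dict = field(default_factory=dict)

    @property
    def selected(self) -> pd.Index:
        """V n C n F, in dataset sample order."""
        return self.V.intersection(self.C).intersection(self.F)

    def __len__(self) -> int:
        return len(self.selected)


@dataclass
class QueryResult:
    """Per-gene scores (NaN = undefined) with optional descending ranks."""

    scores: pd.Series
    ranks: pd.Series | None = None
    descriptor: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.scores.empty

    def defined(self) -> pd.Series:
        return self.scores.dropna()


def _empty_result(descriptor: dict) -> QueryResult:
    return QueryResult(scores=pd.Series(dtype=float), descriptor=descriptor)


def select_samples(
    ds: ExpressionDataset,
    voi: VOI,
    ontology: Ontology | None = None,
    parcellation: Parcellation | None = None,
    cell_types: Iterable[str] | None = None,
    meta: Mapping[str, Iterable] | None = None,
) -> SampleSelection:
    """Resolve the V, C and F sample subsets for one dataset and VOI.

    ``cell_types=None`` and ``meta=None`` mean "no filter" (all samples).
    Region-annotated datasets need the ontology and parcellation to map
    annotations to voxel sets.
    """
    if not ds.is_annotated:
        raise ValueError("dataset carries no region/voxel annotation; annotate first")
    samples = ds.samples

    if ds.is_voxel_backed:
        vox = ds.sample_meta[VOXEL_COL].to_numpy(dtype=np.int64)
        in_voi = np.isin(vox, voi.linear)
        V = samples[in_voi]
    else:
        if ontology is None or parcellation is None:
            raise ValueError("region-annotated dataset requires ontology and parcellation")
        region_ids = ds.sample_meta[REGION_COL]
        hit: dict[int, bool] = {}
        for rid in pd.unique(region_ids):
            hit[rid] = region_voxels(parcellation, ontology, int(rid)).intersects(voi)
        V = samples[region_ids.map(hit).to_numpy(dtype=bool)]

    if cell_types is None:
        C = samples
    else:
        if CELL_TYPE_COL not in ds.sample_meta.columns:
            raise FilterError(f"dataset has no {CELL_TYPE_COL!r} metadata")
        wanted = set(cell_types) if not isinstance(cell_types, str) else {cell_types}
        C = samples[ds.sample_meta[CELL_TYPE_COL].isin(wanted).to_numpy()]

    if meta is None:
        F = samples
    else:
        mask = np.ones(len(samples), dtype=bool)
        for attr, allowed in meta.items():
            if attr not in ds.sample_meta.columns:
                raise FilterError(f"unknown metadata attribute {attr!r}")
            allowed = {allowed} if isinstance(allowed, str) else set(allowed)
            mask &= ds.sample_meta[attr].isin(allowed).to_numpy()
        F = samples[mask]

    descriptor = {
        "dataset": ds.name,
        "voi": voi.provenance,
        "cell_types": sorted(wanted) if cell_types is not None else "all",
        "meta": {k: sorted({v} if isinstance(v, str) else set(v)) for k, v in meta.items()}
        if meta
        else "all",
    }
    return SampleSelection(V=V, C=C, F=F, descriptor=descriptor)


def _mean_over(ds: ExpressionDataset, cols: pd.Index) -> pd.Series:
    return ds.values[list(cols)].mean(axis=1)


def mean_expression(ds: ExpressionDataset, sel: SampleSelection) -> QueryResult:
    """Mean expression per gene over V n C n F."""
    desc = {**sel.descriptor, "query": "mean"}
    chosen = sel.selected
    if len(chosen) == 0:
        return _empty_result(desc)
    return QueryResult(scores=_mean_over(ds, chosen), descriptor=desc)


def _ratio_query(ds, sel, denom_cols: pd.Index, query_name: str) -> QueryResult:
    desc = {**sel.descriptor, "query": query_name}
    chosen = sel.selected
    if len(chosen) == 0 or len(denom_cols) == 0:
        return _empty_result(desc)
    num = _mean_over(ds, chosen)
    den = _mean_over(ds, denom_cols)
    scores = num / den.where(den != 0)  # zero denominator -> NaN (undefined)
    return QueryResult(scores=scores, descriptor=desc)


def region_specificity(ds: ExpressionDataset, sel: SampleSelection) -> QueryResult:
    """VOI mean normalized by the brain-wide mean over the same C n F."""
    return _ratio_query(ds, sel, sel.C.intersection(sel.F), "region-specificity")


def cell_type_specificity(ds: ExpressionDataset, sel: SampleSelection) -> QueryResult:
    """VOI mean for the chosen cell type normalized by all cell types in the VOI."""
    return _ratio_query(ds, sel, sel.V.intersection(sel.F), "celltype-specificity")


def enrichment(ds: ExpressionDataset, sel: SampleSelection) -> QueryResult:
    """VOI mean for the chosen filters normalized by all samples in the VOI."""
    return _ratio_query(ds, sel, sel.V, "enrichment")


QUERIES = {
    "mean": mean_expression,
    "region-specificity": region_specificity,
    "celltype-specificity": cell_type_specificity,
    "enrichment": enrichment,
}


def gene_ranks(res: QueryResult) -> QueryResult:
    """Attach descending ranks (1 = highest score, ties averaged).

    Genes with undefined scores are left unranked.
    """
    if res.defined().empty:
        return _empty_result(res.descriptor)
    ranks = res.scores.rank(ascending=False, method="average", na_option="keep")
    return QueryResult(scores=res.scores, ranks=ranks, descriptor=dict(res.descriptor))


def coverage_table(
    datasets: Sequence[ExpressionDataset],
    ont: Ontology,
    parc: Parcellation,
    regions: Sequence[int],
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Sample counts per (dataset, metadata subset) row and region column.

    Each cell counts the samples a VOI query on that region would select
    for that dataset subset.  The original region annotations contributing
    to each cell are recorded in ``result.attrs['sample_region_annotations']``
    keyed by (row, region) — the data-provenance view.
    """
    rows = []
    counts = {}
    annotations: dict[tuple, list] = {}
    region_vois = {r: region_voxels(parc, ont, int(r)) for r in regions}

    for ds in datasets:
        if group_by:
            missing = [a for a in group_by if a not in ds.sample_meta.columns]
            if missing:
                raise FilterError(f"dataset {ds.name!r} lacks attributes {missing}")
            groups = ds.sample_meta.groupby(list(group_by), observed=True).groups
            subsets = [
                ((ds.name,) + (key if isinstance(key, tuple) else (key,)), pd.Index(idx))
                for key, idx in groups.items()
            ]
        else:
            subsets = [((ds.name,), ds.samples)]

        for row_key, sample_ids in subsets:
            rows.append(row_key)
            sub = ds.subset_samples(sample_ids)
            for r, voi in region_vois.items():
                sel = select_samples(sub, voi, ontology=ont, parcellation=parc)
                chosen = sel.V
                counts[(row_key, r)] = len(chosen)
                if REGION_COL in sub.sample_meta.columns and len(chosen):
                    annotations[(row_key, r)] = sorted(
                        sub.sample_meta.loc[chosen, REGION_COL].unique().tolist()
                    )

    index = pd.MultiIndex.from_tuples(rows, names=["dataset"] + list(group_by))
    table = pd.DataFrame(0, index=index, columns=list(regions), dtype=int)
    for (row_key, r), n in counts.items():
        table.loc[row_key, r] = n
    table.attrs["sample_region_annotations"] = annotations
    return table


def regional_profile_table(
    ds: ExpressionDataset,
    regions: Sequence[int],
    ont: Ontology,
    parc: Parcellation,
    query: str = "mean",
    cell_types: Iterable[str] | None = None,
    meta: Mapping[str, Iterable] | None = None,
) -> pd.DataFrame:
    """Regions x genes table of query scores, one VOI query per region.

    This is the expression side of the expression-connectivity
    correlation workflow: each row holds the per-gene score (mean
    expression by default, or any of the other queries) for the VOI of
    one region.  Regions whose query comes back empty are filled with NaN.
    """
    if query not in QUERIES:
        raise ValueError(f"unknown query {query!r}; choose from {sorted(QUERIES)}")
    fn = QUERIES[query]
    rows = {}
    for r in regions:
        voi = region_voxels(parc, ont, int(r))
        sel = select_samples(ds, voi, ontology=ont, parcellation=parc, cell_types=cell_types, meta=meta)
        res = fn(ds, sel)
        rows[r] = res.scores if not res.empty else pd.Series(np.nan, index=ds.genes)
    table = pd.DataFrame(rows).T
    table.index.name = "region"
    return table


def write_query_tsv(res: QueryResult, path) -> None:
    """Write (gene, score, rank) as TSV with a ``#``-prefixed header block."""
    res = res if res.ranks is not None or res.empty else gene_ranks(res)
    with open(path, "w") as fh:
        for key, val in res.descriptor.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("gene_id\tscore\trank\n")
        ranks = res.ranks if res.ranks is not None else pd.Series(dtype=float)
        for gene, score in res.scores.items():
            rank = ranks.get(gene, np.nan)
            score_s = "NA" if pd.isna(score) else f"{score:.10g}"
            rank_s = "NA" if pd.isna(rank) else f"{rank:g}"
            fh.write(f"{gene}\t{score_s}\t{rank_s}\n")
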