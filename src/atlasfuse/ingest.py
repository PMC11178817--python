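"""Loading, QC filtering, normalization and ontology annotation of expression data.

An :class:`ExpressionDataset` is a genes x samples matrix with per-sample
metadata (cell type, age, phenotype, ...).  Samples are either physical
specimens annotated with a brain-region id, or — for imaging collections —
individual voxels (one sample per voxel), which lets one query code path
serve both data kinds.

Normalization follows the usual single-cell / bulk conventions: counts per
million (CPM) for count matrices, RPKM-to-TPM conversion for bulk data
distributed as RPKM, log2(x+1) for readability, and a scaled outlier-robust
sigmoid mapping microarray values to the unit interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from atlasfuse.atlas import Ontology
from atlasfuse.errors import StateError

__all__ = [
    "ExpressionDataset",
    "GeneReference",
    "qc_filter_cells",
    "normalize_cpm",
    "rpkm_to_tpm",
    "log2p1",
    "scaled_robust_sigmoid",
    "match_genes",
    "annotate_samples",
    "read_expression_tsv",
    "write_expression_tsv",
]

#: allowed normalization states, in the order they typically occur
NORM_STATES = ("raw", "rpkm", "cpm", "tpm", "log2p1", "sigmoid-unit")

REGION_COL = "region_id"
VOXEL_COL = "voxel"
CELL_TYPE_COL = "cell_type"


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    sample_meta
        DataFrame indexed by sample id; columns are metadata attributes
        (``cell_type``, ``age``, ``phenotype``, ...).  After annotation a
        ``region_id`` column holds the ontology id each sample maps to;
        voxel-backed datasets carry a ``voxel`` column of linear voxel
        indices instead.
    norm
        Normalization state, one of :data:`NORM_STATES`.
    name
        Dataset identifier used in query descriptors and coverage tables.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    norm: str = "raw"
    name: str = "dataset"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.norm not in NORM_STATES:
            raise StateError(f"unknown normalization state {self.norm!r}")
        if not self.values.columns.equals(self.sample_meta.index):
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample ids of matrix and metadata differ")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite entries")
        if self.norm != "log2p1" and vals.size and (vals < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    @property
    def is_voxel_backed(self) -> bool:
        return VOXEL_COL in self.sample_meta.columns

    @property
    def is_annotated(self) -> bool:
        return REGION_COL in self.sample_meta.columns or self.is_voxel_backed

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            sample_meta=self.sample_meta.loc[sample_ids],
            attrs=dict(self.attrs),
        )

    def with_norm(self, values: pd.DataFrame, norm: str) -> "ExpressionDataset":
        return replace(self, values=values, norm=norm, attrs=dict(self.attrs))


@dataclass
class GeneReference:
    """Canonical gene table mapping symbols / Ensembl / Entrez ids.

    ``table`` columns: ``symbol``, ``ensembl_id``, ``entrez_id``,
    ``canonical`` (unique canonical gene id).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"symbol", "ensembl_id", "entrez_id", "canonical"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gene reference missing columns {sorted(missing)}")
        if self.table["canonical"].duplicated().any():
            raise ValueError("canonical gene ids must be unique")

    @classmethod
    def from_tsv(cls, path) -> "GeneReference":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def lookup(self, gene_id: str) -> str | None:
        """Resolve one id to its canonical id; symbol > Ensembl > Entrez."""
        for col in ("symbol", "ensembl_id", "entrez_id"):
            hit = self.table.loc[self.table[col] == gene_id, "canonical"]
            if len(hit):
                return str(hit.iloc[0])
        return None


def _require_counts(ds: ExpressionDataset) -> np.ndarray:
    if ds.norm != "raw":
        raise StateError(f"operation requires raw counts, dataset is {ds.norm!r}")
    vals = ds.values.to_numpy()
    if not np.allclose(vals, np.rint(vals)):
        raise StateError("raw count matrix contains non-integer values")
    return vals


def qc_filter_cells(
    ds: ExpressionDataset,
    min_genes: int = 50,
    max_genes: int = 5000,
    mad_k: float = 5.0,
) -> ExpressionDataset:
    """Remove low-quality cells by unique-gene-count thresholds and a MAD rule.

    A sample's unique gene count is the number of genes with a nonzero
    count.  Samples below ``min_genes`` or above ``max_genes`` are dropped
    first (empty droplets / doublets); among the remainder, samples whose
    unique gene count deviates from the median by more than
    ``mad_k * MAD`` (median absolute deviation) are dropped as outliers.

    Removal counts are recorded in ``attrs['qc']`` of the result.
    """
    counts = _require_counts(ds)
    ugc = pd.Series((counts > 0).sum(axis=0), index=ds.samples)

    keep_range = (ugc >= min_genes) & (ugc <= max_genes)
    n_range_removed = int((~keep_range).sum())

    ugc_kept = ugc[keep_range]
    med = ugc_kept.median()
    mad = (ugc_kept - med).abs().median()
    keep_mad = (ugc_kept - med).abs() <= mad_k * mad
    n_mad_removed = int((~keep_mad).sum())

    kept = ugc_kept.index[keep_mad]
    out = ds.subset_samples(kept)
    out.attrs["qc"] = {
        "removed_gene_count_range": n_range_removed,
        "removed_mad_outliers": n_mad_removed,
        "retained": len(kept),
    }
    return out


def normalize_cpm(ds: ExpressionDataset) -> ExpressionDataset:
    """Rescale every sample (column) of a raw count matrix to sum 1e6."""
    _require_counts(ds)
    totals = ds.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s) {list(zero[:5])}; run QC first")
    return ds.with_norm(ds.values / totals * 1e6, "cpm")


def rpkm_to_tpm(ds: ExpressionDataset) -> ExpressionDataset:
    """Convert RPKM values to TPM: per sample, tpm = rpkm / sum(rpkm) * 1e6."""
    if ds.norm not in ("raw", "rpkm"):
        raise StateError(f"rpkm_to_tpm requires RPKM input, dataset is {ds.norm!r}")
    totals = ds.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s) {list(zero[:5])}")
    return ds.with_norm(ds.values / totals * 1e6, "tpm")


def log2p1(ds: ExpressionDataset) -> ExpressionDataset:
    """Apply log2(x + 1) entrywise (offset 1 accounts for zeros)."""
    vals = ds.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("log2p1 requires nonnegative values")
    return ds.with_norm(np.log2(ds.values + 1.0), "log2p1")


def scaled_robust_sigmoid(values) -> np.ndarray:
    """Outlier-robust sigmoid normalization rescaled to the unit interval.

    ``y = 1 / (1 + exp(-(x - median) / (IQR / 1.349)))`` followed by
    min-max rescaling to [0, 1].  The scale IQR/1.349 estimates the
    standard deviation consistently under normality, making the transform
    insensitive to extreme values.  A constant input (IQR = 0) yields an
    all-zero vector with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        warnings.warn("IQR is zero; returning constant 0 vector", stacklevel=2)
        return np.zeros_like(x)
    from scipy.special import expit

    y = expit((x - med) / (iqr / 1.349))
    return (y - y.min()) / (y.max() - y.min())


def sigmoid_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Apply :func:`scaled_robust_sigmoid` to every gene row."""
    vals = np.apply_along_axis(scaled_robust_sigmoid, 1, ds.values.to_numpy())
    return ds.with_norm(pd.DataFrame(vals, index=ds.genes, columns=ds.samples), "sigmoid-unit")


def match_genes(ds: ExpressionDataset, ref: GeneReference) -> ExpressionDataset:
    """Map dataset gene ids to canonical ids; drop unmatched, collapse duplicates.

    Ids are resolved with precedence symbol > Ensembl > Entrez.  When two
    dataset rows resolve to the same canonical gene, the row with the
    larger total signal is kept (avoids double-counting in CPM).  The match
    count is recorded in ``attrs['gene_matching']``.
    """
    mapping: dict[str, str] = {}
    for col in ("entrez_id", "ensembl_id", "symbol"):  # later cols override: symbol wins
        sub = ref.table.dropna(subset=[col])
        mapping.update(dict(zip(sub[col], sub["canonical"])))

    canonical = ds.genes.map(lambda g: mapping.get(str(g)))
    matched = canonical.notna()
    vals = ds.values.loc[matched].copy()
    vals.index = pd.Index(canonical[matched], name="gene")

    if vals.index.duplicated().any():
        totals = vals.sum(axis=1)
        order = np.argsort(-totals.to_numpy(), kind="stable")
        vals = vals.iloc[order]
        vals = vals[~vals.index.duplicated(keep="first")]

    n_matched = int(vals.shape[0])
    if n_matched == 0:
        warnings.warn("no genes matched the reference", stacklevel=2)
    out = replace(ds, values=vals.sort_index(), attrs=dict(ds.attrs))
    out.attrs["gene_matching"] = {
        "input_genes": ds.n_genes,
        "matched_genes": n_matched,
        "dropped_unmatched": int((~matched).sum()),
    }
    return out


def annotate_samples(
    ds: ExpressionDataset,
    ont: Ontology,
    mapping: dict[str, int] | pd.Series,
    region_attr: str = "region",
) -> ExpressionDataset:
    """Attach ontology region ids to samples via a region-name mapping.

    Samples whose ``region_attr`` metadata value has no entry in
    ``mapping`` are removed (and counted in ``attrs['annotation']``), the
    behaviour used for cells that cannot be matched to any brain region.
    """
    if isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    for name, rid in mapping.items():
        if int(rid) not in ont:
            raise ValueError(f"mapping target {rid} for {name!r} not in ontology")
    if region_attr not in ds.sample_meta.columns:
        raise ValueError(f"samples carry no {region_attr!r} metadata")

    region_ids = ds.sample_meta[region_attr].map(lambda r: mapping.get(r))
    keep = region_ids.notna()
    out = ds.subset_samples(ds.samples[keep])
    out.sample_meta = out.sample_meta.copy()
    out.sample_meta[REGION_COL] = region_ids[keep].astype(int)
    out.attrs["annotation"] = {
        "mapped": int(keep.sum()),
        "removed_unmapped": int((~keep).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# Text interfaces

def read_expression_tsv(matrix_path, meta_path=None, *, name="dataset", norm="raw", sep="\t") -> ExpressionDataset:
    """Read a genes x samples matrix (first column gene ids, header sample ids)
    and an optional sample metadata table (first column sample ids)."""
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep, index_col=0)
    else:
        meta = pd.DataFrame(index=values.columns)
    return ExpressionDataset(values=values, sample_meta=meta, norm=norm, name=name)


def write_expression_tsv(ds: ExpressionDataset, matrix_path, meta_path=None, sep="\t") -> None:
    ds.values.to_csv(matrix_path, sep=sep)
    if meta_path is not None:
        ds.sample_meta.to_csv(meta_path, sep=sep)
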