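"""Cross-species expression-connectivity correlation statistics.

The workflow correlates, per gene, its regional expression profile (from
the VOI query layer: mean expression or cell-type specificity per
consensus region) against a regional connectivity profile (source or
target strength of a seed area), yielding one Spearman coefficient per
gene.  Downstream statistics:

- extreme-gene selection: top and bottom quantile (default 1%) of genes
  by coefficient;
- cross-species overlap: genes whose homolog falls in the corresponding
  extreme set of the other species — candidate conserved connectivity
  correlates;
- distribution-shift test: two-sample Kolmogorov-Smirnov between the
  coefficient distributions of two gene groups (e.g. genes expressed in
  excitatory vs inhibitory cell types);
- direction test: one-sample t-test of a coefficient sample against zero
  (chance level);
- inter-dataset concordance: Spearman correlation of per-cell-type mean
  expression vectors across shared genes between two datasets, with a
  one-sided rank-sum test that matched cell-type pairs correlate higher
  than unmatched pairs.

Per-gene correlations use average ranks on ties; gene-level p-values are
deliberately not computed — selection is by coefficient quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from atlasfuse.errors import AlignmentError

__all__ = [
    "CorrelationProfile",
    "HomologMap",
    "gene_connectivity_correlation",
    "extreme_genes",
    "overlap_conserved",
    "correlation_shift_test",
    "homolog_direction_test",
    "dataset_concordance",
]


@dataclass
class CorrelationProfile:
    """Per-gene Spearman coefficients against one connectivity profile."""

    coefficients: pd.Series  # index: gene id; NaN = undefined (constant input)
    n_regions: int
    kind: str = ""  # e.g. 'SC-source', 'FC-target'
    filters: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.coefficients.dropna()
        if len(vals) and ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("Spearman coefficients must lie in [-1, 1]")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions for a correlation profile")

    def defined(self) -> pd.Series:
        return self.coefficients.dropna()


@dataclass
class HomologMap:
    """Unique gene-id pairs between two species."""

    pairs: pd.DataFrame  # columns: species_a, species_b

    def __post_init__(self):
        if list(self.pairs.columns) != ["species_a", "species_b"]:
            self.pairs = self.pairs.set_axis(["species_a", "species_b"], axis=1)
        if self.pairs.duplicated().any():
            self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "HomologMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["species_a"], self.pairs["species_b"]))

    def __len__(self) -> int:
        return len(self.pairs)


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis, method="average")


def gene_connectivity_correlation(
    expr: pd.DataFrame,
    conn: pd.Series,
    kind: str = "",
    filters: dict | None = None,
) -> CorrelationProfile:
    """Spearman correlation per gene between regional expression and connectivity.

    Parameters
    ----------
    expr
        Regions x genes table of per-region expression scores (mean
        expression or specificity from the query layer).
    conn
        Per-region connectivity strength, indexed like ``expr`` rows.

    Genes (or a connectivity profile) constant across regions have an
    undefined coefficient (NaN).
    """
    if not expr.index.equals(conn.index):
        if set(expr.index) != set(conn.index):
            raise AlignmentError("expression and connectivity cover different regions")
        conn = conn.loc[expr.index]
    n = len(expr.index)
    if n < 3:
        raise AlignmentError(f"need >= 3 regions, got {n}")

    x = expr.to_numpy(dtype=float)
    y = conn.to_numpy(dtype=float)
    rx = _rank(x, axis=0)
    ry = _rank(y)
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=0) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (rx_c * ry_c[:, None]).sum(axis=0) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(
        coefficients=pd.Series(r, index=expr.columns),
        n_regions=n,
        kind=kind,
        filters=dict(filters or {}),
    )


def extreme_genes(prof: CorrelationProfile, q: float = 0.01) -> tuple[list, list]:
    """Top and bottom ``q`` fraction of genes by coefficient.

    Returns ``(top, bottom)``, each of size ``ceil(q * n_defined)``,
    disjoint by construction.  Ties at the cutoff are broken by gene-id
    order for determinism.
    """
    if not (0 < q < 0.5):
        raise ValueError(f"q must be in (0, 0.5), got {q}")
    defined = prof.defined()
    n = len(defined)
    if n < int(np.ceil(1 / q)):
        raise ValueError(f"need at least {int(np.ceil(1 / q))} defined genes, got {n}")
    k = int(np.ceil(q * n))
    # sort by coefficient, ties by gene id
    frame = defined.rename("r").rename_axis("gene").reset_index()
    top = frame.sort_values(["r", "gene"], ascending=[False, True])["gene"].head(k).tolist()
    bottom = frame.sort_values(["r", "gene"], ascending=[True, True])["gene"].head(k).tolist()
    if set(top) & set(bottom):
        raise ValueError("top and bottom sets overlap; too few distinct coefficients")
    return top, bottom


def overlap_conserved(
    sets_a: tuple[list, list],
    sets_b: tuple[list, list],
    hmap: HomologMap,
) -> dict[str, list]:
    """Genes (species-A ids) whose homolog is in the matching extreme set of B.

    Returns ``{'top': [...], 'bottom': [...]}``.
    """
    if len(hmap) == 0:
        warnings.warn("empty homolog map; overlap is empty", stacklevel=2)
        return {"top": [], "bottom": []}
    a2b = hmap.a_to_b()
    top_a, bottom_a = sets_a
    top_b, bottom_b = (set(sets_b[0]), set(sets_b[1]))
    return {
        "top": sorted(g for g in top_a if a2b.get(g) in top_b),
        "bottom": sorted(g for g in bottom_a if a2b.get(g) in bottom_b),
    }


def correlation_shift_test(r_group_a, r_group_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between coefficient distributions."""
    a = np.asarray(r_group_a, dtype=float)
    b = np.asarray(r_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 coefficients")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def homolog_direction_test(r_values) -> tuple[float, float]:
    """One-sample t-test of the mean coefficient against zero (chance level)."""
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 coefficients")
    if np.ptp(r) == 0:
        raise ValueError("zero-variance sample")
    res = stats.ttest_1samp(r, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def dataset_concordance(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    matched_groups: list[tuple[str, str]],
) -> tuple[pd.DataFrame, float]:
    """Inter-dataset rank concordance of per-group mean expression.

    Parameters
    ----------
    means_a, means_b
        Genes x groups tables of mean expression per cell-type group,
        on a shared (homolog-matched) gene index.
    matched_groups
        Pairs ``(group_in_a, group_in_b)`` annotating which cell types
        correspond across datasets.

    Returns the groups_a x groups_b Spearman correlation matrix over all
    shared genes, and the one-sided Wilcoxon rank-sum p-value testing that
    matched-pair correlations exceed unmatched-pair correlations.
    """
    shared = means_a.index.intersection(means_b.index)
    if len(shared) < 3:
        raise AlignmentError(f"need >= 3 shared genes, got {len(shared)}")
    a = means_a.loc[shared]
    b = means_b.loc[shared]
    ra = _rank(a.to_numpy(dtype=float), axis=0)
    rb = _rank(b.to_numpy(dtype=float), axis=0)
    ra_c = ra - ra.mean(axis=0)
    rb_c = rb - rb.mean(axis=0)
    denom = np.sqrt(np.outer((ra_c**2).sum(axis=0), (rb_c**2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, ra_c.T @ rb_c / denom, np.nan)
    matrix = pd.DataFrame(corr, index=a.columns, columns=b.columns)

    matched = set(matched_groups)
    matched_vals, unmatched_vals = [], []
    for ga in matrix.index:
        for gb in matrix.columns:
            v = matrix.loc[ga, gb]
            if np.isnan(v):
                continue
            (matched_vals if (ga, gb) in matched else unmatched_vals).append(v)
    if matched_vals and unmatched_vals:
        p = float(
            stats.mannwhitneyu(matched_vals, unmatched_vals, alternative="greater").pvalue
        )
    else:
        p = float("nan")
    return matrix, p
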