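"""Per-cell heteroplasmy, QC, expression correlation, and threshold scan.

Heteroplasmy of a cell at a genotyped locus is the fraction of reads
carrying the alternate allele, ``alt / (alt + ref)``. Cells are retained
for analysis when their transcriptome passes feature-count and
mitochondrial-fraction QC and the locus has enough — but not implausibly
many — reads (strictly more than 25 and fewer than 250 by default).

The dosage analysis ranks genes by the Spearman correlation between their
expression and heteroplasmy across cells that express them, Fisher
Z-transforms the coefficients (``atanh``), and optionally re-estimates the
primary-locus effect by ordinary least squares while controlling for
off-target/background variant heteroplasmies. The threshold scan splits
cells at each 10%-increment heteroplasmy threshold, correlates expression
with heteroplasmy separately above and below the split, and reports the
absolute difference of the Fisher-Z coefficients per gene and bin; the bin
with the largest median delta localizes the dosage at which the
transcriptional phenotype switches on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

FISHER_Z_CAP = 1.0 - 1e-12


class ZeroCoverageError(ValueError):
    """Heteroplasmy is undefined at a locus with no reads."""


def compute_heteroplasmy(alt, ref):
    """Per-cell heteroplasmy ``alt / (alt + ref)``; requires coverage > 0."""
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("read counts must be non-negative")
    cov = alt + ref
    if np.any(cov == 0):
        raise ZeroCoverageError("zero coverage: heteroplasmy undefined")
    out = alt / cov
    return float(out) if out.ndim == 0 else out


def locus_table(allele_counts: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Rows of the long allele-count table for one locus, indexed by cell."""
    t = allele_counts.loc[allele_counts["locus"] == locus]
    if t.empty:
        raise KeyError(f"locus {locus!r} absent from allele-count table")
    return t.set_index("cell_id")


def qc_filter_cells(
    obs: pd.DataFrame,
    allele_counts: pd.DataFrame,
    locus: str,
    min_features: int = 1000,
    max_features: int = 7000,
    max_pct_mito: float = 5.0,
    min_coverage: int = 25,
    max_coverage: int = 250,
) -> pd.Index:
    """Cell IDs passing transcriptome and locus-coverage QC.

    Feature bounds are inclusive (cells with *fewer than* ``min_features``
    or *greater than* ``max_features`` features are removed, so the bounds
    themselves survive); the coverage window is strict
    (``min_coverage < alt + ref < max_coverage``). ``obs`` needs columns
    ``n_features`` and ``pct_mito`` indexed by cell ID.
    """
    lt = locus_table(allele_counts, locus)
    cov = (lt["alt"] + lt["ref"]).reindex(obs.index).fillna(0)
    keep = (
        (obs["n_features"] >= min_features)
        & (obs["n_features"] <= max_features)
        & (obs["pct_mito"] <= max_pct_mito)
        & (cov > min_coverage)
        & (cov < max_coverage)
    )
    return obs.index[keep]


def cell_heteroplasmy(allele_counts: pd.DataFrame, locus: str, cells) -> pd.Series:
    """Heteroplasmy per cell at ``locus`` for the given (QC-passed) cells."""
    lt = locus_table(allele_counts, locus).loc[list(cells)]
    return pd.Series(
        compute_heteroplasmy(lt["alt"].to_numpy(), lt["ref"].to_numpy()),
        index=lt.index,
        name=locus,
    )


def fisher_z(rho) -> float | np.ndarray:
    """Fisher Z-transform ``atanh(rho)``; |rho| = 1 is capped to keep it finite."""
    r = np.clip(np.asarray(rho, dtype=float), -FISHER_Z_CAP, FISHER_Z_CAP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _expression_vector(adata, gene: str) -> np.ndarray:
    col = adata[:, gene].X
    return np.asarray(
        col.todense() if sparse.issparse(col) else col, dtype=float
    ).ravel()


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    n_cells_used: int
    rho: float
    fisher_z: float
    p: float


def gene_het_correlation(
    adata,
    het: pd.Series,
    gene: str,
    min_cells: int = 50,
) -> CorrelationResult | None:
    """Spearman correlation of a gene's expression with heteroplasmy.

    Only cells with nonzero expression of the gene enter; the gene is
    skipped (None) unless strictly more than ``min_cells`` such cells exist
    or if either vector is constant. Ties are handled by mid-ranks; the
    p-value uses the t approximation for n > 30 and exact permutation
    below.
    """
    cells = het.index.intersection(adata.obs_names)
    expr = pd.Series(_expression_vector(adata[cells], gene), index=cells)
    nz = expr.index[expr > 0]
    if len(nz) <= min_cells:
        return None
    e = expr.loc[nz].to_numpy()
    hh = het.loc[nz].to_numpy()
    if np.all(e == e[0]) or np.all(hh == hh[0]):
        return None
    res = stats.spearmanr(hh, e, alternative="two-sided")
    if len(nz) <= 30:
        perm = stats.permutation_test(
            (hh,),
            lambda x: stats.spearmanr(x, e).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=np.random.default_rng(0),
        )
        p = float(perm.pvalue)
    else:
        p = float(res.pvalue)
    rho = float(res.statistic)
    return CorrelationResult(gene, int(len(nz)), rho, fisher_z(rho), p)


def correlate_all_genes(
    adata, het: pd.Series, min_cells: int = 50
) -> pd.DataFrame:
    """Heteroplasmy-expression correlation for every gene; ranked by Fisher Z.

    Rank 1 is the most negative Z (the strongest decline with heteroplasmy).
    Genes skipped for insufficient expressing cells are absent.
    """
    rows = []
    for gene in adata.var_names:
        r = gene_het_correlation(adata, het, gene, min_cells=min_cells)
        if r is not None:
            rows.append(r.__dict__)
    out = pd.DataFrame(
        rows, columns=["gene", "n_cells_used", "rho", "fisher_z", "p"]
    )
    if len(out):
        out = out.sort_values(
            ["fisher_z", "gene"], kind="mergesort"
        ).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    else:
        out["rank"] = pd.Series(dtype=int)
    return out


def covariate_regression(
    adata,
    gene: str,
    het: pd.Series,
    covariates: pd.DataFrame,
) -> tuple[float, float]:
    """OLS of expression on primary-locus heteroplasmy plus covariate loci.

    ``covariates`` holds one column per additional locus (e.g. off-target
    edits and background variants), aligned on cell ID. Returns the
    primary-locus coefficient and its t-test p-value. Constant covariate
    columns cannot confound and are dropped (so all-zero covariates reduce
    the fit to the simple regression slope); a design left rank-deficient
    by genuinely collinear columns raises with their names.
    """
    cells = het.index.intersection(covariates.index).intersection(adata.obs_names)
    y = pd.Series(_expression_vector(adata[cells], gene), index=cells)
    if het.loc[cells].nunique() <= 1:
        raise ValueError("primary-locus heteroplasmy is constant across cells")
    cov = covariates.loc[cells]
    cov = cov.loc[:, cov.nunique() > 1]
    X = pd.concat([het.loc[cells].rename("primary"), cov], axis=1)
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        collinear = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(
            f"design matrix is rank deficient (collinear: {collinear})"
        )
    fit = sm.OLS(y.to_numpy(), Xc.to_numpy()).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def export_ranked_list(results: pd.DataFrame) -> pd.DataFrame:
    """(gene, fisher_z) table in decreasing Z order, ties broken by gene name.

    The format expected by preranked gene-set enrichment tools.
    """
    out = results[["gene", "fisher_z"]].copy()
    out["_neg"] = -out["fisher_z"]
    out = out.sort_values(["_neg", "gene"], kind="mergesort").drop(columns="_neg")
    return out.reset_index(drop=True)


DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass
class ThresholdScan:
    """Result of the heteroplasmy threshold scan.

    ``per_gene`` has one row per (threshold, gene) with the upper/lower
    Fisher-Z coefficients and their absolute delta; ``aggregate`` has the
    median delta and eligible-gene count per threshold (NaN where no gene
    was eligible); ``argmax`` is the threshold with the largest median
    delta, or None when every bin is empty.
    """

    per_gene: pd.DataFrame
    aggregate: pd.DataFrame
    argmax: float | None


def threshold_scan(
    adata,
    het: pd.Series,
    thresholds=DEFAULT_THRESHOLDS,
    min_cells: int = 100,
    upper_inclusive: bool = False,
) -> ThresholdScan:
    """Scan heteroplasmy thresholds for the largest expression-correlation shift.

    For each threshold ``t`` the cells split into lower (``h <= t``) and
    upper (``h > t``) groups (set ``upper_inclusive`` to move the boundary
    cell to the upper group). For every gene with at least ``min_cells``
    nonzero-expression cells on *each* side, Spearman correlations between
    expression and heteroplasmy are computed per side, Fisher Z-transformed,
    and their absolute difference recorded. Deltas are always >= 0.
    """
    cells = het.index.intersection(adata.obs_names)
    sub = adata[cells]
    h = het.loc[cells].to_numpy()
    X = sub.X
    X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
    genes = list(sub.var_names)

    rows = []
    for t in thresholds:
        upper = h >= t if upper_inclusive else h > t
        lower = ~upper
        for j, gene in enumerate(genes):
            e = X[:, j]
            nz = e > 0
            lo, up = lower & nz, upper & nz
            if lo.sum() < min_cells or up.sum() < min_cells:
                continue
            r_lo = stats.spearmanr(h[lo], e[lo]).statistic
            r_up = stats.spearmanr(h[up], e[up]).statistic
            if np.isnan(r_lo) or np.isnan(r_up):
                continue
            z_lo, z_up = fisher_z(r_lo), fisher_z(r_up)
            rows.append(
                {
                    "threshold": float(t),
                    "gene": gene,
                    "n_lower": int(lo.sum()),
                    "n_upper": int(up.sum()),
                    "z_lower": z_lo,
                    "z_upper": z_up,
                    "delta": abs(z_up - z_lo),
                }
            )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "threshold", "gene", "n_lower", "n_upper", "z_lower", "z_upper", "delta",
        ],
    )
    agg_rows = []
    for t in thresholds:
        d = per_gene.loc[per_gene["threshold"] == float(t), "delta"]
        agg_rows.append(
            {
                "threshold": float(t),
                "n_genes": int(len(d)),
                "median_delta": float(d.median()) if len(d) else np.nan,
            }
        )
    aggregate = pd.DataFrame(agg_rows)
    if aggregate["median_delta"].notna().any():
        argmax = float(
            aggregate.loc[aggregate["median_delta"].idxmax(), "threshold"]
        )
    else:
        argmax = None
    return ThresholdScan(per_gene=per_gene, aggregate=aggregate, argmax=argmax)
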