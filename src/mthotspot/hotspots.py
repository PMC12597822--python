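"""Trinucleotide-context mutability model and binomial recurrence test.

The recurrence statistic asks, for each mtDNA position, whether the number
of independent tumors mutated there exceeds what the gene's background
mutability predicts. The background is a 64-class trinucleotide-context
model fitted from the cohort itself:

* ``mu_context`` — fraction of all somatic SNVs (outside the control region
  and the blacklist) whose position carries a given reference 3-mer;
* ``mu_pos`` — the mutability of a position's own context;
* ``mu_gene`` — the sum of ``mu_pos`` over a gene's positions with nonzero
  mutability;
* ``P_pos,gene = mu_pos / mu_gene`` — the chance that a mutation landing in
  the gene lands on this particular position.

A position with ``x`` mutated tumors out of ``n`` total mutation events in
its gene is then scored with the one-sided binomial upper tail
``P(X >= x), X ~ Binomial(n, P_pos,gene)``, and q-values are produced by
Benjamini–Hochberg adjustment across the whole testing family. Hotspots
are units with ``q < 0.05``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import CONTEXTS, MtReference

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.05


class ModelFitError(ValueError):
    """Raised when no usable SNVs remain to fit the mutability model."""


@dataclass
class MutabilityModel:
    """Fitted per-context mutability and its per-position / per-gene sums."""

    mu_context: dict[str, float]
    mu_pos: np.ndarray  # length L; mutability of each position's context
    mu_gene: dict[str, float]
    total_snvs: int

    def position_mu(self, pos: int) -> float:
        return float(self.mu_pos[pos - 1])

    def as_frame(self) -> pd.DataFrame:
        """Audit dump of the 64-context table."""
        return pd.DataFrame(
            {"context": CONTEXTS, "mu": [self.mu_context[c] for c in CONTEXTS]}
        )


def _snv_events(calls: pd.DataFrame, ref: MtReference) -> pd.DataFrame:
    """SNV rows outside control/blacklist, one event per (sample, pos, alt)."""
    df = calls
    if "type" in df.columns:
        df = df[df["type"] == "SNV"]
    pos = df["pos"].to_numpy(dtype=np.int64)
    keep = ~ref.excluded_mask()[pos - 1]
    df = df.loc[keep]
    return df.drop_duplicates(subset=["sample_id", "pos", "alt"])


def fit_mutability(calls: pd.DataFrame, ref: MtReference) -> MutabilityModel:
    """Fit the 64-context mutability model from filtered somatic SNVs.

    Control-region and blacklisted positions are removed before tabulation.
    ``mu_context`` is (number of SNVs in that context) / (total SNVs);
    the 64 values sum to 1.
    """
    events = _snv_events(calls, ref)
    total = len(events)
    if total == 0:
        raise ModelFitError("no SNVs outside control/blacklisted regions")
    ctx_codes = ref.context_codes[events["pos"].to_numpy(dtype=np.int64) - 1]
    counts = np.bincount(ctx_codes, minlength=64)
    mu = counts / total
    mu_context = {c: float(mu[i]) for i, c in enumerate(CONTEXTS)}
    mu_pos = mu[ref.context_codes]
    # Genes accumulate mutability only over positions that can mutate under
    # the fitted model (nonzero-mu contexts) and that are testable at all
    # (outside control region / blacklist).
    usable = ~ref.excluded_mask()
    mu_gene: dict[str, float] = {}
    for g in ref.genes:
        p = g.positions(ref.length) - 1
        p = p[usable[p]]
        mu_gene[g.name] = float(mu_pos[p].sum())
    return MutabilityModel(
        mu_context=mu_context, mu_pos=mu_pos, mu_gene=mu_gene, total_snvs=total
    )


def position_probability(
    model: MutabilityModel, pos: int, gene: str
) -> float | None:
    """``P_pos,gene = mu_pos / mu_gene``; None marks an untestable position.

    Positions whose context never mutated (``mu_pos = 0``) cannot enter the
    binomial test family and are flagged with None.
    """
    mg = model.mu_gene.get(gene)
    if mg is None:
        raise KeyError(f"unknown gene {gene!r}")
    if mg <= 0:
        raise ValueError(f"gene {gene!r} has zero total mutability")
    mp = model.position_mu(pos)
    if mp == 0:
        return None
    return mp / mg


def binomial_upper_tail(x, n, p):
    """One-sided binomial p-value ``P(X >= x)`` for ``X ~ Binomial(n, p)``.

    Computed through the regularized incomplete beta function (survival
    function), which is numerically exact for any cohort-scale ``n``.
    Accepts scalars or arrays.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("require 0 < p <= 1")
    out = stats.binom.sf(x - 1, n, p)
    if out.ndim == 0:
        return float(out)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_hotspots(
    calls: pd.DataFrame,
    ref: MtReference,
    mode: str = "position",
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    model: MutabilityModel | None = None,
) -> pd.DataFrame:
    """Score recurrence at every testable unit and flag hotspots.

    Parameters
    ----------
    calls
        Filtered somatic calls (see :func:`mthotspot.filtering.filter_somatic`).
    mode
        ``"position"`` (default): the unit is a genomic position; the testing
        family is every position with nonzero context mutability inside a
        gene, including positions never observed mutated (their p-value is 1).
        ``"allele"``: the unit is an observed (position, alt) pair, matching
        a per-mutant-allele reading of the testing family.
    model
        Optionally a pre-fitted :class:`MutabilityModel`; fitted from
        ``calls`` when omitted.

    Returns
    -------
    DataFrame with columns ``pos`` (, ``alt``), ``gene``, ``x`` (tumors
    mutated at the unit), ``n`` (tumor-deduplicated mutation events in the
    gene), ``p_pos``
    (binomial success probability), ``p_binom``, ``q``, ``is_hotspot``.
    Control-region and blacklisted positions never appear.
    """
    if mode not in ("position", "allele"):
        raise ValueError("mode must be 'position' or 'allele'")
    model = model if model is not None else fit_mutability(calls, ref)
    events = _snv_events(calls, ref)

    gene_idx = ref.gene_index_array
    usable = ~ref.excluded_mask()
    gene_names = np.array([g.name for g in ref.genes])

    ev_pos = events["pos"].to_numpy(dtype=np.int64)
    ev_gene = gene_idx[ev_pos - 1]
    genic = ev_gene >= 0
    orphans = (model.mu_pos[ev_pos - 1] == 0) & genic
    if orphans.any():
        logger.warning(
            "%d observed mutation events at zero-mutability positions are "
            "excluded from the testing family",
            int(orphans.sum()),
        )
    events = events.loc[genic & ~orphans]
    ev_pos = events["pos"].to_numpy(dtype=np.int64)
    ev_gene = gene_idx[ev_pos - 1]

    # Recurrence means independent patients: a (tumor, position) pair
    # contributes at most 1 to x and at most 1 to n.
    uniq = events.drop_duplicates(subset=["sample_id", "pos"])
    n_gene = np.bincount(
        gene_idx[uniq["pos"].to_numpy(dtype=np.int64) - 1], minlength=len(ref.genes)
    )

    if mode == "position":
        # Family: every usable genic position with nonzero mu in a gene with
        # events and nonzero total mutability.
        fam_mask = usable & (gene_idx >= 0) & (model.mu_pos > 0)
        fam_pos = np.flatnonzero(fam_mask) + 1
        fam_gene = gene_idx[fam_pos - 1]
        mu_g = np.array([model.mu_gene[g.name] for g in ref.genes])
        fam_keep = (n_gene[fam_gene] > 0) & (mu_g[fam_gene] > 0)
        fam_pos, fam_gene = fam_pos[fam_keep], fam_gene[fam_keep]

        # x: distinct tumors mutated at the position.
        x_by_pos = np.bincount(
            uniq["pos"].to_numpy(dtype=np.int64) - 1, minlength=ref.length
        )
        x = x_by_pos[fam_pos - 1]
        res = pd.DataFrame(
            {
                "pos": fam_pos,
                "gene": gene_names[fam_gene],
                "x": x,
                "n": n_gene[fam_gene],
                "p_pos": model.mu_pos[fam_pos - 1] / mu_g[fam_gene],
            }
        )
    else:
        grouped = (
            events.groupby(["pos", "alt"])["sample_id"].nunique().reset_index()
        )
        a_pos = grouped["pos"].to_numpy(dtype=np.int64)
        a_gene = gene_idx[a_pos - 1]
        mu_g = np.array([model.mu_gene[g.name] for g in ref.genes])
        res = pd.DataFrame(
            {
                "pos": a_pos,
                "alt": grouped["alt"].to_numpy(),
                "gene": gene_names[a_gene],
                "x": grouped["sample_id"].to_numpy(),
                "n": n_gene[a_gene],
                "p_pos": model.mu_pos[a_pos - 1] / mu_g[a_gene],
            }
        )

    res["p_binom"] = binomial_upper_tail(
        res["x"].to_numpy(), res["n"].to_numpy(), res["p_pos"].to_numpy()
    )
    res["q"] = bh_adjust(res["p_binom"].to_numpy())
    res["is_hotspot"] = res["q"] < q_threshold
    return res.sort_values(["q", "pos"], kind="mergesort").reset_index(drop=True)
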