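"""Germline constraint, enrichment statistics, and co-occurrence tests.

A position is *germline constrained* when fewer than 2 of the surveyed
individuals (196,554 in the emulated population database) carry a
homoplasmic polymorphism there; positions absent from the carrier table
implicitly have count 0. Enrichment of hotspot positions among constrained
or Watson-Crick-paired sites uses the two-sided Fisher exact test;
conservation-rate shifts use the Wilcoxon rank-sum test; tissue enrichment
uses a two-sided binomial test; and mtDNA/nuclear-driver co-occurrence uses
a chi-squared test per cancer type with a 5% prevalence floor. Two-sided
binomial and Fisher p-values use the minimum-likelihood definition of
two-sidedness (sum of outcomes no more likely than the observed one),
matching the reference statistical environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hotspots import bh_adjust
from .reference import MtReference

DEFAULT_TOTAL_INDIVIDUALS = 196_554
STRUCTURE_CLASSES = ("WC", "non-WC", "loop-or-other")


@dataclass
class GermlineTable:
    """Sparse map of position -> homoplasmic carrier count.

    Absent positions read as 0 carriers (positions never reported as
    homoplasmically polymorphic).
    """

    carriers: Mapping[int, int]
    total_individuals: int = DEFAULT_TOTAL_INDIVIDUALS

    def count(self, pos: int) -> int:
        return int(self.carriers.get(pos, 0))

    def is_constrained(self, pos: int) -> bool:
        """Fewer than 2 homoplasmic carriers (the count criterion)."""
        return self.count(pos) < 2


def is_germline_constrained(table: GermlineTable, pos: int) -> bool:
    return table.is_constrained(pos)


@dataclass(frozen=True)
class Fisher2x2Result:
    odds_ratio: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_2x2(a: int, b: int, c: int, d: int) -> Fisher2x2Result:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The odds ratio is the cross-product ``ad/bc`` (``inf`` when ``bc = 0``
    with ``ad > 0``; ``nan`` when both products vanish); the p-value sums
    hypergeometric tables with probability <= that of the observed table.
    """
    cells = [a, b, c, d]
    if any(v < 0 for v in cells):
        raise ValueError("cell counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsr = np.float64(a) * d / (np.float64(b) * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return Fisher2x2Result(float(oddsr), float(p), ((a, b), (c, d)))


def constraint_enrichment(
    hotspot_positions: Iterable[int],
    other_positions: Iterable[int],
    table: GermlineTable,
) -> Fisher2x2Result:
    """Are hotspot positions enriched for germline constraint?

    ``other_positions`` is the comparison set (typically non-hotspot mutated
    positions of the same genes; an all-positions denominator is equally
    valid — pass whichever set matches the question asked).
    """
    hs = list(dict.fromkeys(hotspot_positions))
    ot = list(dict.fromkeys(other_positions))
    if not hs or not ot:
        raise ValueError("both position groups must be non-empty")
    a = sum(table.is_constrained(p) for p in hs)
    c = sum(table.is_constrained(p) for p in ot)
    return fisher_2x2(a, len(hs) - a, c, len(ot) - c)


def structure_enrichment(annotations: pd.DataFrame) -> Fisher2x2Result:
    """Watson-Crick pairing enrichment at hotspot vs non-hotspot positions.

    ``annotations`` needs columns ``structure_class`` (one of ``"WC"``,
    ``"non-WC"``, ``"loop-or-other"``) and boolean ``is_hotspot``; non-WC
    and loop-or-other are pooled as the non-pairing class.
    """
    wc = annotations["structure_class"] == "WC"
    hs = annotations["is_hotspot"].astype(bool)
    return fisher_2x2(
        int((hs & wc).sum()),
        int((hs & ~wc).sum()),
        int((~hs & wc).sum()),
        int((~hs & ~wc).sum()),
    )


def conservation_comparison(
    hotspot_values: Sequence[float],
    other_values: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of conservation rates.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    values and no ties, the tie-corrected normal approximation otherwise.
    Returns ``(U statistic, p)``.
    """
    x = np.asarray(hotspot_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def tissue_enrichment(n_tissue: int, x: int, p_overall: float) -> float:
    """Two-sided binomial p for tissue enrichment/depletion of hotspot carriers.

    ``n_tissue`` patients in the tissue, ``x`` of them carrying an rRNA
    hotspot, against the cohort-wide carrier rate ``p_overall``.
    """
    if not 0 <= x <= n_tissue:
        raise ValueError("require 0 <= x <= n")
    if not 0 < p_overall < 1:
        raise ValueError("p_overall must lie strictly in (0, 1)")
    return float(stats.binomtest(x, n_tissue, p_overall, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# mtDNA alteration levels and nuclear co-occurrence

MT_LEVELS = ("any_mt", "truncating", "hotspot", "any_rrna", "rrna_hotspot")
RRNA_GENES = ("MT-RNR1", "MT-RNR2")


def mt_alteration_levels(
    calls: pd.DataFrame,
    ref: MtReference,
    hotspot_positions: Iterable[int],
    samples: Sequence[str] | None = None,
    rrna_genes: Sequence[str] = RRNA_GENES,
) -> pd.DataFrame:
    """Per-sample boolean indicators at five nested mtDNA alteration levels.

    Levels: any mtDNA mutation; truncating mutation (``truncating`` flag on
    input rows); hotspot mutation; any rRNA-gene mutation; rRNA hotspot.
    """
    hs = set(hotspot_positions)
    gene_idx = ref.gene_index_array
    gene_names = np.array([g.name for g in ref.genes])
    pos = calls["pos"].to_numpy(dtype=np.int64)
    gi = gene_idx[pos - 1]
    in_rrna = np.isin(np.where(gi >= 0, gene_names[np.maximum(gi, 0)], ""), rrna_genes)
    in_hs = np.isin(pos, list(hs))
    trunc = (
        calls["truncating"].to_numpy(dtype=bool)
        if "truncating" in calls.columns
        else np.zeros(len(calls), dtype=bool)
    )
    flags = pd.DataFrame(
        {
            "sample_id": calls["sample_id"].to_numpy(),
            "any_mt": True,
            "truncating": trunc,
            "hotspot": in_hs,
            "any_rrna": in_rrna,
            "rrna_hotspot": in_hs & in_rrna,
        }
    )
    agg = flags.groupby("sample_id").any()
    if samples is not None:
        agg = agg.reindex(samples, fill_value=False)
    return agg.astype(bool)


def cooccurrence_tests(
    nuclear: pd.DataFrame,
    mt_status: pd.DataFrame,
    cancer_types: pd.Series,
    min_prevalence: float = 0.05,
    min_expected: float = 5.0,
    correction: str = "bh",
    yates: bool = False,
) -> pd.DataFrame:
    """Chi-squared co-occurrence of nuclear driver and mtDNA alterations.

    Within each cancer type, each nuclear gene mutated in at least
    ``min_prevalence`` of that type's patients is tested against each mtDNA
    alteration level. The 2x2 chi-squared is computed without continuity
    correction by default; tables with any expected cell below
    ``min_expected`` are flagged (``low_expected``), not suppressed.
    Adjustment across the full result family is Benjamini–Hochberg
    (``correction="bh"``) or Bonferroni (``"bonferroni"``).
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    if not nuclear.index.equals(mt_status.index) or not nuclear.index.equals(
        cancer_types.index
    ):
        raise ValueError("sample indices of the inputs must be aligned")
    rows = []
    for ctype, idx in cancer_types.groupby(cancer_types).groups.items():
        nuc = nuclear.loc[idx].astype(bool)
        mts = mt_status.loc[idx].astype(bool)
        prevalent = nuc.columns[nuc.mean(axis=0) >= min_prevalence]
        for gene in prevalent:
            g = nuc[gene].to_numpy()
            for level in mts.columns:
                m = mts[level].to_numpy()
                a = int((g & m).sum())
                b = int((g & ~m).sum())
                c = int((~g & m).sum())
                d = int((~g & ~m).sum())
                table = np.array([[a, b], [c, d]])
                if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                    continue  # degenerate margin, chi-squared undefined
                chi2, p, _, expected = stats.chi2_contingency(
                    table, correction=yates
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    oddsr = float(np.float64(a) * d / (np.float64(b) * c))
                rows.append(
                    {
                        "cancer_type": ctype,
                        "gene": gene,
                        "level": level,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "chi2": float(chi2),
                        "odds_ratio": oddsr,
                        "p": float(p),
                        "low_expected": bool(expected.min() < min_expected),
                    }
                )
    result = pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "gene", "level", "a", "b", "c", "d",
            "chi2", "odds_ratio", "p", "low_expected",
        ],
    )
    if len(result):
        if correction == "bh":
            result["q"] = bh_adjust(result["p"].to_numpy())
        else:
            result["q"] = np.minimum(result["p"].to_numpy() * len(result), 1.0)
    else:
        result["q"] = pd.Series(dtype=float)
    return result
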