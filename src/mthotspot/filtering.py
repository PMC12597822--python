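"""Somatic mtDNA call retention rules.

A call survives iff all of the following hold, read strictly as printed:

* tumor heteroplasmy  > 5%   (``tumor_vaf > 0.05``),
* matched-normal heteroplasmy < 1% (``normal_vaf < 0.01``),
* at least two supporting reads on each strand (``alt_fwd >= 2`` and
  ``alt_rev >= 2``),
* position outside the hypermutable blacklist (513-525, 3105-3109).

Control-region calls are retained here; the control region is removed
later, at hotspot testing. Thresholds are parameters, not constants: a more
sensitive 1% tumor threshold is known to admit strand-artifact calls
(noncanonical T>G enrichment), which is why 5% is the default.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .reference import DEFAULT_BLACKLIST, MtReference, _interval_contains

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "pos", "tumor_vaf", "normal_vaf", "alt_fwd", "alt_rev")


class MalformedCallError(ValueError):
    """Raised with the offending row indices when input rows are invalid."""

    def __init__(self, rows, message):
        self.rows = list(rows)
        super().__init__(f"{message} (row indices: {self.rows})")


def _validate(calls: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")
    numeric = calls[["tumor_vaf", "normal_vaf", "alt_fwd", "alt_rev", "pos"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1)
    bad |= (numeric["tumor_vaf"] < 0) | (numeric["tumor_vaf"] > 1)
    bad |= (numeric["normal_vaf"] < 0) | (numeric["normal_vaf"] > 1)
    bad |= (numeric["alt_fwd"] < 0) | (numeric["alt_rev"] < 0)
    if bad.any():
        raise MalformedCallError(
            calls.index[bad], "malformed variant rows (NaN or out-of-range fields)"
        )


def filter_somatic(
    calls: pd.DataFrame,
    ref: MtReference | None = None,
    min_tumor_vaf: float = 0.05,
    max_normal_vaf: float = 0.01,
    min_strand_reads: int = 2,
    blacklist: tuple[tuple[int, int], ...] | None = None,
) -> pd.DataFrame:
    """Apply the somatic retention rules; row order preserved, input untouched.

    Comparisons against ``min_tumor_vaf`` and ``max_normal_vaf`` are strict
    (``>`` / ``<``); strand support uses ``>=``. Indel rows (``type`` column
    equal to ``"indel"``) pass through the same rules with a warning, since
    no indel-specific rule set is defined.
    """
    _validate(calls)
    if blacklist is None:
        blacklist = ref.blacklist if ref is not None else DEFAULT_BLACKLIST

    if "type" in calls.columns and (calls["type"] == "indel").any():
        warnings.warn(
            "indel calls are passed through SNV retention rules "
            "(no indel-specific rule set is defined)",
            stacklevel=2,
        )

    pos = calls["pos"].to_numpy(dtype=np.int64)
    in_black = np.zeros(len(calls), dtype=bool)
    for start, end in blacklist:
        if start <= end:
            in_black |= (pos >= start) & (pos <= end)
        else:
            in_black |= (pos >= start) | (pos <= end)

    rules = {
        "tumor_vaf": calls["tumor_vaf"].to_numpy() > min_tumor_vaf,
        "normal_vaf": calls["normal_vaf"].to_numpy() < max_normal_vaf,
        "strand_support": (calls["alt_fwd"].to_numpy() >= min_strand_reads)
        & (calls["alt_rev"].to_numpy() >= min_strand_reads),
        "blacklist": ~in_black,
    }
    keep = np.ones(len(calls), dtype=bool)
    for name, mask in rules.items():
        removed = int((keep & ~mask).sum())
        keep &= mask
        logger.info("filter rule %-14s removed %d calls", name, removed)
    return calls.loc[keep]


def in_any_interval(intervals, pos: int) -> bool:
    """Wrap-aware closed-interval membership over a list of intervals."""
    return any(_interval_contains(s, e, pos) for s, e in intervals)
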