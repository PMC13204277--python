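"""Per-sample hard filtering of variant calls.

A call is removed when any of three criteria fires, all strict
inequalities (boundary values are kept):

* site quality below ``min_qual`` (default 100),
* total read depth below ``min_dp`` (default 20),
* best-supported alternate allele depth as a fraction of depth below
  ``min_alt_fraction`` (default 1/6).

The fraction's denominator is the site DP by default; ``sum_ad`` is
available for callers whose DP drifts from the AD sum.  Filtering is
per sample: a variant may survive in some samples and not in others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd

from .model import SampleCall, VariantKey

logger = logging.getLogger(__name__)

LOW_QUAL = "low_qual"
LOW_DEPTH = "low_depth"
LOW_ALT_FRACTION = "low_alt_fraction"


@dataclass(frozen=True)
class QCThresholds:
    """Removal thresholds; a call is dropped when a value is strictly below."""

    min_qual: float = 100.0
    min_dp: int = 20
    min_alt_fraction: float = 1.0 / 6.0
    fraction_denominator: str = "dp"  # "dp" or "sum_ad"

    def __post_init__(self) -> None:
        if self.fraction_denominator not in ("dp", "sum_ad"):
            raise ValueError(f"unknown denominator mode {self.fraction_denominator!r}")


@dataclass(frozen=True)
class FilterDecision:
    key: VariantKey
    sample_id: str
    kept: bool
    reasons: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be true iff reasons is empty")


def alt_fraction(call: SampleCall, denominator: str = "dp") -> float | None:
    """Best-supported alternate allele depth over total depth.

    Returns None when AD is absent or holds no alt entries (the
    criterion is then skipped by :func:`apply_filters`).
    """
    if call.ad is None or len(call.ad) < 2:
        return None
    denom = call.dp if denominator == "dp" else sum(call.ad)
    if denom <= 0:
        return 0.0
    return max(call.ad[1:]) / denom


def apply_filters(
    key: VariantKey, call: SampleCall, thresholds: QCThresholds | None = None
) -> FilterDecision:
    """Evaluate all three criteria for one call; every failure is listed."""
    t = thresholds or QCThresholds()
    reasons: List[str] = []
    if call.qual < t.min_qual:
        reasons.append(LOW_QUAL)
    if call.dp < t.min_dp:
        reasons.append(LOW_DEPTH)
    frac = alt_fraction(call, t.fraction_denominator)
    if frac is None:
        logger.debug("AD missing for %s in %s; alt-fraction criterion skipped", key, call.sample_id)
    elif frac < t.min_alt_fraction:
        reasons.append(LOW_ALT_FRACTION)
    return FilterDecision(key=key, sample_id=call.sample_id, kept=not reasons, reasons=tuple(reasons))


Cohort = Mapping[str, Iterable[Tuple[VariantKey, SampleCall]]]


def filter_cohort(
    cohort: Cohort, thresholds: QCThresholds | None = None
) -> Tuple[Dict[str, List[Tuple[VariantKey, SampleCall]]], pd.DataFrame]:
    """Filter every sample's calls; return kept calls plus a QC summary.

    The summary has one row per sample with the input count, per-criterion
    failure counts (a call can contribute to several), the number of calls
    whose alt-fraction criterion was skipped for missing AD, and the kept
    count.
    """
    t = thresholds or QCThresholds()
    kept: Dict[str, List[Tuple[VariantKey, SampleCall]]] = {}
    rows = []
    for sample_id, calls in cohort.items():
        calls = list(calls)
        if not calls:
            logger.warning("sample %s has no calls", sample_id)
        surviving = []
        n_fail = {LOW_QUAL: 0, LOW_DEPTH: 0, LOW_ALT_FRACTION: 0}
        n_ad_missing = 0
        for key, call in calls:
            if alt_fraction(call, t.fraction_denominator) is None:
                n_ad_missing += 1
            decision = apply_filters(key, call, t)
            for reason in decision.reasons:
                n_fail[reason] += 1
            if decision.kept:
                surviving.append((key, call))
        kept[sample_id] = surviving
        rows.append(
            {
                "sample_id": sample_id,
                "n_input": len(calls),
                "n_fail_qual": n_fail[LOW_QUAL],
                "n_fail_depth": n_fail[LOW_DEPTH],
                "n_fail_fraction": n_fail[LOW_ALT_FRACTION],
                "n_ad_missing": n_ad_missing,
                "n_kept": len(surviving),
            }
        )
    return kept, pd.DataFrame(rows)
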