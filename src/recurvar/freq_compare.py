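"""Exact binomial comparison of cohort frequencies against reference
cohorts, with Benjamini-Hochberg correction.

Two modes share the machinery: per-variant allele-frequency comparison
(observed alt alleles over 2n chromosomes against each reference AF) and
ancestry-composition comparison (individuals per ancestry group against
a reference proportion).  Two-sided p-values use the minimum-likelihood
convention: the sum of probabilities of all outcomes no more likely than
the observed one.  BH adjustment is applied separately within each
reference cohort's family of tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .model import VariantKey

logger = logging.getLogger(__name__)

#: Smallest positive double; stands in for a structurally-zero p-value
#: (observed count impossible under a degenerate reference frequency).
MIN_P = math.ulp(0.0)


@dataclass(frozen=True)
class FrequencyTestResult:
    """One exact binomial test of a cohort count against a reference frequency."""

    key: Union[VariantKey, str]
    cohort: str
    observed: int
    trials: int
    ref_freq: float
    p_raw: float
    p_adj: float
    enriched: bool
    degenerate: bool = False  # ref_freq was exactly 0 or 1

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adj < alpha


def exact_binomial_p(observed: int, trials: int, ref_freq: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method).

    Degenerate reference frequencies are handled exactly: under
    ref_freq 0 (or 1) any observation other than the forced outcome has
    probability zero, reported as the smallest positive double with a
    warning rather than dropped.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= observed <= trials:
        raise ValueError(f"observed {observed} out of 0..{trials}")
    if not 0.0 <= ref_freq <= 1.0:
        raise ValueError(f"ref_freq {ref_freq} out of [0,1]")
    if ref_freq == 0.0 or ref_freq == 1.0:
        forced = 0 if ref_freq == 0.0 else trials
        if observed == forced:
            return 1.0
        logger.warning(
            "observed %d/%d impossible under ref_freq %g; p clamped to %g",
            observed, trials, ref_freq, MIN_P,
        )
        return MIN_P
    p = binomtest(observed, trials, ref_freq, alternative="two-sided").pvalue
    return min(1.0, max(float(p), MIN_P))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    pvals = list(p_values)
    if not pvals:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvals):
        raise ValueError("p-values must lie in (0, 1]")
    if len(pvals) == 1:
        return [pvals[0]]
    return list(multipletests(pvals, method="fdr_bh")[1])


def _adjust_within_cohorts(results: List[FrequencyTestResult]) -> List[FrequencyTestResult]:
    by_cohort: Dict[str, List[int]] = {}
    for i, r in enumerate(results):
        by_cohort.setdefault(r.cohort, []).append(i)
    adjusted = list(results)
    for idxs in by_cohort.values():
        adj = bh_adjust([results[i].p_raw for i in idxs])
        for i, p_adj in zip(idxs, adj):
            r = results[i]
            adjusted[i] = FrequencyTestResult(
                key=r.key, cohort=r.cohort, observed=r.observed, trials=r.trials,
                ref_freq=r.ref_freq, p_raw=r.p_raw, p_adj=min(1.0, max(float(p_adj), r.p_raw)),
                enriched=r.enriched, degenerate=r.degenerate,
            )
    return adjusted


def compare_cohort_frequencies(
    observed_counts: Mapping[VariantKey, int],
    reference_afs: Mapping[str, Mapping[VariantKey, float]],
    trials: int,
    alpha: float = 0.05,
) -> Tuple[List[FrequencyTestResult], List[VariantKey]]:
    """Test each variant's cohort allele frequency against every reference.

    ``observed_counts`` maps variant to alt allele count over ``trials``
    chromosomes (2n for n diploid samples by default; pass n for
    carrier-count mode).  A test exists only where the reference reports
    a frequency; variants absent from every reference are returned in
    the exclusion list, untested.  BH families are per reference cohort.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    results: List[FrequencyTestResult] = []
    excluded: List[VariantKey] = []
    for key in sorted(observed_counts, key=lambda k: k.sort_key):
        obs = observed_counts[key]
        tested = False
        for cohort, table in reference_afs.items():
            if key not in table:
                continue
            ref = table[key]
            p = exact_binomial_p(obs, trials, ref)
            results.append(
                FrequencyTestResult(
                    key=key, cohort=cohort, observed=obs, trials=trials, ref_freq=ref,
                    p_raw=p, p_adj=p, enriched=obs / trials > ref,
                    degenerate=ref in (0.0, 1.0),
                )
            )
            tested = True
        if not tested:
            excluded.append(key)
    return _adjust_within_cohorts(results), excluded


def compare_ancestry_composition(
    cohort_counts: Mapping[str, int],
    reference_compositions: Mapping[str, Mapping[str, float]],
) -> List[FrequencyTestResult]:
    """Test each ancestry group's cohort proportion against references.

    Trials are individuals (the cohort size), not alleles.  Groups
    missing from a reference composition are skipped with a warning.
    BH families are per reference cohort.
    """
    n = sum(cohort_counts.values())
    if n < 1:
        raise ValueError("cohort is empty")
    results: List[FrequencyTestResult] = []
    for cohort, composition in reference_compositions.items():
        for group in sorted(cohort_counts):
            if group not in composition:
                logger.warning("ancestry group %s absent from reference %s; skipped", group, cohort)
                continue
            ref = composition[group]
            obs = cohort_counts[group]
            p = exact_binomial_p(obs, n, ref)
            results.append(
                FrequencyTestResult(
                    key=group, cohort=cohort, observed=obs, trials=n, ref_freq=ref,
                    p_raw=p, p_adj=p, enriched=obs / n > ref, degenerate=ref in (0.0, 1.0),
                )
            )
    return _adjust_within_cohorts(results)


def significant_enriched(
    results: Iterable[FrequencyTestResult], alpha: float = 0.05
) -> List[FrequencyTestResult]:
    """Subset with BH-adjusted p below alpha and cohort frequency above reference."""
    return [r for r in results if r.significant(alpha) and r.enriched]
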