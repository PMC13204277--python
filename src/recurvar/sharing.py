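"""Variant sharing across a cohort: presence matrix, sharing spectrum,
recurrence threshold, and the Wilson prevalence bound.

"Presence" by default means the sample's called genotype carries the alt
allele (het or hom); ``presence="record"`` counts any surviving call,
reproducing pure record-based sharing.  A missing genotype counts as
absent.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import SampleCall, VariantKey

logger = logging.getLogger(__name__)


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


@dataclass
class CohortMatrix:
    """Binary variant-by-sample presence matrix after QC."""

    variants: List[VariantKey]
    samples: List[str]
    presence: np.ndarray  # bool, shape (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.variants), len(self.samples)):
            raise ValueError("presence shape does not match variant/sample lists")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def row_sums(self) -> np.ndarray:
        return self.presence.sum(axis=1)


@dataclass
class SharingSpectrum:
    """Distribution of variants by the number of samples carrying them."""

    counts_exact: Dict[int, int]
    counts_at_least: Dict[int, int]
    n_samples: int
    n_variants: int

    def percent_exact(self, k: int, decimals: int = 1) -> float:
        return percent(self.counts_exact[k], self.n_variants, decimals)

    def percent_at_least(self, k: int, decimals: int = 1) -> float:
        return percent(self.counts_at_least[k], self.n_variants, decimals)

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts_exact)
        return pd.DataFrame(
            {
                "k": ks,
                "exact": [self.counts_exact[k] for k in ks],
                "at_least": [self.counts_at_least[k] for k in ks],
                "pct_exact": [self.percent_exact(k, 2) for k in ks],
                "pct_at_least": [self.percent_at_least(k, 2) for k in ks],
            }
        )


Cohort = Mapping[str, Iterable[Tuple[VariantKey, SampleCall]]]


def build_matrix(filtered: Cohort, presence: str = "genotype") -> CohortMatrix:
    """Build the presence matrix over the union of post-QC variants.

    presence="genotype" requires the call's GT to carry the keyed alt
    allele; presence="record" counts any kept call.  Duplicate
    (variant, sample) pairs are collapsed with a warning.
    """
    if presence not in ("genotype", "record"):
        raise ValueError(f"unknown presence mode {presence!r}")
    samples = list(filtered.keys())
    cells: Set[Tuple[VariantKey, str]] = set()
    n_dup = 0
    for sample_id, calls in filtered.items():
        for key, call in calls:
            if presence == "genotype" and not call.carries_alt():
                continue
            if (key, sample_id) in cells:
                n_dup += 1
            cells.add((key, sample_id))
    if n_dup:
        logger.warning("collapsed %d duplicate (variant, sample) pairs", n_dup)
    variants = sorted({key for key, _ in cells}, key=lambda k: k.sort_key)
    vindex = {v: i for i, v in enumerate(variants)}
    sindex = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(variants), len(samples)), dtype=bool)
    for key, sample_id in cells:
        mat[vindex[key], sindex[sample_id]] = True
    return CohortMatrix(variants=variants, samples=samples, presence=mat)


def spectrum(matrix: CohortMatrix) -> SharingSpectrum:
    """Exact and cumulative sharing counts over k = 1..n_samples."""
    sums = Counter(int(s) for s in matrix.row_sums())
    n = matrix.n_samples
    counts_exact = {k: sums.get(k, 0) for k in range(1, n + 1)}
    counts_at_least: Dict[int, int] = {}
    running = 0
    for k in range(n, 0, -1):
        running += counts_exact[k]
        counts_at_least[k] = running
    counts_at_least = {k: counts_at_least[k] for k in range(1, n + 1)}
    return SharingSpectrum(
        counts_exact=counts_exact,
        counts_at_least=counts_at_least,
        n_samples=n,
        n_variants=matrix.n_variants,
    )


def default_min_samples(n_samples: int, fraction: float = 0.8) -> int:
    """Smallest carrier count meeting the recurrence fraction (ceil)."""
    return math.ceil(fraction * n_samples)


def recurrent_variants(matrix: CohortMatrix, min_samples: Optional[int] = None) -> Set[VariantKey]:
    """Variants present in at least ``min_samples`` samples (default 80% of n)."""
    k = default_min_samples(matrix.n_samples) if min_samples is None else min_samples
    if not 1 <= k <= matrix.n_samples:
        raise ValueError(f"min_samples {k} out of range 1..{matrix.n_samples}")
    sums = matrix.row_sums()
    return {v for v, s in zip(matrix.variants, sums) if s >= k}


def wilson_lower_bound(successes: int, n: int, confidence: float = 0.95) -> float:
    """Lower bound of the two-sided Wilson score interval for a proportion.

    Closed-form inversion of the normal-approximation score test, without
    continuity correction.  For 8 successes in 10 trials at 95% the bound
    is ~0.4902, i.e. a variant seen in 8/10 samples has an estimated true
    prevalence plausibly above 49%.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} out of 0..{n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if successes == 0:
        return 0.0
    z = norm.ppf(0.5 + confidence / 2.0)
    phat = successes / n
    z2n = z * z / n
    center = phat + z2n / 2.0
    half = z * math.sqrt(phat * (1.0 - phat) / n + z2n / (4.0 * n))
    lower = (center - half) / (1.0 + z2n)
    return min(max(lower, 0.0), 1.0)


def alt_allele_counts(filtered: Cohort) -> Counter:
    """Alt allele count per variant over all samples' called genotypes."""
    counts: Counter = Counter()
    for _, calls in filtered.items():
        for key, call in calls:
            counts[key] += sum(1 for a in call.gt_alleles if a == call.alt_index)
    return counts


def threshold_sensitivity(
    matrix: CohortMatrix,
    is_deleterious: Callable[[VariantKey], bool],
    genes_by_key: Optional[Mapping[VariantKey, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Prioritized variant (and gene) counts at every recurrence cutoff.

    One row per k = 1..n_samples with the number of variants passing both
    recurrence (>= k) and the deleteriousness predicate; non-increasing
    in k by construction.
    """
    sums = matrix.row_sums()
    deleterious = np.array([is_deleterious(v) for v in matrix.variants], dtype=bool)
    rows = []
    for k in range(1, matrix.n_samples + 1):
        mask = (sums >= k) & deleterious
        genes: Set[str] = set()
        if genes_by_key is not None:
            for v, m in zip(matrix.variants, mask):
                if m:
                    genes.update(genes_by_key.get(v, ()))
        rows.append({"k": k, "n_variants": int(mask.sum()), "n_genes": len(genes)})
    return pd.DataFrame(rows)
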