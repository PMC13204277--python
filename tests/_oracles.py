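"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity from first principles
(enumeration, set membership, literal predicates) and share no code with
the implementation they check.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Set, Tuple


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def two_sided_binomial_enum(observed: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p by full outcome enumeration.

    Minimum-likelihood convention: sum the probabilities of every
    outcome whose probability does not exceed that of the observed one
    (with a small relative tolerance against float noise, matching the
    common implementation convention).
    """
    p_obs = binom_pmf(observed, n, p0)
    cutoff = p_obs * (1.0 + 1e-7)
    total = sum(binom_pmf(k, n, p0) for k in range(n + 1) if binom_pmf(k, n, p0) <= cutoff)
    return min(1.0, total)


def bh_stepup(pvals: Sequence[float]) -> List[float]:
    """Textbook Benjamini-Hochberg step-up, returned in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adj[i] = running_min
    return adj


def qc_remove(qual: float, dp: int, ad: Tuple[int, ...] | None) -> bool:
    """Literal re-statement of the three removal predicates (strict <)."""
    if qual < 100:
        return True
    if dp < 20:
        return True
    if ad is not None and len(ad) >= 2:
        frac = (max(ad[1:]) / dp) if dp > 0 else 0.0
        if frac < 1 / 6:
            return True
    return False


def sharing_counts(carriers_by_variant: Dict[object, Set[str]]) -> Counter:
    """Variants per exact carrier count, by direct set membership."""
    return Counter(len(s) for s in carriers_by_variant.values())


def count_deleterious_votes(calls: Dict[str, str], rubric: Dict[str, Iterable[str]]) -> int:
    return sum(
        1
        for name, codes in rubric.items()
        if calls.get(name, ".") not in (".", "", None) and calls[name] in set(codes)
    )


def wilson_lower_by_inversion(successes: int, n: int, confidence: float) -> float:
    """Smallest proportion not rejected by the one-boundary score test.

    Bisection on p of the statistic (phat - p) / sqrt(p(1-p)/n) <= z.
    """
    from scipy.stats import norm

    if successes == 0:
        return 0.0
    z = norm.ppf(0.5 + confidence / 2.0)
    phat = successes / n
    lo, hi = 1e-15, phat
    for _ in range(200):
        mid = (lo + hi) / 2.0
        stat = (phat - mid) / math.sqrt(mid * (1.0 - mid) / n)
        if stat <= z:
            hi = mid
        else:
            lo = mid
    return hi
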