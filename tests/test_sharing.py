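"""Presence matrix, sharing spectrum, recurrence and the Wilson bound."""

from __future__ import annotations

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from recurvar import (
    SampleCall,
    VariantKey,
    alt_allele_counts,
    build_matrix,
    percent,
    recurrent_variants,
    spectrum,
    threshold_sensitivity,
    wilson_lower_bound,
)
from recurvar.sharing import CohortMatrix, default_min_samples

import _oracles


def key(i, chrom="chr1"):
    return VariantKey(chrom, i, "G", "A")


def call(sample, gt=(0, 1)):
    return SampleCall(sample, 500.0, 40, (20, 20), gt)


class TestBuildMatrix:
    def test_fully_shared_variant(self):
        cohort = {s: [(key(1), call(s))] for s in ("S01", "S02", "S03")}
        m = build_matrix(cohort)
        assert m.presence.shape == (1, 3)
        assert m.presence.all()

    def test_disjoint_sets_give_singleton_rows(self):
        cohort = {
            "S01": [(key(i), call("S01")) for i in range(1, 5)],
            "S02": [(key(i), call("S02")) for i in range(10, 16)],
        }
        m = build_matrix(cohort)
        assert m.presence.shape == (10, 2)
        assert (m.row_sums() == 1).all()

    def test_homref_genotype_not_present_in_genotype_mode(self):
        cohort = {"S01": [(key(1), call("S01", gt=(0, 0)))]}
        assert build_matrix(cohort, presence="genotype").n_variants == 0
        assert build_matrix(cohort, presence="record").n_variants == 1

    def test_missing_genotype_counts_absent(self):
        cohort = {"S01": [(key(1), call("S01", gt=(-1, -1)))]}
        assert build_matrix(cohort, presence="genotype").n_variants == 0

    def test_matches_brute_force_membership_table(self):
        rng = np.random.default_rng(9)
        samples = [f"S{i:02d}" for i in range(1, 11)]
        carriers = {key(i): set(rng.choice(samples, rng.integers(1, 11), replace=False)) for i in range(1, 51)}
        cohort = {
            s: [(k, call(s)) for k, members in carriers.items() if s in members]
            for s in samples
        }
        m = build_matrix(cohort)
        assert m.n_variants == 50
        for k_, members in carriers.items():
            row = m.presence[m.variants.index(k_)]
            assert {s for s, bit in zip(m.samples, row) if bit} == members

    def test_variant_order_is_deterministic(self):
        cohort = {"S01": [(key(5), call("S01")), (key(2), call("S01")), (key(9, "chr2"), call("S01"))]}
        m = build_matrix(cohort)
        assert [v.pos for v in m.variants] == [2, 5, 9]


class TestSpectrum:
    def _matrix_from_rowsums(self, sums, n=10):
        rows = [[1] * s + [0] * (n - s) for s in sums]
        return CohortMatrix(
            variants=[key(i + 1) for i in range(len(sums))],
            samples=[f"S{i:02d}" for i in range(1, n + 1)],
            presence=np.array(rows, dtype=bool),
        )

    def test_exact_and_cumulative_counts(self):
        spec = spectrum(self._matrix_from_rowsums([1, 1, 2, 10]))
        assert spec.counts_exact[1] == 2 and spec.counts_exact[2] == 1 and spec.counts_exact[10] == 1
        assert spec.counts_at_least[8] == 1
        assert spec.counts_at_least[1] == 4

    def test_conservation_and_monotone_cumulative(self):
        rng = np.random.default_rng(12)
        spec = spectrum(self._matrix_from_rowsums(rng.integers(1, 11, size=200)))
        assert sum(spec.counts_exact.values()) == spec.n_variants == 200
        at_least = [spec.counts_at_least[k] for k in range(1, 11)]
        assert at_least == sorted(at_least, reverse=True)
        # cumulative = tail sums of exact
        for k in range(1, 11):
            assert spec.counts_at_least[k] == sum(spec.counts_exact[j] for j in range(k, 11))

    def test_matches_brute_force_counter(self):
        rng = np.random.default_rng(13)
        sums = list(rng.integers(1, 11, size=100))
        spec = spectrum(self._matrix_from_rowsums(sums))
        brute = _oracles.sharing_counts({i: set(range(s)) for i, s in enumerate(sums)})
        for k in range(1, 11):
            assert spec.counts_exact[k] == brute.get(k, 0)


def test_percent_reproduces_printed_sharing_arithmetic():
    # union-level percentages at 1-2 printed decimals
    assert percent(4.24e6, 11.40e6, 1) == 37.2
    assert percent(409_811, 11.40e6, 1) == 3.6
    assert percent(584_927, 11.40e6, 2) == 5.13


class TestRecurrentVariants:
    def _matrix(self, sums, n=10):
        rows = [[1] * s + [0] * (n - s) for s in sums]
        return CohortMatrix(
            variants=[key(i + 1) for i in range(len(sums))],
            samples=[f"S{i:02d}" for i in range(1, n + 1)],
            presence=np.array(rows, dtype=bool),
        )

    def test_min_one_returns_everything(self):
        m = self._matrix([1, 3, 5, 10])
        assert recurrent_variants(m, 1) == set(m.variants)

    def test_full_sharing_cutoff(self):
        m = self._matrix([1, 9, 10])
        assert recurrent_variants(m, 10) == {key(3)}

    def test_default_is_eighty_percent_ceiling(self):
        assert default_min_samples(10) == 8
        assert default_min_samples(9) == 8  # ceil(7.2)
        m = self._matrix([7, 8, 9])
        assert recurrent_variants(m) == {key(2), key(3)}

    def test_out_of_range_cutoff_is_fatal(self):
        m = self._matrix([1])
        with pytest.raises(ValueError):
            recurrent_variants(m, 0)
        with pytest.raises(ValueError):
            recurrent_variants(m, 11)

    def test_matches_brute_force_row_sums(self):
        rng = np.random.default_rng(21)
        sums = list(rng.integers(1, 11, size=100))
        m = self._matrix(sums)
        for k in (1, 5, 8, 10):
            expected = {key(i + 1) for i, s in enumerate(sums) if s >= k}
            assert recurrent_variants(m, k) == expected


class TestWilsonLowerBound:
    def test_eight_of_ten_exceeds_49_percent(self):
        assert wilson_lower_bound(8, 10, 0.95) > 0.49

    def test_zero_successes_is_exactly_zero(self):
        for n in (1, 10, 500):
            assert wilson_lower_bound(0, n, 0.95) == 0.0

    def test_agrees_with_score_test_inversion_oracle(self):
        got = wilson_lower_bound(8, 10, 0.95)
        assert round(got, 4) == 0.4902
        assert got == pytest.approx(_oracles.wilson_lower_by_inversion(8, 10, 0.95), abs=1e-9)

    @pytest.mark.parametrize("s,n,conf", [(1, 7, 0.9), (8, 10, 0.95), (25, 40, 0.99), (3, 3, 0.95)])
    def test_agrees_with_statsmodels(self, s, n, conf):
        expected = proportion_confint(s, n, alpha=1 - conf, method="wilson")[0]
        assert wilson_lower_bound(s, n, conf) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_successes(self):
        bounds = [wilson_lower_bound(s, 25, 0.95) for s in range(26)]
        assert all(b1 <= b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_tends_to_observed_proportion_at_large_n(self):
        assert wilson_lower_bound(80_000, 100_000, 0.95) == pytest.approx(0.8, abs=0.005)

    def test_invalid_arguments_fatal(self):
        with pytest.raises(ValueError):
            wilson_lower_bound(11, 10)
        with pytest.raises(ValueError):
            wilson_lower_bound(2, 0)
        with pytest.raises(ValueError):
            wilson_lower_bound(2, 10, confidence=1.0)


def test_alt_allele_counts_sum_genotypes():
    cohort = {
        "S01": [(key(1), call("S01", gt=(0, 1)))],
        "S02": [(key(1), call("S02", gt=(1, 1)))],
        "S03": [(key(1), call("S03", gt=(0, 0)))],
    }
    assert alt_allele_counts(cohort)[key(1)] == 3


class TestThresholdSensitivity:
    def _matrix(self, sums, n=10):
        rows = [[1] * s + [0] * (n - s) for s in sums]
        return CohortMatrix(
            variants=[key(i + 1) for i in range(len(sums))],
            samples=[f"S{i:02d}" for i in range(1, n + 1)],
            presence=np.array(rows, dtype=bool),
        )

    def test_k1_row_equals_total_deleterious_and_monotone(self):
        rng = np.random.default_rng(30)
        sums = list(rng.integers(1, 11, size=80))
        deleterious = {key(i + 1) for i in range(80) if rng.random() < 0.3}
        m = self._matrix(sums)
        genes = {key(i + 1): [f"G{i % 7}"] for i in range(80)}
        table = threshold_sensitivity(m, deleterious.__contains__, genes)
        assert table.loc[table["k"] == 1, "n_variants"].item() == len(deleterious)
        counts = list(table["n_variants"])
        assert counts == sorted(counts, reverse=True)
        # brute-force recount at each k
        for k in range(1, 11):
            expected = sum(1 for i, s in enumerate(sums) if s >= k and key(i + 1) in deleterious)
            assert table.loc[table["k"] == k, "n_variants"].item() == expected
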