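"""Exact binomial allelic test and SAD score post-processing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from crevar.allelic import (
    AlleleCountObservation,
    MotifScorer,
    allelic_ratio,
    classify_mechanism,
    exact_binomial_two_sided,
    sad_raw,
    sad_zscores,
    saturation_mutagenesis,
)


def binom_two_sided_oracle(n, k, pi0=0.5):
    """Independent enumeration of all n+1 outcomes."""
    pk = math.comb(n, k) * pi0**k * (1 - pi0) ** (n - k)
    total = 0.0
    for i in range(n + 1):
        pi = math.comb(n, i) * pi0**i * (1 - pi0) ** (n - i)
        if pi <= pk * (1 + 1e-7):
            total += pi
    return min(total, 1.0)


class TestExactBinomial:
    @pytest.mark.parametrize("n,k,expected", [
        (10, 5, 1.0),
        (10, 8, 112 / 1024),       # outcomes {0,1,2,8,9,10}
        (3, 3, 0.25),              # outcomes {0,3}
    ])
    def test_hand_computed_values(self, n, k, expected):
        p = exact_binomial_two_sided(AlleleCountObservation(k, n))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 26):
            for k in range(n + 1):
                got = exact_binomial_two_sided(AlleleCountObservation(k, n))
                assert got == pytest.approx(binom_two_sided_oracle(n, k),
                                            rel=1e-10), (n, k)

    def test_matches_scipy_binomtest(self):
        for n, k, pi0 in [(151, 120, 0.5), (40, 13, 0.3), (75, 60, 0.7)]:
            got = exact_binomial_two_sided(AlleleCountObservation(k, n, pi0))
            ref = stats.binomtest(k, n, pi0, alternative="two-sided").pvalue
            assert got == pytest.approx(ref, rel=1e-9)

    @given(st.integers(1, 60), st.data())
    def test_symmetric_at_half(self, n, data):
        k = data.draw(st.integers(0, n))
        p1 = exact_binomial_two_sided(AlleleCountObservation(k, n))
        p2 = exact_binomial_two_sided(AlleleCountObservation(n - k, n))
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert 0 < p1 <= 1

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within (conservative side of)
        the 99% binomial CI over 2000 simulated observations at n=100."""
        rng = np.random.default_rng(2024)
        alpha, reps, n = 0.05, 2000, 100
        rejections = sum(
            exact_binomial_two_sided(
                AlleleCountObservation(int(rng.binomial(n, 0.5)), n)) < alpha
            for _ in range(reps))
        rate = rejections / reps
        ci = 2.576 * math.sqrt(alpha * (1 - alpha) / reps)
        assert rate <= alpha + ci

    def test_power_against_strong_imbalance(self):
        """Allelic ratios near 4 at coverage ~150 are essentially always
        detected at a stringent threshold (alpha = 1e-6)."""
        rng = np.random.default_rng(7)
        hits = sum(
            exact_binomial_two_sided(
                AlleleCountObservation(int(rng.binomial(151, 0.8)), 151)) < 1e-6
            for _ in range(500))
        assert hits / 500 > 0.99

    def test_invalid_observations_rejected(self):
        with pytest.raises(ValueError):
            AlleleCountObservation(5, 4)
        with pytest.raises(ValueError):
            AlleleCountObservation(0, 0)
        with pytest.raises(ValueError):
            AlleleCountObservation(1, 2, pi0=1.0)


class TestAllelicRatio:
    def test_examples(self):
        assert allelic_ratio(AlleleCountObservation(40, 50)) == (4.0, False)
        assert allelic_ratio(AlleleCountObservation(25, 50)) == (1.0, False)
        ratio, flagged = allelic_ratio(AlleleCountObservation(50, 50))
        assert math.isinf(ratio) and flagged


class TestSadRaw:
    def test_null_scorer_gives_zero(self):
        scorer = MotifScorer("TTTT", n_bins=20)
        assert sad_raw(scorer, "A" * 20, "A" * 10 + "C" + "A" * 9) == 0.0

    def test_motif_gain(self):
        scorer = MotifScorer("ACGT", n_bins=20)
        ref = "A" * 20
        alt = "A" * 8 + "ACGT" + "A" * 8
        assert sad_raw(scorer, ref, alt) == 4.0

    def test_antisymmetry(self):
        scorer = MotifScorer("ACGT", n_bins=20)
        ref, alt = "A" * 20, "A" * 8 + "ACGT" + "A" * 8
        assert sad_raw(scorer, ref, alt) == -sad_raw(scorer, alt, ref)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            sad_raw(lambda s: np.zeros(len(s)), "AAAA", "AA")


class TestSadZ:
    def test_population_sd_standardization(self):
        df = pd.DataFrame({"sample": "cMN7_e10.5", "raw": [-1.0, 0.0, 1.0],
                           "is_indel": False})
        z = sad_zscores(df)["z"]
        np.testing.assert_allclose(z, [-1.22474487, 0, 1.22474487], atol=1e-8)

    def test_snv_z_has_zero_mean_unit_sd_per_group(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "sample": ["a"] * 50 + ["b"] * 50,
            "raw": rng.normal(3, 2, 100),
            "is_indel": False})
        out = sad_zscores(df)
        for _, grp in out.groupby("sample"):
            assert grp.z.mean() == pytest.approx(0, abs=1e-9)
            assert grp.z.std(ddof=0) == pytest.approx(1, abs=1e-9)

    def test_indels_use_snv_null(self):
        df = pd.DataFrame({
            "sample": "a",
            "raw": [-1.0, 0.0, 1.0, 0.0, 5.0],
            "is_indel": [False, False, False, True, True]})
        out = sad_zscores(df)
        assert out.z.iloc[3] == pytest.approx(0.0)   # indel at SNV mean
        assert out.z.iloc[4] == pytest.approx(5.0 / math.sqrt(2 / 3))

    def test_constant_group_flagged(self):
        df = pd.DataFrame({"sample": "a", "raw": [2.0, 2.0, 2.0],
                           "is_indel": False})
        out = sad_zscores(df)
        assert out.flagged.all() and out.z.isna().all()


class TestMechanism:
    @pytest.mark.parametrize("z,mech,sig", [
        (-11.77, "LoF", True),
        (2.29, "GoF", True),
        (0.11, "GoF", False),
        (0.0, "neutral", False),
        (-2.0, "LoF", False),    # strictly greater than 2 required
    ])
    def test_calls(self, z, mech, sig):
        assert classify_mechanism(z) == (mech, sig)


class TestSaturation:
    def test_shape_and_null(self):
        res = saturation_mutagenesis({"s1": MotifScorer("TTTT", n_bins=10)},
                                     "A" * 10)
        assert res.delta.shape == (10, 3, 1)
        assert np.nanmax(np.abs(res.delta)) == 0.0

    def test_entries_match_direct_sad_raw(self):
        scorer = MotifScorer("ACG", n_bins=12)
        seq = "AACGTACGTAAC"
        res = saturation_mutagenesis({"s": scorer}, seq)
        for i in (0, 5, 11):
            for j, alt in enumerate(res.alt_bases[i]):
                mutated = seq[:i] + alt + seq[i + 1:]
                assert res.delta[i, j, 0] == sad_raw(scorer, seq, mutated)

    def test_non_acgt_position_skipped(self):
        res = saturation_mutagenesis({"s": MotifScorer("AC", n_bins=5)}, "AANCA")
        assert res.skipped.tolist() == [False, False, True, False, False]
        assert np.isnan(res.delta[2]).all()

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            saturation_mutagenesis({"s": MotifScorer("AC")}, "")
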