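"""Group statistics: rank tests vs enumeration, ANOVA oracle, Bonferroni."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swdscope import (
    bonferroni_factor,
    compare_spectra,
    kruskal_wallis,
    mann_whitney,
    one_way_anova,
    percent_of_control,
    turnover_ratio,
)
from swdscope.stats import analyze_group_table, group_turnover
from swdscope.types import DegenerateSignalError, ParameterError, PowerSpectrum, StatResult


def enumerate_mwu_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    a, b = list(a), list(b)
    pooled = np.array(a + b)
    n = len(a)

    def u_stat(ga, gb):
        return float(sum(np.sum(x > gb) + 0.5 * np.sum(x == gb) for x in ga))

    obs = u_stat(np.array(a), np.array(b))
    u_max = n * len(b)
    lo = min(obs, u_max - obs)
    count = total = 0
    for comb in itertools.combinations(range(pooled.size), n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if u <= lo + 1e-9 or u >= u_max - lo - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_three_vs_three(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(0.1)

    def test_identical_singleton_groups_not_significant(self):
        r = mann_whitney([5.0, 5.0], [5.0, 5.0])
        assert r.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb,seed", [(3, 3, 0), (4, 4, 1), (5, 6, 2),
                                            (7, 7, 3), (6, 8, 4), (3, 7, 5)])
    def test_exact_p_matches_full_enumeration(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=na)
        b = rng.normal(0.8, 1.0, size=nb)
        assert mann_whitney(a, b).p_raw == pytest.approx(enumerate_mwu_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])


class TestAnovaAndKruskal:
    def test_identical_groups_give_zero_f(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums_of_squares(self):
        r = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert r.statistic == pytest.approx(13.5, rel=1e-10)
        assert r.df == (1, 4)

    def test_f_is_squared_t_for_two_groups(self, rng):
        from scipy.stats import ttest_ind

        a, b = rng.normal(size=8), rng.normal(0.5, 1.0, size=9)
        f = one_way_anova([a, b]).statistic
        t = ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_direct_sums_of_squares_oracle(self, rng):
        groups = [rng.normal(loc=m, size=n) for m, n in [(0, 5), (0.3, 7), (1.0, 6)]]
        grand = np.concatenate(groups).mean()
        ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        k, n_tot = 3, sum(g.size for g in groups)
        expected = (ssb / (k - 1)) / (ssw / (n_tot - k))
        assert one_way_anova(groups).statistic == pytest.approx(expected, rel=1e-10)

    def test_degenerate_variance_flagged(self):
        with pytest.raises(DegenerateSignalError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_kruskal_on_shifted_groups(self, rng):
        a, b, c = rng.normal(size=10), rng.normal(2, 1, 10), rng.normal(4, 1, 10)
        r = kruskal_wallis([a, b, c])
        assert r.df == (2,)
        assert r.p_raw < 0.01


class TestBonferroni:
    @pytest.mark.parametrize("nf,nc,expected", [(52, 6, 312), (1, 1, 1), (52, 1, 52)])
    def test_factor_is_exact_product(self, nf, nc, expected):
        assert bonferroni_factor(nf, nc) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni_factor(0, 6)

    @given(p=st.floats(min_value=0.0, max_value=1.0),
           factor=st.integers(min_value=1, max_value=1000))
    def test_adjusted_p_clipped_and_monotone(self, p, factor):
        r = StatResult("t", 0.0, None, p, multiplicity_factor=factor)
        assert r.p_adjusted == min(1.0, factor * p)

    def test_flagging_monotone_in_alpha(self, rng):
        freqs = np.arange(0.5, 26.5, 0.5)
        ga = [PowerSpectrum(freqs, rng.gamma(20, 2.0, freqs.size)) for _ in range(12)]
        gb = [PowerSpectrum(freqs, rng.gamma(20, 1.0, freqs.size)) for _ in range(12)]
        strict = compare_spectra(ga, gb, alpha=0.01, n_comparisons=6).flagged
        loose = compare_spectra(ga, gb, alpha=0.05, n_comparisons=6).flagged
        assert np.all(loose[strict])  # strict set is a subset of the loose set


class TestCompareSpectra:
    def test_identical_groups_flag_nothing(self):
        freqs = np.arange(0.5, 26.5, 0.5)
        rng = np.random.default_rng(0)
        spectra = [PowerSpectrum(freqs, rng.gamma(20, 1.0, freqs.size))
                   for _ in range(10)]
        comp = compare_spectra(spectra, list(spectra), n_comparisons=6)
        assert comp.flagged.sum() == 0

    def test_planted_effect_found_at_eight_hertz(self):
        rng = np.random.default_rng(42)
        freqs = np.arange(0.5, 26.5, 0.5)  # 52 analyzed frequencies
        i8 = int(np.argmin(np.abs(freqs - 8.0)))

        def spectrum(boost):
            p = rng.gamma(20, 1.0, freqs.size)
            p[i8] *= boost
            return PowerSpectrum(freqs, p)

        ga = [spectrum(2.0) for _ in range(25)]
        gb = [spectrum(1.0) for _ in range(25)]
        comp = compare_spectra(ga, gb, n_comparisons=6)
        assert comp.multiplicity_factor == 312
        assert all(r.multiplicity_factor == 312 for r in comp.results)
        assert comp.flagged[i8]
        assert comp.flagged.sum() <= 2  # at most one spurious bin

    def test_small_groups_rejected(self):
        freqs = np.arange(0.5, 5.5, 0.5)
        one = [PowerSpectrum(freqs, np.ones(freqs.size))]
        with pytest.raises(ParameterError):
            compare_spectra(one, one * 3)


class TestSummaries:
    @pytest.mark.parametrize("drug,vehicle,expected", [
        (176.2, 209.6, 84.1),
        (4.0, 1.1, 363.6),
        (50.1, 28.5, 175.8),
        (82.9, 53.1, 156.1),
        (2.3, 2.0, 115.0),
    ])
    def test_percent_of_control_matches_forced_swim_table(self, drug, vehicle, expected):
        assert percent_of_control(drug, vehicle) == expected

    @given(x=st.floats(min_value=0.1, max_value=1e6))
    def test_percent_of_control_identity(self, x):
        assert percent_of_control(x, x) == 100.0

    def test_zero_control_rejected(self):
        with pytest.raises(ParameterError):
            percent_of_control(1.0, 0.0)

    def test_turnover_ratio_examples(self):
        assert turnover_ratio(1.34, 10.63) == pytest.approx(0.126, abs=5e-4)
        assert turnover_ratio(0.0, 3.0) == 0.0

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_turnover_unit_invariance(self, c):
        assert turnover_ratio(1.34 * c, 10.63 * c) == pytest.approx(
            turnover_ratio(1.34, 10.63))

    def test_group_turnover_is_mean_of_per_sample_ratios(self):
        m = [1.0, 2.0, 3.0]
        p = [10.0, 10.0, 10.0]
        assert group_turnover(m, p) == pytest.approx(0.2)

    def test_group_table_roundtrip(self):
        table = pd.DataFrame({
            "group": ["vehicle"] * 5 + ["drug"] * 5,
            "immobility_s": [210, 205, 215, 208, 211, 175, 180, 170, 178, 176],
            "dives": [1, 2, 1, 0, 1, 4, 5, 3, 4, 4],
        })
        out = analyze_group_table(table, "group")
        assert list(out["measure"]) == ["immobility_s", "dives"]
        assert (out["multiplicity_factor"] == 2).all()
        assert (out["p_adjusted"] >= out["p_raw"]).all()
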