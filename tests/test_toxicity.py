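"""CFU normalization, MIC logic, doubling time, two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

from nanorad import (
    CFUToxicityTable,
    GrowthCurve,
    doubling_time,
    minimal_inhibitory_concentration,
    normalized_cfu,
    simulate_toxicity_table,
    two_factor_anova,
)


def make_table(cells: dict, n_rep: int = 2) -> CFUToxicityTable:
    """cells: {(concentration, time_h): [counts...]}"""
    rows = []
    for (conc, t), counts in cells.items():
        for i, c in enumerate(counts, 1):
            rows.append({"concentration": conc, "time_h": t, "replicate": i, "cfu_count": c})
    return CFUToxicityTable(data=pd.DataFrame(rows))


class TestNormalizedCfu:
    def test_treated_equal_control_gives_unit_ratio(self):
        table = make_table({(0, 3): [100, 110], (5, 3): [100, 110]})
        out = normalized_cfu(table)
        row = out[out["concentration"] == 5].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)

    def test_all_zero_treated_gives_zero_ratio(self):
        table = make_table({(0, 3): [100, 110], (5, 3): [0, 0]})
        out = normalized_cfu(table)
        assert out[out["concentration"] == 5]["ratio"].iloc[0] == 0.0

    def test_zero_control_mean_rejected(self):
        table = make_table({(0, 3): [0, 0], (5, 3): [10, 20]})
        with pytest.raises(ValueError, match="control mean"):
            normalized_cfu(table)

    def test_reproduces_simulated_means(self):
        """A table generated around 42% (3 h) and 18% (12 h) survival at
        the 3e6 particles-per-cell level normalizes back to those means."""
        table = simulate_toxicity_table(
            condition_means={(3e6, 3.0): 0.42, (3e6, 12.0): 0.18},
            sds={(3e6, 3.0): 0.08, (3e6, 12.0): 0.03},
            control_count_mean=500,
            n_replicates=3,
            seed=11,
        )
        out = normalized_cfu(table)
        for t, mean, sd in [(3.0, 0.42, 0.08), (12.0, 0.18, 0.03)]:
            row = out[(out["concentration"] == 3e6) & (out["time_h"] == t)].iloc[0]
            se = np.sqrt(sd**2 / 3 + mean**2 / 500 / 3)  # replicate + counting
            assert row["ratio"] == pytest.approx(mean, abs=2.5 * se)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            make_table({(5, 3): [10, 20]})


class TestMinimalInhibitoryConcentration:
    @pytest.fixture
    def ratio_fixture(self) -> pd.DataFrame:
        # survival ratios across the administered concentration series
        return pd.DataFrame(
            {
                "concentration": [0.0, 2.9, 4.8, 9.6, 19.2],
                "time_h": [12.0] * 5,
                "ratio": [1.0, 0.95, 0.75, 0.42, 0.20],
                "ratio_sd": [0.02] * 5,
                "n_replicates": [3] * 5,
            }
        )

    def test_default_threshold_picks_first_significant_drop(self, ratio_fixture):
        assert minimal_inhibitory_concentration(ratio_fixture) == 4.8

    def test_no_concentration_qualifies(self, ratio_fixture):
        mild = ratio_fixture.assign(ratio=[1.0, 0.98, 0.95, 0.93, 0.91])
        assert minimal_inhibitory_concentration(mild) is None

    def test_stricter_threshold_moves_mic_up(self, ratio_fixture):
        assert minimal_inhibitory_concentration(ratio_fixture, reduction_threshold=0.5) == 9.6

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            minimal_inhibitory_concentration(pd.DataFrame(columns=["concentration", "ratio"]))

    def test_significance_gate(self):
        """With the ANOVA supplied, a >20% drop only counts when it is
        Tukey-significant against the same-time control."""
        rng = np.random.default_rng(5)
        cells = {
            (0.0, 3.0): rng.poisson(500, 4).tolist(),
            (4.8, 3.0): rng.poisson(250, 4).tolist(),  # strong, significant drop
            (0.0, 12.0): rng.poisson(500, 4).tolist(),
            (4.8, 12.0): rng.poisson(240, 4).tolist(),
        }
        table = make_table(cells)
        ratios = normalized_cfu(table)
        anova = two_factor_anova(table)
        assert minimal_inhibitory_concentration(ratios, significance=anova) == 4.8


class TestDoublingTime:
    def test_exact_exponential(self):
        t = np.arange(0, 720, 60, dtype=float)
        curve = GrowthCurve(times=t, od600=0.1 * 2 ** (t / 144.0))
        assert doubling_time(curve) == pytest.approx(144.0, rel=1e-9)

    def test_noisy_slow_growth_recovered(self):
        from nanorad import simulate_growth_curve

        t = np.arange(0, 2400, 120, dtype=float)
        curve = simulate_growth_curve(
            lag=0.0, doubling_time=455.0, carrying_od=50.0, od0=0.1,
            times=t, noise_cv=0.02, seed=4,
        )
        assert doubling_time(curve) == pytest.approx(455.0, abs=15.0)

    def test_flat_curve_raises(self):
        t = np.arange(0, 300, 60, dtype=float)
        with pytest.raises(ValueError, match="no[ -]growth|exponential"):
            doubling_time(GrowthCurve(times=t, od600=np.full_like(t, 0.3)))

    def test_invariant_under_od_scaling(self):
        t = np.arange(0, 720, 60, dtype=float)
        od = 0.1 * 2 ** (t / 200.0)
        a = doubling_time(GrowthCurve(times=t, od600=od))
        b = doubling_time(GrowthCurve(times=t, od600=10 * od))
        assert a == pytest.approx(b, rel=1e-12)

    def test_explicit_window(self):
        t = np.arange(0, 720, 60, dtype=float)
        curve = GrowthCurve(times=t, od600=0.1 * 2 ** (t / 144.0))
        assert doubling_time(curve, window=(120.0, 600.0)) == pytest.approx(144.0, rel=1e-9)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            GrowthCurve(times=np.array([0.0, 60.0, 60.0, 120.0]), od600=np.ones(4))
        with pytest.raises(ValueError, match="4 points"):
            GrowthCurve(times=np.array([0.0, 60.0]), od600=np.array([0.1, 0.2]))


class TestTwoFactorAnova:
    @pytest.fixture
    def balanced_2x2(self) -> CFUToxicityTable:
        return make_table(
            {
                (0.0, 3.0): [10, 12],
                (0.0, 12.0): [14, 16],
                (1.0, 3.0): [20, 22],
                (1.0, 12.0): [30, 32],
            }
        )

    def test_hand_computed_decomposition(self, balanced_2x2):
        """Balanced 2x2 with 2 replicates: SS_conc=338, SS_time=98,
        SS_interaction=18, SS_error=8 (worked out by hand)."""
        res = two_factor_anova(balanced_2x2)
        tab = res.anova_table
        assert tab.loc["C(concentration)", "sum_sq"] == pytest.approx(338.0, rel=1e-9)
        assert tab.loc["C(time_h)", "sum_sq"] == pytest.approx(98.0, rel=1e-9)
        assert tab.loc["C(concentration):C(time_h)", "sum_sq"] == pytest.approx(18.0, rel=1e-9)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(8.0, rel=1e-9)
        assert tab.loc["C(concentration)", "F"] == pytest.approx(169.0, rel=1e-9)
        assert tab["df"].sum() == len(balanced_2x2.data) - 1

    def test_balanced_sums_decompose_total(self, balanced_2x2):
        res = two_factor_anova(balanced_2x2)
        y = balanced_2x2.data["cfu_count"].astype(float)
        ss_total = ((y - y.mean()) ** 2).sum()
        assert res.anova_table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_null_data_rejection_rate_is_nominal(self):
        """With a single common mean, factor effects should only be
        flagged at roughly the nominal 5% rate across seeded repeats."""
        rng = np.random.default_rng(0)
        rejections, n_rep = 0, 40
        for _ in range(n_rep):
            cells = {
                (c, t): rng.poisson(200, 3).tolist()
                for c in (0.0, 1.0) for t in (3.0, 12.0)
            }
            res = two_factor_anova(make_table(cells))
            p = res.anova_table["PR(>F)"].iloc[:3]
            rejections += int((p < 0.05).any())
        # 3 tests per repeat at alpha=0.05 -> family rate ~14%; allow slack
        assert rejections / n_rep < 0.35

    def test_tukey_identical_groups(self):
        table = make_table(
            {
                (0.0, 3.0): [10, 12, 11],
                (1.0, 3.0): [10, 12, 11],
                (0.0, 12.0): [10, 12, 11],
                (1.0, 12.0): [10, 12, 11],
            }
        )
        res = two_factor_anova(table)
        for tab in res.tukey_tables.values():
            assert np.all(tab["p_adj"] > 0.95)

    def test_tukey_adjusted_not_below_unadjusted(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        cells = {
            (c, t): rng.poisson(m, 4).tolist()
            for (c, m) in [(0.0, 300), (1.0, 260), (2.0, 180)]
            for t in (3.0, 12.0)
        }
        table = make_table(cells)
        res = two_factor_anova(table)
        df = table.data
        for t, tab in res.tukey_tables.items():
            sub = df[df["time_h"] == t]
            groups = [g["cfu_count"].to_numpy(float) for _, g in sub.groupby("concentration")]
            dof = sum(len(g) - 1 for g in groups)
            mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / dof
            by_conc = {c: g["cfu_count"] for c, g in sub.groupby("concentration")}
            for _, row in tab.iterrows():
                g1, g2 = by_conc[row["group1"]], by_conc[row["group2"]]
                # unadjusted p from the same pooled variance and df that
                # the studentized-range test uses
                se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
                t_stat = abs(g1.mean() - g2.mean()) / se
                p_raw = 2 * stats.t.sf(t_stat, dof)
                assert row["p_adj"] >= p_raw - 1e-9

    def test_single_level_factor_rejected(self):
        table = make_table({(0.0, 3.0): [10, 12], (1.0, 3.0): [20, 22]})
        with pytest.raises(ValueError, match="levels"):
            two_factor_anova(table)
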