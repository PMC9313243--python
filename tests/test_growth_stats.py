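"""Plate-averaged growth statistics: ANOVA battery and contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qdcoloc.growth_stats import (average_pseudoreplicates,
                                  holm_sidak_adjust, linear_trend_contrast,
                                  one_way_anova, sidak_adjust, two_way_anova)
from qdcoloc.simulate import simulate_growth_table


def plate_table(treatments, genotypes=None, plates=4, seeds=10, noise=1.0,
                rng_seed=0, **kw):
    return average_pseudoreplicates(simulate_growth_table(
        treatments, genotypes, plates, seeds, noise, rng_seed, **kw))


class TestAveraging:
    def test_single_seedling_identity(self):
        df = simulate_growth_table({"a": 0, "b": 1}, seeds_per_plate=1,
                                   noise_sd=1.0, rng_seed=1)
        out = average_pseudoreplicates(df)
        assert np.allclose(sorted(out["value"]), sorted(df["value"]))

    def test_simple_mean(self):
        df = pd.DataFrame({"plate_id": ["p1", "p1"], "treatment": ["a", "a"],
                           "measure_name": ["m", "m"], "value": [2.0, 4.0]})
        assert average_pseudoreplicates(df)["value"].iloc[0] == 3.0

    def test_plate_count_preserved(self):
        df = simulate_growth_table({"a": 0, "b": 1}, plates_per_treatment=4)
        out = average_pseudoreplicates(df)
        assert len(out) == df["plate_id"].nunique()

    def test_grand_mean_preserved_with_balanced_plates(self):
        df = simulate_growth_table({"a": 0, "b": 1}, noise_sd=1.0, rng_seed=2)
        out = average_pseudoreplicates(df)
        assert out["value"].mean() == pytest.approx(df["value"].mean())


class TestAdjustments:
    def test_single_comparison_identity(self):
        assert holm_sidak_adjust([0.04])[0] == pytest.approx(0.04)
        assert sidak_adjust([0.04])[0] == pytest.approx(0.04)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.2, 0.04, 0.7, 0.03])
        assert np.allclose(holm_sidak_adjust(p),
                           multipletests(p, method="holm-sidak")[1])
        assert np.allclose(sidak_adjust(p),
                           multipletests(p, method="sidak")[1])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_adjusted_never_smaller_than_raw_and_monotone(self, p):
        p = np.array(p)
        for adjust in (holm_sidak_adjust, sidak_adjust):
            adj = adjust(p)
            assert (adj >= p - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()


class TestOneWay:
    def test_equal_means_zero_noise_F_zero(self):
        df = plate_table({"a": 0.0, "b": 0.0}, noise=0.0)
        rep = one_way_anova(df)
        assert rep.anova_table["F"].iloc[0] == 0.0
        assert rep.anova_table["p"].iloc[0] == 1.0

    def test_matches_scipy_f_oneway(self):
        df = plate_table({"MSO": 0, "MEL": 2, "RAM": 1}, plates=8,
                         noise=1.0, rng_seed=3, plate_sd=0.5)
        rep = one_way_anova(df)
        groups = [g["value"].to_numpy() for _, g in df.groupby("treatment")]
        F, p = stats.f_oneway(*groups)
        assert rep.anova_table["F"].iloc[0] == pytest.approx(F, rel=1e-8)
        assert rep.anova_table["p"].iloc[0] == pytest.approx(p, rel=1e-8)

    def test_recovers_large_treatment_effect(self):
        df = plate_table({"ctrl": 0.0, "dose": 2.0}, plates=8, noise=1.0,
                         rng_seed=4)
        rep = one_way_anova(df)
        assert rep.anova_table["p"].iloc[0] < 0.01
        assert rep.comparisons["p_adj"].iloc[0] < 0.05

    def test_sum_of_squares_identity(self):
        df = plate_table({"a": 0, "b": 1, "c": 2}, noise=1.0, rng_seed=5)
        rep = one_way_anova(df)
        vals = df["value"].to_numpy()
        ss_total = ((vals - vals.mean()) ** 2).sum()
        assert rep.anova_table["ss"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_absent_group_in_comparison_rejected(self):
        df = plate_table({"a": 0, "b": 1})
        with pytest.raises(ValueError, match="absent"):
            one_way_anova(df, comparisons=[("a", "zz")])

    def test_tukey_alternative_runs(self):
        df = plate_table({"a": 0, "b": 2, "c": 0}, plates=6, noise=1.0,
                         rng_seed=6)
        rep = one_way_anova(df, method="tukey")
        assert len(rep.comparisons) == 3
        assert rep.comparisons["p_adj"].between(0, 1).all()

    def test_deterministic(self):
        df = plate_table({"a": 0, "b": 1}, noise=1.0, rng_seed=7)
        r1, r2 = one_way_anova(df), one_way_anova(df)
        assert r1.comparisons.equals(r2.comparisons)


class TestTwoWay:
    def test_null_genotype_mostly_non_significant(self):
        """With no simulated genotype effect, all per-treatment comparisons
        are non-significant at alpha = 0.05 in >= 90% of replicates."""
        clean = 0
        n_rep = 100
        for i in range(n_rep):
            df = plate_table({"MSO": 0.0, "MEL": 1.0},
                             {"wt": 0.0, "mut": 0.0},
                             plates=4, noise=1.0, rng_seed=1000 + i)
            rep = two_way_anova(df)
            clean += (rep.comparisons["p_adj"] >= 0.05).all()
        assert clean / n_rep >= 0.90

    def test_sidak_single_treatment_identity(self):
        df = plate_table({"MSO": 0.0}, {"wt": 0.0, "mut": 1.0}, plates=4,
                         noise=1.0, rng_seed=8)
        rep = two_way_anova(df, factors=("genotype", "treatment"))
        assert rep.comparisons["p_adj"].iloc[0] == pytest.approx(
            rep.comparisons["p_raw"].iloc[0])

    def test_interaction_pattern_detected_only_where_simulated(self):
        """Mutant blunts the response under MEL/RAM but not MSO/TAS: the
        within-treatment comparison is significant only in those cells."""
        rows = []
        rng = np.random.default_rng(9)
        for treatment in ("MSO", "MEL", "RAM", "TAS"):
            for genotype in ("wt", "mut"):
                eff = 3.0 if (treatment in ("MEL", "RAM") and genotype == "wt") else 0.0
                for p in range(6):
                    rows.append({"plate_id": f"{treatment}_{genotype}_{p}",
                                 "treatment": treatment, "genotype": genotype,
                                 "measure_name": "n_roots",
                                 "value": 10 + eff + rng.normal(0, 0.8)})
        rep = two_way_anova(pd.DataFrame(rows))
        sig = rep.comparisons.set_index("within")["p_adj"] < 0.05
        assert sig["MEL"] and sig["RAM"]
        assert not sig["MSO"] and not sig["TAS"]

    def test_empty_cell_rejected_with_name(self):
        df = plate_table({"a": 0.0, "b": 1.0}, {"wt": 0.0, "mut": 0.0},
                         plates=4, noise=1.0, rng_seed=10)
        df = df[~((df["treatment"] == "b") & (df["genotype"] == "mut"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df)

    def test_type2_table_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = plate_table({"a": 0, "b": 1}, {"wt": 0, "mut": -1},
                         plates=5, noise=1.0, rng_seed=11)
        rep = two_way_anova(df)
        m = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
        aov = sm.stats.anova_lm(m, typ=2)
        assert rep.anova_table["F"].iloc[0] == pytest.approx(
            aov["F"].iloc[0], rel=1e-10)


class TestLinearTrend:
    def test_equal_means_zero_estimate(self):
        df = plate_table({"d0": 0.0, "d1": 0.0, "d2": 0.0}, noise=0.0)
        tr = linear_trend_contrast(df, ["d0", "d1", "d2"])
        assert tr.estimate == 0.0
        assert tr.p_value == 1.0

    def test_integer_centred_coefficients(self):
        df = plate_table({"d0": 0, "d1": 1, "d2": 2, "d3": 3}, noise=1.0,
                         rng_seed=12)
        tr = linear_trend_contrast(df, ["d0", "d1", "d2", "d3"])
        assert list(tr.coefficients.values()) == [-3.0, -1.0, 1.0, 3.0]
        tr3 = linear_trend_contrast(df, ["d0", "d1", "d2"])
        assert list(tr3.coefficients.values()) == [-1.0, 0.0, 1.0]

    def test_dose_series_detected_flat_series_not(self):
        """A melatonin-like dose series (effect linear in rank) shows a
        significant trend; a flat series does not."""
        dose = plate_table({"0": 0.0, "50": 0.8, "100": 1.6, "250": 2.4},
                           plates=4, noise=0.8, rng_seed=13)
        flat = plate_table({"0": 0.0, "1": 0.0, "5": 0.0, "10": 0.0},
                           plates=4, noise=0.8, rng_seed=14)
        doses = ["0", "50", "100", "250"]
        assert linear_trend_contrast(dose, doses).p_value < 0.05
        assert linear_trend_contrast(
            flat, ["0", "1", "5", "10"]).p_value >= 0.05

    def test_vanishing_noise_drives_p_to_zero(self):
        ps = []
        for noise in (1.0, 0.3, 0.05):
            df = plate_table({"d0": 0.0, "d1": 1.0, "d2": 2.0}, plates=4,
                             noise=noise, rng_seed=15)
            ps.append(linear_trend_contrast(df, ["d0", "d1", "d2"]).p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_requires_three_groups(self):
        df = plate_table({"a": 0.0, "b": 1.0}, noise=1.0, rng_seed=16)
        with pytest.raises(ValueError, match=">= 3"):
            linear_trend_contrast(df, ["a", "b"])

    def test_value_and_log_codings(self):
        df = plate_table({"0.1": 0.0, "1": 1.0, "10": 2.0}, noise=0.5,
                         rng_seed=17)
        tr = linear_trend_contrast(df, ["0.1", "1", "10"], coding="log",
                                   dose_values=[0.1, 1.0, 10.0])
        assert abs(sum(tr.coefficients.values())) < 1e-9
        with pytest.raises(ValueError, match="dose value"):
            linear_trend_contrast(df, ["0.1", "1", "10"], coding="value")
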