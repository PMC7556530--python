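"""Equity metrics: hand-checked examples and independent oracles."""

import numpy as np
import pandas as pd
import pytest

import riskequity as req
from riskequity.metrics import (
    anova_r2,
    boxplot_summary,
    compare_groups,
    equity_report,
    npd_fraction,
    targeting,
)


def toy_table(wealth_cdf, died, quintile=None, **extra):
    n = len(wealth_cdf)
    df = pd.DataFrame(
        {
            "birth_id": np.arange(n),
            "wealth_cdf": wealth_cdf,
            "died_u5": died,
            "wealth_quintile": quintile if quintile is not None else np.clip(np.ceil(5 * np.asarray(wealth_cdf)).astype(int), 1, 5),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


def bruteforce_r2(p, groups):
    """Independent one-way ANOVA R^2 in pure python."""
    grand = sum(p) / len(p)
    sst = sum((x - grand) ** 2 for x in p)
    if sst == 0:
        return 0.0
    ssb = 0.0
    for g in set(groups):
        vals = [x for x, gg in zip(p, groups) if gg == g]
        m = sum(vals) / len(vals)
        ssb += len(vals) * (m - grand) ** 2
    return ssb / sst


class TestNpd:
    def test_uniform_deaths_near_point_eight(self):
        rng = np.random.default_rng(0)
        n = 50000
        w = (np.arange(n) + 0.5) / n
        died = rng.uniform(size=n) < 0.1
        table = toy_table(w, died.astype(int))
        assert npd_fraction(table) == pytest.approx(0.8, abs=0.02)

    def test_all_deaths_poorest_quintile(self):
        table = toy_table([0.1] * 5 + [0.9] * 5, [1] * 5 + [0] * 5)
        assert npd_fraction(table) == 0.0

    def test_counting_example(self):
        # 2 deaths in quintile 1, 3 in quintiles 2-5 -> 3/5
        w = [0.1, 0.1, 0.3, 0.5, 0.7, 0.9, 0.1, 0.3, 0.5, 0.9]
        died = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        assert npd_fraction(toy_table(w, died)) == pytest.approx(0.6)

    def test_zero_deaths_flagged_missing(self):
        assert np.isnan(npd_fraction(toy_table([0.1, 0.9], [0, 0])))


class TestAnovaR2:
    def test_fully_separated_groups(self):
        res = anova_r2(np.array([[0.1, 0.1, 0.3, 0.3]]), ["A", "A", "B", "B"])
        assert res.r2_draws[0] == pytest.approx(1.0)

    def test_identical_group_means(self):
        res = anova_r2(np.array([[0.1, 0.3, 0.1, 0.3]]), ["A", "A", "B", "B"])
        assert res.r2_draws[0] == pytest.approx(0.0)

    def test_hand_computed_point_eight(self):
        # SS_between 0.04 / SS_total 0.05
        res = anova_r2(np.array([[0.1, 0.2, 0.3, 0.4]]), ["A", "A", "B", "B"])
        assert res.r2_draws[0] == pytest.approx(0.8, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Exact agreement with an independent oracle, draw by draw."""
        for _ in range(20):
            n = int(rng.integers(4, 21))
            S = int(rng.integers(1, 6))
            P = rng.uniform(0.01, 0.99, size=(S, n))
            groups = rng.integers(0, 3, size=n).astype(str)
            if len(set(groups)) < 2:
                continue
            res = anova_r2(P, groups)
            for s in range(S):
                assert res.r2_draws[s] == pytest.approx(bruteforce_r2(list(P[s]), list(groups)), abs=1e-12)

    def test_single_group_zero_with_warning(self):
        res = anova_r2(np.array([[0.1, 0.2]]), ["A", "A"])
        assert res.mean == 0.0

    def test_constant_draw_gives_zero(self):
        res = anova_r2(np.array([[0.2, 0.2, 0.2, 0.2]]), ["A", "A", "B", "B"])
        assert res.r2_draws[0] == 0.0

    def test_logit_scale_variant(self):
        """Logit-scale decomposition agrees with brute force on log-odds."""
        from scipy.special import logit as slogit

        P = np.array([[0.1, 0.2, 0.3, 0.4]])
        res = anova_r2(P, ["A", "A", "B", "B"], scale="logit")
        expected = bruteforce_r2(list(slogit(P[0])), ["A", "A", "B", "B"])
        assert res.r2_draws[0] == pytest.approx(expected, abs=1e-12)
        with pytest.raises(ValueError):
            anova_r2(P, ["A", "A", "B", "B"], scale="nope")

    def test_interval_ordered_within_unit(self, rng):
        P = rng.uniform(0.05, 0.95, size=(50, 12))
        res = anova_r2(P, ["A"] * 6 + ["B"] * 6)
        lo, hi = res.interval
        assert 0 <= lo <= res.mean <= hi <= 1


class TestBoxplotSummary:
    def test_single_value_collapses(self):
        out = boxplot_summary([0.2, 0.5], ["A", "B"])
        assert (out.loc["A"] == 0.2).all() and (out.loc["B"] == 0.5).all()

    def test_one_to_hundred(self):
        vals = np.arange(1.0, 101.0)
        out = boxplot_summary(vals, ["g"] * 100)
        assert out.loc["g", "median"] == pytest.approx(50.5)
        assert out.loc["g", "q1"] == pytest.approx(np.percentile(vals, 25))
        assert out.loc["g", "whisker_low"] >= vals.min()
        assert out.loc["g", "whisker_high"] <= vals.max()

    def test_outlier_does_not_stretch_whiskers(self):
        vals = np.concatenate([np.arange(1.0, 101.0), [10000.0]])
        out = boxplot_summary(vals, ["g"] * 101)
        base = boxplot_summary(np.arange(1.0, 101.0), ["g"] * 100)
        assert out.loc["g", "whisker_high"] == base.loc["g", "whisker_high"]


class TestTargeting:
    def test_identical_rankings_zero_gain(self):
        w = np.linspace(0.05, 0.95, 10)
        risk = 1 - w  # poorest exactly the riskiest
        died = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        res = targeting(risk[None, :], toy_table(w, died), q=0.2)
        assert res.efficiency_gain_draws[0] == pytest.approx(0.0)

    def test_worked_gain_of_100_percent(self):
        # top-2 risk births both die (HR = 1.0); poorest 2 contain 1 death (0.5)
        w = np.array([0.05, 0.1, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
        died = np.array([1, 0, 1, 1, 0, 0, 0, 0, 0, 0])
        risk = np.array([0.5, 0.1, 0.9, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        res = targeting(risk[None, :], toy_table(w, died), q=0.2)
        assert res.mortality_poor == pytest.approx(0.5)
        assert res.mortality_highrisk_draws[0] == pytest.approx(1.0)
        assert res.efficiency_gain_draws[0] == pytest.approx(100.0)

    def test_gain_invariant_to_monotone_transform_of_risk(self, rng):
        w = rng.uniform(size=50)
        died = (rng.uniform(size=50) < 0.3).astype(int)
        P = rng.uniform(0.01, 0.6, size=(20, 50))
        base = targeting(P, toy_table(w, died))
        warped = targeting(P**3 / (P**3 + (1 - P) ** 3), toy_table(w, died))
        assert np.allclose(base.efficiency_gain_draws, warped.efficiency_gain_draws)

    def test_true_risk_targeting_beats_every_other_subset(self):
        """Exhaustive check on a 12-birth instance: the top-q true-risk set
        has the highest expected death count of all size-k subsets."""
        from itertools import combinations

        rng = np.random.default_rng(99)
        p = rng.uniform(0.02, 0.6, size=12)
        table = toy_table(rng.uniform(size=12), np.zeros(12, dtype=int))
        k = 2  # floor(0.2 * 12)
        res = targeting(p[None, :], table.assign(died_u5=0), q=0.2)
        top = np.argsort(-p)[:k]
        best = p[top].sum()
        for subset in combinations(range(12), k):
            assert p[list(subset)].sum() <= best + 1e-12
        assert res.n_targeted == k

    def test_zero_poor_deaths_flagged(self):
        w = np.linspace(0.05, 0.95, 10)
        died = [0, 0, 0, 0, 0, 0, 0, 0, 1, 1]
        res = targeting(np.full((1, 10), 0.1), toy_table(w, died))
        assert not res.gain_defined and np.isnan(res.efficiency_gain_mean)


class TestCompareGroups:
    def test_worked_odds_ratio_of_nine(self):
        # 8 births, top-4 risk: prevalence 3/4 vs 1/4 -> OR (3*3)/(1*1) = 9
        risk = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1])
        urban = ["urban", "urban", "urban", "rural", "urban", "rural", "rural", "rural"]
        table = toy_table(np.linspace(0.1, 0.9, 8), [0] * 8, urban=urban)
        res = compare_groups(risk[None, :], table, q=0.5)
        assert res.draws["urban"][0] == pytest.approx(9.0)

    def test_independent_covariate_interval_contains_null(self, rng):
        n = 400
        P = rng.uniform(0.05, 0.5, size=(100, n))
        sexes = np.where(rng.uniform(size=n) < 0.5, "male", "female")
        table = toy_table(rng.uniform(size=n), np.zeros(n, dtype=int), sex=sexes)
        res = compare_groups(P, table)
        lo, hi = res.table.loc["sex", ["lower", "upper"]]
        assert lo < 1 < hi and not res.table.loc["sex", "significant"]

    def test_gradient_scenario_high_risk_group_is_poorer(self, gradient_data):
        _, dataset, truth, table = gradient_data
        pt = truth.table.set_index("birth_id").loc[table["birth_id"], "p_true"].to_numpy()
        res = compare_groups(pt[None, :], table)
        assert res.table.loc["wealth_cdf", "mean"] < 0

    def test_constant_covariate_skipped(self):
        table = toy_table(np.linspace(0.1, 0.9, 8), [0] * 8, urban=["rural"] * 8)
        res = compare_groups(np.linspace(0.1, 0.8, 8)[None, :], table, q=0.5)
        assert "urban" not in res.table.index


class TestEquityScenarioInvariant:
    def test_equity_scenario_npd_and_wealth_r2_near_null(self):
        """Under perfect equity the NPD sits at its 80% benchmark and the
        fitted wealth-quintile R^2 interval reaches below 0.02."""
        from riskequity.design import ModelSpec, build_design
        from riskequity.model import posterior_risk, sample_model

        dataset, _ = req.generate_survey(req.equity_scenario(n_mothers=10500, seed=31, heterogeneous=True))
        table, _ = req.build_analysis_table(dataset.births)
        npd = npd_fraction(table)
        deaths = int(table["died_u5"].sum())
        assert abs(npd - 0.8) <= 2.576 * np.sqrt(0.8 * 0.2 / deaths)
        spec = ModelSpec(
            continuous_covariates=("maternal_age", "wealth_cdf", "birth_order"),
            binary_covariates=("sex", "prior_death"),
            spline_knots={"wealth_cdf": (0.2, 0.4, 0.6, 0.8), "maternal_age": (), "birth_order": ()},
            max_interaction_order=1, cluster_effect=True,
            chains=2, warmup=300, draws_total=400, seed=32,
        )
        d = build_design(table, spec)
        draws, _ = sample_model(d, table["died_u5"].to_numpy(), spec)
        res = anova_r2(posterior_risk(draws, d), table["wealth_quintile"].to_numpy())
        assert res.interval[0] < 0.02


class TestEquityReport:
    def test_report_assembles_and_serializes(self, small_fit, tmp_path):
        model, table = small_fit
        post = model.predict_risk()
        report = equity_report(post, table)
        frame = report.to_frame()
        assert "npd" in frame.index and "efficiency_gain_pct" in frame.index
        payload = report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
        assert set(payload) >= {"npd", "anova_r2", "targeting", "comparison"}
        assert 0 <= payload["npd"] <= 1


def test_boxplot_figure_renders(tmp_path, rng):
    from riskequity.plotting import plot_risk_boxplots

    values = rng.uniform(0.01, 0.3, 200)
    groups = rng.integers(1, 6, 200)
    fig = plot_risk_boxplots(values, groups, path=tmp_path / "box.png")
    assert (tmp_path / "box.png").exists()
    import matplotlib.pyplot as plt

    plt.close(fig)
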