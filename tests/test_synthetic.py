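import dataclasses
import itertools

import numpy as np
import pytest

from cmburden.patterns import TYPE_NAMES, pattern_codes
from cmburden.synthetic import (
    OutcomeSpec,
    SimulationConfig,
    exact_pattern_probs,
    export_ground_truth,
    simulate_burden_table,
    simulate_exposures,
    simulate_microdata,
    simulate_outcomes,
)

from conftest import no_exposure_confounders


def _pairwise_log_or(exp: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Empirical log odds ratio and its Woolf standard error."""
    a = float(((exp[:, i] == 1) & (exp[:, j] == 1)).sum())
    b = float(((exp[:, i] == 1) & (exp[:, j] == 0)).sum())
    c = float(((exp[:, i] == 0) & (exp[:, j] == 1)).sum())
    d = float(((exp[:, i] == 0) & (exp[:, j] == 0)).sum())
    return np.log(a * d / (b * c)), np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


class TestExposures:
    def test_determinism(self, flat_config):
        cfg = dataclasses.replace(flat_config, n_respondents=2000)
        assert simulate_exposures(cfg, 9).equals(simulate_exposures(cfg, 9))
        assert not simulate_exposures(cfg, 9).equals(simulate_exposures(cfg, 10))

    def test_independence_config_gives_unit_odds_ratios(self, flat_config):
        md = simulate_exposures(flat_config, seed=1)
        exp = md[list(TYPE_NAMES)].to_numpy()
        for i, j in itertools.combinations(range(5), 2):
            lor, se = _pairwise_log_or(exp, i, j)
            assert abs(lor) < 3.5 * se, f"pair {i},{j}: log OR {lor:.3f} (SE {se:.3f})"

    def test_positive_pairwise_term_raises_odds_ratio(self):
        lam = [0.0] * 10
        lam[8] = 0.8  # (EA, EDV) pair
        cfg = SimulationConfig(
            n_respondents=50000,
            pairwise_log_odds=tuple(lam),
            age_log_coef=0.0,
            age_sq_coef=0.0,
            confounders=no_exposure_confounders(),
        )
        md = simulate_exposures(cfg, seed=2)
        exp = md[list(TYPE_NAMES)].to_numpy()
        lor, se = _pairwise_log_or(exp, 2, 4)
        assert lor > 3 * se

    def test_empirical_cells_converge_to_exact_probabilities(self, default_config):
        cfg = dataclasses.replace(default_config, n_respondents=200000)
        md = simulate_exposures(cfg, seed=3)
        codes = md[list(TYPE_NAMES)].astype(str).agg("".join, axis=1)
        emp = codes.value_counts(normalize=True).reindex(pattern_codes()).fillna(0.0)
        probs = exact_pattern_probs(cfg)
        # population-level truth: weight strata by gender split and by the
        # number of survey ages each 5-year band contains
        from cmburden.agegroups import group_ages

        n_ages_total = cfg.age_range[1] - cfg.age_range[0] + 1
        gshare = {"women": cfg.prop_female, "men": 1 - cfg.prop_female}
        pop = np.zeros(32)
        for (g, grp), chunk in probs.groupby(["gender", "age_group"], sort=False):
            w = gshare[g] * len(group_ages(grp, *cfg.age_range)) / n_ages_total
            pop += w * chunk.set_index("pattern").loc[pattern_codes(), "proportion"].to_numpy()
        tv = 0.5 * np.abs(emp.to_numpy() - pop).sum()
        assert tv < 0.01

    def test_study_condition_prevalence(self, md20k):
        """Any-maltreatment and multi-type prevalence land in the study range."""
        exp = md20k[list(TYPE_NAMES)]
        n_types = exp.sum(axis=1)
        for gender, lo, hi in [("women", 0.63, 0.70), ("men", 0.56, 0.63)]:
            assert lo < (n_types[md20k.gender == gender] > 0).mean() < hi
        assert 0.35 < (n_types >= 2).mean() < 0.44


class TestOutcomes:
    def test_null_model_prevalence_matches_baseline(self):
        cfg = SimulationConfig(
            n_respondents=50000,
            outcomes=(OutcomeSpec("mdd", 0.10, (1.0,) * 6),),
            confounders=(),
        )
        md = simulate_microdata(cfg, seed=4)
        n_types = md[list(TYPE_NAMES)].sum(axis=1)
        for lvl in range(5):
            grp = md.loc[n_types == lvl, "mdd"]
            se = np.sqrt(0.1 * 0.9 / len(grp))
            assert abs(grp.mean() - 0.10) < 4 * se

    def test_dose_response_risk_ratio_recovered(self):
        cfg = SimulationConfig(
            n_respondents=100000,
            outcomes=(OutcomeSpec("mdd", 0.05, (1, 1, 1, 1, 1, 10.0)),),
            confounders=(),
        )
        md = simulate_microdata(cfg, seed=5)
        n_types = md[list(TYPE_NAMES)].sum(axis=1)
        r5 = md.loc[n_types == 5, "mdd"].mean()
        r0 = md.loc[n_types == 0, "mdd"].mean()
        assert 8.5 < r5 / r0 < 11.5

    def test_probability_cap_warns(self):
        cfg = SimulationConfig(
            n_respondents=5000,
            outcomes=(OutcomeSpec("mdd", 0.5, (1, 1, 1, 1, 1, 10.0)),),
            confounders=(),
        )
        exp = simulate_exposures(cfg, seed=6)
        with pytest.warns(UserWarning, match="capped"):
            simulate_outcomes(exp, cfg, seed=7)

    def test_missing_exposures_rejected(self, default_config):
        import pandas as pd

        with pytest.raises(ValueError, match="exposure columns"):
            simulate_outcomes(pd.DataFrame({"gender": ["women"]}), default_config, 1)


class TestBurdenTable:
    def test_daly_identity_and_determinism(self, default_config):
        bt = simulate_burden_table(default_config, seed=8)
        assert np.allclose(bt["daly"], bt["yll"] + bt["yld"])
        assert (bt[["deaths", "yll", "yld", "daly"]] >= 0).all().all()
        assert bt.equals(simulate_burden_table(default_config, seed=8))

    def test_nonfatal_causes_have_no_mortality(self, default_config):
        bt = simulate_burden_table(default_config, seed=8)
        anx = bt[bt["cause"].isin(["anxiety_total", "mdd"])]
        assert (anx["deaths"] == 0).all() and (anx["yll"] == 0).all()

    def test_smoking_rows_flagged_attributable(self, default_config):
        bt = simulate_burden_table(default_config, seed=8)
        assert (bt.loc[bt["cause"] == "smoking_attributable", "burden_type"] == "attributable").all()
        assert (bt.loc[bt["cause"] == "mdd", "burden_type"] == "total").all()


class TestGroundTruth:
    def test_independence_cells_are_product_of_marginals(self, flat_config):
        probs = exact_pattern_probs(flat_config)
        m = np.asarray(flat_config.marginal_prevalence)
        chunk = probs[(probs.gender == "women") & (probs.age_group == "40–44")]
        p = chunk.set_index("pattern").loc[pattern_codes(), "proportion"].to_numpy()
        X = np.array([[int(c) for c in code] for code in pattern_codes()])
        expected = np.prod(np.where(X == 1, m, 1 - m), axis=1)
        assert np.allclose(p, expected, atol=1e-12)

    def test_null_rr_gives_zero_paf_everywhere(self):
        cfg = SimulationConfig(outcomes=(OutcomeSpec("mdd", 0.1, (1.0,) * 6),))
        gt = export_ground_truth(cfg)
        assert np.allclose(gt.true_paf["paf"], 0.0)

    def test_truth_paf_matches_arithmetic_oracle(self, default_config):
        gt = export_ground_truth(default_config)
        probs = gt.pattern_probs
        chunk = probs[(probs.gender == "men") & (probs.age_group == "30–34")]
        p = chunk.set_index("pattern").loc[pattern_codes(), "proportion"].to_numpy()
        spec = default_config.outcome("ptsd")
        n_types = np.array([c.count("1") for c in pattern_codes()])
        rr = spec.rr("men")[n_types]
        # independent arithmetic: sum p(RR-1) / (1 + sum p(RR-1))
        excess = float(np.sum(p * (rr - 1)))
        expected = excess / (1 + excess)
        got = gt.true_paf.query(
            "outcome=='ptsd' and gender=='men' and age_group=='30–34'"
        )["paf"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_stratum_distributions_sum_to_one(self, default_config):
        probs = exact_pattern_probs(default_config)
        sums = probs.groupby(["gender", "age_group"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_respondents": 0},
            {"marginal_prevalence": (0.5, 0.5, 0.5, 0.5, 1.1)},
            {"pairwise_log_odds": (np.inf,) * 10},
            {"weight_mode": "other"},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_reference_rr_must_be_one(self):
        with pytest.raises(ValueError, match="reference RR"):
            SimulationConfig(outcomes=(OutcomeSpec("mdd", 0.1, (2, 2, 2, 2, 2, 2)),))
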