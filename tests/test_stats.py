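import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import moralcomp as mc
from moralcomp.simulate import EmotionGenSpec


@pytest.fixture(autouse=True)
def _quiet_mixedlm():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def noise_free_emotions(design, n=8, **kw):
    spec_kw = dict(intercept_sd=0.0, slope_sd=0.0, resid_sd=0.0, discretize=False)
    spec_kw.update(kw)
    return mc.generate_emotions(design, EmotionGenSpec(**spec_kw), n, seed=0).ratings


class TestManipulationCheck:
    def test_identical_ratings_give_zero_f(self):
        df = pd.DataFrame(
            dict(participant_id=list("abcd") * 2, level=[1] * 4 + [2] * 4, rating=5.0)
        )
        out = mc.manipulation_check(df, level_col="level")
        assert out.F.iloc[0] == 0.0
        assert out.partial_eta_sq.iloc[0] == 0.0

    def test_two_level_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(4, 1, 20), rng.normal(5, 1, 20)
        df = pd.DataFrame(
            dict(
                participant_id=[f"p{i}" for i in range(20)] * 2,
                level=[1] * 20 + [2] * 20,
                rating=np.concatenate([a, b]),
            )
        )
        out = mc.manipulation_check(df, level_col="level")
        t = sps.ttest_rel(b, a)
        assert out.F.iloc[0] == pytest.approx(t.statistic**2)
        assert out.p.iloc[0] == pytest.approx(t.pvalue)
        assert out.df1.iloc[0] == 1 and out.df2.iloc[0] == 19

    def test_missing_cells_identify_participants(self):
        df = pd.DataFrame(
            dict(participant_id=["a", "a", "b"], level=[1, 2, 1], rating=[1.0, 2.0, 3.0])
        )
        with pytest.raises(ValueError, match="b"):
            mc.manipulation_check(df, level_col="level")


class TestEmotionRegression:
    def test_noise_free_interaction_is_exact(self, design):
        # continuous noise-free ratings: guilt - shame harm-slope difference
        # equals the generating 0.74 - 0.23 = 0.51 exactly
        emotions = noise_free_emotions(design)
        er = mc.emotion_regression(emotions, "harm")
        assert er.fallback == "ols"
        assert er.interaction["estimate"] == pytest.approx(0.51, abs=1e-8)
        assert er.simple_slopes.loc["guilt", "slope"] == pytest.approx(0.74, abs=1e-8)
        assert er.simple_slopes.loc["shame", "slope"] == pytest.approx(0.23, abs=1e-8)
        er_r = mc.emotion_regression(emotions, "responsibility")
        assert er_r.interaction["estimate"] == pytest.approx(0.57 - 0.93, abs=1e-8)

    def test_coding_flip_reverses_interaction_sign(self, design):
        emotions = mc.generate_emotions(design, EmotionGenSpec(), 15, seed=4).ratings
        er = mc.emotion_regression(emotions, "harm")
        swapped = emotions.rename(columns={"guilt": "shame", "shame": "guilt"})
        er_sw = mc.emotion_regression(swapped, "harm")
        assert np.sign(er.interaction["estimate"]) == -np.sign(er_sw.interaction["estimate"])

    def test_noisy_cohort_recovers_interactions(self, design):
        emotions = mc.generate_emotions(design, EmotionGenSpec(), 40, seed=5).ratings
        harm = mc.emotion_regression(emotions, "harm")
        resp = mc.emotion_regression(emotions, "responsibility")
        assert harm.interaction["estimate"] == pytest.approx(0.51, abs=0.25)
        assert harm.interaction["p"] < 0.01
        assert resp.interaction["estimate"] == pytest.approx(-0.36, abs=0.25)

    def test_full_three_way_model(self, design):
        emotions = mc.generate_emotions(design, EmotionGenSpec(), 25, seed=6).ratings
        er = mc.emotion_regression(emotions, "full")
        assert set(er.interaction) == {"harm_x_type", "responsibility_x_type"}
        assert np.sign(er.interaction["harm_x_type"]["estimate"]) > 0
        assert np.sign(er.interaction["responsibility_x_type"]["estimate"]) < 0

    def test_null_interaction_ci_coverage(self, design):
        """Zero-slope generator: the interaction's 95% CI covers zero at
        roughly the nominal rate (reduced replicates)."""
        spec = EmotionGenSpec(
            guilt_harm_slope=0.0, shame_harm_slope=0.0,
            guilt_resp_slope=0.0, shame_resp_slope=0.0,
            guilt_intercept=5.0, shame_intercept=5.0, slope_sd=0.0,
        )
        cover = 0
        reps = 40
        for i in range(reps):
            emotions = mc.generate_emotions(design, spec, 30, seed=100 + i).ratings
            er = mc.emotion_regression(emotions, "harm")
            est, se = er.interaction["estimate"], er.interaction["se"]
            cover += abs(est) <= 1.96 * se
        assert cover / reps >= 0.85


class TestCompensationRegression:
    def test_winner_is_guilt_plus_shame_in_majority(self, design):
        wins = 0
        for seed in range(100, 107):
            ds = mc.generate_dataset(n_participants=40, seed=seed, emotion_mediated=True)
            comp = mc.compensation_regression(mc.merge_emotions(ds.trials, ds.emotions))
            wins += comp.winner == "III"
        assert wins >= 4  # majority of 7 replicate cohorts

    def test_zero_shame_weight_rejected_by_wald(self, design):
        from moralcomp.simulate import EmotionAgentSpec, generate_decisions_from_emotions

        ds = mc.generate_dataset(n_participants=40, seed=200, emotion_mediated=True)
        agent = EmotionAgentSpec(shame_weight=0.0, shame_weight_sd=0.0)
        trials = generate_decisions_from_emotions(
            ds.trials.drop(columns="decision").assign(decision=pd.NA),
            ds.emotions, agent, seed=201,
        )
        comp = mc.compensation_regression(mc.merge_emotions(trials, ds.emotions))
        assert comp.wald_p < 0.05

    def test_identical_columns_give_zero_wald(self, design):
        ds = mc.generate_dataset(n_participants=10, seed=55, emotion_mediated=True)
        data = mc.merge_emotions(ds.trials, ds.emotions)
        data["shame"] = data["guilt"]
        comp = mc.compensation_regression(data)
        assert comp.wald_chi2 == pytest.approx(0.0, abs=1e-6)

    def test_coefficients_near_generating_weights(self, design):
        ds = mc.generate_dataset(n_participants=40, seed=102, emotion_mediated=True)
        comp = mc.compensation_regression(mc.merge_emotions(ds.trials, ds.emotions))
        coef = comp.results["III"]
        est = coef.fe_params if hasattr(coef, "fe_params") else coef.params
        assert est["guilt"] == pytest.approx(0.22, abs=0.08)
        assert est["shame"] == pytest.approx(0.10, abs=0.08)


class TestExtractSensitivities:
    def test_noise_free_equals_common_slopes(self, design):
        emotions = noise_free_emotions(design)
        harm = mc.emotion_regression(emotions, "harm")
        resp = mc.emotion_regression(emotions, "responsibility")
        # noise-free compensation: decision = 1 + 0.3*guilt + 0.2*shame exactly
        trials = mc.build_schedules(design, 8, seed=0)
        data = trials[trials.condition == "self_error"].merge(
            emotions, on=["participant_id", "harm", "responsibility"]
        )
        data["decision"] = 1 + 0.3 * data.guilt + 0.2 * data.shame
        comp = mc.compensation_regression(data)
        sens = mc.extract_sensitivities(harm, resp, comp)
        assert np.allclose(sens["harm_guilt"], 0.74, atol=1e-6)
        assert np.allclose(sens["harm_shame"], 0.23, atol=1e-6)
        assert np.allclose(sens["resp_guilt"], 0.57, atol=1e-6)
        assert np.allclose(sens["guilt_comp"], 0.3, atol=1e-6)
        assert np.allclose(sens["shame_comp"], 0.2, atol=1e-6)

    def test_heterogeneous_cohort_recovery(self, design):
        ds = mc.generate_dataset(n_participants=40, seed=67, emotion_mediated=True)
        truth = pd.DataFrame(ds.truth["emotion_truth"]).set_index("participant_id")
        harm = mc.emotion_regression(ds.emotions, "harm")
        resp = mc.emotion_regression(ds.emotions, "responsibility")
        comp = mc.compensation_regression(mc.merge_emotions(ds.trials, ds.emotions))
        sens = mc.extract_sensitivities(harm, resp, comp)
        pairs = [
            ("harm_guilt", "guilt_harm_slope"),
            ("harm_shame", "shame_harm_slope"),
            ("resp_guilt", "guilt_resp_slope"),
            ("resp_shame", "shame_resp_slope"),
        ]
        rs = [
            np.corrcoef(truth[t], sens[c].reindex(truth.index))[0, 1] for c, t in pairs
        ]
        assert min(rs) >= 0.7
        assert np.mean(rs) >= 0.8

    def test_kappa_tracks_emotion_driven_sensitivity(self, design):
        # emotion-generated decisions: compensatory sensitivity kappa
        # correlates positively with the guilt-to-compensation coupling
        rs = []
        for seed in (66, 67):
            ds = mc.generate_dataset(n_participants=40, seed=seed, emotion_mediated=True)
            harm = mc.emotion_regression(ds.emotions, "harm")
            resp = mc.emotion_regression(ds.emotions, "responsibility")
            comp = mc.compensation_regression(mc.merge_emotions(ds.trials, ds.emotions))
            sens = mc.extract_sensitivities(harm, resp, comp)
            kappa = mc.CompensationChoiceModel(ds.trials, "1.3").fit().params["kappa"]
            rs.append(np.corrcoef(kappa, sens["guilt_comp"].reindex(kappa.index))[0, 1])
        assert np.mean(rs) > 0.1
        assert min(rs) > 0.0


class TestDependentCorrelationTest:
    def test_equal_correlations_give_zero(self):
        z, p = mc.dependent_correlation_test(0.4, 0.4, 0.3, 50)
        assert z == 0.0 and p == 1.0

    def test_sign_symmetry(self):
        z1, _ = mc.dependent_correlation_test(0.6, 0.3, 0.2, 40)
        z2, _ = mc.dependent_correlation_test(0.3, 0.6, 0.2, 40)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mc.dependent_correlation_test(1.0, 0.3, 0.2, 40)
        with pytest.raises(ValueError):
            mc.dependent_correlation_test(0.5, 0.3, 0.2, 3)


class TestBootstrapMediation:
    def test_full_collinear_mediation(self):
        x = np.random.default_rng(0).normal(size=50)
        res = mc.bootstrap_mediation(x, x, x, n_boot=500, seed=1)
        assert res.indirect == pytest.approx(res.c_total)
        assert res.significant
        assert res.ci[0] > 0

    def test_permuting_outcome_breaks_significance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        m = 0.8 * x + 0.3 * rng.normal(size=80)
        y = 0.8 * m + 0.3 * rng.normal(size=80)
        res = mc.bootstrap_mediation(x, m, y, n_boot=1000, seed=2)
        assert res.significant
        y_perm = rng.permutation(y)
        res_perm = mc.bootstrap_mediation(x, m, y_perm, n_boot=1000, seed=3)
        assert not res_perm.significant

    def test_input_validation(self):
        x = np.arange(12, dtype=float)
        with pytest.raises(ValueError):
            mc.bootstrap_mediation(x, x, np.full(12, 3.0))  # zero variance
        with pytest.raises(ValueError):
            mc.bootstrap_mediation(x[:5], x[:5], x[:5])  # too short
        with pytest.raises(ValueError):
            mc.bootstrap_mediation(x, x[:5], x)  # length mismatch


class TestTraitCorrelations:
    def test_trait_equal_to_compensation(self):
        comp = pd.Series(
            np.linspace(1, 8, 12), index=[f"p{i}" for i in range(12)]
        )
        traits = pd.DataFrame({"mirror": comp, "flat": 3.0})
        out = mc.trait_correlations(traits, comp)
        assert out.loc["mirror", "r"] == pytest.approx(1.0)
        assert out.loc["mirror", "p"] < 1e-6
        assert not out.loc["flat", "defined"]

    def test_coupled_trait_detected(self, design):
        ds = mc.generate_dataset(n_participants=42, seed=9)
        comp = (
            ds.trials[ds.trials.condition == "self_error"]
            .groupby("participant_id").decision.mean().astype(float)
        )
        traits = mc.generate_traits(42, seed=10, couple_to=comp, coupling=1.0,
                                    participant_ids=list(comp.index))
        out = mc.trait_correlations(traits, comp)
        assert out.loc["guilt_repair_action", "r"] > 0.5
        assert out.loc["guilt_repair_action", "p"] < 0.001
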