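"""Stimulus coding, behavioral rules, mixed models, contrasts, FDR, BF."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from multiword import design as dz
from multiword import simulate as sim
from multiword import stats as st
from multiword.design import Condition, Location, TrialSpec, WordPlacement


def _trial(condition, words, fillers=(90, 91, 92, 93, 94, 95)):
    n = 6 - len(words)
    return TrialSpec(run_index=1, trial_index=1, condition=condition,
                     words=words, filler_word_ids=fillers[:n])


LEXICON = {0: "about", 1: "table", 2: "light",
           90: "plant", 91: "mouse", 92: "grape", 93: "chair",
           94: "bread", 95: "cloud"}


class TestStimulusCoding:
    def test_two_word_concatenation(self):
        t = _trial(Condition.TWO_SEQ,
                   (WordPlacement(0, 1, Location.TOP),
                    WordPlacement(1, 2, Location.BOTTOM)))
        assert st.code_stimulus_id(t, LEXICON) == "abouttable"

    def test_simultaneous_top_then_bottom(self):
        t = _trial(Condition.TWO_SIM,
                   (WordPlacement(1, 1, Location.TOP),
                    WordPlacement(0, 1, Location.BOTTOM)))
        assert st.code_stimulus_id(t, LEXICON) == "tableabout"

    def test_one_word(self):
        t = _trial(Condition.ONE, (WordPlacement(2, 2, Location.TOP),))
        assert st.code_stimulus_id(t, LEXICON) == "light"

    def test_zero_word_ff_suffix_from_early_frames(self):
        t = _trial(Condition.ZERO, ())
        rng = np.random.default_rng(0)
        code = st.code_stimulus_id(t, LEXICON, rng)
        assert code.endswith("_ff")
        # sampled from the four fillers placed in frames 1-2
        early = {LEXICON[i] for i in t.filler_word_ids[:4]}
        assert code[:-3] in early

    def test_missing_word_errors(self):
        t = _trial(Condition.ONE, (WordPlacement(999, 1, Location.TOP),))
        with pytest.raises(KeyError):
            st.code_stimulus_id(t, LEXICON)


class TestAccuracy:
    def _responses(self, session, response, button=1200.0):
        ddf = session.to_frame()
        return pd.DataFrame(
            {"subject": 1, "run": ddf["run"], "trial": ddf["trial"],
             "response": response, "button_time_ms": button}
        )

    def test_correct_two_sim_report(self, small_session):
        resp = self._responses(small_session, 2)
        out = st.compute_accuracy(resp, small_session)
        two = out[out["condition"] == "TWO_SIM"]
        assert (two["correct"] == 1).all()
        assert (out.loc[out["condition"] == "ZERO", "correct"] == 0).all()

    def test_late_button_is_no_response(self, small_session):
        resp = self._responses(small_session, 2, button=4301.0)
        out = st.compute_accuracy(resp, small_session)
        assert out["no_response"].all()
        assert out["correct"].isna().all()
        at_limit = st.compute_accuracy(
            self._responses(small_session, 2, button=4300.0), small_session
        )
        assert not at_limit["no_response"].any()

    def test_invalid_response_code_rejected(self, small_session):
        resp = self._responses(small_session, 5)
        with pytest.raises(ValueError):
            st.compute_accuracy(resp, small_session)

    def test_generator_accuracy_recovered(self, small_word_list,
                                          small_session):
        # known 85% accuracy in every condition, ~2000 trials
        preset = sim.BehaviorGeneratorPreset(
            accuracy={c.value: 0.85 for c in Condition}, no_response_p=0.0
        )
        frames = []
        for s in range(16):
            beh = sim.gen_behavior(preset, small_session, seed=400 + s,
                                   subject=s)
            frames.append(st.compute_accuracy(beh, small_session))
        acc = pd.concat(frames)["correct"]
        n = acc.notna().sum()
        p_hat = acc.mean()
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(p_hat - 0.85) <= 1.96 * se


class TestResponseTimes:
    def test_exclusion_rules(self, small_session):
        ddf = small_session.to_frame()
        resp = pd.DataFrame(
            {"subject": 1, "run": ddf["run"], "trial": ddf["trial"],
             "response": ddf["condition"].map(
                 {c.value: c.n_words for c in Condition}),
             "button_time_ms": 1233.0}
        )
        out = st.rt_from_critical_frame(
            st.compute_accuracy(resp, small_session), small_session
        )
        sim_f1 = (out["condition"] == "TWO_SIM") & (out["word1_frame"] == 1)
        one_f1 = (out["condition"] == "ONE") & (out["word1_frame"] == 1)
        assert out.loc[sim_f1, "rt_excluded"].all()
        assert out.loc[one_f1, "rt_excluded"].all()
        assert not out.loc[out["condition"] == "TWO_SEQ",
                           "rt_excluded"].any()
        assert not out.loc[out["condition"] == "ZERO", "rt_excluded"].any()

    def test_rt_measured_from_frame_two_onset(self, small_session):
        ddf = small_session.to_frame()
        resp = pd.DataFrame(
            {"subject": 1, "run": ddf["run"], "trial": ddf["trial"],
             "response": ddf["condition"].map(
                 {c.value: c.n_words for c in Condition}),
             "button_time_ms": 1233.0}
        )
        out = st.rt_from_critical_frame(
            st.compute_accuracy(resp, small_session), small_session
        )
        assert (out["rt_ms"] == 1000.0).all()
        analyzed = out[out["rt_analyzable"]]
        assert len(analyzed) > 0
        assert not analyzed["rt_excluded"].any()


class TestFitMixed:
    def test_zero_noise_exact_recovery(self, small_session):
        preset = sim.BetaGeneratorPreset(
            roi="t", w_slope=0.2, subject_int_sd=0, subject_slope_sd=0,
            item_sd=0, resid_sd=0, n_subjects=3,
        )
        betas = sim.gen_betas(preset, small_session, seed=1,
                              conditions=["ZERO", "ONE", "TWO_SEQ"])
        fit = st.fit_mixed(betas, st.ANALYSES["word_count"])
        assert fit.params["n_words"] == pytest.approx(0.2, abs=1e-8)

    def test_single_subject_rejected(self, small_session):
        preset = sim.BetaGeneratorPreset(roi="t", n_subjects=1)
        betas = sim.gen_betas(preset, small_session, seed=2)
        with pytest.raises(ValueError):
            st.fit_mixed(betas, st.ANALYSES["word_count"])

    def test_df_convention(self, small_session):
        preset = sim.BetaGeneratorPreset(roi="t", n_subjects=4)
        betas = sim.gen_betas(preset, small_session, seed=3,
                              conditions=["ZERO", "ONE", "TWO_SEQ"])
        spec = replace(st.ANALYSES["word_count"], item_intercept=False)
        fit = st.fit_mixed(betas, spec)
        assert fit.n_fixed == 2  # intercept + W
        assert fit.df_denominator == len(betas) - 2

    def test_item_variance_recovered_when_present(self, small_word_list,
                                                  small_session):
        big = sim.BetaGeneratorPreset(roi="t", item_sd=0.3, resid_sd=0.1,
                                      subject_int_sd=0.02,
                                      subject_slope_sd=0.0, n_subjects=6)
        none = replace(big, item_sd=0.0)
        b1 = sim.gen_betas(big, small_session, seed=4,
                           word_list=small_word_list,
                           conditions=["ZERO", "ONE", "TWO_SEQ"])
        b0 = sim.gen_betas(none, small_session, seed=4,
                           word_list=small_word_list,
                           conditions=["ZERO", "ONE", "TWO_SEQ"])
        f1 = st.fit_mixed(b1, st.ANALYSES["word_count"])
        f0 = st.fit_mixed(b0, st.ANALYSES["word_count"])
        vc1 = float(f1.model_result.vcomp[0])
        vc0 = float(f0.model_result.vcomp[0])
        assert vc1 > 9 * max(vc0, 1e-6)  # sd ratio > 3

    def test_parameter_recovery_within_two_se(self, small_session):
        """Refitting data generated under the number-of-words model
        recovers the slope within 2 SE in >= 90% of replicates."""
        preset = sim.BetaGeneratorPreset(roi="t", w_slope=0.116,
                                         n_subjects=12)
        spec = replace(st.ANALYSES["word_count"], item_intercept=False)
        good = 0
        reps = 20
        for r in range(reps):
            betas = sim.gen_betas(preset, small_session, seed=600 + r,
                                  conditions=["ZERO", "ONE", "TWO_SEQ"])
            fit = st.fit_mixed(betas, spec)
            err = abs(fit.params["n_words"] - 0.116)
            good += err <= 2 * fit.bse["n_words"]
        assert good >= int(0.9 * reps) - 1

    def test_binomial_family_accuracy_effects(self, small_session):
        preset = sim.BehaviorGeneratorPreset(
            accuracy={"ZERO": 0.97, "ONE": 0.90, "TWO_SEQ": 0.90,
                      "TWO_SIM": 0.75},
            no_response_p=0.0,
        )
        frames = []
        for s in range(10):
            beh = sim.gen_behavior(preset, small_session, seed=700 + s,
                                   subject=s)
            frames.append(st.compute_accuracy(beh, small_session))
        data = pd.concat(frames, ignore_index=True)
        data["stim_id"] = (data["run"].astype(str) + "_"
                           + data["trial"].astype(str))
        fit = st.fit_mixed(data, st.ANALYSES["accuracy"])
        est = fit.params
        # TWO_SIM logit well below TWO_SEQ; ZERO the highest
        sim_c = est['C(condition, Treatment("ZERO"))[T.TWO_SIM]']
        seq_c = est['C(condition, Treatment("ZERO"))[T.TWO_SEQ]']
        assert sim_c < seq_c < 0
        assert any("reduced" in r for r in fit.reduction)


@pytest.fixture(scope="module")
def noisefree_fit(small_session):
    preset = sim.BetaGeneratorPreset(
        roi="t", w_slope=0.1, cond_effects={"TWO_SIM": -0.05},
        subject_int_sd=0, subject_slope_sd=0, item_sd=0, resid_sd=0,
        n_subjects=3, intercept=0.3,
    )
    betas = sim.gen_betas(preset, small_session, seed=5,
                          conditions=["TWO_SEQ", "TWO_SIM"])
    return st.fit_mixed(betas, st.ANALYSES["suppression"])


class TestContrasts:
    def test_identity_contrast_recovers_intercept(self, noisefree_fit):
        res = st.pairwise_contrast(noisefree_fit, {"Intercept": 1.0})
        assert res.estimate == pytest.approx(0.5, abs=1e-8)  # 0.3 + 0.1*2

    def test_condition_gap_recovered(self, noisefree_fit):
        res = st.pairwise_contrast(noisefree_fit, {"TWO_SIM": 1.0})
        assert res.estimate == pytest.approx(-0.05, abs=1e-8)
        assert res.df_den == noisefree_fit.n_obs - 2

    def test_gap_recovery_with_noise(self, small_session):
        preset = sim.BetaGeneratorPreset(
            roi="t", w_slope=0.1, cond_effects={"TWO_SIM": -0.1},
            n_subjects=14,
        )
        betas = sim.gen_betas(preset, small_session, seed=6,
                              conditions=["TWO_SEQ", "TWO_SIM"])
        spec = replace(st.ANALYSES["suppression"], item_intercept=False)
        fit = st.fit_mixed(betas, spec)
        res = st.pairwise_contrast(fit, {"TWO_SIM": 1.0})
        assert abs(res.estimate - (-0.1)) <= 2 * res.se

    def test_zero_contrast_rejected(self, noisefree_fit):
        with pytest.raises(ValueError):
            st.pairwise_contrast(noisefree_fit, np.zeros(2))

    def test_wrong_length_rejected(self, noisefree_fit):
        with pytest.raises(ValueError):
            st.pairwise_contrast(noisefree_fit, np.ones(5))

    def test_term_f_test(self, small_session):
        preset = sim.BetaGeneratorPreset(
            roi="t", w_slope=0.1, cond_effects={"TWO_SIM": -0.2},
            n_subjects=8,
        )
        betas = sim.gen_betas(preset, small_session, seed=8,
                              conditions=["TWO_SEQ", "TWO_SIM"])
        spec = replace(st.ANALYSES["suppression"], item_intercept=False)
        fit = st.fit_mixed(betas, spec)
        res = st.term_f_test(fit, "TWO_SIM")
        assert res.df_num == 1
        assert res.f_value > 10  # strong true gap
        assert res.p_value < 0.01


def brute_force_bh(pvals, q=0.05):
    """Independent step-up oracle: find the largest k with p_(k) <=
    k q / m, reject the k smallest; adjusted p by direct min-max."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(
            min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj
    k = 0
    for i in range(m):
        if ranked[i] <= (i + 1) * q / m:
            k = i + 1
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return out, reject


class TestFdr:
    def test_single_p_unchanged(self):
        adj, rej = st.fdr_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_example(self):
        adj, _ = st.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        adj, rej = st.fdr_adjust([1.0, 1.0])
        assert np.allclose(adj, 1.0)
        assert not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_adjust([0.5, 1.2])

    def test_matches_brute_force_on_grid_sample(self):
        """BH equals the brute-force step-up enumeration for grid
        p-vectors of every length up to 6 (exhaustive at lengths 1-2,
        a large seeded sample above)."""
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        rng = np.random.default_rng(0)
        cases = [[p] for p in grid]
        cases += [[a, b] for a in grid[::5] for b in grid[::5]]
        for m in (3, 4, 5, 6):
            for _ in range(300):
                cases.append(list(rng.choice(grid, size=m)))
        for p in cases:
            adj, rej = st.fdr_adjust(p)
            oadj, orej = brute_force_bh(p)
            assert np.allclose(adj, oadj, atol=1e-12), p
            assert (rej == orej).all(), p

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        adj, _ = st.fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestBayesFactor:
    def _fits(self, effect, n=500, seed=0):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(10), n // 10)
        x = rng.normal(size=n)
        y = effect * x + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x": x, "subject": subj})
        alt = st.MixedModelSpec("y", "x", "", False, "gaussian")
        null = st.MixedModelSpec("y", "1", "", False, "gaussian")
        return (st.fit_mixed(data, alt), st.fit_mixed(data, null))

    def test_identical_models_bf_one(self, small_session):
        preset = sim.BetaGeneratorPreset(roi="t", n_subjects=3)
        betas = sim.gen_betas(preset, small_session, seed=7)
        spec = replace(st.ANALYSES["word_count"], item_intercept=False)
        fit = st.fit_mixed(betas, spec)
        assert st.bayes_factor_bic(fit, fit) == pytest.approx(1.0)

    def test_strong_effect_large_bf(self):
        alt, null = self._fits(effect=2.0, seed=1)
        assert st.bayes_factor_bic(alt, null) > 100

    def test_null_effect_favors_null(self):
        wins = 0
        reps = 20
        for r in range(reps):
            alt, null = self._fits(effect=0.0, n=200, seed=100 + r)
            wins += st.bayes_factor_bic(alt, null) < 1
        assert wins > reps / 2

    def test_mismatched_n_warns(self):
        alt, _ = self._fits(effect=0.0, n=200, seed=5)
        _, null = self._fits(effect=0.0, n=300, seed=6)
        with pytest.warns(UserWarning):
            st.bayes_factor_bic(alt, null)
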