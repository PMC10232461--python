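import numpy as np
import pytest
from scipy import stats

from taskspike.relevance import (
    HoldGoFit,
    assign_task_type,
    classify_cohort,
    classify_relevance,
    classify_slope,
    hold_go_slope,
    relevance_index,
    type_fractions,
)
from taskspike.session import SpikeTrain, TrialEvent
from taskspike.simulate import NeuronSpec, simulate_neuron


def _train(times):
    return SpikeTrain("n0", "CA1", np.asarray(times, float), 1.0)


class TestRelevanceIndex:
    def test_uniform_grid_null_identity(self):
        # spikes placed at uniform quantiles -> KS statistic ~ 1/(2n), p ~ 1
        rel = (np.arange(200) + 0.5) / 200 - 0.5
        p = relevance_index(_train(rel + 50.0), [50.0], (-0.5, 0.5))
        assert p > 0.99

    def test_zero_spikes_returns_one(self):
        assert relevance_index(_train([]), [10.0], (-0.5, 0.5)) == 1.0

    def test_go_archetype_crosses_criterion(self, behavior_320):
        _, trials, _ = behavior_320
        spec = NeuronSpec("n0", "Go", "CA1", baseline_hz=4.0, effect=4.0,
                          preferred_side="right")
        st = simulate_neuron("Go", trials, spec, seed=3)
        align = [t.release_onset for t in trials
                 if t.completed and t.released_side == "right"][:100]
        assert relevance_index(st, align, (-0.5, 0.5)) < 1e-6

    def test_null_calibration_small(self, behavior_320):
        _, trials, _ = behavior_320
        align = [t.release_onset for t in trials if t.completed][:100]
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            span = align[-1] + 5.0
            spikes = np.sort(rng.uniform(0, span, rng.poisson(3.0 * span)))
            pvals.append(relevance_index(spikes, align, (-0.5, 0.5)))
        pvals = np.array(pvals)
        assert (pvals < 1e-6).sum() == 0
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_two_sample_mode_agrees_roughly(self, rng):
        rel = rng.uniform(-0.5, 0.5, 300)
        p1 = relevance_index(_train(rel + 10.0), [10.0], (-0.5, 0.5))
        p2 = relevance_index(_train(rel + 10.0), [10.0], (-0.5, 0.5),
                             two_sample=True, rng=rng)
        assert p1 > 0.05 and p2 > 0.05


class TestClassifyRelevance:
    def test_preferred_side_is_smaller_p(self, behavior_320):
        _, trials, _ = behavior_320
        spec = NeuronSpec("n0", "Go", "CA1", baseline_hz=4.0, effect=6.0,
                          preferred_side="right", side_bias=0.0)
        st = simulate_neuron("Go", trials, spec, seed=1)
        # hemisphere left -> contra is the right limb -> preferred contra
        tr = classify_relevance(st, trials, hemisphere="left")
        assert tr.preferred_side == "contra"
        assert tr.preferred_side_physical == "right"
        assert tr.p_release_contra < tr.p_release_ipsi

    def test_exact_tie_broken_to_contra(self):
        # one trial per side with identical relative spike patterns
        trials = [
            TrialEvent(0, 1.0, 1.5, "right", True, False, 2.5, "right", 2.9),
            TrialEvent(1, 10.0, 1.5, "left", False, False, 11.5, "left", None),
        ]
        rel = np.linspace(-0.4, 0.4, 9)
        st = _train(np.sort(np.concatenate([2.5 + rel, 11.5 + rel])))
        tr = classify_relevance(st, trials)
        assert tr.p_release_contra == tr.p_release_ipsi
        assert tr.preferred_side == "contra"

    def test_no_correct_trials_flags_reward(self):
        trials = [TrialEvent(0, 1.0, 1.5, "right", False, False, 2.5, "left", None)]
        tr = classify_relevance(_train([2.0]), trials)
        assert not tr.reward_computable


class TestHoldGoSlope:
    @staticmethod
    def _deterministic_trials(holds, side="right"):
        trials, t = [], 2.0
        for i, h in enumerate(holds):
            trials.append(TrialEvent(i, round(t, 6), round(h, 6), side, True, False,
                                     round(t + h, 6), side, round(t + h + 0.5, 6)))
            t += h + 3.0
        return trials

    def _ramp_spikes(self, trials, rate_per_s=16.0, base_hz=4.0):
        # stratified quasi-spikes matching a linear ramp density: one point
        # per quantile stratum, jittered so strata don't align across trials
        jit = np.random.default_rng(99)
        out = []
        for t in trials:
            lam = 0.5 * rate_per_s * t.hold_duration ** 2
            m = int(round(lam))
            q = (np.arange(m) + jit.uniform(0, 1, m)) / m
            out.append(t.hold_onset + t.hold_duration * np.sqrt(q))
            # constant-rate background so PETH bins are defined everywhere
            # (grid anchored at the window start; holding times vary, so the
            # grid is incommensurate with the release alignment)
            out.append(np.arange(t.hold_onset - 3.0,
                                 t.hold_onset + t.hold_duration + 0.5, 1.0 / base_hz))
        return np.unique(np.round(np.concatenate(out), 6))

    def test_linear_ramp_slope_minus_one(self):
        rng = np.random.default_rng(0)
        holds = np.concatenate([rng.uniform(1.0, 1.4, 30), rng.uniform(1.4, 1.9, 30),
                                rng.uniform(1.9, 2.4, 30), rng.uniform(2.4, 3.0, 30)])
        trials = self._deterministic_trials(holds)
        st = _train(self._ramp_spikes(trials))
        # smoothing heavy enough that the shortest-hold range, whose ramp
        # peaks below the 75% criterion, correctly drops out of the fit
        fit = hold_go_slope(st, trials, "right", smooth_sigma_ms=60.0)
        assert fit.class_label == "Hold"
        assert fit.slope == pytest.approx(-1.0, abs=0.1)
        # intersections shift about one-for-one with holding time and match
        # the closed form t* = (criterion - base) / ramp_rate - mean_hold
        valid = ~np.isnan(fit.intersection_times)
        closed = (fit.criterion_level - 4.0) / 16.0 - fit.range_mean_hold
        assert valid.sum() >= 3
        assert np.allclose(fit.intersection_times[valid], closed[valid], atol=0.07)
        assert np.all(np.diff(fit.intersection_times[valid]) < 0)

    def test_go_bump_slope_near_zero(self, behavior_320):
        _, trials, _ = behavior_320
        spec = NeuronSpec("n0", "Go", "CA1", baseline_hz=4.0, effect=6.0,
                          preferred_side="right")
        st = simulate_neuron("Go", trials, spec, seed=5)
        fit = hold_go_slope(st, trials, "right")
        assert fit.class_label == "Go"
        assert abs(fit.slope) < 0.3

    def test_too_few_trials_indeterminate(self):
        trials = self._deterministic_trials([1.2, 1.5, 2.0])
        fit = hold_go_slope(_train([2.0]), trials, "right")
        assert fit.class_label == "indeterminate"

    @pytest.mark.parametrize("slope,expected", [
        (-0.5, "Hold"), (-0.49, "Go"), (-1.2, "Hold"), (0.0, "Go"),
    ])
    def test_slope_boundary_rule(self, slope, expected):
        assert classify_slope(slope) == expected

    def test_absolute_slope_mode(self):
        assert classify_slope(0.8, absolute_slope=True) == "Hold"
        assert classify_slope(0.8) == "Go"


class TestAssignTaskType:
    @staticmethod
    def _rel(p_rel=1.0, p_rew=1.0):
        from taskspike.relevance import TaskRelevance

        return TaskRelevance(p_rel, 1.0, p_rew, "contra", "right", True)

    @staticmethod
    def _fit(label):
        return HoldGoFit([], np.empty(0), 1.0, np.empty(0), -1.0, 0.0, 4, label)

    @pytest.mark.parametrize("p_rel,p_rew,fit,peak_before,expected", [
        (1e-8, 1e-8, "Hold", True, "Hold&Reward"),
        (1e-8, 1.0, "Hold", True, "Hold"),
        (1e-8, 1e-8, "Go", True, "Go&Reward"),
        (1e-8, 1.0, "Go", False, "Go"),
        (1.0, 1e-8, None, False, "Reward"),
        (1.0, 1.0, None, False, "none"),
    ])
    def test_taxonomy_rules(self, p_rel, p_rew, fit, peak_before, expected):
        holdgo = self._fit(fit) if fit else None
        assert assign_task_type(self._rel(p_rel, p_rew), holdgo, peak_before) == expected


class TestCohort:
    def test_archetype_recovery_small(self, small_cohort):
        session, truth = small_cohort
        classified = classify_cohort(session)
        merged = classified.merge(truth.neurons[["neuron_id", "archetype"]],
                                  on="neuron_id")
        assert (merged["archetype"] == merged["type"]).mean() >= 0.8

    def test_type_fractions_sum_to_one(self, small_cohort):
        session, _ = small_cohort
        tf = type_fractions(classify_cohort(session))
        sums = tf.groupby("region")["proportion"].sum()
        assert np.allclose(sums, 1.0)
        counts = tf.groupby("region")["count"].sum().sum()
        assert counts == len(classify_cohort(session))

    def test_empty_and_single(self):
        import pandas as pd

        assert len(type_fractions(pd.DataFrame())) == 0
        one = pd.DataFrame([{"region": "CA1", "type": "Go"}])
        tf = type_fractions(one)
        assert tf.loc[tf["type"] == "Go", "proportion"].iloc[0] == 1.0
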