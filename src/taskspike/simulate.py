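"""Synthetic session generator with ground truth.

Emulates a self-paced two-pedal release task: the animal holds both pedals
in the holding area (0-30% of range of motion) for at least 1 s, then
releases the left or the right pedal; a correct release (matching the
current block side) is rewarded 300-700 ms later (100 ms steps at random).
Blocks alternate once the performance rule is met (more than 30 correct and
80% correct over the 10 most recent completed trials) or after 100 rewards.

Spike trains are drawn from inhomogeneous Poisson processes: a constant
baseline plus archetype kernels with known ground truth --

* ``Hold``: linear ramp at a fixed rise rate from hold onset to release,
  so the time at which the rate crosses any fixed level shifts one-for-one
  with holding time (the signature the intersection-slope analysis keys on);
* ``Go``: a phasic Gaussian bump tied to release onset (holding-time
  independent), optionally offset before (preparatory) or after (feedback)
  the release;
* ``Reward``: a Gaussian bump after reward delivery on correct trials only;
* ``Hold&Reward`` / ``Go&Reward``: kernel sums; ``none``: baseline only.

Stimulation epochs emulate antidromic collision physics for projection
neurons: control stimulations evoke an antidromic spike at a fixed latency
(jitter < 0.1 ms) unless a spontaneous spike fell within one conduction
round-trip before the stimulus; test stimulations triggered on a spontaneous
spike always collide.  Window-trough amplitudes are drawn from two separated
Gaussians (spike present vs absent) for ROC thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from taskspike.session import (
    REWARD_DELAYS,
    PedalTrace,
    Session,
    SpikeTrain,
    StimEpoch,
    TrialEvent,
)

ARCHETYPES = ("Hold", "Hold&Reward", "Go", "Go&Reward", "Reward", "none")


@dataclass(frozen=True)
class BlockRules:
    """Block-switch criterion.

    A block ends when the rat has more than ``min_correct`` rewarded trials
    and at least ``recent_frac`` correct among the ``recent_n`` most recent
    completed trials, or unconditionally once ``max_rewards`` rewards have
    been collected.  ``use_performance_rule=False`` disables the first
    clause (blocks then always run to ``max_rewards``).
    """

    min_correct: int = 30
    recent_n: int = 10
    recent_frac: float = 0.8
    max_rewards: int = 100
    use_performance_rule: bool = True


@dataclass(frozen=True)
class NeuronSpec:
    neuron_id: str
    archetype: str
    region: str
    baseline_hz: float = 4.0
    effect: float = 6.0          # kernel peak amplitude in units of baseline
    waveform_ms: float = 1.0     # spike onset-to-peak duration
    preferred_side: str = "right"
    side_bias: float = 0.3       # kernel amplitude fraction on non-preferred side
    go_offset_s: float = 0.0     # Go bump center relative to release onset
    go_sigma_s: float = 0.05
    reward_offset_s: float = 0.3
    reward_sigma_s: float = 0.06
    hold_ref_s: float = 1.5      # holding time at which the ramp reaches effect x baseline
    projection_target: str | None = None   # {"mPFC", "CA1", None}
    antidromic_latency_ms: float | None = None
    stim_tested: bool = False              # include in collision testing even
                                           # when not a projection neuron


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_trials_target: int = 120
    min_hold: float = 1.0
    hold_exp_mean: float = 0.8   # exponential mean of holding time beyond min_hold
    hold_trunc: float = 2.0      # truncation of the exponential part (hold in [1, 3] s)
    error_rate: float = 0.10
    immature_rate: float = 0.05
    reward_delay_set: tuple = REWARD_DELAYS
    block_rules: BlockRules = field(default_factory=BlockRules)
    pedal_sample_rate: float = 1000.0
    release_rise_time: float = 0.08
    iti_range: tuple = (1.0, 2.5)
    hold_position: float = 10.0  # pedal percent while holding
    rest_position: float = 70.0  # pedal percent between trials
    pedal_noise_sd: float = 0.4
    neuron_specs: tuple = ()

    def validate(self) -> None:
        for p in (self.error_rate, self.immature_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")
        if self.pedal_sample_rate <= 0 or self.min_hold <= 0:
            raise ValueError("rates must be positive")
        if tuple(round(d, 3) for d in self.reward_delay_set) != REWARD_DELAYS:
            raise ValueError("reward_delay_set must be {0.3..0.7 step 0.1} s")


@dataclass
class GroundTruth:
    """Generative labels, aligned to the session by neuron_id."""

    neurons: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(config: SimConfig, rng: np.random.Generator | None = None
                      ) -> tuple[list[TrialEvent], dict[str, PedalTrace]]:
    """Simulate the trial table and both pedal traces."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    trials: list[TrialEvent] = []
    block_side = "right" if rng.random() < 0.5 else "left"
    block_correct = 0
    recent: list[bool] = []
    rules = config.block_rules
    t = round(float(rng.uniform(*config.iti_range)), 6)

    for trial_id in range(config.n_trials_target):
        immature = bool(rng.random() < config.immature_rate)
        if immature:
            hold = float(rng.uniform(0.2, 0.95))
            trials.append(TrialEvent(trial_id, round(t, 6), round(hold, 6),
                                     block_side, correct=False, immature=True))
            t += hold
        else:
            extra = float(rng.exponential(config.hold_exp_mean))
            while extra > config.hold_trunc:
                extra = float(rng.exponential(config.hold_exp_mean))
            hold = config.min_hold + extra
            correct = bool(rng.random() >= config.error_rate)
            side = block_side if correct else ("left" if block_side == "right" else "right")
            t = round(t, 6)
            hold = round(hold, 6)
            release = round(t + hold, 6)
            reward = None
            if correct:
                reward = round(release + float(rng.choice(config.reward_delay_set)), 6)
                block_correct += 1
            trials.append(TrialEvent(trial_id, t, hold, block_side,
                                     correct=correct, immature=False,
                                     release_onset=release, released_side=side,
                                     reward_onset=reward))
            recent.append(correct)
            recent = recent[-rules.recent_n:]
            perf_ok = (rules.use_performance_rule
                       and block_correct > rules.min_correct
                       and len(recent) >= rules.recent_n
                       and np.mean(recent) >= rules.recent_frac)
            if perf_ok or block_correct >= rules.max_rewards:
                block_side = "left" if block_side == "right" else "right"
                block_correct = 0
                recent = []
            t = release
        t += float(rng.uniform(*config.iti_range))

    traces = _pedal_traces(config, trials, rng)
    return trials, traces


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _pedal_traces(config: SimConfig, trials: list[TrialEvent],
                  rng: np.random.Generator) -> dict[str, PedalTrace]:
    t_end = (max((t.hold_onset + t.hold_duration) for t in trials) + 2.0) if trials else 2.0
    n = int(np.ceil(t_end * config.pedal_sample_rate)) + 1
    times = np.round(np.arange(n) / config.pedal_sample_rate, 6)
    pos = {s: np.full(n, config.rest_position) for s in ("left", "right")}
    rise = config.release_rise_time
    press_dur = 0.2

    for tr in trials:
        t0, t1 = tr.hold_onset, tr.hold_onset + tr.hold_duration
        for side in ("left", "right"):
            p = pos[side]
            # press both pedals down over press_dur ending at hold onset
            i0, i1 = np.searchsorted(times, [t0 - press_dur, t0])
            frac = _smoothstep((times[i0:i1] - (t0 - press_dur)) / press_dur)
            p[i0:i1] = config.rest_position + frac * (config.hold_position - config.rest_position)
            # release: the released pedal rises at release onset, the other
            # (and both, for immature trials) 0.3 s later
            if tr.immature or side != tr.released_side:
                t_up = t1 + 0.3
            else:
                t_up = t1
            j0 = np.searchsorted(times, t0)
            j1 = np.searchsorted(times, t_up)
            hold_noise = rng.normal(0.0, config.pedal_noise_sd, j1 - j0)
            p[j0:j1] = np.clip(config.hold_position + hold_noise, 0.0, 29.0)
            j2 = np.searchsorted(times, t_up + rise)
            frac = _smoothstep((times[j1:j2] - t_up) / rise)
            p[j1:j2] = config.hold_position + frac * (config.rest_position - config.hold_position)

    return {
        s: PedalTrace(s, times, np.round(np.clip(pos[s], 0.0, 100.0), 4),
                      config.pedal_sample_rate)
        for s in ("left", "right")
    }


# ---------------------------------------------------------------------------
# spike trains


def _side_factor(trial: TrialEvent, spec: NeuronSpec) -> float:
    return 1.0 if trial.released_side == spec.preferred_side else spec.side_bias


def _gaussian_bump(rng, center: float, sigma: float, amp: float) -> np.ndarray:
    """Event times of an inhomogeneous Poisson Gaussian-bump intensity."""
    n = rng.poisson(amp * sigma * np.sqrt(2.0 * np.pi))
    x = rng.normal(center, sigma, n)
    return x[np.abs(x - center) <= 4.0 * sigma]


def simulate_neuron(archetype: str, trials: list[TrialEvent], spec: NeuronSpec,
                    seed: int | np.random.Generator, t_span: float | None = None
                    ) -> SpikeTrain:
    """Draw one spike train from baseline + archetype kernels."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype: {archetype!r}")
    if not trials:
        raise ValueError("trials must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_span is None:
        t_span = max(t.hold_onset + t.hold_duration for t in trials) + 2.0

    n_base = rng.poisson(spec.baseline_hz * t_span)
    spikes = [rng.uniform(0.0, t_span, n_base)]

    want_hold = archetype in ("Hold", "Hold&Reward")
    want_go = archetype in ("Go", "Go&Reward")
    want_reward = archetype in ("Reward", "Go&Reward", "Hold&Reward")
    ramp_rate = spec.effect * spec.baseline_hz / spec.hold_ref_s
    go_amp = spec.effect * spec.baseline_hz
    rew_amp = spec.effect * spec.baseline_hz

    for tr in trials:
        if tr.completed:
            sf = _side_factor(tr, spec)
            if want_hold:
                h = tr.hold_duration
                lam = 0.5 * ramp_rate * sf * h * h
                n = rng.poisson(lam)
                spikes.append(tr.hold_onset + h * np.sqrt(rng.uniform(0.0, 1.0, n)))
            if want_go:
                spikes.append(_gaussian_bump(rng, tr.release_onset + spec.go_offset_s,
                                             spec.go_sigma_s, go_amp * sf))
        if want_reward and tr.reward_onset is not None:
            spikes.append(_gaussian_bump(rng, tr.reward_onset + spec.reward_offset_s,
                                         spec.reward_sigma_s, rew_amp))

    all_spikes = np.unique(np.round(np.concatenate(spikes), 6))
    all_spikes = all_spikes[(all_spikes >= 0.0) & (all_spikes <= t_span)]
    return SpikeTrain(spec.neuron_id, spec.region, all_spikes, spec.waveform_ms)


# ---------------------------------------------------------------------------
# stimulation / collision physics

#: Trough-amplitude model for ROC thresholding (arbitrary filtered units).
TROUGH_PRESENT = (-60.0, 5.0)
TROUGH_ABSENT = (-5.0, 3.0)
ANTIDROMIC_JITTER_MS = 0.03
FF_RELIABILITY = {100: 0.95, 200: 0.7}


def simulate_stimulation(spikes: SpikeTrain, spec: NeuronSpec,
                         n_control: int, n_test: int,
                         seed: int | np.random.Generator,
                         start_time: float | None = None,
                         n_ff_pairs: int = 10) -> StimEpoch:
    """Simulate a tentative collision-test epoch for one neuron.

    Projection neurons respond to control stimulation with an antidromic
    spike at ``spec.antidromic_latency_ms`` (+- <0.1 ms jitter) unless a
    spontaneous spike occurred within one conduction round-trip before the
    stimulus; test stimulations are triggered 2 ms after a spontaneous spike
    and therefore always collide.  Non-projection neurons never produce
    antidromic spikes.
    """
    if n_control < 1 or n_test < 1:
        raise ValueError("n_control and n_test must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_proj = spec.projection_target is not None
    lat = spec.antidromic_latency_ms if is_proj else 10.0
    if is_proj and (lat is None or lat < 3.0):
        raise ValueError("projection neurons need antidromic_latency_ms >= 3 ms")
    t0 = start_time if start_time is not None else (
        float(spikes.spike_times[-1]) + 10.0 if spikes.n_spikes() else 10.0)
    roundtrip_s = 2.0 * lat / 1000.0
    rate = max(spikes.n_spikes() / max(float(spikes.spike_times[-1]), 1.0), 0.1) \
        if spikes.n_spikes() else 0.1

    rows = []
    t = t0
    kinds = ["control"] * n_control + ["test"] * n_test \
        + ["ff100"] * n_ff_pairs + ["ff200"] * n_ff_pairs
    for kind in kinds:
        trigger = np.nan
        if kind == "test":
            # stimulate 2 ms after a detected spontaneous spike
            trigger = t - 0.002
        if not is_proj:
            present = False
        elif kind == "test":
            present = False  # collision: trigger within round-trip by construction
        elif kind == "control":
            # spontaneous spike in the preceding round-trip window -> collision
            present = rng.random() >= 1.0 - np.exp(-rate * roundtrip_s)
        else:
            freq = 100 if kind == "ff100" else 200
            present = rng.random() < FF_RELIABILITY[freq]
        if present:
            trough = rng.normal(*TROUGH_PRESENT)
            peak = lat + rng.normal(0.0, ANTIDROMIC_JITTER_MS)
        else:
            trough = rng.normal(*TROUGH_ABSENT)
            peak = rng.uniform(lat - 1.0, lat + 1.0)
        rows.append({"stim_time_s": round(t, 6), "neuron_id": spikes.neuron_id,
                     "kind": kind, "trigger_spike_time_s": trigger,
                     "trough": trough, "peak_ms": peak, "spike_present": int(present)})
        t += 0.25

    site = spec.projection_target or "mPFC"
    return StimEpoch(site=site, pulse_ms=1.0, events=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(config: SimConfig, n_control: int = 30, n_test: int = 30
                    ) -> tuple[Session, GroundTruth]:
    """Full session with all neuron specs realized, plus aligned ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.neuron_specs) + 2)
    rng_beh = np.random.default_rng(children[0])
    trials, traces = simulate_behavior(config, rng_beh)
    t_span = float(traces["left"].sample_times[-1])

    spike_trains, truth_rows, stim_epochs = [], [], []
    rng_stim = np.random.default_rng(children[1])
    for spec, child in zip(config.neuron_specs, children[2:]):
        rng = np.random.default_rng(child)
        st = simulate_neuron(spec.archetype, trials, spec, rng, t_span=t_span)
        spike_trains.append(st)
        truth_rows.append({
            "neuron_id": spec.neuron_id, "archetype": spec.archetype,
            "region": spec.region, "preferred_side": spec.preferred_side,
            "waveform_ms": spec.waveform_ms,
            "true_class": "RS" if spec.waveform_ms >= 0.72 else "FS",
            "baseline_hz": spec.baseline_hz, "effect": spec.effect,
            "go_offset_s": spec.go_offset_s,
            "projection_target": spec.projection_target or "",
            "antidromic_latency_ms": spec.antidromic_latency_ms,
        })
        if spec.projection_target is not None or spec.stim_tested:
            stim_epochs.append(simulate_stimulation(st, spec, n_control, n_test, rng_stim))

    # canonical form: one epoch per (site, pulse), as stored on disk
    merged: dict[tuple, list] = {}
    for ep in stim_epochs:
        merged.setdefault((ep.site, ep.pulse_ms), []).append(ep.events)
    stim_epochs = [StimEpoch(site=site, pulse_ms=pulse,
                             events=pd.concat(evs, ignore_index=True))
                   for (site, pulse), evs in sorted(merged.items())]

    truth = GroundTruth(pd.DataFrame(truth_rows), config)
    session = Session(trials=trials, pedal_traces=traces, spike_trains=spike_trains,
                      stim_epochs=stim_epochs,
                      metadata={"group": "post-training", "recorded_hemisphere": "left",
                                "session_id": f"sim-{config.seed}"})
    return session, truth


def _alternate(i: int, a, b):
    return a if i % 2 == 0 else b


def cohort_specs(n_per_type: int, regions=("CA1", "LECs", "LECd"),
                 baseline_hz: float = 4.0, effect: float = 6.0,
                 fs_fraction: float = 0.15,
                 go_offsets=(-0.225, 0.062)) -> tuple[NeuronSpec, ...]:
    """Neuron specs with ``n_per_type`` neurons per archetype (incl. none).

    Regions cycle; preferred sides alternate; Go-kernel centers alternate
    between a preparatory (pre-release) and a feedback (post-release) offset;
    a fraction of the ``none`` neurons are fast-spiking (short waveform).
    """
    specs = []
    idx = 0
    n_fs = min(n_per_type - 1, int(round(fs_fraction * n_per_type * len(ARCHETYPES))))
    for arch in ARCHETYPES:
        for i in range(n_per_type):
            waveform = 1.0
            if arch == "none" and i < n_fs:
                waveform = 0.3
            specs.append(NeuronSpec(
                neuron_id=f"n{idx:03d}", archetype=arch,
                region=regions[idx % len(regions)],
                baseline_hz=baseline_hz, effect=effect, waveform_ms=waveform,
                preferred_side=_alternate(i, "right", "left"),
                go_offset_s=go_offsets[i % 2] if arch in ("Go", "Go&Reward") else 0.0,
            ))
            idx += 1
    return tuple(specs)


def projection_specs(n_projection: int, n_non: int, baseline_hz: float = 3.0,
                     seed: int = 0) -> tuple[NeuronSpec, ...]:
    """LEC neurons for collision testing: half project to mPFC, half to CA1."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_projection):
        specs.append(NeuronSpec(
            neuron_id=f"p{i:03d}", archetype="none", region="LECd",
            baseline_hz=baseline_hz,
            projection_target=_alternate(i, "mPFC", "CA1"),
            antidromic_latency_ms=float(np.round(rng.uniform(5.0, 25.0), 2)),
        ))
    for i in range(n_non):
        specs.append(NeuronSpec(neuron_id=f"q{i:03d}", archetype="none",
                                region="LECd", baseline_hz=baseline_hz,
                                stim_tested=True))
    return tuple(specs)


def recovery_cohort_config(seed: int = 0, n_per_type: int = 20,
                           n_trials: int = 320,
                           pedal_sample_rate: float = 200.0) -> SimConfig:
    """Study conditions for archetype-recovery experiments: a multi-hour
    self-paced session (~320 trials, ~150 completed per side) and a cohort
    with ``n_per_type`` neurons per archetype including non-task neurons."""
    return SimConfig(seed=seed, n_trials_target=n_trials,
                     pedal_sample_rate=pedal_sample_rate,
                     neuron_specs=cohort_specs(n_per_type=n_per_type))


def default_config(seed: int = 0) -> SimConfig:
    """Default study conditions: 120-trial session, 24 task neurons across
    the six archetypes plus a small projection-identified subset."""
    specs = cohort_specs(n_per_type=4) + tuple(
        replace(s, neuron_id=s.neuron_id) for s in projection_specs(4, 4, seed=seed)
    )
    return SimConfig(seed=seed, neuron_specs=specs)
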