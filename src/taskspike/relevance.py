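"""Task-relevance testing and the Hold/Go/Reward taxonomy.

A neuron's *task relevance index* is the p-value of a KS test comparing the
pooled distribution of spike times around an alignment event against
uniformity on the analysis window; a neuron is task-related when the index
falls below a stringent criterion (1e-6) in contra- or ipsilateral release
trials (window: release onset +-500 ms) or after reward delivery (window:
onset to 1000 ms).  Release-related neurons are split into Hold-type
(activity ramps with holding time) and Go-type (phasic, holding-time
independent) by regressing the time at which each holding-time range's PETH
rises through 75% of the all-averaged PETH peak on the range's mean holding
time: slopes at or below -0.5 are Hold, others Go.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from taskspike.peth import Peth, compute_peth, pooled_relative_times, smooth_peth
from taskspike.session import Session, SpikeTrain, TrialEvent, validate_inclusion

RELEVANCE_CRITERION = 1e-6
RELEASE_WINDOW = (-0.5, 0.5)
REWARD_WINDOW = (0.0, 1.0)
SLOPE_THRESHOLD = -0.5
TASK_TYPES = ("Hold", "Hold&Reward", "Go", "Go&Reward", "Reward", "none")


@dataclass
class TaskRelevance:
    p_release_contra: float
    p_release_ipsi: float
    p_reward: float
    preferred_side: str            # {"contra", "ipsi"}
    preferred_side_physical: str   # {"left", "right"}
    included: bool
    reward_computable: bool = True
    criterion: float = RELEVANCE_CRITERION

    @property
    def release_significant(self) -> bool:
        return min(self.p_release_contra, self.p_release_ipsi) < self.criterion

    @property
    def reward_significant(self) -> bool:
        return self.reward_computable and self.p_reward < self.criterion


@dataclass
class HoldGoFit:
    range_bounds: list          # (lo, hi) holding time per range
    range_mean_hold: np.ndarray
    criterion_level: float      # Hz; 75% of the all-averaged PETH peak
    intersection_times: np.ndarray  # s relative to release; NaN where omitted
    slope: float
    intercept: float
    n_valid: int
    class_label: str            # {"Hold", "Go", "indeterminate"}


def contra_side(hemisphere: str) -> str:
    """Physical side contralateral to the recorded hemisphere."""
    return "right" if hemisphere == "left" else "left"


def relevance_index(spikes: SpikeTrain | np.ndarray, align_times, window,
                    two_sample: bool = False,
                    rng: np.random.Generator | None = None) -> float:
    """KS p-value of pooled relative spike times against uniformity.

    The default is a one-sample KS test against the uniform CDF on the
    window (deterministic).  ``two_sample=True`` instead compares against a
    single draw of the same number of uniformly distributed spike positions,
    which is the noisier Monte-Carlo variant; it requires ``rng``.
    Zero pooled spikes return 1.0.
    """
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    rel = pooled_relative_times(times, align_times, window)
    if rel.size == 0:
        return 1.0
    lo, hi = window
    if two_sample:
        if rng is None:
            raise ValueError("two_sample mode needs an rng")
        ref = rng.uniform(lo, hi, rel.size)
        return float(stats.ks_2samp(rel, ref).pvalue)
    return float(stats.kstest(rel, "uniform", args=(lo, hi - lo)).pvalue)


def classify_relevance(spikes: SpikeTrain, trials: list[TrialEvent],
                       hemisphere: str = "left",
                       criterion: float = RELEVANCE_CRITERION) -> TaskRelevance:
    """Per-side release relevance, reward relevance, and preferred side."""
    contra = contra_side(hemisphere)
    completed = [t for t in trials if t.completed]
    rel_contra = [t.release_onset for t in completed if t.released_side == contra]
    rel_ipsi = [t.release_onset for t in completed if t.released_side != contra]
    rewards = [t.reward_onset for t in completed if t.reward_onset is not None]

    p_contra = relevance_index(spikes, rel_contra, RELEASE_WINDOW) if rel_contra else 1.0
    p_ipsi = relevance_index(spikes, rel_ipsi, RELEASE_WINDOW) if rel_ipsi else 1.0
    reward_ok = len(rewards) > 0
    p_reward = relevance_index(spikes, rewards, REWARD_WINDOW) if reward_ok else 1.0

    # tie broken toward contra
    preferred = "contra" if p_contra <= p_ipsi else "ipsi"
    pref_physical = contra if preferred == "contra" else ("left" if contra == "right" else "right")
    return TaskRelevance(p_contra, p_ipsi, p_reward, preferred, pref_physical,
                         included=validate_inclusion(spikes, trials),
                         reward_computable=reward_ok, criterion=criterion)


# ---------------------------------------------------------------------------
# Hold vs Go by the 75%-criterion intersection slope


def _backward_crossing(centers: np.ndarray, rates: np.ndarray, peak_idx: int,
                       level: float) -> float | None:
    """Scanning backward from the peak, the interpolated time where the rate
    last rises through ``level``."""
    below = np.nonzero(rates[: peak_idx + 1] < level)[0]
    if below.size == 0:
        return float(centers[0])  # already above criterion at window start
    j = below[-1]
    if j == peak_idx:
        return None
    r0, r1 = rates[j], rates[j + 1]
    frac = (level - r0) / (r1 - r0) if r1 > r0 else 1.0
    return float(centers[j] + frac * (centers[j + 1] - centers[j]))


def hold_go_slope(spikes: SpikeTrain, trials: list[TrialEvent],
                  preferred_side: str, bin_width: float = 0.02,
                  criterion_frac: float = 0.75, n_ranges: int = 4,
                  min_trials_per_range: int = 5,
                  smooth_sigma_ms: float = 40.0,
                  absolute_slope: bool = False) -> HoldGoFit:
    """Intersection-slope classification into Hold vs Go.

    Preferred-side completed trials are split into ``n_ranges`` holding-time
    ranges (quantiles, balancing trial counts).  The criterion level is
    ``criterion_frac`` of the all-trials PETH peak; each range contributes
    the time its PETH last rises through the criterion before its peak
    (lightly smoothed for a stable crossing), and the slope of intersection
    time against mean holding time decides the class (<= -0.5: Hold).
    """
    pref = [t for t in trials if t.completed and t.released_side == preferred_side]
    holds = np.array([t.hold_duration for t in pref])
    releases = np.array([t.release_onset for t in pref])
    if len(pref) < n_ranges * min_trials_per_range:
        return HoldGoFit([], np.empty(0), np.nan, np.empty(0), np.nan, np.nan,
                         0, "indeterminate")

    lo = -min(3.0, float(holds.max()))
    window = (lo, 0.5)

    def smoothed(align):
        peth = compute_peth(spikes, align, window, bin_width=bin_width)
        return smooth_peth(peth, smooth_sigma_ms)

    all_peth = smoothed(releases)
    criterion_level = criterion_frac * float(all_peth.rates.max())

    order = np.argsort(holds, kind="stable")
    groups = np.array_split(order, n_ranges)
    bounds, mean_holds, inters = [], [], []
    for g in groups:
        h = holds[g]
        bounds.append((float(h.min()), float(h.max())))
        mean_holds.append(float(h.mean()))
        rp = smoothed(releases[g])
        peak_idx = int(np.argmax(rp.rates))
        if rp.rates[peak_idx] < criterion_level:
            inters.append(np.nan)
            continue
        x = _backward_crossing(rp.bin_centers, rp.rates, peak_idx, criterion_level)
        inters.append(np.nan if x is None else x)

    mean_holds = np.asarray(mean_holds)
    inters = np.asarray(inters)
    valid = ~np.isnan(inters)
    if valid.sum() < 2:
        return HoldGoFit(bounds, mean_holds, criterion_level, inters,
                         np.nan, np.nan, int(valid.sum()), "indeterminate")
    res = stats.linregress(mean_holds[valid], inters[valid])
    slope = float(res.slope)
    return HoldGoFit(bounds, mean_holds, criterion_level, inters,
                     slope, float(res.intercept), int(valid.sum()),
                     classify_slope(slope, absolute_slope))


def classify_slope(slope: float, absolute_slope: bool = False) -> str:
    """Hold iff the intersection-time slope is at or below -0.5 (boundary
    inclusive); ``absolute_slope`` applies the threshold to |slope|."""
    crit = -abs(slope) if absolute_slope else slope
    return "Hold" if crit <= SLOPE_THRESHOLD else "Go"


def release_peak_time(spikes: SpikeTrain, trials: list[TrialEvent],
                      preferred_side: str, sigma_ms: float = 12.5) -> float:
    """Peak time (s) of the smoothed release-aligned PETH on the preferred side."""
    align = [t.release_onset for t in trials
             if t.completed and t.released_side == preferred_side]
    sp = smooth_peth(spikes, sigma_ms, align_times=align, window=RELEASE_WINDOW)
    return float(sp.bin_centers[int(np.argmax(sp.rates))])


def assign_task_type(relevance: TaskRelevance, holdgo: HoldGoFit | None,
                     peak_before_release: bool) -> str:
    """Compose the five-type taxonomy from the significance pattern.

    Release-significant neurons take a Hold or Go component: Hold requires a
    valid intersection fit with a Hold-class slope (the ramp signature);
    release-significant neurons without it -- including those whose peak
    follows the release (post-movement subpopulation) -- are Go.  Reward
    significance appends "&Reward"; reward-only neurons are Reward-type.
    """
    if relevance.release_significant:
        hold = holdgo is not None and holdgo.class_label == "Hold"
        component = "Hold" if hold else "Go"
        return component + ("&Reward" if relevance.reward_significant else "")
    if relevance.reward_significant:
        return "Reward"
    return "none"


def classify_neuron(spikes: SpikeTrain, trials: list[TrialEvent],
                    hemisphere: str = "left") -> dict:
    """Full per-neuron classification record."""
    rel = classify_relevance(spikes, trials, hemisphere)
    holdgo = None
    peak_before = False
    if rel.release_significant:
        holdgo = hold_go_slope(spikes, trials, rel.preferred_side_physical)
        peak_before = release_peak_time(spikes, trials, rel.preferred_side_physical) <= 0.0
    label = assign_task_type(rel, holdgo, peak_before)
    return {
        "neuron_id": spikes.neuron_id, "region": spikes.region,
        "p_contra": rel.p_release_contra, "p_ipsi": rel.p_release_ipsi,
        "p_reward": rel.p_reward, "preferred_side": rel.preferred_side,
        "preferred_side_physical": rel.preferred_side_physical,
        "included": rel.included,
        "slope": np.nan if holdgo is None else holdgo.slope,
        "peak_before_release": peak_before,
        "type": label,
    }


def classify_cohort(session: Session, include_all: bool = False) -> pd.DataFrame:
    """Classify every (included) neuron of a session."""
    hemi = session.metadata.get("recorded_hemisphere", "left")
    rows = []
    for st in session.spike_trains:
        if include_all or validate_inclusion(st, session.trials):
            rows.append(classify_neuron(st, session.trials, hemi))
    return pd.DataFrame(rows)


def type_fractions(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of task types per region."""
    if classified.empty:
        return pd.DataFrame(columns=["region", "type", "count", "proportion"])
    out = []
    for region, g in classified.groupby("region"):
        counts = g["type"].value_counts()
        for label in TASK_TYPES:
            c = int(counts.get(label, 0))
            out.append({"region": region, "type": label, "count": c,
                        "proportion": c / len(g)})
    return pd.DataFrame(out)
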