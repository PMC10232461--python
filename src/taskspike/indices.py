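"""Laterality and reward-modulation indices.

Normalized activity on each side is the peak-period rate over the baseline
rate minus one (c for contralateral, i for ipsilateral releases); the
laterality index maps (c, i) into [-1, +1] with +1 meaning purely
contralateral preference.  The reward modulation index contrasts
peak-period rates between rewarded (correct) and unrewarded (error) trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from taskspike.peth import compute_peth, pooled_relative_times
from taskspike.relevance import RELEASE_WINDOW, contra_side
from taskspike.session import SpikeTrain, TrialEvent

PEAK_HALF_WIDTH = 0.150        # peak period: center of peak bin +- 150 ms
BASELINE_WINDOW = (-1.0, -0.7)  # relative to release onset
HOLD_WINDOW = (-1.0, 0.0)
GO_REWARDMOD_HALF_WIDTH = 0.250
REWARD_REWARDMOD_WINDOW = (0.0, 0.5)
SURROGATE_REWARD_DELAY = 0.5   # stand-in reward time on unrewarded trials


def normalized_activity(sr_peak: float, sr_baseline: float) -> float:
    """SR_peak / SR_baseline - 1; NaN (undefined) when the baseline is zero."""
    if sr_baseline <= 0:
        return float("nan")
    return sr_peak / sr_baseline - 1.0


def laterality_index(c: float, i: float) -> float:
    """Piecewise laterality index in [-1, +1].

    (c - i) / (c + i) when both normalized activities are positive; +1 when
    only the contralateral one is, -1 when only the ipsilateral one is.
    When neither is positive the index is undefined (NaN) and the neuron is
    excluded from laterality summaries.  Exact zeros fall in the
    non-positive branch.
    """
    if np.isnan(c) or np.isnan(i):
        return float("nan")
    if c > 0 and i > 0:
        return (c - i) / (c + i)
    if c > 0:
        return 1.0
    if i > 0:
        return -1.0
    return float("nan")


def reward_modulation_index(sr_r: float, sr_nr: float) -> float:
    """(SR_r - SR_nr) / (SR_r + SR_nr); NaN when both rates are zero."""
    if sr_r < 0 or sr_nr < 0:
        raise ValueError("rates must be nonnegative")
    if sr_r + sr_nr == 0:
        return float("nan")
    return (sr_r - sr_nr) / (sr_r + sr_nr)


@dataclass
class ActivityIndices:
    peak_center: float          # s relative to release (preferred-side peak bin)
    sr_peak_contra: float
    sr_peak_ipsi: float
    sr_baseline_contra: float
    sr_baseline_ipsi: float
    c: float
    i: float
    laterality: float
    sr_rewarded: float
    sr_unrewarded: float
    reward_modulation: float


def _mean_rate(spike_times: np.ndarray, align_times, window) -> float:
    align_times = np.asarray(align_times, float)
    if align_times.size == 0:
        return float("nan")
    n = pooled_relative_times(spike_times, align_times, window).size
    return n / (align_times.size * (window[1] - window[0]))


def activity_indices(spikes: SpikeTrain, trials: list[TrialEvent],
                     preferred_side: str, hemisphere: str = "left",
                     kind: str = "go") -> ActivityIndices:
    """All side- and reward-contrast indices for one neuron.

    The peak bin is located on the preferred-side unsmoothed 20 ms PETH in
    the release window, and the same absolute peak period is reused on the
    non-preferred side.  ``kind`` selects the reward-modulation peak period:
    ``"go"`` uses peak center +-250 ms around release; ``"reward"`` uses
    reward onset to 500 ms (with a surrogate reward time of release +500 ms
    on unrewarded trials, which have no reward event).
    """
    contra = contra_side(hemisphere)
    completed = [t for t in trials if t.completed]
    rel_by_side = {
        "contra": [t.release_onset for t in completed if t.released_side == contra],
        "ipsi": [t.release_onset for t in completed if t.released_side != contra],
    }
    pref_key = "contra" if preferred_side == contra else "ipsi"
    peth = compute_peth(spikes, rel_by_side[pref_key], RELEASE_WINDOW)
    peak_center = float(peth.bin_centers[int(np.argmax(peth.rates))])
    peak_win = (peak_center - PEAK_HALF_WIDTH, peak_center + PEAK_HALF_WIDTH)

    times = spikes.spike_times
    sr_peak = {k: _mean_rate(times, v, peak_win) for k, v in rel_by_side.items()}
    sr_base = {k: _mean_rate(times, v, BASELINE_WINDOW) for k, v in rel_by_side.items()}
    c = normalized_activity(sr_peak["contra"], sr_base["contra"])
    i = normalized_activity(sr_peak["ipsi"], sr_base["ipsi"])

    rewarded = [t for t in completed if t.correct]
    unrewarded = [t for t in completed if not t.correct]
    if kind == "go":
        win = (peak_center - GO_REWARDMOD_HALF_WIDTH, peak_center + GO_REWARDMOD_HALF_WIDTH)
        sr_r = _mean_rate(times, [t.release_onset for t in rewarded], win)
        sr_nr = _mean_rate(times, [t.release_onset for t in unrewarded], win)
    elif kind == "reward":
        win = REWARD_REWARDMOD_WINDOW
        sr_r = _mean_rate(times, [t.reward_onset for t in rewarded], win)
        sr_nr = _mean_rate(times, [t.release_onset + SURROGATE_REWARD_DELAY
                                   for t in unrewarded], win)
    else:
        raise ValueError("kind must be 'go' or 'reward'")
    rmi = reward_modulation_index(max(sr_r, 0.0), max(sr_nr, 0.0)) \
        if not (np.isnan(sr_r) or np.isnan(sr_nr)) else float("nan")

    return ActivityIndices(
        peak_center=peak_center,
        sr_peak_contra=sr_peak["contra"], sr_peak_ipsi=sr_peak["ipsi"],
        sr_baseline_contra=sr_base["contra"], sr_baseline_ipsi=sr_base["ipsi"],
        c=c, i=i, laterality=laterality_index(c, i),
        sr_rewarded=sr_r, sr_unrewarded=sr_nr, reward_modulation=rmi,
    )


def hold_side_rates(spikes: SpikeTrain, trials: list[TrialEvent],
                    hemisphere: str = "left") -> tuple[float, float]:
    """Mean holding-period rates (-1000 to 0 ms pre-release), contra and ipsi."""
    contra = contra_side(hemisphere)
    completed = [t for t in trials if t.completed]
    con = _mean_rate(spikes.spike_times,
                     [t.release_onset for t in completed if t.released_side == contra],
                     HOLD_WINDOW)
    ips = _mean_rate(spikes.spike_times,
                     [t.release_onset for t in completed if t.released_side != contra],
                     HOLD_WINDOW)
    return con, ips
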