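"""Event-aligned firing-rate metrics.

PETHs (peri-event time histograms) are trial-averaged rates in fixed bins
(20 ms by default, matching the figures of the analysis this implements);
smoothed PETHs convolve a fine-binned rate with a Gaussian kernel.
Also here: release-onset detection from pedal traces, ongoing rate, and
regular-spiking vs fast-spiking classification by minimum cross-entropy
thresholding of the spike-duration histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from taskspike.session import PedalTrace, SpikeTrain, TrialEvent


@dataclass
class Peth:
    bin_edges: np.ndarray      # seconds relative to the alignment event
    rates: np.ndarray          # Hz per bin
    n_trials: int
    alignment: str = "release"
    side: str = "all"
    smoothing_sigma_ms: float | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def pooled_relative_times(spike_times: np.ndarray, align_times, window) -> np.ndarray:
    """Spike times relative to each alignment event, pooled across trials."""
    align_times = np.asarray(align_times, float)
    lo, hi = window
    out = []
    for a in align_times:
        i0, i1 = np.searchsorted(spike_times, [a + lo, a + hi])
        out.append(spike_times[i0:i1] - a)
    return np.concatenate(out) if out else np.empty(0)


def compute_peth(spikes: SpikeTrain | np.ndarray, align_times, window,
                 bin_width: float = 0.02, alignment: str = "release",
                 side: str = "all") -> Peth:
    """Unsmoothed PETH: rate_b = count_b / (n_trials * bin_width)."""
    align_times = np.asarray(align_times, float)
    if align_times.size == 0:
        raise ValueError("align_times must be non-empty")
    lo, hi = window
    if not lo < hi:
        raise ValueError("window start must precede end")
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    rel = pooled_relative_times(times, align_times, (lo, edges[-1]))
    counts, _ = np.histogram(rel, bins=edges)
    rates = counts / (align_times.size * bin_width)
    return Peth(edges, rates, int(align_times.size), alignment, side)


def smooth_peth(source, sigma_ms: float, resolution_ms: float = 1.0,
                align_times=None, window=None, alignment: str = "release",
                side: str = "all") -> Peth:
    """Gaussian-smoothed PETH.

    ``source`` is either a :class:`Peth` (its rates are convolved in place
    on its own grid) or spike times / a :class:`SpikeTrain`, in which case
    ``align_times`` and ``window`` are required and the rate is built on a
    fine grid of ``resolution_ms`` bins before convolution.  The default
    1 ms internal resolution is indistinguishable from finer grids for the
    sigmas used here (>= 12.5 ms); pass ``resolution_ms=0.05`` for exactness.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be > 0")
    if isinstance(source, Peth):
        sig_bins = sigma_ms / 1000.0 / source.bin_width
        rates = gaussian_filter1d(source.rates, sig_bins, mode="constant")
        return Peth(source.bin_edges, rates, source.n_trials, source.alignment,
                    source.side, smoothing_sigma_ms=sigma_ms)
    peth = compute_peth(source, align_times, window,
                        bin_width=resolution_ms / 1000.0,
                        alignment=alignment, side=side)
    rates = gaussian_filter1d(peth.rates, sigma_ms / resolution_ms, mode="constant")
    return Peth(peth.bin_edges, rates, peth.n_trials, alignment, side,
                smoothing_sigma_ms=sigma_ms)


def ongoing_rate(spikes: SpikeTrain | np.ndarray, epoch) -> float:
    """Mean spike rate (Hz) over the epoch ``(start, end)``."""
    start, end = epoch
    if end <= start:
        raise ValueError("epoch end must exceed start")
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    i0, i1 = np.searchsorted(times, [start, end])
    return (i1 - i0) / (end - start)


# ---------------------------------------------------------------------------
# release-onset detection

HOLDING_AREA_MAX = 30.0  # percent of pedal range of motion


class NoReleaseDetected(ValueError):
    pass


def detect_release_onset(trace: PedalTrace, trial: TrialEvent,
                         excursion_pct: float = 5.0,
                         absolute: bool = False) -> float:
    """Release onset from a pedal trace.

    Finds the first crossing of the 30% holding-area boundary after the end
    of the holding period (coarse task-progression detection), then scans
    backward to the last sample at or below a 5% excursion above the local
    holding baseline (the within-trial median position); the first sample
    exceeding that excursion is the release onset.  With ``absolute=True``
    the 5% criterion is absolute pedal position instead of baseline-relative.
    """
    t = trace.sample_times
    p = trace.positions
    i_hold = np.searchsorted(t, trial.hold_onset)
    i_end = np.searchsorted(t, trial.hold_onset + trial.hold_duration + 1.0)
    seg = p[i_hold:i_end]
    above = np.nonzero(seg > HOLDING_AREA_MAX)[0]
    if above.size == 0:
        raise NoReleaseDetected(
            f"trial {trial.trial_id}: no 30% crossing after hold onset")
    i30 = above[0]
    baseline = float(np.median(seg[:i30])) if i30 > 0 else 0.0
    level = excursion_pct if absolute else baseline + excursion_pct
    below = np.nonzero(seg[:i30] <= level)[0]
    i_on = (below[-1] + 1) if below.size else i30
    return float(t[i_hold + min(i_on, i30)])


# ---------------------------------------------------------------------------
# RS/FS classification


@dataclass
class WaveformClassification:
    threshold_ms: float
    labels: np.ndarray                 # per-neuron {"RS", "FS"}
    candidate_thresholds: np.ndarray
    cross_entropy_curve: np.ndarray
    degenerate: bool = False


def classify_rs_fs(durations_ms, bin_width_ms: float = 0.02) -> WaveformClassification:
    """Split spike durations into RS (>= threshold) and FS (< threshold).

    The threshold minimizes the Li-Lee minimum-cross-entropy objective over
    candidate thresholds on the duration histogram: for each candidate t the
    objective is -(S_lo ln mu_lo + S_hi ln mu_hi) with S the duration-weighted
    mass and mu the mean duration on each side.  Boundary durations are RS.
    """
    d = np.asarray(durations_ms, float)
    if d.size < 2:
        raise ValueError("need at least 2 durations")
    lo, hi = d.min(), d.max()
    degenerate = False
    if hi - lo < bin_width_ms:
        warnings.warn("degenerate duration distribution; threshold unreliable")
        thr = float(lo)
        return WaveformClassification(thr, np.where(d >= thr, "RS", "FS"),
                                      np.array([thr]), np.array([np.nan]),
                                      degenerate=True)
    edges = np.arange(lo, hi + 2 * bin_width_ms, bin_width_ms)
    hist, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist * centers                       # duration-weighted mass per bin
    cum_n = np.cumsum(hist)
    cum_w = np.cumsum(w)
    total_n, total_w = cum_n[-1], cum_w[-1]

    obj = np.full(centers.size - 1, np.inf)
    for j in range(centers.size - 1):        # threshold between bins j and j+1
        n_lo, w_lo = cum_n[j], cum_w[j]
        n_hi, w_hi = total_n - n_lo, total_w - w_lo
        if n_lo == 0 or n_hi == 0:
            continue
        mu_lo, mu_hi = w_lo / n_lo, w_hi / n_hi
        obj[j] = -(w_lo * np.log(mu_lo) + w_hi * np.log(mu_hi))
    if not np.isfinite(obj).any():
        degenerate = True
        j_best = 0
        warnings.warn("flat cross-entropy objective; threshold unreliable")
    else:
        # the objective is flat across empty inter-mode bins: take the
        # middle of the minimal plateau (the center of the gap)
        plateau = np.flatnonzero(obj <= obj.min() + 1e-9 * abs(obj.min()))
        j_best = int(plateau[plateau.size // 2])
    thr = float(edges[j_best + 1])
    labels = label_durations(d, thr)
    return WaveformClassification(thr, labels, edges[1:-1], obj, degenerate=degenerate)


def label_durations(durations_ms, threshold_ms: float) -> np.ndarray:
    """RS for durations at or above the threshold, FS below (boundary -> RS)."""
    return np.where(np.asarray(durations_ms, float) >= threshold_ms, "RS", "FS")
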