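"""Collision-test identification of projection neurons (Multi-Linc style).

Antidromic spikes evoked by axonal stimulation are counted inside a
post-stimulus window by thresholding the window's most negative amplitude
(spike trough) with an ROC-derived cut-off.  A neuron is accepted as a
projection neuron when all of the following hold:

* control spike probability above 50%,
* test (spike-triggered) probability below half the control probability
  -- collisional disappearance,
* a 2x2 chi-square test of spike / no-spike counts in control vs test
  events at p < 0.05,
* constant latency: the IQR (jitter) of trough times is below 0.5 ms,
* frequency-following (when paired-pulse data exist): reliability >= 0.8
  at 100 Hz and >= 0.5 at 200 Hz.

The antidromic latency is the median of trough times from stimulation
onset; its jitter is the 75th minus the 25th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

CHI2_ALPHA = 0.05
JITTER_MAX_MS = 0.5
MIN_CONTROL_SPIKES = 10   # pre-screen: antidromic-like responses in many control traces
FF_PASS = {"ff100": 0.8, "ff200": 0.5}


@dataclass
class CollisionTest:
    neuron_id: str
    trough_threshold: float
    control_counts: tuple          # (spike, no_spike)
    test_counts: tuple
    p_control: float
    p_test: float
    chi2_stat: float
    chi2_p: float
    latency_median_ms: float
    jitter_ms: float
    passes: bool
    criteria: dict = field(default_factory=dict)
    low_confidence_threshold: bool = False


def roc_threshold(trough_values, labels=None) -> tuple[float, bool]:
    """Amplitude cut-off separating spike-present from spike-absent troughs.

    With ground-truth ``labels`` (1 = spike present) the threshold maximizes
    Youden's J over the ROC of trough value as a classifier (spikes are the
    *more negative* troughs).  Without labels, a 2-means split of the trough
    values provides pseudo-labels first.  Returns ``(threshold, low_conf)``
    where ``low_conf`` flags unimodal/degenerate inputs.
    """
    v = np.asarray(trough_values, float)
    if v.size < 10:
        raise ValueError("need at least 10 trough values")
    low_conf = False
    if np.ptp(v) == 0:
        return float(v[0]), True
    if labels is None:
        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(v.reshape(-1, 1))
        neg = int(np.argmin(km.cluster_centers_[:, 0]))
        labels = (km.labels_ == neg).astype(int)
        lo, hi = np.sort(km.cluster_centers_[:, 0])
        # unimodality check: a genuine spike/no-spike split separates the
        # 2-means centers far beyond the within-cluster spreads
        s_within = sum(v[km.labels_ == j].std() for j in (0, 1))
        if labels.sum() in (0, v.size) or (hi - lo) < 2.5 * (s_within + 1e-12):
            low_conf = True
    labels = np.asarray(labels, int)
    if labels.sum() in (0, v.size):
        return float(v.min() - 1.0), True

    # candidate cut points between sorted values; classify "spike" as v <= thr
    order = np.argsort(v)
    vs, ls = v[order], labels[order]
    n_pos, n_neg = ls.sum(), (1 - ls).sum()
    tp = np.cumsum(ls)
    fp = np.cumsum(1 - ls)
    j_stat = tp / n_pos - fp / n_neg
    j_best = int(np.argmax(j_stat))
    thr = vs[j_best] if j_best == vs.size - 1 else 0.5 * (vs[j_best] + vs[j_best + 1])
    return float(thr), low_conf


def spike_probabilities(control_troughs, test_troughs, threshold: float
                        ) -> tuple[float, float, np.ndarray]:
    """Spike probabilities and the 2x2 (control/test x spike/no-spike) table."""
    c = np.asarray(control_troughs, float)
    t = np.asarray(test_troughs, float)
    if c.size == 0 or t.size == 0:
        raise ValueError("empty control or test events")
    counts = np.array([
        [int((c <= threshold).sum()), int((c > threshold).sum())],
        [int((t <= threshold).sum()), int((t > threshold).sum())],
    ])
    return counts[0, 0] / c.size, counts[1, 0] / t.size, counts


def collision_decision(counts, yates: bool = False) -> tuple[float, float, bool]:
    """Pearson chi-square (2x2) on spike/no-spike x control/test counts."""
    counts = np.asarray(counts, int)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has a zero margin")
    stat, p, _, _ = chi2_contingency(counts, correction=yates)
    return float(stat), float(p), bool(p < CHI2_ALPHA)


def latency_jitter(peak_positions_ms) -> tuple[float, float, bool]:
    """Median latency, IQR jitter, and the constant-latency (<0.5 ms) gate."""
    p = np.asarray(peak_positions_ms, float)
    if p.size < 3:
        return (float(np.median(p)) if p.size else float("nan"), float("nan"), False)
    q25, q75 = np.percentile(p, [25, 75])
    jitter = float(q75 - q25)
    return float(np.median(p)), jitter, jitter < JITTER_MAX_MS


def identify_projection(events: pd.DataFrame, neuron_id: str | None = None,
                        use_truth_labels: bool = False,
                        yates: bool = False) -> CollisionTest:
    """Compose the full projection-identification decision for one neuron.

    ``events`` is the per-neuron stimulation table (see
    :class:`taskspike.session.StimEpoch`): columns ``kind`` in
    {control, test, ff100, ff200}, ``trough``, ``peak_ms``, and optionally a
    simulation-truth ``spike_present`` column (used only when
    ``use_truth_labels`` is set).
    """
    if neuron_id is not None:
        events = events[events["neuron_id"] == neuron_id]
    nid = neuron_id or (events["neuron_id"].iloc[0] if len(events) else "?")
    control = events[events["kind"] == "control"]
    test = events[events["kind"] == "test"]
    if len(control) == 0 or len(test) == 0:
        raise ValueError(f"neuron {nid}: missing control or test events")

    pooled = pd.concat([control, test])
    labels = pooled["spike_present"].to_numpy() \
        if use_truth_labels and "spike_present" in pooled else None
    thr, low_conf = roc_threshold(pooled["trough"].to_numpy(), labels)

    p_control, p_test, counts = spike_probabilities(
        control["trough"].to_numpy(), test["trough"].to_numpy(), thr)

    criteria = {}
    criteria["prescreen_control_spikes"] = bool(
        counts[0, 0] >= MIN_CONTROL_SPIKES and not low_conf)
    criteria["control_above_half"] = bool(p_control > 0.5)
    criteria["test_below_half_control"] = bool(p_test < 0.5 * p_control)

    if criteria["control_above_half"] and counts[:, 0].sum() > 0 and counts[:, 1].sum() > 0:
        chi2_stat, chi2_p, chi2_pass = collision_decision(counts, yates=yates)
    else:
        chi2_stat, chi2_p, chi2_pass = float("nan"), float("nan"), False
    criteria["chi2"] = chi2_pass

    spike_peaks = control.loc[control["trough"] <= thr, "peak_ms"].to_numpy()
    lat_med, jitter, const_lat = latency_jitter(spike_peaks)
    criteria["constant_latency"] = const_lat

    for kind, level in FF_PASS.items():
        ff = events[events["kind"] == kind]
        if len(ff):
            rel = float((ff["trough"].to_numpy() <= thr).mean())
            criteria[f"{kind}_reliability"] = bool(rel >= level)

    passes = all(criteria.values())
    return CollisionTest(nid, thr, tuple(counts[0]), tuple(counts[1]),
                         p_control, p_test, chi2_stat, chi2_p,
                         lat_med, jitter, passes, criteria, low_conf)


def collision_cohort(stim_epochs, **kwargs) -> pd.DataFrame:
    """Run projection identification for every neuron with stimulation data."""
    rows = []
    for ep in stim_epochs:
        for nid, g in ep.events.groupby("neuron_id"):
            try:
                ct = identify_projection(g, **kwargs)
            except ValueError:
                continue
            rows.append({
                "neuron_id": nid, "site": ep.site, "threshold": ct.trough_threshold,
                "p_control": ct.p_control, "p_test": ct.p_test,
                "chi2": ct.chi2_stat, "chi2_p": ct.chi2_p,
                "latency_ms": ct.latency_median_ms, "jitter_ms": ct.jitter_ms,
                "passes": ct.passes,
            })
    return pd.DataFrame(rows)
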