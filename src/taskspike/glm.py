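"""Stepwise GLM classification of time vs pedal coding.

The smoothed spike rate (Gaussian sigma = 150 ms) is regressed on three
candidate predictors sampled on a common within-trial grid: the left and
right pedal trajectories and the *trial time* (elapsed seconds since the
most recent pedal-holding onset, resetting at every hold onset).  Terms
enter by a partial F-test at p < 0.05 and leave at p > 0.10, iterated to a
fixed point from an intercept-only model; Bonferroni-corrected term
p-values (factor 3, one per candidate) then classify cells as Time-,
Time&Pedal-, or Pedal-correlated.

The fit is a Gaussian-identity linear model: the response is a continuous
smoothed rate, not a count, so deviance F-tests reduce to partial F-tests
on residual sums of squares.  Smoothed-rate samples are serially correlated
by construction; p-values are reported without correction for this (the
``decimate`` option subsamples the grid to roughly independent samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from taskspike.session import Session, SpikeTrain

CANDIDATE_TERMS = ("left_pedal", "right_pedal", "trial_time")
BONFERRONI_FACTOR = 3


@dataclass
class GlmCellResult:
    neuron_id: str
    candidate_terms: tuple
    selected_terms: list
    coefficients: dict
    term_p_values: dict
    alpha_add: float = 0.05
    alpha_remove: float = 0.10
    corrected_alpha: float = 0.05 / BONFERRONI_FACTOR
    dropped_terms: list = field(default_factory=list)  # rank-deficient candidates
    converged: bool = True
    n_samples: int = 0
    class_label: str = "none"


def build_design(session: Session, neuron: SpikeTrain,
                 resolution_ms: float = 20.0, sigma_ms: float = 150.0,
                 smooth_resolution_ms: float = 1.0) -> pd.DataFrame:
    """Aligned response and predictor series on the within-trial grid.

    Samples are restricted to spans between consecutive hold onsets (the
    last span ends 2 s after the final release); the response is the
    session-wide Gaussian-smoothed rate evaluated on the grid.
    """
    trials = session.trials
    if not trials:
        raise ValueError("session has no trials")
    t_end = float(session.pedal_traces["left"].sample_times[-1])

    # smoothed rate on a fine grid, then sampled at the design resolution
    fine = smooth_resolution_ms / 1000.0
    n_fine = int(np.ceil(t_end / fine))
    counts, edges = np.histogram(neuron.spike_times, bins=n_fine, range=(0.0, t_end))
    rate_fine = gaussian_filter1d(counts / fine, sigma_ms / smooth_resolution_ms,
                                  mode="constant")

    step = resolution_ms / 1000.0
    grid = np.arange(step / 2.0, t_end, step)
    rate = np.interp(grid, 0.5 * (edges[:-1] + edges[1:]), rate_fine)

    starts = np.array([t.hold_onset for t in trials])
    span_ends = np.append(starts[1:], min(t_end, starts[-1] + trials[-1].hold_duration + 2.0))
    idx = np.searchsorted(starts, grid, side="right") - 1
    in_span = (idx >= 0) & (grid < span_ends[np.clip(idx, 0, len(starts) - 1)])
    grid, rate, idx = grid[in_span], rate[in_span], idx[in_span]
    trial_time = grid - starts[idx]

    left = session.pedal_traces["left"]
    right = session.pedal_traces["right"]
    lp = np.interp(grid, left.sample_times, left.positions)
    rp = np.interp(grid, right.sample_times, right.positions)
    return pd.DataFrame({"t": grid, "rate": rate, "left_pedal": lp,
                         "right_pedal": rp, "trial_time": trial_time})


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _design_matrix(design: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(design))] + [design[t].to_numpy() for t in terms]
    return np.column_stack(cols)


def _partial_f_p(rss0: float, rss1: float, df_diff: int, df_resid: int) -> float:
    if rss1 <= 0 or df_resid <= 0:
        return 0.0
    f = max((rss0 - rss1) / df_diff / (rss1 / df_resid), 0.0)
    return float(stats.f.sf(f, df_diff, df_resid))


def stepwise_fit(design: pd.DataFrame, neuron_id: str = "",
                 alpha_add: float = 0.05, alpha_remove: float = 0.10,
                 max_iter: int = 20, decimate: int = 1) -> GlmCellResult:
    """Forward-backward stepwise selection from an intercept-only model."""
    if decimate > 1:
        design = design.iloc[::decimate].reset_index(drop=True)
    y = design["rate"].to_numpy()
    n = len(design)
    candidates = []
    dropped = []
    for t in CANDIDATE_TERMS:
        if np.ptp(design[t].to_numpy()) == 0:
            dropped.append(t)  # constant predictor: rank-deficient, excluded
        else:
            candidates.append(t)

    selected: list[str] = []
    converged = False
    for _ in range(max_iter):
        changed = False
        # forward: best addition below alpha_add
        rss_cur = _rss(_design_matrix(design, selected), y)
        best_p, best_t = None, None
        for t in candidates:
            if t in selected:
                continue
            rss1 = _rss(_design_matrix(design, selected + [t]), y)
            p = _partial_f_p(rss_cur, rss1, 1, n - len(selected) - 2)
            if best_p is None or p < best_p:
                best_p, best_t = p, t
        if best_t is not None and best_p < alpha_add:
            selected.append(best_t)
            changed = True
        # backward: worst removal above alpha_remove
        if selected:
            rss_full = _rss(_design_matrix(design, selected), y)
            worst_p, worst_t = None, None
            for t in selected:
                rest = [u for u in selected if u != t]
                rss0 = _rss(_design_matrix(design, rest), y)
                p = _partial_f_p(rss0, rss_full, 1, n - len(selected) - 1)
                if worst_p is None or p > worst_p:
                    worst_p, worst_t = p, t
            if worst_p is not None and worst_p > alpha_remove:
                selected.remove(worst_t)
                changed = True
        if not changed:
            converged = True
            break

    # final coefficients and per-candidate p-values in the final model context
    X = _design_matrix(design, selected)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefficients = {"intercept": float(beta[0])}
    coefficients.update({t: float(b) for t, b in zip(selected, beta[1:])})
    rss_full = _rss(X, y)
    p_values = {}
    for t in candidates:
        if t in selected:
            rest = [u for u in selected if u != t]
            rss0 = _rss(_design_matrix(design, rest), y)
            p_values[t] = _partial_f_p(rss0, rss_full, 1, n - len(selected) - 1)
        else:
            rss1 = _rss(_design_matrix(design, selected + [t]), y)
            p_values[t] = _partial_f_p(rss_full, rss1, 1, n - len(selected) - 2)
    for t in dropped:
        p_values[t] = float("nan")

    result = GlmCellResult(neuron_id=neuron_id, candidate_terms=CANDIDATE_TERMS,
                           selected_terms=selected, coefficients=coefficients,
                           term_p_values=p_values, alpha_add=alpha_add,
                           alpha_remove=alpha_remove, dropped_terms=dropped,
                           converged=converged, n_samples=n)
    result.class_label = classify_glm(result)
    return result


def classify_glm(result: GlmCellResult) -> str:
    """Time / Time&Pedal / Pedal / none from Bonferroni-corrected p-values."""
    alpha = result.corrected_alpha
    sig = {t for t in result.selected_terms
           if result.term_p_values.get(t, 1.0) < alpha}
    time_sig = "trial_time" in sig
    pedal_sig = bool(sig & {"left_pedal", "right_pedal"})
    if time_sig and pedal_sig:
        return "Time&Pedal"
    if time_sig:
        return "Time"
    if pedal_sig:
        return "Pedal"
    return "none"


def glm_cohort(session: Session, **kwargs) -> pd.DataFrame:
    rows = []
    for st in session.spike_trains:
        design = build_design(session, st)
        res = stepwise_fit(design, neuron_id=st.neuron_id, **kwargs)
        rows.append({
            "neuron_id": st.neuron_id, "region": st.region,
            "selected_terms": "+".join(res.selected_terms) or "-",
            **{f"p_{t}": res.term_p_values.get(t, np.nan) for t in CANDIDATE_TERMS},
            **{f"coef_{t}": res.coefficients.get(t, np.nan) for t in CANDIDATE_TERMS},
            "class": res.class_label,
        })
    return pd.DataFrame(rows)
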