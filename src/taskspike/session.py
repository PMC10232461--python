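"""Session data model and tabular I/O.

A *session* is one recording block: a table of behavioral trials, two pedal
position traces (left/right, percent of range of motion), the spike trains
of all simultaneously isolated neurons, and optionally the optogenetic
stimulation events used for collision testing.

On disk a session is a directory of plain TSV files (``trials.tsv``,
``spikes.tsv``, ``neurons.tsv``, ``pedals.tsv``, ``stims.tsv``,
``meta.yaml``) plus a ``manifest.json`` with SHA-256 checksums so silent
corruption is detected on read.  All times are session-relative seconds
stored at microsecond precision (recordings are digitized at 20 kHz, so
50 us native resolution); pedal positions are stored at 0.0001% precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SIDES = ("left", "right")
REGIONS = ("CA1", "LECs", "LECd", "M1")
STIM_SITES = ("mPFC", "CA1")
REWARD_DELAYS = (0.3, 0.4, 0.5, 0.6, 0.7)

#: Inclusion gates for single-neuron analysis: at least this many completed
#: trials and this many spikes during task performance.
MIN_TRIALS = 20
MIN_SPIKES = 250


class SessionValidationError(ValueError):
    """A session violated one of the documented invariants."""


class SessionReadError(IOError):
    """A session directory is missing a component or failed its checksum."""


@dataclass
class TrialEvent:
    """One behavioral trial.

    Completed trials have ``release_onset == hold_onset + hold_duration`` and
    a released side; immature trials (holding period < 1 s not completed)
    carry only hold onset/duration.  Correct trials additionally carry a
    reward onset 300-700 ms (100 ms steps) after release.
    """

    trial_id: int
    hold_onset: float
    hold_duration: float
    block_side: str
    correct: bool
    immature: bool
    release_onset: float | None = None
    released_side: str | None = None
    reward_onset: float | None = None

    @property
    def completed(self) -> bool:
        return not self.immature


@dataclass
class PedalTrace:
    side: str
    sample_times: np.ndarray
    positions: np.ndarray
    sample_rate: float


@dataclass
class SpikeTrain:
    """Sorted spike times of one isolated neuron."""

    neuron_id: str
    region: str
    spike_times: np.ndarray
    spike_duration_ms: float
    cell_class: str = "unset"  # {"RS", "FS", "unset"}

    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class StimEpoch:
    """Stimulation events at one site, with per-neuron response measurements.

    ``events`` has one row per (stimulus, neuron) pair:
    ``stim_time_s, neuron_id, kind, trigger_spike_time_s, trough, peak_ms``
    where ``kind`` is ``control`` (no trigger), ``test`` (triggered on a
    spontaneous spike), or ``ff100``/``ff200`` (second pulse of a
    frequency-following pair).  ``trough`` is the most negative filtered
    amplitude in the post-stimulus window and ``peak_ms`` its time from
    stimulation onset.
    """

    site: str
    pulse_ms: float
    events: pd.DataFrame

    @property
    def stim_times(self) -> np.ndarray:
        return self.events["stim_time_s"].to_numpy()


@dataclass
class Session:
    trials: list[TrialEvent]
    pedal_traces: dict[str, PedalTrace]
    spike_trains: list[SpikeTrain]
    stim_epochs: list[StimEpoch] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def completed_trials(self) -> list[TrialEvent]:
        return [t for t in self.trials if t.completed]

    def neuron(self, neuron_id: str) -> SpikeTrain:
        for st in self.spike_trains:
            if st.neuron_id == neuron_id:
                return st
        raise KeyError(neuron_id)


# ---------------------------------------------------------------------------
# validation


def validate_trials(trials: list[TrialEvent]) -> None:
    bad: list[str] = []
    for t in trials:
        if t.immature:
            if t.correct:
                bad.append(f"trial {t.trial_id}: immature trial marked correct")
            if t.reward_onset is not None:
                bad.append(f"trial {t.trial_id}: immature trial has reward_onset")
            if t.hold_duration >= 1.0:
                bad.append(f"trial {t.trial_id}: immature trial with hold >= 1 s")
            continue
        if t.hold_duration < 1.0:
            bad.append(f"trial {t.trial_id}: completed trial with hold < 1 s")
        if t.release_onset is None or t.released_side is None:
            bad.append(f"trial {t.trial_id}: completed trial missing release")
            continue
        if abs(t.release_onset - (t.hold_onset + t.hold_duration)) > 1e-6:
            bad.append(f"trial {t.trial_id}: release_onset != hold_onset + hold_duration")
        if t.correct != (t.released_side == t.block_side):
            bad.append(f"trial {t.trial_id}: correct flag inconsistent with sides")
        if t.correct:
            if t.reward_onset is None:
                bad.append(f"trial {t.trial_id}: correct trial missing reward_onset")
            else:
                delay = t.reward_onset - t.release_onset
                if min(abs(delay - d) for d in REWARD_DELAYS) > 1e-6:
                    bad.append(
                        f"trial {t.trial_id}: reward delay {delay:.3f} s not in "
                        "{0.3,0.4,0.5,0.6,0.7}"
                    )
        elif t.reward_onset is not None:
            bad.append(f"trial {t.trial_id}: unrewarded trial has reward_onset")
    if bad:
        raise SessionValidationError("invalid trials:\n" + "\n".join(bad))


def validate_session(session: Session) -> None:
    """Check all documented invariants; raise listing every offending row."""
    validate_trials(session.trials)
    bad: list[str] = []
    for side, trace in session.pedal_traces.items():
        if trace.side != side:
            bad.append(f"pedal trace keyed {side} labeled {trace.side}")
        if np.any(trace.positions < 0) or np.any(trace.positions > 100):
            bad.append(f"pedal {side}: position outside [0, 100]")
        dt = np.diff(trace.sample_times)
        if trace.sample_times.size > 1 and (
            np.any(dt <= 0) or np.ptp(dt) > 2e-6
        ):
            bad.append(f"pedal {side}: sample times not uniform/increasing")
    span_hi = max(
        (t.sample_times[-1] for t in session.pedal_traces.values() if t.sample_times.size),
        default=np.inf,
    )
    for st in session.spike_trains:
        if st.region not in REGIONS:
            bad.append(f"neuron {st.neuron_id}: unknown region {st.region}")
        if st.spike_duration_ms <= 0:
            bad.append(f"neuron {st.neuron_id}: nonpositive spike duration")
        if np.any(np.diff(st.spike_times) <= 0):
            bad.append(f"neuron {st.neuron_id}: spike times not strictly increasing")
    for t in session.trials:
        for name, v in (("hold_onset", t.hold_onset), ("release_onset", t.release_onset),
                        ("reward_onset", t.reward_onset)):
            if v is not None and not (0.0 <= v <= span_hi + 1e-6):
                bad.append(f"trial {t.trial_id}: {name} {v:.3f} outside trace span")
    for ep in session.stim_epochs:
        if ep.site not in STIM_SITES:
            bad.append(f"stim epoch: unknown site {ep.site}")
        st_times = ep.events["stim_time_s"].to_numpy()
        if np.any(np.diff(np.sort(st_times)) < 0):  # pragma: no cover - defensive
            bad.append("stim epoch: unsorted times")
        triggered = ep.events["kind"].eq("test")
        if ep.events.loc[triggered, "trigger_spike_time_s"].isna().any():
            bad.append(f"stim epoch {ep.site}: triggered stim missing trigger spike time")
        known = set(nt.neuron_id for nt in session.spike_trains)
        unknown = set(ep.events["neuron_id"]) - known
        if unknown:
            bad.append(f"stim epoch {ep.site}: unknown neuron ids {sorted(unknown)}")
    if bad:
        raise SessionValidationError("invalid session:\n" + "\n".join(bad))


def validate_inclusion(spikes: SpikeTrain, trials: list[TrialEvent]) -> bool:
    """Single-neuron inclusion gate: >=20 completed trials and >=250 spikes."""
    n_completed = sum(1 for t in trials if t.completed)
    return n_completed >= MIN_TRIALS and spikes.n_spikes() >= MIN_SPIKES


# ---------------------------------------------------------------------------
# tabular I/O

_TRIAL_COLS = [
    "trial_id", "hold_onset_s", "hold_duration_s", "release_onset_s",
    "released_side", "block_side", "correct", "immature", "reward_onset_s",
]


def _fmt(x: float | None, prec: int = 6) -> str:
    return "" if x is None else f"{x:.{prec}f}"


def write_session(session: Session, path: str | Path) -> None:
    """Write a validated session to ``path`` as TSV files plus a manifest."""
    validate_session(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trials:
        rows.append({
            "trial_id": t.trial_id,
            "hold_onset_s": _fmt(t.hold_onset),
            "hold_duration_s": _fmt(t.hold_duration),
            "release_onset_s": _fmt(t.release_onset),
            "released_side": t.released_side or "",
            "block_side": t.block_side,
            "correct": int(t.correct),
            "immature": int(t.immature),
            "reward_onset_s": _fmt(t.reward_onset),
        })
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(path / "trials.tsv", sep="\t", index=False)

    with open(path / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\tregion\tspike_time_s\n")
        for st in session.spike_trains:
            for s in st.spike_times:
                fh.write(f"{st.neuron_id}\t{st.region}\t{s:.6f}\n")
    with open(path / "neurons.tsv", "w") as fh:
        fh.write("neuron_id\tregion\tspike_duration_ms\tcell_class\n")
        for st in session.spike_trains:
            fh.write(f"{st.neuron_id}\t{st.region}\t{st.spike_duration_ms:.4f}\t{st.cell_class}\n")

    left = session.pedal_traces["left"]
    right = session.pedal_traces["right"]
    with open(path / "pedals.tsv", "w") as fh:
        fh.write("time_s\tleft_pct\tright_pct\n")
        for t, lp, rp in zip(left.sample_times, left.positions, right.positions):
            fh.write(f"{t:.6f}\t{lp:.4f}\t{rp:.4f}\n")

    stim_frames = []
    for ep in session.stim_epochs:
        df = ep.events.copy()
        df.insert(0, "site", ep.site)
        df.insert(1, "pulse_ms", ep.pulse_ms)
        stim_frames.append(df)
    if stim_frames:
        allstim = pd.concat(stim_frames, ignore_index=True)
        allstim.to_csv(path / "stims.tsv", sep="\t", index=False, float_format="%.6f")

    meta = dict(session.metadata)
    meta["pedal_sample_rate_hz"] = float(left.sample_rate)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    manifest = {}
    for f in sorted(p.name for p in path.iterdir() if p.name != "manifest.json"):
        manifest[f] = hashlib.sha256((path / f).read_bytes()).hexdigest()
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for required in ("trials.tsv", "spikes.tsv", "neurons.tsv", "pedals.tsv", "meta.yaml"):
        if not (path / required).exists():
            raise SessionReadError(f"missing component: {required}")
    mpath = path / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        for fname, digest in manifest.items():
            fp = path / fname
            if not fp.exists():
                raise SessionReadError(f"missing component: {fname}")
            if hashlib.sha256(fp.read_bytes()).hexdigest() != digest:
                raise SessionReadError(f"checksum mismatch in {fname}")

    tdf = pd.read_csv(path / "trials.tsv", sep="\t", dtype={"released_side": "string"})
    trials = []
    for r in tdf.itertuples(index=False):
        side = r.released_side
        trials.append(TrialEvent(
            trial_id=int(r.trial_id),
            hold_onset=float(r.hold_onset_s),
            hold_duration=float(r.hold_duration_s),
            release_onset=_opt_float(r.release_onset_s),
            released_side=None if pd.isna(side) or side == "" else str(side),
            block_side=str(r.block_side),
            correct=bool(r.correct),
            immature=bool(r.immature),
            reward_onset=_opt_float(r.reward_onset_s),
        ))

    ndf = pd.read_csv(path / "neurons.tsv", sep="\t")
    sdf = pd.read_csv(path / "spikes.tsv", sep="\t")
    by_neuron = {k: g["spike_time_s"].to_numpy(float) for k, g in sdf.groupby("neuron_id")}
    spike_trains = []
    for r in ndf.itertuples(index=False):
        spike_trains.append(SpikeTrain(
            neuron_id=str(r.neuron_id),
            region=str(r.region),
            spike_times=by_neuron.get(str(r.neuron_id), np.empty(0)),
            spike_duration_ms=float(r.spike_duration_ms),
            cell_class=str(r.cell_class),
        ))

    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    rate = float(meta.pop("pedal_sample_rate_hz", np.nan))
    pdf = pd.read_csv(path / "pedals.tsv", sep="\t")
    times = pdf["time_s"].to_numpy(float)
    traces = {
        "left": PedalTrace("left", times, pdf["left_pct"].to_numpy(float), rate),
        "right": PedalTrace("right", times, pdf["right_pct"].to_numpy(float), rate),
    }

    stim_epochs = []
    if (path / "stims.tsv").exists():
        adf = pd.read_csv(path / "stims.tsv", sep="\t")
        for (site, pulse), g in adf.groupby(["site", "pulse_ms"], sort=True):
            ev = g.drop(columns=["site", "pulse_ms"]).reset_index(drop=True)
            stim_epochs.append(StimEpoch(site=str(site), pulse_ms=float(pulse), events=ev))

    session = Session(trials=trials, pedal_traces=traces, spike_trains=spike_trains,
                      stim_epochs=stim_epochs, metadata=meta)
    validate_session(session)
    return session
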