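"""End-to-end orchestration: simulate -> classify -> indices -> glm ->
cluster -> flow -> collision -> report.

Per-stage seeds fan out deterministically from the global seed, so an
identical configuration yields byte-identical report tables.  Failure of a
single neuron's analysis is logged and skipped, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from taskspike import collision as col
from taskspike import glm as glm_mod
from taskspike import latency as lat
from taskspike import relevance as rel
from taskspike.indices import activity_indices
from taskspike.peth import classify_rs_fs, smooth_peth
from taskspike.session import Session, validate_inclusion, write_session
from taskspike.simulate import (
    BlockRules,
    GroundTruth,
    NeuronSpec,
    SimConfig,
    cohort_specs,
    projection_specs,
    simulate_cohort,
)

log = logging.getLogger("taskspike")

RELEASE_TYPES = ("Hold", "Hold&Reward", "Go", "Go&Reward")
REWARD_TYPES = ("Hold&Reward", "Go&Reward", "Reward")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path | None = None
    sim: SimConfig | None = None
    stages: dict = field(default_factory=lambda: {
        "classify": True, "indices": True, "glm": True,
        "cluster": True, "flow": True, "collision": True,
    })
    gmm_repeats: int = 200
    gmm_k_max: int = 5
    flow_B: int = 1000
    flow_repeats_2d: int = 10
    glm_decimate: int = 1
    write_session_dir: bool = False

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        specs = cohort_specs(n_per_type=6) + projection_specs(4, 4, seed=self.seed)
        return SimConfig(seed=self.seed, neuron_specs=specs)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "sim" in raw:
        s = dict(raw.pop("sim"))
        if "block_rules" in s:
            s["block_rules"] = BlockRules(**s["block_rules"])
        if "neuron_specs" in s:
            s["neuron_specs"] = tuple(NeuronSpec(**ns) for ns in s["neuron_specs"])
        if "reward_delay_set" in s:
            s["reward_delay_set"] = tuple(s["reward_delay_set"])
        if "iti_range" in s:
            s["iti_range"] = tuple(s["iti_range"])
        sim = SimConfig(**s)
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(sim=sim, **raw)


@dataclass
class Report:
    tables: dict
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        lines = ["# taskspike pipeline report", ""]
        for key, val in sorted(self.provenance.items()):
            lines.append(f"- {key}: {val}")
        lines.append("")
        for name, df in self.tables.items():
            lines.append(f"## {name}")
            lines.append(df.to_csv(sep="\t", index=False, float_format="%.6g"))
        (outdir / "report.md").write_text("\n".join(lines))


def run_pipeline(config: PipelineConfig) -> Report:
    sim = config.resolved_sim()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(("cluster", "flow"), ss.spawn(2))}

    session, truth = simulate_cohort(sim)
    if config.write_session_dir and config.outdir:
        write_session(session, Path(config.outdir) / "session")

    outputs: dict[str, pd.DataFrame] = {}
    outputs["ground_truth"] = truth.neurons

    if config.stages.get("classify", True):
        classified = rel.classify_cohort(session)
        wf = classify_rs_fs([st.spike_duration_ms for st in session.spike_trains])
        cls_map = {st.neuron_id: lab for st, lab in
                   zip(session.spike_trains, wf.labels)}
        classified["cell_class"] = classified["neuron_id"].map(cls_map)
        outputs["classifications"] = classified

    if config.stages.get("indices", True) and "classifications" in outputs:
        rows = []
        for r in outputs["classifications"].itertuples(index=False):
            if r.type == "none":
                continue
            try:
                neuron = session.neuron(r.neuron_id)
                kind = "reward" if r.type == "Reward" else "go"
                ai = activity_indices(neuron, session.trials,
                                      r.preferred_side_physical,
                                      session.metadata.get("recorded_hemisphere", "left"),
                                      kind=kind)
            except Exception as exc:  # one neuron's failure is not fatal
                log.warning("indices failed for %s: %s", r.neuron_id, exc)
                continue
            rows.append({"neuron_id": r.neuron_id, "region": r.region,
                         "type": r.type, "c": ai.c, "i": ai.i,
                         "laterality": ai.laterality,
                         "sr_rewarded": ai.sr_rewarded,
                         "sr_unrewarded": ai.sr_unrewarded,
                         "reward_modulation": ai.reward_modulation})
        outputs["indices"] = pd.DataFrame(rows)

    if config.stages.get("glm", True):
        outputs["glm"] = glm_mod.glm_cohort(session, decimate=config.glm_decimate)

    latencies = None
    if "classifications" in outputs:
        latencies = _peak_latencies(session, outputs["classifications"])
        outputs["latencies"] = latencies

    if config.stages.get("cluster", True) and latencies is not None:
        rows = []
        for align in ("release", "reward"):
            samp = latencies.loc[latencies["alignment"] == align, "latency_ms"]
            if len(samp) >= 2 * config.gmm_k_max:
                sel = lat.gmm_select(samp, range(1, config.gmm_k_max + 1),
                                     repeats=config.gmm_repeats,
                                     seed=seeds["cluster"])
                xm = lat.xmeans_check(samp, config.gmm_k_max, seed=seeds["cluster"])
                for k in sel.k_range:
                    rows.append({"alignment": align, "k": k,
                                 "mean_bic": sel.mean_bic[k],
                                 "chosen": int(k == sel.chosen_k),
                                 "xmeans_k": xm, "n": sel.n})
        outputs["gmm_selection"] = pd.DataFrame(rows)

    if config.stages.get("flow", True) and latencies is not None:
        byreg = {r: latencies.loc[(latencies["alignment"] == "release")
                                  & (latencies["region"] == r), "latency_ms"].to_numpy()
                 for r in lat.REGION_KEYS}
        if all(v.size for v in byreg.values()):
            fr = lat.bootstrap_flow(byreg, B=config.flow_B, seed=seeds["flow"],
                                    repeats_2d=config.flow_repeats_2d)
            outputs["flow_samples"] = pd.DataFrame({
                "lag_cs_ms": fr.lag_cs, "lag_cd_ms": fr.lag_cd,
                "cluster": fr.cluster_assignments, "order": fr.order_labels,
            })
            outputs["flow_summary"] = (
                outputs["flow_samples"]["order"].value_counts(normalize=True)
                .rename_axis("order").reset_index(name="fraction")
                .sort_values("order", kind="stable").reset_index(drop=True))
        else:
            log.warning("flow skipped: some region has no latencies")

    if config.stages.get("collision", True) and session.stim_epochs:
        outputs["collision"] = col.collision_cohort(session.stim_epochs)

    return make_report(outputs, truth, provenance={
        "seed": config.seed, "n_trials": sim.n_trials_target,
        "n_neurons": len(sim.neuron_specs), "gmm_repeats": config.gmm_repeats,
        "flow_B": config.flow_B,
        "stages": ",".join(k for k, v in config.stages.items() if v),
    })


def _peak_latencies(session: Session, classified: pd.DataFrame) -> pd.DataFrame:
    """Smoothed-PETH peak latencies for task-related neurons, per alignment."""
    rows = []
    completed = session.completed_trials()
    for r in classified.itertuples(index=False):
        neuron = session.neuron(r.neuron_id)
        if r.type in RELEASE_TYPES:
            align = [t.release_onset for t in completed
                     if t.released_side == r.preferred_side_physical]
            sp = smooth_peth(neuron, 12.5, align_times=align, window=rel.RELEASE_WINDOW)
            ms, flat = lat.peak_latency(sp, rel.RELEASE_WINDOW)
            if not flat:
                rows.append({"neuron_id": r.neuron_id, "region": r.region,
                             "alignment": "release", "latency_ms": ms})
        if r.type in REWARD_TYPES:
            align = [t.reward_onset for t in completed if t.reward_onset is not None]
            sp = smooth_peth(neuron, 12.5, align_times=align, window=rel.REWARD_WINDOW)
            ms, flat = lat.peak_latency(sp, rel.REWARD_WINDOW)
            if not flat:
                rows.append({"neuron_id": r.neuron_id, "region": r.region,
                             "alignment": "reward", "latency_ms": ms})
    return pd.DataFrame(rows, columns=["neuron_id", "region", "alignment", "latency_ms"])


def make_report(outputs: dict, truth: GroundTruth | None = None,
                provenance: dict | None = None) -> Report:
    """Assemble summary tables; add recovery diagnostics when truth is known."""
    if not outputs:
        raise ValueError("no stage outputs to report")
    tables = dict(outputs)
    if "classifications" in outputs:
        tables["type_fractions"] = rel.type_fractions(outputs["classifications"])
        if truth is not None:
            merged = outputs["classifications"].merge(
                truth.neurons[["neuron_id", "archetype"]], on="neuron_id",
                how="left", validate="one_to_one")
            cm = pd.crosstab(merged["archetype"], merged["type"])
            cm.index.name = "planted"
            tables["confusion"] = cm.reset_index()
            tables["recovery"] = pd.DataFrame([{
                "n": len(merged),
                "exact_agreement": float((merged["archetype"] == merged["type"]).mean()),
            }])
    if "indices" in outputs and len(outputs["indices"]):
        tables["population_tests"] = _population_tests(outputs["indices"],
                                                       outputs.get("latencies"))
    return Report(tables, provenance or {})


def _population_tests(indices: pd.DataFrame, latencies: pd.DataFrame | None
                      ) -> pd.DataFrame:
    """Cohort-level summaries: signed-rank on indices, Kruskal-Wallis plus
    Holm-corrected pairwise rank tests on release latencies across regions."""
    rows = []
    for colname in ("laterality", "reward_modulation"):
        v = indices[colname].dropna().to_numpy()
        v = v[np.isfinite(v)]
        if v.size >= 5 and np.any(v != 0):
            try:
                w = stats.wilcoxon(v)
                rows.append({"test": f"signed_rank_{colname}", "stat": float(w.statistic),
                             "p": float(w.pvalue), "n": int(v.size)})
            except ValueError:
                pass
    if latencies is not None and len(latencies):
        groups = [g["latency_ms"].to_numpy()
                  for _, g in latencies[latencies["alignment"] == "release"]
                  .groupby("region") if len(g) >= 3]
        if len(groups) >= 2:
            kw = stats.kruskal(*groups)
            rows.append({"test": "kruskal_release_latency", "stat": float(kw.statistic),
                         "p": float(kw.pvalue), "n": int(sum(len(g) for g in groups))})
            pvals = np.array([stats.mannwhitneyu(a, b).pvalue
                              for i, a in enumerate(groups) for b in groups[i + 1:]])
            m = len(pvals)
            holm = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(np.argsort(pvals)):
                running = max(running, min(1.0, pvals[idx] * (m - rank)))
                holm[idx] = running
            for j, p in enumerate(holm):
                rows.append({"test": f"pairwise_latency_{j}", "stat": np.nan,
                             "p": float(p), "n": int(sum(len(g) for g in groups))})
    return pd.DataFrame(rows, columns=["test", "stat", "p", "n"])
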