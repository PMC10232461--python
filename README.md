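# taskspike

Spike-train analysis for head-fixed rodent experiments using a **self-paced
pedal-release task**: the animal presses both pedals into a holding area
(0–30% of the range of motion) for at least 1 s, then spontaneously releases
the left or the right pedal; releases matching the current block side are
rewarded 300–700 ms later. `taskspike` implements the full single-neuron
analysis chain for such sessions, plus a synthetic-session generator with
ground truth so every stage can be validated end to end.

The chain covers:

- **Session model & I/O** — trials, pedal traces, spike trains and
  stimulation events as plain TSV files with checksums
  (`taskspike.session`).
- **PETH metrics** — peri-event time histograms (20 ms bins), Gaussian
  smoothing, pedal release-onset detection (30% crossing, 5% backtrack),
  and RS/FS classification by minimum cross-entropy thresholding of spike
  duration (`taskspike.peth`).
- **Task-relevance taxonomy** — the task relevance index is the p-value of
  a KS test of pooled event-aligned spike times against uniformity; neurons
  with p < 10⁻⁶ around pedal release (±500 ms, per side) or reward delivery
  (0–1000 ms) are task-related. Release-related neurons split into
  **Hold-type** (activity ramps with holding time) and **Go-type** (phasic,
  holding-time independent) by regressing the time each holding-time
  range's PETH rises through 75% of the all-averaged PETH peak on the
  range's mean holding time: slope ≤ −0.5 → Hold (`taskspike.relevance`).
- **Modulation indices** (`taskspike.indices`) — with `c, i =
  SR_peak/SR_baseline − 1` (peak bin ±150 ms vs −1000..−700 ms):

  ```
  laterality = (c − i)/(c + i)  if c > 0 and i > 0
             = +1               if c > 0 and i < 0
             = −1               if c < 0 and i > 0
  reward modulation = (SR_r − SR_nr)/(SR_r + SR_nr)
  ```

- **Stepwise GLM** — the σ = 150 ms smoothed rate regressed on left/right
  pedal trajectories and trial time (elapsed since the last hold onset),
  forward/backward selection by partial F-tests (add p < 0.05, remove
  p > 0.10), Bonferroni-corrected classification into Time / Time&Pedal /
  Pedal cells (`taskspike.glm`).
- **Latency clustering & pseudo-signal flow** — PETH peak latencies
  clustered by a 1D Gaussian mixture, EM repeated (default 1000×) for
  k = 1..5, k chosen by minimum mean BIC (BIC = −2 ln L + k ln n), with an
  x-means cross-check; 1000-repeat bootstrap of inter-region lag pairs
  (CA1−LECs, CA1−LECd) with 2D GMM clustering and firing-order labels
  (`taskspike.latency`).
- **Collision-test projection identification** — ROC trough threshold,
  control/test spike probabilities, 2×2 χ² collision decision, antidromic
  latency (median) with jitter (IQR < 0.5 ms), frequency-following checks
  (`taskspike.collision`).

## Worked example

```python
from taskspike.simulate import recovery_cohort_config, simulate_cohort
from taskspike.relevance import classify_cohort, type_fractions

session, truth = simulate_cohort(recovery_cohort_config(seed=29))
classified = classify_cohort(session)
merged = classified.merge(truth.neurons[["neuron_id", "archetype"]], on="neuron_id")
print((merged["archetype"] == merged["type"]).mean())
print(type_fractions(classified).head(6).to_string(index=False))
```

prints

```
1.0
region        type  count  proportion
   CA1        Hold      7       0.175
   CA1 Hold&Reward      7       0.175
   CA1          Go      6       0.150
   CA1   Go&Reward      7       0.175
   CA1      Reward      7       0.175
   CA1        none      6       0.150
```

i.e. all 120 planted archetypes (20 per type, across CA1/LECs/LECd)
are recovered exactly, and the per-region type fractions match the planted
design. The full pipeline — simulate → classify → indices → GLM → cluster →
flow → collision → report — runs via

```sh
taskspike run --seed 17 --out report/
```

and writes TSV tables (classifications, indices, GLM classes, GMM
selection, flow samples, collision decisions, confusion vs ground truth)
plus a markdown summary; identical seeds give byte-identical tables.

## Layout

```
src/taskspike/
  session.py    # data model, TSV I/O, validation, inclusion gates
  simulate.py   # behavior + archetype spike + stimulation generator
  peth.py       # PETHs, smoothing, release detection, RS/FS threshold
  relevance.py  # KS relevance, Hold/Go slope, taxonomy
  indices.py    # laterality & reward-modulation indices
  glm.py        # stepwise GLM time/pedal classification
  latency.py    # GMM/BIC, x-means, bootstrap flow
  collision.py  # Multi-Linc-style projection identification
  pipeline.py   # orchestration and report
  cli.py        # `taskspike` command-line interface
```

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
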