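# breathkit

Whole-body plethysmography breath analysis for rodent respiratory
phenotyping: breath segmentation from calibrated flow traces, an
artifact-rejection cascade, per-animal respiratory metrics, and genotype
group comparison — plus a synthetic-trace generator with known ground truth
so the whole pipeline is testable without recordings.

## What it does

1. **simulate** — generate flow traces (`time_s,flow_ml_s` CSV) built from
   half-sine breaths with lognormal breath-length jitter calibrated in
   closed form to a target mean interbreath-interval irregularity (IBII).
   Phenotype presets (`WT`, `SCA1_6mo`, `SCA1_late`, `SCA1_rescued_late`)
   encode the qualitative orderings of a spinocerebellar-ataxia breathing
   phenotype: reduced tidal volume with compensatory rate increase early,
   a deeper volume deficit without further compensation late, and partial
   rescue. Injectable artifacts: sniff bursts (>600 breaths/min runs),
   prolonged expirations, volume-asymmetric breaths, movement spikes.
   Every breath is emitted in a ground-truth TSV.
2. **segment** — breath detection by upward zero-crossings with Schmitt
   hysteresis after low-pass baseline removal; per breath: inspiratory and
   expiratory durations (Ti/Te), inspiratory/expiratory tidal volumes
   (trapezoidal integrals), onset-to-onset breath length, instantaneous
   rate.
3. **qc** — the rejection cascade, all comparisons strict:
   - per-breath rules: Ti under 0.025 s, Te over 10 s, or Vte more than
     2 × Vti;
   - a sliding window of 200 breaths (step 1) over the survivors: a window
     with more than 10% of breaths faster than 600 breaths/min is rejected
     and all of its breaths excluded;
   - animals with fewer than 100 reliable breaths are excluded.
4. **summarize** — frequency (mean instantaneous rate), tidal volume
   (mean Vti), minute ventilation (frequency × tidal volume, exact), and
   mean IBII = |L(n+1) − L(n)|/L(n) over originally-consecutive reliable
   pairs (exclusions break the chain, they are never bridged).
5. **cohort** — per-animal pipeline orchestration from a metadata TSV and
   one-way fixed-effects ANOVA per metric across genotype groups.

## CLI

```sh
# 10 wild-type animals, 30-minute recordings
breathkit simulate --preset WT --n 10 --seed 1 --out-dir traces/

# single-animal steps
breathkit segment --in traces/WT_00.csv --out breaths.tsv
breathkit qc --in breaths.tsv --out breaths.qc.tsv --report qc.json
breathkit summarize --in breaths.qc.tsv --report qc.json --out summary.tsv

# whole cohort from a metadata TSV (animal_id, genotype, age_group, trace_path)
breathkit cohort --metadata traces/metadata.tsv --out-dir results/
```

Exit codes: 0 success, 2 input error, 3 configuration error.  Config files
are YAML key-value mappings mirroring `SimConfig` / `SegmentationParams` /
`QCConfig` fields, e.g. `breathkit qc --config qc.yaml` with
`ti_min: 0.025`.

## Library use

```python
from breathkit import (SimConfig, simulate_trace, segment_breaths,
                       apply_qc, summarize_animal)

trace, truth = simulate_trace(SimConfig(duration=1800, base_rate=180, seed=1))
table = segment_breaths(trace)
reliable, report = apply_qc(table)
summary = summarize_animal(reliable, report)
```

Two deliberately-exposed ambiguity switches on `QCConfig`: `window_stage`
(window filter after — default — or before the per-breath rules) and
`window_mode` (rejected windows exclude all member breaths — default — or
only their fast breaths).
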