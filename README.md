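# torsadex

Analysis toolkit for preclinical proarrhythmia studies in paced, AV-blocked
large-animal models: ECG and monophasic action potential (MAP) repolarization
metrics, beat-to-beat variability, an arrhythmia severity score, LV-pressure
hemodynamics, and patch-clamp current decomposition. A seeded synthetic-signal
generator with exact, closed-form ground truth stands in for raw recordings,
so every analysis path can be validated by parameter recovery.

## What it computes

- **ECG intervals** (`torsadex.ecg_intervals`) — RR, PP, QRS, QT over n
  consecutive complexes; JT = QT − QRS; Van de Water rate correction
  QTc = QT − 0.087·(RR − 1000); JTc = QTc − QRS; tangent-method T-end
  delineation (ground-truth annotations always take precedence); analysis
  window selection anchored at 5 min after infusion onset or the first
  ectopic beat within those 5 min.
- **MAP analysis** (`torsadex.map_analysis`) — MAP duration at a
  configurable repolarization fraction (default 80%); exclusion of ectopic
  beats and beats with a P wave near the T end; short-term variability
  (STV) of a 30-beat duration series, with both the `sqrt2` divisor
  (n·√2, default) and the `literal` divisor (n·2); ΔMAPD = LV − RV.
- **Arrhythmia scoring** (`torsadex.arrhythmia_scoring`) — runs of
  consecutive ectopic complexes classified as sEB (1), mEB (2–5), TdP (≥6)
  or defibrillated TdP (>10 s, shocked); point rubric 1 / 2 / 3–5 / 6–49 /
  50–75–100; arrhythmia score = mean of the three highest-scored events in
  the 10-min window (padded with regular-beat scores, so a clean window
  scores exactly 1); cohort incidence summaries.
- **Hemodynamics** (`torsadex.hemodynamics`) — smoothed dP/dt extrema over
  five consecutive pressure cycles, QLVPend (QRS onset to pressure-cycle
  end), and the electromechanical window EMW = QLVPend − QT.
- **Cellular electrophysiology** (`torsadex.cell_ephys`) — peak tail
  current at −50 mV after the +60 mV step (settled-level reference),
  capacitance normalization, pharmacological subtraction into slow/fast
  delayed-rectifier components and residual, APD90/APD50 and cellular STV.
- **Synthetic signals** (`torsadex.synthetic_signals`) — seeded generators
  for paced rhythms with AV dissociation, drug-ramped repolarization
  prolongation, AR(1) beat-to-beat variability with a closed-form expected
  STV, scheduled ectopy/TdP runs, LV pressure cycles, voltage-clamp sweep
  sets, and cellular AP trains.
- **I/O** (`torsadex.signal_io`) — versioned CSV trace container with a
  `#`-header block, JSON annotations, CSV summary tables. Round-trips are
  bit-exact.
- **Pipeline** (`torsadex.pipeline`) — full study orchestration from a
  JSON/YAML config, with per-subject outputs, mean ± SD summary grids and
  machine-readable exclusion logs.

## CLI

```sh
torsadex simulate --duration 60 --stv 1.5 --seed 3 \
    --events '[{"onset_s": 20, "kind": "TdP", "run_length": 8}]' --out-dir sim/
torsadex analyze-ecg sim/trace.csv --annotations sim/annotations.json --n-complexes 5
torsadex analyze-map sim/trace.csv --annotations sim/annotations.json \
    --fraction 0.8 --stv-beats 30 --stv-divisor sqrt2
torsadex analyze-pressure pressure.csv --cycles 5 --qrs-onset 40 --qt 360
torsadex score-arrhythmia sim/annotations.json --window-start 0 --window-min 10
torsadex analyze-cells --capacitance 150 --iks 300 --ikr 400 --noise-sd 2
torsadex run-study config.json
torsadex report config.json
```

## Conventions

Times are milliseconds from recording start, 0-based sample indexing,
half-open intervals. Default sampling rate 1 kHz. The STV divisor ambiguity
(n·√2 vs n·2) is preserved explicitly: both modes are implemented and differ
by exactly √2.
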