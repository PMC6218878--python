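# cardioresp

Time-independent causal-path analysis of cardiorespiratory activity.

Cardiac and respiratory control interact continuously — respiratory sinus
arrhythmia, vagal tone, breath-to-breath variability — yet routine
physiological monitoring (e.g. of athletes at rest) usually analyses the ECG
alone. `cardioresp` implements a whole-recording, time-independent
alternative: each ~6-minute two-channel recording (single-lead ECG +
impedance pneumography, 250 Hz, one per body position) is compressed into
ten parameters per subject, and causal structure is then sought across
subjects with an ensemble of discovery methods. The package is aimed at
researchers in cardiorespiratory physiology and sports science who want a
reproducible, fully scripted version of that workflow — including a
synthetic-data module so every stage can be exercised and validated without
access to any recordings.

## The parameters

Per recording: mean heart rate HR (beats/min); RMSSD, the root-mean-square
of successive RR-interval differences (ms), and lnRMSSD = ln RMSSD; mean
breathing rate RR (breaths/min); coefficients of variation of the
instantaneous breathing rate (ciRR), inspiratory/expiratory durations
(cInsT, cExpT) and amplitudes (cInsV, cExpV); and the Breathing Regularity
index

```
BR = 100 − 20·[tanh(ciRR) + tanh(cInsT) + tanh(cExpT) + tanh(cInsV) + tanh(cExpV)]  [%]
```

which the tanh saturation keeps in (0, 100]: 100% is perfectly regular
breathing.

Signals are preprocessed with median-filter ECG detrending, Pan-Tompkins
R-peak detection, normalized-LMS subtraction of the heartbeat artifact from
the impedance channel, 400 ms smoothing, and adaptive delimitation of
breathing phases on the differentiated (flow-related) signal.

## The statistics

* **Screening** — for each parameter pair, the regression `X = α + βY + ε`
  with a flat prior gives a Student-t posterior for β;
  `cor(X,Y) = β̂·σ(Y)/σ(X)` (which reduces to Pearson's r) is reported when
  the maximum probability of effect MPE = max{P(β>0|D), P(β<0|D)} exceeds 0.9.
* **Causal discovery** — five learners over the per-position tables:
  pairwise generalized correlations
  `r*_{y|x} = sign(r_xy)·√(1 − E[(Y−E(Y|X))²]/var Y)` with a bootstrap
  asymmetry test; hill-climbing and tabu search over DAGs with the Gaussian
  BIC; greedy equivalence search (GES) over CPDAGs; and CAM-lite (greedy
  additive-spline order search with significance pruning). A consensus
  report counts per-direction support across methods.
* **Mediation** — for candidate paths X→M→Y, OLS fits `M = i₁ + aX` and
  `Y = i₂ + c′X + bM` give the Sobel statistic
  `z = ab/√(b²se_a² + a²se_b²)` with a two-sided normal p-value.

## Worked example

Twelve synthetic subjects, two body positions each (the generator raises
heart rate and lowers RMSSD when "standing"), full pipeline with three of
the graph learners:

```python
from cardioresp.pipeline import RunConfig, run_pipeline, render_report, simulate_cohort

cohort = simulate_cohort(12, seed=5, duration_s=120.0)
report = run_pipeline(RunConfig(out_dir="demo_out", signal_records=cohort,
                                seed=1, methods=("hc", "tabu", "ges")))
print(render_report(report))
```

prints (abridged):

```
Stages:
  input_records: 24
  extract[supine]: 12
  extract[standing]: 12
  correlate[supine]: 17
  ...
Position tests:
        HR: paired-t  stat=+202.903 p=5.227e-21 (Shapiro p=0.942, n=12)
     RMSSD: paired-t  stat=-49.441 p=2.845e-14 (Shapiro p=0.57, n=12)
  ...
--- supine ---
Consensus over 3 methods (min support 3):
  HR -> cInsV: 3  [HC,TABU,GES]
  cExpV -> cInsV: 3  [HC,TABU,GES]
  RR -> HR: 2.5  [HC,TABU,GES(und)]
  ...
```

The paired tests recover the built-in orthostatic shift on every parameter
(HR up, RMSSD down, breathing faster and more variable when standing); the
consensus section lists each directed claim with the methods supporting it
(undirected CPDAG edges count half for each direction). All artifacts —
parameter CSVs, the masked correlation matrix, GraphML/DOT graphs,
edge lists with support counts, the mediation table and a JSON run
report — land in `demo_out/`.

The same stages are available from the shell:

```bash
cardioresp simulate signals --config scenario.yaml --out sig/
cardioresp extract --signals sig/ --out params/
cardioresp discover --params params/params_supine.csv --position supine \
    --methods gc,hc,tabu,ges,cam --seed 42 --out graphs/
cardioresp mediate --params params/params_all.csv --standard-paths
cardioresp run --signals sig/ --out full_run/
```

## Reference data

The deposited athlete-cohort parameter table (one CSV covering both body
positions in the canonical `subject_id,position,HR,...,BR` schema, or any
layout plus a `*_mapping.yaml` column map) can be placed at
`data/datasheet1_parameters.csv`; `cardioresp.io.load_reference_cohort()`
then returns the supine and standing tables, and the two reference-cohort
tests in `tests/test_acceptance.py` check the published correlation and
mediation values against it. Without the file those two tests fail with a
clear message; everything else is self-contained.

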