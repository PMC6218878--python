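# Methods

This note documents the models and procedures implemented in `cardioresp`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions that shape the results.

## 1. Signal model and preprocessing

A recording is two synchronous channels at a fixed sampling rate
(default 250 Hz): a single-lead ECG and an impedance-pneumography (IP)
signal linearly related to tidal volume. IP amplitudes are deliberately
left in uncalibrated impedance units; every downstream use is a
coefficient of variation, which is unit-free, so volume calibration is not
required.

**ECG detrending.** The baseline is estimated with a 0.6 s running median
and subtracted. A median tracks slow drift without being dragged by the
brief QRS complexes, and has a single parameter. Residual mean is removed.

**R-peak detection** follows the Pan-Tompkins recipe with its classic
constants: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
differentiation, squaring, 150 ms moving-window integration, then adaptive
dual thresholds with running signal/noise levels (update weights 0.125,
threshold = noise + 0.25·(signal − noise)) and a search-back at half
threshold when the current interval exceeds 1.66× the running RR average.
Accepted peaks are refined to the local ECG maximum within ±50 ms.
Intervals under 200 ms are physiologically impossible and are merged
(keeping the larger peak); detections within 0.3 s of either record edge
are discarded because the band-pass transient can fake a peak there. A
recording with no detectable beats yields an empty, flagged series rather
than an exception, so cohort extraction can log and skip it.

**Cardiac-artifact removal from IP.** The heartbeat perturbs thoracic
impedance; the artifact is beat-locked, so the filter reference is a unit
impulse train at the detected R-peak samples, shifted half a window early
so the learned FIR template (0.4 s of taps) spans the beat symmetrically.
A normalized-LMS loop (step 0.05) adapts the taps over two sweeps of the
record against the mean-centered IP; the taps from the final sweep are
averaged (plain averaging removes the recency bias of the LMS estimate),
and the template is then detrended with an edge-anchored line: the true
artifact is compact around the beat, so any linear trend across the window
edges is leaked respiratory baseline (locally ~linear over 0.4 s). The
frozen template convolved with the impulse train is subtracted everywhere,
so early beats are cleaned as well as late ones and the output is
deterministic. With no beats available the input is returned unchanged
with a warning flag.

**Smoothing.** Centered moving average, window `round(0.4·fs)` samples,
edges handled by shrinking the window; length preserved.

**Breath delimitation.** The smoothed IP is differentiated into a
flow-related signal. Upward zero-crossings open inspirations, downward
ones open expirations. A crossing is accepted only when the following
same-sign flow lobe's area exceeds 20% of the running median lobe area
over the last 8 accepted lobes; because flow is the derivative of IP, a
lobe's area equals the IP excursion across it, which makes the rule
invariant to channel offset and positive scaling. The running median is
seeded from breath-sized lobes only (those at least a quarter of the
largest), since ripple and artifact residue produce many tiny lobes that
would drag a plain percentile down. A first "inspiration" opening at
sample 0 is a partial breath whose true onset precedes the recording and
is dropped, not imputed. Fewer than three complete breaths is an error
("insufficient respiratory activity").

Open choices made here: amplitudes are onset-to-peak excursions (not
integrals); per-beat cleaning uses a 200–3000 ms plausibility gate.

## 2. Parameters

HR = 60000/mean(RR in ms). RMSSD = √mean(ΔRR²) in ms; a constant RR series
gives RMSSD = 0, leaving lnRMSSD undefined — the recording is flagged and
excluded rather than imputed. Respiratory rate uses inspiratory-onset to
inspiratory-onset periods, consistent with the instantaneous rate
definition iRR = 60/period. All five CVs use the sample (n−1) standard
deviation; the convention is a one-line switch (`ddof`). Breathing
Regularity is

BR = 100 − 20·Σ tanh(CV) over {ciRR, cInsT, cExpT, cInsV, cExpV},

strictly decreasing in each argument, equal to 100 when all CVs vanish and
approaching 0 as they diverge.

Cohort extraction runs the full chain per recording and excludes failures
wholesale, logging the failing stage; exclusion counts always reconcile
input and output row counts.

## 3. Association screening

For a pair (X, Y) the package fits X = α + βY + ε. With a flat prior the
posterior of β is Student-t centered on the least-squares slope with the
usual standard error and n−2 degrees of freedom, so everything is closed
form and deterministic — no sampler. The reported correlation
β̂·σ(Y)/σ(X) algebraically equals Pearson's r; the added value of the
Bayesian formulation is the significance gate: MPE, the posterior mass on
the dominant sign of β, must exceed 0.9. Under a true null this gate fires
with probability 0.2 (it is equivalent to two-sided p < 0.2), which the
test suite verifies by simulation. No multiple-testing correction is
applied across the 45 pairs; the screening is deliberately permissive and
the masked matrix is presentational.

Supine-vs-standing comparisons use Shapiro-Wilk on the paired differences
(the differences are what the paired t-test assumes normal) to choose
between a paired t-test and a Wilcoxon signed-rank test, both two-sided at
α = 0.05. All-zero differences are degenerate and reported with p = 1.

## 4. Causal discovery

All learners receive the same per-position table and the same structural
mask: the pairs RMSSD–lnRMSSD and BR–{each of its five input CVs} are
deterministic transforms, ill-conditioned under a Gaussian score, and are
forbidden during search by default (configurable; an alternative switch
drops the derived columns entirely).

**Generalized correlations (GC).** GMC(Y|X) = 1 − E[(Y−E(Y|X))²]/var(Y)
with E(Y|X) from Nadaraya-Watson kernel regression (Gaussian kernel,
Silverman rule-of-thumb bandwidth), clipped to [0,1];
r*_{y|x} = sign(r_xy)·√GMC. When X drives Y through a nonlinear mechanism
with additive noise, X explains Y better than the reverse, so the larger
|r*| points away from the likelier cause's partner. The asymmetry must
survive a paired bootstrap (500 resamples of the |r*| difference, sign
test, two-sided, α = 0.05), else the pair is "undecided". In the graph
variant each pair must additionally pass the MPE screen, mirroring the
analysis flow that treats only meaningfully correlated pairs as causal
candidates. The n×n kernel matrix is computed in single precision — GMC is
a ratio of second moments, far above float32 resolution — which roughly
halves runtime.

**Score.** Gaussian BIC, decomposable by node: the maximized Gaussian
log-likelihood of each node's linear regression on its parents minus
(k/2)·ln n, with k counting slopes, intercept and variance. MLE residual
variance makes the total score constant on Markov-equivalence classes.
Collinear parent sets fall back to a small ridge (λ = 1e−8) with a logged
warning; residual variance is floored at 1e−12.

**Hill-climbing / tabu.** Single-edge add/delete/reverse moves from the
empty graph, acyclicity enforced per move, strict improvement threshold
1e−9, lexicographic tie-breaks on (operation, node pair) in canonical
column order — results are deterministic for a fixed seed. Optional
restarts perturb the optimum with random edge flips. Tabu continues past
the local optimum for up to 100 further iterations, taking the best
admissible move even when it lowers the score while forbidding the
inverses of the last 10 moves, and returns the best graph seen — hence
never worse than hill-climbing under the same tie-breaks.

**GES.** Genuine equivalence-class search: forward Insert(X,Y,T) and
backward Delete(X,Y,H) operators with their validity conditions (clique
checks, blocked semi-directed paths), scored locally; after each operator
the PDAG is completed to a CPDAG by consistent extension (Dor-Tarsi) and
re-closure (v-structures + Meek rules R1–R3). Output is a CPDAG: a pure
chain stays undirected, a collider is oriented. On three-node problems the
suite checks GES against exhaustive enumeration of all 25 DAGs.

**CAM-lite.** Each conditional is a sum of univariate cubic B-spline
functions (5 basis columns per parent, knots at quantiles). Stage 1
greedily adds the edge with the largest additive-model log-likelihood gain
while the gain exceeds the BIC penalty for one spline block, respecting
acyclicity. Stage 2 fixes the implied topological order (canonical column
order breaking ties), refits each node on all predecessors, and keeps only
predecessors whose spline block passes an F-test at prune_alpha = 0.001
(the published CAM default). When the full predecessor design would exceed
the sample size, the refit falls back to the searched parents. Nonlinear
mechanisms give the direction away; for linear-Gaussian data only the
skeleton is meaningful, and the tests assert no more than that.

**Consensus.** Directed edges contribute 1 to their direction, undirected
CPDAG edges 0.5 to each. Paths are maximal chains whose consecutive edges
all meet the support threshold (default 3 of 5 methods).

## 5. Mediation

For X→M→Y: OLS fits M = i₁ + aX and Y = i₂ + c′X + bM; indirect effect
a·b; Sobel z = ab/√(b²se_a² + a²se_b²) using the first-order delta-method
variance (a flag adds the second-order se_a²se_b² term); two-sided normal
p. a·b = 0 gives z = 0, p = 1 exactly. p-values are invariant to affine
rescaling of any variable, so standardization conventions are immaterial.
The batch report evaluates five pre-registered exploratory paths (three
supine, two standing) on independently analyzed position tables. The Sobel
test is conservative under the null for small effects, which the suite
verifies (null rejection ≤ 6% at α = 0.05).

## 6. Synthetic data

**Signals.** Breaths are concatenated: a monotone quarter-sine rise over
`ins_frac` of the period, then an exponential decay with τ = ExpT/4.
Per-breath duration and amplitude multipliers are log-normal with unit
mean and the requested CV (log-normality guarantees positivity). The RR
series is 60000/HR plus RSA modulation — `rsa_gain` (ms per unit) times
the noise-free IP excursion at the beat time, a simple controllable
coupling — plus white jitter whose scale is solved (a quadratic in the
realized successive differences) so the realized RMSSD matches
`rmssd_target`; when RSA alone exceeds the target the jitter is zero. The
ECG is an 80 ms symmetric biphasic template placed at beat samples — only
timing fidelity matters downstream, not morphology. The IP channel adds a
heartbeat-synchronous Gaussian bump (width 50 ms) scaled by
`cardiac_artifact_gain` and white noise on both channels. Ground truth
records the realized (not merely requested) parameter values and all event
times.

Defaults describe a resting adult: 6 min at 250 Hz, 60 beats/min,
RMSSD 50 ms, 14 breaths/min, inspiratory fraction 0.4, duration CV 0.10,
amplitude CV 0.15, artifact gain 0.05, noise SD 0.01. The scenario sampler
used for recovery testing draws uniformly over HR 50–90, RMSSD 20–80 ms,
breathing 10–20/min, RSA gain 10–40 ms, CVs 0.05–0.25, artifact 0–0.1 and
noise 0–0.02, at 180 s per record — long enough for stable CV estimates
while keeping a 20-scenario sweep fast.

Not emulated: P/T waves and ECG morphology pathology, baroreflex and other
closed-loop dynamics, movement artifacts, apnea, ectopy. Passing recovery
tests therefore demonstrates correctness of the event detection and
parameter arithmetic under clean-to-moderately-noisy conditions, not
robustness to arrhythmia or motion; on real recordings the wholesale
exclusion path is expected to carry more weight.

**SCM tables.** Nodes are sampled in topological order; children are sums
of parent mechanisms — linear(coefficient) or a closed library of additive
nonlinearities (square, cube, exp with a clipped argument, sin) — plus
independent Gaussian noise. The closed library keeps ground truth
serializable. Cycles are rejected with the offending cycle named.

## 7. Pipeline

Supine and standing are analyzed fully independently; the orthostatic
change is only reported descriptively via the paired tests. Runs are
deterministic for a fixed config and seed (byte-identical artifacts,
hash-checked in the tests); no subject is dropped silently. The report
module is text-first; plotting is an optional extra and its absence never
fails a run.

## 8. Known limitations

* Latent-confounder semantics (PAG-learning methods) are out of scope; the
  ensemble assumes causal sufficiency over the ten parameters.
* Time-resolved (within-subject) causality — Granger, transfer entropy —
  is out of scope by design; the unit of analysis is the whole recording.
* The generalized-correlation direction rule is only informative for
  nonlinear additive-noise mechanisms; it is near-chance for linear
  Gaussian pairs, and the bootstrap keeps such pairs "undecided".
* The reference-cohort checks require the deposited parameter dataset
  (`data/datasheet1_parameters.csv`), which is not distributable with the
  package; without it those two tests fail with a clear message and all
  other results are computed from synthetic data.
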