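# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind the package, at the level of detail a maintainer or
reviewer needs to re-derive them.

## Signal model and preprocessing

Raw sEMG is assumed bandpass-filtered at acquisition; filtering is treated
as part of acquisition, not of the decoder, so the pipeline accepts
pre-filtered or synthetic signals. A trigger channel defines the epoch
onset: the first sample whose rectified amplitude reaches 30 µV, followed by
a maximum-peak search over the next 20 ms (inclusive of the crossing
sample). Amplitude means absolute value — sEMG is bipolar, and a one-sided
rule would miss negative-going bursts. The onset index is broadcast to all
channels.

Features are RMS values over adjacent (non-overlapping) 50 ms windows; a
trailing partial window is dropped rather than padded. Pen traces sampled on
the same 50 ms clock are differenced into increments; window *i* of the
features is paired with increment *i* of the trace, both clocks starting at
the epoch onset. Increments and traces are exact inverses under cumulative
summation from the trace origin.

## State model

The filter state is the increment pair (Δx, Δy). Its dynamics are fit by
two-regressor least squares without an intercept (the increment process is
zero-mean by construction for closed strokes and nearly so otherwise);
pooling across trials uses only within-trial transition pairs, so no
regression row straddles a trial boundary. Process and observation noise
covariances are sample covariances (n−1 denominator) of the paired
residuals, symmetrized; rank-deficient regressor matrices fall back to the
minimum-norm solution with a warning rather than an error, since degenerate
strokes (straight lines) are legitimate inputs.

Kalman numerics: covariances are re-symmetrized after every step;
P̂ + R is inverted via a linear solve, with a 1e-10 ridge added (and a
warning emitted) if its condition number exceeds 1e12. The update is the
standard identity-measurement form K = P̂(P̂+R)⁻¹ because the observation
(the evolved models' output) already lives in state space. Every
reconstruction re-initializes S₀ = 0, P₀ = I₂ — trial boundaries reset the
filter.

## The GEP engine

Genomes follow standard Karva semantics: each gene has a 15-symbol head
(functions or terminals) and a 16-symbol tail (terminals only; tail length
h(a−1)+1 with maximum arity 2 gives the 31-symbol gene), decoded
breadth-first into an expression tree whose unused suffix is non-coding.
Chromosomes carry 6 genes linked by addition. Population size is 200.

Protected operators make every genome total and finite: x/0 → 1, inv(0) → 1,
√x → √|x|, exp clamped at exp(50), products and squares saturated at ±1e30.
The vectorized evaluator is checked against an independently written
recursive tree-walk evaluator for exact agreement.

**Operator rates.** All published rates are interpreted per genome symbol.
Point mutation (0.00138) applies symbol-wise — about 0.26 mutations per
186-symbol chromosome per generation; head positions may mutate to any other
symbol, tail positions only to other terminals. The structural operators are
single events per chromosome (or per mating pair), so their per-symbol rates
convert to event probabilities min(1, rate × 186): inversion and the three
transpositions (0.00546) fire roughly once per chromosome per generation,
the three recombinations (0.00277) on roughly half the pairs. The
per-chromosome reading of the same numbers (≈0.005 events per chromosome)
was tested and produces an essentially inert search — no meaningful
improvement over 200 generations — so the per-symbol reading, which matches
how mutation rates are conventionally expressed in this algorithm family,
is the default. IS/RIS transposon lengths are uniform on {1, 2, 3}; IS
inserts at a non-root head position, RIS at the root of the same gene, and
both truncate at the head boundary, so validity is preserved by
construction (and fuzz-tested).

**Fitness and selection.** Fitness is 1000/(1 + RMSE), the maximum 1000 at a
perfect fit. Selection is roulette-wheel sampling on *windowed* fitness —
weights (f − f_min)³ — with single-elite preservation. Plain
fitness-proportional roulette was measured to provide almost no selection
pressure here (population fitness ratios ≈1.2), and with the small variation
rates above the search stalls; shifting by the population minimum and cubing
restores a meaningful gradient while keeping the roulette mechanism. Plain
roulette and binary tournament remain available as configuration options.

**Calibrated linking.** The terminal set contains no numerical constants,
so raw addition-linked genomes cannot express targets whose coefficients
lie outside the language (e.g. 0.4·|T1−T2|): under RMSE fitness the best
*reachable* uncalibrated model is then often a near-constant, and the search
is actively repelled from the correct structure because its scale is wrong.
The engine therefore fits, per chromosome and in closed form, least-squares
linking coefficients: prediction = Σ w_g·gene_g + intercept (a direct
generalization of linear output scaling in symbolic regression, with the 6
decoded genes as the basis). Each gene only has to discover a useful basis
function; scale, sign and the zeroing-out of junk genes are analytic. The
calibration is part of the trained model (serialized with it, rendered into
the exported formula string) and identical at train and predict time.
Uncalibrated plain-addition linking remains available
(`linear_scaling=False`). Saturated gene columns (magnitude > 1e12) are
excluded from the calibration basis since they carry no usable signal.

**Termination.** 200 generations by default, with early stop when the best
RMSE has not improved by more than 1e-8 over 50 consecutive generations.
One RNG stream per run, seeded from the config; the draw order (population
init, then per generation: selection indices, then the operators in the
fixed order mutation → inversion → IS → RIS → gene transposition →
one-point → two-point → gene recombination) is fixed, so runs are
bit-reproducible. Gene evaluations are memoized by coding region and
chromosome RMSEs by genome, which is what keeps 200×200 evaluations per run
affordable after the population begins to converge.

The X and Y observation models are trained with derived seeds (seed,
seed + 1), so the pair is reproducible from one number.

## Synthetic data

The generator emulates the study conditions: 14 one-stroke shapes plus 10
digits, by default 40 trials per symbol, sampled at the 50 ms clock, with a
7-channel feature stream derived from the trace's instantaneous velocity.

Symbol curves are parametric (lines, half-sine arch, trigonometric
circle/ellipse and figure-eight, piecewise-linear square/triangle) with
digits as Catmull-Rom splines through hand-placed control points
(equivalent to piecewise cubic Béziers); all are arc-length parameterized.
The tablet units are arbitrary (default scale 100 per symbol); workspace
units are not modeled. Trial-to-trial variability is a monotone jitter of
the arc-length parameterization (increments |N(1, 0.15)|) plus
moving-average-smoothed coordinate noise with SD 2% of the symbol scale, so
strokes never "teleport". Start points are exact.

The default forward model for channel c is

    g_c(Δ) = |a_c Δx + b_c Δy| + o_c + d_c · sin(e_c · u_c),

with u_c = Δx for four channels and Δy for three. This mimics rectified
antagonist muscle drives plus a nonlinear (sinusoidal) component of
activation. Mixing the sinusoid axes is what makes the map injective: if
every sinusoid took Δx, the even |·| terms would leave ±Δy
indistinguishable whenever Δx = 0. The per-channel offset o_c = d_c keeps
noiseless activations nonnegative, so the clip-at-zero applied after adding
noise (RMS amplitudes cannot be negative) never distorts the planted map.
Injectivity is verified numerically on a velocity grid in the tests.
Gaussian feature noise has SD 1.0 by default — about 10% of a typical
channel amplitude, a realistic noise level for windowed sEMG features; the
noiseless regime is uninteresting for the fused decoder because filtering
then has nothing to correct. A purely linear variant (signed drives,
positive offsets, no sinusoids) provides the solvable limit in which all
three decoders should be near-perfect.

Raw 1000 Hz signals, when requested, are amplitude-modulated Gaussian noise
renormalized per 50 ms window to the exact target RMS, with a quiescent
(< 30 µV) pre-onset period and a deterministic 120 µV trigger peak at
onset, so onset detection recovers the construction exactly.

What the generator does *not* emulate: muscle synergies and crosstalk,
nonstationary baselines, electrode lift, multi-stroke symbols, and
inter-subject variability (seeds stand in for subjects). Passing tests on
this world demonstrate correctness of the algorithms and the claimed
qualitative ordering of the methods under a nonlinear, noisy observation
map — not performance on human recordings.

## Evaluation protocol

R² is the squared Pearson correlation between the true and reconstructed
sequence of one coordinate of one trial; per-symbol tables report mean ± SD
across trials, which is the only aggregation consistent with reporting SDs.
A constant sequence (e.g. the y-coordinate of an ideal horizontal line) has
undefined correlation and is reported as missing, never as zero; the
generator's jitter makes this rare in practice. Splits are 70/30 at trial
granularity, stratified by symbol, to avoid within-trial leakage.
Within-group experiments pool all symbols into one model set; between-group
experiments train one set per symbol.

The paired Wilcoxon signed-rank test drops zero differences, midranks ties,
and uses an exact null distribution — computed by convolution over doubled
(integer) ranks, equivalent to full 2ⁿ sign enumeration — for up to 25
informative pairs, switching to a tie-corrected normal approximation with
continuity correction beyond. One-sided ("fused beats baseline") is the
default, configurable. The exact path is verified against brute-force
enumeration and against an independent library implementation on tie-free
data.

## Problem sizes used in the shipped experiments

The method-ordering experiment runs 5 symbols × 40 trials × 10 splits
(within-group, so 2 GEP runs per split) with 16-point traces; planted-model
recovery uses 300 training / 200 test rows; state-model recovery uses 10⁴
steps × 10 seeds. These sizes give stable statistics (hundreds of paired
trials for the Wilcoxon comparisons) while keeping a full run in the
minutes range; larger traces and between-group designs scale linearly
through the same interfaces.

## Known limitations

* The evolutionary search is stochastic; with the published population size
  and 200 generations, recovered-model quality varies a few percent across
  seeds (planted-model test R² typically 0.95–0.99).
* The KF baseline's observation map has no intercept term (C = H·RMS), so
  channels with a large common offset load part of that offset onto the
  increment prediction; this faithfully reproduces the baseline's published
  structure but is one reason it trails the symbolic models.
* The no-intercept BiLR dynamics assume zero-mean increments; strongly
  drifting strokes violate this mildly.
* Closed shapes (circle, ellipse, figure-eight digits) are intrinsically
  harder — small angular errors accumulate over the stroke — mirroring the
  qualitative difficulty reported for such symbols in this literature.
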