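# Methods

This note documents the statistical procedures implemented in
`simsens`, the assumptions behind them, the defaults and why they were
chosen, what the bundled toy simulator does and does not emulate, and
the package's known limitations.

## Scope and assumptions

All four techniques assume that a *calibration* has already been
performed: there is a baseline parameter assignment producing reference
simulation behaviour, measured through one or more scalar response
measures per run.  Responses are not assumed normally distributed —
stochastic simulations routinely produce skewed, bounded or multimodal
outputs — so all distribution comparisons use the non-parametric
Vargha-Delaney A-Test rather than t-tests on responses.  (The only
t-tests in the package compare *sensitivity indices* across resample
curves, which is a different, approximately normal quantity.)

Techniques exchange data as plain CSV: one row per run (or per
parameter set), one column per response, `.` decimal separator, UTF-8.
Rows with missing or non-numeric cells are excluded at ingestion with a
logged count; a missing response column is a hard error.  Every
analysis logs and reports the total number of rows it consumed so that
design bookkeeping can be audited.

## The A-Test (effect magnitude)

For samples X, Y: `A = [#(x > y) + 0.5 #(x = y)] / (n1 n2)`, the
probability that a random draw from X exceeds one from Y with ties
counted half.  The implementation uses the rank-sum identity
`A = (R1 − n1(n1+1)/2)/(n1 n2)` with average ranks for ties, which is
bit-identical to pair enumeration (rank sums of half-integers are
dyadic); the O(n1·n2) enumeration route is retained and cross-checked
in tests.  Direction is irrelevant for magnitude, so scores are folded:
`A' = 0.5 + |A − 0.5|`.  Magnitude bands default to the test authors'
conventions — small ≥ 0.56, medium ≥ 0.64, large ≥ 0.71 — and are
configurable.  NaN inputs are rejected rather than dropped, because
silent dropping changes the probability being estimated.

## Technique 1: consistency (aleatory) analysis

At each candidate sample size *s*, `subset_count` (default 20)
independent subsets of *s* runs are collected under identical
parameters.  Each run is summarised by the *median* of its per-record
values (e.g. per-cell velocities), making the run summary robust to
within-run outliers.  Subsets 2..20 are scored against subset 1 (fixed
reference, as the procedure is defined; no all-pairs comparison, whose
quadratic cost buys little).  The recommended sample size is the
smallest analysed size whose maximum folded score over all subsets and
responses is strictly below the tolerance.  The tolerance defaults to
0.56 — the criterion is "aleatory effect smaller than small".  No
interpolation between analysed sizes is attempted; the recommendation
is restricted to the sizes actually analysed.

## Technique 2: robustness (one-at-a-time)

The perturbation grid for a parameter is `lower + k·increment`,
`k = 0..⌊(upper − lower)/increment⌋` (computed by multiplication, not
repeated addition, so no floating-point drift accumulates; the upper
bound is included exactly when it lies on the grid, within 1e-9
relative tolerance).  Every perturbed assignment restores all other
parameters to their calibrated values.  The baseline distribution is a
separately supplied condition rather than a grid point, because the
calibrated value need not lie on any grid.  Each condition is scored
against baseline per response; conditions whose folded score reaches
the large threshold are flagged.  For the six-parameter case-study
configuration at its stated increments the design has 64 perturbed
conditions plus baseline = 65.

## Technique 3: latin hypercube + PRCC

Sampling: each parameter's range is divided into N equal strata; one
uniform draw is taken inside each stratum (uniform rather than
midpoint, to preserve coverage across repeated designs) and the strata
are permuted independently per parameter.  R candidate designs
(default 20) are drawn and the one minimising the maximum absolute
pairwise Spearman correlation between columns is kept — a cheap,
deterministic-given-seed alternative to iterative column optimisation
that reliably keeps |ρ| < 0.1 at N = 500.

Analysis: per-set responses are medians over replicates.  All columns
are rank-transformed (average ranks); for parameter j, the ranks of
x_j and of the response are each residualised by least squares (with
intercept) on the ranks of the remaining K−1 parameters, and the PRCC
is the Pearson correlation of the residuals.  With K = 1 this reduces
exactly to Spearman's ρ.  Significance uses
`t = ρ_p √(df/(1 − ρ_p²))`, `df = N − 2 − (K − 1)`, two-sided.  The
published procedure reports PRCCs without a test; the t-approximation
is supplied here with its formula stated so users can ignore it if
they prefer.  Constant columns yield an undefined coefficient and are
reported as 0 with a warning.

## Technique 4: eFAST

Sampling: over the symmetric grid `s_j = π(2j − NS − 1)/NS`, parameter
k follows the triangle wave
`x_k = lower + span·(½ + arcsin(sin(ω_k s_j + φ_k))/π)`, which sweeps
its range with a uniform marginal distribution.  NS must be odd; the
parameter of interest gets `ω_max = ⌊(NS − 1)/(2M)⌋` (M = 4 harmonics
by default; NS < 4M + 1 is rejected with the minimal admissible NS
named), and the complementary parameters get low frequencies in
`[1, ⌊ω_max/2⌋]`.  Complementary frequencies cycle through the **odd**
integers 1, 3, 5, … of that band: assigning harmonically related pairs
such as 1 and 2 makes two complementary parameters trace a two-branch
Lissajous figure, and for models with interactions this distorts the
per-curve total variance badly (on the Ishigami benchmark, the
first-order index of x2 then scatters with sd ≈ 0.19 across curves;
restricting to odd frequencies collapses this to ≈ 0.0005 around the
analytic value).  Phases φ are drawn uniformly per parameter per
resample curve from the seeded generator.

Analysis: with Fourier coefficients
`A_k = (1/NS) Σ y_j cos(k s_j)`, `B_k` likewise with sine,
`D_total = 2 Σ_{k≤(NS−1)/2} (A_k² + B_k²)`,
`Si = D_{ω_max}/D_total` summing M harmonics of ω_max, and
`STi = 1 − D_complement/D_total` with the complement band
`k ≤ ⌊ω_max/2⌋`.  Because the Si harmonics lie strictly above the
complement band, `0 ≤ Si ≤ STi ≤ 1` holds identically whenever
`D_total > 0`; a constant response yields zero indices with a warning
rather than an error (a dead output under a sweep is a legitimate,
detectable finding).  Indices are aggregated as means over the NR
curves with standard error `sd/√NR`; each real parameter's per-curve
indices are compared with the dummy's via a one-sided Welch t-test
(the unequal-variance form, since nothing guarantees equal variances;
with NR = 3 either form is fragile — see limitations).  The dummy's
indices are non-zero in general (aliasing and the STi band
approximation), which is exactly why it is the comparator.

## The toy simulator

Per cell, with V0 = 10 (arbitrary speed units), n_steps = 100:

    w        = (1 − e^(−vcamSlope)) / (1 − e^(−2))            ∈ [0.25, 1]
    adhesion = maxVCAM · (0.35 + 0.65 · thresholdBind · w)    ∈ [0, 1]
    Velocity = V0 (1 − 0.7 adhesion) e^ε,                     ε ~ N(0, 0.2²)
    gain     = clamp(0.5 − chemoThreshold, 0, 1) · chemoLower/0.08
    Displacement = Velocity · n_steps · (0.2 + 0.8 gain) e^η, η ~ N(0, 0.3²)

The multiplicative structure of `adhesion` makes the influence
ordering for Velocity structural rather than statistical:
`maxVCAMeffectProbabilityCutoff` scales the whole term (largest main
effect), `thresholdBindProbability` scales only 65% of it, and
`vcamSlope` enters through the saturating, range-compressed factor w.
`chemoThreshold` and `chemoLowerLinearAdjust` act only on Displacement
through the gain (with a flat region for chemoThreshold > 0.5, giving
PRCC/eFAST a non-linearity to cope with), and
`chemoUpperLinearAdjust` is read but deliberately never used — a true
negative that every technique must report as such.  Lognormal noise
keeps responses positive and non-normal.  Defaults: 50 cells per run,
σ_v = 0.2, σ_d = 0.3, chosen so that a single run's median has ≈ 5%
relative noise — large enough that consistency analysis needs
hundreds of replicates, small enough that 20-replicate medians expose
the sensitivity structure.

Calibrated values (0.3, 0.045, 0.3, 0.5, 1.0, 0.5 in the parameter
order above) are mid-range and lie on the one-at-a-time increment
grids, so the grid point at the calibrated value scores ≈ 0.5 against
baseline as a built-in consistency check.

Per-run seeds are `master_seed + run_counter` over numpy's PCG64, so
any dataset is reproducible bit for bit from one integer.

What the toy model does **not** emulate: spatial agent interactions,
chemokine diffusion fields, time-varying responses, correlated noise
between cells, or any biological calibration target.  Passing
recoveries on it demonstrate that the *statistical machinery* detects
designed effects of realistic magnitude under lognormal noise — not
that any particular biological simulator is well calibrated.

## Problem sizes used in tests and the acceptance script

The bookkeeping pipelines run at the full study sizes (19,120
consistency runs; 65 × 500 robustness runs; 500 × 500 latin-hypercube
runs) with 5 cells per run, which leaves run counts untouched while
keeping the whole acceptance script around two minutes on one CPU.
Recovery analyses use 100 replicates per robustness condition, 200
sets × 20 replicates for PRCC, and NS = 65, NR = 3, 5 replicates for
toy eFAST — sizes at which the designed effects are comfortably above
the noise floor.  The Ishigami benchmark uses NS = 257, NR = 5, M = 4.

## Known limitations

* With NR = 3 resample curves the dummy-comparison t-test has 2–4
  degrees of freedom; its p-values are coarse.  More curves sharpen it
  at linear cost.
* The best-of-R correlation minimisation controls, but does not
  eliminate, spurious LHS column correlations; for very small N an
  iterative column-adjustment scheme would do better.
* eFAST first-order indices for parameters whose true Si is 0 estimate
  an aliasing noise floor, not zero; judge them against the dummy, not
  against 0.
* When duplicate complementary frequencies are unavoidable (more than
  ⌈⌊ω_max/2⌋/2⌉ complementary parameters), the complementary set is
  internally confounded; Si of the parameter of interest is
  unaffected, but the complement's internal structure is not resolved.
* The consistency recommendation selects the smallest qualifying
  analysed size even if a larger analysed size fails the tolerance;
  with noisy max-score curves, inspect the full summary table rather
  than the single recommended number.
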