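# simsens

Uncertainty and sensitivity analysis for stochastic biological
simulations.

Agent-based and other stochastic simulators of biological systems face
two kinds of uncertainty: **aleatory** (run-to-run variation from the
simulator's random elements, present even at fixed parameters) and
**epistemic** (parameters whose biological values are unknown and had to
be assumed).  Before a simulation result can be interpreted as biology
rather than as an artefact of parametrisation or stochasticity, both
must be quantified.  `simsens` provides four complementary techniques
for doing so, aimed at modellers of cell behaviour and tissue
development but applicable to any simulator that emits tabular
responses:

1. **Consistency (aleatory) analysis.**  For each candidate sample size
   *s*, 20 subsets of *s* replicate runs at fixed calibrated parameters
   are gathered; subsets 2–20 are contrasted with subset 1 using the
   Vargha-Delaney A-Test, *A* = P(x > y) + ½ P(x = y), folded onto
   [0.5, 1] since only effect magnitude matters.  The smallest *s*
   whose maximum folded score falls below the "small"-effect threshold
   (0.56) is the number of replicates needed to suppress stochastic
   noise.

2. **Robustness (one-at-a-time) analysis.**  Each parameter is swept
   from its lower to upper bound at a fixed increment while all others
   stay calibrated; each perturbed response distribution is scored
   against the baseline with the A-Test.  Folded scores ≥ 0.71 mark
   perturbations with a scientifically significant ("large") effect.

3. **Latin-hypercube sampling + PRCC.**  All parameters are perturbed
   simultaneously over a stratified latin hypercube (one sample per
   equal-width stratum per parameter, permutations chosen best-of-R to
   minimise spurious column correlations).  Influence is quantified by
   partial rank correlation coefficients: the Pearson correlation of
   rank residuals of parameter and response after removing the linear
   rank effects of all other parameters, with a t-based p-value on
   N − 2 − (K − 1) degrees of freedom.

4. **eFAST.**  Parameters are driven through their ranges along
   sinusoidal search curves, the parameter of interest at a high
   frequency ω_max = ⌊(NS−1)/2M⌋ and the complementary set at low odd
   frequencies.  Fourier analysis of the response partitions its
   variance into a first-order index Si (variance explained by the
   parameter alone) and total-order index STi (including all its
   interactions), averaged over NR phase-reshuffled resample curves.
   A sampled "dummy" parameter with no simulator effect provides the
   noise floor; real parameters are compared to it with one-sided
   Welch t-tests.

A bundled **toy simulator** emulates a six-parameter cell-behaviour
case study (responses: cell `Velocity` and `Displacement`) with designed
ground-truth sensitivities — including one deliberately inert parameter —
so every technique can be validated end to end in seconds.

## Worked example

Score two response samples with the A-Test, then run a global
LHS/PRCC analysis on the toy simulator:

```python
import tempfile
from simsens import a_test, case_study_parameters, lhs_sample
from simsens.toy_simulator import generate_lhs_dataset
from simsens.lhs_prcc import analyse_lhs_dir

score = a_test([77.1, 78.3, 80.2, 81.0], [69.4, 72.0, 74.6, 78.1])
print(f"A = {score.a:.3f}, folded = {score.a_normalised:.3f}, magnitude = {score.magnitude}")

params = case_study_parameters()
design = lhs_sample(params, n=100, seed=42)
with tempfile.TemporaryDirectory() as tmp:
    generate_lhs_dataset(tmp, design, replicates=20, seed=42)
    result, medians = analyse_lhs_dir(tmp, ["Velocity", "Displacement"], design=design)
velocity = result.table[result.table.response == "Velocity"]
print(velocity.sort_values("prcc", key=abs, ascending=False).round(3).to_string(index=False))
```

prints

```
A = 0.938, folded = 0.938, magnitude = large
                     parameter response   prcc  p_value
maxVCAMeffectProbabilityCutoff Velocity -0.973    0.000
      thresholdBindProbability Velocity -0.803    0.000
                     vcamSlope Velocity -0.553    0.000
                chemoThreshold Velocity -0.146    0.159
        chemoUpperLinearAdjust Velocity  0.084    0.416
        chemoLowerLinearAdjust Velocity  0.047    0.651
```

The A-Test reports a large effect (0.938 ≫ 0.71): a random draw from
the first sample exceeds one from the second 94% of the time.  The
PRCC table recovers the toy model's ground truth: the adhesion cutoff
dominates cell velocity (|ρ| = 0.97, negative because adhesion slows
cells), binding probability and adhesion slope follow, and the three
chemotaxis parameters are statistically indistinguishable from zero
influence on velocity.

The same workflow is available from the shell; each `analyse` command
also writes summary CSVs and diagnostic plots:

```sh
simsens lhs sample     --config examples/case_study.yaml --out data/
simsens toysim run     --config examples/case_study.yaml --technique lhs --replicates 20 --out data/
simsens lhs analyse    --config examples/case_study.yaml --in data/ --out results/
```

(`consistency`, `robustness` and `efast` subcommands follow the same
sample → run → analyse pattern; see `simsens --help`.)

## Layout

```
src/simsens/
  params_io.py      parameter specs, YAML config, CSV ingestion, design writing
  atest.py          Vargha-Delaney A-Test and magnitude classification
  consistency.py    technique 1: aleatory analysis
  robustness.py     technique 2: one-at-a-time perturbation
  lhs_prcc.py       technique 3: latin hypercube + PRCC
  efast.py          technique 4: eFAST variance decomposition
  toy_simulator.py  synthetic case-study simulator with known sensitivities
  cli.py            `simsens` command-line interface
docs/methods.md     models, assumptions, numerical choices, limitations
```
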