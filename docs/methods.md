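# Model and methods

`adaswitch` couples a mechanistic stochastic model of the *E. coli*
adaptive response to DNA alkylation stress with the analysis pipeline used
on single-cell microscopy and flow-cytometry data.  This note documents the
model, its assumptions, the calibration, and what the synthetic data do and
do not emulate.

## The generative model

### Basal gene expression and the master switch

Each adaptive-response gene (*ada*, *alkB*, *alkA*, *aidB*) is expressed in
the OFF state as a birth–death process: constant synthesis at `k_b` and
first-order dilution at `gamma` (min⁻¹).  The stationary law is
Poisson(`k_b/gamma`); the shipped means are 1.0 (Ada), 0.25 (AlkB), 2.6
(AlkA) and 0.05 (AidB) molecules per cell, matching single-molecule
counting of the basal state.  `gamma = 0.0075 min⁻¹` reflects slow
effective protein turnover (dilution-limited, with growth slowed under
stress); together with the Poisson(1) Ada distribution it controls how long
zero-Ada cells wait for their first Ada molecule, and therefore the size of
the Delayed subpopulation.

The switch is triggered by methylation of a single Ada molecule.
Methylated phosphotriester lesions accumulate with integrated exposure, so
the per-molecule methylation hazard ramps with time: the cumulative
per-molecule hazard is `Lambda(t) = (k_m * m^eta * t)^s` for a constant
dose `m`, with shape `s = 4.2` and dose exponent `eta = 1.35`.  A cell with
`n(t)` Ada molecules switches with hazard `n(t) * dLambda/dt`; cells with
zero Ada cannot switch at all until a molecule is born.  Both samplers
(per-cell and vectorised) integrate the hazard exactly between
birth–death jumps and invert it against a unit-exponential draw — no time
discretisation is involved in the trigger.

The `ada_C321A` variant constitutively de-represses its own promoter; it is
modelled as pre-activated, switching at rate `c321a_switch_rate` from MMS
onset (homogeneous, near-immediate activation).  `dada_alkB` never
switches.

### Induction and expression fluctuations

After the switch at `t_on`, each induced gene relaxes exponentially
(timescale `tau_rise = 25 min`) toward `N_ss * d(t)`, where `N_ss` is the
induced level (300 molecules for *ada*, a ~300-fold amplification over the
basal mean) and `d(t)` is a per-cell mean-reverting (Ornstein–Uhlenbeck)
fluctuation process with mean 1, stationary SD `fluct_sd = 0.25` and
reversion rate `fluct_reversion = 0.012 min⁻¹` (~80 min correlation time).
`d(t)` encodes slow cell-to-cell variation in damage load and expression
capacity; it is *shared* between *ada* and *alkB* (one operon, read
synchronously) and by *alkA*, which reads it with a lag `tau_lag = 8 min`.
This minimal shared-process structure is what produces (i) tightly
correlated activation delays with `alkA delay = ada delay + 8 min`, and
(ii) a positive steady-state cross-correlation between the two reporters,
peaked at a positive lag, that vanishes in shuffled-pair and
constitutive-reporter controls.  The constitutive segmentation-marker
channel carries an independent fluctuation process.

Fluorescence is observed on a 3-min frame grid as
`F = c*n(t - maturation) + b + N(0, sigma_F^2)`; maturation defaults to 0.

### Lesions, mismatches and mutations

Three lesion pools are produced linearly in dose and removed by first-order
repair once the responsible protein is induced:

| pool | lesion class | repaired by | repair starts |
|------|--------------|-------------|---------------|
| alka | 3meA-type    | AlkA        | `t_on + tau_lag` |
| alkb | 3meC/1meA-type | AlkB      | `t_on` |
| mug  | O6meG-type   | Ada (C321)  | `t_on` (never in `ada_C321A`) |

Genotype deletions zero the corresponding repair for all time;
`dada_alkB` never induces anything.  Post-activation repair operates at
`beta_on = 0.4 min⁻¹`; pre-activation repair is 0 (the constitutive Ogt/Tag
background is folded into the net production rates).

The MutL-focus (mismatch) intensity is

    lambda_mis(t) = r_0 + u^q * ( r_mug * m^(p-1) * L_mug + r_tox * (L_alka + L_alkb) )

with basal rate `r_0 = 4e-3` foci cell⁻¹ min⁻¹ and `p =
mug_dose_exponent = 3`: the *conversion* of O6meG lesions into replication
mismatches is superlinear in dose, representing saturation of mismatch
surveillance at high MMS.  `u` is a per-cell lognormal
damage-susceptibility factor (sigma `susceptibility_sd = 0.5`, mean 1); it
enters mutagenesis as `u^q` with `q = 0.5` because toxic and mutagenic
damage share the cell's exposure only partially.  Foci are drawn per frame
as Poisson(`lambda_mis * 3 min`); when foci persist across consecutive
frames the analysis counts only the first frame as a mismatch event.  Each
mismatch becomes a fixed mutation with `p_fix = 0.01` (the canonical ~1%
MMR escape probability), and each fixed mutation confers rifampicin
resistance with `p_rif = 0.1` (a package-scale choice that keeps simulated
colony counts in the hundreds; only frequency *ratios* are interpreted).

### Toxicity and survival

Toxicity is indirect.  Unrepaired alka/alkb lesions stall replication
forks: each pool drives a fork compartment at `fork_rate` per lesion per
minute, and a stalled fork can only be resolved (rate
`fork_resolution_on = 0.3 min⁻¹`) once its causative lesion class is under
repair — before that, forks persist (`fork_resolution_off = 5e-4`).  The
death hazard is `hazard_scale * u * D(t)` with `D` the total stalled-fork
load.  This two-stage structure makes the cumulative hazard of an
unprotected cell grow like t³, which is what separates repair-null death
over 4 h (<10% survival) from the much milder 90-min exposure of Delayed
wild-type cells, while cells that activate early accrue very little.  The
mug pool contributes a small fork rate (`mug_fork_rate`), representing
futile mismatch-repair cycling at O6meG:T; it is negligible for wild type
but accounts for the ~10% mortality of `ada_C321A` over 4 h.

Death times are sampled by inverting the cumulative hazard against an
exponential draw; fates are lysed/arrested/escaped with fixed probabilities
(0.5/0.3/0.2).  In survival analysis, lysed and arrested cells are deaths;
escaped cells (filamentation out of the channel) are right-censored by
default because their death is unobserved.

### FACS experiments

The sort-and-plate experiment is simulated at event level with vectorised
exact draws (switch time, susceptibility, damage integrals, survival,
mutations, reporter intensity), which scales to the ~10⁶-cell sorts.  In
the batch-culture observation model, lysed cells are lost from the event
stream; growth-arrested cells are intact, measured and sorted, but form
colonies only with probability `arrest_recovery = 0.35` after the stress is
washed out (arrest under MMS is partially reversible; lysis is not).
Mismatch accrual for arrested cells is evaluated at the sampling time, a
small approximation since most arrests occur late in the 90-min window.
FACS intensities carry an extra lognormal measurement spread
(`facs_log_sd = 0.10`).

Gates follow the published construction: the Delayed gate is centred on the
log₁₀-intensity mode of an untreated culture with half-width 3 SD of the
untreated spread; the Activated gate has identical width, centred on the
treated-culture mode beyond the Delayed gate.  Events between or outside
gates are excluded.  Equal numbers are sorted per gate (capped at the
smaller gate population), plated, and rifampicin-resistant colonies counted;
mutant frequency is colonies per sorted cell, and the Delayed share of
total mutants weights colony counts by gate percentages.

### Counting snapshots

Single-molecule counting snapshots draw from the OFF-state stationary law,
except for a small spontaneously induced subpopulation (5% for *alkA*,
drawn at ~25 molecules) representing cells that triggered the response
without exogenous stress; these fall almost entirely into the censored
">8" bin, reproducing the ~5% uncountable AlkA cells while the countable
cells remain Poisson(2.6).  The summary reports the censored fraction and
two estimators: a right-censored MLE (censored cells contribute the
Poisson tail mass) and a right-truncated MLE on countable cells only.  The
truncated estimator is the headline basal mean: it is insensitive to a
contaminating induced subpopulation in the censored bin.

## Numerics

* Gillespie simulation and hazard inversion are exact for basal expression
  and the switch; no step-size error enters the trigger.
* Lesion/fork/hazard/mismatch dynamics are integrated on a 1-min grid
  (`damage_grid_dt`) with exact exponential-decay updates per step and
  trapezoidal accumulation of hazard and intensity; halving the step does
  not visibly change any headline statistic.
* The OU fluctuation process is sampled exactly on a 1-min grid and
  linearly interpolated; FACS event-level draws use its stationary law.
* Cross-correlations are normalised by full-window variances (no
  per-overlap re-centering), which guarantees values in [−1, 1]; with a
  window of length N frames this induces the usual ≈ −1/N small-sample
  bias at large lags.
* Gate modes are kernel-density maxima (Gaussian KDE, Silverman
  bandwidth) on log₁₀ intensity; ties and degenerate inputs raise errors
  rather than guessing.
* Mutation counts use the Poisson thinning identity
  `P(RifR) = 1 − (1 − p_rif)^N`, `N ~ Poisson(p_fix·Λ)`.

## Calibration

Constants not fixed by first principles were tuned once, by the documented
grid search in `scripts/calibrate.py` (also `adaswitch calibrate`), against
the published summary statistics: mean/SD of called activation delays
(63 ± 19 min, AlkA offset +8 min), basal count statistics (AlkA 2.6/cell
with ~5% censored, AlkB single-molecule fraction ~20%, Fano ≈ 1), survival
at 4 h of 1 mM MMS (<10% for repair-nulls, ≈90% for `ada_C321A`), the
Delayed-gate fraction (≈15% at 3 mM), and the Delayed:Activated mutant
frequency ratios (≈1.5/≈5/≈4 at 1/3/10 mM) with the Delayed mutant share
(≈53% at 3 mM).  The search proceeds in three nearly separable stages
(trigger scale from delays; mug fork rate from `ada_C321A` survival;
mutation/recovery constants from the ratio targets on cached event-level
simulations).  The result ships as `calibration/default.yaml`; it is data,
not code.

## Problem sizes

Default analysis scales are chosen for desk-scale reproduction: delay
statistics use 139-cell dual-reporter populations (three seeds), survival
curves 500 cells per genotype and seed, counting snapshots 10⁴ cells, and
sort-and-plate experiments event streams of 3–7 × 10⁶ cells so that 10⁶
cells can be sorted per gate at 3 mM.  The test suite uses somewhat smaller
sizes with tolerances widened to 3 Monte-Carlo standard errors where
appropriate.

## What the synthetic data are and are not

The generator emulates: Poisson basal copy numbers with a counting limit;
heterogeneous, dose-accelerated switch timing with a zero-Ada Delayed
subpopulation; operon-coupled and lagged induction with shared slow
fluctuations; transient (wild-type) versus sustained (repair-null,
`ada_C321A`) mismatch-rate curves; genotype-dependent survival; and
bimodal reporter distributions with gate-resolved mutant frequencies.

It does not emulate: cell geometry, segmentation or imaging noise beyond a
Gaussian intensity term; lineage structure beyond the mother cell; cell
division and dilution noise in the ON state (the OU process stands in for
both); SOS induction dynamics; dose–response of growth rate; or
plate-level mutant ecology (each sorted cell plates independently).
Passing tests therefore demonstrate internal consistency of the pipeline
and the mechanistic adequacy of this model class at the published summary
level — not pixel-level realism.

## Known limitations

* Wild-type survival at 1 mM/4 h comes out near 60–70%, lower than the
  near-unaffected survival in the source experiments; the pre-activation
  fork-load needed to kill repair-nulls within 4 h necessarily costs the
  later-activating wild-type cells.  All graded survival contrasts
  (repair-nulls, `ada_C321A`) are unaffected.
* The Delayed-gate fraction at 1 mM (~33%) is larger than at 3 mM by
  construction (switching is slower at lower dose); the source reports a
  gate fraction only at 3 mM.
* `escape` fates are drawn from a fixed categorical distribution rather
  than a filamentation model; survival curves treat them as censored.
* The event-level FACS path evaluates mutation accrual of arrested cells
  at the sampling time rather than their arrest time.
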