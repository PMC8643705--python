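# adaswitch

Stochastic simulation and single-cell analysis of the *Escherichia coli*
adaptive response to DNA alkylation stress.

## The problem

The adaptive response (the *ada–alkB* operon, *alkA*, and *aidB*) protects
*E. coli* against methylating agents such as MMS.  Its master regulator Ada
is present at roughly **one molecule per cell**: methylation of a single Ada
molecule converts it into a transcriptional activator of its own operon,
and positive feedback then amplifies expression several hundred-fold.
Because cells with zero Ada molecules cannot trigger the feedback at all,
an isogenic population splits under stress into a majority that activates
quickly ("Activated") and a minority that stays unprotected for hours
("Delayed").  The Delayed cells accumulate DNA mismatches and fixed
mutations at elevated rates while remaining largely viable — a transient
hypermutable subpopulation that boosts the genetic plasticity of the whole
population.

`adaswitch` provides, for anyone studying such stochastic stress-response
circuits:

* a **generative model** of the switch — basal birth–death expression with
  Poisson stationary copy numbers, an exactly-sampled single-molecule
  methylation trigger with hazard `n(t) · d/dt (k_m m^η t)^s`, lesion pools
  with genotype-specific repair, replication-fork toxicity, mismatch
  (MutL-focus) statistics, mutation fixation and survival;
* the **analysis pipeline** used on mother-machine and FACS data:
  baseline-corrected traces, threshold-based activation-delay calling,
  dual-reporter delay regression, steady-state cross-correlation with
  shuffled and constitutive-reporter controls, molecule-count summaries
  and Poisson fits under a ">8" counting limit, mismatch-rate curves with
  30-min smoothing, Kaplan–Meier survival, kernel-density FACS gating, and
  mutant-frequency / plasticity-share accounting.

Genotypes: `wild_type`, `dalkA`, `dalkB`, `dada_alkB`, `ada_C321A`
(regulator-competent but O6meG-repair-deficient).

## Worked example

Simulate a 139-cell dual-reporter (Ada-CFP / AlkA-mYPet analogue)
population under a 1 mM MMS step and call activation delays:

```python
import numpy as np
from adaswitch import MMSProfile, default_params, simulate_population
from adaswitch.traces import call_population, delay_fit, traces_from_population

params = default_params()
pop = simulate_population(139, params, MMSProfile.step(1.0, onset=30.0),
                          horizon=210.0, seed=1)
traces = traces_from_population(pop)
ada = [c for c in call_population(traces, "ada") if c.label == "Activated"]
alka = [c for c in call_population(traces, "alka") if c.label == "Activated"]
fit = delay_fit(ada, alka)
print(f"mean ada delay : {np.mean([c.delay for c in ada]):5.1f} min "
      f"(SD {np.std([c.delay for c in ada], ddof=1):.1f})")
print(f"mean alkA delay: {np.mean([c.delay for c in alka]):5.1f} min")
print(f"alkA = {fit.slope:.2f} * ada + {fit.intercept:.1f} min  (r = {fit.r:.2f})")
```

which prints

```
mean ada delay :  62.8 min (SD 17.9)
mean alkA delay:  70.8 min
alkA = 1.00 * ada + 8.1 min  (r = 1.00)
```

The interpretation: under 1 mM MMS the average cell switches about an hour
after exposure with broad cell-to-cell spread (cells that never cross the
detection threshold within 2 h are labelled Delayed, not averaged here),
and the *alkA* delay tracks the *ada* delay cell by cell with unit slope
and a fixed ~8-min offset — the signature of one shared stochastic trigger
feeding the whole regulon.

The same objects drive everything else, e.g. a full sort-and-plate
experiment at 3 mM:

```python
from adaswitch import simulate_facs_experiment
from adaswitch.facs import define_gates, apply_gates, run_sort_assay, plasticity_share

untreated = simulate_facs_experiment(params, 0.0, 200_000, t_sample=90.0, seed=2)
treated = simulate_facs_experiment(params, 3.0, 2_000_000, t_sample=90.0, seed=3)
gates = define_gates(untreated, treated)          # Delayed / Activated
assays = run_sort_assay(treated, gates, n_sort=1_000_000,
                        plating_efficiency=1.0, seed=4)
share = plasticity_share(assays)
```

There is also a CLI (`adaswitch simulate|analyze-traces|analyze-counts|
mismatch-rates|survival|facs|report|demo|calibrate`); `adaswitch demo
--out run --seed 0` touches every stage and writes a `report.json`.

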