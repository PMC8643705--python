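"""Shared fixtures: simulated populations and event streams reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

from adaswitch.params import MMSProfile, default_params
from adaswitch.simulate import simulate_facs_experiment, simulate_population

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")

MASTER_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def wt_pop(params):
    """Dual-reporter wild-type population, 1 mM step at t=30 min."""
    return simulate_population(139, params, MMSProfile.step(1.0, onset=30.0),
                               300.0, MASTER_SEEDS[0])


@pytest.fixture(scope="session")
def steady_pop(params):
    """Long wild-type run for steady-state fluctuation analysis."""
    return simulate_population(100, params, MMSProfile.step(1.0, onset=30.0),
                               600.0, MASTER_SEEDS[1])


@pytest.fixture(scope="session")
def wt_pops(params):
    """Three seeds of the delay-calling population (n=139 each)."""
    mms = MMSProfile.step(1.0, onset=30.0)
    return [simulate_population(139, params, mms, 210.0, s)
            for s in MASTER_SEEDS]


@pytest.fixture(scope="session")
def survival_pops(params):
    """200-cell populations per genotype and seed, 1 mM from t=0, 4 h."""
    mms = MMSProfile.step(1.0, onset=0.0)
    out = {}
    for genotype in ("wild_type", "dalkA", "dalkB", "dada_alkB", "ada_C321A"):
        gp = params.replace(genotype=genotype)
        out[genotype] = [simulate_population(200, gp, mms, 240.0, s)
                         for s in MASTER_SEEDS]
    return out


@pytest.fixture(scope="session")
def facs_runs(params):
    """Sort-and-plate experiments per dose and seed (event-level)."""
    from adaswitch.facs import (apply_gates, define_gates, plasticity_share,
                                run_sort_assay)

    out = {}
    for dose in (1.0, 3.0, 10.0):
        per_seed = []
        for seed in MASTER_SEEDS:
            rng = np.random.default_rng(seed)
            untreated = simulate_facs_experiment(params, 0.0, 60_000, 90.0, rng)
            treated = simulate_facs_experiment(params, dose, 700_000, 90.0, rng)
            gates = define_gates(untreated, treated)
            sort_res = apply_gates(treated, gates)
            assays = run_sort_assay(treated, gates, 1_000_000, 1.0, rng)
            by = {a.subpopulation: a for a in assays}
            per_seed.append({
                "ratio": by["Delayed"].frequency / by["Activated"].frequency,
                "delayed_pct": 100.0 * sort_res.fractions["Delayed"],
                "share": plasticity_share(assays).shares["Delayed"],
                "assays": by,
                "gates": gates,
            })
        out[dose] = per_seed
    return out


def stochastic_tolerance(values, target, rel=0.15):
    """Stochastic tolerance: max(3 Monte-Carlo SEs of the mean, rel*target)."""
    values = np.asarray(values, dtype=float)
    sem = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
    return max(3.0 * sem, rel * abs(target))
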