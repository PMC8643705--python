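"""Generative-model tests: stationarity, identities, determinism, dose response."""

import numpy as np
import pytest
from scipy import stats

from adaswitch.params import MMSProfile, ParameterError, default_params
from adaswitch.simulate import (colony_assay, facs_snapshot, simulate_cell,
                                simulate_facs_experiment, simulate_population,
                                snapshot_molecule_counts)
from adaswitch.switching import sample_switch_time, \
    sample_switch_times_vectorised


class TestOffStateExpression:
    def test_stationary_law_is_poisson(self, params):
        """OFF-state copy numbers follow Poisson(k_b/gamma) (chi-square, n=1e4)."""
        snap = snapshot_molecule_counts("ada", 10_000, params, seed=5)
        counts = snap.counts[~snap.censored]
        lam = params.basal_means["ada"]
        n = len(counts)
        # pool the tail so every expected bin count is >= 5
        kmax = int(stats.poisson.isf(5.0 / n, lam))
        obs = np.bincount(np.minimum(counts, kmax),
                          minlength=kmax + 1).astype(float)
        exp = stats.poisson.pmf(np.arange(kmax + 1), lam)
        exp[-1] += stats.poisson.sf(kmax, lam)
        p = stats.chisquare(obs, exp * n).pvalue
        assert p > 0.01
        # fraction with zero Ada molecules ~ e^-1
        assert np.mean(counts == 0) == pytest.approx(np.exp(-1), abs=0.02)

    def test_zero_rate_gene_all_zero(self, params):
        p = params.replace(basal_means={**params.basal_means, "aidb": 0.0})
        snap = snapshot_molecule_counts("aidb", 500, p, seed=0)
        assert np.all(snap.counts == 0) and not snap.censored.any()

    def test_unknown_gene_rejected(self, params):
        with pytest.raises(ParameterError, match="unknown gene"):
            snapshot_molecule_counts("recA", 10, params, seed=0)


@pytest.fixture(scope="module")
def quiet_pop(params):
    return simulate_population(150, params, MMSProfile.none(), 240.0, 21)


class TestNoStressIdentity:
    def test_no_switching_without_mms(self, quiet_pop):
        assert all(c.t_on is None for c in quiet_pop.cells)

    def test_no_deaths_without_toxic_lesions(self, quiet_pop):
        assert all(c.fate == "alive" for c in quiet_pop.cells)

    def test_foci_rate_recovers_r0(self, quiet_pop, params):
        """With m=0 the focus-event rate estimates r_0 within 3 MC SEs."""
        n_events = sum(len(c.foci_frames) for c in quiet_pop.cells)
        total_time = sum(c.times[-1] for c in quiet_pop.cells)
        rate = n_events / total_time
        se = np.sqrt(n_events) / total_time
        assert abs(rate - params.r_0) < 3 * se + 1e-9


class TestDeterminism:
    def test_population_bit_identical(self, params):
        mms = MMSProfile.step(1.0, onset=30.0)
        a = simulate_population(3, params, mms, 120.0, 42)
        b = simulate_population(3, params, mms, 120.0, 42)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.t_on == cb.t_on and ca.fate == cb.fate
            for ch in ca.fluorescence:
                np.testing.assert_array_equal(ca.fluorescence[ch],
                                              cb.fluorescence[ch])
            np.testing.assert_array_equal(ca.foci_frames, cb.foci_frames)

    def test_facs_event_tables_identical(self, params):
        a = simulate_facs_experiment(params, 3.0, 20_000, 90.0, 7)
        b = simulate_facs_experiment(params, 3.0, 20_000, 90.0, 7)
        assert a.equals(b)


class TestSwitchKinetics:
    def test_delay_decreases_with_methylation_rate(self, params):
        """First-passage monotonicity: higher k_m means earlier switching."""
        means = []
        for scale in (0.5, 1.0, 2.0):
            p = params.replace(k_m=params.k_m * scale)
            t_on, _ = sample_switch_times_vectorised(p, 1.0, 600.0, 4000,
                                                     np.random.default_rng(3))
            means.append(np.mean(t_on[np.isfinite(t_on)]))
        assert means[0] > means[1] > means[2]

    def test_delay_decreases_with_dose(self, params):
        means = []
        for dose in (1.0, 3.0, 10.0):
            t_on, _ = sample_switch_times_vectorised(params, dose, 600.0, 4000,
                                                     np.random.default_rng(4))
            means.append(np.mean(t_on[np.isfinite(t_on)]))
        assert means[0] > means[1] > means[2]

    def test_scalar_and_vector_samplers_agree(self, params):
        """The per-cell and vectorised switch samplers share one law (KS test)."""
        mms = MMSProfile.step(1.0, onset=0.0)
        rng = np.random.default_rng(8)
        scalar = []
        for _ in range(800):
            t_on, _ = sample_switch_time(params, mms, 300.0, rng)
            scalar.append(np.inf if t_on is None else t_on)
        vec, _ = sample_switch_times_vectorised(params, 1.0, 300.0, 4000,
                                                np.random.default_rng(9))
        sf, vf = np.asarray(scalar), vec
        # compare switch fractions and finite-time distributions
        assert abs(np.isfinite(sf).mean() - np.isfinite(vf).mean()) < 0.05
        p = stats.ks_2samp(sf[np.isfinite(sf)], vf[np.isfinite(vf)]).pvalue
        assert p > 0.01

    def test_never_switches_without_ada(self, params):
        p = params.replace(genotype="dada_alkB")
        t_on, _ = sample_switch_times_vectorised(p, 3.0, 300.0, 500,
                                                 np.random.default_rng(1))
        assert not np.isfinite(t_on).any()


class TestInduction:
    def test_on_off_amplification_exceeds_100fold(self, wt_pop):
        """Mean induced ada copy number is >= 100x the basal mean."""
        on_levels = [c.copy_numbers["ada"][-1] for c in wt_pop.cells
                     if c.t_on is not None and c.t_on < 150
                     and c.death_time is None]
        assert np.mean(on_levels) >= 100 * wt_pop.params.basal_means["ada"]

    def test_aidb_never_induces(self, wt_pop):
        for c in wt_pop.cells:
            n = c.copy_numbers["aidb"]
            assert np.nanmax(n) < 10


class TestCellRecordContract:
    def test_horizon_validation(self, params):
        with pytest.raises(ParameterError):
            simulate_cell(params, MMSProfile.none(), -5.0, 0)
        with pytest.raises(ParameterError):
            simulate_cell(params, MMSProfile.none(), 1.0, 0)

    def test_death_truncates_observation(self, params):
        p = params.replace(genotype="dada_alkB")
        pop = simulate_population(60, p, MMSProfile.step(3.0, onset=0.0),
                                  240.0, 31)
        dead = [c for c in pop.cells if c.fate != "alive"]
        assert dead, "expected deaths in a repair-null at 3 mM"
        for c in dead:
            after = c.times > c.death_time
            assert np.all(np.isnan(c.fluorescence["ada"][after]))
            if c.foci_frames.size:
                assert c.times[c.foci_frames].max() <= c.death_time


class TestFacsSnapshotAndColonies:
    def test_snapshot_excludes_dead_cells(self, survival_pops):
        pop = survival_pops["dada_alkB"][0]
        ev = facs_snapshot(pop, 240.0, seed=1)
        alive_ids = {c.cell_id for c in pop.cells if c.fate == "alive"}
        assert set(ev.cell_id) == alive_ids

    def test_empty_snapshot_warns(self, params):
        pop = simulate_population(5, params, MMSProfile.none(), 60.0, 2)
        for c in pop.cells:  # force all dead
            c.fate = "lysed"
            c.death_time = 10.0
        with pytest.warns(UserWarning, match="no live cells"):
            ev = facs_snapshot(pop, 60.0, seed=1)
        assert len(ev) == 0

    def test_colony_assay_oracle(self, params):
        """Binomial mean/variance oracle at full and partial efficiency."""
        import pandas as pd
        rng = np.random.default_rng(0)
        n = 100_000
        df = pd.DataFrame({"alive": np.ones(n, bool),
                           "rif_resistant": rng.random(n) < 0.01})
        k = int(df.rif_resistant.sum())
        assert colony_assay(df, 1.0, seed=1) == k
        eff = 0.4
        draws = [colony_assay(df, eff, seed=s) for s in range(20)]
        mean, var = k * eff, k * eff * (1 - eff)
        assert abs(np.mean(draws) - mean) < 4 * np.sqrt(var / 20)

    def test_colony_assay_empty_and_none_resistant(self, params):
        import pandas as pd
        assert colony_assay(pd.DataFrame(columns=["alive", "rif_resistant"]),
                            1.0, seed=0) == 0
        df = pd.DataFrame({"alive": [True] * 5, "rif_resistant": [False] * 5})
        assert colony_assay(df, 1.0, seed=0) == 0
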