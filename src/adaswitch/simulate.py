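"""Forward simulation of single cells, populations, snapshots and assays.

This is the synthetic-data generator for the whole pipeline: it produces
mother-machine-like fluorescence time traces, MutL-focus series, survival
fates, single-molecule counting snapshots and FACS/mutation-assay event
tables from the stochastic adaptive-response model (see :mod:`.switching`
and :mod:`.damage`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage import propagate_damage
from .params import CHANNELS, FATES, GENES, MMSProfile, ParameterError, SimParams
from .switching import (gillespie_birth_death, path_at, sample_switch_time,
                        sample_switch_times_vectorised)


@dataclass
class CellRecord:
    """One simulated mother cell."""

    cell_id: int
    times: np.ndarray                   # frame times, min
    copy_numbers: dict                  # channel -> molecules (NaN after death)
    fluorescence: dict                  # channel -> a.u. (NaN after death)
    t_on: float | None                  # switch time, min (None = never)
    foci_frames: np.ndarray             # frame indices with >= 1 MutL focus
    foci_counts: np.ndarray             # focus count in those frames
    n_mutations: int
    rif_resistant: bool
    fate: str                           # alive | lysed | arrested | escaped
    death_time: float | None
    susceptibility: float               # per-cell damage factor u
    seed: int | None = None

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if (self.death_time is None) != (self.fate == "alive"):
            raise ValueError("death_time must be present iff fate != alive")

    @property
    def alive_mask(self) -> np.ndarray:
        """Frames at which the cell is still observed."""
        if self.death_time is None:
            return np.ones_like(self.times, dtype=bool)
        return self.times <= self.death_time


@dataclass
class PopulationDataset:
    """A set of cells simulated on a common frame grid."""

    cells: list
    mms: MMSProfile
    genotype: str
    params: SimParams
    seed: int
    horizon: float

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")

    @property
    def times(self) -> np.ndarray:
        return self.cells[0].times

    def __len__(self) -> int:
        return len(self.cells)


def _frame_grid(params: SimParams, horizon: float) -> np.ndarray:
    if horizon < params.frame_interval:
        raise ParameterError("horizon must cover at least one frame interval")
    n_frames = int(np.floor(horizon / params.frame_interval)) + 1
    return np.arange(n_frames) * params.frame_interval


def _ou_path(theta, sigma, t_grid, rng, mean=1.0):
    """Exact sampling of a stationary mean-reverting (OU) process."""
    d = np.empty(t_grid.size)
    d[0] = mean + sigma * rng.standard_normal()
    for k in range(1, t_grid.size):
        dt = t_grid[k] - t_grid[k - 1]
        a = np.exp(-theta * dt)
        d[k] = mean + (d[k - 1] - mean) * a + sigma * np.sqrt(1 - a * a) * rng.standard_normal()
    return d


def _rng_from(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_cell(params: SimParams, mms: MMSProfile, horizon: float,
                  seed, cell_id: int = 0) -> CellRecord:
    """Simulate one cell for ``horizon`` minutes under the dose profile."""
    if not np.isfinite(horizon) or horizon <= 0:
        raise ParameterError("horizon must be finite and > 0")
    rng = _rng_from(seed)
    frames = _frame_grid(params, horizon)

    u = float(rng.lognormal(-0.5 * params.susceptibility_sd**2,
                            params.susceptibility_sd))

    t_on, (ada_t, ada_n) = sample_switch_time(params, mms, horizon, rng)

    # Basal paths for the remaining genes, run to each gene's own takeover.
    act_time = {"ada": t_on, "alkb": t_on,
                "alka": None if t_on is None else t_on + params.tau_lag,
                "aidb": None}
    basal = {"ada": (ada_t, ada_n)}
    for g in ("alkb", "alka", "aidb"):
        end = horizon if act_time[g] is None else min(act_time[g], horizon)
        basal[g] = gillespie_birth_death(
            params.birth_rate(g), params.dilution_rate,
            rng.poisson(params.basal_means[g]), end, rng)

    # Shared expression-fluctuation process (1-min grid, pre-padded for the
    # alkA read-out lag) plus an independent one for the constitutive marker.
    fine = np.arange(-params.tau_lag - 1.0, horizon + 1.0, 1.0)
    d_shared = _ou_path(params.fluct_reversion, params.fluct_sd, fine, rng)
    d_const = _ou_path(params.fluct_reversion, params.fluct_sd, fine, rng)

    def d_at(t, lag=0.0, which=None):
        arr = d_shared if which is None else which
        return np.interp(np.asarray(t, dtype=float) - lag, fine, arr)

    # Damage, death and mismatches.
    hist = propagate_damage(params, mms, np.inf if t_on is None else t_on,
                            horizon, store_paths=True)
    cum_haz = hist.cumulative_hazard(u)
    E = rng.exponential()
    if cum_haz[-1] >= E:
        death_time = float(np.interp(E, cum_haz, hist.t))
        fates, probs = zip(*params.fate_probs.items())
        fate = str(rng.choice(fates, p=probs))
    else:
        death_time, fate = None, "alive"
    obs_end = horizon if death_time is None else death_time

    cum_mis = hist.cumulative_mismatch(params, u ** params.mismatch_u_exponent)
    mis_at = lambda t: np.interp(t, hist.t, cum_mis)
    edges = np.append(frames, frames[-1] + params.frame_interval)
    lam = np.diff(mis_at(np.clip(edges, 0.0, obs_end)))
    counts = rng.poisson(lam)
    counts[frames > obs_end] = 0
    foci_frames = np.flatnonzero(counts)
    n_mut = int(rng.poisson(params.p_fix * mis_at(obs_end)))
    rif = bool(rng.random() < 1.0 - (1.0 - params.p_rif) ** n_mut) if n_mut else False

    # Copy numbers and fluorescence on the frame grid.
    copy, fluor = {}, {}
    t_eval = frames - params.maturation_delay
    for g in GENES:
        bt, bn = basal[g]
        n_path = path_at(bt, bn, np.clip(t_eval, 0.0, None)).astype(float)
        t_act = act_time[g]
        if t_act is not None and params.induced_levels[g] > 0:
            post = t_eval > t_act
            if post.any():
                dt_act = t_eval[post] - t_act
                relax = -np.expm1(-dt_act / params.tau_rise)
                lag = params.tau_lag if g == "alka" else 0.0
                n_at_act = float(path_at(bt, bn, min(t_act, bt[-1] if bt.size else 0.0)))
                n_path[post] = (n_at_act * np.exp(-dt_act / params.tau_rise)
                                + params.induced_levels[g] * d_at(t_eval[post], lag) * relax)
        copy[g] = n_path
    copy["constitutive"] = params.constitutive_level * d_at(t_eval, which=d_const)
    dead_frames = frames > obs_end
    for ch in CHANNELS:
        copy[ch][dead_frames] = np.nan
        f = (params.fluor_scale * copy[ch] + params.fluor_background
             + params.fluor_noise_sd * rng.standard_normal(frames.size))
        f[dead_frames] = np.nan
        fluor[ch] = f

    return CellRecord(
        cell_id=cell_id, times=frames, copy_numbers=copy, fluorescence=fluor,
        t_on=t_on, foci_frames=foci_frames, foci_counts=counts[foci_frames],
        n_mutations=n_mut, rif_resistant=rif, fate=fate, death_time=death_time,
        susceptibility=u,
        seed=seed if isinstance(seed, (int, np.integer)) else None)


def simulate_population(n: int, params: SimParams, mms: MMSProfile,
                        horizon: float, seed: int) -> PopulationDataset:
    """Simulate n independent cells with per-cell streams spawned from seed."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    cells = [
        simulate_cell(params, mms, horizon, np.random.default_rng(child), cell_id=i)
        for i, child in enumerate(ss.spawn(n))
    ]
    return PopulationDataset(cells=cells, mms=mms, genotype=params.genotype,
                             params=params, seed=seed, horizon=horizon)


# ---------------------------------------------------------------------------
# Single-molecule counting snapshots
# ---------------------------------------------------------------------------

def snapshot_molecule_counts(gene: str, n: int, params: SimParams, seed):
    """Draw a basal-state single-molecule counting snapshot for one gene.

    Counts follow the OFF-state stationary law, Poisson(basal mean), except
    for a small fraction of cells with a spontaneously induced response
    (``spontaneous_active``) whose counts are drawn at ``spontaneous_level``.
    Counts above ``count_limit`` cannot be resolved by the spot counter and
    are recorded as censored (">limit").
    """
    from .counts import CountSnapshot

    if gene not in GENES:
        raise ParameterError(f"unknown gene {gene!r}; expected one of {GENES}")
    rng = _rng_from(seed)
    counts = rng.poisson(params.basal_means[gene], size=n)
    p_spont = params.spontaneous_active[gene]
    if p_spont > 0:
        mask = rng.random(n) < p_spont
        counts[mask] = rng.poisson(params.spontaneous_level, size=int(mask.sum()))
    censored = counts > params.count_limit
    counts = np.where(censored, params.count_limit + 1, counts)
    return CountSnapshot(counts=counts, censored=censored,
                         limit=params.count_limit, gene=gene)


# ---------------------------------------------------------------------------
# FACS snapshots, event-level experiments and colony assays
# ---------------------------------------------------------------------------

def facs_snapshot(pop: PopulationDataset, t_sample: float, seed) -> pd.DataFrame:
    """One FACS event per live cell at t_sample (dead cells are excluded).

    Reporter (gfp_au) intensity is the ada-channel fluorescence and the
    constitutive marker (mkate_au) the constitutive channel, both with
    lognormal measurement spread.
    """
    if not 0 <= t_sample <= pop.horizon:
        raise ParameterError("t_sample outside the simulated horizon")
    rng = _rng_from(seed)
    params = pop.params
    frame = int(round(t_sample / params.frame_interval))
    rows = []
    for cell in pop.cells:
        if cell.death_time is not None and cell.death_time <= t_sample:
            continue
        gfp = cell.fluorescence["ada"][frame]
        mkate = cell.fluorescence["constitutive"][frame]
        rows.append((cell.cell_id, gfp, mkate, cell.rif_resistant, True))
    if not rows:
        warnings.warn("no live cells at t_sample; empty FACS event table")
        return pd.DataFrame(columns=["cell_id", "gfp_au", "mkate_au",
                                     "rif_resistant", "alive"])
    df = pd.DataFrame(rows, columns=["cell_id", "gfp_au", "mkate_au",
                                     "rif_resistant", "alive"])
    spread = np.exp(params.facs_log_sd * rng.standard_normal((len(df), 2)))
    df["gfp_au"] = np.maximum(df["gfp_au"].to_numpy(), 1.0) * spread[:, 0]
    df["mkate_au"] = np.maximum(df["mkate_au"].to_numpy(), 1.0) * spread[:, 1]
    return df


def simulate_facs_experiment(params: SimParams, dose: float, n_cells: int,
                             t_sample: float, seed, chunk: int = 100_000) -> pd.DataFrame:
    """Event-level simulation of a sort-and-plate experiment.

    A batch culture is exposed to a single MMS step from t=0 and measured at
    ``t_sample``.  The per-cell state (switch time, damage, survival,
    mutations, reporter fluorescence) is drawn with vectorised exact
    sampling, which scales to the ~10^6-cell sorts of the mutation assays.
    Lysed cells are lost from the event stream; growth-arrested (dead but
    intact) cells are still measured and sorted but cannot form colonies.

    Returns a DataFrame of FACS events with hidden ground-truth columns
    (``alive``, ``rif_resistant``) used by :func:`colony_assay`.
    """
    rng = _rng_from(seed)
    mms = MMSProfile.step(dose, onset=0.0)
    frames = []
    offset = 0
    remaining = int(n_cells)
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        t_on, n_basal = sample_switch_times_vectorised(params, dose, t_sample, m, rng)
        u = rng.lognormal(-0.5 * params.susceptibility_sd**2,
                          params.susceptibility_sd, size=m)
        hist = propagate_damage(params, mms, t_on, t_sample, store_paths=False)
        cum_haz = u * hist.hazard_unit[:, -1]
        alive = rng.random(m) < np.exp(-cum_haz)
        # Dead cells: lysed ones leave the stream; arrested (intact) cells
        # remain measurable events and recover plating ability with
        # probability arrest_recovery once the stress is washed out.
        p_lysed = params.fate_probs["lysed"] * params.lysed_intact_loss
        intact = alive | (rng.random(m) >= p_lysed)
        viable = alive | (intact & (rng.random(m) < params.arrest_recovery))

        u_mis = u ** params.mismatch_u_exponent
        lam_mis = params.r_0 * t_sample + u_mis * hist.mismatch_unit[:, -1]
        n_mut = rng.poisson(params.p_fix * lam_mis)
        rif = rng.random(m) < 1.0 - (1.0 - params.p_rif) ** n_mut

        switched = np.isfinite(t_on)
        dt_act = np.where(switched, t_sample - t_on, 0.0)
        relax = -np.expm1(-dt_act / params.tau_rise)
        d = np.maximum(1.0 + params.fluct_sd * rng.standard_normal(m), 0.05)
        n_ada = np.where(
            switched,
            params.basal_means["ada"] * np.exp(-dt_act / params.tau_rise)
            + params.induced_levels["ada"] * d * relax,
            n_basal.astype(float))
        gfp = (params.fluor_scale * n_ada + params.fluor_background
               + params.fluor_noise_sd * rng.standard_normal(m))
        d_c = np.maximum(1.0 + params.fluct_sd * rng.standard_normal(m), 0.05)
        mkate = (params.fluor_scale * params.constitutive_level * d_c
                 + params.fluor_background
                 + params.fluor_noise_sd * rng.standard_normal(m))
        df = pd.DataFrame({
            "cell_id": np.arange(offset, offset + m),
            "gfp_au": np.maximum(gfp, 1.0) * np.exp(
                params.facs_log_sd * rng.standard_normal(m)),
            "mkate_au": np.maximum(mkate, 1.0) * np.exp(
                params.facs_log_sd * rng.standard_normal(m)),
            "rif_resistant": rif,
            "alive": viable,   # viable for plating (survivors + recovered arrests)
        })[intact]
        offset += m
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def colony_assay(sorted_cells, plating_efficiency: float, seed) -> int:
    """Rifampicin-resistant colony count from a sorted subset of cells.

    Accepts either CellRecord objects or a DataFrame with ``alive`` and
    ``rif_resistant`` columns.  Each live resistant cell plates with the
    given efficiency.
    """
    if not 0 < plating_efficiency <= 1:
        raise ParameterError("plating_efficiency must be in (0, 1]")
    rng = _rng_from(seed)
    if isinstance(sorted_cells, pd.DataFrame):
        if len(sorted_cells) == 0:
            return 0
        n_res = int((sorted_cells["alive"] & sorted_cells["rif_resistant"]).sum())
    else:
        cells = list(sorted_cells)
        if not cells:
            return 0
        n_res = sum(1 for c in cells if c.fate == "alive" and c.rif_resistant)
    return int(rng.binomial(n_res, plating_efficiency))
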