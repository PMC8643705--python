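"""FACS gating, sorting, mutant frequency and plasticity-share accounting.

The Delayed gate is placed on the reporter-intensity mode of an untreated
culture (cells that never induced the response sit at basal intensity); the
Activated gate has the same width and is centred on the global mode of the
treated culture.  Events between or outside the gates are excluded.  Mutant
frequency is rifampicin-resistant colonies per sorted cell, and a
subpopulation's share of the population's viable mutants weights its colony
count by the percentage of cells it represents.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


class FacsError(ValueError):
    pass


@dataclass(frozen=True)
class Gate:
    label: str                       # Delayed | Activated
    lo: float                        # log10 intensity, inclusive
    hi: float                        # log10 intensity, exclusive

    def __post_init__(self):
        if self.label not in ("Delayed", "Activated"):
            raise FacsError(f"bad gate label {self.label!r}")
        if not self.lo < self.hi:
            raise FacsError("gate lower bound must be below upper bound")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, log10_intensity) -> np.ndarray:
        x = np.asarray(log10_intensity, dtype=float)
        return (x >= self.lo) & (x < self.hi)


@dataclass
class SortResult:
    members: dict                    # label -> integer row indices
    fractions: dict                  # label -> fraction of all events
    excluded_fraction: float
    n_events: int


@dataclass
class MutationAssayResult:
    subpopulation: str
    n_sorted: int
    colonies: int
    frequency: float
    frequency_exact: Fraction
    sorted_percentage: float         # % of all events in this gate


@dataclass
class PlasticityShare:
    shares: dict                     # subpopulation -> % of total viable mutants

    def __post_init__(self):
        total = sum(self.shares.values())
        if abs(total - 100.0) > 1e-6:
            raise FacsError("shares must sum to 100%")


def _log_mode(log_intensity: np.ndarray, above: float | None = None) -> float:
    """Kernel-density mode (Silverman bandwidth) of log10 intensities.

    With ``above`` set, the mode is sought only among values beyond that
    bound (used to find the activated peak past the basal one).
    """
    if above is not None:
        log_intensity = log_intensity[log_intensity > above]
        if log_intensity.size < 10:
            raise FacsError(
                "gates overlap: peaks are insufficiently separated; "
                "reduce width_sigmas or check that the treated culture activated")
    kde = gaussian_kde(log_intensity, bw_method="silverman")
    grid = np.linspace(log_intensity.min(), log_intensity.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def define_gates(untreated: pd.DataFrame, treated: pd.DataFrame,
                 width_sigmas: float = 3.0, column: str = "gfp_au") -> tuple:
    """Construct the (Delayed, Activated) gates from event tables.

    The Delayed gate is centred on the untreated log10-intensity mode with
    half-width ``width_sigmas`` times the untreated SD; the Activated gate
    has identical width, centred on the treated-distribution mode.
    """
    for name, df in (("untreated", untreated), ("treated", treated)):
        if len(df) == 0:
            raise FacsError(f"{name} event set is empty")
        if np.any(df[column].to_numpy() <= 0):
            raise FacsError(f"{name} intensities must be > 0 for log gating")
    lu = np.log10(untreated[column].to_numpy())
    lt = np.log10(treated[column].to_numpy())
    half = width_sigmas * float(lu.std(ddof=1))
    if half <= 0:
        raise FacsError("untreated intensities have zero spread")
    centre_d = _log_mode(lu)
    delayed = Gate("Delayed", centre_d - half, centre_d + half)
    # The activated peak is the treated mode beyond the basal (Delayed) gate.
    centre_a = _log_mode(lt, above=delayed.hi)
    activated = Gate("Activated", centre_a - half, centre_a + half)
    if delayed.hi > activated.lo and activated.hi > delayed.lo:
        raise FacsError(
            "gates overlap: peaks are insufficiently separated; "
            "reduce width_sigmas or check that the treated culture activated")
    return delayed, activated


def apply_gates(events: pd.DataFrame, gates, column: str = "gfp_au") -> SortResult:
    """Assign events to gates; report per-gate fractions and the excluded rest."""
    los = [g.lo for g in gates]
    his = [g.hi for g in gates]
    for i, g in enumerate(gates):
        for j, h in enumerate(gates):
            if i < j and g.hi > h.lo and h.hi > g.lo:
                raise FacsError("gates must be disjoint")
    x = np.log10(events[column].to_numpy())
    members, fractions = {}, {}
    n = len(events)
    assigned = np.zeros(n, dtype=bool)
    for g in gates:
        mask = g.contains(x)
        members[g.label] = np.flatnonzero(mask)
        fractions[g.label] = float(mask.sum() / n) if n else 0.0
        assigned |= mask
    return SortResult(members=members, fractions=fractions,
                      excluded_fraction=float((~assigned).sum() / n) if n else 0.0,
                      n_events=n)


def mutant_frequency(colonies: int, n_sorted: int) -> tuple:
    """(float, Fraction) mutant frequency = colonies / cells sorted."""
    if n_sorted < 1:
        raise FacsError("n_sorted must be >= 1")
    if colonies < 0:
        raise FacsError("colonies must be >= 0")
    frac = Fraction(int(colonies), int(n_sorted))
    return float(frac), frac


def plasticity_share(assays, survival_fractions: dict | None = None) -> PlasticityShare:
    """Share of total viable mutants per subpopulation.

    weight_i = colonies_i * sorted_percentage_i; shares normalised to 100%.
    Requires >= 2 subpopulations sorted at equal depth.  The literal
    counts-times-percentage accounting is the default; passing
    ``survival_fractions`` (subpopulation -> fraction) additionally weights
    each subpopulation by its survival, a correction the standard
    accounting does not apply.
    """
    assays = list(assays)
    if len(assays) < 2:
        raise FacsError("need >= 2 subpopulations")
    depths = {a.n_sorted for a in assays}
    if len(depths) != 1:
        raise FacsError("subpopulations must be sorted at equal depth")
    sf = survival_fractions or {}
    weights = {a.subpopulation:
               a.colonies * a.sorted_percentage * sf.get(a.subpopulation, 1.0)
               for a in assays}
    total = sum(weights.values())
    if total <= 0:
        raise FacsError("no viable mutants in any subpopulation; share undefined")
    return PlasticityShare({k: 100.0 * w / total for k, w in weights.items()})


def run_sort_assay(events: pd.DataFrame, gates, n_sort: int,
                   plating_efficiency: float, seed,
                   column: str = "gfp_au") -> list:
    """Sort equal numbers of events per gate, plate, and count colonies.

    Returns a list of MutationAssayResult (one per gate).  ``n_sort`` is
    capped at the smallest gate population so depths stay equal, as in the
    10^6-cell sorts of the original assay design.
    """
    from .simulate import colony_assay

    rng = np.random.default_rng(seed)
    sort_res = apply_gates(events, gates, column=column)
    n_avail = min(len(sort_res.members[g.label]) for g in gates)
    if n_avail < 1:
        raise FacsError("a gate has no events; cannot sort")
    n_sort = int(min(n_sort, n_avail))
    out = []
    for g in gates:
        idx = rng.choice(sort_res.members[g.label], size=n_sort, replace=False)
        sorted_cells = events.iloc[idx]
        colonies = colony_assay(sorted_cells, plating_efficiency,
                                rng.integers(0, 2**31 - 1))
        freq, frac = mutant_frequency(colonies, n_sort)
        out.append(MutationAssayResult(
            subpopulation=g.label, n_sorted=n_sort, colonies=colonies,
            frequency=freq, frequency_exact=frac,
            sorted_percentage=100.0 * sort_res.fractions[g.label]))
    return out
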