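"""Mismatch-event and survival analysis of focus/fate records.

MutL foci persisting over several frames mark one underlying DNA mismatch:
only the first frame of each consecutive run is counted as an event.  The
population mismatch rate divides the events in each frame by the frame
interval and the number of cells still observed, and is optionally smoothed
with a centred moving-average filter.  Survival is summarised with the
product-limit (Kaplan-Meier) estimator; lysis and growth arrest are deaths,
while cells escaping the channels by filamentation are right-censored by
default (their death is unconfirmed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .params import FATES


class MismatchError(ValueError):
    pass


@dataclass
class FociSeries:
    """Frame indices (per cell) at which >= 1 focus is present."""

    frames: dict                 # cell_id -> sorted int array

    def __post_init__(self):
        clean = {}
        for cid, fr in self.frames.items():
            fr = np.asarray(fr, dtype=int)
            if fr.size and (np.any(np.diff(fr) < 0) or fr.min() < 0):
                raise MismatchError(f"cell {cid}: frames must be sorted and >= 0")
            clean[cid] = fr
        self.frames = clean


@dataclass
class MismatchEvents:
    events: dict                 # cell_id -> event frame indices


@dataclass
class RateCurve:
    times: np.ndarray            # min
    rate: np.ndarray             # foci cell^-1 min^-1
    at_risk: np.ndarray          # observed cells per frame
    smoothing_window: float | None = None


@dataclass
class SurvivalCurve:
    times: np.ndarray            # min (event grid, starts at 0)
    survival: np.ndarray         # fraction surviving
    counts: dict                 # fate -> number of cells
    escape_policy: str = "censor"


def dedup_foci(series: FociSeries) -> MismatchEvents:
    """Collapse each run of consecutive focus-positive frames to its first frame."""
    events = {}
    for cid, fr in series.frames.items():
        if fr.size == 0:
            events[cid] = fr.copy()
            continue
        first = np.ones(fr.size, dtype=bool)
        first[1:] = np.diff(fr) > 1
        events[cid] = fr[first]
    return MismatchEvents(events=events)


def mismatch_rate_curve(events: MismatchEvents, at_risk: np.ndarray,
                        interval: float) -> RateCurve:
    """rate(frame) = events(frame) / (interval * cells observed at frame)."""
    if interval <= 0:
        raise MismatchError("interval must be > 0")
    at_risk = np.asarray(at_risk, dtype=float)
    n_frames = at_risk.size
    counts = np.zeros(n_frames)
    for cid, fr in events.events.items():
        if fr.size and fr.max() >= n_frames:
            raise MismatchError(f"cell {cid}: event frame beyond at_risk grid")
        np.add.at(counts, fr, 1.0)
    if np.any((counts > 0) & (at_risk <= 0)):
        raise MismatchError("event recorded at a frame with no observed cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(at_risk > 0, counts / (interval * at_risk), 0.0)
    times = np.arange(n_frames) * interval
    return RateCurve(times=times, rate=rate, at_risk=at_risk)


def smooth_curve(curve: RateCurve, window: float) -> RateCurve:
    """Centred moving average over ``window`` minutes (shrinking at edges)."""
    if curve.times.size < 2:
        raise MismatchError("curve too short to smooth")
    dt = float(curve.times[1] - curve.times[0])
    half_frames = int(round(window / 2.0 / dt))
    if window < dt or half_frames < 1:
        raise MismatchError("window must span at least one frame interval")
    n = curve.rate.size
    out = np.empty(n)
    for i in range(n):
        h = min(half_frames, i, n - 1 - i)   # symmetric shrink at edges
        out[i] = curve.rate[i - h: i + h + 1].mean()
    return RateCurve(times=curve.times.copy(), rate=out,
                     at_risk=curve.at_risk.copy(), smoothing_window=float(window))


def population_foci(pop, at_risk_mode: str = "observed") -> tuple:
    """(FociSeries, at_risk) for a simulated PopulationDataset.

    ``at_risk_mode='observed'`` (default) counts, per frame, the cells still
    alive and observed; ``'initial'`` normalises every frame by the starting
    cell number instead.
    """
    if at_risk_mode not in ("observed", "initial"):
        raise MismatchError(f"unknown at_risk_mode {at_risk_mode!r}")
    frames = {c.cell_id: c.foci_frames for c in pop.cells}
    times = pop.times
    if at_risk_mode == "initial":
        return FociSeries(frames=frames), np.full(times.size, float(len(pop)))
    at_risk = np.zeros(times.size)
    for c in pop.cells:
        at_risk += c.alive_mask
    return FociSeries(frames=frames), at_risk


@dataclass
class FateRecord:
    cell_id: int
    fate: str
    death_time: float | None


def survival_curve(fates, horizon: float, escape_policy: str = "censor") -> SurvivalCurve:
    """Product-limit survival estimate from per-cell fate records.

    ``fates`` may be FateRecord objects or CellRecord-like objects with
    ``fate`` and ``death_time`` attributes.  Lysed and arrested cells are
    deaths at their recorded times; escaped cells are right-censored at
    their escape time (escape_policy='censor', default) or treated as
    deaths (escape_policy='death').  Cells alive at the horizon are
    censored there.
    """
    if escape_policy not in ("censor", "death"):
        raise MismatchError(f"unknown escape_policy {escape_policy!r}")
    durations, observed = [], []
    counts = {f: 0 for f in FATES}
    for rec in fates:
        if rec.fate not in FATES:
            raise MismatchError(f"unknown fate {rec.fate!r}")
        counts[rec.fate] += 1
        if rec.fate == "alive":
            durations.append(horizon)
            observed.append(False)
        else:
            if rec.death_time is None or rec.death_time > horizon:
                raise MismatchError("death_time must be <= horizon")
            durations.append(rec.death_time)
            if rec.fate == "escaped":
                observed.append(escape_policy == "death")
            else:
                observed.append(True)
    if not durations:
        raise MismatchError("no cells")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    grid = np.concatenate(([0.0], np.sort(np.unique(durations)), [horizon]))
    grid = np.unique(grid)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return SurvivalCurve(times=grid, survival=surv, counts=counts,
                         escape_policy=escape_policy)


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Step-function evaluation of the survival curve at time t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[max(idx, 0)])
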