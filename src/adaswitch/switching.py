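"""Sampling of the stochastic Ada master switch.

Basal expression of each adaptive-response gene is a birth-death process
(constant synthesis k_b, first-order dilution gamma) whose stationary law is
Poisson(k_b/gamma).  Under MMS the methylated-phosphotriester load on the
chromosome grows with the integrated dose, so the per-Ada-molecule
methylation hazard ramps with exposure: the cumulative per-molecule hazard is

    Lambda(t) = (k_m * integral_0^t m(tau)**eta dtau) ** s

with shape s (``trigger_shape``) and dose exponent eta
(``trigger_dose_exponent``).  A cell with n(t) Ada molecules switches with
instantaneous hazard n(t) * dLambda/dt; cells with zero Ada cannot switch
until a molecule is born.  Both samplers below are exact: between Gillespie
jumps of n the cumulative hazard is integrated analytically and inverted
against a unit-exponential draw.
"""

from __future__ import annotations

import numpy as np

from .params import MMSProfile, SimParams


def gillespie_birth_death(k_b, gamma, n0, t_max, rng):
    """Exact path of a birth-death process on [0, t_max].

    Returns (jump_times, values): values[i] holds on [jump_times[i],
    jump_times[i+1]); jump_times[0] == 0.
    """
    times = [0.0]
    values = [int(n0)]
    t, n = 0.0, int(n0)
    while True:
        rate = k_b + gamma * n
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= t_max:
            break
        if rng.random() < k_b / rate:
            n += 1
        else:
            n -= 1
        times.append(t)
        values.append(n)
    return np.asarray(times), np.asarray(values)


def path_at(times, values, query):
    """Evaluate a piecewise-constant path at query times."""
    idx = np.searchsorted(times, query, side="right") - 1
    return values[np.clip(idx, 0, len(values) - 1)]


def _trigger_integral(params: SimParams, mms: MMSProfile, t):
    """k_m * integral m**eta dtau, the 'trigger clock' M(t)."""
    return params.k_m * mms.integral(t, params.trigger_dose_exponent)


def _invert_trigger(params: SimParams, mms: MMSProfile, target):
    """Smallest t with M(t) == target (target > 0); inf if never reached."""
    target = np.asarray(target, dtype=float)
    # Piecewise-linear M(t): walk the dose segments.
    edges = list(mms.breakpoints) + [np.inf]
    t_out = np.full(target.shape, np.inf)
    acc = 0.0
    for i, d in enumerate(mms.doses):
        lo, hi = edges[i], edges[i + 1]
        slope = params.k_m * d**params.trigger_dose_exponent
        seg_len = hi - lo
        seg_gain = slope * seg_len if np.isfinite(seg_len) else np.inf
        hit = (target > acc) & (target <= acc + seg_gain) & np.isinf(t_out)
        if slope > 0:
            t_out = np.where(hit, lo + (target - acc) / slope, t_out)
        acc = acc + (seg_gain if np.isfinite(seg_gain) else 0.0)
        if not np.isfinite(seg_gain):
            break
    t_out = np.where(target <= 0, 0.0, t_out)
    return t_out


def sample_switch_time(params: SimParams, mms: MMSProfile, horizon: float, rng):
    """Exact switch time for one cell; returns (t_on or None, ada path).

    The ada birth-death path is simulated jointly with the switch hazard so
    that the pre-switch copy-number trace is available for the observation
    model.  For the ``dada_alkB`` genotype no switch ever occurs; for
    ``ada_C321A`` the regulon is pre-activated (elevated basal Ada) and the
    switch fires at rate ``c321a_switch_rate`` from MMS onset.
    """
    k_b = params.birth_rate("ada")
    gamma = params.dilution_rate
    n0 = rng.poisson(params.basal_means["ada"])

    if params.genotype == "dada_alkB":
        times, values = gillespie_birth_death(k_b, gamma, n0, horizon, rng)
        return None, (times, values)
    if params.genotype == "ada_C321A":
        onset = mms.onset
        if not np.any(np.asarray(mms.doses) > 0):
            t_on = None
        else:
            t_on = onset + rng.exponential(1.0 / params.c321a_switch_rate)
            t_on = t_on if t_on < horizon else None
        times, values = gillespie_birth_death(
            k_b, gamma, n0, t_on if t_on is not None else horizon, rng)
        return t_on, (times, values)

    s = params.trigger_shape
    target_E = rng.exponential()  # unit-exponential threshold on total hazard
    acc_hazard = 0.0
    t, n = 0.0, int(n0)
    times = [0.0]
    values = [int(n0)]
    while t < horizon:
        rate = k_b + gamma * n
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_next = min(t + dt, horizon)
        if n > 0:
            lam_lo = _trigger_integral(params, mms, t) ** s
            lam_hi = _trigger_integral(params, mms, t_next) ** s
            gain = n * (lam_hi - lam_lo)
            if acc_hazard + gain >= target_E:
                lam_target = lam_lo + (target_E - acc_hazard) / n
                t_on = float(_invert_trigger(params, mms, lam_target ** (1.0 / s)))
                return t_on, (np.asarray(times), np.asarray(values))
            acc_hazard += gain
        if t + dt >= horizon:
            break
        t = t + dt
        if rng.random() < k_b / rate:
            n += 1
        else:
            n -= 1
        times.append(t)
        values.append(n)
    return None, (np.asarray(times), np.asarray(values))


def sample_switch_times_vectorised(params: SimParams, dose: float, horizon: float,
                                   n_cells: int, rng):
    """Vectorised exact switch sampler for a single-step dose from t=0.

    Returns (t_on array with inf where no switch, n_final array of basal Ada
    copies at `horizon` for cells that never switched).  Used by the
    event-level FACS experiment simulator where millions of cells are needed.
    """
    k_b = params.birth_rate("ada")
    gamma = params.dilution_rate
    s = params.trigger_shape
    slope = params.k_m * dose**params.trigger_dose_exponent

    n = rng.poisson(params.basal_means["ada"], size=n_cells).astype(np.int64)
    t = np.zeros(n_cells)
    t_on = np.full(n_cells, np.inf)
    if params.genotype == "dada_alkB" or dose <= 0:
        pass
    elif params.genotype == "ada_C321A":
        draw = rng.exponential(1.0 / params.c321a_switch_rate, size=n_cells)
        t_on = np.where(draw < horizon, draw, np.inf)
    else:
        E = rng.exponential(size=n_cells)
        active = np.ones(n_cells, dtype=bool)
        # Guard: expected jump count is ~horizon * (k_b + gamma * E[n]).
        for _ in range(10000):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            ni, ti = n[idx], t[idx]
            rate = k_b + gamma * ni
            dt = rng.exponential(1.0 / rate)
            t_next = np.minimum(ti + dt, horizon)
            lam_lo = (slope * ti) ** s
            lam_hi = (slope * t_next) ** s
            gain = np.where(ni > 0, ni * (lam_hi - lam_lo), 0.0)
            fired = (E[idx] <= gain) & (ni > 0)
            if fired.any():
                j = idx[fired]
                lam_t = lam_lo[fired] + E[j] / ni[fired]
                t_on[j] = lam_t ** (1.0 / s) / slope
                active[j] = False
            E[idx] = np.where(fired, E[idx], E[idx] - gain)
            done = (ti + dt >= horizon) & ~fired
            active[idx[done]] = False
            move = ~fired & ~done
            jm = idx[move]
            t[jm] = ti[move] + dt[move]
            birth = rng.random(jm.size) < k_b / rate[move]
            n[jm] = ni[move] + np.where(birth, 1, -1)
        else:  # pragma: no cover - defensive
            raise RuntimeError("switch sampler failed to converge")
    # For never-switched cells, n is a mid-path value; evolving it to the
    # horizon does not change its (stationary) law, so use it directly.
    return t_on, n
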