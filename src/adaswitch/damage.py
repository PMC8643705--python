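"""Lesion, replication-fork and mismatch dynamics downstream of the switch.

Three lesion pools are tracked per cell, all produced in proportion to the
MMS concentration and removed by first-order repair once the corresponding
repair protein is induced:

* ``alka`` pool - 3meA-type lesions, repaired by AlkA from t_on + tau_lag;
* ``alkb`` pool - 3meC/1meA-type lesions, repaired by AlkB from t_on
  (ada-alkB operon);
* ``mug``  pool - O6meG-type mutagenic lesions, repaired by Ada's own
  methyltransferase domain from t_on (absent in ada_C321A).

All pools are produced linearly in dose.  The conversion of O6meG lesions
into replication mismatches is itself dose-dependent (mismatch surveillance
saturates at high MMS), so the mismatch intensity weights the mug pool by
``m ** (mug_dose_exponent - 1)``:

    lambda_mis = r_0 + u * (r_mug * m**(p-1) * L_mug + r_tox * (L_alka + L_alkb))

Toxicity is indirect: unrepaired lesions stall replication forks (formed at
``fork_rate`` per alka/alkb lesion and at the much smaller
``mug_fork_rate`` per mug lesion, capturing futile mismatch-repair cycling
at O6meG).  A stalled fork can only be resolved once the causative lesion
class is being repaired: each lesion pool drives its own fork compartment,
resolved at ``fork_resolution_on`` after that pool's repair onset and at
``fork_resolution_off`` before.  The death hazard is
``hazard_scale * u * D_total`` where u is the cell's lognormal
damage-susceptibility factor.

Everything is integrated on a fixed grid (``damage_grid_dt``) with exact
exponential updates for the decaying pools; the functions are vectorised
over cells (t_on may be an array, with inf meaning "never activates").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MMSProfile, SimParams

_NO_REPAIR = {
    "alka": ("dalkA", "dada_alkB"),
    "alkb": ("dalkB", "dada_alkB"),
    "mug": ("ada_C321A", "dada_alkB"),
}


def repair_start_times(params: SimParams, t_on):
    """Per-pool repair onset times given activation times (inf = never)."""
    t_on = np.asarray(t_on, dtype=float)
    out = {}
    for pool, lag in (("alka", params.tau_lag), ("alkb", 0.0), ("mug", 0.0)):
        if params.genotype in _NO_REPAIR[pool]:
            out[pool] = np.full_like(t_on, np.inf)
        else:
            out[pool] = t_on + lag
    return out


@dataclass
class DamageHistory:
    """Unit-susceptibility damage trajectories on the integration grid.

    ``hazard_unit`` is the cumulative death hazard for u = 1 (multiply by u).
    ``mismatch_unit`` is the damage-driven part of the cumulative mismatch
    intensity; the full cumulative intensity is ``r_0 * t + u *
    mismatch_unit``.  Arrays have shape (n_cells, n_grid) (or (n_grid,) for
    scalar t_on).
    """

    t: np.ndarray
    lesions: dict
    forks: np.ndarray
    hazard_unit: np.ndarray
    mismatch_unit: np.ndarray
    scalar: bool

    def cumulative_mismatch(self, params: SimParams, u):
        u = np.asarray(u, dtype=float)
        if not self.scalar:
            u = u[:, None]
        return params.r_0 * self.t + u * self.mismatch_unit

    def cumulative_hazard(self, u):
        u = np.asarray(u, dtype=float)
        if not self.scalar:
            u = u[:, None]
        return u * self.hazard_unit


def _decay_step(L, prod, beta, dt):
    """Exact one-step update of dL/dt = prod - beta*L with constants."""
    if np.isscalar(beta):
        beta = np.full_like(L, float(beta))
    decayed = L * np.exp(-beta * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(beta > 0, prod * -np.expm1(-beta * dt) / np.where(beta > 0, beta, 1.0),
                        prod * dt)
    return decayed + gain


def propagate_damage(params: SimParams, mms: MMSProfile, t_on, horizon: float,
                     store_paths: bool = True) -> DamageHistory:
    """Integrate lesion pools, fork damage, hazard and mismatch intensity.

    With ``store_paths=False`` only the final grid point is kept (used by the
    large event-level simulations); the returned arrays then have a single
    time column.
    """
    scalar = np.isscalar(t_on) or (t_on is None) or getattr(t_on, "ndim", 1) == 0
    t_arr = np.atleast_1d(np.asarray(
        np.inf if t_on is None else t_on, dtype=float))
    n = t_arr.size
    dt = params.damage_grid_dt
    grid = np.arange(0.0, horizon + 0.5 * dt, dt)
    grid[-1] = min(grid[-1], horizon)

    rep = repair_start_times(params, t_arr)

    m_grid = mms.dose_at(grid)
    prod = {
        "alka": params.alpha_alka * m_grid,
        "alkb": params.alpha_alkb * m_grid,
        "mug": params.alpha_mug * m_grid,
    }
    conv = m_grid ** (params.mug_dose_exponent - 1.0)  # mismatch conversion
    beta_mug_on = params.beta_on * params.induced_repair_scale

    L = {p: np.zeros(n) for p in ("alka", "alkb", "mug")}
    Dp = {p: np.zeros(n) for p in L}     # per-pool stalled-fork compartments
    D = np.zeros(n)
    H = np.zeros(n)
    Q = np.zeros(n)
    kappa = {"alka": params.fork_rate, "alkb": params.fork_rate,
             "mug": params.mug_fork_rate}

    keep = store_paths
    paths = {p: [L[p].copy()] for p in L} if keep else None
    d_path = [D.copy()] if keep else None
    h_path = [H.copy()] if keep else None
    q_path = [Q.copy()] if keep else None

    for k in range(1, grid.size):
        t_mid = grid[k - 1]
        step = grid[k] - grid[k - 1]
        tox_prev = L["alka"] + L["alkb"]
        mis_prev = params.r_mug * conv[k - 1] * L["mug"] + params.r_tox * tox_prev
        D_prev = D
        D = np.zeros(n)
        for pool in L:
            L_old = L[pool]
            beta_on = beta_mug_on if pool == "mug" else params.beta_on
            repairing = t_mid >= rep[pool]
            beta = np.where(repairing, beta_on, params.beta_off)
            L[pool] = _decay_step(L_old, prod[pool][k - 1], beta, step)
            rho = np.where(repairing, params.fork_resolution_on,
                           params.fork_resolution_off)
            Dp[pool] = _decay_step(Dp[pool], kappa[pool] * 0.5 * (L_old + L[pool]),
                                   rho, step)
            D = D + Dp[pool]
        # Trapezoidal accumulation of hazard and mismatch intensity.
        H = H + params.hazard_scale * 0.5 * (D_prev + D) * step
        mis_new = (params.r_mug * conv[k - 1] * L["mug"]
                   + params.r_tox * (L["alka"] + L["alkb"]))
        Q = Q + 0.5 * (mis_prev + mis_new) * step
        if keep:
            for p in L:
                paths[p].append(L[p].copy())
            d_path.append(D.copy())
            h_path.append(H.copy())
            q_path.append(Q.copy())

    def _stack(lst):
        arr = np.stack(lst, axis=-1)
        return arr[0] if scalar else arr

    if keep:
        return DamageHistory(
            t=grid,
            lesions={p: _stack(paths[p]) for p in paths},
            forks=_stack(d_path),
            hazard_unit=_stack(h_path),
            mismatch_unit=_stack(q_path),
            scalar=scalar,
        )
    return DamageHistory(
        t=grid[-1:],
        lesions={p: (L[p][0] if scalar else L[p][:, None]) for p in L},
        forks=D[0] if scalar else D[:, None],
        hazard_unit=H[0] if scalar else H[:, None],
        mismatch_unit=Q[0] if scalar else Q[:, None],
        scalar=scalar,
    )
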