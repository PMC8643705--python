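"""Model parameters, dose profiles and genotypes for the adaptive-response simulator.

The simulator describes the *E. coli* adaptive response to methylating agents
(MMS): the master regulator Ada is expressed at ~1 molecule per cell, and the
methylation of a single Ada molecule triggers positive-feedback amplification
of the whole regulon (*ada-alkB* operon, *alkA*; *aidB* stays silent).  Cells
that happen to contain zero Ada molecules cannot trigger the switch until one
is produced, which creates a minority "Delayed" subpopulation lacking all
inducible alkylation-repair proteins.

All times are minutes, doses are mM MMS, copy numbers are molecules per cell,
fluorescence is arbitrary units (a.u.).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

GENES = ("ada", "alkb", "alka", "aidb")
CHANNELS = GENES + ("constitutive",)

GENOTYPES = ("wild_type", "dalkB", "dalkA", "dada_alkB", "ada_C321A")

FATES = ("alive", "lysed", "arrested", "escaped")


class ParameterError(ValueError):
    """Raised when a simulation parameter is invalid; names the parameter."""


@dataclass(frozen=True)
class MMSProfile:
    """Piecewise-constant MMS concentration m(t).

    ``breakpoints`` are the left edges (min) of each dose segment;
    ``doses`` the corresponding concentrations (mM).  Before the first
    breakpoint the dose is 0.  The canonical case is a single step:
    ``MMSProfile.step(1.0, onset=30.0)``.
    """

    breakpoints: tuple[float, ...]
    doses: tuple[float, ...]

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        ds = np.asarray(self.doses, dtype=float)
        if bp.size != ds.size:
            raise ParameterError("breakpoints and doses must have equal length")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ParameterError("breakpoints must be strictly increasing")
        if np.any(ds < 0) or not np.all(np.isfinite(ds)):
            raise ParameterError("doses must be finite and >= 0")

    @classmethod
    def step(cls, dose: float, onset: float = 0.0) -> "MMSProfile":
        return cls(breakpoints=(float(onset),), doses=(float(dose),))

    @classmethod
    def none(cls) -> "MMSProfile":
        return cls(breakpoints=(), doses=())

    @property
    def onset(self) -> float:
        """Time of first non-zero dose (0 if never dosed)."""
        for b, d in zip(self.breakpoints, self.doses):
            if d > 0:
                return b
        return 0.0

    def dose_at(self, t) -> np.ndarray:
        """Concentration m(t) for scalar or array t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for b, d in zip(self.breakpoints, self.doses):
            out = np.where(t >= b, d, out)
        return out

    def integral(self, t, exponent: float = 1.0) -> np.ndarray:
        """Integral of m(tau)**exponent from 0 to t (vectorised in t)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        edges = list(self.breakpoints) + [np.inf]
        for i, d in enumerate(self.doses):
            lo, hi = edges[i], edges[i + 1]
            seg = np.clip(t, lo, hi) - lo
            out = out + np.maximum(seg, 0.0) * d**exponent
        return out

    def to_dict(self) -> dict:
        return {"breakpoints": list(self.breakpoints), "doses": list(self.doses)}


_POSITIVE = (
    "dilution_rate", "trigger_shape", "tau_rise", "beta_on",
    "fluct_reversion", "frame_interval", "damage_grid_dt",
    "c321a_switch_rate", "induced_repair_scale",
)
_NONNEG = (
    "k_m", "trigger_dose_exponent", "tau_lag", "fluct_sd",
    "alpha_alka", "alpha_alkb", "alpha_mug", "mug_dose_exponent",
    "beta_off", "fork_rate", "mug_fork_rate",
    "fork_resolution_off", "fork_resolution_on",
    "hazard_scale", "susceptibility_sd", "r_0", "r_mug", "r_tox",
    "mismatch_u_exponent",
    "fluor_scale", "fluor_background", "fluor_noise_sd", "maturation_delay",
    "facs_log_sd", "constitutive_level", "spontaneous_level",
)
_PROBS = ("p_fix", "p_rif", "lysed_intact_loss", "arrest_recovery")


@dataclass
class SimParams:
    """All tunable constants of the generative model.

    The defaults below are placeholders; use :func:`default_params` to load
    the shipped calibration, which was produced by the documented grid search
    (``scripts/calibrate.py``) against the published single-cell summary
    statistics.
    """

    # --- basal (OFF-state) gene expression: birth-death with dilution ---
    basal_means: dict = field(default_factory=lambda: {
        "ada": 1.0, "alkb": 0.25, "alka": 2.6, "aidb": 0.05})
    dilution_rate: float = 0.0075          # gamma, min^-1 (protein dilution)

    # --- the stochastic Ada switch ---
    k_m: float = 0.0143                   # min^-1 mM^-eta per Ada molecule
    trigger_shape: float = 4.2            # Weibull-like exponent of the trigger ramp
    trigger_dose_exponent: float = 1.35   # eta: dose acceleration of the trigger
    c321a_switch_rate: float = 0.5        # min^-1: ada_C321A pre-activated regulon

    # --- ON-state induction ---
    induced_levels: dict = field(default_factory=lambda: {
        "ada": 300.0, "alkb": 100.0, "alka": 250.0, "aidb": 0.0})
    tau_rise: float = 25.0                # min, relaxation to induced level
    tau_lag: float = 8.0                  # min, alkA lags the ada-alkB operon

    # --- shared expression fluctuation process (mean-reverting, mean 1) ---
    fluct_reversion: float = 0.012        # theta, min^-1
    fluct_sd: float = 0.25                # stationary SD of d(t)

    # --- lesion dynamics (per mM of MMS, unit-susceptibility cell) ---
    alpha_alka: float = 0.5               # 3meA-type lesions min^-1 mM^-1
    alpha_alkb: float = 0.5               # 3meC/1meA-type lesions min^-1 mM^-1
    alpha_mug: float = 1.0                # O6meG-type lesions min^-1 mM^-1
    mug_dose_exponent: float = 3.0        # p: mismatch yield scales as m**p
    beta_off: float = 0.0                 # min^-1 pre-activation repair
    beta_on: float = 0.4                  # min^-1 post-activation repair

    # --- replication-fork damage and death ---
    fork_rate: float = 0.02               # stalled forks per toxic lesion per min
    mug_fork_rate: float = 2.1e-4         # forks per mug lesion (futile MMR cycling)
    fork_resolution_off: float = 5.0e-4    # min^-1 before activation
    fork_resolution_on: float = 0.3       # min^-1 after activation
    hazard_scale: float = 2.2e-4          # h_0, min^-1 per stalled fork
    susceptibility_sd: float = 0.5        # lognormal sigma of per-cell damage factor u
    fate_probs: dict = field(default_factory=lambda: {
        "lysed": 0.5, "arrested": 0.3, "escaped": 0.2})
    lysed_intact_loss: float = 1.0        # P(lysed cell lost from a FACS stream)
    arrest_recovery: float = 0.35         # P(arrested cell plates once stress removed)

    # --- mismatch (MutL focus) and mutation model ---
    r_0: float = 4.0e-3                   # basal foci cell^-1 min^-1
    r_mug: float = 2.0e-4                 # foci min^-1 per mutagenic lesion
    r_tox: float = 6.67e-5                 # foci min^-1 per toxic lesion
    mismatch_u_exponent: float = 0.5      # damage factor acts as u**q on mismatches
    p_fix: float = 0.01                   # P(mismatch -> fixed mutation)
    p_rif: float = 0.1                    # P(fixed mutation -> RifR)

    # --- observation model ---
    fluor_scale: float = 1.0              # c, a.u. per molecule
    fluor_background: float = 50.0        # b, a.u.
    fluor_noise_sd: float = 2.0           # sigma_F, a.u.
    maturation_delay: float = 0.0         # min
    frame_interval: float = 3.0           # min between frames
    facs_log_sd: float = 0.10             # lognormal FACS measurement spread (ln)
    constitutive_level: float = 200.0     # molecules, constitutive channel

    # --- single-molecule counting snapshots ---
    count_limit: int = 8                  # counts above this are censored
    spontaneous_active: dict = field(default_factory=lambda: {
        "ada": 0.0, "alkb": 0.0, "alka": 0.05, "aidb": 0.0})
    spontaneous_level: float = 25.0       # mean count of spontaneously induced cells

    # --- numerics ---
    damage_grid_dt: float = 1.0           # min, grid for lesion/hazard integration
    induced_repair_scale: float = 1.0     # multiplies beta_on for the mug pool

    genotype: str = "wild_type"

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name in _POSITIVE:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"parameter {name!r} must be finite and > 0, got {v}")
        for name in _NONNEG:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"parameter {name!r} must be finite and >= 0, got {v}")
        for name in _PROBS:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ParameterError(f"parameter {name!r} must be in [0, 1], got {v}")
        if self.genotype not in GENOTYPES:
            raise ParameterError(
                f"parameter 'genotype' must be one of {GENOTYPES}, got {self.genotype!r}")
        for d, keys in ((self.basal_means, GENES), (self.induced_levels, GENES),
                        (self.spontaneous_active, GENES)):
            for g in keys:
                if g not in d:
                    raise ParameterError(f"missing gene {g!r} in {d}")
                if not np.isfinite(d[g]) or d[g] < 0:
                    raise ParameterError(f"value for gene {g!r} must be >= 0")
        fp = self.fate_probs
        if set(fp) != {"lysed", "arrested", "escaped"}:
            raise ParameterError("fate_probs must have keys lysed/arrested/escaped")
        tot = sum(fp.values())
        if not np.isclose(tot, 1.0):
            raise ParameterError(f"fate_probs must sum to 1, got {tot}")
        if not 1 <= self.count_limit:
            raise ParameterError("count_limit must be >= 1")

    # -- derived quantities ----------------------------------------------
    def birth_rate(self, gene: str) -> float:
        """Basal synthesis rate k_b (molecules/min) giving the stationary mean."""
        return self.basal_means[gene] * self.dilution_rate

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                if isinstance(v, dict):
                    base = dict(getattr(cls(), f.name))
                    extra = set(v) - set(base)
                    if extra:
                        raise ParameterError(
                            f"unknown key(s) {sorted(extra)} in parameter {f.name!r}")
                    base.update(v)
                    v = base
                merged[f.name] = v
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_params(genotype: str = "wild_type", **overrides) -> SimParams:
    """The shipped default calibration (see ``calibration/default.yaml``)."""
    ref = importlib.resources.files("adaswitch") / "calibration" / "default.yaml"
    data = yaml.safe_load(ref.read_text()) or {}
    data["genotype"] = genotype
    data.update(overrides)
    return SimParams.from_dict(data)
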