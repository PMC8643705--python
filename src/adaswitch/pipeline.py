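"""Run configuration and the stage-oriented pipeline driver.

A RunConfig captures everything needed to reproduce a run: simulation
settings, analysis parameters, and the master seed.  ``run_pipeline``
executes the requested stages in dependency order inside a run directory,
writing a resolved-config snapshot and schema-validated artifacts with
sidecar metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import MMSProfile, ParameterError, SimParams, default_params
from . import counts as counts_mod
from . import facs as facs_mod
from . import io as io_mod
from . import mismatch as mismatch_mod
from . import traces as traces_mod
from .simulate import simulate_facs_experiment, simulate_population, \
    snapshot_molecule_counts

STAGES = ("simulate", "analyze-traces", "analyze-counts", "mismatch-rates",
          "survival", "facs", "report")


@dataclass
class RunConfig:
    stages: tuple = STAGES
    outdir: str = "run"
    seed: int = 0
    verbosity: int = 1
    # simulation
    genotype: str = "wild_type"
    dose_mM: float = 1.0
    onset_min: float = 30.0
    horizon_min: float = 210.0
    n_cells: int = 139
    param_overrides: dict = field(default_factory=dict)
    # trace analysis
    k_sigma: float = 5.0
    min_frames: int = 3
    delay_cutoff_min: float = 120.0
    steady_window_start_min: float = 180.0
    max_lag_min: float = 15.0
    # counts
    count_n: int = 10000
    # damage/survival
    smooth_window_min: float = 30.0
    escape_policy: str = "censor"
    # facs
    facs_t_sample_min: float = 90.0
    facs_n_events: int = 500_000
    facs_n_untreated: int = 50_000
    n_sort: int = 1_000_000
    width_sigmas: float = 3.0
    plating_efficiency: float = 1.0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def params(self) -> SimParams:
        return default_params(genotype=self.genotype, **self.param_overrides)


def _log(cfg, msg):
    if cfg.verbosity:
        print(f"[adaswitch] {msg}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = dataclasses.asdict(config)
    snapshot["package_version"] = __version__
    with open(out / "config.json", "w") as fh:
        json.dump(snapshot, fh, indent=2, sort_keys=True)

    params = config.params()
    mms = MMSProfile.step(config.dose_mM, onset=config.onset_min)
    report: dict = {"package_version": __version__, "seed": config.seed}
    pop = None

    def need(stage):
        return stage in config.stages

    if need("simulate"):
        _log(config, f"simulating {config.n_cells} cells "
                     f"({config.genotype}, {config.dose_mM} mM)")
        pop = simulate_population(config.n_cells, params, mms,
                                  config.horizon_min, config.seed)
        io_mod.write_population(pop, out / "population")
        report["n_cells"] = len(pop)
        report["fraction_switched"] = float(
            np.mean([c.t_on is not None for c in pop.cells]))

    def require_pop(stage):
        if pop is None:
            raise ParameterError(
                f"stage {stage!r} needs simulation output; run 'simulate' first")

    if need("analyze-traces"):
        require_pop("analyze-traces")
        trs = traces_mod.traces_from_population(pop)
        rows = []
        fits = {}
        calls_by_channel = {}
        for ch in ("ada", "alka"):
            calls = traces_mod.call_population(
                trs, ch, k_sigma=config.k_sigma, min_frames=config.min_frames,
                delay_cutoff=config.delay_cutoff_min)
            calls_by_channel[ch] = calls
            for c in calls:
                rows.append((c.cell_id, ch,
                             np.nan if c.delay is None else c.delay, c.label))
            act = [c.delay for c in calls if c.label == "Activated"]
            fits[ch] = {"mean_delay_min": float(np.mean(act)) if act else None,
                        "sd_delay_min": float(np.std(act, ddof=1)) if len(act) > 1 else None,
                        "n_activated": len(act)}
        io_mod.write_table(pd.DataFrame(
            rows, columns=["cell_id", "channel", "delay_min", "label"]),
            out / "calls.csv", "calls")
        try:
            fit = traces_mod.delay_fit(
                [c for c in calls_by_channel["ada"] if c.label == "Activated"],
                [c for c in calls_by_channel["alka"] if c.label == "Activated"])
            fits["pairing"] = dataclasses.asdict(fit)
        except traces_mod.TraceError as err:
            fits["pairing"] = {"error": str(err)}
        with open(out / "delay_fit.json", "w") as fh:
            json.dump(fits, fh, indent=2)
        report["delays"] = fits
        # steady-state cross-correlation with both controls
        cc_rows = []
        for mode in ("paired", "shuffled", "constitutive"):
            try:
                cc = traces_mod.steady_state_crosscorr(
                    trs, "ada", "alka",
                    window=(config.steady_window_start_min, config.horizon_min),
                    max_lag=config.max_lag_min, mode=mode, seed=config.seed)
            except traces_mod.TraceError as err:
                _log(config, f"cross-correlation {mode} skipped: {err}")
                continue
            for lag, val in zip(cc.lags, cc.correlation):
                cc_rows.append((lag, val, cc.n_cells, mode))
        if cc_rows:
            io_mod.write_table(pd.DataFrame(
                cc_rows, columns=["lag_min", "mean_corr", "n", "mode"]),
                out / "crosscorr.csv", "correlation")

    if need("analyze-counts"):
        _log(config, "basal molecule-count snapshots")
        summary = {}
        rows = []
        hist_rows = []
        rng = np.random.default_rng(np.random.SeedSequence(
            config.seed).spawn(1)[0])
        for gene in ("ada", "alkb", "alka", "aidb"):
            snap = snapshot_molecule_counts(gene, config.count_n, params, rng)
            s = counts_mod.summarize_counts(snap)
            bins = [str(k) for k in range(snap.limit + 1)] + [f">{snap.limit}"]
            for b, n_cells, frac in zip(bins, s.histogram, s.histogram_frac_all):
                hist_rows.append((gene, b, int(n_cells), float(frac)))
            entry = {"mean_uncensored": s.mean_uncensored,
                     "frac_zero": s.frac_zero, "frac_one": s.frac_one,
                     "frac_censored": s.frac_censored}
            try:
                f = counts_mod.fit_poisson(snap)
                entry.update(lam_censored=f.lam, lam_truncated=f.lam_truncated,
                             fano=f.fano, gof_pvalue=f.gof_pvalue)
            except counts_mod.CountError as err:
                entry["fit_error"] = str(err)
            summary[gene] = entry
            for i, (cnt, cen) in enumerate(zip(snap.counts, snap.censored)):
                rows.append((i, gene, int(cnt), bool(cen)))
        io_mod.write_table(pd.DataFrame(
            rows, columns=["cell_id", "gene", "count", "censored"]),
            out / "counts.csv", "counts")
        io_mod.write_table(pd.DataFrame(
            hist_rows, columns=["gene", "count_bin", "n_cells", "frac_of_all"]),
            out / "count_histogram.csv", "count_histogram")
        with open(out / "count_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        report["counts"] = summary

    if need("mismatch-rates"):
        require_pop("mismatch-rates")
        series, at_risk = mismatch_mod.population_foci(pop)
        events = mismatch_mod.dedup_foci(series)
        curve = mismatch_mod.mismatch_rate_curve(events, at_risk,
                                                 params.frame_interval)
        sm = mismatch_mod.smooth_curve(curve, config.smooth_window_min)
        io_mod.write_table(pd.DataFrame({
            "time_min": sm.times, "rate_per_cell_per_min": sm.rate,
            "n_at_risk": sm.at_risk}), out / "mismatch_rate.csv", "rate_curve")
        report["mismatch_rate"] = {
            "peak": float(sm.rate.max()),
            "peak_time_min": float(sm.times[int(np.argmax(sm.rate))]),
            "final_hour_mean": float(sm.rate[sm.times >= sm.times[-1] - 60].mean()),
        }

    if need("survival"):
        require_pop("survival")
        sc = mismatch_mod.survival_curve(pop.cells, config.horizon_min,
                                         escape_policy=config.escape_policy)
        io_mod.write_table(pd.DataFrame({
            "time_min": sc.times, "fraction_surviving": sc.survival}),
            out / "survival.csv", "survival")
        report["survival"] = {
            "fraction_at_horizon": mismatch_mod.survival_at(sc, config.horizon_min),
            "fates": sc.counts,
        }

    if need("facs"):
        _log(config, f"event-level FACS experiment at {config.dose_mM} mM")
        ss = np.random.SeedSequence(config.seed).spawn(3)
        untreated = simulate_facs_experiment(
            params, 0.0, config.facs_n_untreated, config.facs_t_sample_min,
            np.random.default_rng(ss[0]))
        treated = simulate_facs_experiment(
            params, config.dose_mM, config.facs_n_events,
            config.facs_t_sample_min, np.random.default_rng(ss[1]))
        io_mod.write_table(treated, out / "facs_events.csv", "facs")
        gates = facs_mod.define_gates(untreated, treated,
                                      width_sigmas=config.width_sigmas)
        sort_res = facs_mod.apply_gates(treated, gates)
        assays = facs_mod.run_sort_assay(
            treated, gates, config.n_sort, config.plating_efficiency,
            np.random.default_rng(ss[2]))
        share = facs_mod.plasticity_share(assays)
        facs_report = {
            "gates": {g.label: [g.lo, g.hi] for g in gates},
            "fractions_pct": {k: 100 * v for k, v in sort_res.fractions.items()},
            "excluded_pct": 100 * sort_res.excluded_fraction,
            "assays": [{k: (float(v) if isinstance(v, float) else v)
                        for k, v in dataclasses.asdict(a).items()
                        if k != "frequency_exact"} for a in assays],
            "delayed_activated_ratio": (
                assays[0].frequency / assays[1].frequency
                if assays[1].frequency > 0 else None),
            "plasticity_share_pct": share.shares,
        }
        with open(out / "facs_report.json", "w") as fh:
            json.dump(facs_report, fh, indent=2)
        report["facs"] = facs_report

    if need("report"):
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        _log(config, f"report written to {out / 'report.json'}")
    return out
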