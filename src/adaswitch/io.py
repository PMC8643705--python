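"""Schema-validated CSV tables and JSON sidecars for all pipeline artifacts.

Every table is written with a one-line ``#`` header comment declaring the
units of each column, then a standard CSV header.  Readers validate column
names and dtypes and report the offending rows.  A JSON sidecar accompanies
simulation outputs with the parameters, genotype, dose profile, seed and
package version, so every artifact is reproducible from its metadata.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .params import MMSProfile, SimParams
from .simulate import CellRecord, PopulationDataset


class SchemaError(ValueError):
    pass


#: table name -> (column -> (dtype kind, unit))
SCHEMAS = {
    "traces": {"cell_id": ("i", "-"), "time_min": ("f", "min"),
               "channel": ("O", "-"), "intensity_au": ("f", "a.u.")},
    "foci": {"cell_id": ("i", "-"), "frame_index": ("i", "-"),
             "time_min": ("f", "min")},
    "cells": {"cell_id": ("i", "-"), "t_on_min": ("f", "min"),
              "fate": ("O", "-"), "death_time_min": ("f", "min"),
              "n_mutations": ("i", "count"), "rif_resistant": ("b", "flag")},
    "facs": {"cell_id": ("i", "-"), "gfp_au": ("f", "a.u."),
             "mkate_au": ("f", "a.u.")},
    "counts": {"cell_id": ("i", "-"), "gene": ("O", "-"),
               "count": ("i", "molecules"), "censored": ("b", "flag")},
    "colonies": {"subpopulation": ("O", "-"), "replicate": ("i", "-"),
                 "n_sorted": ("i", "cells"), "colonies": ("i", "count")},
    "calls": {"cell_id": ("i", "-"), "channel": ("O", "-"),
              "delay_min": ("f", "min"), "label": ("O", "-")},
    "correlation": {"lag_min": ("f", "min"), "mean_corr": ("f", "-"),
                    "n": ("i", "cells"), "mode": ("O", "-")},
    "rate_curve": {"time_min": ("f", "min"),
                   "rate_per_cell_per_min": ("f", "foci/cell/min"),
                   "n_at_risk": ("f", "cells")},
    "survival": {"time_min": ("f", "min"), "fraction_surviving": ("f", "-")},
    "count_histogram": {"gene": ("O", "-"), "count_bin": ("O", "molecules"),
                        "n_cells": ("i", "cells"),
                        "frac_of_all": ("f", "-")},
}


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema}: missing column(s) {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    units = ", ".join(f"{c}[{u}]" for c, (_, u) in cols.items())
    with open(path, "w") as fh:
        fh.write(f"# schema={schema}; units: {units}\n")
        df[list(cols)].to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{schema}: file {path} is empty")
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema}: missing column(s) {sorted(missing)} in {path}")
    for col, (kind, _) in cols.items():
        s = df[col]
        if len(df) == 0:
            continue
        if kind == "i":
            if not np.issubdtype(s.dtype, np.integer):
                bad = s[pd.to_numeric(s, errors="coerce").isna()]
                if len(bad):
                    raise SchemaError(
                        f"{schema}: column {col!r} not integer at rows "
                        f"{bad.index[:5].tolist()}")
                df[col] = s.astype(np.int64)
        elif kind == "f":
            coerced = pd.to_numeric(s, errors="coerce")
            bad = s[coerced.isna() & s.notna()]
            if len(bad):
                raise SchemaError(
                    f"{schema}: column {col!r} not numeric at rows "
                    f"{bad.index[:5].tolist()}")
            df[col] = coerced.astype(float)
        elif kind == "b":
            df[col] = s.astype(bool)
    if "time_min" in cols and len(df) > 1 and "cell_id" in cols:
        keys = ["cell_id"] + (["channel"] if "channel" in cols else [])
        g = df.groupby(keys)["time_min"]
        if (g.apply(lambda x: (np.diff(x) < 0).any())).any():
            raise SchemaError(f"{schema}: time_min not sorted within cell")
    return df


# ---------------------------------------------------------------------------
# PopulationDataset round-trip
# ---------------------------------------------------------------------------

def population_to_tables(pop: PopulationDataset) -> dict:
    """Long-format tables for a simulated population."""
    rows_tr, rows_fo, rows_ce = [], [], []
    for c in pop.cells:
        for ch, arr in c.fluorescence.items():
            for t, v in zip(c.times, arr):
                rows_tr.append((c.cell_id, t, ch, v))
        for fr in c.foci_frames:
            rows_fo.append((c.cell_id, int(fr), c.times[int(fr)]))
        rows_ce.append((c.cell_id,
                        np.nan if c.t_on is None else c.t_on,
                        c.fate,
                        np.nan if c.death_time is None else c.death_time,
                        c.n_mutations, c.rif_resistant))
    traces = pd.DataFrame(rows_tr, columns=["cell_id", "time_min", "channel",
                                            "intensity_au"])
    foci = pd.DataFrame(rows_fo, columns=["cell_id", "frame_index", "time_min"])
    cells = pd.DataFrame(rows_ce, columns=["cell_id", "t_on_min", "fate",
                                           "death_time_min", "n_mutations",
                                           "rif_resistant"])
    if foci.empty:
        foci = foci.astype({"cell_id": np.int64, "frame_index": np.int64,
                            "time_min": float})
    return {"traces": traces, "foci": foci, "cells": cells}


def sidecar_dict(pop: PopulationDataset) -> dict:
    from . import __version__

    params = pop.params.to_dict()
    fingerprint = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]
    return {
        "package_version": __version__,
        "seed": pop.seed,
        "genotype": pop.genotype,
        "horizon_min": pop.horizon,
        "n_cells": len(pop),
        "mms_profile": pop.mms.to_dict(),
        "params": params,
        "params_fingerprint": fingerprint,
    }


def write_population(pop: PopulationDataset, outdir) -> dict:
    """Write traces/foci/cells CSVs plus the JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = population_to_tables(pop)
    paths = {}
    for name, df in tables.items():
        paths[name] = outdir / f"{name}.csv"
        write_table(df, paths[name], name)
    paths["meta"] = outdir / "meta.json"
    with open(paths["meta"], "w") as fh:
        json.dump(sidecar_dict(pop), fh, indent=2, sort_keys=True)
    return paths


def read_population(outdir) -> dict:
    """Read back the population tables and sidecar written by write_population."""
    outdir = Path(outdir)
    out = {name: read_table(outdir / f"{name}.csv", name)
           for name in ("traces", "foci", "cells")}
    with open(outdir / "meta.json") as fh:
        out["meta"] = json.load(fh)
    return out


def traces_from_tables(traces: pd.DataFrame, onset: float):
    """Rebuild Trace objects from a long-format traces table."""
    from .traces import Trace

    out = []
    for cid, sub in traces.groupby("cell_id"):
        wide = sub.pivot_table(index="time_min", columns="channel",
                               values="intensity_au", dropna=False)
        out.append(Trace(cell_id=int(cid), times=wide.index.to_numpy(),
                         channels={ch: wide[ch].to_numpy() for ch in wide.columns},
                         onset=onset))
    return out


def population_from_tables(tables: dict, params: SimParams | None = None):
    """Reconstruct a lightweight PopulationDataset from written tables.

    Fluorescence traces and fates are restored exactly; copy-number paths
    (not serialised) are left empty.
    """
    meta = tables["meta"]
    params = params or SimParams.from_dict(meta["params"])
    mms = MMSProfile(tuple(meta["mms_profile"]["breakpoints"]),
                     tuple(meta["mms_profile"]["doses"]))
    cells = []
    foci_by_cell = {int(c): g["frame_index"].to_numpy()
                    for c, g in tables["foci"].groupby("cell_id")}
    tr = tables["traces"]
    for _, row in tables["cells"].iterrows():
        cid = int(row.cell_id)
        sub = tr[tr.cell_id == cid]
        wide = sub.pivot_table(index="time_min", columns="channel",
                               values="intensity_au", dropna=False)
        death = None if pd.isna(row.death_time_min) else float(row.death_time_min)
        frames = np.sort(foci_by_cell.get(cid, np.empty(0, dtype=int)))
        cells.append(CellRecord(
            cell_id=cid, times=wide.index.to_numpy(),
            copy_numbers={},
            fluorescence={ch: wide[ch].to_numpy() for ch in wide.columns},
            t_on=None if pd.isna(row.t_on_min) else float(row.t_on_min),
            foci_frames=frames, foci_counts=np.ones(frames.size, dtype=int),
            n_mutations=int(row.n_mutations),
            rif_resistant=bool(row.rif_resistant),
            fate=str(row.fate), death_time=death, susceptibility=float("nan")))
    return PopulationDataset(cells=cells, mms=mms, genotype=meta["genotype"],
                             params=params, seed=meta["seed"],
                             horizon=meta["horizon_min"])
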