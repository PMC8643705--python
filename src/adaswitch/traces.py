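"""Analysis of single-cell fluorescence time traces.

Implements the trace-level pipeline: baseline correction against the
pre-stress window, population-average (optionally max-normalised) induction
curves, threshold-based activation-delay calling with Activated/Delayed
classification, the paired delay regression between two reporters, and
steady-state cross-correlation analysis with shuffled-pair and
constitutive-reporter null controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DELAY_CUTOFF_DEFAULT = 120.0  # min; later calls are classified Delayed


class TraceError(ValueError):
    pass


@dataclass
class Trace:
    """A per-cell multi-channel fluorescence time series.

    ``onset`` is the time of stress (MMS) addition and must lie on the frame
    grid.  ``baseline``/``baseline_sd`` are filled by
    :func:`baseline_subtract`.
    """

    cell_id: int
    times: np.ndarray
    channels: dict                       # channel -> intensity array (a.u.)
    onset: float
    baseline: dict = field(default_factory=dict)
    baseline_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise TraceError(f"cell {self.cell_id}: trace too short")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise TraceError(f"cell {self.cell_id}: times must be evenly increasing")
        for ch, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.times.shape:
                raise TraceError(f"cell {self.cell_id}: channel {ch!r} misaligned")
            self.channels[ch] = arr
        on_grid = np.isclose(self.times, self.onset).any()
        if not on_grid:
            raise TraceError(f"cell {self.cell_id}: onset not on the frame grid")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ActivationCall:
    cell_id: int
    channel: str
    delay: float | None                  # min from onset
    label: str                           # Activated | Delayed | NoCall
    threshold: float                     # a.u.

    def __post_init__(self):
        if self.label not in ("Activated", "Delayed", "NoCall"):
            raise ValueError(f"bad label {self.label!r}")
        if self.delay is not None and self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class DelayFit:
    """Paired-delay statistics between two reporters (OLS of B on A)."""

    r: float
    slope: float
    intercept: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float                     # paired mean of (B - A)
    n: int
    n_excluded: int


@dataclass
class CrossCorrelation:
    lags: np.ndarray                     # min, symmetric about 0
    correlation: np.ndarray              # mean over cells, in [-1, 1]
    n_cells: int
    n_skipped: int
    mode: str                            # paired | shuffled | constitutive


def from_cell_record(cell) -> Trace:
    """Build a Trace from a simulated CellRecord (onset from frame 0 dose)."""
    return Trace(cell_id=cell.cell_id, times=cell.times.copy(),
                 channels={ch: arr.copy() for ch, arr in cell.fluorescence.items()},
                 onset=0.0)


def traces_from_population(pop) -> list:
    """Traces for a PopulationDataset, with the MMS onset attached."""
    onset = pop.mms.onset
    out = []
    for cell in pop.cells:
        out.append(Trace(
            cell_id=cell.cell_id, times=cell.times.copy(),
            channels={ch: arr.copy() for ch, arr in cell.fluorescence.items()},
            onset=onset))
    return out


def baseline_subtract(trace: Trace, channel: str) -> Trace:
    """Subtract the mean pre-onset intensity; record baseline mean and SD."""
    pre = trace.times < trace.onset
    if pre.sum() < 3:
        raise TraceError(
            f"cell {trace.cell_id}: need >= 3 pre-onset frames, have {int(pre.sum())}")
    y = trace.channels[channel]
    base = float(np.nanmean(y[pre]))
    sd = float(np.nanstd(y[pre], ddof=1))
    new_channels = dict(trace.channels)
    new_channels[channel] = y - base
    out = Trace(cell_id=trace.cell_id, times=trace.times, channels=new_channels,
                onset=trace.onset, baseline=dict(trace.baseline),
                baseline_sd=dict(trace.baseline_sd))
    out.baseline[channel] = base
    out.baseline_sd[channel] = sd
    return out


def population_mean_curve(traces, channel: str, normalize: bool = False):
    """Pointwise mean of baseline-subtracted traces; optionally /max.

    Returns (times, curve).  Cells contribute while observed (NaN frames
    after death are ignored framewise).
    """
    if not traces:
        raise TraceError("need at least one trace")
    t0 = traces[0].times
    for tr in traces:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise TraceError("traces must share a common frame grid")
    stack = np.vstack([tr.channels[channel] for tr in traces])
    with np.errstate(invalid="ignore"):
        curve = np.nanmean(stack, axis=0)
    if normalize:
        peak = np.nanmax(curve)
        if not peak > 0:
            raise TraceError("cannot normalise: curve maximum is not positive")
        curve = curve / peak
    return t0.copy(), curve


def detect_activation_delay(trace: Trace, channel: str, k_sigma: float = 5.0,
                            min_frames: int = 3, window: float | None = None,
                            delay_cutoff: float = DELAY_CUTOFF_DEFAULT) -> ActivationCall:
    """Call the activation delay of one reporter channel.

    The activation time is the first post-onset frame at which the
    baseline-subtracted intensity exceeds ``k_sigma`` baseline SDs for at
    least ``min_frames`` consecutive frames.  Cells whose delay exceeds
    ``delay_cutoff`` (or that never cross within ``window``) are labelled
    Delayed; cells whose observation ends (death) before a call is possible
    are NoCall.
    """
    if channel not in trace.baseline_sd:
        raise TraceError(
            f"cell {trace.cell_id}: baseline_subtract must be applied first")
    thresh = k_sigma * trace.baseline_sd[channel]
    y = trace.channels[channel]
    t = trace.times
    post = t >= trace.onset
    end = trace.onset + window if window is not None else t[-1]
    if window is not None and end > t[-1]:
        end = t[-1]
    valid = post & (t <= end) & np.isfinite(y)
    idx = np.flatnonzero(valid)
    above = y[idx] > thresh
    # First run of >= min_frames consecutive crossings.
    run = 0
    hit = None
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_frames:
            hit = idx[j - min_frames + 1]
            break
    if hit is not None:
        delay = float(t[hit] - trace.onset)
        label = "Activated" if delay <= delay_cutoff else "Delayed"
        return ActivationCall(trace.cell_id, channel, delay, label, thresh)
    # No crossing: Delayed if the cell was observable through the window,
    # NoCall if the trace ended early (death) without covering it.
    observed_to = t[np.isfinite(y)][-1] if np.isfinite(y).any() else trace.onset
    if observed_to >= min(end, trace.onset + delay_cutoff):
        return ActivationCall(trace.cell_id, channel, None, "Delayed", thresh)
    return ActivationCall(trace.cell_id, channel, None, "NoCall", thresh)


def call_population(traces, channel: str, **kwargs) -> list:
    out = []
    for tr in traces:
        tb = baseline_subtract(tr, channel)
        out.append(detect_activation_delay(tb, channel, **kwargs))
    return out


def delay_fit(calls_a, calls_b) -> DelayFit:
    """Pearson r and OLS of channel-B delays on channel-A delays (by cell)."""
    a_map = {c.cell_id: c.delay for c in calls_a if c.delay is not None}
    b_map = {c.cell_id: c.delay for c in calls_b if c.delay is not None}
    common = sorted(set(a_map) & set(b_map))
    n_excluded = len({c.cell_id for c in calls_a} | {c.cell_id for c in calls_b}) - len(common)
    if len(common) < 2:
        raise TraceError("need >= 2 cells with delays called in both channels")
    a = np.array([a_map[i] for i in common])
    b = np.array([b_map[i] for i in common])
    if np.allclose(a, a[0]):
        raise TraceError("degenerate fit: no variance in channel-A delays")
    res = stats.linregress(a, b)
    return DelayFit(
        r=float(res.rvalue), slope=float(res.slope), intercept=float(res.intercept),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        mean_diff=float((b - a).mean()), n=len(common), n_excluded=int(n_excluded))


def steady_state_crosscorr(traces, channel_a: str, channel_b: str,
                           window: tuple, max_lag: float,
                           mode: str = "paired", seed=None) -> CrossCorrelation:
    """Average per-cell normalised cross-correlation over a steady-state window.

    Each cell's two channel segments are mean-subtracted over the window and
    the correlation coefficient computed at each lag, normalised by the
    full-window standard deviations (no per-overlap re-centering), so values
    lie in [-1, 1].  Positive lag means channel_b lags channel_a.

    mode='shuffled' pairs channel_b from a random different cell (seeded);
    mode='constitutive' substitutes the constitutive channel for channel_b.
    """
    if mode not in ("paired", "shuffled", "constitutive"):
        raise TraceError(f"unknown mode {mode!r}")
    t0, t1 = window
    if t1 - t0 < 2 * max_lag:
        raise TraceError("window must be at least twice max_lag")
    dt = traces[0].frame_interval
    lag_steps = int(round(max_lag / dt))
    lags = np.arange(-lag_steps, lag_steps + 1) * dt

    segs_a, segs_b = [], []
    n_skipped = 0
    for tr in traces:
        sel = (tr.times >= t0) & (tr.times <= t1)
        a = tr.channels[channel_a][sel]
        b_ch = channel_b if mode != "constitutive" else "constitutive"
        b = tr.channels[b_ch][sel]
        if np.isnan(a).any() or np.isnan(b).any():
            n_skipped += 1
            continue
        if a.std() == 0 or b.std() == 0:
            n_skipped += 1
            continue
        segs_a.append(a)
        segs_b.append(b)
    if not segs_a:
        raise TraceError("no usable cells in the steady-state window")
    if mode == "shuffled":
        rng = np.random.default_rng(seed)
        k = len(segs_b)
        if k < 2:
            raise TraceError("shuffled control needs >= 2 usable cells")
        perm = (np.arange(k) + 1 + rng.integers(0, k - 1)) % k  # derangement
        segs_b = [segs_b[i] for i in perm]

    curves = []
    for a, b in zip(segs_a, segs_b):
        a = a - a.mean()
        b = b - b.mean()
        norm = len(a) * a.std() * b.std()
        cc = np.correlate(b, a, mode="full") / norm
        centre = len(a) - 1
        curves.append(cc[centre - lag_steps: centre + lag_steps + 1])
    corr = np.mean(np.vstack(curves), axis=0)
    return CrossCorrelation(lags=lags, correlation=corr, n_cells=len(curves),
                            n_skipped=n_skipped, mode=mode)
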