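"""Single-molecule copy-number statistics with a counting limit.

Spot-based single-molecule counting cannot resolve more than ``limit``
(default 8) molecules in one cell; such cells are recorded only as
">limit" (censored).  The summaries report the countable-cell statistics,
and the Poisson fit offers both a right-censored maximum-likelihood estimate
(censored cells contribute P(X > limit)) and a right-truncated estimate that
uses the countable cells only.  The truncated estimate is the robust choice
when the censored bin may contain a distinct (e.g. spontaneously induced)
subpopulation rather than the Poisson tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class CountError(ValueError):
    pass


@dataclass
class CountSnapshot:
    counts: np.ndarray           # per-cell counts; censored cells hold limit+1
    censored: np.ndarray         # bool per cell
    limit: int = 8
    gene: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.counts.size < 1:
            raise CountError("snapshot must contain at least one cell")
        if self.counts.shape != self.censored.shape:
            raise CountError("counts and censored flags misaligned")
        if np.any(self.counts < 0):
            raise CountError("counts must be non-negative")
        if np.any(self.counts[~self.censored] > self.limit):
            raise CountError("uncensored counts must be <= limit")

    @property
    def uncensored(self) -> np.ndarray:
        return self.counts[~self.censored]

    def __len__(self):
        return self.counts.size


@dataclass
class CountSummary:
    n: int
    n_censored: int
    mean_uncensored: float
    frac_zero: float
    frac_one: float
    frac_ge_one: float
    frac_censored: float
    histogram: np.ndarray        # bins 0..limit plus censored bin
    histogram_frac_all: np.ndarray       # normalised over all cells
    histogram_frac_uncensored: np.ndarray  # normalised over countable cells


@dataclass
class PoissonFit:
    lam: float                   # right-censored MLE (censored cells in tail)
    lam_truncated: float         # right-truncated MLE on countable cells
    fano: float                  # variance/mean of the countable counts
    gof_pvalue: float
    n_used: int
    n_censored: int
    degenerate: bool = False


def summarize_counts(snapshot: CountSnapshot) -> CountSummary:
    """Histogram and headline fractions of a counting snapshot."""
    n = len(snapshot)
    unc = snapshot.uncensored
    n_cens = int(snapshot.censored.sum())
    hist = np.bincount(unc, minlength=snapshot.limit + 1)[: snapshot.limit + 1]
    hist = np.append(hist, n_cens)
    return CountSummary(
        n=n, n_censored=n_cens,
        mean_uncensored=float(unc.mean()) if unc.size else float("nan"),
        frac_zero=float((unc == 0).sum() / n),
        frac_one=float((unc == 1).sum() / n),
        frac_ge_one=float(((unc >= 1).sum() + n_cens) / n),
        frac_censored=float(n_cens / n),
        histogram=hist,
        histogram_frac_all=hist / n,
        histogram_frac_uncensored=(hist / unc.size if unc.size else hist * np.nan),
    )


def _truncated_mle(unc: np.ndarray, limit: int) -> float:
    """MLE of lambda for a Poisson right-truncated at `limit`."""
    xbar = unc.mean()
    if xbar == 0:
        return 0.0

    def score(lam):
        # E[X | X <= limit] - xbar
        k = np.arange(limit + 1)
        pk = stats.poisson.pmf(k, lam)
        return (k * pk).sum() / pk.sum() - xbar

    hi = max(4.0 * xbar + 1.0, float(limit) * 4.0)
    return float(optimize.brentq(score, 1e-9, hi, xtol=1e-10))


def _censored_mle(unc: np.ndarray, n_cens: int, limit: int) -> float:
    """MLE of lambda with right-censoring: censored cells contribute P(X > limit)."""
    if n_cens == 0:
        return float(unc.mean())

    def negll(lam):
        if lam <= 0:
            return np.inf
        ll = stats.poisson.logpmf(unc, lam).sum()
        tail = stats.poisson.sf(limit, lam)
        ll += n_cens * np.log(max(tail, 1e-300))
        return -ll

    res = optimize.minimize_scalar(negll, bounds=(1e-9, 20.0 * (unc.mean() + 1) + limit),
                                   method="bounded")
    return float(res.x)


def _poisson_gof(unc: np.ndarray, lam: float, limit: int, min_expected: float = 5.0) -> float:
    """Chi-square goodness of fit against truncated Poisson, pooling sparse bins."""
    n = unc.size
    k = np.arange(limit + 1)
    pk = stats.poisson.pmf(k, lam)
    pk = pk / pk.sum()
    obs = np.bincount(unc, minlength=limit + 1)[: limit + 1].astype(float)
    exp = n * pk
    # Pool from the right until every bin has expected >= min_expected.
    obs_p, exp_p = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_p.append(acc_o)
            exp_p.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_p:
        obs_p[-1] += acc_o
        exp_p[-1] += acc_e
    if len(exp_p) < 3:
        return float("nan")
    obs_p = np.asarray(obs_p)
    exp_p = np.asarray(exp_p) * obs_p.sum() / np.sum(exp_p)
    chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
    dof = len(obs_p) - 1 - 1  # one fitted parameter
    return float(stats.chi2.sf(chi2, dof))


def fit_poisson(snapshot: CountSnapshot) -> PoissonFit:
    """Poisson fit of a counting snapshot honouring the counting limit."""
    unc = snapshot.uncensored
    n_cens = int(snapshot.censored.sum())
    if unc.size == 0:
        raise CountError("all cells censored; cannot fit")
    if unc.size < 10:
        raise CountError("need >= 10 uncensored cells to fit")
    if np.all(unc == 0) and n_cens == 0:
        return PoissonFit(lam=0.0, lam_truncated=0.0, fano=0.0, gof_pvalue=float("nan"),
                          n_used=unc.size, n_censored=0, degenerate=True)
    lam_trunc = _truncated_mle(unc, snapshot.limit)
    lam_cens = _censored_mle(unc, n_cens, snapshot.limit)
    mean = unc.mean()
    fano = float(unc.var(ddof=1) / mean) if mean > 0 else 0.0
    gof = _poisson_gof(unc, lam_trunc, snapshot.limit)
    return PoissonFit(lam=lam_cens, lam_truncated=lam_trunc, fano=fano,
                      gof_pvalue=gof, n_used=int(unc.size), n_censored=n_cens,
                      degenerate=bool(mean == 0))
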