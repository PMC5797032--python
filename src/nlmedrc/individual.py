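"""Per-cell-line ("traditional") 4PL curve fitting.

Each cell line's replicate dose-response data is fit in isolation by
nonlinear least squares; the fitted ``xmid`` is the traditionally called
log10 IC50.  Also houses the drug-level response filter that keeps only
drugs showing a real response (some line driven below a viability
threshold) before association testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .fourpl import FourPL, fourpl_curve

__all__ = [
    "IndividualFit",
    "fit_single_curve",
    "traditional_ic50_table",
    "filter_drugs_by_min_viability",
]

# asymptote / midpoint box constraints (percent viability, log10 uM)
_ASYM_LO, _ASYM_HI = -20.0, 150.0
_SCALE_LO, _SCALE_HI = -10.0, -1e-3
_XMID_PAD = 2.0
_SCALE_GRID = (-1.0, -0.5, -0.25)


@dataclass(frozen=True)
class IndividualFit:
    """Least-squares 4PL fit of a single cell line × drug.

    ``loglik`` is the Gaussian log-likelihood at the MLE residual variance
    ``rss / n``.  ``converged=False`` marks fits whose parameters must not
    be used downstream (degenerate data or optimizer failure).
    """

    params: FourPL
    rss: float
    loglik: float
    converged: bool
    n_obs: int


def _residuals_and_jac(theta, x, y):
    left, right, xmid, scale = theta
    w = expit(-(xmid - x) / scale)  # 1/(1+exp((xmid-x)/scale))
    f = right + (left - right) * w
    r = y - f
    dw = w * (1.0 - w)
    jac = np.empty((x.size, 4))
    jac[:, 0] = -w
    jac[:, 1] = -(1.0 - w)
    jac[:, 2] = (left - right) * dw / scale
    jac[:, 3] = -(left - right) * dw * (xmid - x) / scale**2
    return r, jac


def _self_start(x, y) -> FourPL:
    """Heuristic initial values: asymptotes from the extreme doses, xmid from
    the dose nearest the half response, scale from a coarse grid."""
    mean_by_x = pd.Series(y).groupby(pd.Series(x)).mean()
    xs = mean_by_x.index.to_numpy(float)
    ms = mean_by_x.to_numpy(float)
    left0 = float(ms[np.argmin(xs)])
    right0 = float(ms[np.argmax(xs)])
    if left0 == right0:
        left0 += 1.0  # degenerate; the optimizer will sort it out or fail
    mid = 0.5 * (left0 + right0)
    xmid0 = float(xs[np.argmin(np.abs(ms - mid))])
    best = None
    for s0 in _SCALE_GRID:
        r = y - fourpl_curve(x, left0, right0, xmid0, s0)
        rss = float(r @ r)
        if best is None or rss < best[0]:
            best = (rss, s0)
    return FourPL(left0, right0, xmid0, best[1])


def _gaussian_loglik(rss: float, n: int) -> float:
    s2 = max(rss / n, 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + rss / (n * s2))


def fit_single_curve(data: pd.DataFrame, init: FourPL | None = None) -> IndividualFit:
    """Fit a 4PL curve to one cell line's dose-response data by least squares.

    Parameters
    ----------
    data : DataFrame
        Long-format table restricted to a single (cell line, drug) pair,
        with columns ``x`` (log10 µM) and ``response`` (% viability).
        Needs at least 4 distinct concentrations and 8 points in total.
    init : FourPL, optional
        Starting values; a data-driven self-start is used when omitted.
    """
    x = np.asarray(data["x"], float)
    y = np.asarray(data["response"], float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in dose-response data")
    n_doses = np.unique(x).size
    if n_doses < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {n_doses}")
    if x.size < 8:
        raise ValueError(f"need >= 8 observations, got {x.size}")

    flat = FourPL(float(np.mean(y)), float(np.mean(y)) - 1e-6, float(np.median(x)), -0.5)
    if float(np.var(y)) < 1e-12:
        # flat data cannot identify a sigmoid
        return IndividualFit(flat, float(np.var(y) * y.size), _gaussian_loglik(0.0, y.size), False, y.size)

    p0 = (init or _self_start(x, y)).as_array()
    lo = np.array([_ASYM_LO, _ASYM_LO, x.min() - _XMID_PAD, _SCALE_LO])
    hi = np.array([_ASYM_HI, _ASYM_HI, x.max() + _XMID_PAD, _SCALE_HI])
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
    try:
        res = least_squares(
            lambda th: _residuals_and_jac(th, x, y)[0],
            p0,
            jac=lambda th: _residuals_and_jac(th, x, y)[1],
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    except Exception:
        return IndividualFit(flat, float("inf"), -float("inf"), False, y.size)

    params = FourPL(*[float(v) for v in res.x])
    rss = float(2.0 * res.cost)
    converged = bool(res.success) and math.isfinite(rss)
    return IndividualFit(params, rss, _gaussian_loglik(rss, y.size), converged, y.size)


def traditional_ic50_table(screen: pd.DataFrame, drug: str) -> dict[str, float]:
    """Per-cell-line xmid (log10 IC50) from independent fits of one drug.

    Non-converged lines are omitted from the returned mapping.
    """
    if screen.empty:
        raise ValueError("empty screen table")
    sub = screen[screen["drug"] == drug]
    if sub.empty:
        raise KeyError(f"drug {drug!r} not present in screen")
    out: dict[str, float] = {}
    for line, grp in sub.groupby("cell_line", sort=True):
        fit = fit_single_curve(grp)
        if fit.converged:
            out[str(line)] = fit.params.xmid
    return out


def filter_drugs_by_min_viability(screen: pd.DataFrame, threshold: float = 20.0) -> set[str]:
    """Drugs whose replicate-averaged response drops strictly below ``threshold``.

    For each drug, replicate measurements are averaged per (cell line, dose);
    the drug is kept when the minimum of those means over all lines and doses
    is < ``threshold`` (strict), i.e. at least one cell line was driven below
    the viability cutoff somewhere on the dose range.
    """
    if screen.empty:
        return set()
    means = screen.groupby(["drug", "cell_line", "x"], sort=False)["response"].mean()
    min_by_drug = means.groupby(level="drug").min()
    return {str(d) for d, m in min_by_drug.items() if m < threshold}
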