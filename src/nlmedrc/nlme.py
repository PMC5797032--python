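"""Nonlinear mixed-effects (NLME) 4PL fitting with a random x-mid per cell line.

Model
-----
For cell line *i* and well *j* at log10 concentration ``x_ij``:

    y_ij = fourpl(x_ij; left, right, xmid + b_i, scale) + e_ij
    b_i ~ N(0, sd_xmid_re^2),   e_ij ~ N(0, sd_resid^2)

All four curve parameters are fixed (population) effects; only the curve
midpoint carries a Gaussian random effect grouped by cell line, so lines
share asymptotes and slope but differ in potency.  The marginal likelihood
integrates ``b_i`` out per line; the per-line integral is approximated by
the Laplace method at the conditional mode (default) or by adaptive
Gauss-Hermite quadrature.  Conditional modes give each line's x-mid as
``fixed.xmid + b_i`` — the shrinkage ("NLME-called") log10 IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy import stats

from .fourpl import FourPL
from .individual import fit_single_curve

__all__ = [
    "NLMEFitResult",
    "NormalityReport",
    "fit_nlme_pooled",
    "marginal_loglik",
    "conditional_xmids",
    "residual_diagnostics",
]

_SD_RE_FLOOR = 1e-8  # log10 uM; below this the model is effectively fixed-effects
_SD_RESID_FLOOR = 1e-4  # percent viability


@dataclass
class NLMEFitResult:
    """Result of a pooled NLME 4PL fit for one drug."""

    fixed: FourPL
    sd_xmid_re: float
    sd_resid: float
    line_xmid: dict[str, float]
    loglik: float
    converged: bool
    n_lines: int
    n_obs: int
    method: str = "laplace"
    line_b: dict[str, float] = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk check of within-line residual normality."""

    statistic: float
    p_value: float
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


class _MarginalEngine:
    """Evaluates the marginal log-likelihood for line-sorted screen data.

    Keeps the conditional modes ``b`` warm across evaluations so the inner
    per-line Newton solve typically needs only a few iterations.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, line_codes: np.ndarray):
        order = np.argsort(line_codes, kind="stable")
        self.x = np.ascontiguousarray(x[order])
        self.y = np.ascontiguousarray(y[order])
        codes = line_codes[order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.counts = np.diff(np.r_[self.starts, codes.size])
        self.n_lines = self.starts.size
        self.n_obs = codes.size
        self.b = np.zeros(self.n_lines)

    def _solve_modes(self, left, right, xmid, scale, s2, sb2):
        """Penalized (Gauss-Newton damped) solve for the conditional modes."""
        b = self.b
        x, y, starts, counts = self.x, self.y, self.starts, self.counts
        amp = left - right
        for _ in range(60):
            m = np.repeat(xmid + b, counts)
            w = expit(-(m - x) / scale)
            f = right + amp * w
            r = y - f
            fb = -amp * w * (1.0 - w) / scale
            grad = -np.add.reduceat(r * fb, starts) / s2 + b / sb2
            hess = np.add.reduceat(fb * fb, starts) / s2 + 1.0 / sb2
            step = grad / hess
            np.clip(step, -0.5, 0.5, out=step)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.b = b
        return b

    def _per_line_terms(self, left, right, xmid, scale, s2, b):
        x, y, starts, counts = self.x, self.y, self.starts, self.counts
        amp = left - right
        m = np.repeat(xmid + b, counts)
        w = expit(-(m - x) / scale)
        f = right + amp * w
        r = y - f
        fb = -amp * w * (1.0 - w) / scale
        fbb = amp * (1.0 - 2.0 * w) * w * (1.0 - w) / scale**2
        ssr = np.add.reduceat(r * r, starts)
        ssr_pp = 2.0 * (np.add.reduceat(fb * fb, starts) - np.add.reduceat(r * fbb, starts))
        # fall back to the Gauss-Newton curvature where the exact one is not PD
        gn = 2.0 * np.add.reduceat(fb * fb, starts)
        ssr_pp = np.where(ssr_pp > 0, ssr_pp, gn)
        return ssr, ssr_pp

    def loglik(self, theta: np.ndarray, method: str = "laplace", agq_k: int = 9) -> float:
        left, right, xmid, scale, log_sb, log_s = theta
        if scale >= -1e-6 or not np.all(np.isfinite(theta)):
            return -np.inf
        sb = max(math.exp(log_sb), _SD_RE_FLOOR)
        s = max(math.exp(log_s), _SD_RESID_FLOOR)
        s2, sb2 = s * s, sb * sb
        b = self._solve_modes(left, right, xmid, scale, s2, sb2)
        ssr, ssr_pp = self._per_line_terms(left, right, xmid, scale, s2, b)
        gpp = ssr_pp / (2.0 * s2) + 1.0 / sb2
        base = -0.5 * self.counts * math.log(2.0 * math.pi * s2)
        if method == "laplace":
            ll = base - ssr / (2.0 * s2) - b * b / (2.0 * sb2) \
                - 0.5 * np.log1p(sb2 * ssr_pp / (2.0 * s2))
            return float(np.sum(ll))
        if method == "agq":
            nodes, weights = np.polynomial.hermite.hermgauss(agq_k)
            omega = 1.0 / np.sqrt(gpp)
            g_hat = ssr / (2.0 * s2) + b * b / (2.0 * sb2)
            acc = np.zeros(self.n_lines)
            for t_k, w_k in zip(nodes, weights):
                bk = b + math.sqrt(2.0) * omega * t_k
                mk = np.repeat(xmid + bk, self.counts)
                wk = expit(-(mk - self.x) / scale)
                rk = self.y - (right + (left - right) * wk)
                gk = np.add.reduceat(rk * rk, self.starts) / (2.0 * s2) + bk * bk / (2.0 * sb2)
                acc += w_k * np.exp(t_k * t_k - (gk - g_hat))
            ll = base - 0.5 * math.log(2.0 * math.pi * sb2) - g_hat \
                + 0.5 * math.log(2.0) + np.log(omega) + np.log(acc)
            return float(np.sum(ll))
        raise ValueError(f"unknown integration method {method!r}")


def _prepare(screen: pd.DataFrame, drug: str | None):
    if screen.empty:
        raise ValueError("empty screen table")
    if drug is not None:
        sub = screen[screen["drug"] == drug]
        if sub.empty:
            raise KeyError(f"drug {drug!r} not present in screen")
    else:
        drugs = screen["drug"].unique()
        if drugs.size != 1:
            raise ValueError("screen holds several drugs; pass drug explicitly")
        sub = screen
    lines, codes = np.unique(sub["cell_line"].to_numpy(), return_inverse=True)
    return sub, [str(l) for l in lines], codes


def _start_values(sub: pd.DataFrame, lines) -> np.ndarray:
    """Two-stage start: medians of the per-line least-squares fits."""
    fits = []
    for _, grp in sub.groupby("cell_line", sort=True):
        try:
            f = fit_single_curve(grp)
        except ValueError:
            continue
        if f.converged:
            fits.append(f)
    if fits:
        left0 = float(np.median([f.params.left for f in fits]))
        right0 = float(np.median([f.params.right for f in fits]))
        xmid0 = float(np.median([f.params.xmid for f in fits]))
        scale0 = float(np.median([f.params.scale for f in fits]))
        sb0 = float(np.std([f.params.xmid for f in fits])) or 0.1
        s0 = float(np.sqrt(np.mean([f.rss / f.n_obs for f in fits]))) or 1.0
    else:
        y = sub["response"].to_numpy(float)
        left0, right0 = float(np.max(y)), float(np.min(y))
        xmid0, scale0, sb0, s0 = float(np.median(sub["x"])), -0.5, 0.2, 5.0
    return np.array([left0, right0, xmid0, min(scale0, -1e-3),
                     math.log(max(sb0, 1e-3)), math.log(max(s0, 1e-2))])


def fit_nlme_pooled(
    screen: pd.DataFrame,
    drug: str | None = None,
    init: "NLMEFitResult | np.ndarray | None" = None,
    method: str = "laplace",
    agq_k: int = 9,
) -> NLMEFitResult:
    """Fit the random-x-mid NLME 4PL model to all cell lines of one drug.

    Maximizes the marginal likelihood over the four fixed effects and the
    two variance components (optimized on the log-SD scale) with Nelder-Mead
    followed by a quasi-Newton polish.  Deterministic given the data and
    initialization.

    Parameters
    ----------
    screen : DataFrame
        Long-format table with columns cell_line, drug, x, replicate, response.
    drug : str, optional
        Drug to fit; may be omitted when the table holds a single drug.
    init : NLMEFitResult or ndarray, optional
        Warm start (e.g. the pooled fit, when refitting label subsets during
        permutation).  Defaults to medians of the per-line individual fits.
    method : {"laplace", "agq"}
        Per-line integral approximation; ``agq`` uses ``agq_k`` Gauss-Hermite
        nodes centred at the conditional mode.
    """
    sub, lines, codes = _prepare(screen, drug)
    if len(lines) < 2:
        raise ValueError(f"NLME fit needs >= 2 cell lines, got {len(lines)}")
    engine = _MarginalEngine(sub["x"].to_numpy(float), sub["response"].to_numpy(float), codes)

    if init is None:
        x0 = _start_values(sub, lines)
    elif isinstance(init, NLMEFitResult):
        x0 = np.array([init.fixed.left, init.fixed.right, init.fixed.xmid, init.fixed.scale,
                       math.log(max(init.sd_xmid_re, 1e-6)), math.log(max(init.sd_resid, 1e-3))])
    else:
        x0 = np.asarray(init, float)

    def neg(theta):
        ll = engine.loglik(theta, method=method, agq_k=agq_k)
        return -ll if np.isfinite(ll) else 1e12

    if init is not None:
        # warm start (e.g. permutation refits): quasi-Newton alone suffices
        res = minimize(neg, x0, method="L-BFGS-B",
                       options=dict(ftol=1e-11, gtol=1e-8, maxiter=400))
        success = bool(res.success) and res.fun <= neg(x0) + 1e-9
        if not success:  # fall back to the robust simplex path
            res = minimize(neg, x0, method="Nelder-Mead",
                           options=dict(xatol=1e-6, fatol=1e-8, maxiter=6000,
                                        maxfev=8000, adaptive=True))
            success = bool(res.success)
        best, converged = res, success
    else:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options=dict(xatol=1e-6, fatol=1e-8, maxiter=6000, maxfev=8000,
                                    adaptive=True))
        polish = minimize(neg, res.x, method="L-BFGS-B",
                          options=dict(ftol=1e-13, gtol=1e-10, maxiter=200))
        best = polish if polish.fun <= res.fun else res
        converged = bool(res.success or polish.success)
    theta = best.x
    ll = engine.loglik(theta, method=method, agq_k=agq_k)
    b = engine.b.copy()
    fixed = FourPL(float(theta[0]), float(theta[1]), float(theta[2]), float(theta[3]))
    converged = bool(converged and np.isfinite(ll))
    return NLMEFitResult(
        fixed=fixed,
        sd_xmid_re=float(math.exp(theta[4])),
        sd_resid=float(max(math.exp(theta[5]), _SD_RESID_FLOOR)),
        line_xmid={line: float(fixed.xmid + bi) for line, bi in zip(lines, b)},
        loglik=float(ll),
        converged=converged,
        n_lines=len(lines),
        n_obs=int(engine.n_obs),
        method=method,
        line_b={line: float(bi) for line, bi in zip(lines, b)},
    )


def marginal_loglik(
    screen: pd.DataFrame,
    drug: str | None,
    fixed: FourPL,
    sd_xmid_re: float,
    sd_resid: float,
    method: str = "laplace",
    agq_k: int = 9,
) -> float:
    """Marginal log-likelihood of the NLME model at fixed parameter values.

    Useful for checking the integral approximation against brute-force
    quadrature on small instances, and for likelihood profiling.
    """
    sub, _, codes = _prepare(screen, drug)
    engine = _MarginalEngine(sub["x"].to_numpy(float), sub["response"].to_numpy(float), codes)
    theta = np.array([fixed.left, fixed.right, fixed.xmid, fixed.scale,
                      math.log(max(sd_xmid_re, _SD_RE_FLOOR)),
                      math.log(max(sd_resid, _SD_RESID_FLOOR))])
    return engine.loglik(theta, method=method, agq_k=agq_k)


def conditional_xmids(fit: NLMEFitResult) -> dict[str, float]:
    """Per-line x-mid (fixed effect + conditional mode) from a converged fit.

    These shrink toward ``fit.fixed.xmid`` relative to independently fitted
    x-mids, with shrinkage controlled by ``sd_xmid_re`` versus the data.
    """
    if not fit.converged:
        raise ValueError("conditional x-mids requested from a non-converged fit")
    return dict(fit.line_xmid)


def residual_diagnostics(fit: NLMEFitResult, screen: pd.DataFrame, drug: str | None = None) -> NormalityReport:
    """Residuals at the conditional modes, with a Shapiro-Wilk normality test."""
    if not fit.converged:
        raise ValueError("diagnostics requested from a non-converged fit")
    sub, _, _ = _prepare(screen, drug)
    m = sub["cell_line"].map(fit.line_xmid).to_numpy(float)
    x = sub["x"].to_numpy(float)
    w = expit(-(m - x) / fit.fixed.scale)
    resid = sub["response"].to_numpy(float) - (fit.fixed.right + (fit.fixed.left - fit.fixed.right) * w)
    stat, p = stats.shapiro(resid)
    (osm, osr), _ = stats.probplot(resid, fit=True)
    return NormalityReport(float(stat), float(p), resid, osm, osr)
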