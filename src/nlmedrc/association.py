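"""Association tests between cell-line features and drug response.

Three tests are provided:

* ``trad_assoc`` — Pearson correlation or Welch t-test on traditionally
  (per-line) fitted log10 IC50s;
* ``nlme_ic50_assoc`` — the same tests applied to the conditional x-mids of
  a pooled NLME fit;
* ``omnibus_perm_test`` — the omnibus likelihood-ratio NLME test

      LLR = -2 * LL_all + 2 * (LL_plus + LL_minus)

  comparing a pooled fit against group-stratified fits, with significance
  from cell-line label permutations:

      p = (1 + #{LLR_perm > LLR_obs}) / (n_perm + 1)

  Permutations stop early once the p-value can no longer reach ``alpha``,
  and escalate to a larger permutation count when the first pass is
  significant (adaptive permutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .nlme import NLMEFitResult, conditional_xmids, fit_nlme_pooled

__all__ = [
    "GroupAssignment",
    "OmnibusResult",
    "median_split",
    "trad_assoc",
    "nlme_ic50_assoc",
    "llr_from_logliks",
    "llr_statistic",
    "perm_pvalue",
    "early_stop_threshold",
    "omnibus_perm_test",
    "bonferroni_adjust",
]

PLUS, MINUS = "plus", "minus"


@dataclass(frozen=True)
class GroupAssignment:
    """Binary cell-line labels ("plus"/"minus"), e.g. over-/under-expressers."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = set(self.labels.values())
        if not vals <= {PLUS, MINUS}:
            raise ValueError(f"labels must be {PLUS!r}/{MINUS!r}, got {sorted(vals)}")
        if vals != {PLUS, MINUS}:
            raise ValueError("both groups must be present")

    def lines(self, label: str) -> list[str]:
        return sorted(l for l, v in self.labels.items() if v == label)


def median_split(features: Mapping[str, float]) -> GroupAssignment:
    """Label lines strictly above the median feature value "plus", rest "minus"."""
    med = float(np.median(list(features.values())))
    return GroupAssignment({l: PLUS if v > med else MINUS for l, v in features.items()})


@dataclass(frozen=True)
class OmnibusResult:
    """Outcome of one omnibus LR permutation test (grouping × drug)."""

    llr: float
    n_perm: int
    exceed_count: int
    p_value: float
    stopped_early: bool
    escalated: bool

    def __post_init__(self) -> None:
        assert abs(self.p_value - perm_pvalue(self.exceed_count, self.n_perm)) < 1e-12


def _paired(values: Mapping[str, float], feature: Mapping[str, float | str]):
    keys = sorted(set(values) & set(feature))
    v = np.array([values[k] for k in keys], float)
    f = [feature[k] for k in keys]
    ok = np.isfinite(v)
    return v[ok], [fi for fi, o in zip(f, ok) if o]


def trad_assoc(ic50s: Mapping[str, float], feature: Mapping, mode: str = "pearson"):
    """Associate per-line log10 IC50s with a feature.

    ``mode="pearson"`` treats the feature as continuous; ``mode="ttest"``
    expects a binary feature (two distinct values or plus/minus labels) and
    runs a two-sided Welch t-test.  Lines missing from either input are
    dropped pairwise.  Returns ``(statistic, p_value)``.
    """
    v, f = _paired(ic50s, feature)
    if v.size == 0:
        raise ValueError("no paired observations")
    if np.ptp(v) == 0:
        raise ValueError("IC50 values are constant; association undefined")
    if mode == "pearson":
        fv = np.asarray(f, float)
        if v.size < 3:
            raise ValueError("pearson mode needs >= 3 paired observations")
        if np.ptp(fv) == 0:
            raise ValueError("feature values are constant")
        r, p = stats.pearsonr(v, fv)
        return float(r), float(p)
    if mode == "ttest":
        groups = sorted(set(f), key=str)
        if len(groups) != 2:
            raise ValueError(f"ttest mode needs a binary feature, got {len(groups)} levels")
        a = v[[fi == groups[0] for fi in f]]
        b = v[[fi == groups[1] for fi in f]]
        if a.size < 2 or b.size < 2:
            raise ValueError("ttest mode needs >= 2 observations per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    raise ValueError(f"unknown mode {mode!r}")


def nlme_ic50_assoc(fit: NLMEFitResult, feature: Mapping, mode: str = "pearson"):
    """``trad_assoc`` applied to the conditional x-mids of an NLME fit."""
    return trad_assoc(conditional_xmids(fit), feature, mode=mode)


def llr_from_logliks(ll_all: float, ll_plus: float, ll_minus: float) -> float:
    """Omnibus statistic: ``-2*LL_all + 2*(LL_plus + LL_minus)``."""
    return -2.0 * ll_all + 2.0 * (ll_plus + ll_minus)


def _screen_subset(screen: pd.DataFrame, drug: str | None, lines) -> pd.DataFrame:
    sub = screen if drug is None else screen[screen["drug"] == drug]
    return sub[sub["cell_line"].isin(list(lines))]


def _group_loglik(screen, drug, lines, init) -> float:
    fit = fit_nlme_pooled(_screen_subset(screen, drug, lines), drug, init=init)
    if not fit.converged:
        # one retry from a perturbed start before giving up
        jitter = np.array([1.0, 1.0, 0.05, -0.02, 0.0, 0.0])
        x0 = np.array([fit.fixed.left, fit.fixed.right, fit.fixed.xmid, fit.fixed.scale,
                       math.log(max(fit.sd_xmid_re, 1e-6)), math.log(max(fit.sd_resid, 1e-3))])
        fit = fit_nlme_pooled(_screen_subset(screen, drug, lines), drug, init=x0 + jitter)
        if not fit.converged:
            raise RuntimeError(f"NLME fit failed to converge for group of {len(lines)} lines")
    return fit.loglik


def llr_statistic(screen: pd.DataFrame, drug: str | None, groups: GroupAssignment) -> float:
    """Observed omnibus LLR for a grouping: pooled fit vs per-group fits."""
    plus, minus = groups.lines(PLUS), groups.lines(MINUS)
    if len(plus) < 2 or len(minus) < 2:
        raise ValueError("each group needs >= 2 cell lines")
    all_lines = plus + minus
    fit_all = fit_nlme_pooled(_screen_subset(screen, drug, all_lines), drug)
    if not fit_all.converged:
        raise RuntimeError("pooled NLME fit did not converge")
    ll_plus = _group_loglik(screen, drug, plus, fit_all)
    ll_minus = _group_loglik(screen, drug, minus, fit_all)
    return llr_from_logliks(fit_all.loglik, ll_plus, ll_minus)


def perm_pvalue(exceed_count: int, n_perm: int) -> float:
    """Permutation p-value ``(1 + exceed_count) / (n_perm + 1)``."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 <= exceed_count <= n_perm:
        raise ValueError(f"exceed_count must be in [0, {n_perm}], got {exceed_count}")
    return (1.0 + exceed_count) / (n_perm + 1.0)


def early_stop_threshold(n_perm: int, alpha: float) -> int:
    """Exceedance count at which p can no longer fall below ``alpha``."""
    return math.floor(alpha * (n_perm + 1))


def omnibus_perm_test(
    screen: pd.DataFrame,
    drug: str | None,
    groups: GroupAssignment,
    n_perm: int = 100,
    alpha: float = 0.05,
    adaptive_n: int | None = 9999,
    seed: int | None = None,
) -> OmnibusResult:
    """Omnibus LR NLME test with a permutation null.

    Cell-line labels are permuted (each line's wells stay attached to it);
    the pooled log-likelihood is computed once, only the two group fits are
    redone per permutation, warm-started from the pooled fit.  Exceedance is
    strict (``LLR_perm > LLR_obs``; ties do not count).  Permutations stop
    early once ``exceed_count >= floor(alpha * (n_perm + 1))``.  If the
    first pass gives ``p <= alpha`` and ``adaptive_n`` is set, the test is
    rerun from scratch at ``adaptive_n`` permutations with a fresh seed
    stream and that p-value is reported.
    """
    plus, minus = groups.lines(PLUS), groups.lines(MINUS)
    if len(plus) < 2 or len(minus) < 2:
        raise ValueError("each group needs >= 2 cell lines")
    all_lines = plus + minus
    fit_all = fit_nlme_pooled(_screen_subset(screen, drug, all_lines), drug)
    if not fit_all.converged:
        raise RuntimeError("pooled NLME fit did not converge")

    def split_llr(labels: np.ndarray) -> float:
        p_lines = [l for l, lab in zip(all_lines, labels) if lab]
        m_lines = [l for l, lab in zip(all_lines, labels) if not lab]
        ll_p = _group_loglik(screen, drug, p_lines, fit_all)
        ll_m = _group_loglik(screen, drug, m_lines, fit_all)
        return llr_from_logliks(fit_all.loglik, ll_p, ll_m)

    obs_labels = np.array([l in set(plus) for l in all_lines])
    llr_obs = split_llr(obs_labels)

    ss = np.random.SeedSequence(seed)

    def one_pass(n: int, child: np.random.SeedSequence):
        rng = np.random.default_rng(child)
        threshold = early_stop_threshold(n, alpha)
        exceed = 0
        done = 0
        for _ in range(n):
            perm = rng.permutation(obs_labels)
            try:
                llr_p = split_llr(perm)
            except RuntimeError:
                llr_p = np.inf  # conservative: a failed permutation fit counts as exceedance
            done += 1
            if llr_p > llr_obs:
                exceed += 1
                if exceed >= threshold:
                    return exceed, done, True
        return exceed, done, False

    children = ss.spawn(2)
    exceed, done, stopped = one_pass(n_perm, children[0])
    p = perm_pvalue(exceed, done)
    escalated = False
    if p <= alpha and adaptive_n is not None and adaptive_n > n_perm:
        exceed, done, stopped = one_pass(adaptive_n, children[1])
        p = perm_pvalue(exceed, done)
        escalated = True
    return OmnibusResult(llr=float(llr_obs), n_perm=done, exceed_count=exceed,
                         p_value=float(p), stopped_early=stopped, escalated=escalated)


def bonferroni_adjust(pvals) -> list[float]:
    """Bonferroni-adjusted p-values: ``min(1, p * m)`` for m tests."""
    pvals = list(pvals)
    if any((p < 0 or p > 1 or not math.isfinite(p)) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]
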