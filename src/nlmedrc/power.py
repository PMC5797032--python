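"""Type-I error and power estimation by repeated simulation.

For each simulated screen the harness recreates the full analysis pipeline:
split lines into over-/under-expressers at the median simulated intensity,
then apply one or more of

* ``trad_ic50``  — Welch t-test on independently fitted x-mids,
* ``nlme_ic50``  — Welch t-test on NLME conditional x-mids,
* ``omnibus_llr`` — the permutation LR test,

counting rejections at ``p < alpha`` (strict, matching the discreteness of
the permutation p-value).  Seeding is nested (master seed -> per-simulation
seeds -> per-permutation streams) so any single dataset is reconstructible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .association import median_split, omnibus_perm_test, trad_assoc, nlme_ic50_assoc
from .individual import fit_single_curve
from .nlme import fit_nlme_pooled
from .simulate import ScenarioSpec, simulate_screen

__all__ = ["PowerEstimate", "TESTS", "estimate_power", "estimate_power_multi", "table2_summary"]

TESTS = ("trad_ic50", "nlme_ic50", "omnibus_llr")
_MAX_REDRAWS = 5


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection rate of one test under one scenario."""

    scenario: ScenarioSpec
    test: str
    n_sims: int
    rejections: int
    alpha: float
    n_redraws: int = 0

    @property
    def power(self) -> float:
        return self.rejections / self.n_sims

    @property
    def mc_se(self) -> float:
        p = self.power
        return math.sqrt(p * (1.0 - p) / self.n_sims)


def _trad_pvalue(screen, drug, groups) -> float:
    ic50s = {}
    for line, grp in screen[screen["drug"] == drug].groupby("cell_line", sort=True):
        fit = fit_single_curve(grp)
        if fit.converged:
            ic50s[str(line)] = fit.params.xmid
    _, p = trad_assoc(ic50s, groups.labels, mode="ttest")
    return p


def estimate_power_multi(
    spec: ScenarioSpec,
    tests: Sequence[str],
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_perm: int = 99,
    adaptive_n: int | None = None,
) -> dict[str, PowerEstimate]:
    """Estimate rejection rates for several tests on shared simulated screens.

    All requested tests see exactly the same ``n_sims`` simulated datasets,
    which both saves simulation time and makes cross-test power comparisons
    paired.  A screen whose NLME fit does not converge is redrawn (with a
    fresh seed, at most ``_MAX_REDRAWS`` times); a slot that still fails
    counts as a non-rejection for the affected test.
    """
    for t in tests:
        if t not in TESTS:
            raise ValueError(f"unrecognized test {t!r}; expected one of {TESTS}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    master = np.random.SeedSequence(seed)
    sim_ss, perm_ss = master.spawn(2)
    sim_seeds = np.random.default_rng(sim_ss).integers(0, 2**31 - 1, size=(n_sims, _MAX_REDRAWS + 1))
    perm_seeds = np.random.default_rng(perm_ss).integers(0, 2**31 - 1, size=n_sims)

    rejections = {t: 0 for t in tests}
    redraws = 0
    need_nlme = any(t in ("nlme_ic50",) for t in tests)
    for i in range(n_sims):
        sim = None
        nlme_fit = None
        for attempt in range(_MAX_REDRAWS + 1):
            cand = simulate_screen(replace(spec, seed=int(sim_seeds[i, attempt])))
            if not need_nlme:
                sim = cand
                break
            fit = fit_nlme_pooled(cand.screen, spec.drug)
            if fit.converged:
                sim, nlme_fit = cand, fit
                break
            redraws += 1
        if sim is None:  # all redraws failed; count slot as non-rejection
            continue
        groups = median_split(sim.expression)
        for t in tests:
            try:
                if t == "trad_ic50":
                    p = _trad_pvalue(sim.screen, spec.drug, groups)
                elif t == "nlme_ic50":
                    _, p = nlme_ic50_assoc(nlme_fit or fit_nlme_pooled(sim.screen, spec.drug),
                                           groups.labels, mode="ttest")
                else:
                    res = omnibus_perm_test(sim.screen, spec.drug, groups, n_perm=n_perm,
                                            alpha=alpha, adaptive_n=adaptive_n,
                                            seed=int(perm_seeds[i]))
                    p = res.p_value
            except (RuntimeError, ValueError):
                continue  # failed analysis counts as non-rejection
            if p < alpha:
                rejections[t] += 1
    return {t: PowerEstimate(scenario=spec, test=t, n_sims=n_sims, rejections=rejections[t],
                             alpha=alpha, n_redraws=redraws) for t in tests}


def estimate_power(
    spec: ScenarioSpec,
    test: str,
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_perm: int = 99,
    adaptive_n: int | None = None,
) -> PowerEstimate:
    """Rejection rate of one test under ``spec`` over ``n_sims`` simulations."""
    return estimate_power_multi(spec, (test,), n_sims=n_sims, alpha=alpha, seed=seed,
                                n_perm=n_perm, adaptive_n=adaptive_n)[test]


def table2_summary(estimates: Sequence[PowerEstimate]) -> dict[str, tuple[float, float]]:
    """Mean and SD of power per test across a scenario grid.

    Mirrors the fixed-parameter summaries of the simulation study: for each
    test, the arithmetic mean and (sample) SD of the per-scenario powers.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no power estimates supplied")
    out: dict[str, tuple[float, float]] = {}
    for t in sorted({e.test for e in estimates}):
        powers = np.array([e.power for e in estimates if e.test == t])
        sd = float(np.std(powers, ddof=1)) if powers.size > 1 else 0.0
        out[t] = (float(np.mean(powers)), sd)
    return out
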