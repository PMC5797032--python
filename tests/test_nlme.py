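import numpy as np
import pandas as pd
import pytest

from nlmedrc import (
    FourPL,
    ScenarioSpec,
    conditional_xmids,
    eval_fourpl,
    fit_nlme_pooled,
    fit_single_curve,
    marginal_loglik,
    residual_diagnostics,
    simulate_screen,
)


def brute_force_loglik(screen: pd.DataFrame, fixed: FourPL, sd_re: float, sd_resid: float) -> float:
    """Independent oracle: trapezoid integration of the random effect per line
    over +/- 6 SD with 2001 points."""
    total = 0.0
    bgrid = np.linspace(-6 * sd_re, 6 * sd_re, 2001)
    for _, grp in screen.groupby("cell_line"):
        x = grp["x"].to_numpy(float)
        y = grp["response"].to_numpy(float)
        # log integrand on the grid
        ll_b = np.empty(bgrid.size)
        for k, b in enumerate(bgrid):
            mu = eval_fourpl(FourPL(fixed.left, fixed.right, fixed.xmid + b, fixed.scale), x)
            ll_b[k] = (-0.5 * np.sum((y - mu) ** 2) / sd_resid**2
                       - x.size / 2 * np.log(2 * np.pi * sd_resid**2)
                       - 0.5 * b**2 / sd_re**2 - 0.5 * np.log(2 * np.pi * sd_re**2))
        m = ll_b.max()
        total += m + np.log(np.trapezoid(np.exp(ll_b - m), bgrid))
    return total


def _tiny_screen(seed: int, n_lines: int = 3) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = np.log10(np.array([0.1, 0.4, 2.0]))
    truth = FourPL(100, 10, -0.5, -0.5)
    rows = []
    for i in range(n_lines):
        b = rng.normal(0, 0.3)
        mu = eval_fourpl(FourPL(100, 10, -0.5 + b, -0.5), x)
        for xd, m in zip(x, mu):
            rows.append((f"L{i}", "d", float(xd), 1, float(m + rng.normal(0, 8.0))))
    return pd.DataFrame(rows, columns=["cell_line", "drug", "x", "replicate", "response"])


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("method", ["laplace", "agq"])
def test_marginal_loglik_matches_quadrature_oracle(seed, method):
    """Laplace/AGQ per-line integrals agree with brute-force 1-D quadrature."""
    screen = _tiny_screen(seed)
    fixed = FourPL(100, 10, -0.5, -0.5)
    approx = marginal_loglik(screen, "d", fixed, sd_xmid_re=0.3, sd_resid=8.0, method=method)
    exact = brute_force_loglik(screen, fixed, 0.3, 8.0)
    assert approx == pytest.approx(exact, abs=0.05)


def test_zero_variance_limit_equals_pooled_least_squares():
    """With a shared x-mid, the random-effect SD collapses and the marginal
    log-likelihood equals the pooled fixed-effects least-squares one."""
    sim = simulate_screen(ScenarioSpec(n_lines=10, xmid_re_sd=0.0, noise_sd=1.0, seed=11))
    fit = fit_nlme_pooled(sim.screen, "drug1")
    ls = fit_single_curve(sim.screen)  # one 4PL over all wells
    assert fit.converged
    assert fit.sd_xmid_re <= 1e-3
    assert fit.loglik == pytest.approx(ls.loglik, abs=1e-4)
    xm = conditional_xmids(fit)
    assert max(abs(v - fit.fixed.xmid) for v in xm.values()) <= 1e-6


def test_parameter_recovery_50_lines(null_screen_50, null_fit_50):
    """Fixed effects and variance components recovered from a 50-line screen."""
    fit = null_fit_50
    truth = np.array([100.0, 10.0, -0.5, -0.5])
    # tolerances sized to ~3 Monte-Carlo SEs of each estimate under the
    # generator: the xmid fixed effect has SE ~ 0.3/sqrt(50) ~ 0.042, and the
    # right asymptote (barely observed: the top dose sits ~3 scale units past
    # the midpoint) has SE ~ 1.2
    tol = np.array([10.0, 3.5, 0.13, 0.05])
    for est, tr, ab in zip(fit.fixed.as_array(), truth, tol):
        assert est == pytest.approx(tr, abs=ab)
    assert 0.2 <= fit.sd_xmid_re <= 0.4
    assert fit.sd_resid == pytest.approx(10.0, rel=0.15)
    assert fit.n_lines == 50 and fit.n_obs == 50 * 27


def test_loglik_not_worse_than_no_random_effect(null_screen_50, null_fit_50):
    """Monotone improvement: the NLME optimum dominates the sd_re -> 0 model."""
    ls = fit_single_curve(null_screen_50.screen)
    assert null_fit_50.loglik >= ls.loglik - 1e-6


def test_single_line_rejected(null_screen_50):
    one = null_screen_50.screen[null_screen_50.screen["cell_line"] == "CL001"]
    with pytest.raises(ValueError, match=">= 2 cell lines"):
        fit_nlme_pooled(one, "drug1")


def test_conditional_xmids_shrink_and_cover_lines(null_screen_50, null_fit_50):
    xm = conditional_xmids(null_fit_50)
    assert set(xm) == set(null_screen_50.expression)
    indiv = []
    for line, grp in null_screen_50.screen.groupby("cell_line"):
        f = fit_single_curve(grp)
        if f.converged:
            indiv.append((line, f.params.xmid))
    sd_cond = np.std([xm[l] for l, _ in indiv])
    sd_indiv = np.std([v for _, v in indiv])
    assert sd_cond < sd_indiv


def test_residual_diagnostics_gaussian_noise(null_screen_50, null_fit_50):
    rep = residual_diagnostics(null_fit_50, null_screen_50.screen, "drug1")
    assert rep.residuals.size == null_fit_50.n_obs
    # mean residual ~ 0 relative to its standard error
    se = null_fit_50.sd_resid / np.sqrt(null_fit_50.n_obs)
    assert abs(rep.residuals.mean()) < 3 * se
    assert rep.p_value > 1e-4  # Gaussian noise should not be flagrantly rejected
    assert rep.qq_theoretical.size == rep.qq_sample.size == rep.residuals.size


def test_deterministic_repeat(null_screen_50):
    f1 = fit_nlme_pooled(null_screen_50.screen, "drug1")
    f2 = fit_nlme_pooled(null_screen_50.screen, "drug1")
    assert f1.loglik == f2.loglik
    assert f1.fixed == f2.fixed
    assert f1.line_xmid == f2.line_xmid


def test_nonconverged_fit_refused_downstream(null_fit_50):
    import dataclasses

    broken = dataclasses.replace(null_fit_50, converged=False)
    with pytest.raises(ValueError):
        conditional_xmids(broken)
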