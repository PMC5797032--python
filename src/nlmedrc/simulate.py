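"""Synthetic HTS dose-response screens for null and alternative scenarios.

Emulates a nine-concentration (0.02-10 µM) triplicate viability screen over
a panel of cell lines.  Each line's curve is 4PL with its x-mid drawn from a
normal distribution around its group mean (SD 0.3 log10 µM by default); well
noise is additive Gaussian with a per-dose SD (constant 10% viability by
default).  Half the lines are randomly assigned as over-expressers of a
hypothetical gene (intensity ~ N(8, 1)) and half as under-expressers
(~ N(3, 1)); under the alternative the under-expressing half additionally
receives different curve parameters, under the null both halves share the
same generating curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .fourpl import FourPL, fourpl_curve

__all__ = ["ScenarioSpec", "SimulatedScreen", "simulate_screen", "scenario_grid",
           "DEFAULT_DOSES_UM", "PARAMETER_LEVELS"]

DEFAULT_DOSES_UM = (0.02, 0.04, 0.1, 0.2, 0.4, 1.0, 2.0, 4.0, 10.0)
DEFAULT_GROUP1 = FourPL(100.0, 10.0, -0.5, -0.5)

# group-2 parameter levels spanned by the simulation study
PARAMETER_LEVELS = {
    "left": (100.0, 90.0, 80.0, 70.0),
    "right": (10.0, 20.0, 30.0, 40.0),
    "xmid": (-0.5, -0.4, -0.25, 0.0),
    "scale": (-0.5, -0.4, -0.2),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating model for one simulated screen.

    ``group2=None`` is the null scenario: both expression groups share
    ``group1``'s curve.  ``noise_sd`` is a scalar or a per-dose vector of
    response SDs in % viability.
    """

    n_lines: int = 50
    replicates: int = 3
    doses_um: Sequence[float] = DEFAULT_DOSES_UM
    group1: FourPL = DEFAULT_GROUP1
    group2: FourPL | None = None
    xmid_re_sd: float = 0.3
    noise_sd: float | Sequence[float] = 10.0
    expr_high: tuple[float, float] = (8.0, 1.0)
    expr_low: tuple[float, float] = (3.0, 1.0)
    seed: int | None = None
    drug: str = "drug1"

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_lines % 2:
            raise ValueError("n_lines must be an even number >= 2 (half/half split)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        doses = np.asarray(self.doses_um, float)
        if doses.size < 4 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be >= 4 positive, strictly increasing values")
        sd = np.broadcast_to(np.asarray(self.noise_sd, float), doses.shape)
        if np.any(sd <= 0):
            raise ValueError("noise_sd entries must be > 0")
        if self.xmid_re_sd < 0:
            raise ValueError("xmid_re_sd must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.group2 is None or self.group2 == self.group1

    def noise_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.noise_sd, float),
                               (len(self.doses_um),)).astype(float)


@dataclass(frozen=True)
class SimulatedScreen:
    """A simulated screen plus its generating truth."""

    screen: pd.DataFrame
    expression: dict[str, float]
    curve_group: dict[str, str]          # line -> "group1" | "group2"
    line_params: dict[str, FourPL] = field(repr=False, default_factory=dict)
    spec: ScenarioSpec | None = field(repr=False, default=None)


def simulate_screen(spec: ScenarioSpec) -> SimulatedScreen:
    """Draw one screen from ``spec``; fully determined by ``spec.seed``.

    Returns a long-format table (one row per line × dose × replicate, so
    ``n_lines * replicates * len(doses)`` rows) together with the simulated
    expression intensities and the true group/curve of every line.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines
    half = n // 2
    lines = [f"CL{i + 1:03d}" for i in range(n)]
    order = rng.permutation(n)
    over = set(order[:half])  # over-expressers carry group 1's curve

    x = np.log10(np.asarray(spec.doses_um, float))
    noise = spec.noise_vector()
    g2 = spec.group2 or spec.group1

    rows = []
    expression: dict[str, float] = {}
    curve_group: dict[str, str] = {}
    line_params: dict[str, FourPL] = {}
    for i, line in enumerate(lines):
        if i in over:
            base, grp, (mu_e, sd_e) = spec.group1, "group1", spec.expr_high
        else:
            base, grp, (mu_e, sd_e) = g2, "group2", spec.expr_low
        xmid_i = rng.normal(base.xmid, spec.xmid_re_sd)
        params = FourPL(base.left, base.right, float(xmid_i), base.scale)
        expression[line] = float(rng.normal(mu_e, sd_e))
        curve_group[line] = grp if not spec.is_null else "group1"
        line_params[line] = params
        mean = fourpl_curve(x, params.left, params.right, params.xmid, params.scale)
        for rep in range(1, spec.replicates + 1):
            resp = mean + rng.normal(0.0, noise)
            for xd, r in zip(x, resp):
                rows.append((line, spec.drug, float(xd), rep, float(r)))
    screen = pd.DataFrame(rows, columns=["cell_line", "drug", "x", "replicate", "response"])
    return SimulatedScreen(screen=screen, expression=expression,
                           curve_group=curve_group, line_params=line_params, spec=spec)


def scenario_grid(
    fixed_param: str | None = None,
    fixed_value: float | None = None,
    base: ScenarioSpec | None = None,
    levels: dict[str, Sequence[float]] | None = None,
    exclude: Sequence[FourPL] = (),
) -> list[ScenarioSpec]:
    """Enumerate alternative scenarios over the group-2 parameter levels.

    Group 1 is always the reference curve (100, 10, -0.5, -0.5).  With
    ``fixed_param`` given, that group-2 parameter is held at ``fixed_value``
    while the other three run over their levels (e.g. fixed left -> 48
    scenarios); with no fixed parameter the full cross of all levels (192
    combinations) is returned.  ``exclude`` drops specific group-2 curves.
    """
    base = base or ScenarioSpec()
    levels = {**PARAMETER_LEVELS, **(levels or {})}
    if fixed_param is not None:
        if fixed_param not in levels:
            raise ValueError(f"unknown parameter {fixed_param!r}; expected one of {sorted(levels)}")
        if fixed_value is None:
            raise ValueError("fixed_value required when fixed_param is given")
        levels = dict(levels)
        levels[fixed_param] = (float(fixed_value),)
    excluded = set(exclude)
    specs = []
    for left, right, xmid, scale in product(levels["left"], levels["right"],
                                            levels["xmid"], levels["scale"]):
        g2 = FourPL(left, right, xmid, scale)
        if g2 in excluded:
            continue
        specs.append(replace(base, group2=g2))
    return specs
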