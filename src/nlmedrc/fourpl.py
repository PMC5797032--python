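"""Four-parameter logistic (4PL) dose-response curve.

The 4PL sigmoid used throughout this package is

    y(x) = right + (left - right) / (1 + exp((xmid - x) / scale))

with ``x`` the log10 drug concentration in µM.  ``left`` is the asymptote
approached at low dose, ``right`` the asymptote at high dose, ``xmid`` the
log10 concentration at half response (the operational log10 IC50), and
``scale`` the slope parameter.  For inhibition curves the convention is
``scale < 0`` and ``left > right``: viability starts near ``left`` (e.g.
100%) and falls to ``right`` as dose increases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["FourPL", "eval_fourpl", "fourpl_curve", "ic50_concentration"]


@dataclass(frozen=True)
class FourPL:
    """Parameters of a four-parameter logistic curve.

    Attributes
    ----------
    left : float
        Asymptote at low dose, in response units (% viability).
    right : float
        Asymptote at high dose, in response units (% viability).
    xmid : float
        log10(concentration in µM) at half response; the log10 IC50.
    scale : float
        Slope parameter in log10-concentration units; must be nonzero.
        Negative for inhibition curves (response decreasing in dose).
    """

    left: float
    right: float
    xmid: float
    scale: float

    def __post_init__(self) -> None:
        vals = (self.left, self.right, self.xmid, self.scale)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"FourPL parameters must be finite, got {vals}")
        if self.scale == 0:
            raise ValueError("FourPL scale parameter must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.left, self.right, self.xmid, self.scale], float)


def fourpl_curve(x, left, right, xmid, scale):
    """Evaluate the 4PL curve from raw parameters (vectorised in ``x``)."""
    if scale == 0:
        raise ValueError("scale must be nonzero")
    x = np.asarray(x, float)
    # expit keeps the tails exact (0/1) instead of overflowing exp()
    return right + (left - right) * expit(-(xmid - x) / scale)


def eval_fourpl(params: FourPL, x):
    """Response (% viability) of the curve ``params`` at log10 concentration ``x``.

    At ``x = xmid`` this is exactly ``(left + right) / 2``; responses are
    bounded by the two asymptotes for all finite ``x``.
    """
    return fourpl_curve(x, params.left, params.right, params.xmid, params.scale)


def ic50_concentration(params: FourPL) -> float:
    """IC50 in µM implied by the curve midpoint: ``10 ** xmid``."""
    return float(10.0 ** params.xmid)
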