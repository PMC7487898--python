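"""Adaptive general robust regression loss.

The loss

    f(x, alpha, c) = (|alpha - 2| / alpha) * (((x/c)^2 / |alpha - 2| + 1)^(alpha/2) - 1)

interpolates between familiar robust losses through its shape parameter
alpha — L2 at alpha=2, Charbonnier (smooth L1) at alpha=1, Cauchy at
alpha=0 — while c sets the width of the quadratic bowl around x=0. Treating
exp(-f) as an unnormalized density gives a negative log-likelihood

    nll(x) = log(c * Z(alpha)) + f(x, alpha, c),
    Z(alpha) = integral exp(-f(x, alpha, 1)) dx,

whose minimization trains alpha and c jointly with the model instead of
hand-tuning a robustness constant. alpha is restricted to (0, 2] so that
Z(alpha) is finite; the singular points alpha -> 0 and alpha -> 2 are
handled by their analytic limits (Cauchy and scaled-L2 respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from . import nn
from .nn import Tensor

__all__ = [
    "general_loss",
    "partition_Z",
    "PartitionTable",
    "RobustLossParams",
    "robust_nll",
    "robust_nll_op",
    "ALPHA_MIN",
]

# Switch-over window around the singular alpha values; inside it the
# analytic limit expression is used.
_SINGULAR_EPS = 1e-4
#: alpha is kept away from 0 by this margin in the trainable parameterization.
ALPHA_MIN = 1e-3


def general_loss(x, alpha: float, c: float):
    """Robust loss f(x, alpha, c); vectorized over ``x``.

    ``alpha`` must lie in [0, 2] and ``c`` must be positive.
    """
    if c <= 0:
        raise ValueError(f"scale c must be positive, got {c}")
    if not 0.0 <= alpha <= 2.0:
        raise ValueError(f"shape alpha must be in [0, 2], got {alpha}")
    x = np.asarray(x, dtype=np.float64)
    q = (x / c) ** 2
    if alpha >= 2.0 - _SINGULAR_EPS:
        return 0.5 * q
    if alpha <= _SINGULAR_EPS:
        return np.log1p(0.5 * q)
    b = 2.0 - alpha
    return (b / alpha) * ((q / b + 1.0) ** (alpha / 2.0) - 1.0)


def _dloss_dx(x, alpha: float, c: float):
    """d f / d x. Continuous across the singular-alpha limits."""
    x = np.asarray(x, dtype=np.float64)
    q = (x / c) ** 2
    b = 2.0 - alpha
    if b < 1e-12:
        factor = np.ones_like(q)
    else:
        factor = (q / b + 1.0) ** (-b / 2.0)
    return (x / c ** 2) * factor


def _dloss_dalpha(x, alpha: float, c: float):
    """d f / d alpha; finite differences inside the singular windows."""
    x = np.asarray(x, dtype=np.float64)
    if alpha <= _SINGULAR_EPS * 2 or alpha >= 2.0 - _SINGULAR_EPS * 2:
        h = 1e-5
        lo, hi = max(alpha - h, 0.0), min(alpha + h, 2.0)
        return (general_loss(x, hi, c) - general_loss(x, lo, c)) / (hi - lo)
    q = (x / c) ** 2
    b = 2.0 - alpha
    u = q / b + 1.0
    ua = u ** (alpha / 2.0)
    du_da = (u - 1.0) / b                      # since db/dalpha = -1
    t1 = -(2.0 / alpha ** 2) * (ua - 1.0)
    t2 = (b / alpha) * ua * (0.5 * np.log(u) + (alpha / 2.0) * du_da / u)
    return t1 + t2


def partition_Z(alpha: float) -> float:
    """Normalizer Z(alpha) = integral of exp(-f(x, alpha, 1)) over the line.

    Computed by adaptive quadrature; raises for alpha < 0, where the loss is
    bounded at infinity and the integral diverges.
    """
    if alpha < 0:
        raise ValueError(f"Z(alpha) diverges for alpha < 0 (got {alpha})")
    if alpha > 2.0:
        raise ValueError(f"alpha > 2 is outside the supported range (got {alpha})")
    if alpha >= 2.0 - 1e-12:
        return math.sqrt(2.0 * math.pi)
    if alpha <= 1e-12:
        return math.pi * math.sqrt(2.0)
    val, _ = quad(lambda t: math.exp(-general_loss(t, alpha, 1.0)),
                  0.0, np.inf, limit=400, epsabs=1e-10, epsrel=1e-8)
    return 2.0 * val


@dataclass
class PartitionTable:
    """Precomputed log Z(alpha) on an alpha grid with linear interpolation."""

    n_points: int = 256
    alphas: np.ndarray = field(init=False)
    log_z: np.ndarray = field(init=False)

    def __post_init__(self):
        self.alphas = np.linspace(0.0, 2.0, self.n_points)
        self.log_z = np.array([math.log(partition_Z(a)) for a in self.alphas])

    def logZ(self, alpha: float) -> float:
        if not 0.0 <= alpha <= 2.0:
            raise ValueError(f"alpha must be in [0, 2], got {alpha}")
        return float(np.interp(alpha, self.alphas, self.log_z))

    def dlogZ_dalpha(self, alpha: float) -> float:
        """Slope of the piecewise-linear interpolant at ``alpha``."""
        i = int(np.clip(np.searchsorted(self.alphas, alpha) - 1, 0, self.n_points - 2))
        return float((self.log_z[i + 1] - self.log_z[i])
                     / (self.alphas[i + 1] - self.alphas[i]))


_TABLE: PartitionTable | None = None


def _default_table() -> PartitionTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = PartitionTable()
    return _TABLE


def robust_nll(x, alpha: float, c: float, table: PartitionTable | None = None):
    """Negative log-likelihood log(c Z(alpha)) + f(x, alpha, c) (NumPy)."""
    table = table or _default_table()
    return math.log(c) + table.logZ(alpha) + general_loss(x, alpha, c)


@dataclass
class RobustLossParams:
    """Trainable (alpha, c) via unconstrained latents.

    alpha = ALPHA_MIN + (2 - ALPHA_MIN) * sigmoid(alpha_latent), keeping the
    shape in (0, 2]; c = softplus(scale_latent) + 1e-6 keeps the scale
    positive. Defaults start at alpha ~= 1 and c = 1.
    """

    alpha_latent: Tensor = field(default_factory=lambda: Tensor(0.0, requires_grad=True))
    scale_latent: Tensor = field(
        default_factory=lambda: Tensor(math.log(math.e - 1.0), requires_grad=True))

    def alpha(self) -> Tensor:
        return nn.sigmoid(self.alpha_latent) * (2.0 - ALPHA_MIN) + ALPHA_MIN

    def c(self) -> Tensor:
        return nn.softplus(self.scale_latent) + 1e-6

    def parameters(self) -> list[Tensor]:
        return [self.alpha_latent, self.scale_latent]

    def values(self) -> tuple[float, float]:
        return self.alpha().item(), self.c().item()


def robust_nll_op(x: Tensor, alpha: Tensor, c: Tensor,
                  table: PartitionTable | None = None) -> Tensor:
    """Autodiff robust NLL; differentiable in the residuals, alpha and c.

    ``alpha`` and ``c`` are scalar tensors (typically produced by
    :class:`RobustLossParams`); the log-partition derivative comes from the
    interpolation table's piecewise-linear slope.
    """
    table = table or _default_table()
    a = float(alpha.data)
    cc = float(c.data)
    f = general_loss(x.data, a, cc)
    out = Tensor(math.log(cc) + table.logZ(a) + f)
    out.requires_grad = x.requires_grad or alpha.requires_grad or c.requires_grad
    if out.requires_grad:
        out._parents = (x, alpha, c)
        q = (x.data / cc) ** 2

        def bw():
            g = out.grad
            if x.requires_grad:
                x._accum(g * _dloss_dx(x.data, a, cc))
            if alpha.requires_grad:
                dfda = _dloss_dalpha(x.data, a, cc)
                alpha._accum(np.sum(g * (dfda + table.dlogZ_dalpha(a))))
            if c.requires_grad:
                dfdc = -(q / cc) * ((q / (2.0 - a) + 1.0) ** (-(2.0 - a) / 2.0)
                                    if a < 2.0 - 1e-12 else 1.0)
                c._accum(np.sum(g * (dfdc + 1.0 / cc)))

        out._backward = bw
    return out
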