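"""Low-noise (Fisher-information) approximation of the capacity-cost
problem, and the linear-Gaussian surrogate channel.

In the low-noise regime the capacity-achieving input distribution under an
average-cost constraint W is

    p(lam)  proportional to  sqrt(J(lam) / (2 pi e)) * exp(-lam_W w(lam)),

where J = mu'(lam)^2 / sigma^2(lam) is the (second-moment) Fisher
information and lam_W the cost multiplier fixed by <w, p> = W; the
normalization fixes the second multiplier lam_1.  The associated capacity
lower bound is C_low = 1 - lam_1 + lam_W W in nats, i.e.
C_low = ln Z(lam_W) + lam_W W with Z the normalization integral; values are
reported in bits.

For the linear surrogate (mean g*lam, variance g*lam*FF, affine cost
w0*lam + W0) this collapses to the closed form

    C_low(W) = 1/2 * log2[ (W - W0) / (w_AP * FF) ],   w_AP = w0 / g,

which the grid solver must reproduce and which lower-bounds the
Blahut-Arimoto capacity of the discretized surrogate channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .information import mutual_information
from .statistics import ChannelModel, gaussian_rows

__all__ = [
    "LinearModelSpec",
    "linear_model_channel",
    "fisher_curve",
    "fisher_1d",
    "LowNoiseSolution",
    "solve_low_noise",
    "solve_low_noise_quad",
    "capacity_low_noise_linear",
    "efficiency_low_noise",
]

_LOG2E = np.log2(np.e)


@dataclass
class LinearModelSpec:
    """Linear-Gaussian surrogate: mean g*lam, variance g*lam*FF, cost
    w0*lam + W0 on lam in [lam_min, lam_max] (lam_min > 0)."""

    g: float  # counts per kHz
    FF: float
    w0: float  # cost per kHz
    W0: float  # resting cost
    lam_min: float
    lam_max: float

    def __post_init__(self) -> None:
        if min(self.g, self.FF, self.w0) <= 0:
            raise ValueError("g, FF, w0 must be > 0")
        if not 0 < self.lam_min < self.lam_max:
            raise ValueError("require 0 < lam_min < lam_max")

    @property
    def w_ap(self) -> float:
        return self.w0 / self.g


def linear_model_channel(
    spec: LinearModelSpec, n_lambda: int = 200, n_max: int | None = None
) -> tuple[ChannelModel, np.ndarray]:
    """Discretized surrogate channel and its affine cost vector."""
    lam = np.linspace(spec.lam_min, spec.lam_max, n_lambda)
    mu = spec.g * lam
    var = spec.g * lam * spec.FF
    if n_max is None:
        n_max = int(np.ceil(np.max(mu + 6.0 * np.sqrt(var))))
    channel = ChannelModel(
        lambda_grid=lam,
        cond_pmf=gaussian_rows(mu, var, n_max),
        outputs=np.arange(n_max + 1, dtype=float),
    )
    cost = spec.w0 * lam + spec.W0
    return channel, cost


def fisher_curve(io) -> np.ndarray:
    """J(lam) = mu'(lam)^2 / sigma^2(lam) on the dense grid of ``io``."""
    if np.any(io.var <= 0):
        raise ValueError("variance must be positive on the grid")
    dmu = np.gradient(io.mu, io.lambda_grid)
    return dmu**2 / io.var


def fisher_1d(io, lam: float) -> float:
    """Scalar second-moment Fisher information at stimulus ``lam``."""
    J = fisher_curve(io)
    if not io.lambda_grid[0] <= lam <= io.lambda_grid[-1]:
        raise ValueError("lambda outside the fitted grid")
    return float(np.interp(lam, io.lambda_grid, J))


@dataclass
class LowNoiseSolution:
    lam_grid: np.ndarray | None
    p: np.ndarray | None  # probability vector on the grid (None in quad mode)
    lam_1: float
    lam_W: float
    C_low: float  # bits
    W: float


def _lamW_bracket(mean_cost, W: float, scale: float) -> tuple[float, float]:
    """Bracket the root of mean_cost(lam_W) - W; mean_cost is decreasing."""
    s = 1.0 / scale
    lo, hi = -s, s
    for _ in range(80):
        f_lo = mean_cost(lo) - W
        f_hi = mean_cost(hi) - W
        if f_lo > 0 >= f_hi:
            return lo, hi
        if f_lo <= 0:
            lo *= 2.0
        if f_hi > 0:
            hi *= 2.0
    raise RuntimeError(
        f"could not bracket the cost multiplier for W={W}; "
        "is W inside the achievable cost range?"
    )


def solve_low_noise(J: np.ndarray, w: np.ndarray, W: float, lam: np.ndarray) -> LowNoiseSolution:
    """Grid solver: p proportional to sqrt(J) exp(-lam_W w), trapezoid
    quadrature, multiplier solved so that <w, p> = W exactly.

    Returns the input distribution as a probability vector over the grid
    (density times trapezoid weight, normalized) and the capacity lower
    bound C_low in bits.
    """
    lam = np.asarray(lam, dtype=float)
    J = np.asarray(J, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(J[1:-1] <= 0):
        raise ValueError("Fisher information must be positive on the grid interior")
    if not (w.min() < W < w.max()):
        raise ValueError(f"W={W} outside the achievable cost range ({w.min()}, {w.max()})")
    # trapezoid weights
    tw = np.empty_like(lam)
    tw[1:-1] = 0.5 * (lam[2:] - lam[:-2])
    tw[0] = 0.5 * (lam[1] - lam[0])
    tw[-1] = 0.5 * (lam[-1] - lam[-2])
    amp = np.sqrt(np.maximum(J, 0.0) / (2.0 * np.pi * np.e)) * tw
    w_ref = w.min()  # shift for overflow-safe exponentials
    wc = w - w_ref

    def weights(lam_W: float) -> np.ndarray:
        return amp * np.exp(-lam_W * wc)

    def mean_cost(lam_W: float) -> float:
        u = weights(lam_W)
        return float((u @ w) / u.sum())

    lo, hi = _lamW_bracket(mean_cost, W, scale=max(w.max() - w_ref, 1e-300))
    lam_W = optimize.brentq(lambda s: mean_cost(s) - W, lo, hi, xtol=1e-300, rtol=1e-15)
    u = weights(lam_W)
    Zs = u.sum()
    p = u / Zs
    ln_Z = np.log(Zs) - lam_W * w_ref
    lam_1 = 1.0 - ln_Z
    C_low = (ln_Z + lam_W * W) * _LOG2E
    return LowNoiseSolution(lam_grid=lam, p=p, lam_1=lam_1, lam_W=lam_W, C_low=C_low, W=W)


def solve_low_noise_quad(
    J, w, W: float, bounds: tuple[float, float]
) -> LowNoiseSolution:
    """Adaptive-quadrature variant for callable J(lam), w(lam).

    Integrates the un-discretized density over ``bounds`` (handles
    integrable endpoint singularities such as J ~ 1/lam), for use when the
    continuum value is wanted, e.g. to compare with closed forms.
    """
    a, b = bounds
    w_ref = min(w(a), w(b))

    def density(lam, lam_W):
        return np.sqrt(J(lam) / (2.0 * np.pi * np.e)) * np.exp(-lam_W * (w(lam) - w_ref))

    def Z_of(lam_W):
        val, _ = integrate.quad(density, a, b, args=(lam_W,), limit=200)
        return val

    def mean_cost(lam_W):
        num, _ = integrate.quad(
            lambda x: density(x, lam_W) * w(x), a, b, limit=200
        )
        return num / Z_of(lam_W)

    wa, wb = w(a), w(b)
    lo, hi = _lamW_bracket(mean_cost, W, scale=max(abs(wb - wa), 1e-300))
    lam_W = optimize.brentq(lambda s: mean_cost(s) - W, lo, hi, rtol=1e-14)
    ln_Z = np.log(Z_of(lam_W)) - lam_W * w_ref
    lam_1 = 1.0 - ln_Z
    C_low = (ln_Z + lam_W * W) * _LOG2E
    return LowNoiseSolution(lam_grid=None, p=None, lam_1=lam_1, lam_W=lam_W, C_low=C_low, W=W)


def capacity_low_noise_linear(spec: LinearModelSpec, W: float) -> float:
    """Closed-form low-noise capacity bound of the linear surrogate (bits)."""
    arg = (W - spec.W0) / (spec.w_ap * spec.FF)
    if arg <= 0:
        raise ValueError("W must exceed the resting cost W0")
    return 0.5 * np.log2(arg)


def efficiency_low_noise(
    channel: ChannelModel,
    w: np.ndarray,
    J: np.ndarray,
    n_W: int = 60,
    margin: float = 0.02,
) -> tuple[float, float, np.ndarray]:
    """Information-metabolic efficiency using low-noise input distributions.

    For each cost budget W on a grid spanning the achievable range, the
    low-noise optimal input distribution is built on the channel's stimulus
    grid and the *exact* mutual information of the channel under it is
    evaluated; the efficiency is the maximum of I/W over the sweep.  Since
    every p is feasible, this never exceeds the Jimbo-Kunisawa optimum.

    Returns (E, W_at_max, E_sweep).
    """
    w = np.asarray(w, dtype=float)
    span = w.max() - w.min()
    # log-spaced: the efficiency peak of C(W)/W sits close to the resting
    # cost, where a linear sweep would barely sample
    W_grid = np.geomspace(w.min() + margin * span, w.max() - margin * span, n_W)
    E_sweep = np.full(n_W, np.nan)
    for i, W in enumerate(W_grid):
        try:
            sol = solve_low_noise(J, w, float(W), channel.lambda_grid)
        except (ValueError, RuntimeError):
            continue
        info = mutual_information(sol.p, channel)
        E_sweep[i] = info / W
    if np.all(np.isnan(E_sweep)):
        raise RuntimeError("low-noise solution failed on the whole cost sweep")
    i_best = int(np.nanargmax(E_sweep))
    return float(E_sweep[i_best]), float(W_grid[i_best]), E_sweep
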