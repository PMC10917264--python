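"""Mutual information, capacity-cost function and information-metabolic
efficiency on discrete memoryless channels.

The capacity-cost function is

    C(W) = sup_{p : <w, p> <= W} I(Lambda; N)   [bits],

computed with the cost-constrained Blahut-Arimoto algorithm: for a
multiplier s >= 0 the alternating update

    p'(lam)  proportional to  p(lam) * exp( D(f_lam || q_p) - s w(lam) )

maximizes I(p) - s W(p) (a concave program), with the Csiszár double bound
max_lam [D - s w] >= max_p [I - s W] >= I(p) - s W(p) as the stopping
criterion; an outer bisection on s meets the average-cost constraint.

The information-metabolic efficiency E = max_W C(W)/W = max_p I(p)/W(p) is
obtained directly by Dinkelbach fractional programming: iterate
E <- I(p_E)/W(p_E) where p_E maximizes I - E W (the same tilted
Blahut-Arimoto solve).  The sequence increases monotonically to the optimum
and converges superlinearly; E* satisfies max_p [I - E* W] = 0.

All public quantities are in bits; costs are in whatever unit the cost
vector carries (ATP per window throughout this package, so E is bits per
ATP — multiply by 1e12 for bits per 10^12 ATP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from .statistics import ChannelModel

__all__ = [
    "mutual_information",
    "TiltedBAResult",
    "blahut_arimoto_tilted",
    "ConstrainedCapacity",
    "capacity_cost",
    "EfficiencyResult",
    "info_metabolic_efficiency",
    "CapacityResult",
    "capacity_cost_curve",
]

_LN2 = np.log(2.0)


def _channel_matrix(channel) -> np.ndarray:
    if isinstance(channel, ChannelModel):
        return channel.cond_pmf
    return np.asarray(channel, dtype=float)


def mutual_information(p: np.ndarray, channel) -> float:
    """I(Lambda; N) in bits for input distribution ``p`` over the rows.

    Direct evaluation of sum_lam p(lam) sum_n f(n|lam) log2 f(n|lam)/q(n)
    with q = p f and 0 log 0 = 0.
    """
    F = _channel_matrix(channel)
    p = np.asarray(p, dtype=float)
    if p.shape != (F.shape[0],):
        raise ValueError("p must match the channel input grid")
    if np.any(p < -1e-12):
        raise ValueError("p must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must sum to 1 within 1e-9")
    q = p @ F
    # sum_i p_i sum_n rel_entr(F_in, q_n) = I in nats
    kl = rel_entr(F, q[None, :]).sum(axis=1)
    kl = np.where(p > 0, kl, 0.0)  # rows with p=0 do not contribute
    return float((p @ kl) / _LN2)


@dataclass
class TiltedBAResult:
    p: np.ndarray
    information: float  # bits
    avg_cost: float
    iterations: int
    gap: float  # bits, Csiszár double-bound gap at exit


def blahut_arimoto_tilted(
    F: np.ndarray,
    w: np.ndarray,
    s: float,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    p0: np.ndarray | None = None,
) -> TiltedBAResult:
    """Maximize I(p) - s * <w, p> (nats-internal; reported in bits).

    ``tol`` is the double-bound gap in bits at which iteration stops.
    """
    F = np.asarray(F, dtype=float)
    w = np.asarray(w, dtype=float)
    K = F.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        logF = np.where(F > 0, np.log(F), 0.0)
    neg_H = np.einsum("ij,ij->i", F, logF)  # sum_n F ln F per row
    if p0 is None:
        p = np.full(K, 1.0 / K)
    else:
        p = np.maximum(np.asarray(p0, dtype=float), 1e-300)
        p = p / p.sum()
    sw = s * w
    # single precision for the two large mat-vecs on big channels; the
    # resulting ~1e-6 relative error is far below any tolerance used there
    F_mv = F.astype(np.float32) if F.size > 2_000_000 else F

    def divergences(p):
        # q_n >= p_i F_in for every i, so the clamp only guards dead columns
        q = p.astype(F_mv.dtype) @ F_mv
        log_q = np.log(np.maximum(q.astype(float), 1e-300))
        return neg_H - (F_mv @ log_q.astype(F_mv.dtype)).astype(float)  # KL per row, nats

    # Natural-gradient ascent with an adaptive step gamma >= 1 (gamma = 1 is
    # the classical update).  The objective p @ t is monitored every
    # iteration; on a decrease the step is rejected and gamma shrinks, so
    # ascent stays monotone and the exit gap certifies the value regardless
    # of the path taken.
    gap = np.inf
    it = 0
    gamma = 1.0
    locked = False  # permanent fallback to the classical step on stall
    lb_prev = -np.inf
    p_prev = p
    gap_best = np.inf
    stall = 0
    for it in range(1, max_iter + 1):
        D = divergences(p)
        t = D - sw
        ub = t.max()
        lb = float(p @ t)
        if lb < lb_prev - 1e-15 * max(abs(lb_prev), 1.0):
            # overshoot: back off to the last accepted point
            gamma = max(1.0, gamma / 2.0)
            p = p_prev
            D = divergences(p)
            t = D - sw
            ub = t.max()
            lb = float(p @ t)
        elif not locked:
            gamma = min(gamma * 1.1, 16.0)
        gap = (ub - lb) / _LN2
        if gap < tol:
            break
        # a step-size limit cycle can stall the gap; lock to gamma = 1 then
        if gap < 0.995 * gap_best:
            gap_best = gap
            stall = 0
        else:
            stall += 1
            if stall > 100 and not locked:
                locked = True
                gamma = 1.0
        lb_prev = lb
        p_prev = p
        p = p * np.exp(gamma * (t - ub))
        total = p.sum()
        if total <= 0 or not np.isfinite(total):
            raise RuntimeError("Blahut-Arimoto update degenerated")
        p = p / total
    D = divergences(p)
    info = float(p @ D) / _LN2
    return TiltedBAResult(
        p=p,
        information=info,
        avg_cost=float(p @ w),
        iterations=it,
        gap=gap,
    )


@dataclass
class ConstrainedCapacity:
    capacity: float  # bits
    p: np.ndarray
    avg_cost: float
    multiplier: float  # s at the solution (0 if the constraint is slack)
    iterations: int
    gap: float


def capacity_cost(
    channel,
    w: np.ndarray,
    W: float,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    cost_rtol: float = 1e-6,
    p0: np.ndarray | None = None,
) -> ConstrainedCapacity:
    """Capacity under the average-cost constraint <w, p> <= W.

    The supremum over the open constraint set is attained on its closure, so
    the constraint is treated as <= with relative tolerance ``cost_rtol``.
    """
    F = _channel_matrix(channel)
    w = np.asarray(w, dtype=float)
    if W < w.min():
        raise ValueError(f"W={W} below the minimum achievable cost {w.min()}")
    res = blahut_arimoto_tilted(F, w, 0.0, tol=tol, max_iter=max_iter, p0=p0)
    if res.avg_cost <= W * (1 + cost_rtol):
        return ConstrainedCapacity(
            capacity=res.information,
            p=res.p,
            avg_cost=res.avg_cost,
            multiplier=0.0,
            iterations=res.iterations,
            gap=res.gap,
        )
    # bracket the multiplier: avg cost decreases with s
    s_lo, s_hi = 0.0, 1.0 / max(W, 1e-300)
    res_hi = blahut_arimoto_tilted(F, w, s_hi, tol=tol, max_iter=max_iter, p0=res.p)
    while res_hi.avg_cost > W:
        s_lo = s_hi
        s_hi *= 4.0
        res_hi = blahut_arimoto_tilted(F, w, s_hi, tol=tol, max_iter=max_iter, p0=res_hi.p)
        if s_hi > 1e12 / max(W, 1e-300):
            raise RuntimeError("multiplier bracket not found; cost constraint infeasible?")
    best = res_hi
    for _ in range(200):
        if abs(best.avg_cost - W) <= cost_rtol * W:
            break
        s_mid = 0.5 * (s_lo + s_hi)
        res_mid = blahut_arimoto_tilted(F, w, s_mid, tol=tol, max_iter=max_iter, p0=best.p)
        if res_mid.avg_cost > W:
            s_lo = s_mid
        else:
            s_hi = s_mid
            best = res_mid
        if (s_hi - s_lo) <= 1e-14 * max(s_hi, 1.0):
            break
    s_star = 0.5 * (s_lo + s_hi)
    return ConstrainedCapacity(
        capacity=best.information,
        p=best.p,
        avg_cost=best.avg_cost,
        multiplier=s_star,
        iterations=best.iterations,
        gap=best.gap,
    )


@dataclass
class EfficiencyResult:
    efficiency: float  # bits per cost unit
    W_star: float  # optimizing average cost
    p: np.ndarray
    information: float  # bits at the optimum
    iterations: int  # Dinkelbach outer iterations
    converged: bool


def info_metabolic_efficiency(
    channel,
    w: np.ndarray,
    tol: float = 1e-9,
    rtol: float = 1e-7,
    max_outer: int = 100,
    ba_max_iter: int = 100_000,
    p0: np.ndarray | None = None,
) -> EfficiencyResult:
    """Maximize I(p) / <w, p> (Jimbo-Kunisawa objective) by Dinkelbach
    iteration over the cost-tilted Blahut-Arimoto solver.

    Returns the efficiency in bits per cost unit, the optimizing average
    cost W* and the maximizer p*; agrees with max_W C(W)/W.
    """
    F = _channel_matrix(channel)
    w = np.asarray(w, dtype=float)
    keep = w > 0
    if not keep.all():
        if np.any(~keep & (w < 0)):
            raise ValueError("costs must be nonnegative")
        warnings.warn("pruning zero-cost inputs before the ratio maximization", stacklevel=2)
        F = F[keep]
        w = w[keep]
    K = F.shape[0]
    if p0 is not None:
        p = np.maximum(np.asarray(p0, dtype=float)[keep], 1e-300)
        p = p / p.sum()
    else:
        p = np.full(K, 1.0 / K)
    E_nats = mutual_information(p, F) * _LN2 / float(p @ w)
    if E_nats <= 0:
        warnings.warn("channel carries no information; efficiency = 0", stacklevel=2)
        full_p = np.zeros(keep.size)
        full_p[keep] = p
        return EfficiencyResult(0.0, float(p @ w), full_p, 0.0, 0, True)
    converged = False
    it = 0
    res = None
    for it in range(1, max_outer + 1):
        res = blahut_arimoto_tilted(F, w, E_nats, tol=tol, max_iter=ba_max_iter, p0=p)
        p = res.p
        E_new = res.information * _LN2 / res.avg_cost
        if E_new - E_nats <= rtol * max(E_new, 1e-300):
            E_nats = max(E_new, E_nats)
            converged = True
            break
        E_nats = E_new
    full_p = np.zeros(keep.size)
    full_p[keep] = p
    return EfficiencyResult(
        efficiency=E_nats / _LN2,
        W_star=res.avg_cost,
        p=full_p,
        information=res.information,
        iterations=it,
        converged=converged,
    )


@dataclass
class CapacityResult:
    """Capacity-cost curve with the efficiency summary.

    ``C`` is in bits and nondecreasing, concave in ``W``; ``E`` is the
    information-metabolic efficiency max_W C(W)/W in bits per cost unit and
    ``W_star`` its optimizing cost.
    """

    W_grid: np.ndarray
    C: np.ndarray
    p_star: list
    E: float
    W_star: float
    diagnostics: dict = field(default_factory=dict)


def capacity_cost_curve(
    channel,
    w: np.ndarray,
    W_grid: np.ndarray,
    tol: float = 1e-9,
    ba_max_iter: int = 100_000,
) -> CapacityResult:
    """C(W) over a grid of cost budgets plus the Jimbo-Kunisawa efficiency."""
    w = np.asarray(w, dtype=float)
    W_grid = np.asarray(W_grid, dtype=float)
    C = np.full(W_grid.size, np.nan)
    ps = []
    gaps = []
    for i, W in enumerate(W_grid):
        if W < w.min():
            ps.append(None)
            gaps.append(np.nan)
            continue
        res = capacity_cost(channel, w, float(W), tol=tol, max_iter=ba_max_iter)
        C[i] = res.capacity
        ps.append(res.p)
        gaps.append(res.gap)
    eff = info_metabolic_efficiency(channel, w, tol=tol, ba_max_iter=ba_max_iter)
    return CapacityResult(
        W_grid=W_grid,
        C=C,
        p_star=ps,
        E=eff.efficiency,
        W_star=eff.W_star,
        diagnostics={"gaps": np.asarray(gaps), "jk_iterations": eff.iterations},
    )
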