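"""ATP accounting of network activity.

Signalling cost is dominated by the Na+/K+-ATPase pumping out the Na+ that
enters with (i) action potentials and (ii) excitatory synaptic currents, at
one ATP per 3 Na+ ions.

Action potential: to depolarize the membrane by dV = 100 mV with
C_m = 150 pF the minimum charge influx is dV*C_m = 1.5e-11 C, i.e.
9.375e7 Na+ ions.  The influx is quadrupled for the simultaneous opening of
K+ channels, giving 1.25e8 ATP at the soma, and multiplied by 4 again since
~75% of the per-spike cost sits in axonal propagation: 5.0e8 ATP per spike.

Synaptic current: the excitatory synaptic conductance G is carried by mixed
Na+/K+ channels with reversals E_Na = 90 mV and E_K = -105 mV.  Requiring
g_Na (V-E_Na) + g_K (V-E_K) = G (V-E_e) with g_Na + g_K = G gives the
voltage-independent split g_Na = G (E_K - E_e) / (E_K - E_Na); the Na+
carried by I_Na = g_Na (V-E_Na) over a window Delta_T costs
|I_Na| * Delta_T / (3e) ATP.

The cost curve w(lambda_ext) sums, per counting window: action potentials of
the excitatory, inhibitory and external populations (external population
rate = lambda_ext / P_ext), and the excitatory synaptic currents in the
excitatory and inhibitory populations (external + recurrent + background
conductances).  Inhibitory synaptic currents and synaptic currents inside
the external population are excluded from the accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ELEMENTARY_CHARGE",
    "E_NA",
    "E_K",
    "APCostModel",
    "APCostBreakdown",
    "action_potential_cost",
    "total_capacitance",
    "sodium_fraction",
    "sodium_current_split",
    "synaptic_current_cost",
    "CostCurve",
    "activity_cost",
    "CostSlope",
    "cost_slope",
]

ELEMENTARY_CHARGE = 1.6e-19  # C
E_NA = 90.0  # mV, synaptic Na+ channel reversal
E_K = -105.0  # mV, synaptic K+ channel reversal


def total_capacitance(diameter_um: float = 69.0, c_m: float = 1.0) -> float:
    """Total membrane capacitance (pF) of a spherical cell.

    ``diameter_um`` in micrometers, ``c_m`` specific capacitance in
    uF/cm^2.  Surface pi*D^2; the defaults give ~150 pF.
    """
    d_cm = diameter_um * 1e-4
    area_cm2 = np.pi * d_cm**2
    return float(area_cm2 * c_m * 1e6)  # uF -> pF


@dataclass
class APCostModel:
    """Parameters of the per-spike ATP estimate."""

    delta_V: float = 100.0  # mV depolarization
    C_m: float = 150.0  # pF
    overlap_factor: float = 4.0  # Na+/K+ channel co-activation
    axon_factor: float = 4.0  # somatic cost is ~25% of the total
    atp_per_na: float = 1.0 / 3.0  # Na+/K+-ATPase stoichiometry

    def __post_init__(self) -> None:
        for name in ("delta_V", "C_m", "overlap_factor", "axon_factor", "atp_per_na"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class APCostBreakdown:
    charge: float  # C
    min_ions: float  # minimum Na+ count
    na_influx: float  # after channel-overlap correction
    ionic_cost: float  # ATP at the soma
    total: float  # ATP including axonal propagation


def action_potential_cost(model: APCostModel | None = None) -> APCostBreakdown:
    """ATP cost of one action potential with intermediate quantities."""
    m = model or APCostModel()
    charge = m.delta_V * 1e-3 * m.C_m * 1e-12  # V * F = C
    min_ions = charge / ELEMENTARY_CHARGE
    na_influx = m.overlap_factor * min_ions
    ionic_cost = na_influx * m.atp_per_na
    total = m.axon_factor * ionic_cost
    return APCostBreakdown(
        charge=charge,
        min_ions=min_ions,
        na_influx=na_influx,
        ionic_cost=ionic_cost,
        total=total,
    )


def sodium_fraction(E_e: float = 0.0, E_Na: float = E_NA, E_K_: float = E_K) -> float:
    """Fraction g_Na / G of the excitatory synaptic conductance."""
    if E_K_ == E_Na:
        raise ValueError("E_K == E_Na makes the channel split singular")
    return (E_K_ - E_e) / (E_K_ - E_Na)


def sodium_current_split(
    V: float,
    G: float,
    E_e: float = 0.0,
    E_Na: float = E_NA,
    E_K_: float = E_K,
) -> tuple[float, float]:
    """Split the excitatory synaptic conductance G into its Na+ component.

    Returns (g_Na in nS, I_Na in pA) solving
    g_Na (V-E_Na) + g_K (V-E_K) = G (V-E_e),  g_Na + g_K = G.
    Requires E_K < E_e < E_Na.
    """
    if G < 0:
        raise ValueError("G must be >= 0")
    if not (E_K_ < E_e < E_Na):
        raise ValueError("require E_K < E_e < E_Na")
    g_na = G * sodium_fraction(E_e, E_Na, E_K_)
    return g_na, g_na * (V - E_Na)


def synaptic_current_cost(mean_i_na: float, delta_T: float) -> float:
    """ATP to pump out the Na+ carried by a mean current over ``delta_T`` s.

    ``mean_i_na`` in amperes; cost = |I_Na| * Delta_T / (3 e).
    """
    if delta_T <= 0:
        raise ValueError("delta_T must be > 0")
    return abs(mean_i_na) * delta_T / (3.0 * ELEMENTARY_CHARGE)


@dataclass
class CostCurve:
    """Metabolic cost per counting window along the stimulus grid.

    All components in ATP per Delta_T.  ``external_ap + evoked_ap +
    synaptic`` sums to ``w`` exactly; ``W0 = w(lambda_min)`` is the resting
    cost when the grid starts at zero stimulus.
    """

    lambda_grid: np.ndarray  # kHz
    w: np.ndarray  # ATP
    external_ap: np.ndarray
    evoked_ap: np.ndarray
    synaptic: np.ndarray
    delta_T: float = 1.0

    @property
    def W0(self) -> float:
        return float(self.w[0])


def activity_cost(
    ensemble,
    io,
    config,
    ap_cost: float | None = None,
) -> CostCurve:
    """Build the cost curve w(lambda_ext) on the dense grid of ``io``.

    Uses the per-stimulus mean firing rates and mean excitatory-synaptic Na+
    currents recorded in ``ensemble`` (linearly interpolated between sampled
    stimuli, like the response moments).  ``ap_cost`` defaults to the full
    5.0e8 ATP per spike for all three populations.
    """
    if ap_cost is None:
        ap_cost = action_potential_cost().total
    if config.P_ext <= 0:
        raise ValueError("P_ext must be > 0 for the external-population cost")
    if ensemble.i_na_exc is None or ensemble.i_na_inh is None:
        raise ValueError("ensemble lacks Na-current records")
    lam = io.lambda_grid
    dT = ensemble.delta_T
    # evoked spikes (dense grid, Hz per neuron)
    evoked_ap = (config.n_exc * io.mu_exc + config.n_inh * io.mu_inh) * ap_cost * dT
    # external population spikes: total rate lambda/P_ext kHz -> Hz
    external_ap = (lam / config.P_ext) * 1000.0 * ap_cost * dT
    # synaptic Na+ currents: pA -> A
    i_exc = np.interp(lam, ensemble.lambda_grid, np.abs(ensemble.i_na_exc)) * 1e-12
    i_inh = np.interp(lam, ensemble.lambda_grid, np.abs(ensemble.i_na_inh)) * 1e-12
    synaptic = (
        (config.n_exc * i_exc + config.n_inh * i_inh)
        * dT
        / (3.0 * ELEMENTARY_CHARGE)
    )
    w = external_ap + evoked_ap + synaptic
    return CostCurve(
        lambda_grid=lam,
        w=w,
        external_ap=external_ap,
        evoked_ap=evoked_ap,
        synaptic=synaptic,
        delta_T=dT,
    )


@dataclass
class CostSlope:
    """Derived cost scalars: local slope w0(lambda), resting cost W0 and the
    per-output-spike cost w_AP = w0 / gain, with a least-squares linear
    summary (w(lambda) ~ w0_fit * lambda + W0_fit)."""

    lambda_grid: np.ndarray
    w0: np.ndarray  # ATP per kHz, per lambda
    w_ap: np.ndarray  # ATP per output spike, NaN where gain == 0
    W0: float
    w0_fit: float
    W0_fit: float


def cost_slope(cost: CostCurve, io) -> CostSlope:
    """Finite-difference cost slope and the linear-model scalars (w0, W0, w_AP)."""
    lam = cost.lambda_grid
    if lam.shape != io.lambda_grid.shape or not np.allclose(lam, io.lambda_grid):
        raise ValueError("cost and io curves must share the lambda grid")
    w0 = np.gradient(cost.w, lam)
    g = np.gradient(io.mu, lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ap = np.where(g != 0, w0 / g, np.nan)
    slope, intercept = np.polyfit(lam, cost.w, 1)
    return CostSlope(
        lambda_grid=lam,
        w0=w0,
        w_ap=w_ap,
        W0=cost.W0,
        w0_fit=float(slope),
        W0_fit=float(intercept),
    )
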