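"""Network configuration.

The model is a three-population network: an external population of Poisson
neurons driving an excitatory and an inhibitory population of conductance-based
leaky integrate-and-fire (LIF) neurons.  All single-neuron and synaptic
parameters live in :class:`NetworkConfig`; the defaults are the reference
cortical-patch parameter set (800 excitatory / 200 inhibitory neurons, 1000
external neurons, membrane capacitance 150 pF, resting potential -80 mV,
conductance synapses with 5 ms decay).

Two parameters are the experimental axes of the study and have no single
canonical value:

* ``P_ext`` — probability that an external neuron synapses onto a network
  neuron.  Controls how much input is *shared* between neurons and hence the
  noise correlations.
* ``a_rec`` — amplitude of the recurrent excitatory synapses (nS).  Inhibitory
  synapses are scaled by ``alpha`` (a_inh = alpha * a_rec), so ``a_rec`` sets
  the strength of the inhibition-dominated recurrent feedback.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["NetworkConfig", "load_config", "save_config"]


@dataclass
class NetworkConfig:
    """All parameters of the spiking-network simulation.

    Units: conductances/amplitudes nS, potentials mV, capacitance pF, time
    constants and integration step ms, rates kHz, counting window s.
    """

    # population sizes
    n_ext: int = 1000
    n_exc: int = 800
    n_inh: int = 200
    # connectivity
    P_ext: float = 0.2
    P_rec: float = 0.2
    connection_mode: str = "random"  # "random" | "fixed_in_degree"
    # synaptic amplitudes (nS)
    a_ext: float = 1.0
    a_rec: float = 0.1
    alpha: float = 20.0
    # single-neuron parameters
    C_m: float = 150.0  # pF
    g_L: float = 10.0  # nS
    E_L: float = -80.0  # mV
    E_e: float = 0.0  # mV
    E_i: float = -80.0  # mV
    tau_exc: float = 5.0  # ms
    tau_inh: float = 5.0  # ms
    theta_exc: float = -55.0  # mV
    theta_inh: float = -60.0  # mV
    # background (Ornstein-Uhlenbeck) input
    lambda_bcg_exc: float = 0.5  # kHz
    lambda_bcg_inh: float = 0.125  # kHz
    background_on: bool = True
    clip_background: bool = False  # clamp OU conductances at 0 at use time
    # integration / counting
    dt: float = 0.1  # ms
    Delta_T: float = 1.0  # s
    warmup: float = 0.2  # s discarded before the counting window

    def __post_init__(self) -> None:
        if self.connection_mode not in ("random", "fixed_in_degree"):
            raise ValueError(f"unknown connection_mode {self.connection_mode!r}")
        for name in ("a_ext", "a_rec", "alpha", "g_L", "C_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("P_ext", "P_rec"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.E_i <= self.E_L < self.theta_inh):
            raise ValueError("require E_i <= E_L < theta_inh")
        if not (self.theta_exc < self.E_e):
            raise ValueError("require theta_exc < E_e")

    # derived amplitudes
    @property
    def a_inh(self) -> float:
        """Inhibitory recurrent amplitude (nS), alpha-scaled."""
        return self.alpha * self.a_rec

    @property
    def a_bcg_exc(self) -> float:
        return self.a_ext

    @property
    def a_bcg_inh(self) -> float:
        return self.alpha * self.a_ext

    @property
    def n_net(self) -> int:
        """Number of simulated (non-external) neurons."""
        return self.n_exc + self.n_inh

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def miniature(cls, **overrides) -> "NetworkConfig":
        """A quarter-scale network for desk-scale runs and tests.

        Population sizes are divided by four; recurrent and external
        in-degrees shrink by the same factor, so amplitude grids meant for
        the full network should be scaled up by ~4 to probe a comparable
        total synaptic drive per neuron.
        """
        base = dict(n_ext=250, n_exc=200, n_inh=50)
        base.update(overrides)
        return cls(**base)


def load_config(path: str | Path) -> NetworkConfig:
    """Read a :class:`NetworkConfig` from a YAML mapping of field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return NetworkConfig(**data)


def save_config(config: NetworkConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
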