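"""Connectivity generation and input/background parameterization.

Wiring is Bernoulli per (post, pre) pair: a uniform random matrix R is drawn
and an entry of the weight matrix is set to the synaptic amplitude where
R < P.  In ``fixed_in_degree`` mode the external in-degree is made exact by
keeping, per postsynaptic row, the k = round(n_ext * P_ext) largest entries
of the uniform matrix (which is an unbiased uniform choice of k inputs).

The external drive is parametrized by the mean summed input rate onto a
single network neuron, lambda_ext (kHz).  Each of the n_ext Poisson neurons
then fires at lambda_ext / (n_ext * P_ext), so the expected input per neuron
is independent of P_ext while the *total* external population rate scales as
lambda_ext / P_ext — the mechanism by which shared input (high P_ext) saves
external spikes.

The background synaptic bombardment from unmodelled cortex is an
Ornstein-Uhlenbeck conductance whose mean and stationary standard deviation
match an exponential Poisson shot noise with amplitude a and rate lambda:
mu = a*tau*lambda, sigma = a*sqrt(lambda*tau/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .config import NetworkConfig

__all__ = [
    "ConnectivitySet",
    "build_connectivity",
    "external_rate_per_neuron",
    "ou_background_params",
]


@dataclass
class ConnectivitySet:
    """Sparse weight matrices, shape (n_post, n_pre), entries in nS.

    ``W_ext``: external -> network, entries a_ext.
    ``W_exc``: excitatory -> network, entries a_rec.
    ``W_inh``: inhibitory -> network, entries alpha * a_rec.
    Postsynaptic index runs over [excitatory | inhibitory] neurons.
    """

    W_ext: sp.csr_matrix
    W_exc: sp.csr_matrix
    W_inh: sp.csr_matrix
    seed: int

    def presyn_targets(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) of postsynaptic targets per presynaptic neuron."""
        W = {"ext": self.W_ext, "exc": self.W_exc, "inh": self.W_inh}[which]
        csc = W.tocsc()
        return csc.indptr.astype(np.int64), csc.indices.astype(np.int64)


def _bernoulli_block(rng_mat: np.ndarray, p: float, amplitude: float) -> sp.csr_matrix:
    mask = rng_mat < p
    out = sp.csr_matrix(mask.astype(np.float64) * amplitude)
    return out


def build_connectivity(config: NetworkConfig, seed: int) -> ConnectivitySet:
    """Draw the frozen wiring of the network.

    A single uniform matrix per block; the external block honours
    ``config.connection_mode``.  Recurrent blocks (exc->exc, exc->inh,
    inh->inh, inh->exc) always use ``P_rec``.
    """
    rng = np.random.default_rng(seed)
    n_post = config.n_net

    R_ext = rng.random((n_post, config.n_ext))
    if config.connection_mode == "fixed_in_degree":
        k_exact = config.n_ext * config.P_ext
        k = int(round(k_exact))
        if abs(k_exact - k) > 1e-9:
            warnings.warn(
                f"n_ext * P_ext = {k_exact} is not an integer; using k = {k}",
                stacklevel=2,
            )
        W = np.zeros_like(R_ext)
        if k > 0:
            # keep the k largest uniform entries per row -> uniform k-subset
            idx = np.argpartition(R_ext, -k, axis=1)[:, -k:]
            np.put_along_axis(W, idx, config.a_ext, axis=1)
        W_ext = sp.csr_matrix(W)
    else:
        W_ext = _bernoulli_block(R_ext, config.P_ext, config.a_ext)

    R_exc = rng.random((n_post, config.n_exc))
    R_inh = rng.random((n_post, config.n_inh))
    W_exc = _bernoulli_block(R_exc, config.P_rec, config.a_rec)
    W_inh = _bernoulli_block(R_inh, config.P_rec, config.a_inh)
    return ConnectivitySet(W_ext=W_ext, W_exc=W_exc, W_inh=W_inh, seed=seed)


def external_rate_per_neuron(lambda_ext: float, config: NetworkConfig) -> float:
    """Firing rate (kHz) of one external Poisson neuron.

    Chosen so the expected summed synaptic input rate onto one postsynaptic
    neuron equals ``lambda_ext`` for every P_ext:
    lambda_ext0 = lambda_ext / (n_ext * P_ext).
    """
    if lambda_ext < 0:
        raise ValueError("lambda_ext must be >= 0")
    if config.P_ext <= 0:
        raise ValueError("P_ext must be > 0 to deliver external input")
    return lambda_ext / (config.n_ext * config.P_ext)


def ou_background_params(a: float, tau: float, lambda_bcg: float) -> tuple[float, float]:
    """(mu, sigma) of the OU conductance matching Poisson shot-noise moments.

    Parameters: amplitude ``a`` (nS), synaptic decay ``tau`` (ms), background
    rate ``lambda_bcg`` (kHz).  Returns mean and stationary std in nS.
    """
    if a < 0 or tau < 0 or lambda_bcg < 0:
        raise ValueError("a, tau, lambda_bcg must be >= 0")
    mu = a * tau * lambda_bcg
    sigma = a * np.sqrt(lambda_bcg * tau / 2.0)
    return mu, sigma
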