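"""Trial-ensemble statistics and the discretized stimulus-response channel.

The network output is the total spike count of the excitatory + inhibitory
populations in a window Delta_T.  From the sampled stimulus grid the mean
mu(lambda) and variance sigma^2(lambda) of the total count are linearly
interpolated onto a dense grid (1000 points by default), and the channel is
the discretized normal distribution f(n | lambda) over n = 0..n_max with
those moments, normalized by the explicit sum over the output alphabet.

Correlation and Fano statistics quantify why shared input hurts the summed
readout: with n_tot neurons of single-neuron Fano factor FF0 and mean
pairwise correlation r, the population Fano factor is approximately
FF0 * (1 + (n_tot - 1) r), so even weak correlations dominate for large
populations.  The exact decomposition

    Var(sum N_i) / E(sum N_i) = (v / mu_bar) * (1 + (n_tot - 1) c / v)

(v mean single-neuron variance, c mean pairwise covariance, mu_bar mean
count) holds for any count matrix and is exposed alongside the direct ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IOCurve",
    "ChannelModel",
    "FanoDecomposition",
    "mean_pairwise_correlation",
    "fano_single",
    "fano_population",
    "fit_io_curve",
    "gain",
    "discretized_gaussian_channel",
    "gaussian_rows",
    "exponential_tuning_mean",
]


def mean_pairwise_correlation(counts: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered neuron pairs.

    ``counts`` is (trials x neurons).  Neurons with zero variance across
    trials are excluded pairwise; if fewer than two remain the result is
    undefined and NaN is returned with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a (>=2 trials, >=2 neurons) count matrix")
    keep = counts.var(axis=0) > 0
    if keep.sum() < 2:
        warnings.warn("fewer than two neurons with nonzero variance", stacklevel=2)
        return float("nan")
    r = np.corrcoef(counts[:, keep], rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def fano_single(counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-neuron Fano factors Var/E (unbiased variance) and their mean.

    Neurons with zero mean count get NaN and are excluded from the mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    valid = ~np.isnan(ff)
    mean_ff = float(ff[valid].mean()) if valid.any() else float("nan")
    return ff, mean_ff


@dataclass
class FanoDecomposition:
    """Population Fano factor with its variance/covariance decomposition."""

    ff: float  # Var(sum)/E(sum), direct
    mean_variance: float  # v
    mean_covariance: float  # c, over ordered pairs i != j
    mean_count: float  # mu_bar
    decomposition: float  # (v/mu_bar)(1 + (n-1) c/v), algebraically == ff
    mean_correlation: float  # r_bar over pairs (NaN if undefined)
    approx: float  # FF0 (1 + (n-1) r_bar)


def fano_population(counts: np.ndarray) -> FanoDecomposition:
    """Fano factor of the summed population activity and its decomposition."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    n = counts.shape[1]
    total = counts.sum(axis=1)
    mean_total = total.mean()
    if mean_total == 0:
        warnings.warn("zero mean total count; population Fano undefined", stacklevel=2)
        nan = float("nan")
        return FanoDecomposition(nan, 0.0, 0.0, 0.0, nan, nan, nan)
    ff = float(total.var(ddof=1) / mean_total)
    cov = np.cov(counts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    v = float(np.diag(cov).mean())
    off = cov.sum() - np.trace(cov)
    c = float(off / (n * (n - 1))) if n > 1 else 0.0
    mu_bar = float(counts.mean())
    decomposition = (v / mu_bar) * (1.0 + (n - 1) * (c / v if v > 0 else 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            r_bar = mean_pairwise_correlation(counts)
        except ValueError:
            r_bar = float("nan")
    ff0 = v / mu_bar
    approx = ff0 * (1.0 + (n - 1) * r_bar) if np.isfinite(r_bar) else float("nan")
    return FanoDecomposition(
        ff=ff,
        mean_variance=v,
        mean_covariance=c,
        mean_count=mu_bar,
        decomposition=decomposition,
        mean_correlation=r_bar,
        approx=approx,
    )


@dataclass
class IOCurve:
    """Smoothed input-output relationship on a dense stimulus grid.

    ``mu`` / ``var`` are mean and variance of the *total* population count
    per window; ``mu_exc`` / ``mu_inh`` are mean single-neuron rates in Hz.
    Values at sampled stimuli equal the ensemble's empirical moments exactly
    (linear interpolation through the knots).
    """

    lambda_grid: np.ndarray  # kHz, dense and equidistant
    mu: np.ndarray
    var: np.ndarray
    mu_exc: np.ndarray
    mu_inh: np.ndarray
    knots: np.ndarray  # sampled stimulus grid


def fit_io_curve(ensemble, n_dense: int = 1000) -> IOCurve:
    """Linear interpolation of the ensemble moments onto a dense grid."""
    knots = np.asarray(ensemble.lambda_grid, dtype=float)
    if knots.size < 2:
        raise ValueError("need >= 2 stimulus levels")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("stimulus grid must be strictly increasing")
    mu_k, var_k = ensemble.population_moments()
    me_k, mi_k = ensemble.mean_rates()
    lam = np.linspace(knots[0], knots[-1], n_dense)
    return IOCurve(
        lambda_grid=lam,
        mu=np.interp(lam, knots, mu_k),
        var=np.interp(lam, knots, var_k),
        mu_exc=np.interp(lam, knots, me_k),
        mu_inh=np.interp(lam, knots, mi_k),
        knots=knots,
    )


def gain(io: IOCurve, lam: float | np.ndarray | None = None) -> float | np.ndarray:
    """d mu / d lambda (counts per kHz) by central differences on the grid.

    One-sided at the endpoints.  With ``lam=None`` the full gradient array
    on the dense grid is returned; otherwise the gradient is interpolated
    at ``lam`` (which must lie inside the grid).
    """
    g = np.gradient(io.mu, io.lambda_grid)
    if lam is None:
        return g
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < io.lambda_grid[0]) or np.any(lam_arr > io.lambda_grid[-1]):
        raise ValueError("lambda outside the fitted grid")
    out = np.interp(lam_arr, io.lambda_grid, g)
    return float(out) if np.isscalar(lam) else out


@dataclass
class ChannelModel:
    """Discrete memoryless channel f(output | lambda).

    ``cond_pmf`` is (n_inputs x n_outputs) and row-stochastic;
    ``outputs`` holds the numeric value of each output symbol (spike counts
    for the summed-activity channel, stimulus estimates for the
    Cramér-Rao decoding channel).
    """

    lambda_grid: np.ndarray
    cond_pmf: np.ndarray
    outputs: np.ndarray
    delta_T: float = 1.0

    def __post_init__(self) -> None:
        pmf = self.cond_pmf
        if np.any(pmf < 0):
            raise ValueError("conditional pmf has negative entries")
        rows = pmf.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-12:
            raise ValueError("conditional pmf rows must sum to 1 within 1e-12")

    def row_mean(self) -> np.ndarray:
        return self.cond_pmf @ self.outputs

    def row_var(self) -> np.ndarray:
        m = self.row_mean()
        return self.cond_pmf @ self.outputs**2 - m**2


def gaussian_rows(mu: np.ndarray, var: np.ndarray, n_max: int) -> np.ndarray:
    """Row-stochastic discretized normal pmfs over counts 0..n_max.

    Rows with zero variance degenerate to a point mass at round(mu).
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    n = np.arange(n_max + 1, dtype=float)
    pmf = np.zeros((mu.size, n.size))
    pos = var > 0
    if pos.any():
        z = -((n[None, :] - mu[pos, None]) ** 2) / (2.0 * var[pos, None])
        z -= z.max(axis=1, keepdims=True)  # guard underflow of whole rows
        rows = np.exp(z)
        pmf[pos] = rows / rows.sum(axis=1, keepdims=True)
    if (~pos).any():
        idx = np.clip(np.round(mu[~pos]).astype(int), 0, n_max)
        pmf[np.flatnonzero(~pos), idx] = 1.0
    return pmf


def discretized_gaussian_channel(io: IOCurve, n_max: int | None = None) -> ChannelModel:
    """Channel with discretized-normal rows matching the IO-curve moments.

    The output alphabet is 0..n_max with n_max = ceil(max(mu + 6 sigma)) by
    default, keeping the truncated probability mass below ~1e-8.
    """
    sigma = np.sqrt(np.maximum(io.var, 0.0))
    if np.any((io.var <= 0) & (io.mu > 0)):
        warnings.warn("zero variance at some stimuli; degenerate channel rows", stacklevel=2)
    if n_max is None:
        n_max = int(np.ceil(np.max(io.mu + 6.0 * sigma)))
    pmf = gaussian_rows(io.mu, io.var, n_max)
    return ChannelModel(
        lambda_grid=io.lambda_grid.copy(),
        cond_pmf=pmf,
        outputs=np.arange(n_max + 1, dtype=float),
    )


def exponential_tuning_mean(c1: float, c2: float, lam: float, sigma: float) -> float:
    """Mean of c1*exp(c2*X) with X ~ Normal(lam, sigma^2).

    The lognormal moment identity c1*exp(c2*lam + c2^2 sigma^2 / 2): the
    expected rate of an exponential tuning curve under input that varies
    across neurons, strictly increasing in sigma for c2 != 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return c1 * np.exp(c2 * lam + 0.5 * c2**2 * sigma**2)
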