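"""Correlation/Fano statistics, IO-curve smoothing and the Gaussian channel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import integrate

import infomet as im
from infomet.statistics import (
    IOCurve,
    discretized_gaussian_channel,
    exponential_tuning_mean,
    fano_population,
    fano_single,
    fit_io_curve,
    gain,
    mean_pairwise_correlation,
)


class _FakeEnsemble:
    """Minimal stand-in carrying precomputed moments (synthetic)."""

    def __init__(self, lam, mu, var, mu_exc=None, mu_inh=None):
        self.lambda_grid = np.asarray(lam, float)
        S = self.lambda_grid.size
        self._mu = np.asarray(mu, float)
        self._var = np.asarray(var, float)
        self._me = np.zeros(S) if mu_exc is None else np.asarray(mu_exc, float)
        self._mi = np.zeros(S) if mu_inh is None else np.asarray(mu_inh, float)

    def population_moments(self):
        return self._mu, self._var

    def mean_rates(self):
        return self._me, self._mi


def test_identical_neurons_are_perfectly_correlated():
    col = np.array([1.0, 4.0, 2.0, 7.0])
    counts = np.column_stack([col, col, col])
    assert mean_pairwise_correlation(counts) == pytest.approx(1.0)


def test_perfect_anticorrelation():
    counts = np.column_stack([[1, 2, 3], [3, 2, 1]])
    assert mean_pairwise_correlation(counts) == pytest.approx(-1.0)


def test_independent_poisson_columns_are_uncorrelated():
    rng = np.random.default_rng(1)
    counts = rng.poisson(8.0, size=(10_000, 8))
    assert abs(mean_pairwise_correlation(counts)) < 0.02


def test_zero_variance_neurons_are_excluded():
    counts = np.column_stack([[2, 2, 2], [1, 5, 3], [0, 1, 2]])
    r_full = mean_pairwise_correlation(counts)
    r_drop = mean_pairwise_correlation(counts[:, 1:])
    assert r_full == pytest.approx(r_drop)
    with pytest.warns(UserWarning):
        assert np.isnan(mean_pairwise_correlation(np.ones((3, 3))))


def test_fano_single_examples():
    ff, mean_ff = fano_single(np.full((10, 3), 4.0))
    assert np.allclose(ff, 0.0) and mean_ff == 0.0
    # counts (0, 2): sample variance 2, mean 1
    ff, _ = fano_single(np.array([[0.0], [2.0]]))
    assert ff[0] == pytest.approx(2.0)
    rng = np.random.default_rng(2)
    _, mean_ff = fano_single(rng.poisson(10.0, size=(100_000, 3)))
    assert mean_ff == pytest.approx(1.0, abs=0.02)


@settings(max_examples=40, deadline=None)
@given(
    arrays(
        np.int64,
        st.tuples(st.integers(3, 12), st.integers(2, 8)),
        elements=st.integers(0, 30),
    )
)
def test_population_fano_decomposition_is_an_identity(counts):
    # Var(sum)/E(sum) must equal the variance/covariance decomposition
    # exactly for any count matrix with a nonzero total
    if counts.sum() == 0:
        return
    d = fano_population(counts)
    assert d.decomposition == pytest.approx(d.ff, rel=1e-12)


def test_duplicated_neuron_population_fano():
    rng = np.random.default_rng(3)
    col = rng.poisson(6.0, size=200).astype(float)
    n_copies = 5
    counts = np.tile(col[:, None], (1, n_copies))
    d = fano_population(counts)
    ff_single = np.var(col, ddof=1) / col.mean()
    assert d.ff == pytest.approx(n_copies * ff_single, rel=1e-9)
    assert d.approx == pytest.approx(d.ff, rel=1e-9)  # r = 1 exactly


def test_independent_columns_have_negligible_covariance_term():
    rng = np.random.default_rng(4)
    counts = rng.poisson(5.0, size=(100_000, 5))
    d = fano_population(counts)
    direct = counts.sum(axis=1).var(ddof=1) / counts.sum(axis=1).mean()
    assert d.ff == pytest.approx(direct, rel=1e-12)
    assert abs(d.mean_covariance) < 0.05 * d.mean_variance
    assert d.ff == pytest.approx(d.mean_variance / d.mean_count, rel=0.05)


def test_io_curve_interpolation_is_exact_at_knots_and_linear():
    lam = np.array([0.0, 1.0, 2.0, 3.0])
    mu = np.array([0.0, 10.0, 20.0, 30.0])  # linear
    var = np.array([1.0, 3.0, 2.0, 5.0])
    io = fit_io_curve(_FakeEnsemble(lam, mu, var), n_dense=301)
    for k in range(4):
        i = np.argmin(np.abs(io.lambda_grid - lam[k]))
        assert io.mu[i] == pytest.approx(mu[k])
        assert io.var[i] == pytest.approx(var[k])
    assert np.allclose(io.mu, 10.0 * io.lambda_grid)  # stays linear
    # midpoint between knots = arithmetic mean
    i = np.argmin(np.abs(io.lambda_grid - 2.5))
    assert io.var[i] == pytest.approx(0.5 * (2.0 + 5.0))
    with pytest.raises(ValueError):
        fit_io_curve(_FakeEnsemble(lam[::-1], mu, var))


def test_gain_finite_differences():
    lam = np.linspace(0.1, 3.0, 500)
    io_lin = IOCurve(lam, 10.0 * lam, np.ones_like(lam), lam, lam, lam)
    assert np.allclose(gain(io_lin), 10.0)
    io_sq = IOCurve(lam, lam**2, np.ones_like(lam), lam, lam, lam)
    assert gain(io_sq, 1.0) == pytest.approx(2.0, abs=0.01)
    io_const = IOCurve(lam, np.full_like(lam, 7.0), np.ones_like(lam), lam, lam, lam)
    assert np.allclose(gain(io_const), 0.0)
    with pytest.raises(ValueError):
        gain(io_lin, 5.0)


def test_discretized_gaussian_channel_rows():
    lam = np.linspace(0.5, 2.0, 50)
    mu = 100.0 * lam / 2.0 + 50.0
    var = 25.0 * np.ones_like(lam)
    io = IOCurve(lam, mu, var, mu, mu, lam)
    ch = discretized_gaussian_channel(io)
    assert np.max(np.abs(ch.cond_pmf.sum(axis=1) - 1.0)) < 1e-12
    assert np.all(ch.cond_pmf >= 0)
    assert np.max(np.abs(ch.row_mean() - mu)) < 0.1
    assert np.max(np.abs(ch.row_var() - var)) < 1.0


def test_degenerate_zero_variance_row_is_a_point_mass():
    lam = np.array([1.0, 2.0])
    io = IOCurve(lam, np.array([10.2, 20.0]), np.array([0.0, 4.0]), lam, lam, lam)
    ch = discretized_gaussian_channel(io)
    assert ch.cond_pmf[0, 10] == 1.0
    assert ch.cond_pmf[0].sum() == 1.0


def test_exponential_tuning_mean():
    assert exponential_tuning_mean(2.0, 0.5, 1.0, 0.0) == pytest.approx(2.0 * np.exp(0.5))
    # strictly increasing in sigma for c2 != 0
    vals = [exponential_tuning_mean(1.0, 1.0, 0.5, s) for s in (0.0, 0.5, 1.0, 2.0)]
    assert np.all(np.diff(vals) > 0)
    # adaptive quadrature oracle
    for c1, c2, lam, sig in ((1.0, 1.0, 0.0, 1.0), (2.0, -0.7, 1.5, 0.8)):
        center = lam + c2 * sig**2  # mode of the tilted Gaussian integrand
        oracle, _ = integrate.quad(
            lambda x: c1 * np.exp(c2 * x) * np.exp(-((x - lam) ** 2) / (2 * sig**2))
            / (sig * np.sqrt(2 * np.pi)),
            center - 15 * sig,
            center + 15 * sig,
        )
        assert exponential_tuning_mean(c1, c2, lam, sig) == pytest.approx(oracle, abs=1e-8)
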