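"""Population Fisher information, Cramér-Rao channel, bias extrapolation."""

import numpy as np
import pytest

import infomet as im
from infomet.decoding import (
    PopulationFisherCurve,
    bias_correct_quadratic,
    cramer_rao_channel,
    fisher_population,
    pca_project,
)


class _FakeEnsemble:
    def __init__(self, counts, lam):
        self.counts = counts
        self.lambda_grid = np.asarray(lam, float)


def _gaussian_ensemble(rng, lam, mean_fn, cov, n_trials=400):
    S, k = len(lam), cov.shape[0]
    L = np.linalg.cholesky(cov)
    out = np.empty((S, n_trials, k))
    for s, x in enumerate(lam):
        out[s] = mean_fn(x) + rng.standard_normal((n_trials, k)) @ L.T
    return out


def test_pca_projection_preserves_orthogonal_structure():
    rng = np.random.default_rng(0)
    lam = np.linspace(0.5, 2.0, 6)
    counts = rng.poisson(10.0, size=(6, 50, 8)).astype(float)
    proj = pca_project(_FakeEnsemble(counts, lam), n_components=8)
    assert np.all(np.diff(proj.explained_variance) <= 1e-9)
    # orthonormal loadings
    assert np.allclose(proj.components @ proj.components.T, np.eye(8), atol=1e-10)
    # full-rank projection preserves total variance and reconstructs exactly
    pooled = counts.reshape(-1, 8)
    recon = proj.projected.reshape(-1, 8) @ proj.components + proj.mean
    assert np.allclose(recon, pooled, atol=1e-8)
    var_orig = pooled.var(axis=0, ddof=1).sum()
    assert proj.projected.reshape(-1, 8).var(axis=0, ddof=1).sum() == pytest.approx(
        var_orig, rel=1e-9
    )


def test_pca_reduces_components_with_warning():
    rng = np.random.default_rng(1)
    counts = rng.poisson(5.0, size=(3, 4, 10)).astype(float)
    with pytest.warns(UserWarning):
        proj = pca_project(_FakeEnsemble(counts, [0.1, 0.2, 0.3]), n_components=50)
    assert proj.n_components <= 12


def test_population_fisher_reduces_to_scalar_case():
    # 1-D response, constant variance: J = mu'(lam)^2 / sigma^2
    lam = np.linspace(1.0, 2.0, 11)
    slope, sigma2 = 7.0, 4.0
    means = (slope * lam)[:, None]
    covs = np.full((11, 1, 1), sigma2)
    res = fisher_population(lambda_grid=lam, means=means, covs=covs, reg=0.0)
    assert np.allclose(res.J_pop, slope**2 / sigma2, rtol=1e-9)
    assert np.allclose(res.term_cov, 0.0, atol=1e-12)


def test_population_fisher_adds_over_independent_dimensions():
    lam = np.linspace(1.0, 2.0, 9)
    means = np.column_stack([3.0 * lam, -2.0 * lam])
    covs = np.tile(np.diag([2.0, 5.0]), (9, 1, 1))
    res = fisher_population(lambda_grid=lam, means=means, covs=covs, reg=0.0)
    expected = 3.0**2 / 2.0 + 2.0**2 / 5.0
    assert np.allclose(res.J_pop, expected, rtol=1e-9)


def test_population_fisher_matches_analytic_two_dim_oracle():
    # f(lam) = (a lam, b lam^2), Sigma(lam) = [[1 + c lam, r], [r, 2]]
    a, b, c, r = 3.0, 1.5, 0.4, 0.3
    h = 1e-4
    lam = np.arange(1.0, 1.5, h)
    means = np.column_stack([a * lam, b * lam**2])
    covs = np.empty((lam.size, 2, 2))
    covs[:, 0, 0] = 1.0 + c * lam
    covs[:, 0, 1] = covs[:, 1, 0] = r
    covs[:, 1, 1] = 2.0
    res = fisher_population(lambda_grid=lam, means=means, covs=covs, reg=0.0)
    i = lam.size // 2
    x = lam[i]
    fp = np.array([a, 2 * b * x])
    Sig = np.array([[1.0 + c * x, r], [r, 2.0]])
    dSig = np.array([[c, 0.0], [0.0, 0.0]])
    Si = np.linalg.inv(Sig)
    oracle = fp @ Si @ fp + 0.5 * np.trace(Si @ dSig @ Si @ dSig)
    assert res.J_pop[i] == pytest.approx(oracle, abs=1e-8)
    assert np.all(res.term_cov >= 0)


def test_population_fisher_from_sampled_gaussian_trials():
    rng = np.random.default_rng(2)
    lam = np.linspace(1.0, 2.0, 9)
    cov = np.array([[2.0, 0.5], [0.5, 1.0]])
    counts = _gaussian_ensemble(rng, lam, lambda x: np.array([5.0 * x, -3.0 * x]), cov, 800)
    proj_like = _FakeEnsemble(counts, lam)
    proj = pca_project(proj_like, n_components=2)
    res = fisher_population(proj)
    slope = np.array([5.0, -3.0])
    expected = slope @ np.linalg.inv(cov) @ slope
    assert np.median(res.J_pop) == pytest.approx(expected, rel=0.25)


def test_cramer_rao_channel_rows_and_variance():
    lam = np.linspace(0.0, 10.0, 400)
    J = np.full(lam.size, 1.0)  # sd 1.0, well resolved by the grid
    curve = PopulationFisherCurve(lam, J, J, np.zeros_like(J))
    ch = cramer_rao_channel(curve)
    assert np.max(np.abs(ch.cond_pmf.sum(axis=1) - 1.0)) < 1e-12
    mid = lam.size // 2
    var = ch.cond_pmf[mid] @ (lam - lam[mid]) ** 2
    assert var == pytest.approx(1.0 / J[mid], rel=0.02)
    # scaling J by 4 halves the conditional standard deviation
    ch4 = cramer_rao_channel(PopulationFisherCurve(lam, 4 * J, 4 * J, np.zeros_like(J)))
    var4 = ch4.cond_pmf[mid] @ (lam - lam[mid]) ** 2
    assert np.sqrt(var4) == pytest.approx(0.5 * np.sqrt(var), rel=0.05)


def test_cramer_rao_channel_drops_degenerate_points():
    lam = np.linspace(0.0, 1.0, 5)
    J = np.array([0.0, 4.0, 4.0, 4.0, 4.0])
    with pytest.warns(UserWarning):
        ch = cramer_rao_channel(PopulationFisherCurve(lam, J, J, np.zeros_like(J)))
    assert ch.cond_pmf.shape == (4, 5)


def test_bias_extrapolation_recovers_quadratic_law():
    # identical estimates at every trial count: no bias
    E0, a, b = bias_correct_quadratic(2.5, 2.5, 2.5, k=1000)
    assert (E0, a, b) == pytest.approx((2.5, 0.0, 0.0))
    # forward-generate from known coefficients, then invert
    true = (2.0, 50.0, 1000.0)
    k = 10800
    es = [true[0] + true[1] / j + true[2] / j**2 for j in (k, k / 2, k / 4)]
    E0, a, b = bias_correct_quadratic(*es, k=k)
    assert (E0, a, b) == pytest.approx(true, rel=1e-9)
    with pytest.raises(ValueError):
        bias_correct_quadratic(1.0, 1.0, 1.0, k=0)


def test_vector_readout_carries_at_least_the_summed_information():
    # anti-correlated noise: the sum discards information the vector keeps
    rng = np.random.default_rng(3)
    lam = np.linspace(1.0, 2.0, 9)
    cov = np.array([[1.0, -0.6], [-0.6, 1.0]])
    counts = _gaussian_ensemble(rng, lam, lambda x: np.array([4.0 * x, 4.0 * x]), cov, 600)
    proj = pca_project(_FakeEnsemble(counts, lam), n_components=2)
    J_vec = fisher_population(proj).J_pop
    summed = counts.sum(axis=2)
    mu = summed.mean(axis=1)
    var = summed.var(axis=1, ddof=1)
    dmu = np.gradient(mu, lam)
    J_sum = dmu**2 / var
    assert np.median(J_vec) > np.median(J_sum)
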