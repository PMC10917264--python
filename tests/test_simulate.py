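"""LIF integrator contracts: closed forms, determinism, input accounting."""

import numpy as np
import pytest

import infomet as im
from infomet.simulate import find_lambda_max, simulate_trial, trial_seed


def _single_neuron_config(**kw):
    return im.NetworkConfig(
        n_ext=1,
        n_exc=1,
        n_inh=0,
        P_ext=1.0,
        P_rec=0.0,
        a_rec=0.0,
        background_on=False,
        warmup=0.0,
        **kw,
    )


def _reference_rate(cfg, i_inject, duration_ms, dt):
    """Independent high-resolution forward integrator (plain Python)."""
    v = cfg.E_L
    spikes = 0
    steps = int(round(duration_ms / dt))
    for _ in range(steps):
        v += dt * (cfg.g_L * (cfg.E_L - v) + i_inject) / cfg.C_m
        if v >= cfg.theta_exc:
            v = cfg.E_L
            spikes += 1
    return spikes / duration_ms * 1000.0  # Hz


def test_constant_current_rate_matches_closed_form_and_fine_integrator():
    cfg = _single_neuron_config()
    conn = im.build_connectivity(cfg, seed=0)
    i_inject = 300.0  # pA, above rheobase g_L * (theta - E_L) = 250 pA
    sd = simulate_trial(cfg, conn, 0.0, 10.0, seed=1, i_inject=i_inject)
    rate = sd.counts[0] / 10.0
    # closed-form LIF frequency
    tau_m = cfg.C_m / cfg.g_L
    v_inf = cfg.E_L + i_inject / cfg.g_L
    period = tau_m * np.log((v_inf - cfg.E_L) / (v_inf - cfg.theta_exc))
    assert rate == pytest.approx(1000.0 / period, rel=0.01)
    # refined-step (dt/20) reference integrator
    assert rate == pytest.approx(_reference_rate(cfg, i_inject, 10_000.0, cfg.dt / 20), rel=0.01)


def test_quiet_network_stays_at_rest():
    cfg = _single_neuron_config()
    conn = im.build_connectivity(cfg, seed=0)
    sd = simulate_trial(cfg, conn, 0.0, 1.0, seed=3)
    assert sd.counts.sum() == 0
    assert sd.i_na[0] == 0.0
    assert sd.ext_count == 0


def test_equal_seeds_give_bit_identical_trials():
    cfg = im.NetworkConfig.miniature(P_ext=0.5, a_rec=0.2)
    conn = im.build_connectivity(cfg, seed=3)
    a = simulate_trial(cfg, conn, 1.0, 1.0, seed=7)
    b = simulate_trial(cfg, conn, 1.0, 1.0, seed=7)
    assert np.array_equal(a.counts, b.counts)
    assert a.ext_count == b.ext_count
    assert np.array_equal(a.i_na, b.i_na)
    assert all(np.array_equal(x, y) for x, y in zip(a.times, b.times))


def test_spike_times_are_within_window_and_increasing(tiny_config):
    cfg = tiny_config
    conn = im.build_connectivity(cfg, seed=5)
    sd = simulate_trial(cfg, conn, 2.0, 0.5, seed=9)
    assert sd.counts.sum() > 0
    for t in sd.times:
        if t.size:
            assert t[0] >= 0.0 and t[-1] <= 500.0
            assert np.all(np.diff(t) > 0)
    raster = sd.raster()
    assert raster.shape[0] == sd.counts.sum()


def test_zero_recurrent_amplitude_equals_unwired_recurrence():
    # a_rec = 0 must behave exactly like a feedforward network (P_rec = 0)
    base = dict(n_ext=100, n_exc=40, n_inh=10, P_ext=0.5, background_on=False, warmup=0.0)
    cfg_a = im.NetworkConfig.miniature(**base, a_rec=0.0, P_rec=0.2)
    cfg_b = im.NetworkConfig.miniature(**base, a_rec=0.3, P_rec=0.0)
    sd_a = simulate_trial(cfg_a, im.build_connectivity(cfg_a, seed=1), 2.0, 1.0, seed=4)
    sd_b = simulate_trial(cfg_b, im.build_connectivity(cfg_b, seed=1), 2.0, 1.0, seed=4)
    assert np.array_equal(sd_a.counts, sd_b.counts)


def test_external_population_rate_scales_inversely_with_p_ext():
    lam = 1.0  # kHz mean input per neuron
    for P_ext, expect in ((1.0, 1000.0), (0.5, 2000.0)):
        cfg = im.NetworkConfig.miniature(P_ext=P_ext, background_on=False, warmup=0.0)
        conn = im.build_connectivity(cfg, seed=1)
        counts = [
            simulate_trial(cfg, conn, lam, 1.0, seed=10 + k, record_times=False).ext_count
            for k in range(4)
        ]
        assert np.mean(counts) == pytest.approx(expect, rel=0.05)


def test_stronger_inhibitory_scaling_suppresses_output():
    # raising alpha at fixed a_rec makes the net recurrent current more
    # hyperpolarizing, so the driven output rate must drop
    rates = {}
    for alpha in (15.0, 25.0):
        cfg = im.NetworkConfig.miniature(P_ext=0.5, a_rec=0.4, alpha=alpha)
        conn = im.build_connectivity(cfg, seed=2)
        out = [
            simulate_trial(cfg, conn, 2.0, 1.0, seed=20 + k, record_times=False).counts.sum()
            for k in range(3)
        ]
        rates[alpha] = np.mean(out)
    assert rates[25.0] < rates[15.0]


def test_shared_input_increases_correlations_and_population_fano():
    # fixed in-degree isolates the input-overlap effect from gain changes
    stats = {}
    for P_ext in (0.1, 0.9):
        cfg = im.NetworkConfig.miniature(
            n_ext=100,
            n_exc=60,
            n_inh=15,
            P_ext=P_ext,
            a_rec=0.0,
            connection_mode="fixed_in_degree",
        )
        conn = im.build_connectivity(cfg, seed=3)
        counts = np.stack(
            [
                simulate_trial(cfg, conn, 2.0, 1.0, seed=trial_seed(33, 0, k),
                               record_times=False).counts
                for k in range(60)
            ]
        )
        stats[P_ext] = (
            im.mean_pairwise_correlation(counts),
            im.fano_population(counts).ff,
        )
    assert stats[0.9][0] > stats[0.1][0]
    assert stats[0.9][1] > stats[0.1][1]


def test_find_lambda_max_linear_surrogate():
    assert find_lambda_max(rate_fn=lambda lam: 10.0 * lam, target_rate=30.0) == pytest.approx(
        3.0, rel=0.02
    )


def test_find_lambda_max_error_contracts():
    with pytest.raises(ValueError):
        find_lambda_max(rate_fn=lambda lam: 10.0 * lam, target_rate=0.0)
    with pytest.raises(ValueError):  # spontaneous rate already above target
        find_lambda_max(rate_fn=lambda lam: 5.0 + lam, target_rate=2.0)
    with pytest.raises(ValueError):  # saturating response never brackets
        find_lambda_max(rate_fn=lambda lam: lam / (1.0 + lam), target_rate=2.0)


def test_find_lambda_max_resimulation_hits_target(tiny_config):
    cfg = tiny_config.replace(background_on=True)
    conn = im.build_connectivity(cfg, seed=6)
    target = 0.03 * cfg.n_net  # kHz
    lam_max = find_lambda_max(cfg, conn, trials_per_probe=4, base_seed=55)
    out = [
        simulate_trial(cfg, conn, lam_max, 1.0, seed=trial_seed(56, 0, k),
                       record_times=False).counts.sum() / 1000.0
        for k in range(8)
    ]
    assert np.mean(out) == pytest.approx(target, rel=0.1)


def test_run_ensemble_contracts(tiny_config):
    cfg = tiny_config
    conn = im.build_connectivity(cfg, seed=1)
    ens = im.run_ensemble(cfg, conn, lambda_max=2.0, n_trials=4, n_stimuli=5, base_seed=9)
    assert ens.lambda_grid[0] == 0.0 and ens.lambda_grid[-1] == 2.0
    assert ens.counts.shape == (5, 4, cfg.n_net)
    # stimulus 0 in a quiet fixture (background off): no input at all
    assert ens.counts[0].sum() == 0
    # full reproducibility from the base seed
    ens2 = im.run_ensemble(cfg, conn, lambda_max=2.0, n_trials=4, n_stimuli=5, base_seed=9)
    assert np.array_equal(ens.counts, ens2.counts)
    assert np.array_equal(ens.i_na_exc, ens2.i_na_exc)
    with pytest.raises(ValueError):
        im.run_ensemble(cfg, conn, 2.0, n_trials=1, n_stimuli=5, base_seed=9)
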