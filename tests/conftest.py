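"""Shared fixtures.

The expensive fixture is ``mini_grid``: a quarter-scale-network pipeline run
(stimulus ensemble -> IO curve -> cost -> channel -> efficiency) at three
recurrence strengths with fully shared input (P_ext = 1), computed once per
session and reused by the acceptance tests for the low-noise comparison and
for the shape of the efficiency-vs-recurrence curve.
"""

from __future__ import annotations

import numpy as np
import pytest

import infomet as im
from infomet.lownoise import efficiency_low_noise, fisher_curve


@pytest.fixture(scope="session")
def tiny_config():
    """A very small quiet network for fast structural tests."""
    return im.NetworkConfig.miniature(
        n_ext=40, n_exc=20, n_inh=5, P_ext=0.5, a_rec=0.2, background_on=False
    )


@pytest.fixture(scope="session")
def mini_grid():
    """Efficiency pipeline at a_rec in {0, 0.4, 1.2} nS, P_ext = 1.

    1/8-scale network (150 ext / 100 exc / 25 inh); the a_rec grid is the
    ~4x-scaled counterpart of the full-scale {0, 0.1, 0.3} nS range, matching
    the 4x smaller recurrent in-degree, and stays inside the dynamically
    stable range of the scaled model.
    """
    results = {}
    for a_rec in (0.0, 0.4, 1.2):
        cfg = im.NetworkConfig.miniature(
            n_ext=150, n_exc=100, n_inh=25, a_rec=a_rec, P_ext=1.0
        )
        conn = im.build_connectivity(cfg, seed=11)
        lam_max = im.find_lambda_max(cfg, conn, trials_per_probe=2, base_seed=101)
        ens = im.run_ensemble(
            cfg, conn, lam_max, n_trials=80, n_stimuli=10, base_seed=101
        )
        io = im.fit_io_curve(ens, n_dense=320)
        cost = im.activity_cost(ens, io, cfg)
        channel = im.discretized_gaussian_channel(io)
        eff = im.info_metabolic_efficiency(
            channel, cost.w, tol=1e-4, rtol=1e-4, ba_max_iter=30_000
        )
        E_low, _, _ = efficiency_low_noise(channel, cost.w, fisher_curve(io))
        results[a_rec] = {
            "config": cfg,
            "ensemble": ens,
            "io": io,
            "cost": cost,
            "channel": channel,
            "E": eff.efficiency,
            "E_low": E_low,
        }
    return results
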