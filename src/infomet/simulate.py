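"""Forward simulation of the spiking network.

Each excitatory/inhibitory neuron is a conductance-based leaky
integrate-and-fire unit,

    C_m dV/dt = g_L (E_L - V) + I_rec + I_ext + I_bcg,

with recurrent, external and background currents carried by exponentially
decaying synaptic conductances.  A presynaptic spike adds the connection
weight to the target conductance (delta pulse into the exponential synapse);
the background drive is an Ornstein-Uhlenbeck conductance pair (excitatory
and inhibitory) updated with the exact discrete-time OU recursion.  When V
crosses the population threshold the neuron spikes and V resets to E_L.  No
refractory period and no synaptic delays: a spike takes effect on the next
integration step.

Numerics: forward Euler for the membrane equation at ``config.dt`` (default
0.1 ms), exact exponential decay for the synaptic conductances, exact OU
update for the background.  The external Poisson population is sampled per
step as a Poisson number of population spikes assigned to uniformly chosen
external neurons, which is an exact sampling of n_ext independent Poisson
processes.  OU innovations are pre-generated in chunks (single-precision,
from a PCG stream separate from the in-kernel spike stream) so the two
randomness sources form independent named streams per trial.

The OU background is *not* clipped by default: negative conductance
excursions (frequent for the inhibitory background, whose stationary
standard deviation is comparable to its mean) transiently turn the
inhibitory term into net depolarizing drive, and this is what sustains the
sub-hertz spontaneous activity of the network at zero stimulus.  Set
``config.clip_background = True`` to clamp the background conductances at
zero at use time instead (the OU state itself is never clipped); with
clipping the spontaneous rate collapses by more than an order of magnitude.

For the metabolic-cost accounting the integrator also accumulates, per
neuron, the time-averaged Na+ component of the excitatory synaptic current
(external + recurrent excitatory + excitatory background conductance), see
:mod:`infomet.cost`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import NetworkConfig
from .connectivity import ConnectivitySet, external_rate_per_neuron, ou_background_params
from .cost import E_NA, E_K, sodium_fraction

__all__ = [
    "SpikeData",
    "TrialEnsemble",
    "simulate_trial",
    "find_lambda_max",
    "run_ensemble",
    "trial_seed",
]

_STATUS_OK = 0
_STATUS_OVERFLOW = 1
_STATUS_NUMERIC = 2
_CHUNK = 5000  # integration steps per noise chunk


@njit(cache=True)
def _simulate_chunk(
    do_seed,
    spike_seed,
    step0,
    steps,
    steps_warm,
    dt,
    n_exc,
    n_inh,
    n_ext,
    Cm,
    gL,
    EL,
    Ee,
    Ei,
    th_exc,
    th_inh,
    d_exc,
    d_inh,
    ext_indptr,
    ext_indices,
    w_ext,
    exc_indptr,
    exc_indices,
    w_exc,
    inh_indptr,
    inh_indices,
    w_inh,
    k_mean,
    bcg_on,
    clip_bcg,
    mu_be,
    sc_be,
    mu_bi,
    sc_bi,
    noise_e,
    noise_i,
    i_inject,
    na_frac,
    e_na,
    record_times,
    # mutable state
    V,
    g_ext,
    g_exc,
    g_inh,
    g_be,
    g_bi,
    counts,
    ina,
    fired,
    spike_neuron,
    spike_time,
    counters,  # [ext_count, nsp]
):
    if do_seed:
        np.random.seed(spike_seed)
    n = n_exc + n_inh
    max_spikes = spike_neuron.shape[0]
    nsp = counters[1]
    status = _STATUS_OK
    inv_cm_dt = dt / Cm
    for tl in range(steps):
        t = step0 + tl
        counting = t >= steps_warm
        for i in range(n):
            ge_tot = g_ext[i] + g_exc[i]
            gbe = g_be[i]
            gbi = g_bi[i]
            if clip_bcg:
                if gbe < 0.0:
                    gbe = 0.0
                if gbi < 0.0:
                    gbi = 0.0
            v = V[i]
            cur = (
                gL * (EL - v)
                + (ge_tot + gbe) * (Ee - v)
                + (g_inh[i] + gbi) * (Ei - v)
                + i_inject
            )
            if counting:
                # Na+ accounting never counts a negative background excursion
                ge_na = ge_tot + gbe if gbe > 0.0 else ge_tot
                ina[i] += na_frac * ge_na * (v - e_na)
            v = v + cur * inv_cm_dt
            th = th_exc if i < n_exc else th_inh
            if v >= th:
                v = EL
                fired[i] = True
                if counting:
                    counts[i] += 1
                    if record_times:
                        if nsp < max_spikes:
                            spike_neuron[nsp] = i
                            spike_time[nsp] = (t - steps_warm) * dt
                            nsp += 1
                        else:
                            status = _STATUS_OVERFLOW
            else:
                fired[i] = False
            V[i] = v
            g_ext[i] *= d_exc
            g_exc[i] *= d_exc
            g_inh[i] *= d_inh
            if bcg_on:
                g_be[i] = mu_be + (g_be[i] - mu_be) * d_exc + sc_be * noise_e[tl, i]
                g_bi[i] = mu_bi + (g_bi[i] - mu_bi) * d_inh + sc_bi * noise_i[tl, i]
        for i in range(n_exc):
            if fired[i]:
                for k in range(exc_indptr[i], exc_indptr[i + 1]):
                    g_exc[exc_indices[k]] += w_exc
        for i in range(n_inh):
            if fired[n_exc + i]:
                for k in range(inh_indptr[i], inh_indptr[i + 1]):
                    g_inh[inh_indices[k]] += w_inh
        if k_mean > 0.0:
            K = np.random.poisson(k_mean)
            for _ in range(K):
                j = int(np.random.random() * n_ext)
                if j >= n_ext:
                    j = n_ext - 1
                for k in range(ext_indptr[j], ext_indptr[j + 1]):
                    g_ext[ext_indices[k]] += w_ext
            if counting:
                counters[0] += K
        if tl % 500 == 0:
            for i in range(n):
                if not np.isfinite(V[i]):
                    counters[1] = nsp
                    return _STATUS_NUMERIC
    counters[1] = nsp
    return status


@dataclass
class SpikeData:
    """Spikes and current bookkeeping of one trial.

    ``times`` holds per-neuron spike times in ms from the start of the
    counting window (excitatory neurons first, then inhibitory);
    ``i_na`` the time-averaged Na+ synaptic current per neuron (pA, inward
    negative); ``ext_count`` the number of external-population spikes during
    the window.
    """

    times: list
    counts: np.ndarray
    i_na: np.ndarray
    ext_count: int
    duration: float  # s
    lambda_ext: float  # kHz
    seed: int
    n_exc: int
    n_inh: int

    @property
    def rates(self) -> np.ndarray:
        """Per-neuron firing rates in Hz."""
        return self.counts / self.duration

    def raster(self) -> np.ndarray:
        """(n_spikes, 2) array of (neuron_id, time_ms) rows, time-sorted."""
        rows = [
            np.column_stack([np.full(t.size, i, dtype=float), t])
            for i, t in enumerate(self.times)
            if t.size
        ]
        if not rows:
            return np.empty((0, 2))
        out = np.concatenate(rows)
        return out[np.argsort(out[:, 1], kind="stable")]


def _kernel_args(config: NetworkConfig, conn: ConnectivitySet, lambda_ext: float) -> dict:
    ext_indptr, ext_indices = conn.presyn_targets("ext")
    exc_indptr, exc_indices = conn.presyn_targets("exc")
    inh_indptr, inh_indices = conn.presyn_targets("inh")
    if lambda_ext > 0:
        lam0 = external_rate_per_neuron(lambda_ext, config)  # kHz per ext neuron
        k_mean = config.n_ext * lam0 * config.dt  # expected pop spikes per step
    else:
        k_mean = 0.0
    mu_be, sg_be = ou_background_params(config.a_bcg_exc, config.tau_exc, config.lambda_bcg_exc)
    mu_bi, sg_bi = ou_background_params(config.a_bcg_inh, config.tau_inh, config.lambda_bcg_inh)
    d_exc = float(np.exp(-config.dt / config.tau_exc))
    d_inh = float(np.exp(-config.dt / config.tau_inh))
    return dict(
        dt=config.dt,
        n_exc=config.n_exc,
        n_inh=config.n_inh,
        n_ext=config.n_ext,
        Cm=config.C_m,
        gL=config.g_L,
        EL=config.E_L,
        Ee=config.E_e,
        Ei=config.E_i,
        th_exc=config.theta_exc,
        th_inh=config.theta_inh,
        d_exc=d_exc,
        d_inh=d_inh,
        ext_indptr=ext_indptr,
        ext_indices=ext_indices,
        w_ext=config.a_ext,
        exc_indptr=exc_indptr,
        exc_indices=exc_indices,
        w_exc=config.a_rec,
        inh_indptr=inh_indptr,
        inh_indices=inh_indices,
        w_inh=config.a_inh,
        k_mean=k_mean,
        bcg_on=config.background_on,
        clip_bcg=config.clip_background,
        mu_be=mu_be,
        sc_be=sg_be * float(np.sqrt(1.0 - d_exc**2)),
        mu_bi=mu_bi,
        sc_bi=sg_bi * float(np.sqrt(1.0 - d_inh**2)),
        na_frac=sodium_fraction(config.E_e, E_NA, E_K),
        e_na=E_NA,
    )


def simulate_trial(
    config: NetworkConfig,
    conn: ConnectivitySet,
    lambda_ext: float,
    duration: float,
    seed: int,
    record_times: bool = True,
    i_inject: float = 0.0,
) -> SpikeData:
    """Simulate one trial and count spikes over a window of ``duration`` s.

    A warm-up interval of ``config.warmup`` s (initial conditions: V = E_L,
    synapses at zero, OU background at its mean) is simulated first and
    discarded.  Identical arguments produce bit-identical output.

    ``i_inject`` adds a constant current (pA) to every neuron; zero in the
    model proper, useful for calibration against closed-form LIF rates.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if lambda_ext < 0:
        raise ValueError("lambda_ext must be >= 0")
    steps_count = int(round(duration * 1000.0 / config.dt))
    steps_warm = int(round(config.warmup * 1000.0 / config.dt))
    total_steps = steps_warm + steps_count
    args = _kernel_args(config, conn, lambda_ext)
    n = config.n_net
    cap = int(n * duration * 300) + 1024 if record_times else 1
    while True:
        counts = np.zeros(n, np.int64)
        ina = np.zeros(n)
        spike_neuron = np.empty(cap, np.int64)
        spike_time = np.empty(cap, np.float64)
        counters = np.zeros(2, np.int64)
        state = dict(
            V=np.full(n, config.E_L),
            g_ext=np.zeros(n),
            g_exc=np.zeros(n),
            g_inh=np.zeros(n),
            g_be=np.full(n, args["mu_be"] if config.background_on else 0.0),
            g_bi=np.full(n, args["mu_bi"] if config.background_on else 0.0),
            fired=np.zeros(n, np.bool_),
        )
        noise_rng = np.random.Generator(
            np.random.SFC64(np.random.SeedSequence([int(seed), 7]))
        )
        status = _STATUS_OK
        step0 = 0
        empty = np.zeros((1, n))
        while step0 < total_steps:
            steps = min(_CHUNK, total_steps - step0)
            if config.background_on:
                noise_e = noise_rng.standard_normal((steps, n))
                noise_i = noise_rng.standard_normal((steps, n))
            else:
                noise_e = noise_i = empty
            status = _simulate_chunk(
                do_seed=step0 == 0,
                spike_seed=int(seed) % (2**31),
                step0=step0,
                steps=steps,
                steps_warm=steps_warm,
                noise_e=noise_e,
                noise_i=noise_i,
                i_inject=i_inject,
                record_times=record_times,
                counts=counts,
                ina=ina,
                spike_neuron=spike_neuron,
                spike_time=spike_time,
                counters=counters,
                **state,
                **args,
            )
            if status != _STATUS_OK:
                break
            step0 += steps
        if status == _STATUS_NUMERIC:
            raise RuntimeError(
                f"membrane potential diverged (lambda_ext={lambda_ext} kHz, "
                f"seed={seed}); check dt and synaptic amplitudes"
            )
        if status == _STATUS_OVERFLOW and cap < n * steps_count:
            cap *= 4
            continue
        break
    nsp = int(counters[1])
    if record_times:
        order = np.argsort(spike_neuron[:nsp], kind="stable")
        neuron_sorted = spike_neuron[:nsp][order]
        time_sorted = spike_time[:nsp][order]
        splits = np.searchsorted(neuron_sorted, np.arange(1, n))
        times = [np.ascontiguousarray(a) for a in np.split(time_sorted, splits)]
    else:
        times = [np.empty(0) for _ in range(n)]
    return SpikeData(
        times=times,
        counts=counts,
        i_na=ina / steps_count,
        ext_count=int(counters[0]),
        duration=duration,
        lambda_ext=lambda_ext,
        seed=seed,
        n_exc=config.n_exc,
        n_inh=config.n_inh,
    )


def trial_seed(base_seed: int, stimulus: int, trial: int) -> int:
    """Deterministic per-trial seed derived from one base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(stimulus), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))


def find_lambda_max(
    config: NetworkConfig | None = None,
    conn: ConnectivitySet | None = None,
    target_rate: float | None = None,
    trials_per_probe: int = 3,
    base_seed: int = 0,
    rel_tol: float = 0.02,
    ceiling: float | None = None,
    rate_fn=None,
    max_iter: int = 40,
) -> float:
    """Input intensity (kHz) at which the mean total output rate hits target.

    ``target_rate`` defaults to 30 Hz per neuron, i.e. 0.03 * n_net kHz of
    total population rate (30 kHz for the full 1000-neuron network).
    Bracketing by doubling followed by bisection; assumes the output is
    monotone nondecreasing in lambda_ext.  ``rate_fn`` replaces the simulated
    probe with an arbitrary lambda -> kHz map (surrogates, tests).
    """
    if rate_fn is None:
        if config is None or conn is None:
            raise ValueError("need (config, conn) or rate_fn")
        if target_rate is None:
            target_rate = 0.03 * config.n_net
        probe_counter = [0]

        def rate_fn(lam: float) -> float:
            rates = []
            for _ in range(trials_per_probe):
                probe_counter[0] += 1
                seed = trial_seed(base_seed, 1_000_000, probe_counter[0])
                sd = simulate_trial(
                    config, conn, lam, config.Delta_T, seed, record_times=False
                )
                rates.append(sd.counts.sum() / sd.duration / 1000.0)  # kHz
            return float(np.mean(rates))

    elif target_rate is None:
        target_rate = 30.0
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if ceiling is None:
        ceiling = 1000.0 * target_rate

    r0 = rate_fn(0.0)
    if r0 >= target_rate:
        raise ValueError(
            f"output at lambda_ext=0 ({r0:.3g} kHz) already >= target ({target_rate} kHz)"
        )
    hi = target_rate / 2.0
    r_hi = rate_fn(hi)
    while r_hi < target_rate:
        hi *= 2.0
        if hi > ceiling:
            raise ValueError(f"no bracket found below ceiling {ceiling} kHz")
        r_hi = rate_fn(hi)
    lo = hi / 2.0 if hi > target_rate / 2.0 else 0.0
    best, best_err = hi, abs(r_hi - target_rate)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rate_fn(mid)
        err = abs(r_mid - target_rate)
        if err < best_err:
            best, best_err = mid, err
        if err <= rel_tol * target_rate:
            return mid
        if r_mid < target_rate:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"lambda_max search stopped at relative error {best_err / target_rate:.3f}",
        stacklevel=2,
    )
    return best


@dataclass
class TrialEnsemble:
    """Spike counts over repeated trials at each stimulus intensity.

    ``counts`` has shape (n_stimuli, n_trials, n_neurons) with one frozen
    connectivity across all stimuli and trials.  ``i_na_exc`` / ``i_na_inh``
    are the per-stimulus mean Na+ synaptic currents of a single excitatory /
    inhibitory neuron (pA, inward negative), required by the cost model.
    """

    lambda_grid: np.ndarray  # kHz, equidistant from 0 to lambda_max
    counts: np.ndarray  # (S, T, N) uint32
    i_na_exc: np.ndarray  # (S,) pA
    i_na_inh: np.ndarray  # (S,) pA
    config: NetworkConfig
    connectivity_seed: int
    base_seed: int
    delta_T: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_stimuli, n_trials, n_neurons)")

    @property
    def n_stimuli(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """(S, T) summed population count per trial."""
        return self.counts.sum(axis=2)

    def population_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and unbiased variance of the total count per stimulus."""
        tot = self.total_counts()
        return tot.mean(axis=1), tot.var(axis=1, ddof=1)

    def mean_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-stimulus mean single-neuron rate (Hz) for exc and inh."""
        n_exc = self.config.n_exc
        mu_exc = self.counts[:, :, :n_exc].mean(axis=(1, 2)) / self.delta_T
        mu_inh = self.counts[:, :, n_exc:].mean(axis=(1, 2)) / self.delta_T
        return mu_exc, mu_inh


def run_ensemble(
    config: NetworkConfig,
    conn: ConnectivitySet,
    lambda_max: float,
    n_trials: int,
    n_stimuli: int = 31,
    base_seed: int = 0,
) -> TrialEnsemble:
    """Simulate ``n_trials`` independent trials at each of ``n_stimuli``
    equidistant stimulus intensities in [0, lambda_max].

    Trial seeds are derived deterministically from ``base_seed``, so the
    ensemble is reproducible as a whole and any single trial in isolation.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 (variance undefined otherwise)")
    if n_stimuli < 2:
        raise ValueError("n_stimuli must be >= 2")
    if lambda_max <= 0:
        raise ValueError("lambda_max must be > 0")
    grid = np.linspace(0.0, lambda_max, n_stimuli)
    n = config.n_net
    counts = np.zeros((n_stimuli, n_trials, n), np.uint32)
    i_na_exc = np.zeros(n_stimuli)
    i_na_inh = np.zeros(n_stimuli)
    for s, lam in enumerate(grid):
        acc_exc = 0.0
        acc_inh = 0.0
        for t in range(n_trials):
            sd = simulate_trial(
                config,
                conn,
                float(lam),
                config.Delta_T,
                trial_seed(base_seed, s, t),
                record_times=False,
            )
            counts[s, t] = sd.counts
            acc_exc += sd.i_na[: config.n_exc].mean()
            acc_inh += sd.i_na[config.n_exc :].mean()
        i_na_exc[s] = acc_exc / n_trials
        i_na_inh[s] = acc_inh / n_trials
    return TrialEnsemble(
        lambda_grid=grid,
        counts=counts,
        i_na_exc=i_na_exc,
        i_na_inh=i_na_inh,
        config=config,
        connectivity_seed=conn.seed,
        base_seed=base_seed,
        delta_T=config.Delta_T,
    )
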