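# Methods

`infomet` studies how shared feedforward input and inhibition-dominated
recurrence shape the amount of information a cortical micro-population can
transmit per molecule of ATP.  This note documents the model, the numerical
choices, and what the desk-scale defaults do and do not show.

## Network model

Three populations: `n_ext` external Poisson neurons, `n_exc` excitatory and
`n_inh` inhibitory conductance-based leaky integrate-and-fire neurons,

    C_m dV/dt = g_L (E_L − V) + g_exc_tot (E_e − V) + g_inh_tot (E_i − V),

with exponentially decaying synaptic conductances (τ_exc = τ_inh = 5 ms): a
presynaptic spike adds the connection amplitude to the target conductance.
Spike at V ≥ θ (θ_exc = −55 mV, θ_inh = −60 mV), reset to E_L = −80 mV, no
refractory period, no synaptic delays (a spike acts on the next step).
Defaults are the reference cortical-patch values (1000/800/200 neurons,
C_m = 150 pF, g_L = 10 nS, E_e = 0 mV, E_i = −80 mV, a_ext = 1 nS,
P_rec = 0.2, α = 20 so a_inh = 20·a_rec).

Wiring is Bernoulli per (post, pre) pair with probabilities `P_ext`
(external) and `P_rec` (all four recurrent blocks); `fixed_in_degree` mode
makes every neuron receive exactly round(n_ext·P_ext) external synapses
(the k largest entries of the row of the uniform matrix), which isolates the
input-overlap effect from in-degree heterogeneity.  Because the external
random matrix is drawn first from the connectivity seed, it is identical
across `P_ext` values at a fixed seed.

The stimulus λ_ext (kHz) is the *mean summed external input rate per
neuron*: each external neuron fires at λ_ext/(n_ext·P_ext), so the mean
drive is independent of P_ext while the total external population rate —
and with it the external spike cost — scales as λ_ext/P_ext.  Shared input
(high P_ext) is therefore metabolically cheap but correlates the neurons.

### Background input

Unmodelled cortex is represented by one excitatory and one inhibitory
Ornstein–Uhlenbeck conductance per neuron whose mean a·τ·λ and stationary
standard deviation a·√(λτ/2) match exponential Poisson shot noise with
rates λ_bcg,exc = 0.5 kHz (amplitude a_ext) and λ_bcg,inh = 0.125 kHz
(amplitude α·a_ext), giving a 5:1 inhibitory-to-excitatory mean conductance
ratio.

The OU conductances are **not clipped at zero** by default.  The inhibitory
background has σ ≈ μ, so ~13% of the time its conductance is negative;
because E_i = E_L, a negative inhibitory conductance transiently
destabilizes the membrane (the effective conductance drops and the
effective reversal depolarizes), and these excursions are what drive the
sub-hertz spontaneous activity: with the default parameters the full-size
network fires at ≈ 0.9 Hz at λ_ext = 0 (≈ 0.6 Hz excitatory, ≈ 2 Hz
inhibitory), inside the expected 0.5–1 Hz band.  With `clip_background =
True` (conductances clamped at zero at use time, the OU state untouched)
the same parameters yield ≈ 0.02 Hz: Gaussian-symmetric background noise
clipped at zero simply cannot push the membrane 12–17 mV above its resting
point often enough.  We therefore treat the unclipped process as the model
definition and expose clipping as an option.  The Na⁺-cost bookkeeping
always ignores negative background excursions (no negative influx).

### Integration

Forward Euler for the membrane at dt = 0.1 ms; exact exponential decay for
synaptic conductances; exact discrete-time OU recursion for the background.
The integrator is validated against the closed-form constant-current LIF
rate and an independent dt/20 reference integrator (≤ 1% rate error).
Initial conditions V = E_L, synapses at zero, OU at its mean; a 200 ms
warm-up is discarded before the Δ_T = 1 s counting window.  Per-trial
randomness uses two named streams derived from the trial seed — a
bulk-generated SFC64 stream for the OU innovations and a Mersenne-Twister
in-kernel stream for external/recurrent spikes — so any single trial is
bit-reproducible in isolation.

## Stimulus–response channel

For each parameter set, λ_max is found by bisection so the mean total
output rate reaches 30 Hz per neuron (30 kHz for the full network), the
stimulus range [0, λ_max] is sampled at equidistant intensities, and the
mean μ(λ) and unbiased variance σ²(λ) of the total spike count per window
are linearly interpolated onto a dense grid.  The channel f(n|λ) is the
discretized normal with those moments over counts n = 0..n_max,
n_max = ceil(max(μ + 6σ)) (truncated mass < 1e−8), normalized row by row.

## Metabolic cost

Per action potential: depolarizing 100 mV across 150 pF (π·D²·c_m for a
69 μm sphere at 1 μF/cm²) moves 1.5e−11 C ≈ 9.375e7 Na⁺; quadrupled for
Na⁺/K⁺ channel overlap and divided by 3 (pump stoichiometry) gives 1.25e8
ATP at the soma, ×4 for axonal propagation: 5.0e8 ATP, applied to all
three populations.  Excitatory synaptic current: the conductance splits as
g_Na = G·(E_K−E_e)/(E_K−E_Na) (E_Na = 90 mV, E_K = −105 mV); the simulator
accumulates I_Na = g_Na(V−E_Na) per step over the counting window for the
external + recurrent excitatory + excitatory background conductances, and
the pump cost is |⟨I_Na⟩|·Δ_T/(3e).  Inhibitory currents and costs inside
the external population are excluded.  The cost curve is then

    w(λ) = [n_exc μ_exc + n_inh μ_inh + λ/P_ext (total external rate)]·W_AP·Δ_T
           + (n_exc ⟨I_Na,exc⟩ + n_inh ⟨I_Na,inh⟩)·Δ_T/(3e),

with resting cost W0 = w(0) (background-evoked spikes and currents only).

## Information maximization

Capacity-cost C(W) = sup_{⟨w,p⟩≤W} I(Λ;N) is computed with the
cost-constrained Blahut–Arimoto algorithm: the tilted update
p′ ∝ p·exp(D(f_λ‖q_p) − s·w(λ)) maximizes I − sW, bisection on s meets the
budget, and the Csiszár double bound (max_λ vs average of the tilted
divergence) certifies the value; iteration stops when the gap is below the
tolerance (1e−9 bits in unit tests, 1e−4 bits for network-scale channels,
where the certificate still bounds the error at ~0.01% of the result).
Large channel matrices use single-precision mat-vecs; an adaptive step
size γ ∈ [1, 16] with a monotonicity safeguard (reject and shrink on an
objective decrease) accelerates the classical update several-fold without
affecting the exit certificate.

The information-metabolic efficiency E = max_p I(p)/⟨w,p⟩ is computed by
Dinkelbach fractional programming: repeatedly maximize I − E·W with the
tilted solver and update E ← I/W.  The sequence increases monotonically to
the optimum (E* is the unique zero of F(E) = max_p[I − E·W]); five or so
outer iterations suffice.  This realizes the ratio maximization the
Jimbo–Kunisawa algorithm performs and is cross-checked against a dense
C(W)/W sweep in the tests.  E is reported in bits per 10¹² ATP.

## Low-noise approximation

With Fisher information J = μ′²/σ² the near-optimal input density is
p(λ) ∝ √(J/2πe)·exp(−λ_W·w(λ)), with λ_W solved by bracketed root finding
so ⟨w,p⟩ = W and the normalization fixing λ_1; C_low = ln Z + λ_W·W (nats,
reported in bits).  The derivation is natural-log native; for the linear
surrogate (mean gλ, variance gλ·FF, affine cost) it collapses to
C_low = ½·log₂[(W−W0)/(w_AP·FF)], which the quadrature solver reproduces
to 1e−6.  On grids the integrals are trapezoidal; the quadrature variant
handles the 1/√λ endpoint singularity of the linear model.  The
efficiency under the approximation sweeps a log-spaced budget grid,
evaluates the exact channel mutual information under each low-noise
distribution and takes the maximal ratio; being a feasible-input
construction it can only underestimate the Jimbo–Kunisawa optimum.

## Population decoding

When the readout sees the rate vector rather than its sum, responses are
projected onto principal components fitted across all stimuli, and the
Gaussian population Fisher information J_pop = f′ᵀΣ⁻¹f′ + ½Tr[(Σ⁻¹Σ′)²]
is evaluated on the sampled stimulus grid with central differences
(one-sided at the ends) after diagonal loading Σ ← Σ + 1e−6·mean(diag)·I.
An efficient unbiased decoder yields λ̂ ~ Normal(λ, 1/J_pop): a noisy
identity channel over the stimulus grid whose efficiency is maximized the
same way.  Finite trial counts bias information upward; the efficiency is
computed at k, k/2 and k/4 trials (disjoint random subsets, averaged) and
extrapolated with E_k = E_0 + a/k + b/k².  Desk default: 50 components
(500 at full scale, where the bias/benefit trade-off saturates).

## Desk-scale profile and what it shows

The study grid (9 P_ext × 10 a_rec values, 31 stimuli, 10800 one-second
trials of the 1000-neuron network) is overnight/cluster scale.  The desk
profile uses a 1/8-scale network (150/100/25 neurons) with the a_rec grid
scaled ×4 (matching the ×4 smaller recurrent in-degree) and restricted to
the dynamically stable range of the scaled model (a_rec ≤ 1.2 nS at
α = 20; stronger recurrence makes the sparse 25-neuron inhibitory
population unable to track excitation and the response explodes),
10 stimuli × ~80 trials, and a 320-point dense grid.

Two caveats follow from the scale reduction and are visible in the
numbers.  First, the correlation penalty on the summed readout scales as
(n_tot − 1)·r̄, so a 125-neuron population pays ~8× less for shared input
than the 1000-neuron network; the efficiency gain from decorrelating
recurrence is correspondingly compressed at desk scale.  Second, the
efficiency optimum sits near the resting cost (most of the optimal input
mass at λ ≈ 0), where counts are ~8× smaller than at full scale; the
low-noise approximation, which is exact only as relative response noise
vanishes and which cannot concentrate mass at the boundary the way the
exact maximizer does, is noticeably looser there.  At desk scale the
low-noise efficiency falls 8–9% below the Jimbo–Kunisawa value for
P_ext ≥ 0.5 but 16–17% below it at P_ext = 0.1 (and raising the trial
count does not close the gap, so it is structural, not estimator noise);
the ≤10% agreement is a property of full-scale channels.  Passing desk-scale tests therefore
validates the machinery and the direction of every effect, not the
full-scale magnitudes.

## Known limitations

No spike-frequency adaptation, no synaptic delays or refractoriness, no
per-neuron parameter heterogeneity beyond the exc/inh threshold split, and
no decoder implementations (the Cramér–Rao channel is a bound, not an
algorithm).  The Gaussian channel discretization assumes the count
distribution is well-summarized by its first two moments; near-synchronous
regimes (very strong recurrence in the scaled model) violate this and are
excluded from the desk grid.
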