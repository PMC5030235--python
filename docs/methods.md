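# Methods

## Model

The network consists of N conductance-based (COBA) leaky integrate-and-fire
neurons, all excitatory, globally coupled without self-coupling and without
synaptic delays.  Between spikes,

    τ dV_i/dt = (V_rest − V_i) + g_i (E_ex − V_i) + I_ext [+ noise],
    τ_ex dg_i/dt = −g_i ,

and a spike of neuron j increments every conductance by
Δg_i = K_i w_ij / (N − 1).  When V_i reaches V_θ the neuron emits a spike
(y_i = 1 for `spike_width_steps` timesteps), V_i is reset to V_rest and
clamped there for the refractory period t_ref, during which the membrane
equation is suspended.  The conductance is interpreted as synaptic drive,
not membrane state: it keeps decaying **and keeps receiving increments**
while the neuron is refractory.  (Whether inputs should accumulate during
refractoriness is a modelling choice; suspending only the membrane equation
is the interpretation adopted here.)

Default constants (units ms, mV): τ = 20, τ_ex = 5, V_rest = −60,
V_θ = −50, E_ex = 0, t_ref = 5, dt = 0.01, N = 100.  Rates are carried
internally in spikes/ms and converted to Hz only at reporting boundaries.

Coupling heterogeneity is one-dimensional: K_i are either placed
equidistantly on [K̄ − ΔK, K̄ + ΔK] or drawn from the flat distribution on
that interval (and then sorted, so neuron index doubles as coupling rank in
both schemes; for large N the two are statistically indistinguishable).
Weight jitter replaces w_ij = 1 by 1 + η, η ~ flat(−ΔW, +ΔW).  Jittered
matrices are *not* renormalized by default — η has zero mean, so the
normalization Σ_j w_ij/(N−1) = 1 holds in expectation — but a `renormalize`
flag enforces it exactly when wanted.

## Integration scheme

Forward Euler for V at fixed dt (default 0.01 ms), with the conductance
decay applied as the exact factor exp(−dt/τ_ex) per step; this removes the
stiffest linear part from the discretization at negligible cost.  Order of
operations within a step:

1. membrane update for non-refractory neurons (refractory ones stay clamped
   at V_rest while their timer decreases by dt);
2. exact conductance decay;
3. threshold check on the updated V: spike, reset, refractory onset;
4. conductance increments from all neurons currently spiking, summed with
   no within-step ordering; they first influence the *next* step's membrane
   update (a causal, order-independent one-step spike width).

I_ext enters additively inside the parenthesis that drives τV̇, in mV.
Membrane noise, when enabled, adds noise_sd·√dt·ξ/τ to each V update
(ξ standard normal), making the noise strength timestep-invariant;
noise_sd is in mV·ms^1/2.  Non-finite V aborts the run with the offending
neuron and time.  Empirically the per-neuron rate error of the Euler scheme
against the closed-form constant-conductance solution scales linearly in dt
(verified by the dt vs dt/10 error-ratio test), and none of the reported
state classifications change between dt = 0.01 and 0.001 ms.

## Initial conditions and ignition

Membrane potentials start uniformly on [V_rest, V_θ); initial spike
indicators and refractory timers are zero.  Because the units are excitable,
a network started with g = 0 can never fire — every V decays monotonically
to rest — so the initial conductances are drawn uniformly from [0, 1].
This places most neurons transiently above the drive threshold
(V_θ − V_rest)/(E_ex − V_θ) = 0.2 and acts as an ignition kick that decays
within a few τ_ex; whether activity is then sustained is decided entirely by
the couplings (low-K̄ networks die out, as they must).  A master seed spawns
independent streams for initial conditions, weight jitter and noise, so
toggling one randomness source does not shift the others.

## Stationary mean field

In the asynchronous drifting state the mean field r̄ (spikes/ms) is constant
in time, each conductance settles at g*_i = τ_ex K_i r̄, and the linear
membrane equation gives a closed-form time-to-threshold

    t*_i = −(1/B_i) ln[(B_i V_θ − A_i)/(B_i V_rest − A_i)],
    A_i = (V_rest + g*_i E_ex)/τ,   B_i = (1 + g*_i)/τ,

finite only when K_i r̄ > (1/τ_ex)(V_θ − V_rest)/(E_ex − V_θ) = 0.04 /ms at
defaults.  The self-consistency map sends r̄ to the average of
1/(t*_i + t_ref) over **all** N neurons, silent ones contributing zero
(required for partially inactive states to be self-consistent).  The map is
nondecreasing and bounded by 1/t_ref, so the solver scans the residual
downward from 1/t_ref on a 2000-point grid and brackets each sign change
with Brent's method (tolerance 1e−10 /ms); the largest fixed point is
returned as "the" SMF solution (it describes the active branch), with all
bracketed roots exposed for diagnostics and no claim about the dynamical
stability of coexisting roots.  r̄ = 0 always solves the self-consistency
and is returned when no positive root exists.  A thermodynamic-limit variant
replaces the N-point average by 256-node Gauss–Legendre quadrature over the
flat K-distribution.

Phase boundaries in the (K̄, ΔK) plane follow by bisection: the
inactive/partially-inactive curve is where a positive fixed point first
exists; the partially-inactive/fully-drifting curve is where the weakest
neuron (K̄ − ΔK) first satisfies the firing condition at the
self-consistent rate.  The theory holds for drifting states only; it is not
applied where synchronized clusters exist.

## Measurement and classification

Rates are spike counts over a measurement window that starts after a
settling transient (defaults: 2 s transient, 10 s window).  The classifier
labels neurons below 1 Hz inactive; the longest run of consecutive-rank
active neurons whose rates agree pairwise within 0.5% is a synchronized
plateau if it spans at least max(3, 5% of N) neurons; remaining active
neurons are drifting; the label (I, I+D, D, D+S, S) is assembled from the
nonzero fractions.  Synchrony is thus diagnosed operationally from rate
equality — locked neurons keep finite pairwise phase lags, which the label
ignores.  The plateau tolerance is a convention (exposed as a parameter);
nothing in the model singles out a unique value.

Two resolution requirements matter in practice and are enforced in every
anchor-classification context in this repository (test fixtures, acceptance
script, examples):

* **Window length.**  Counting quantizes rates to 1000/t_measure Hz.  The
  flattest drifting continua have local slopes ~0.4 Hz/neuron, so a 10-s
  window (0.1 Hz resolution) occasionally produces spurious minimum-size
  plateaus (~10% of seeds at K̄ = 3, ΔK/K̄ = 0.6); a 20-s window (0.05 Hz)
  eliminates them.
* **Settling time.**  Lock-in to full synchrony near the mixed/synchronized
  boundary can take more than 10 s of simulated time for some initial
  conditions; anchor classifications therefore use a 10-s transient.

ISI statistics use spikes after the transient; per-neuron mean T_i, standard
deviation σ_i and CV_i = σ_i/T_i, with neurons having fewer than two spikes
excluded and reported.  The normalized-interval histogram bins s/T_i into
100 bins on [0, 3], density-normalized per neuron and averaged over neurons.

## Chaos diagnostic

A neuron's ISI sequence is embedded as consecutive pairs (s(n), s(n+1)) — a
two-dimensional delay embedding; periodic firing collapses to a point, a
limit cycle has dimension 1.  The box-counting (Minkowski) dimension
overlays the **tight bounding square** of the point set (maximal extent over
both axes, centered — keeping cells square) with 2^r × 2^r grids, counts
occupied cells N_box(r), and fits the least-squares slope of log2 N_box
against r.  The slope-in-(r, log2 N_box) reading is the only dimensionally
consistent interpretation of "log(N_box)/log(r)" when r indexes dyadic grid
refinement, and it is what the estimator implements.  Default fit ranges:
r = 2…7 for ≥1e5 points, 2…5 for ≥2e4, 2…4 below; the fit is automatically
capped where N_box exceeds half the number of points, since counts then bend
into the saturation plateau at log2(N_points), and a warning flag is set
when the cap bites.  More points extend the linear range (asserted as a
property test).

Calibration: the estimator recovers 0/1/2 on a repeated point, a uniform
segment and a filled square (1e5 points) within ±0.1, and log3/log2 on the
Sierpinski triangle.  Self-similar sets whose natural base is not 2 (e.g.
middle-third Cantor dusts) exhibit log-periodic oscillations of the local
slope under dyadic grids and converge too slowly for a ±0.1 claim at
practical sizes — a known limitation of fixed-base box counting, not of
this implementation.

For the mixed-state attractor the estimate at dt = 0.01 ms and 2–3·10^4
intervals is D_F ≈ 1.65–1.75 with fit range r = 2…5 (the coordinates are
quantized to dt, which blurs the finest structure); the paper-scale setting
(1.28·10^5 intervals) gives 1.68–1.75 across drifting neurons and seeds.
Values are reported with the fit residual.

## Protocols

All drivers are deterministic given their seeds and record the seed in each
result row.  Parameter ramps are piecewise-constant chunks (default 100 ms)
with the exact network state carried across boundaries — a discretized
linear interpolation; ramp_duration ≥ 100 τ is enforced as an adiabaticity
floor, and observation windows freeze the parameters (default 1 s settle +
5 s measure).  Hysteresis is quantified as the maximal per-rank rate gap
between legs at matched parameters, with ~5% as the irreversibility flag.
The external-input protocol runs two monotone excursions (positive and
negative) from the settled unperturbed state.  The jitter ensemble draws
independent weight matrices (optionally sharing the dynamics seed to isolate
weight variability) and reports per-rank mean ± sd over realizations.
Gaussian-noise robustness uses noise_sd ∈ {0.1, 0.5, 1.0} mV·ms^1/2 as a
convention — robustness is expected but no canonical amplitudes exist.

## Problem sizes used in tests and the acceptance script

N = 100 everywhere except the size-scaling suite (N = 50/100/200); anchor
classifications use 30-s runs (10 s transient + 20 s window); the mean-field
comparison uses 22-s runs; the chaos diagnostic uses a 300-s mixed-state run
collecting ~3.4·10^4 intervals, with the full 1.28·10^5-interval setting
available by lengthening the run.

## Known limitations

* No inhibition, synaptic delays, sparse or structured connectivity beyond
  flat weight jitter; exact event-driven integration is a possible
  optimization, not implemented.
* The SMF theory does not cover synchronized or mixed states, and no
  stability analysis of coexisting fixed points is attempted.
* The five-state classifier presumes the rate continuum is resolvable; at
  small N (≲60) with 10-s windows the minimum plateau size (3 neurons) can
  trigger on a flat continuum.  The defaults are calibrated for N = 100.
* The reported attractor dimension is that of the two-dimensional ISI-pair
  projection, not of the full 2N-dimensional attractor; a fractional value
  indicates chaos but the full-space dimension is not estimated.
* The coexistence region of synchronized and mixed states shifts with the
  spike width; `spike_width_steps` > 1 is supported but exploratory, and no
  quantitative law for the shift is provided.
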