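# Methods

## Model

The package implements spike-based predictive coding of linear dynamical
systems. A target system `dx/dt = A x + c(t)` (J variables, units of the
represented quantity per second) is to be reproduced by N leaky
integrate-and-fire neurons such that a fixed linear decoder recovers it:
each spike of neuron i adds its kernel Γ_i (column i of the J×N matrix Γ)
to the estimate x̂, which then decays at the readout leak λ_d. Writing r
for the identically filtered spike trains, x̂ = Γ r at all times.

Spiking is governed by a greedy efficiency principle: neuron i fires at
time t exactly when firing reduces the instantaneous objective
`‖x − x̂‖² + ν‖r‖₁ + μ‖r‖²`. Expanding the effect of one spike
(x̂ → x̂ + Γ_i, r_i → r_i + 1) gives the firing condition V_i > T_i with

    V_i = Γ_i·(x − x̂) − μ r_i            (membrane voltage = penalised
                                           prediction error)
    T_i = (‖Γ_i‖² + ν + μ) / 2           (threshold)

Differentiating V and substituting the system, decoder and rate equations
yields LIF dynamics

    dV/dt = −λ_V (V − V_rest) + Γᵀ c(t) + Ω_s r + Ω_f o + σ_V η

    Ω_f = −(ΓᵀΓ + μ I)     fast connections, one kick per presynaptic
                            spike; the diagonal implements the reset
                            (drop ‖Γ_i‖² + μ from threshold)
    Ω_s = Γᵀ (A + λ_d I) Γ  slow connections acting on filtered rates;
                            realise the target dynamics and cancel the
                            decoder leak

up to two terms, (ΓᵀA + λ_V Γᵀ)(x − x̂) and μ(λ_d − λ_V) r, which are a
factor ~1/N smaller than the retained drive at the standard kernel scaling
(see below). The voltage leak λ_V is a biological-realism term, not a
consequence of the derivation; it defaults to λ_d, which also makes the
μ-bookkeeping exact. `verify_voltage_identity` recomputes
V − (Γᵀ(x−x̂) − μr) from dense traces of any noiseless run so the size of
the neglected terms is always measurable rather than assumed. Two useful
facts follow and are exploited by the tests:

* the deviation shrinks with N (kernels ~1/N at fixed rates), and
* for a leaky-integrator target with system leak equal to λ_d (A = −λ_d I)
  the neglected terms cancel identically, giving a regime in which the
  greedy descent guarantee — every emitted spike strictly decreases the
  objective — can be checked by brute force with no approximation slack.

## Simulation scheme

Clock-driven Euler integration on a common grid (default dt = 0.1 ms; the
acceptance-level behaviours hold at dt/2). Per step: Euler update of the
reference x; Euler update of V (leak, feedforward Γᵀc, slow drive); voltage
noise injection; decay of r and x̂ by (1 − λ_d dt); spike selection; and
instantaneous application of the winner's fast column. The inner loop never
builds Ω as an N×N matrix: the slow drive is Γᵀ((A + λ_d I) x̂) and a spike
is a rank-one kick −Γᵀ(ΓΓ_k), so one step costs O(N·J). This is what makes
hundreds of simulated seconds (persistence) and hundreds of repeated trials
(count statistics) cheap.

Spike policy. The default is one spike per network per time step — the
neuron with the largest suprathreshold margin, which is the faithful
discrete-time greedy minimiser (the cost decrease of a candidate spike is
2(V_i − T_i)). It also suppresses the "ping-pong" artifact in which
opposite-kernel neurons answer each other within a step. The permissive
all-suprathreshold policy is implemented for studying exactly that
artifact; runaway volleys under it abort with a diagnostic rather than
truncate silently. Exact margin ties (which occur systematically in
noiseless homogeneous networks) are broken uniformly at random from a
dedicated random stream, so switching policies or adding perturbations
never shifts the noise sequence.

Noise convention. σ_V is the standard deviation of the voltage noise added
per time step ("per-step" mode, the convention used when quoting noise
levels here); a sqrt(dt)-scaled diffusion mode is available. σ_V may be a
per-neuron vector; presets specify it as a fixed fraction of each neuron's
threshold-to-reset span, which corresponds to uniform noise after the
physical-unit rescaling.

Physical units. An affine per-neuron map V → aV + b places every neuron's
threshold at −50 mV and reset at −60 mV (configurable); feedforward and
recurrent weights and noise gain rescale accordingly and the resting
potential becomes b (midway between threshold and reset when ν = 0).
Threshold crossings are preserved exactly, so matched-seed runs of raw and
rescaled networks emit identical spike trains — verified to bit precision.

## Working points of the presets

Caption-level constants of the source experiments are not legible in the
text available to this implementation, so the preset parameters were fixed
once by inverting the *stated observables* of the integrator networks —
~5 Hz sustained single-unit rates in the delay epoch, a ~1 ms population
oscillation, CV/CV2/Fano near 1, trial-to-trial count correlations below
0.001, and a ~100 s half-decay of the stored value at a 0.1 s membrane
time constant. At N = 400, λ_d = λ_V = 10 s⁻¹ and a held value x̄ = 2,
those anchors jointly imply an effective readout jump of ≈0.02 per spike
(pooled rate λ_d x̄ / 0.02 ≈ 1 kHz → 1 ms integration cycle; ÷ ~200 active
units → ~5 Hz each).

* Homogeneous perfect integrator: kernels ±0.02, ν = 5e-5, μ = 3e-5,
  per-step noise 0.2 % of the threshold-to-reset span. The noise level was
  selected on a coarse grid to reproduce the stated ~100 s retention
  (92–108 s across seeds); CV ≈ 0.85, 1.0 ms period and 4.9 Hz rates then
  hold without further adjustment. The quadratic cost is what rotates
  firing across the population (with μ → 0 the cycle winner is "sticky"
  and single-unit trains become bursty); the linear cost opens a small
  post-spike margin that prevents noise-triggered counter-spike cascades.
* Leaky variant: sensory leak 100 s⁻¹ (an order of magnitude faster than
  the decoder), same ensemble; responses become transient, no persistence.
* Inhomogeneous integrator (replicated-variable construction): J = 10
  identical copies of the scalar system driven by one shared command;
  kernels are sparse binomial — each neuron carries a sign and each of its
  10 entries is ±0.04 with probability 0.7 — and the behavioural readout is
  the mean of the copies. This yields sparse, random, symmetric
  connectivity and heterogeneous tuning gains. The network runs with
  σ_V = 0: it is fully deterministic, and chaos (a single delayed spike
  reshuffles all later spikes) supplies Poisson-like variability. Trials
  differ through fresh shared sensory noise during the 250 ms charging
  epoch only. ν = 1e-5, μ = 1e-4; the ensemble uniformity (sparsity 0.7)
  matters because jump-size dispersion sets the slow chaotic diffusion of
  the stored value, which in turn controls Fano factors and the sign and
  size of pairwise count correlations.
* Arm, differentiator, oscillator: random kernels normalised to a constant
  norm; the oscillator represents (position, velocity/ω) so that both
  components share one amplitude scale — the raw (x, v) coordinates give
  pathologically anisotropic kernel loads. The differentiator realises
  x₂ ≈ τ_f·dc/dt through a fast low-pass cascade (τ = 20 ms and 10 ms,
  both much faster than the 100 ms decoder, demonstrating tracking beyond
  the decoder timescale).

## Statistics

CV is sd/mean of the inter-spike intervals; CV2 is the local pairwise
measure mean(2|I_{k+1} − I_k| / (I_{k+1} + I_k)) (the source literature
names both but defines only CV2; we implement both and report them
separately). Fano factors are variance/mean of repeated-trial counts;
undefined statistics return NaN markers, never zeros. Correlograms are
spike probabilities per lag bin normalised by reference-spike count
(default 5 ms bins for display; 0.1 ms bins for oscillation detection —
the coarse bin hides the 1 ms comb). The population period estimator
smooths the fine-binned autocorrelogram over 3 bins (a comb line that
straddles a bin edge otherwise splits its mass) and takes the first local
maximum within 60 % of the global one — the raw argmax often lands on a
harmonic.

Noise correlations: Pearson correlations of per-trial counts at a fixed
condition, over all neuron pairs with defined correlations. Two summaries
are reported. The pair-averaged signed correlation pools ~N²/2 nearly
independent estimates, so its sampling error at 500 trials is a few 1e-4
and magnitudes ~1e-3 are resolvable; this is the headline number. The
per-pair |ρ| average is floored at sqrt(2/π)/sqrt(trials−1) ≈ 0.036 at 500
trials even for perfectly independent processes; it is reported with that
independent-Poisson floor for calibration, not as the headline.

E/I decomposition: every synaptic contribution to a neuron (feedforward,
fast kicks as one-step current impulses, slow input) is split by sign
before summation and smoothed with a 2 ms exponential window; E + I equals
the smoothed net input by construction. The neuron's own reset is excluded
by default (it is a reset, not synaptic input). Balance is quantified as
the correlation of E with −I at the stimulus timescale.

GLM effective connectivity: each recorded neuron is modelled as an
inhomogeneous Poisson process whose log-rate is a bias plus a per-bin
feedforward kernel applied to the input and strictly causal per-bin
lateral filters applied to the other units' spikes. The concave Poisson
likelihood is maximised by L-BFGS with analytic gradients (any
quasi-Newton scheme is equivalent here); filters are per-bin with no basis
functions, with an optional ridge penalty (off by default). `simulate_glm`
samples from the same model and serves as ground truth for recovery tests,
which use minutes-scale recordings with correspondingly wider tolerances
than the hours-scale fits the construction is designed for.

## Baselines and scaling

The matched Poisson control removes the fast connections and replaces
threshold crossing by per-step Bernoulli thinning at the instantaneous
rate needed to track the target: demand (A y + c + λ_d y)/γ pooled over
the half-population of matching sign, with y following the deterministic
rate dynamics (slow connections in the mean). At constant y this is the
analytic homogeneous rate λ_d|y|/(γ N/2) per active neuron. Nothing
cancels the shot noise, so the decoded estimate carries variance
γ²·(pooled rate)/(2λ_d) — the Cramér–Rao scale for independent Poisson
units, also provided as an explicit bound from tuning curves.

The scaling experiment rescales the reference ensemble to each size N
(kernels ~1/N so single-unit rates and the readout stay fixed; ν, μ and
σ_V ~1/N² so each neuron's threshold composition is N-invariant — after
physical rescaling the synaptic weights are then independent of N),
measures the tracking RMSE at a held value, and fits log–log slopes with
bootstrap confidence intervals: ≈ −1 for the spiking network versus
≈ −0.5 for the Poisson control. Default sizes 26–400 (the signed ensemble
needs an even split).

## What the synthetic protocols do and do not show

All inputs are generated by the command protocols (noisy steps, push–pull
reaches, kicks, filtered white noise); there is no external data. The
generator reproduces the idealised conditions of the original experiments
— exact linear dynamics, instantaneous synapses, perfectly tuned
connectivity, stationary epochs — so passing tests demonstrate the coding
principle and its signatures, not robustness to biological non-idealities
(synaptic delays and failures, Dale-separated populations, conductance
effects are out of scope by design). Within the model class the known
failure modes are surfaced, not hidden: the ping-pong artifact under the
permissive policy, divergence when the voltage approximation breaks
(flagged with a timestamped diagnostic), and the degradation of the greedy
rule's optimality when kernels are few and opposing.

## Numerical choices and limitations

* Initial state: V = 0, r = 0, x̂ = 0, x = x0; `warm_start_rates` fits
  r ≥ 0 to represent x0 (non-negative least squares) for hold experiments.
* The reference system is integrated on the same Euler grid as the
  network, so decoding error is never confounded by integrator mismatch.
* Subset decoding refits least-squares weights on a held-out window by
  default (the charitable subset decoder); raw-kernel columns are a mode,
  used when comparing against the independent-Poisson construction where
  the analytic expectation is available.
* Determinism: a run is bit-reproducible given (inputs, seed); noise and
  tie-breaks use separate child generators of the seed.
* Problem sizes in the test suite (trial counts, durations, recording
  lengths, sizes per scaling point) are desk-scale versions of the full
  protocols in `scripts/acceptance.py`; both state their sizes explicitly
  and scale up transparently.
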