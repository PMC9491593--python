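# Methods

## The model and its conventions

The extended (four-parameter) Tsodyks–Markram model is simulated
event-driven and exactly: between stimulation pulses every state variable
is a pure exponential relaxation (*u* → *U* with time constant *F*, *R* →
1 with *D*, *I* → 0 with τ_syn), and at each pulse the jump maps are
applied in the order facilitation → depletion → current increment:

    u(t+) = f + (1 − f) u(t−)
    R(t+) = R(t−) (1 − u(t+))
    I(t+) = I(t−) + A u(t+) R(t−)

No numerical ODE solver is used anywhere; the continuous and discrete
simulators agree at pulse times to machine precision by construction, and
the cross-check between them is a regression test, not an independent
derivation.

Two conventions deserve making explicit:

* **Depletion uses the post-facilitation utilization** u(t+).  The
  alternative (depleting with u(t−)) yields a per-pulse recursion that is
  inconsistent with the closed-form steady state used by the fitter; the
  convention chosen here is the standard one and makes the recursion and
  the fixed point mutually consistent.
* **Initial conditions** are u = U, R = 1, I = 0 before the first pulse,
  and the first recorded state is produced by applying the jump maps once,
  so I[1] = A(f + (1 − f)U) exactly; there is no virtual pulse at t = 0.

Units: times and time constants in seconds, frequencies in Hz.  τ_syn
defaults to 3 ms (glutamatergic); use 10 ms for GABAergic synapses.

## Steady state and its fit

The fixed point of the per-pulse map is analytic:

    u∞ = (f + (1−f) U (1−x)) / (1 − (1−f) x),     x = e^(−1/(νF))
    R∞ = (1−y) / (1 − (1−u∞) y),                  y = e^(−1/(νD))
    I∞ = A u∞ R∞ / (1−z),                         z = e^(−1/(ν τ_syn))

The steady-state stage minimizes the sum over frequencies of squared
residuals between observed steady-state amplitudes (mean of the last
k = 10 peaks per series) and I∞(ν; θ) with scipy's bounded trust-region
reflective least-squares and a hand-derived analytic Jacobian (finite
differences are the test oracle, agreement 1e−6).  Because I∞ is linear in
*A*, the scale is profiled out in closed form (Â = ⟨s, y⟩/⟨s, s⟩ for the
unit-scale model curve *s*), which makes the stage a function of the
kinetic parameters only; the Jacobian includes the ∂Â/∂θ terms.  Fitting
bounds are f, U ∈ [1e−4, 1] and F, D ∈ [1e−3, 5] s — generous
physiological STP ranges that keep the exponentials well conditioned.

Mean-of-last-10 is used for the steady-state observation because with
≥ 100-pulse trains the last ten peaks are comfortably inside the settled
regime while averaging measurement noise by √10.

## Transient detection and fit

The transient length N_trans of a series is the least *n* such that every
later consecutive pair changes by less than 5% in magnitude,
|I[m] − I[m−1]| < 0.05 |I[m−1]| for all m ≥ n.  The absolute value
matters: for depressing series the signed differences are negative and a
signed criterion would be vacuous.  Detection runs on the reference data
(never on model output), is capped at 20 pulses inside fitting, and falls
back to the rule-of-thumb 15 when a series is too short to scan.

The transient cost is the per-frequency mean squared error over the first
N_trans peaks, summed over frequencies, plus an anchor penalty
λ‖(θ − θ_anchor)/w‖² with *w* the bound widths.  It is minimized by
Nelder–Mead with the classical coefficients.  Two numerical choices make
this stage robust:

* the simplex moves in [f, U, log F, log D] with initial steps of 5% of
  each bound range (a simplex stepped proportionally to the current
  coordinate cannot move a time constant sitting near its lower bound);
  out-of-bounds proposals are rejected with a large cost, and a premature
  simplex collapse triggers one seeded restart around the best point with
  5% jitter;
* the penalty weight is *relative*: the effective λ is `penalty_factor`
  (default 0.1) times the transient data cost at the anchor.  A fixed
  absolute λ either dominates once the data cost becomes small — freezing
  the search at whatever local minimum the steady-state stage delivered —
  or is too weak to prevent jumps early on.  Scaling by the anchor cost
  keeps the leash proportionate at every stage of convergence and removes
  the penalty's bias at the algorithm's fixed point.
  `penalty_scale="absolute"` restores a fixed λ.

The scale *A* is profiled in this stage too (the model peaks are linear in
*A*), so both stages search the same four-dimensional kinetic space.

## The dual loop

Each round fits the steady state (trust region, ≤ 50 steps, warm-started
at the current estimate) and then the transient (Nelder–Mead, ≤ 300
iterations, warm-started and anchored at the steady-state output).  Ten
rounds are run by default, stopping early when the combined cost
(steady-state sum of squares + unpenalized transient cost) changes by
less than 1e−10 relative between rounds; the returned parameters are the
best over the whole history by combined cost, which also makes the
best-so-far cost trajectory non-increasing under noise.  The budgets were
sized so that, on noiseless eight-frequency data, random ground truths
are recovered within 5% in the large majority of runs (the validation
suite requires at least 90% of 50); lighter budgets leave noticeably more
runs stranded in the valley the two stages share, which is why the
heavier defaults were kept.

With fewer distinct frequencies than free parameters the steady-state
stage is under-determined.  The frozen-U variant holds *U* fixed during
that stage only (*U* moves the steady-state curve least, so freezing it
costs the least steady-state fidelity), halves both per-stage step caps
and doubles the number of rounds — many small, mutually correcting steps
rather than few aggressive ones.  *U* itself is then constrained only by
the transient stage and can remain biased; the reconstruction of the peak
series is nevertheless accurate, which is the quantity such data can
support.

The conventional baseline (`ConventionalLMSE`) runs the same Nelder–Mead
machinery on the mean squared error over the full length of every series,
with no truncation and no anchor.

## Synthetic data

`generate_dataset` simulates the discrete map per frequency and adds
i.i.d. Gaussian noise to the peak amplitudes with standard deviation
`noise_sd_frac` × the maximum absolute clean peak over the dataset; 5%
and 20% are the two conditions used in validation.  Random ground truths
draw f, U uniformly from [0.05, 0.95] and F, D log-uniformly from
[0.05, 1] s — time constants span decades, and the bounds avoid
degenerate synapses that no estimator could tell apart.  The default
protocol uses eight frequencies {5, 10, 20, 30, 50, 100, 130, 200} Hz at
100 pulses; `generate_experimental_dataset` provides the three-frequency
clinical protocol (10/20/130 Hz, 1-s trains).  The five named plasticity
presets span strong depression to strong facilitation and are ordered
both by I∞ at 50 Hz and by the I∞(100 Hz)/I∞(5 Hz) ratio.

What the generator does *not* emulate: stochastic vesicle release,
postsynaptic excitability changes, compound excitatory/inhibitory
responses, slow plasticity or electrode artifacts.  Noise is added to
peak amplitudes, not to continuous traces.  Passing tests therefore show
that the estimator works when the model class is correct and the noise is
additive and Gaussian — not that the TM model describes any particular
synapse.

## Trace processing

`render_trace` superposes one peak-normalized double-exponential kernel
per pulse (linear superposition); `extract_peaks` measures, for each
pulse, the extremum of sign × current in a window after the pulse
relative to the immediately preceding baseline sample, skipping a 1-ms
blanking window for the stimulation artifact.  With overlapping kernels
(high frequency relative to τ_decay) the extracted peaks are the windowed
extrema of the superposed trace, not the original per-pulse amplitudes —
a known, documented bias of peak-based measurement.  `fit_kernel`
least-squares-fits (τ_rise, τ_decay, amplitude, onset) of a single
response; τ_rise < τ_decay is enforced by sorting.

## Scales used in the validation suite

The statistical acceptance checks run at desk scale: 50 random truths for
noiseless recovery, 20 paired initializations for the noisy method
comparison, 3 replicates for the frozen-U reconstruction, 200 parameter
sets for the transient-length grid, 1000 draws for distributional checks
of the sampler.  The benchmark harness (`compare_methods` /
`stpfit benchmark`) exposes flags to run the same experiments at larger
replicate counts.

## Known limitations

* All optimization is local; multi-start lives in the benchmark harness,
  not inside the fitters.  A run stuck in a local minimum is recognizable
  by its combined cost.
* Near-degenerate synapses (e.g. f and U both large, so u ≈ 1 throughout)
  are not identifiable from constant-frequency data at realistic noise;
  no estimator distinguishes parameter sets whose peak series coincide
  within noise.
* The profiled scale *A* absorbs axonal-failure and multi-afferent
  effects; it is reported but not separable from them.
* Constant-interval trains only; Poisson or jittered stimulation is out
  of scope.
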