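# Methods

## Model

The reservoir is a directed network of `N` leaky integrate-and-fire
neurons.  Between spikes, the membrane potential `v_i` of neuron `i`
integrates three contributions: external current kicks of size `R·I_k` mV
(every `τ` ms one neuron is chosen uniformly at random and, if it belongs
to input group `k`, receives one kick), synaptic impulses `W_{i,j}` mV from
each presynaptic spike, and an exponential leak at rate `α` (1/ms).  When
`v_i ≥ θ` the neuron emits a spike, resets to 0 mV and is refractory for
`τ_ref` ms.  Multi-group drive enters every closed-form expression only
through the aggregate `I = Σ n_k I_k / N`; the group structure is retained
by the simulator.

The mean-field approximation replaces synaptic weights, in-degrees and
inter-spike intervals (ISIs) by their population averages `⟨W⟩`, `βN`,
`⟨Δ⟩`.  The averaged potential then satisfies a linear scalar ODE; imposing
periodicity `⟨v(⟨Δ⟩)⟩ = θ` yields the weight-ISI relation implemented in
`theory.w_of_delta_leaky`, its weak-leak limit `w_of_delta_leakfree`, and
the closed-form inverse `delta_of_w_leakfree` on the physical branch.  The
critical weight is the point of steepest descent of that branch, which is
the vertex of the discriminant quadratic:

    W_crit = θ/(βN) − 2RI·τ_ref/(τβN²),  Δ_crit = τ_ref(1 + √(τNθ/(RI·τ_ref) − 1)).

Three conditions bound the regime where this is trustworthy: `α·τ_ref <
1/2`, `θτN/(RI·τ_ref) ≥ 2`, `θτNα/RI < 1`.  `check_validity` reports them;
violations warn rather than fail so off-regime sweeps stay runnable, while
a network with no positive drive is a hard error.

Units: potentials and weights in mV, times in ms, `α` in 1/ms.  A leak of
`0.01` is read as 0.01 ms⁻¹; this is the only reading under which
`α⟨Δ⟩ ≈ 0.08` at the critical ISI of the reference configuration,
consistent with the weak-leak approximation the critical-point derivation
relies on.

## Discretization

The simulator advances on a fixed grid `dt = 0.1` ms (the mapping
"20000 steps ≡ 2 s" of the validation protocol):

- leak is the exact per-step factor `e^{−α·dt}`, so the discrete map agrees
  with the ODE solution between events;
- `round(dt/τ)` external kicks land per step, each on one uniformly chosen
  neuron with replacement (a Poisson(dt/τ) count is available via
  `poisson_events=True`, and is the right choice if `dt < τ` ever arises);
- spikes propagate with a one-step delay; there are no instantaneous
  within-step cascades;
- threshold crossing uses the closed inequality `v ≥ θ` for floating-point
  robustness; reset is to 0 mV and refractoriness lasts `ceil(τ_ref/dt)`
  steps starting the step after the spike, so consecutive spikes of one
  neuron are separated by at least `τ_ref/dt + 1` steps.

**Refractory inputs are buffered by default.**  During refractoriness a
neuron cannot fire, but its potential keeps integrating kicks, synaptic
impulses and leak.  This choice is forced by the mean-field relation
itself, whose averaged potential integrates the full drive over the whole
period `⟨Δ⟩`: with inputs instead discarded (`buffer_refractory=False`,
also provided), the few-percent loss of synaptic efficacy displaces the
empirical ISI enormously near the critical point — exactly where
`d⟨Δ⟩/d⟨W⟩` almost diverges — and the simulated curve detaches from the
theory.  With buffering, the simulated pooled ISI at `0.8·W_crit` is
18.39 ms against a theoretical 18.43 ms.

A consequence worth knowing: the supercritical state is a *desynchronized*
maximum-rate state — every neuron fires each `τ_ref/dt + 1` steps with the
population spread across phases — rather than synchronized full-population
bursts.  Per neuron the activity alternates near-deterministically between
firing and refractory silence, and the total spike count approaches the
refractory-limited ceiling `N·T/(τ_ref/dt + 1)`.

## Topology

`generate_weights` samples three directed ensembles, always with zero
diagonal and nonzero weights i.i.d. Gaussian with mean `⟨W⟩` and standard
deviation `⟨W⟩/10` (the second parameter is a standard deviation; a
variance reading would make the spread scale oddly with `⟨W⟩`).  Negative
draws are kept — they model inhibition, and the theory constrains only the
mean.  `small_world` is a directed Watts-Strogatz construction: a ring
lattice with out-degree `βN` (an even integer), each edge's target rewired
with probability 0.1 (configurable; no canonical value exists for the
validation protocol).  `uniform_random` connects each ordered pair with
probability `βN/(N−1)`; `fully_connected` ignores `β`.  Identical seeds
give bit-identical matrices.

## LZW complexity

The complexity of a raster is the number of entries a standard LZW
compressor (initial dictionary `{"0","1"}`) adds while encoding the
row-major concatenation of all neurons' spike trains (neuron 0's full
series, then neuron 1's, ...; time-major available for sensitivity
analysis).  Counting *added* entries rather than total dictionary size
shifts every value by two and cancels in peak location, the quantity of
interest.  The normalization divides by the mean dictionary growth over 8
seeded Bernoulli(0.5) strings of equal length — the maximally incompressible
reference the supercritical alternating regime is compared against.  For a
constant string the growth is `O(√L)` versus `~L/log L` for the null, so
the normalized value of silent rasters falls below 0.05 once `L ≳ 10⁵`.

## Sweeps

`sweep` runs `n_reps` replicates per grid weight; each (weight, replicate)
cell regenerates topology and simulates under a child seed spawned from
`(master_seed, weight_index, replicate)`, so any cell can be re-run in
isolation.  Aggregation is by median and interquartile range; the
complexity peak is the argmax of the median curve with ties broken toward
the lower weight.  Defaults — 21 weights log-spaced over
`[0.5, 1.5]·W_crit`, 4 replicates, `T = 10⁴` steps — keep a full sweep
around one minute on one core; the peak location is stable from `T ≈ 10⁴`
upward (8 replicates and `T = 2·10⁴` give the same grid point).  At the
reference configuration the peak error against the closed form measures
0.079; with `N = 100` the finite-size offset grows to ≈ 0.34, always in the
direction of the theory underestimating the empirical peak.

## Self-organized quasi-criticality

Every `τ_ref` window the homeostatic rule rescales the mean weight,

    ⟨W⟩ ← ⟨W⟩ · (1 − γ (2·#spikes − N)/N),     γ = 0.1,

where `#spikes` is the window's total spike count, and the update is
realized by multiplying all existing connections by a common factor
(topology and relative weight structure preserved).  The fixed point —
half the neurons firing per refractory period, i.e. a per-neuron ISI of
`2·τ_ref` — coincides with the critical weight under the buffered
discretization: a stationary state satisfies the per-ISI balance
`RI·⟨Δ⟩/(τN) + ⟨W⟩βN = θ`, and substituting `⟨Δ⟩ = 2τ_ref` gives exactly
`W_crit = θ/(βN) − 2RI·τ_ref/(τβN²)`.

Initial membrane potentials are drawn uniformly on `[0, θ)`: from an
all-zero start, a network with a large threshold-to-kick ratio stays
externally un-seedable for thousands of windows while silence inflates the
weight unchecked.  The equilibrium band of the rule is far narrower than
its ±γ multiplicative steps, so the trajectory hovers around `W_crit` in a
bang-bang limit cycle; its inflating (silent) excursions are strongly
right-skewed, and the settled weight is therefore the *median* of the
trailing 25% of the trajectory.  The default run is 2000 windows (2 s of
activity); the divergence guard trips at `10⁶·θ` (configurable), large
enough to tolerate the cold-start inflation the rule recovers from, and
small enough to catch true runaway growth.

With `θ = 10` mV and drives of 2-8 mV the rule settles within 5-10% of the
closed form.  At `θ = 200` mV the cycle widens: external kicks are at most
4% of the threshold, so re-ignition after an activity collapse can take
tens of windows and the settled weight lands 1.4-1.8× above `W_crit`
(settling errors ≈ 0.4-1.0 across seeds).  The corner `θ = 200`, `RI = 2`
additionally sits on the validity boundary (`θτNα/RI = 1`) and does not
re-ignite at all within the run.  An alternative probe mode
(`mode="refresh"`, potentials freshly uniform each window) makes `W_crit`
the rule's *exact* analytic fixed point, but is subject to the same
seeding cap at large `θ` and to cascade truncation by the one-step
synaptic delay; it is provided for experimentation, not as the default.

## What the synthetic conditions do and do not show

All inputs are generated: connectivity from the three ensembles above and
spike rasters from the simulator itself.  The generator mirrors the
validation protocol of the analysis (Gaussian weights, uniform random
drive, fixed `dt`); it does not emulate heterogeneous per-neuron leak,
transmission-delay distributions, conductance synapses, or Dale's law, so
passing tests demonstrate internal consistency of theory and simulation
under the model's own assumptions, not robustness of the closed form to
those biological complications.

## Numerical notes and limitations

- `w_of_delta_*` raise on `⟨Δ⟩ ≤ τ_ref` (pole); `delta_of_w_leakfree`
  raises on a negative discriminant; `critical_isi` requires
  `θτN/(RI·τ_ref) ≥ 1`.
- Relative comparisons of the leaky and leak-free relations are made on the
  mid-branch ISI grid: at the zero-weight root (`⟨Δ⟩ = τNθ/RI`) the
  relative difference is ill-conditioned by cancellation.
- `1 − e^{−x}` is computed via `expm1` so the weak-leak limit is accurate
  down to `α = 10⁻⁸`.
- The finite-difference curvature check uses step sizes at which central
  differences are exact for the quadratic discriminant, keeping roundoff
  out of the `2g''g − (g')²` flatness test.
- Simulation inner loops and the LZW encoder are numba-compiled; the first
  call in a session pays a one-off compilation cost of a few seconds.
- Problem sizes used throughout (N = 1000, T = 10⁴ steps, 4 replicates,
  2000 homeostatic windows) are the package's desk-scale defaults; the
  protocol-scale values (T = 2·10⁴, 8 replicates) are plain arguments away
  and give the same peak locations.
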