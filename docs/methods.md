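# Methods

This note records the models implemented in `recurseg`, their assumptions,
the free parameters and their defaults, the numerical conventions, and what
the synthetic generators do and do not emulate.

## Recurrence-grammar segmentation

**Model.** A multivariate time series is treated as a sampled trajectory on
the unit hypersphere (after normalization, below). Two time points are
*recurrent* at ball size ε when their cosine distance `1 − x·y` is strictly
below ε. The recurrence grammar rewrites the sequence of time indices
`1 … T` by the rules `i → j` for every recurrent pair `i > j` (with
transitive chaining for recurrent triples) until a fixed point; at the
fixed point every time point carries the minimal time index of its
connected component in the recurrence graph. The implementation iterates
synchronous rule sweeps interleaved with transitive rule chaining (pointer
jumping); both operations only ever replace a symbol by a smaller index
from the same component, so the iteration converges to the component
minima — in practice in a handful of sweeps, provably in at most T.

**Transient rule.** A symbol class with fewer than `min_dwell` occurrences
is relabeled 0 (transient). The library default is `min_dwell = 2`: a
state must recur at all. This is deliberately permissive; see the
simulator protocol below for when a stricter threshold is scientifically
appropriate.

**Normalization.** Two modes. `unit` projects each time point onto the
unit sphere. `zscore_unit` (pipeline default) first z-scores each module
over time — removing static amplitude offsets so that cosine distance
compares activation *patterns*, which is appropriate for signals such as
BOLD whose per-module baselines are arbitrary — then row-normalizes.
Zero-variance modules are centered only (with a warning); a zero-norm time
point is an error naming the offending sample. For the synthetic
generators, whose coordinates are already meaningfully scaled, the demo
analyses use `unit`.

## Markov-optimal ball size

The segmentation at ε induces a Markov chain over the transient plus the
metastable classes. Transition probabilities are bigram frequencies,
column-stochastic with the convention `p(i ← j) = #(j→i) / #(leaving j)`;
a state observed only at the final time point has no outgoing bigram and
its column is set absorbing (`p_jj = 1`), which preserves stochasticity
without inventing transitions. Metastable states are indexed in order of
first appearance — deterministic and independent of label values.

The utility `u(ε) = [tr P + h_r + h_c]/(n + 2)` rewards persistent states
(large trace) and uniform routing through the transient (large normalized
entropies of the renormalized transient row and column). Conventions at
the boundary of the formula's domain:

* an empty transient distribution contributes 0;
* `n = 2` (a single metastable state) contributes 0 per entropy term. The
  normalizer `log(n − 1)` vanishes there, so a convention is forced.
  Scoring the one-outcome distribution as maximally entropic instead would
  award every "merge everything, keep a few stray transients" partition a
  utility near `(1 + 2)/4 = 0.75`, which routinely outscores the correct
  multi-state segmentation; treating the degenerate distribution as
  carrying no entropy information keeps the optimizer honest.
* `n = 1` degenerates to `u = p_00 / 3`.

`u` always lies in [0, 1].

**ε grid.** The automatic grid is 50 evenly spaced values between the 5th
and 95th percentile of the off-diagonal pairwise cosine distances —
covering the bulk of the distance distribution without committing to a
scale. If the spread is degenerate (identical states), a single ball size
just above the float-level scatter is used. Ties in the utility break
toward the smallest ε, preferring finer partitions over coarse merges at
equal score.

## Ensemble Hausdorff clustering

Metastable state clouds from all subjects are pooled (transients never
enter) and compared by the Hausdorff distance, the larger of the two
directed max–min cosine distances. It is zero exactly for equal point
sets; overlapping but unequal clouds have positive distance. Thresholding
the distance matrix at θ (strict, mirroring the recurrence plot) and
re-applying the recurrence grammar yields clusters labeled by minimal
pooled index. The default θ = 0.8; because the "smallest set of clusters
covering every subject" criterion is not self-operationalizing, an
optional θ-grid search reports cluster counts and full-coverage flags so
the user can pick the smallest covering solution. The cluster count is
non-increasing in θ.

## Representatives and parcellation projection

Each state cloud is summarized by its member with maximal infinity norm
(sharpest module contrast), ties broken toward the earliest time point.
The barycenter is a natural alternative but blurs contrast between states.
A K×M mixing matrix (regions × modules) maps the representative into
region space, `y = W x`; entries of `y` may be negative, as the basis
orientation of the parcellation is arbitrary. The file reader expects
regions as rows and auto-transposes a modules-as-rows file when the header
indicates it. A synthetic block-structured nonnegative mixing generator
(default K = 45 labeled regions) stands in for atlas-derived overlap
matrices, which are user-supplied inputs.

## Switching-ensemble surrogate

`generate_switching_ensemble` emulates the *shape* of module-averaged,
unit-normalized resting-state recordings: T = 1200 samples, M = 40
modules, a small number of shared metastable states. Defaults: 3 states,
mean dwell 40 samples (geometric), transient length 5, isotropic noise
σ = 0.05 per module, minimum pairwise center angle π/2 (random
high-dimensional directions are near-orthogonal; the angle guarantees the
states are genuinely distinct). Dwell samples scatter around their center
and are re-normalized; transient samples interpolate along the great
circle between consecutive centers with `transient_jitter = 2` times the
dwell dispersion. The jitter encodes that transitions are variable rather
than stereotyped; perfectly repeatable transition paths would themselves
be recurrent structures, and a segmentation method built on recurrences
would (correctly) report them. Subjects share centers but have
independent epoch orders and noise. Exact per-sample labels are returned,
so recovery can be scored by the adjusted Rand index over non-transient
samples.

What the surrogate does **not** emulate: hemodynamic autocorrelation and
spectra, inter-subject amplitude differences, drifting states, or
non-geometric dwell distributions. Passing recovery tests therefore show
that the chain "recurrence plot → grammar → Markov-optimal ε → Hausdorff
pooling" identifies well-separated, noisy, revisited states at realistic
recording lengths — not that it is robust to everything real BOLD does.

## Three canonical switching mechanisms

Minimal phenomenological models, one per mechanism by which a system can
alternate between two metastable activity levels. All are integrated with
fixed-step classical RK4 (Euler–Maruyama for the Brownian term) for exact
reproducibility; integration that produces non-finite values raises with
the offending time.

**Slow-fast hysteresis** (`simulate_slowfast`): slow variable x₁, fast
variable x₂,

```
x₁' = ε (a − x₂)
x₂' = −(x₂ − b − η x₁)(x₂ − c − η x₁)(x₂ − α x₁ − β)
```

with a = 0.3, b = −1, c = 1, α = −2, β = −0.5, ε = 0.004. The fast
nullcline consists of two near-horizontal attracting branches near b and c
crossed by the transversal line x₂ = αx₁ + β; the crossings are
transcritical points. The slow drift carries the occupied branch into its
crossing, the state jumps to the other branch, and the cycle repeats — a
hysteresis loop with two metastable activity levels. The branch tilt
η = −0.05 keeps the branch-tracking error sign-definite; with exactly
horizontal branches the branch lines are invariant and the exponentially
small tracking deviation underflows, so the transcritical passage would
never resolve in floating point. An optional `angle_drift` slowly
modulates the transversal line's slope (default off). Setting the slow
rate to zero (`freeze_slow`) freezes the state on one branch.

**Intermingled basins** (`simulate_riddled`): two coupled, damped
double-well oscillators with sinusoidal forcing,

```
x₁'' = −p x₁' + x₁ − x₁³ + α (x₁ − x₂) + A sin(μ t)
x₂'' = −q x₂' + x₂ − x₂³ − α (x₁ − x₂) + A sin(μ t)
```

with A = 1.011, μ = 0.632, α = −4, p = 0.1, q = 0.005. With the forcing
on, the pair switches irregularly between the two well states, the basins
of the coexisting attractors being finely interwoven; with A = 0 the
system started at a rest state (both oscillators at the same well bottom,
x₁ = x₂ = ±1) stays there. Default observables are the two positions.

**Heteroclinic cycle** (`simulate_heteroclinic`): a four-dimensional flow
on the unit 3-sphere with saddles at the poles (0, 0, 0, ±1), which differ
only in their last coordinate. With rates A(x₄) = α₁ + α₂x₄ and
B(x₄) = α₁ − α₂x₄ the raw field

```
h = ( A x₁ x₄,  −B x₂ x₄,  −γ x₃,  −A x₁² + B x₂² )
```

is projected onto the sphere's tangent space, `f = h − (x·h) x`, so the
unit norm is conserved exactly by the flow (and to integrator precision,
~1e−14 over t = 200 at dt = 1e−3, by RK4). The pole-to-pole connection
lies in the (x₁, x₄) plane, the return path in the (x₂, x₄) plane; x₃ is
transversally contracting (γ = 1). With α₁ = 1, α₂ = −0.1 the contraction
rate 1.1 at each saddle exceeds the expansion rate 0.9, so the cycle is
attracting and noise-free passage times grow monotonically. Noise enters
the last equation only, with amplitude σ(t) = min(a·e^{bt}, σ_cap),
a = 5e−5, b = 0.33: the growing amplitude counteracts the deterministic
slow-down so switching continues indefinitely. The cap (default 0.01)
keeps the late-time dynamics in the weak-noise regime. After each noise
kick the state is projected back onto the sphere. Default initial state:
displaced 1e−2 from the +pole into both connection planes.

## Observation protocol for the simulator demos

The demos (`recurseg.demos`) analyze the simulators the way the pipeline
expects its inputs: the densely integrated orbit is subsampled to
recording length (slow-fast: 1000 of t = 3000; riddled: 1200 of t = 240;
heteroclinic: 120 of t = 100 — a few to a few tens of samples per expected
dwell), lifted into M = 40 modules by a seeded column-orthonormal linear
map (which preserves all pairwise inner products, hence the recurrence
structure), and given isotropic measurement noise 0.05 per module. The
noise matters beyond realism: without it, samples near an attracting
branch or saddle are exponentially close to one another and the utility
can lock onto degenerate micro-classes at ε → 0.

The demo analyses set `min_dwell = T/10`: a metastable state must occupy a
macroscopic fraction of the recording. Cyclically switching systems
retrace their connecting paths, so path samples from repeated traversals
are genuinely recurrent; under the permissive library default those path
recurrences surface as small extra classes. Requiring macroscopic dwell
separates the two metastable activity levels from the switching paths —
the distinction the demos are meant to exhibit.

## Numerical choices and degenerate inputs

* Strict inequalities throughout (`d < ε`, `D < θ`), matching the ball
  definition.
* Time indices inside symbolic sequences are 1-based so 0 is free for the
  transient label.
* Cosine distances are computed as one Gram matrix and clipped to [0, 2];
  the same distance matrix is reused across the whole ε grid.
* Constant trajectories segment into a single covering state (complexity
  1); two-row trajectories run and report complexity 0 or 1.
* All randomness (generators, embeddings, noise) flows through explicit
  integer seeds; identical configuration and seed give byte-identical
  reports.

## Known limitations

* The grammar is O(T²) in memory and per sweep; trajectories much beyond
  T ≈ 10⁴ need chunked or sparse recurrence handling that is not
  implemented.
* Ensemble clustering assumes all subjects share one module space and
  normalization; no cross-space alignment is attempted.
* The θ-selection criterion (minimal covering set) is reported, not
  automatically decided.
* The Hausdorff distance of overlapping-but-unequal clouds is positive;
  clouds are compared as point sets, not as supports of distributions.
* The three ODE models are deliberately minimal mechanism illustrations,
  not biophysical models; their parameters are fixed reference values and
  the models make no claim to match empirical BOLD spectra.
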