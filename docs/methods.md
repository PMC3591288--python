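# Methods

## Model and assumptions

The simulator implements a deterministic, fully connected rate network
of N neurons without self-connections.  The activity equation

    dx_i/dt = S(u_i) − x_i,     u_i = Σ_j J_ij x_j + γ η_i,
    S(u) = tanh(β u),

has neural time constant 1; all times are reported in that unit.  The
sigmoid keeps the state inside [−1, 1]: under the explicit-Euler map
x → (1 − dt)x + dt·S(u) the bound is preserved exactly for any dt ≤ 1,
so no clamping is performed and an assertion (|x_i| ≤ 1 + 1e−12) guards
against integrator misuse.

During learning the couplings co-evolve,

    dJ_ij/dt = ε (ξ_i − x_i) x_j   (i ≠ j),   dJ_ii = 0,

with the input held constant at strength γ.  The rule is local (it uses
only the pre- and postsynaptic activity plus the target value at the
postsynaptic cell), decomposes into anti-Hebbian and supervised parts,
and is identically zero once x = ξ, so each learning step terminates on
its own.  No decay or bound is applied to J.  The diagonal is re-zeroed
after every Euler step, so it is exactly 0 at all times.

Two deliberate choices resolve parameters the model family leaves open:

* **Sigmoid gain β = 2.**  With β = 1 the spontaneous dynamics of a
  network that has learned a single mapping at (γ, ε) = (16, 0.01)
  relax to a fixed point near the origin, which contradicts the
  regime phenomenology this model is built to exhibit (chaotic
  input-free activity wandering near the stored target after one
  learning step).  With β = 2 the one-step spontaneous dynamics are
  chaotic (target-overlap SD ≈ 0.10 against a probe control ≈ 0.06,
  leading Lyapunov exponent > 0) while every multi-mapping statistic
  (capacity ≈ 0.2 N, D_μ sign change near 0.2 N, non-response regime at
  (1, 0.5)) is preserved.  β is a `DynamicsParams`/`LearningParams`
  field and can be changed per run.

* **No 1/N factor in the synaptic rate.**  The learned couplings must
  grow until the recurrent drive overcomes the external bias γ (the
  target projection ξᵀJξ/N reaches O(γ) ≈ 16–20 in the response
  regime).  With a rate ε/N the projection grows at most at rate
  ~ε m(1 − m) and a single step at ε = 0.01 does not finish within
  5·10³ time units; with rate ε the step finishes in ~50–100 units and
  ε retains its meaning as the inverse time-scale ratio of synaptic to
  neural dynamics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 100 | network size (50 used for the scaling check) |
| γ (learning = recall) | 16 | input strength; recall defaults to the learning value |
| ε | 0.01 | synaptic rate; (γ, ε) = (16, 0.01) is the response regime, (1, 0.5) the non-response regime |
| β | 2 | sigmoid gain |
| dt | 0.01 | Euler step for both neural and synaptic integration (synapses are slower by ε, so neural stiffness dominates) |
| convergence threshold | 0.95 | sliding 1-time-unit mean of the target overlap that ends a learning step (tanh saturation keeps overlaps below 1) |
| t_max | 5000 | per-step learning budget; exceeding it raises, never truncates silently |
| t_transient / t_measure | 100 / 400 | discarded and measured stretches of every recall or spontaneous run |
| n_inits | 5 | random initial states behind every recall average |
| θ | 0.01 | capacity threshold on D_μ; any small value gives essentially the same capacity on ensemble-averaged profiles |
| M | 30 | number of recent mappings analyzed (of 40 learned; both exceed the capacity, which is what matters) |
| probes | 10 | random control patterns in the competitor set and SD control |
| initial J | ±1/√N | binary ensemble, zero diagonal; amplitude keeps the initial recurrent drive O(1) |

Seeding: one root seed per experiment is split (`SeedBundle`) into named
streams — patterns, probes, initial J, per-step learning initial states,
recall initial states, analysis — so any sub-experiment replays exactly.
Ensemble runs derive per-network roots from the experiment seed via
`derive_seed`.

## Measurement conventions

Mapping indices in all measurements are **ages**: age 1 is the mapping
learned last.  The time-averaged overlap is linear in the state, so the
batched integrator accumulates the time-mean state per trajectory and
obtains every pattern overlap from it with one matrix product; recall
for all 30 ages × 5 initial states runs as one lock-step batch.

Recall success (age μ) requires the initial-state-averaged m̄ with
target μ to exceed that of every competitor: the other analyzed targets,
all analyzed inputs (including input μ), and the 10 probes.  D_μ and the
capacity use only the target/input pair.  The ensemble capacity applies
the θ-threshold to the *network-averaged* D profile; per-network
capacities are also reported but are noisy, because single-network D
values fluctuate by ~N^(−1/2) ≈ 0.1 ≫ θ (random cross-overlaps between
patterns), which is precisely the artifact the ensemble-averaged
definition suppresses.  For the same reason the non-response-regime
statement "capacity is zero or one" is asserted on the ensemble value.

Spontaneous statistics integrate one input-free trajectory per network
and report the population SD of the overlap with each of the M most
recent targets; the mean overlap is ≈ 0 by the odd symmetry of the
dynamics, so the SD carries the signal.  The probe SD is the matched
control.

Power-law decay exponents fit log(value) against log(μ) by least
squares; the reported exponent uses the convention value ∝ μ^(−exponent).
The capacity-vs-N slope is fitted through the origin (capacity = a·N),
matching the proportionality claim being tested.

## Bifurcation and Lyapunov analysis

Bifurcation scans sweep γ upward, integrating from the previous γ's
final state (continuation) plus 3 independent random restarts to expose
coexisting attractors, and collect strict interior local maxima of the
target- and input-overlap series; a constant series contributes its
single value, and a monotone relaxation contributes its endpoint.  A
grid point is labelled a fixed point when every run's post-transient
overlap range is below 1e−4.

Lyapunov exponents propagate an orthonormal tangent frame with the same
Euler map as the state (Jacobian I + dt(diag(S′(u))J − I)), with QR
reorthonormalization every 10 steps, a 200-unit transient and a
2000-unit accumulation window by default; exponents are time-averaged
log R-diagonals, and the convergence diagnostic compares estimates from
the last half of the run against the whole (flag, not exception, on
drift > 0.05).  The default computes the leading k = min(N, 20)
exponents; only the count of positive exponents (tolerance 1e−3) is
consumed downstream, and the observed counts stay well below 20.  The
Euler-map estimate carries an O(dt·|λ|²) bias, ~0.005 at the default
step for |λ| ≈ 1.

## Synthetic data and what the tests show

All inputs are generated internally: i.i.d. uniform ±1 patterns, initial
activities uniform on [−1, 1], initial couplings binary ±1/√N.  This is
the model's own stated ensemble, not a surrogate for recorded neural
data; passing tests therefore validate the dynamical mechanism (learning
convergence, regime dichotomy, palimpsest capacity ≈ 0.2 N, projection
signatures, bifurcation sequences), and say nothing about correlated or
sparse pattern statistics, noise-driven dynamics, spiking, or biological
parameter ranges.  Correlated/hierarchical pattern ensembles are
explicitly out of scope.

## Problem sizes

Ensemble statistics in the test suite and the acceptance script use 3
networks per condition (40 mappings, N ∈ {50, 100}, 5 initial states
per recall), the package's desk-scale default; the capacity plateau and
the D_μ sign-change age then carry a spread of a few mappings across
seeds, which is the scale of the tolerances used.  Larger ensembles
(e.g. 100 networks) sharpen the same numbers and are available through
the same functions (`train_ensemble(..., n_networks=100)`) or the CLI.

## Known limitations

* The convergence criterion (windowed mean overlap ≥ 0.95 for one time
  unit) is a pragmatic stopping rule; the underlying rule only
  guarantees dJ → 0 as x → ξ.
* Per-network capacities at small N are fluctuation-dominated (see
  above); compare ensembles, not single networks.
* Near the R/NR boundary the regime classification (capacity > 1) is
  finite-size sensitive; the SD ridge marker in `phase_scan` is a
  heuristic.
* Fixed-step Euler at dt = 0.01 is accurate to O(dt) per the
  step-halving and adaptive-integrator checks, but stiff parameter
  combinations (very large γ·β) would need a smaller step.
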