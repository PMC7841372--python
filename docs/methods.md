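# Methods

## Model

The package simulates point agents moving at constant speed κ on an
L-periodic square.  One scalar skill parameter *p* per agent controls
the fidelity of its whole perception–action loop: every noise draw
(uniform on [−ξ, ξ]) enters the dynamics divided by *p*.  High *p*
therefore means accurate perception of one's own position and heading;
low *p* models an unskilled or deafferented agent.  The printed form of
the heading and position equations is ambiguous about whether noise is
multiplied or divided by the skill; the surrounding semantics (skill
*compensates* noise) force division, and this package uses ξ/p
throughout.

Three couplings can be switched independently:

- **self**: the agent's next heading is its own heading plus ξ₂/p;
- **social** (Vicsek alignment): the base heading is the circular mean
  — atan2 of the mean sine and mean cosine — over all agents within the
  interaction radius *r*, counting the agent itself; an agent with no
  neighbour keeps its own heading exactly.  Neighbourhood distance is
  minimum-image periodic Euclidean distance, consistent with the
  periodic arena.
- **environmental** (gradient taxis): a static, circular Gaussian
  concentration bump of unit variance sits at the arena center; its
  analytic gradient, normalized, defines the gradient heading θ_g
  through the two-argument arctangent.  A single-argument arctangent of
  g_y/g_x would lose the quadrant and could never steer agents on the
  far side of the bump, so the quadrant-correct form is used.  θ_g is
  evaluated at the agent's *actual* position, not its noise-perturbed
  perceived one.  At the exact center (‖g‖ ≤ 1e−12) the direction is
  undefined and the agent's current heading is substituted.  The field
  is a single bump on [0, L]²; no periodic images are summed.

The full update, synchronous across agents (all new headings computed
from the time-t snapshot before any position advances), is

    θ' = wrap( α·wrap(base + ξ₂/p) + β·wrap(θ_g + ξ₃/p) ),  α + β = 1
    x' = ( x + ξ₁/p + κ·(cos θ', sin θ') ) mod L

with ξ₁ a per-coordinate 2-vector of independent draws sharing the one
half-width ξ.  `wrap` maps to (−π, π] and is an exact identity for
angles already inside that interval, so noise-free dynamics preserve
headings bit-for-bit.

**Angle mixing.**  The default mixes the two heading terms as a literal
scalar weighted sum of angle *values* (each bracketed term and the
result wrapped), which is how the update is written.  Scalar averaging
of angles has a branch-cut artifact near ±π: when the social term and
the gradient term lie on opposite sides of the cut, the weighted sum
points far from both.  This artifact is part of the model as written
and is retained; a weighted circular-mean variant
(`angle_mixing="circular"`) is provided for sensitivity analysis but is
not the default.  Whether intermediate terms were wrapped in the
original runs is unknowable from the description; wrapping each term is
the convention here.

**Excluded values.**  p = 0 (division by skill) is rejected by config
validation even though the skill range is nominally [0, 100]; runs
require p > 0.  With the environment disabled, β must be exactly 0.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| L | arena side length | 5 | length |
| κ | step length (speed) | 0.05 | length/step |
| ξ | noise half-width (shared by ξ₁, ξ₂, ξ₃) | 0.5 | — |
| p | PK skill per agent | 50 | — |
| α, β | self/social vs gradient weight | 1, 0 | — |
| r | interaction radius | 1 | length |
| n_steps | steps per run | 2500 | steps |
| ε | arrival tolerance | 0.5 | length |
| v_a threshold | coordination cutoff on final-window mean | 0.95 | — |
| window | final fraction of a run used for v_a | 0.1 | — |

L, κ, ξ, r, and n_steps are the study conditions; κ is valid in
(0.001, 0.1) for L = 5 and 0.05 is the value used for all published
graphics.  The sweep grids are p ∈ {1, 5, 10, 20, 30, 40, 50, 100}
(a superset of every spot value the study names) and
ξ ∈ {0.1, 0.5, 1.0, 2.5, 5.0}.

## Observables

- **Order parameter** v_a = (1/nκ)‖Σ κ(cos θᵢ, sin θᵢ)‖; κ cancels but
  is kept for fidelity to the velocity-vector definition.  Ensemble
  coordination is judged on the mean over replicates of each run's mean
  v_a over its final 10% of snapshots; runs are never stopped at
  arrival, so this window always exists.
- **Success / first arrival**: a run succeeds at the first step at
  which *every* agent is simultaneously within plain Euclidean distance
  ε of the field center (the center is interior, so periodicity is
  irrelevant).  τ is averaged over successful runs only and reported as
  missing when no run succeeds.  τ_norm is the min–max normalization of
  mean arrival times across a sweep.

**Calibration of ε.**  The arrival tolerance is the model's one free
observable parameter (the study does not state one).  It was calibrated
once against the chance-level anchor — two high-skill agents with the
gradient term removed (α = 1, β = 0, p = 100) are reported to succeed in
about 40% of runs — by scanning ε ∈ {0.05, 0.1, 0.25, 0.5} at 500
replicates and freezing the value whose success rate is closest to 0.4.
The three smaller candidates give s = 0.002–0.024: in this regime the
pair aligns at first contact, which freezes the inter-agent separation
near r = 1, so simultaneous presence in a disk of radius ≤ 0.25 is
geometrically rare.  ε = 0.5 gives s ≈ 0.37–0.42 across seeds and has a
natural reading — two agents both inside the r/2-disk are mutually
within the interaction radius, i.e. the arrival is itself coordinated —
and is frozen as the package default for *all* reported statistics.
Alternative two-agent arrival definitions (either agent, the pair
midpoint, both-agents-ever with τ the second arrival) were examined at
the same grid during calibration and none reproduces the anchor pair
(s ≈ 0.4 together with τ ≈ 400); the all-agents-simultaneously
definition was retained.

## Randomness and reproducibility

One seeded generator per run.  Draw order is fixed: initial positions
(uniform on [0, L)²), initial headings (uniform on (−π, π]), then per
step and per agent ξ₂, ξ₃, ξ₁ₓ, ξ₁ᵧ.  ξ₃ is drawn even when β = 0 so
the stream layout never depends on which couplings are active.  Because
uniform variates come off the stream sequentially, the per-run noise
may be drawn in one block without changing the stream, which is what
both `simulate` and the lock-step ensemble runner do; the test suite
asserts draw-for-draw agreement between the vectorized stepper, a
repeated-`step()` rollout, and a pure-Python per-agent reference loop.
Ensemble and sweep cells derive child seeds (kept below 2³¹) from the
master seed and the cell index via `numpy.random.SeedSequence`, so
cells use disjoint streams and every result is bit-reproducible from
(config, master seed).

## What the generator does and does not emulate

The simulated conditions are exactly the study's: two (or one) point
agents, uniform random initial conditions, a single static Gaussian
bump, uniform bounded noise, fixed skill.  The model has no inertia, no
body geometry, no learning (p is constant within a run; making α, β
functions of p, or p a function of time, are deliberate extension hooks
left unimplemented), no multi-source or time-varying fields, and no
more than two agents in the published protocols.  Passing tests
therefore certify the minimal model's internal regularities — noise
scaling laws, alignment, taxis, ensemble statistics — not any property
of biological proprioception.

## Numerical choices

- Wrapping to (−π, π] uses π − (π − θ) mod 2π, with an exact-identity
  fast path for in-range angles; −π maps to π.
- atan2-based angles add +0.0 to the sine argument so a signed zero
  cannot produce −π.
- The gradient is analytic (the normalized gradient equals the exact
  unit vector toward the center; asserted to 1e−12); central
  differences are kept only as a test oracle.
- Arrival comparison is exact (`distance ≤ ε`, no tolerance).  A
  noise-free approach that meets the disk boundary exactly can arrive
  one step late through the stepper because position accumulation
  carries ~1e−16 of rounding per step; the analytic worked example
  (arrival at step 19 from one unit away at κ = 0.05, ε = 0.05) is
  exact on the analytic path.
- CSV output uses 17 significant digits and CSV input uses
  round-trip float parsing, so written results reconstruct the binary
  values exactly.
- Ensembles advance all replicates in lock-step on replicate-stacked
  arrays; at study scale (500 × 2500 × 2 agents) one ensemble cell runs
  in a few seconds on one CPU.  Unit tests use reduced replicate counts
  and horizons (stated in each test) for the qualitative regime checks;
  the study-scale checks live in the acceptance test module and the
  acceptance script.

## Known limitations and open discrepancies

Two published regime values are *not* reproduced by this
implementation, at any arrival definition or tolerance examined; both
checks are kept failing rather than loosened, and the corresponding
tests document them:

1. **Alignment-only arrival time.**  With α = 1, β = 0 the reported
   pair is s ≈ 0.4 with τ ≈ 400.  Under these dynamics the aligned pair
   performs a near-ballistic search with frozen geometry; conditional
   arrival times then spread over the whole 2500-step run (measured
   mean ≈ 1050).  A mean of 400 jointly with s = 0.4 is incompatible
   with any memoryless or frozen-geometry search: a hit rate giving
   s = 0.4 over 2500 steps implies a conditional mean near 1100.
2. **Success at β = 0.05.**  The reported s = 1.0 for α = 0.95,
   β = 0.05, p ≥ 50 is measured here at ≈ 0.72.  The gradient weight
   bounds the per-step turn toward the center by ~β·π ≈ 0.16 rad, so a
   coordinated pair cannot orbit tighter than ~κ/(β·π) ≈ 0.3 and in
   practice circles at radius 0.6–1.0, outside the ε = 0.5 disk; only
   noise kicks let it dip inside.  The arrival time of the successful
   runs (≈ 330–400) does match the reported τ < 400.  Reproducing
   s = 1.0 would need ε ≈ 1, which the chance-level anchor excludes
   (it would push the anchor to s ≈ 0.97).

Additionally, the equal-weights regime measures s ≈ 0.95 rather than
1.0: in every failing replicate both agents individually visit the
center (minimum distances ~0.01) but never simultaneously — with
v_a ≈ 0.5 the pair is uncoordinated and its center visits are out of
phase.  This sits exactly at the ±0.05 tolerance boundary.
The minimal coordinating skill on the sweep grid is measured at p = 10
(reported: 20), one grid cell away, within the stated grid-cell
tolerance; the threshold is sensitive to how long pairs must stay
within r during the final observation window.
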