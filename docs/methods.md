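# Methods

## The steering-dynamics model

`routenav` models planar, goal-directed locomotion with obstacle avoidance
as a dynamical system acting on the heading direction φ (radians, world
frame, counterclockwise from +x). The agent translates at constant forward
speed; its heading obeys a damped mass–spring equation with a point
attractor at the goal bearing θ_g and a repeller at each obstacle bearing
θ_Oi:

    φ̈ = −β φ̇
         − γ (φ − θ_g) (e^(−c1 d_g) + c2)
         + Σ_i ε (φ − θ_Oi) e^(−c3 |φ − θ_Oi|) e^(−c4 d_Oi)

- β (1/s) damps turning; γ (1/s²) is the stiffness of the goal attraction;
  ε (1/s²) scales obstacle repulsion. These three are the free parameters
  that characterize an agent.
- c1 (1/m) sets how goal attraction decays with goal distance d_g and c2
  (dimensionless) is its floor, so attraction never vanishes at long range.
  c3 (1/rad) makes repulsion fall off as the obstacle leaves the direction
  of travel, and c4 (1/m) as its distance grows. They are held fixed
  throughout — shipped in `routenav/data/fw_constants.json` with the
  magnitudes of the original route-selection formulation (c1 = 0.4, c2 =
  0.4, c3 = 6.5, c4 = 0.8) and loaded as configuration, not asserted as
  empirical truth.
- Every bearing difference φ − θ is wrapped to (−π, π] before use;
  unwrapped differences would make the stiffness and exponential terms
  meaningless after a full turn.

Routes are not planned: they emerge stepwise from the interplay of the
attractor and repellers. Two structural properties matter for
interpretation. First, φ = θ_g, φ̇ = 0 with no obstacles is an exact
equilibrium. Second, an obstacle dead ahead (φ = θ_Oi exactly) contributes
zero repulsion — an unstable equilibrium. The test suite asserts both, along
with the antisymmetry of the single-obstacle term and the monotone decay of
repulsion with distance.

### Integration

Trajectories are integrated by explicit Euler at dt = 0.02 s, matching the
game's 50 Hz update. The equation is non-stiff at the scales used here, and
first-order convergence is verified by a dt-halving test. Two modes exist:

- `continuous` (default for fitting): the raw dynamics.
- `game`: |φ̇| clamped to 25°/s and |φ̈| to 62.5°/s², the keyboard caps.

A run terminates when the agent disc (radius 0.25 m, chosen symmetric with
the 0.25 m obstacle cylinders; configurable) touches the target
(`reached_target`) or an obstacle (`hit_obstacle`), or after t_max = 20 s
(`timed_out`) — the same cutoff as the preprocessing discard rule, so
simulations cannot outlive admissible trials.

## Task geometry and the navigation game

The field is a 40 × 40 m square centered on the origin, +y pointing from
the starts toward the targets. The canonical design crosses obstacle
configurations with two starts (±5, −16) and three targets ((±12, 16),
(0, 16)); 18 configurations give the full 108-scenario design. Routes are
classed by the lateral relation of start and target: near-side (same side),
far-side (opposite), middle (target centered).

The game environment reproduces the study task: forward speed 10 m/s;
turning accelerates at 62.5°/s² toward the commanded direction, clamped at
25°/s, and decays at the same rate when no key is held; updates at 50 Hz;
episodes end on target capture (+1), collision (−1), or 30 s timeout (−1).
Observations are 11 rays at egocentric angles 0, ±9°, …, ±45°, each
reporting the nearest intersected object class as a one-hot of size 4
(target / obstacle / other / nothing; walls are the only "other" object),
plus the egocentric target bearing and distance — 46 inputs. Actions are a
one-hot pair: move {forward, none} × rotate {left, none, right}. Policies
are queried every 5th frame and their action held between queries. The
maximum ray length defaults to the field diagonal so walls are always
detectable. Ray classification is validated against a brute-force
1-cm-marching oracle on random scenes.

The scripted policy that drives the environment discretizes the model: at
each decision it integrates a desired turning rate from the heading
acceleration and presses left/right when it exceeds a ±2° /s threshold.
One behavior is added beyond the raw discretization: when the goal bearing
error exceeds 35°, the policy stops and turns in place. The game permits
stopping, and at 10 m/s the capped turn rate gives a ≈23 m turning radius,
so a moving agent cannot recover from an overshoot; without the stop-and-
turn maneuver, keyboard episodes frequently time out circling the target.

## Preprocessing

Raw 50 Hz trajectories are linearly interpolated in time to 1,000 samples
(heading via unwrapped-angle interpolation). Two discard rules apply per
scenario: cumulative path length above 1.2× the scenario mean (computed
over all trials before any discards), and duration above 20 s. Each kept
trajectory is reduced to one x-value per half-open 20 cm bin of y over
[−16, 16) — 160 values. Bins average over every visit when a path
backtracks; empty interior bins are filled by linear interpolation between
non-empty neighbors and boundary bins by nearest-value extrapolation (a
trajectory is rejected if it spans less than half the y range). Binning is
idempotent on bin-center data and equivariant under mirror reflection; both
are tested.

## Comparison metrics

- **Pairwise distance**: mean absolute x-difference over the 160 bins
  (meters). It is a pseudometric; property-tested.
- **Group mean / 95% band**: per-bin mean; per-bin empirical 2.5th and
  97.5th percentiles with the linear-interpolation percentile definition
  (fixed and documented so results reproduce bit-exactly).
- **CI containment**: the fraction of bins in which a reference trajectory
  lies inside the band.
- **Route signature**: per obstacle, the side of the travel direction on
  which the obstacle lies at closest approach (cross-product sign). This
  automates what was originally a by-hand judgment. Obstacles never
  approached within a 3 m relevance radius are masked before grouping so
  far-off obstacles do not split routes spuriously. Preferred routes are
  signature groups holding ≥ 10% of a population's trajectories.
- **Aggregation**: between-group distances pair every trajectory of one
  population with every trajectory of the other within a scenario;
  within-group distances pair trajectories of the same population excluding
  same-agent pairs. Both are averaged per agent × route type into a tidy
  table whose factor structure (player × route type, random player ID)
  matches what external mixed-model tools expect. The package deliberately
  does not run those inferential models.

Distances are reported in meters throughout.

## Model fitting and parameter recovery

Free parameters (β, γ, ε) are fitted per trajectory by differential
evolution (SciPy) minimizing the dynamic time warping (DTW) distance
between the observed path and the path simulated from candidate parameters
in the same scenario, using the observation's dt, initial heading, and
duration. DTW uses Euclidean local cost on raw (x, y) samples, the
symmetric match/insert/delete step pattern, and boundary anchoring; the
dynamic program is numba-compiled and verified exactly against exhaustive
warping-path enumeration for short sequences. Candidates whose simulation
produces non-finite state receive a large finite penalty so the population
can leave unstable regions. Default search bounds are β ∈ [0.1, 20] 1/s,
γ ∈ [0.5, 400] 1/s², ε ∈ [1, 1000] 1/s²; optimizer settings (popsize 12,
maxiter 60, tol 0.01, Latin-hypercube init, L-BFGS-B polish, seeded) are
configuration. Collapsed bounds pin a parameter.

Per-agent *characteristic parameters* are the arithmetic means of that
agent's fits (all successful fits; no error cutoff by default) and can be
re-simulated across scenarios.

The recovery study closes the loop: simulate at known parameters,
optionally add Gaussian position noise, refit, and tabulate relative
errors. On the default five-point in-bounds grid with no noise, median
relative errors are below 10⁻⁴ % and the median DTW cost is ≈0 — the free
parameters are jointly identifiable in the default recovery scenario
because its obstacles straddle the direct path (a trajectory that engages
no obstacle constrains ε only weakly; the study quantifies rather than
assumes identifiability).

Open conventions resolved here: DTW is computed on raw 2-D position
sequences without normalization (the y-binned representation serves the
distance metrics, not the fitting objective), and all angular stiffnesses
are in radians. Fitted scales are therefore only comparable to other
radian-based formulations.

## Synthetic populations

The generator produces the statistical structure the analysis assumes,
without any of the study's data:

- **Obstacle configurations**: uniform rejection sampling keeping 2 m
  clearance from walls, starts, targets, and other obstacles; 9 obstacles
  per configuration by default (a generator knob — the original
  per-configuration counts are not public in the main text). A
  configuration is kept only if the mean-parameter agent completes all six
  canonical scenarios (`navigable_obstacle_configs`): the study required
  successful trials of every player, and rejection screens out pathological
  dead-ahead placements at the model's unstable equilibrium.
- **Agents**: characteristic (β, γ, ε) drawn log-normally around profile
  means with a between-agent coefficient of variation (CV); each trial
  re-jitters them with a within-agent CV. Log-normal is a modeling choice
  (positive support, right skew), stated as such.
- **Profiles**: `human_like` — keyboard control, heading-rate noise sd 0.1
  rad/s, CVs 0.3 between / 0.15 within; `drl_like` — keyboard control,
  noise sd 0.02, CVs 0.05 / 0.02. Both populations act through the
  discrete action space, as both humans and the original trained agents
  did; what separates them is parameter spread and input noise. The
  profile means (β, γ, ε) = (10, 100, 500) are a calibration of this
  package: the walking-speed magnitudes in the constants file (3.25, 7.5,
  198) cannot capture a 0.5 m-radius target at 10 m/s — the heading spring
  is too soft and trajectories shave past and time out — so the generator
  uses rate-scaled values that complete the task (≈92% direct completion
  over 48 random scenarios) and lie inside the default fitting bounds.
  These means are generator knobs, not estimates of any study's fits.
- **Trials**: agent × scenario × repetition (6 repetitions by default).
  Collisions re-run the trial with a fresh jitter draw, emulating the
  game's restart-on-collision rule, up to 10 retries; exhausted trials are
  flagged excluded, never silently dropped. Identical seeds give bitwise
  identical datasets.

What the generator does *not* emulate: reaction latency and anticipatory
steering of real players, learning across trials, speed modulation (speed
is constant or zero), and any resemblance to specific study participants.
Passing tests therefore show that the pipeline's machinery is correct and
that the qualitative human-vs-agent variability ordering is reproduced
under the stated noise model — not that real data would yield the study's
quantitative values.

## Pipeline, outputs, and problem sizes

`run_pipeline` executes scenario generation → trial generation →
preprocessing → metrics → fitting (a configurable subset of trials) →
parameter summary, writing tidy CSVs plus a manifest with the seed, stage
counts, and SHA-256 hashes of every output, so any number is traceable to
configuration + seed. The ε summary includes its Box-Cox transform
(maximum-likelihood λ, (x^λ − 1)/λ), since fitted ε distributions are
strongly right-skewed.

Default analysis sizes are chosen to run on a single CPU in minutes: the
shipped comparison uses 10 agents per profile × 6 scenarios × 6
repetitions, and the recovery study a 5-point grid with the reduced
optimizer budget above. All sizes scale up through configuration.

## Known limitations

- Explicit Euler at 50 Hz is the game's clock, not a high-accuracy
  integrator; fitted parameters absorb its discretization error.
- At 10 m/s the repulsion horizon (≈3 m at c4 = 0.8/m) gives ~0.3 s of
  warning, so the model cannot dodge nearly-dead-ahead obstacles late;
  avoidance manifests mainly as widened clearance along curved routes.
- The DTW objective is not convex in (β, γ, ε); differential evolution
  with the default budget recovers noiseless parameters essentially
  exactly, but noisy or near-straight trajectories identify ε weakly.
- Within-group distances of the synthetic populations are smaller than
  real human data would give (the generator's noise model is narrower than
  human behavior); only their ordering is a designed property.
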