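# Methods

This note documents the models and procedures implemented in `navgaze`, the
choices made where the design was genuinely open, and what the synthetic
sessions do and do not establish about real data.

## Arena model

An arena of granularity `n` tiles a regular hexagon of side `n·s` meters
(side length `s` per triangle) with `6n²` equilateral triangles. Each
triangle is a discrete state; each of the `9n² − 3n` interior edges is a
transition, passable unless an obstacle occupies it. The study-scale arena
is `n = 5`, `s = 2 m` (150 states, 210 transitions, ≈260 m²; one state is
0.67% of the area). The lattice is built as rows of alternating up/down
triangles masked to the hexagon, numbered row-major from the bottom; interior
edges are numbered by sorted `(min cell id, max cell id)` so obstacle indices
are portable. Points exactly on an edge belong to the incident cell with the
smaller id.

Closeness centrality is `C(s) = (N−1)/Σ_{s'} d(s', s)`. The distance `d`
defaults to the geodesic under the 12-direction planning metric (in
side-length units), consistent with the value function; unit-step distances
are available via `centrality(..., distance="steps")` since the convention is
not forced by the definition. Betweenness counts shortest paths on the
passable-edge graph (each unordered pair once; networkx's unnormalized
convention). Arena complexity is `100·(max C̄ − C̄)` across a set of arenas,
so the most open arena scores exactly 0.

## Planning

Navigation is a deterministic MDP with twelve headings spaced 30°. Relative
to a cell's own axes the headings form three families with step lengths
`√3/3` (edge-crossing), `1` (same-orientation translation), and `2√3/3`
(vertex-crossing), in side-length units. Feasibility: an edge move needs its
edge passable; a translation needs both edges crossed by the
centroid-to-centroid segment passable; a vertex move needs at least one of
the two minimal edge-wise detours around the shared vertex fully passable
(a navigator can round a wall end). Whether a planner should allow vertex
moves through fully-walled vertices is not decidable from first principles,
so the rule is switchable (`vertex_rule="detour"` default, `"geometric"`
alternative).

Value iteration performs synchronous Bellman backups with per-step reward
equal to the negative step length, γ = 1, values initialized at 0, the goal
clamped to 0 every sweep, and at most 100 sweeps with early stop at
`max|ΔV| < 1e−12`. The fixed point satisfies `V*(s) = −geodesic(s, goal)`
for reachable states; unreachable states keep decreasing until the sweep cap,
which deliberately caps their values — this is what makes toggled-obstacle
value differences finite when a toggle disconnects the goal. Greedy ascent
with deterministic tie-breaking (lowest heading index first) extracts optimal
trajectories. A successor-representation variant computes
`V = M R`, `M = Σ_{t≤100} T_rw^t`, with `T_rw` the row-normalized adjacency
and a one-hot reward at the goal.

Stopping is scored 2 points in the goal state, 1 in a state sharing a border
with it (geometric sharing, regardless of an obstacle on the edge; a
`require_passable` switch inverts this), 0 elsewhere.

## Transition relevance

The relevance of transition `k` for navigating from `s0` to goal `g` is

    Ω_k(s0, g) = [V(s0 | T_k = 1) − V(s0 | T_k = 0)]²

with both values from full value iteration on otherwise-identical arenas.
A path-dependent variant sums the squared value differences over every state
on the optimal path. Per-goal computation is organized around the
observation that one pair of value functions per toggled edge yields Ω for
*all* start states, so a `(n_edges × n_states)` table per goal is cached and
per-frame lookups are O(1).

Per-frame gaze relevance takes the interior edge nearest the gaze ground
point (perpendicular point-to-segment distance, no distance cap by default),
scores it against the participant's current state, and normalizes by the
arena-wide maximum for that state and goal. Frames at the goal state itself
have an all-zero Ω column (the goal value is clamped), and their normalized
relevance is defined as 0. The shuffled null re-scores identical frames
against the goal of a uniformly drawn different trial (seeded); a
single-trial session falls back to a uniform random goal with a warning.

ROC curves plot the cumulative probability of shuffled relevance against the
cumulative probability of true relevance over pooled thresholds; the
trapezoidal area equals the Mann–Whitney `U/(n₁n₂)` with ties counted half
(asserted to 1e−12 against `scipy.stats.mannwhitneyu`). Bootstrap CIs
resample both groups, seeded.

The bottleneck analysis averages per-edge relevance over all start states,
normalizes per goal by the arena max, excludes edges whose midpoint lies
within 1 m of the goal centroid for that goal, averages across goals, and
correlates with the mean betweenness of the two incident states.

## Gaze pipeline

* Blinks: frames with pupil openness < 0.8 are masked from gaze analyses
  (never dropped — position and joystick streams stay intact).
* Epochs: movement onset/offset come from a centered 5-frame moving average
  of the absolute joystick speed crossing 0.2 m/s (≈10% of the 4.75 m/s
  cap); onset is the first up-crossing after goal foveation, offset the last
  frame at or above threshold before the button press. Epochs are search
  `[appearance, foveation)`, pre-movement `[foveation, onset)`, movement
  `[onset, offset]`. All smoothing filters use edge-truncated windows.
* Spread: within-trial spread is `√(E_n[Var_t x + Var_t y])` and
  across-trial spread `√(Var_n[E_t x] + Var_n[E_t y])`, reported in meters
  (raw variances also exposed).
* Trajectory projection: gaze is perpendicularly projected onto the
  trajectory polyline; `f ∈ [0, 1]` is the arc-length fraction; frames
  farther than 2 m from the polyline are masked.
* Saccades: azimuth `atan2(x, √(y²+z²))` and elevation `atan2(z, √(x²+y²))`
  of the head-frame gaze vector (x right, y forward, z up), speed from
  consecutive-frame differences × frame rate, onsets at up-crossings of
  50 °/s.
* Subgoals: turns are maximal intervals where the 8-frame-median-filtered
  absolute heading velocity exceeds 60 °/s, numbered from the goal backwards
  (stop = subgoal 0). Trial time is normalized to 25 points per turn and 100
  per straight segment, indexed backwards from the stop (−1 = stop), with
  overlapping turn intervals merged first.
* Alternative trajectories: loopless paths enumerated in increasing length
  (Yen's algorithm on the feasible-move graph, 200-candidate cap) up to
  1.25× the optimal length, greedily retained so that any two retained paths
  share at most 50% of their states (overlap relative to the shorter path).
  A frame explores an alternative iff its gaze is within 2 m of an
  alternative's states off the executed trajectory and more than 2 m from
  the executed trajectory.

## Sweep detection

The median-filtered (20-frame window) `f` series is scanned for maximal
strictly-monotone runs; exact ties terminate runs (the median filter
produces flats, which must not inflate run lengths), and masked frames split
them. The signed run length `m` is compared with a permutation null built by
re-projecting the same trial's gaze onto the trajectories of 20 randomly
drawn other trials (without replacement when possible) and pooling their run
lengths. Runs with null CDF < α/2 are backward sweeps and CDF > 1 − α/2
forward sweeps, α = 0.02, strict inequalities. Post-processing, in order:
merge same-direction sweeps separated by < 25 frames; drop sweeps
off-trajectory on > 30% of frames; drop sweeps < 25 frames; drop sweeps with
`f`-variance < 0.001; drop sweeps covering < 20% of the trajectory. The
25-frame minimum is applied after merging (the rule order is ambiguous; this
choice is switchable in principle by reordering the documented post-filter
list). Sweep speed is `coverage × trajectory length / duration`.

Two estimator properties worth knowing: (a) the 20-frame filter and the
merge rule stretch detected extents by roughly ±5 frames per side, so the
duration-based speed estimate is biased low by ~20% for 0.3–0.5 s sweeps
and is accurate for longer ones; (b) the null is built from the trial's own
gaze, so trials that genuinely sweep a lot have conservative nulls — and in
open arenas, where different trials' trajectories are near-parallel, the
null is inflated by construction. Sweeping is therefore best characterized
in complex arenas, which matches where the phenomenon concentrates.

## Agent simulations

Agents hold a corrupted adjacency: `⌈0.5 × n_blocked⌉` blocked transitions
believed open and an equal number of open transitions believed blocked
(uniform, seeded, boundary edges never touched). Before navigating, sighted
agents foveate `k` transitions (default 8) — uniformly at random; von Mises
weighted by the bearing of each transition midpoint around the goal
direction (κ = 5; the generating density's σ parameter is redundant with κ
and is not exposed); or the `k` transitions most relevant *under the
subjective model* (the agent cannot consult the truth it lacks; a switch
scores on the true model for comparison). Sampled transitions are corrected
to their true status and the subjective value function recomputed.

Navigation is greedy on subjective values with a 100-step budget (failure is
recorded, not raised). Attempting a truly blocked move fails in place;
discovering an unexpectedly open move succeeds; in both cases the agent
observes the edges that the move would cross (all requirement alternatives
of that action) and corrects them, recomputing values. A subjectively stuck
agent attempts a uniformly random action. Corrections persist within the
trial; the corrupted baseline is redrawn per trial (per-run persistence is a
caller choice since corruption, sampling and navigation are separate calls).

The full experiment crosses policies × arenas × trials × k with corruption
and start/goal pairs shared across policies for paired comparisons. The
default experiment follows the 25-arena × 100-trial design at n = 3 with k
spaced over 2..14; the shipped acceptance suite runs a 10 × 30 version at
k = 8 plus a full-sampling arm, which reproduces the qualitative ordering
(blind ≤ random ≤ goalward ≤ directed in success; reversed in excess path
ratio) with comfortable margins. Excess-ratio comparisons are paired over
the trials every policy completed: success-conditioned means would otherwise
mix in the harder trials that only sighted agents finish.

## Synthetic sessions

The generator emulates the statistical structure the analyses consume, with
every frame annotated: 90 Hz logs; movement along the optimal trajectory
with acceleration-limited trapezoidal speed profiles (cruise 2 m/s, cap
4.75 m/s) and turn-in-place rotations at 120 °/s (safely above the 60 °/s
turn threshold); epoch boundaries (search 1–2 s, pre-movement 1.5–3 s);
a seeded semi-Markov fixation mixture (goal / most-relevant transition /
alternative path / random location / sweep) with geometric dwell times
(mean 0.4 s); scheduled backward sweeps in pre-movement (from the goal,
f = 1, backwards) and forward sweeps during movement (from the participant's
current trajectory fraction toward the goal) at 20–26 m/s along the path,
each flanked by 0.2 s anchor fixations at its departure and arrival points;
Poisson blinks (0.1 Hz, 0.2 s) that drop pupil openness below the 0.8
threshold.

Gaze measurement error is modeled as a quasi-static Ornstein–Uhlenbeck
calibration bias (σ = 1.15° per axis, correlation time 30 s) plus 0.1° white
frame jitter, applied to the gaze ray cast from a 1.72 m vantage and
intersected with the ground plane. The 1.15° figure describes the *spread*
of tracker error; modeling it as i.i.d. per-frame noise at 90 Hz would imply
a perpetual ~146 °/s angular speed — every frame would cross the saccade
threshold — so the correlated-bias model is the physically sensible reading.

What passing tests do and do not show: the generator shares the arena,
planner and relevance code with the analyses (its *annotations* are
independent ground truth, its gaze process is not a model of human gaze).
Detector calibration and recovery results therefore demonstrate internal
consistency of the pipeline under realistic noise, sampling rates and task
geometry — not that human sweeps are detected at these rates. Real gaze has
smooth pursuit, head-eye coordination, and fixation statistics the
semi-Markov mixture does not attempt to reproduce.

## Problem sizes and numerical choices

The shipped suites use n = 3 arenas (54 states) for planner/relevance
oracles, an n = 4 arena for the 200-trial gaze-relevance ROC runs, the
study-scale n = 5 maze (45 obstacles) for the 200-trial detector calibration
and 120-trial recovery runs, and 10 arenas × 30 trials for the agent
experiment; these sizes reproduce every qualitative result with stable
margins. Value iteration is capped at 100 sweeps everywhere, matching the
relevance definition's capped-value semantics. Ties in greedy ascent break
by heading index; ties in directed sampling break by edge index; all
stochastic components consume explicit seeds and are reproducible bit-for-bit.

## Known limitations

* The sweep-speed estimator inherits a low bias for short sweeps (above).
* Relevance at the goal state is identically zero by the clamping
  convention, so frames at the goal carry no relevance signal.
* Obstacle sampling is uniform-with-rejection; heavily obstructed arenas
  (beyond ~45 obstacles at n = 5) are rarely connected, and deliberately
  maze-like designs should be built from explicit obstacle lists instead.
* The generalized relevance for stochastic transitions or heterogeneous
  subjective uncertainty is out of scope.
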