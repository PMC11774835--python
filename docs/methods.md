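# Methods

## The simulated experiment

`remapsim` models context-dependent renewal of a conditioned response (CR)
in a closed-loop reinforcement-learning simulation.  An agent navigates a
T-maze discretized into 238 grid points: a 34x4 top bar carrying the two
arms and a 6x17 stem, 2.8 m along the long axis (grid spacing 2.8/33 m
~ 8.5 cm).  In every trial the agent starts at the bottom center of the
stem and chooses one of four cardinal moves per time step.  Moves into a
wall consume the step.  Entering the reward zone — the four nodes of the
extreme bar column of the rewarded arm — yields +20 and ends the trial;
every other step costs −1; unsuccessful trials are cut off at 400 steps.

The ABA renewal protocol has three phases: acquisition in context A (white
light, left arm rewarded), extinction in context B (blue light, no reward),
and a test back in context A (no reward).  Context salience `s` in [0, 1]
blends context B's illumination from white (s = 0, the AA control) to pure
blue (s = 1).  In the explicit-context variant lighting never changes and
160 binary input units (80 active in A, the other 80 in B) carry context.

## Visual observations

Observations are 80x20 RGB first-person views spanning a 240 degree field
of view, rendered procedurally: a per-column raycast against the maze
outline gives wall distance and world-space hit point; walls carry a fixed
sinusoidal RGB texture of the hit coordinates with distance shading; rows
above the wall slab sample a fixed skybox stripe (a cosine series in
azimuth, acting as distal cues); rows below are floor pixels whose world
position is recovered by ground-plane projection and textured with a fixed
sinusoidal floor pattern.  The textured floor matters: with a
position-independent floor, views along the stem corridor are nearly
degenerate, the network cannot resolve its position there, and acquisition
is slow and unstable.  The
whole image is multiplied by the context light color.  Camera position
(sd 1 cm, clipped at 3 cm) and yaw (sd 10 degrees) are jittered per
observation during behavior; analysis probes render without jitter (the
choice is exposed as a flag).

Two designed properties are worth noting.  First, the pose-to-image map is
injective without jitter, so the visual input fully determines position and
heading.  Second, all textures are even functions of distance from the stem
axis and the skybox is even about due north, which makes the scene exactly
mirror-symmetric: reflecting the pose through the stem axis yields the
horizontally mirrored image.  This gives a strong renderer correctness
check and means left and right arms are distinguished by image chirality
rather than by arbitrary texture differences.

What the renderer does not emulate: photorealistic texture statistics,
occlusion-rich clutter, continuous motion between grid points, and
luminance adaptation.  Conclusions about *which* visual feature drives
remapping in real photographic input are therefore outside what passing
tests can show; the renderer preserves the structural properties the
analyses rely on (smooth pose dependence, proximal + distal cues,
multiplicative context tint with parametric salience).

## The learning agent

The action-value function is a dense feed-forward network: input 4800
(80x20x3), hidden layers 112, 96, 80, 64 — each affine, batch
normalization, rectified linear — and a linear 4-unit output.  Forward,
backward, batch normalization, and the Adam optimizer are implemented
directly in NumPy (float32 throughout); the Adam update runs as a fused
numba kernel since it is memory-bound.

Learning is one-step Q-learning: for a replayed transition (s, a, r, s')
the target is r + gamma * max Q(s', .) with gamma = 0.8, computed in
inference mode; only the taken action's output is regressed (squared
error), and one Adam step (learning rate 1e-4) is applied per uniformly
sampled replay batch (default batch size 32; the desk-scale study uses 16,
see below).  The tabular mixing rate of the Bellman
iteration is absorbed into the optimizer step size.  Action selection is
epsilon-greedy with epsilon = 0.3 in all phases (ties break to the lowest
action index).  Replay is either full-history (never evicts; the "with
replay" condition) or restricted to the five most recent trials (the
ablation).  There is no target network, gradient clipping, or epsilon
annealing.

Three implementation decisions deserve explanation:

* **Time-limit bootstrapping.**  Only goal arrival is stored as a terminal
  transition.  A trial cut off at the step cap ends the episode but its
  last transition still bootstraps through s'.  Treating the cap as a true
  terminal would teach Q = −1 at arbitrary timeout states — above the
  ambient value −1/(1−gamma) = −5 — making aimless wandering look
  attractive; calibration runs with that variant showed exactly this
  instability.

* **Batch-norm calibration at initialization.**  Running statistics are
  initialized from a deterministic forward pass over all 952 poses of the
  starting context instead of the conventional (0, 1).  Without it the
  inference-mode outputs of a fresh network are saturated and the greedy
  action is the same almost everywhere (the argmax field of an untrained
  net collapsed to a single action for 87-100% of poses in three test
  seeds), which strands the agent on a wall for hundreds of steps.  With
  calibration the initial greedy field is input-driven and exploration
  covers the maze.

* **Training intensity and batch size.**  The update cadence and batch
  size are configurable; the desk-scale study uses three batch-16 replay
  updates per environment step.  The higher cadence makes acquisition
  consolidate within tens of trials rather than hundreds; the small batch
  keeps the untrained greedy-action field churning, which is what lets the
  agent discover the reward zone in the first place (large-batch runs sat
  in a frozen action field for dozens of trials).
  During training batch statistics are used (and folded into the running
  statistics with momentum 0.01); behavior rollouts and probing use the
  running statistics.

Weights are initialized fan-in-scaled uniform from the run seed.  Each run
derives four independent RNG streams (initialization, action sampling,
replay sampling, camera jitter) from `base_seed + run_index`, so runs are
bitwise reproducible and sweeps pair runs by seed.

## Behavioral analysis

A trial is a conditioned response (CR) if the agent enters the left arm
(the junction columns above the stem belong to the stem) within the first
50 time steps; wall-bump steps count.  Cumulative response curves (CRC)
are per-run running CR counts, averaged over runs.  The renewal index of a
run is the mean CR fraction over the first 20 test-phase trials minus the
mean over the last 20 extinction trials; renewal appears as a positive
jump at the B-to-A boundary.

## Cell-type classification

Hidden units are probed at all 238 nodes x 4 headings (no jitter,
inference mode) under both context appearances, and classified per context
with gate precedence silent -> context -> partially active -> place-field
pipeline, which makes the five classes a partition:

* **silent**: exactly zero everywhere (exact zeros are meaningful after
  ReLU).
* **context**: activation range within each context at most 0.05% of the
  unit's maximum activation, and mean levels differing across contexts by
  more than that tolerance.  A context cell may be constant-zero in one
  context; in per-context labels such a unit counts as silent there and
  context in the other, and the combined context-cell count includes both
  kinds.
* **partially active**: non-zero activity for a non-empty strict subset of
  the four headings.
* **place-cell-like / heading modulated**: per-heading rate maps are
  smoothed with a mask-normalized Gaussian (sd 2 grid spacings ~ 17 cm;
  kernel renormalized over the maze footprint so constants are invariant
  and mass is conserved away from boundaries), thresholded at half the map
  peak — the conventional place-field boundary — and split into
  4-neighborhood connected clusters.  A heading map is
  excluded if it has more than two clusters or is active at more than half
  the grid points; otherwise its tuning center is the activity-weighted
  centroid of the dominating cluster (largest summed activity; ties by
  node count, then lowest seed node).  If every heading has a center and
  all pairwise center distances stay within four grid spacings the unit is
  a place cell with the mean center; any exclusion or coherence failure
  makes it heading modulated.

The smoothing sd, cluster threshold, and the pairwise reading of the
coherence rule are package choices where the procedure leaves latitude;
all are exposed in `ClassifierParams`.

## Remapping analysis

Population vectors (PVs) are built per grid point from heading-merged
(arithmetic mean over the four headings) activations of all units that are
place-cell-like in at least one recording point, pooled across runs.
Recording points are A (end of acquisition, probed under A lighting),
B (end of extinction, B lighting), A' (the same end-of-extinction network
probed under A lighting — renewal is tested on return to A before further
training), and A'' (end of test).  For each pair of recording points the
Pearson correlation is computed per grid point across the pooled unit
dimension; numerically constant vectors yield undefined entries that are
dropped with counts logged.  An alternative per-unit map-correlation mode
is provided.  Place-field distances are Euclidean distances between merged
centers of units that are place cells in both compared conditions,
normalized by the 2.8 m maze extent.  Two-condition comparisons use
two-sided independent t-tests with means +- SEM.

## Desk-scale study sizes

The full protocol (20 runs x 200-trial phases x 400-step trials) is a
multi-hour computation.  The package's desk-scale battery
(`remapsim.study`) uses 100 acquisition trials, 24 extinction and 24 test
trials (so the two same-context recording intervals span equal trial
counts), the full 400-step cap during acquisition (an untrained agent
needs long trials to discover the reward zone) and a 60-step cap in
unrewarded phases (the CR window is 50 steps), batch-16 replay with three
updates per step, and 2 seeds for the ABA/AA comparisons (1 for the
ablation, 2 per intermediate salience).  Conditions that share the
acquisition phase (ABA at any salience, the AA control) are executed as
branches of a single phase-1 run per seed; this is exact, because context
A's lighting is independent of salience and all random streams are
consumed identically.

At this scale several behavioral quantities sit at their noise floor.
Acquisition quality fluctuates non-monotonically over training (the
network has no target-network stabilizer, so the greedy policy oscillates)
and differs strongly between seeds; conditioned-response rates after
acquisition range from 0 to about 0.5 where the full-scale study reports
near-ceiling responding.  Extinction data never outweigh acquisition data
in the full-history buffer at these phase lengths (the opposite of the
full protocol), so behavioral renewal expresses slowly -- over tens of
test trials rather than immediately -- and the renewal index measured on
the first 20 test trials is frequently indistinguishable from zero even
when policy-level probing of the phase snapshots shows the left-arm
policy disappearing at the end of extinction and returning during the
test phase.  The population-vector remapping results, by contrast, are
robust at desk scale.  All numbers quoted by the test suite and the reproduction
script are computed at this scale; fractions of rare cell types are
noisier than the full-scale figures and phase-end representations have had
less time to consolidate.

## Known limitations

* Acquisition speed and stability depend strongly on the run seed;
  occasional runs consolidate late or relapse, trial-length summaries have
  heavy tails, and every behavioral statistic downstream of the CR rate
  inherits that variability at desk scale.
* With gamma = 0.8 the value gradient more than ~15 steps from the reward
  zone is far below the function-approximation noise floor, so policies
  far from the goal are only weakly constrained; this matches the design
  of the original protocol and is not corrected.
* The classifier's context tolerance is relative to each unit's maximum
  activation; units with tiny dynamic range can be labeled context cells
  from numerically trivial differences.  The planted-population tests pin
  the intended behavior.
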