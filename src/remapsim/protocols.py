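"""Multi-phase experiment orchestration: ABA renewal and its variants.

An experiment is an ordered list of phases, each defined by a context (A or
B), a rewarded arm (left, right, or none), and a trial count.  One network
and one replay buffer persist across all phases of a run.  At the end of
every phase the network is probed over all grid points and headings under
*both* context appearances (lighting A and lighting B), which yields the
recording points of the renewal paradigm:

* ``A``      -- end of phase 1, probed in context A,
* ``B``      -- end of phase 2, probed in context B,
* ``Aprime`` -- the same phase-2-end network probed in context A (renewal is
  tested immediately upon return to A, before any further training),
* ``A2``     -- end of phase 3, probed in context A.

Runs are seeded: run ``r`` derives independent RNG streams for weight
initialization, action sampling, replay sampling, and camera jitter from
``base_seed + r``, so repeated executions are bitwise identical and sweeps
can pair runs across conditions by seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import behavior
from .agent import DQNAgent, TrainingConfig
from .maze import (
    MAX_TRIAL_STEPS,
    ContextSpec,
    MazeGraph,
    ObservationSpec,
    TMazeEnv,
    build_tmaze,
)
from .placefields import ClassifierParams, classify_all, probe_activity

__all__ = [
    "PhaseSpec",
    "ExperimentSpec",
    "RunLog",
    "STANDARD_NAMES",
    "RECORDING_POINTS",
    "standard_spec",
    "run_experiment",
    "run_many",
    "run_salience_sweep",
    "classify_run",
    "cr_matrix",
]

#: Recording-point label -> (phase number, probe context).
RECORDING_POINTS = {
    "A": (1, "A"),
    "B": (2, "B"),
    "Aprime": (2, "A"),
    "A2": (3, "A"),
}

STANDARD_NAMES = (
    "aba_extinction",
    "aa_control",
    "aba_relearning",
    "explicit_context",
    "no_replay",
)


@dataclass(frozen=True)
class PhaseSpec:
    """One experimental phase: context, rewarded arm, and trial count."""

    context_phase: str  # "A" or "B"
    rewarded_arm: Optional[str]  # "left", "right", or None
    n_trials: int

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.context_phase not in ("A", "B"):
            raise ValueError("context_phase must be 'A' or 'B'")


@dataclass(frozen=True)
class ExperimentSpec:
    """Full description of a seeded multi-phase experiment."""

    phases: tuple
    salience: float = 1.0
    context_mode: str = "lighting"
    replay_mode: str = "full_history"
    n_runs: int = 20
    base_seed: int = 1234
    trial_cap: int = MAX_TRIAL_STEPS
    phase_caps: Optional[tuple] = None  # per-phase override of trial_cap
    training: TrainingConfig = TrainingConfig()
    obs_spec: ObservationSpec = ObservationSpec()
    probe_jitter: bool = False  # jitter stays off during analysis probing
    keep_snapshots: bool = True

    @property
    def phase_lengths(self) -> tuple:
        return tuple(p.n_trials for p in self.phases)

    @property
    def n_trials_total(self) -> int:
        return sum(self.phase_lengths)


@dataclass
class RunLog:
    """Complete record of one seeded run."""

    spec: ExperimentSpec
    run_index: int
    seed: int
    trajectories: list = field(default_factory=list)  # per trial: node id list
    trial_lengths: np.ndarray = None
    trial_rewards: np.ndarray = None
    reached_goal: np.ndarray = None
    cr_flags: np.ndarray = None
    activity: dict = field(default_factory=dict)  # (phase#, ctx) -> [ActivityMap]*4
    snapshots: dict = field(default_factory=dict)  # phase# -> network state
    losses: list = field(default_factory=list)

    def maps(self, recording_point: str, layer: int):
        """ActivityMap for a named recording point and hidden layer (1-4)."""
        phase, probe = RECORDING_POINTS[recording_point]
        return self.activity[(phase, probe)][layer - 1]


# ---------------------------------------------------------------------------
# Standard experiment presets
# ---------------------------------------------------------------------------


def standard_spec(
    name: str,
    salience: float = 1.0,
    n_trials_per_phase: int = 200,
    **overrides,
) -> ExperimentSpec:
    """Build one of the named experiment presets.

    ``aba_extinction``: acquisition (A, left arm rewarded), extinction (B, no
    reward), test (A, no reward).  ``aa_control``: the same with context A
    throughout (salience forced to 0).  ``aba_relearning``: right arm
    rewarded in B, left again in the test phase.  ``explicit_context`` and
    ``no_replay`` are the extinction preset with the explicit context
    encoding and the last-five-trials buffer, respectively.
    """
    n = n_trials_per_phase
    if name == "aba_extinction":
        phases = (PhaseSpec("A", "left", n), PhaseSpec("B", None, n), PhaseSpec("A", None, n))
        kw: dict = {"salience": salience}
    elif name == "aa_control":
        phases = (PhaseSpec("A", "left", n), PhaseSpec("B", None, n), PhaseSpec("A", None, n))
        kw = {"salience": 0.0}  # context B rendered identical to A
    elif name == "aba_relearning":
        phases = (PhaseSpec("A", "left", n), PhaseSpec("B", "right", n), PhaseSpec("A", "left", n))
        kw = {"salience": salience}
    elif name == "explicit_context":
        phases = (PhaseSpec("A", "left", n), PhaseSpec("B", None, n), PhaseSpec("A", None, n))
        kw = {"salience": salience, "context_mode": "explicit"}
    elif name == "no_replay":
        phases = (PhaseSpec("A", "left", n), PhaseSpec("B", None, n), PhaseSpec("A", None, n))
        kw = {"salience": salience, "replay_mode": "last_five_trials"}
    else:
        raise ValueError(f"unknown experiment name {name!r}; choose from {STANDARD_NAMES}")
    kw.update(overrides)
    return ExperimentSpec(phases=phases, **kw)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _calibrate_agent(agent, maze, spec):
    """Set batch-norm running statistics from a deterministic probe batch.

    Observations over all poses in the first phase's context (jitter off)
    give the freshly initialized network sensible inference-mode statistics,
    so its greedy-action field is input-driven from the first trial.
    """
    ctx = ContextSpec(salience=spec.salience,
                      phase_label=spec.phases[0].context_phase,
                      mode=spec.context_mode)
    env = TMazeEnv(maze, ctx, obs_spec=spec.obs_spec, jitter=False)
    from .maze import AgentState

    obs = np.stack([
        env.observation(AgentState(node, h, 0), jitter=False)
        for node in range(maze.n_nodes)
        for h in range(4)
    ])
    agent.net.calibrate_batchnorm(obs)


def _probe_both_contexts(agent, maze, spec, phase_number, log):
    base = dict(salience=spec.salience, mode=spec.context_mode)
    for probe in ("A", "B"):
        ctx = ContextSpec(phase_label=probe, **base)
        log.activity[(phase_number, probe)] = probe_activity(
            agent.net, maze.with_goal(None), ctx, spec.obs_spec,
            phase_label=f"phase{phase_number}:{probe}",
        )


class _Runner:
    """Mutable execution state of one run; supports snapshot/branching."""

    def __init__(self, spec: ExperimentSpec, run_index: int):
        self.spec = spec
        self.run_index = run_index
        self.seed = spec.base_seed + run_index
        streams = np.random.SeedSequence(self.seed).spawn(4)
        rng_init, self.rng_action, self.rng_replay, self.rng_jitter = map(
            np.random.default_rng, streams
        )
        input_dim = 80 * 20 * 3 + (160 if spec.context_mode == "explicit" else 0)
        self.cfg = replace(spec.training, seed=self.seed)
        self.agent = DQNAgent(self.cfg, input_dim=input_dim,
                              replay_mode=spec.replay_mode, rng=rng_init)
        self.maze = build_tmaze()
        self.log = RunLog(spec=spec, run_index=run_index, seed=self.seed)
        self.lengths: list = []
        self.rewards: list = []
        self.reached: list = []
        self.trial_counter = 0
        _calibrate_agent(self.agent, self.maze, spec)

    def execute_phase(self, phase_index: int, progress: bool = False) -> None:
        spec, agent, cfg = self.spec, self.agent, self.cfg
        phase = spec.phases[phase_index]
        phase_number = phase_index + 1
        maze = self.maze.with_goal(phase.rewarded_arm)
        ctx = ContextSpec(salience=spec.salience,
                          phase_label=phase.context_phase,
                          mode=spec.context_mode)
        cap = (spec.phase_caps[phase_index] if spec.phase_caps
               else spec.trial_cap)
        env = TMazeEnv(maze, ctx, rng=self.rng_jitter, obs_spec=spec.obs_spec,
                       max_steps=cap, jitter=True)
        for _ in range(phase.n_trials):
            agent.buffer.begin_trial(self.trial_counter)
            obs = env.reset()
            s_idx = agent.buffer.add_observation(obs)
            nodes = [env.state.node]
            total_r = 0.0
            while True:
                a = agent.act(obs, self.rng_action)
                res = env.step_action(a)
                sn_idx = agent.buffer.add_observation(res.observation)
                # bootstrap through time-limit truncation: only goal arrival
                # is a true terminal for the TD target
                agent.buffer.add(s_idx, a, res.reward, sn_idx,
                                 res.terminal and res.reward > 0,
                                 self.trial_counter)
                obs, s_idx = res.observation, sn_idx
                nodes.append(env.state.node)
                total_r += res.reward
                if len(agent.buffer) >= cfg.batch_size:
                    for _ in range(cfg.updates_per_env_step):
                        self.log.losses.append(agent.learn(self.rng_replay))
                if res.terminal:
                    break
            self.lengths.append(env.state.t)
            self.rewards.append(total_r)
            self.reached.append(bool(maze.goal_zone) and nodes[-1] in maze.goal_zone)
            self.log.trajectories.append(nodes)
            self.trial_counter += 1
            if progress and self.trial_counter % 20 == 0:
                print(f"  run {self.run_index}: phase {phase_number}, "
                      f"trial {self.trial_counter}/{self.spec.n_trials_total}")
        _probe_both_contexts(self.agent, self.maze, spec, phase_number, self.log)
        if spec.keep_snapshots:
            self.log.snapshots[phase_number] = agent.net.get_state()

    # -- branching --------------------------------------------------------

    def capture(self) -> dict:
        """Deep snapshot of learner, buffer, RNG streams, and history."""
        import copy

        agent = self.agent
        buf = agent.buffer
        return {
            "net": agent.net.get_state(),
            "opt": {
                "t": agent.optimizer.t,
                "m": {k: v.copy() for k, v in agent.optimizer.m.items()},
                "v": {k: v.copy() for k, v in agent.optimizer.v.items()},
            },
            "buf_obs": buf._obs[: buf._n_obs].copy(),
            "buf_exp": buf._exp[: buf._n_exp].copy(),
            "buf_r": buf._r[: buf._n_exp].copy(),
            "buf_term": buf._term[: buf._n_exp].copy(),
            "rngs": copy.deepcopy(
                (self.rng_action, self.rng_replay, self.rng_jitter)
            ),
            "trial_counter": self.trial_counter,
            "lengths": list(self.lengths),
            "rewards": list(self.rewards),
            "reached": list(self.reached),
            "trajectories": [list(t) for t in self.log.trajectories],
            "losses": list(self.log.losses),
            "snapshots": {k: v for k, v in self.log.snapshots.items()},
            "activity": dict(self.log.activity),
        }

    def restore(self, snap: dict) -> None:
        import copy

        agent = self.agent
        agent.net.set_state(snap["net"])
        agent.optimizer.t = snap["opt"]["t"]
        agent.optimizer.m = {k: v.copy() for k, v in snap["opt"]["m"].items()}
        agent.optimizer.v = {k: v.copy() for k, v in snap["opt"]["v"].items()}
        buf = agent.buffer
        n = len(snap["buf_obs"])
        cap = max(1024, 1 << int(np.ceil(np.log2(max(n, 1) + 1))))
        buf._obs = np.empty((cap, buf.obs_dim), dtype=buf._obs.dtype)
        buf._obs[:n] = snap["buf_obs"]
        buf._n_obs = n
        m = len(snap["buf_exp"])
        mcap = max(1024, 1 << int(np.ceil(np.log2(max(m, 1) + 1))))
        buf._exp = np.empty((mcap, 4), dtype=np.int64)
        buf._exp[:m] = snap["buf_exp"]
        buf._r = np.empty(mcap, dtype=np.float32)
        buf._r[:m] = snap["buf_r"]
        buf._term = np.empty(mcap, dtype=bool)
        buf._term[:m] = snap["buf_term"]
        buf._n_exp = m
        self.rng_action, self.rng_replay, self.rng_jitter = copy.deepcopy(
            snap["rngs"]
        )
        self.trial_counter = snap["trial_counter"]
        self.lengths = list(snap["lengths"])
        self.rewards = list(snap["rewards"])
        self.reached = list(snap["reached"])
        self.log.trajectories = [list(t) for t in snap["trajectories"]]
        self.log.losses = list(snap["losses"])
        self.log.snapshots = dict(snap["snapshots"])
        self.log.activity = dict(snap["activity"])

    def finalize(self) -> RunLog:
        log = self.log
        log.trial_lengths = np.asarray(self.lengths)
        log.trial_rewards = np.asarray(self.rewards)
        log.reached_goal = np.asarray(self.reached)
        log.cr_flags = np.asarray([
            behavior.classify_cr(behavior.TrialTrajectory(tuple(n)), self.maze)
            for n in log.trajectories
        ])
        return log


def run_experiment(spec: ExperimentSpec, run_index: int = 0,
                   progress: bool = False) -> RunLog:
    """Execute all phases of one run and return its complete :class:`RunLog`.

    The run seed is ``spec.base_seed + run_index``; four independent RNG
    streams (initialization, action sampling, replay sampling, camera
    jitter) are spawned from it.  Extinction-phase trials (no rewarded arm)
    may terminate early only at the trial cap; acquisition trials terminate
    at the reward zone.
    """
    runner = _Runner(spec, run_index)
    for i in range(len(spec.phases)):
        runner.execute_phase(i, progress=progress)
    return runner.finalize()


def _branch_compatible(a: ExperimentSpec, b: ExperimentSpec) -> bool:
    first_cap_a = a.phase_caps[0] if a.phase_caps else a.trial_cap
    first_cap_b = b.phase_caps[0] if b.phase_caps else b.trial_cap
    return (
        a.phases[0] == b.phases[0]
        and a.phases[0].context_phase == "A"
        and first_cap_a == first_cap_b
        and a.context_mode == b.context_mode
        and a.replay_mode == b.replay_mode
        and a.base_seed == b.base_seed
        and a.training == b.training
        and a.obs_spec == b.obs_spec
    )


def run_branched(branches: dict, run_index: int = 0,
                 progress: bool = False) -> dict:
    """Run several experiments that share an identical first phase.

    Phase 1 in context A is unaffected by the salience parameter (context A
    lighting is white for every salience), so e.g. the ABA conditions at
    different saliences and the AA control share phase 1 exactly, including
    all RNG stream consumption.  The shared phase is executed once; each
    branch then continues from a deep snapshot of the full learner state.
    Returns ``{branch name: RunLog}``, bitwise identical to running each
    experiment separately.
    """
    specs = list(branches.values())
    for s in specs[1:]:
        if not _branch_compatible(specs[0], s):
            raise ValueError("branch specs do not share an identical phase 1")
    runner = _Runner(specs[0], run_index)
    runner.execute_phase(0, progress=progress)
    snap = runner.capture()
    out = {}
    for name, spec in branches.items():
        runner.spec = spec
        runner.log.spec = spec
        runner.restore(snap)
        # the phase-1 probe depends on the branch's salience: re-probe
        runner.log.activity = {}
        _probe_both_contexts(runner.agent, runner.maze, spec, 1, runner.log)
        if spec.keep_snapshots:
            runner.log.snapshots[1] = runner.agent.net.get_state()
        for i in range(1, len(spec.phases)):
            runner.execute_phase(i, progress=progress)
        out[name] = runner.finalize()
        runner.log = RunLog(spec=specs[0], run_index=run_index, seed=runner.seed)
    return out


def run_many(spec: ExperimentSpec, n_runs: Optional[int] = None,
             progress: bool = False) -> list[RunLog]:
    """Run ``n_runs`` seeded replicates of an experiment."""
    n = spec.n_runs if n_runs is None else n_runs
    return [run_experiment(spec, r, progress=progress) for r in range(n)]


def run_salience_sweep(base: ExperimentSpec, s_values: Sequence[float],
                       n_runs: Optional[int] = None,
                       progress: bool = False) -> dict:
    """One full experiment per salience value, with matched seeds across
    values so per-run comparisons are paired."""
    out = {}
    for s in s_values:
        if not 0.0 <= s <= 1.0:
            raise ValueError("salience values must lie in [0, 1]")
        spec = replace(base, salience=float(s))
        out[float(s)] = run_many(spec, n_runs=n_runs, progress=progress)
    return out


# ---------------------------------------------------------------------------
# Per-run classification glue
# ---------------------------------------------------------------------------


def classify_run(log: RunLog, params: ClassifierParams = ClassifierParams(),
                 maze: Optional[MazeGraph] = None) -> dict:
    """Cell-type classification for every recording point and layer.

    Returns ``{recording point: [CellClassification per layer 1-4]}``.  Each
    recording point is classified from the paired context-A/context-B probes
    of its epoch, so the context-cell gate sees both appearances.
    """
    maze = maze if maze is not None else build_tmaze()
    n_layers = len(log.activity[(1, "A")])
    out: dict = {}
    per_epoch: dict = {}
    for label, (phase_number, probe) in RECORDING_POINTS.items():
        if phase_number not in per_epoch:
            per_epoch[phase_number] = [
                classify_all(log.activity[(phase_number, "A")][li],
                             log.activity[(phase_number, "B")][li],
                             maze, params)
                for li in range(n_layers)
            ]
        out[label] = [per_epoch[phase_number][li][probe] for li in range(n_layers)]
    return out


def cr_matrix(logs: Sequence[RunLog]) -> np.ndarray:
    """Stack per-run CR indicator vectors into a (n_runs, n_trials) matrix."""
    widths = {len(lg.cr_flags) for lg in logs}
    if len(widths) != 1:
        raise ValueError("runs have mismatched trial counts")
    return np.stack([lg.cr_flags.astype(float) for lg in logs])
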