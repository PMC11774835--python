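"""Desk-scale renewal study: the canonical reduced-size experiment battery.

The full protocol (20 runs x 200-trial phases x 400-step trials) is a
multi-hour computation.  This module defines the package's desk-scale
configuration of the same protocol -- fewer runs, shorter phases, a lower
step cap in the unrewarded phases, and a higher replay-training intensity
per environment step -- together with drivers that run the battery and
summarize it.  All empirical claims in the test suite and the reproduction
script are computed at this scale.

Because context A's lighting is white at every salience, all conditions
that share the acquisition phase (ABA at any salience and the AA control)
are executed as branches of a single phase-1 run per seed
(:func:`remapsim.protocols.run_branched`), which is exact and saves most of
the compute; the no-replay ablation trains phase 1 under its own buffer and
runs separately.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from . import behavior
from .agent import TrainingConfig
from .config_io import analyze_experiment
from .placefields import ClassifierParams
from .protocols import (
    ExperimentSpec,
    PhaseSpec,
    cr_matrix,
    run_branched,
    run_experiment,
    run_many,
    standard_spec,
)

__all__ = [
    "STUDY_TRIALS_ACQ",
    "STUDY_TRIALS_EXT",
    "STUDY_CAP_ACQ",
    "STUDY_CAP_EXT",
    "STUDY_TRAINING",
    "study_spec",
    "acquisition_spec",
    "run_battery",
    "sweep_summary",
    "corridor_policy_agreement",
]

# Desk-scale study sizes (see docs/methods.md for the reasoning):
STUDY_TRIALS_ACQ = 100  # acquisition-phase trials
STUDY_TRIALS_EXT = 24   # extinction-phase trials
STUDY_TRIALS_TEST = 24  # test-phase trials
STUDY_CAP_ACQ = 400     # step cap during acquisition (exploration needs it)
STUDY_CAP_EXT = 60      # step cap in unrewarded phases (CR window is 50)
STUDY_TRAINING = TrainingConfig(batch_size=16, updates_per_env_step=3)


def study_spec(name: str, base_seed: int, salience: float = 1.0,
               n_runs: int = 5) -> ExperimentSpec:
    """Desk-scale version of a named experiment preset.

    Acquisition keeps the full 400-step cap (an untrained agent needs long
    trials to discover the reward zone); the unrewarded phases are capped
    at 80 steps, which still contains the full 50-step CR scoring window.
    """
    spec = standard_spec(name, salience=salience, n_runs=n_runs,
                         base_seed=base_seed, training=STUDY_TRAINING)
    per_phase = (STUDY_TRIALS_ACQ, STUDY_TRIALS_EXT, STUDY_TRIALS_TEST)
    phases = tuple(
        replace(p, n_trials=STUDY_TRIALS_ACQ if p.rewarded_arm else per_phase[i])
        for i, p in enumerate(spec.phases)
    )
    return replace(spec, phases=phases, trial_cap=STUDY_CAP_ACQ,
                   phase_caps=tuple(
                       STUDY_CAP_ACQ if p.rewarded_arm else STUDY_CAP_EXT
                       for p in phases
                   ))


def acquisition_spec(base_seed: int, n_trials: int = 100) -> ExperimentSpec:
    """Single acquisition phase at full trial cap (learning-sanity check)."""
    return ExperimentSpec(
        phases=(PhaseSpec("A", "left", n_trials),),
        salience=1.0,
        n_runs=1,
        base_seed=base_seed,
        trial_cap=STUDY_CAP_ACQ,
        training=STUDY_TRAINING,
        keep_snapshots=False,
    )


def run_battery(base_seed: int, n_runs: int = 2, n_noreplay: int = 1,
                sweep_salience: Sequence[float] = (0.2, 0.4),
                n_sweep: int = 2, noreplay_acq_trials: int = 50,
                progress: bool = False) -> dict:
    """Run the full desk-scale battery.

    Per seed, the ABA extinction (s = 1), the AA control (s = 0), and --
    for the first ``n_sweep`` seeds -- the intermediate-salience conditions
    are branches of one shared acquisition phase.  The no-replay ablation
    runs separately (its phase 1 trains with the last-five-trials buffer).

    Returns ``{"aba": [...], "aa": [...], "noreplay": [...],
    "sweep": {s: [...]}}`` with the sweep dict including s = 0 (the AA
    logs) and s = 1 (the ABA logs).
    """
    aba, aa = [], []
    sweep: dict = {float(s): [] for s in sweep_salience}
    for r in range(n_runs):
        branches = {
            "aba": study_spec("aba_extinction", base_seed),
            "aa": study_spec("aa_control", base_seed),
        }
        if r < n_sweep:
            for s in sweep_salience:
                branches[f"s{s:g}"] = study_spec("aba_extinction", base_seed,
                                                 salience=float(s))
        out = run_branched(branches, r, progress=progress)
        aba.append(out["aba"])
        aa.append(out["aa"])
        for s in sweep_salience:
            key = f"s{s:g}"
            if key in out:
                sweep[float(s)].append(out[key])
    nr_spec = study_spec("no_replay", base_seed + 202, n_runs=n_noreplay)
    nr_spec = replace(
        nr_spec,
        phases=(replace(nr_spec.phases[0], n_trials=noreplay_acq_trials),)
        + nr_spec.phases[1:],
    )
    noreplay = run_many(nr_spec, progress=progress)
    sweep[0.0] = aa
    sweep[1.0] = aba
    return {"aba": aba, "aa": aa, "noreplay": noreplay, "sweep": sweep}


def sweep_summary(per_s_logs: dict, params: Optional[ClassifierParams] = None) -> dict:
    """Per-salience A-A', A-B, A'-B mean correlations and early-test CR."""
    params = params if params is not None else ClassifierParams()
    out: dict = {}
    for s, logs in sorted(per_s_logs.items()):
        analysis = analyze_experiment(logs, params)
        crm = cr_matrix(logs)
        phase_lengths = logs[0].spec.phase_lengths
        b2 = phase_lengths[0] + phase_lengths[1]
        window = min(behavior.RENEWAL_WINDOW_TRIALS, phase_lengths[2])
        out[s] = {
            "corr_A_Aprime": _mean_pair_corr(analysis, ("A", "Aprime")),
            "corr_A_B": _mean_pair_corr(analysis, ("A", "B")),
            "corr_Aprime_B": _mean_pair_corr(analysis, ("Aprime", "B")),
            "cr_early_test": float(crm[:, b2 : b2 + window].mean()),
        }
    return out


def _mean_pair_corr(analysis, pair) -> float:
    """Across-layer mean of one recording-point pair's pooled correlation."""
    vals = [s.mean_correlation[pair] for s in analysis["remap"]]
    return float(np.nanmean(vals))


def corridor_policy_agreement(seed: int = 0, n_states: int = 5,
                              n_trials: int = 200, cap: int = 20) -> float:
    """Train a small Q-network on a tabular corridor and compare its greedy
    policy with value iteration.

    The corridor runs west-east with the goal (+20, terminal) at the east
    end and -1 per step; observations are one-hot state encodings.  Returns
    the fraction of non-terminal states where the trained greedy action
    matches the value-iteration optimum.
    """
    from .agent import DQNAgent

    gamma = 0.8

    def mdp_step(s, a):
        s2 = min(s + 1, n_states - 1) if a == 1 else (max(s - 1, 0) if a == 3 else s)
        if s2 == n_states - 1:
            return s2, 20.0, True
        return s2, -1.0, False

    qstar = np.zeros((n_states, 4))
    for _ in range(200):
        v = qstar.max(axis=1)
        for s in range(n_states - 1):
            for a in range(4):
                s2, r, term = mdp_step(s, a)
                qstar[s, a] = r + (0.0 if term else gamma * v[s2])

    obs = np.eye(n_states, dtype=np.float32)
    cfg = TrainingConfig(batch_size=32, adam_learning_rate=1e-3, epsilon=0.3,
                         seed=seed)
    agent = DQNAgent(cfg, input_dim=n_states, hidden_sizes=(16, 16),
                     rng=np.random.default_rng(seed))
    agent.net.calibrate_batchnorm(obs)
    rng = np.random.default_rng(seed + 1)
    for trial in range(n_trials):
        agent.buffer.begin_trial(trial)
        s = 0
        for _ in range(cap):
            a = agent.act(obs[s], rng)
            s2, r, term = mdp_step(s, a)
            i = agent.buffer.add_observation(obs[s])
            j = agent.buffer.add_observation(obs[s2])
            agent.buffer.add(i, a, r, j, term, trial)
            s = s2
            if len(agent.buffer) >= cfg.batch_size:
                agent.learn(rng)
            if term:
                break
    q = agent.net.forward(obs)
    agree = sum(
        int(np.argmax(q[s]) == np.argmax(qstar[s])) for s in range(n_states - 1)
    )
    return agree / (n_states - 1)
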