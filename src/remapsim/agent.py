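"""Deep Q-learning agent: action selection, TD targets, replay, training.

Learning follows one-step Q-learning with a function approximator: for a
sampled experience (s, a, r, s') the chosen action's value is regressed onto
the Bellman target r + gamma * max_a' Q(s', a') (the bootstrap term is
dropped at terminal transitions) under squared error, with one Adam step per
batch.  The tabular mixing rate of the Bellman iteration is absorbed into
the optimizer's step size.

Two replay regimes are supported: a full-history buffer that never evicts
(the "with replay" condition) and a buffer restricted to the five most
recent trials (the "without replay" condition).  Observations are stored
once per environment step and experiences reference them by index, so
consecutive experiences share storage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .maze import ProtocolError
from .network import Adam, QNetwork

__all__ = [
    "TrainingConfig",
    "Experience",
    "ReplayBuffer",
    "select_action",
    "td_target",
    "train_step",
    "DQNAgent",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the Q-learning agent.

    ``gamma`` (reward discount), ``epsilon`` (exploration rate) and
    ``adam_learning_rate`` follow the task's stated values; batch size and
    update cadence are free choices of the package and configurable.
    """

    gamma: float = 0.8
    epsilon: float = 0.3
    adam_learning_rate: float = 1e-4
    batch_size: int = 32
    updates_per_env_step: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass(frozen=True)
class Experience:
    """One replayable transition; observations are indices into the buffer's
    observation store."""

    s: int
    a: int
    r: float
    s_next: int
    terminal: bool
    trial_index: int


class ReplayBuffer:
    """Experience store with full-history or last-five-trials retention."""

    LAST_N_TRIALS = 5

    def __init__(self, mode: str = "full_history", obs_dim: int = 4800,
                 obs_dtype=np.float32):
        if mode not in ("full_history", "last_five_trials"):
            raise ValueError(f"unknown replay mode {mode!r}")
        self.mode = mode
        self.obs_dim = obs_dim
        self._obs = np.empty((1024, obs_dim), dtype=obs_dtype)
        self._n_obs = 0
        # experience fields in parallel growing arrays
        self._exp = np.empty((1024, 4), dtype=np.int64)  # s, a, s_next, trial
        self._r = np.empty(1024, dtype=np.float32)
        self._term = np.empty(1024, dtype=bool)
        self._n_exp = 0

    def __len__(self) -> int:
        return self._n_exp

    def add_observation(self, obs: np.ndarray) -> int:
        """Store one observation, returning its index."""
        if self._n_obs == len(self._obs):
            grown = np.empty((2 * len(self._obs), self.obs_dim),
                             dtype=self._obs.dtype)
            grown[: self._n_obs] = self._obs[: self._n_obs]
            self._obs = grown
        self._obs[self._n_obs] = obs
        self._n_obs += 1
        return self._n_obs - 1

    def add(self, s_idx: int, a: int, r: float, s_next_idx: int,
            terminal: bool, trial_index: int) -> None:
        if self._n_exp == len(self._exp):
            self._exp = np.concatenate([self._exp, np.empty_like(self._exp)])
            self._r = np.concatenate([self._r, np.empty_like(self._r)])
            self._term = np.concatenate([self._term, np.empty_like(self._term)])
        n = self._n_exp
        self._exp[n] = (s_idx, a, s_next_idx, trial_index)
        self._r[n] = r
        self._term[n] = terminal
        self._n_exp = n + 1

    def begin_trial(self, trial_index: int) -> None:
        """Apply the retention policy at a trial boundary."""
        if self.mode != "last_five_trials":
            return
        cutoff = trial_index - self.LAST_N_TRIALS
        keep = self._exp[: self._n_exp, 3] > cutoff
        n_keep = int(keep.sum())
        if n_keep != self._n_exp:
            self._exp[:n_keep] = self._exp[: self._n_exp][keep]
            self._r[:n_keep] = self._r[: self._n_exp][keep]
            self._term[:n_keep] = self._term[: self._n_exp][keep]
            self._n_exp = n_keep

    def trial_indices(self) -> np.ndarray:
        return self._exp[: self._n_exp, 3].copy()

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform sample with replacement: (S, A, R, S_next, terminal)."""
        n = self._n_exp
        if n == 0:
            raise ProtocolError("cannot sample from an empty replay buffer")
        idx = rng.integers(0, n, size=batch_size)
        exp = self._exp[idx]
        S = self._obs[exp[:, 0]].astype(np.float32, copy=False)
        S_next = self._obs[exp[:, 2]].astype(np.float32, copy=False)
        return S, exp[:, 1], self._r[idx], S_next, self._term[idx]


def select_action(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy action choice.

    With probability 1 - epsilon the argmax action is returned (ties broken
    by the lowest action index, numpy's argmax convention); with probability
    epsilon an action is drawn uniformly from all four.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.integers(len(q)))
    return int(np.argmax(q))


def td_target(r: float, q_next: np.ndarray, terminal: bool, gamma: float) -> float:
    """One-step Bellman target: r + gamma * max Q(s', .), truncated at
    terminal transitions."""
    if terminal:
        return float(r)
    return float(r) + gamma * float(np.max(q_next))


def train_step(
    net: QNetwork,
    buffer: ReplayBuffer,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    optimizer: Adam,
) -> float:
    """One replay-batch gradient update; returns the scalar batch loss.

    Only the sampled action's Q-value is regressed to its TD target; the
    other three outputs receive zero error (their targets are the network's
    own predictions).  Bootstrap values max Q(s', .) are computed in
    evaluation mode; the gradient pass runs in training mode (batch
    statistics).
    """
    S, A, R, S_next, T = buffer.sample(cfg.batch_size, rng)
    cache: dict = {}
    q, q_next = net.forward_pair(S, S_next, cache)
    y = R + np.where(T, 0.0, cfg.gamma * q_next.max(axis=1)).astype(np.float32)
    B = len(A)
    err = q[np.arange(B), A] - y
    loss = float(np.mean(err ** 2))
    dq = np.zeros_like(q)
    dq[np.arange(B), A] = 2.0 * err / B
    grads = net.backward(cache, dq)
    optimizer.step(net.params, grads)
    return loss


class DQNAgent:
    """Convenience bundle of network, optimizer, replay buffer, and config."""

    def __init__(
        self,
        cfg: TrainingConfig,
        input_dim: int,
        replay_mode: str = "full_history",
        rng: Optional[np.random.Generator] = None,
        hidden_sizes=None,
    ):
        init_rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        kwargs = {} if hidden_sizes is None else {"hidden_sizes": hidden_sizes}
        self.cfg = cfg
        self.net = QNetwork(input_dim=input_dim, rng=init_rng, **kwargs)
        self.optimizer = Adam(self.net.params, lr=cfg.adam_learning_rate)
        self.buffer = ReplayBuffer(replay_mode, obs_dim=self.net.input_dim)

    def act(self, observation: np.ndarray, rng: np.random.Generator,
            epsilon: Optional[float] = None) -> int:
        eps = self.cfg.epsilon if epsilon is None else epsilon
        return select_action(self.net.q_values(observation), eps, rng)

    def learn(self, rng: np.random.Generator) -> float:
        return train_step(self.net, self.buffer, self.cfg, rng, self.optimizer)
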