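"""Dense Q-network with batch normalization, implemented in NumPy.

The network maps a flattened 80x20x3 RGB observation (optionally extended by
160 explicit context units) to four action values.  Each hidden layer applies
an affine transform, batch normalization, and a rectified-linear activation;
the output layer is purely affine.  Forward, backward (error
backpropagation), and the Adam optimizer are implemented directly on NumPy
arrays in float32.

Batch statistics are used during training passes and exponential running
statistics during inference, so evaluation-mode outputs are deterministic
functions of a single input.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

try:  # fused elementwise update kernel; pure-NumPy fallback below
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, lr_eff, one_m_b1, one_m_b2, sqrt_b2t, eps):  # pragma: no cover
        # p -= (lr/b1t) * m_new / (sqrt(v_new)/sqrt(b2t) + eps), fused in one pass
        for i in range(p.size):
            gi = g[i]
            mi = m[i] + one_m_b1 * (gi - m[i])
            vi = v[i] + one_m_b2 * (gi * gi - v[i])
            m[i] = mi
            v[i] = vi
            p[i] -= lr_eff * mi / (np.sqrt(vi) / sqrt_b2t + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["QNetwork", "Adam", "DEFAULT_HIDDEN_SIZES", "IMAGE_INPUT_DIM"]

DEFAULT_HIDDEN_SIZES = (112, 96, 80, 64)
IMAGE_INPUT_DIM = 80 * 20 * 3  # 4800
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.01  # fraction of the batch statistic mixed into the running one


class QNetwork:
    """Feed-forward action-value network.

    Parameters
    ----------
    input_dim : flattened observation size (4800, or 4960 with explicit
        context units).
    hidden_sizes : widths of the hidden layers (default 112, 96, 80, 64).
    output_dim : number of actions (4).
    rng : generator used for fan-in-scaled uniform weight initialization.
    """

    def __init__(
        self,
        input_dim: int = IMAGE_INPUT_DIM,
        hidden_sizes: Sequence[int] = DEFAULT_HIDDEN_SIZES,
        output_dim: int = 4,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.output_dim = int(output_dim)
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}

        sizes = [self.input_dim, *self.hidden_sizes]
        for k, (fin, fout) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = 1.0 / np.sqrt(fin)
            self.params[f"W{k}"] = rng.uniform(-bound, bound, (fin, fout)).astype(np.float32)
            self.params[f"b{k}"] = rng.uniform(-bound, bound, fout).astype(np.float32)
            self.params[f"g{k}"] = np.ones(fout, dtype=np.float32)
            self.params[f"beta{k}"] = np.zeros(fout, dtype=np.float32)
            self.running[f"mean{k}"] = np.zeros(fout, dtype=np.float32)
            self.running[f"var{k}"] = np.ones(fout, dtype=np.float32)
        fin = sizes[-1]
        bound = 1.0 / np.sqrt(fin)
        self.params["W_out"] = rng.uniform(-bound, bound, (fin, self.output_dim)).astype(np.float32)
        self.params["b_out"] = rng.uniform(-bound, bound, self.output_dim).astype(np.float32)

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_sizes)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, cache: Optional[dict] = None) -> np.ndarray:
        """Q-values for a batch of observations, shape (B, n_actions).

        With ``train=True`` batch statistics are used (and folded into the
        running statistics) and intermediates are stored in ``cache`` for
        :meth:`backward`; otherwise running statistics are used and the pass
        is stateless.
        """
        x = np.ascontiguousarray(np.atleast_2d(x), dtype=np.float32)
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"observation dim {x.shape[1]} does not match network input {self.input_dim}"
            )
        h = x
        if cache is not None:
            cache["x0"] = x
        p = self.params
        for k in range(self.n_hidden_layers):
            z = h @ p[f"W{k}"] + p[f"b{k}"]
            if train:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.running[f"mean{k}"] += _BN_MOMENTUM * (mu - self.running[f"mean{k}"])
                self.running[f"var{k}"] += _BN_MOMENTUM * (var - self.running[f"var{k}"])
            else:
                mu = self.running[f"mean{k}"]
                var = self.running[f"var{k}"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            pre = zhat * p[f"g{k}"] + p[f"beta{k}"]
            a = np.maximum(pre, 0.0)
            if cache is not None:
                cache[f"h{k}"] = h
                cache[f"zhat{k}"] = zhat
                cache[f"inv_std{k}"] = inv_std
                cache[f"mask{k}"] = pre > 0
            h = a
        if cache is not None:
            cache["h_last"] = h
        return h @ p["W_out"] + p["b_out"]

    def calibrate_batchnorm(self, x: np.ndarray) -> None:
        """Initialize running statistics from a calibration batch.

        Sets each layer's running mean/variance to the batch statistics of a
        forward pass over ``x``, so that inference-mode outputs are sensibly
        normalized from the first action on instead of waiting for the
        exponential statistics to converge.
        """
        x = np.ascontiguousarray(np.atleast_2d(x), dtype=np.float32)
        h = x
        p = self.params
        for k in range(self.n_hidden_layers):
            z = h @ p[f"W{k}"] + p[f"b{k}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.running[f"mean{k}"] = mu.astype(np.float32)
            self.running[f"var{k}"] = var.astype(np.float32)
            zhat = (z - mu) / np.sqrt(var + _BN_EPS)
            h = np.maximum(zhat * p[f"g{k}"] + p[f"beta{k}"], 0.0)

    def forward_pair(self, x_train: np.ndarray, x_eval: np.ndarray,
                     cache: dict) -> tuple[np.ndarray, np.ndarray]:
        """Training-mode forward for ``x_train`` and inference-mode forward
        for ``x_eval`` in one pass.

        Equivalent to ``forward(x_eval)`` followed by
        ``forward(x_train, train=True, cache=cache)`` (the eval rows are
        normalized with the pre-update running statistics), but the affine
        transforms run as one combined GEMM per layer.
        """
        B = x_train.shape[0]
        h = np.ascontiguousarray(
            np.concatenate([x_train, x_eval], axis=0), dtype=np.float32
        )
        if h.shape[1] != self.input_dim:
            raise ValueError("observation dim does not match network input")
        cache["x0"] = h[:B]
        p = self.params
        for k in range(self.n_hidden_layers):
            z = h @ p[f"W{k}"] + p[f"b{k}"]
            zt = z[:B]
            mu = zt.mean(axis=0)
            var = zt.var(axis=0)
            run_mu = self.running[f"mean{k}"]
            run_var = self.running[f"var{k}"]
            inv_std_ev = 1.0 / np.sqrt(run_var + _BN_EPS)
            zhat_ev = (z[B:] - run_mu) * inv_std_ev
            self.running[f"mean{k}"] += _BN_MOMENTUM * (mu - run_mu)
            self.running[f"var{k}"] += _BN_MOMENTUM * (var - run_var)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (zt - mu) * inv_std
            pre_t = zhat * p[f"g{k}"] + p[f"beta{k}"]
            pre_e = zhat_ev * p[f"g{k}"] + p[f"beta{k}"]
            a = np.maximum(np.concatenate([pre_t, pre_e], axis=0), 0.0)
            cache[f"h{k}"] = h[:B]
            cache[f"zhat{k}"] = zhat
            cache[f"inv_std{k}"] = inv_std
            cache[f"mask{k}"] = pre_t > 0
            h = a
        cache["h_last"] = h[:B]
        q = h @ p["W_out"] + p["b_out"]
        return q[:B], q[B:]

    def q_values(self, observation: np.ndarray) -> np.ndarray:
        """Evaluation-mode action values for a single observation (shape (4,))."""
        return self.forward(observation, train=False)[0]

    def record_activations(self, observation: np.ndarray) -> list[np.ndarray]:
        """Post-ReLU hidden activations for a single observation.

        Returns one non-negative vector per hidden layer (sizes 112, 96, 80,
        64 in the default configuration), computed in evaluation mode.
        """
        return [a[0] for a in self.record_activations_batch(np.atleast_2d(observation))]

    def record_activations_batch(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-layer post-ReLU activations for a batch; each (B, layer size)."""
        x = np.ascontiguousarray(np.atleast_2d(x), dtype=np.float32)
        h = x
        p = self.params
        acts = []
        for k in range(self.n_hidden_layers):
            z = h @ p[f"W{k}"] + p[f"b{k}"]
            inv_std = 1.0 / np.sqrt(self.running[f"var{k}"] + _BN_EPS)
            pre = (z - self.running[f"mean{k}"]) * inv_std * p[f"g{k}"] + p[f"beta{k}"]
            h = np.maximum(pre, 0.0)
            acts.append(h)
        return acts

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, dq: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters given d(loss)/d(q)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h_last = cache["h_last"]
        grads["W_out"] = h_last.T @ dq
        grads["b_out"] = dq.sum(axis=0)
        dh = dq @ p["W_out"].T
        B = dq.shape[0]
        for k in reversed(range(self.n_hidden_layers)):
            dpre = dh * cache[f"mask{k}"]
            zhat = cache[f"zhat{k}"]
            grads[f"g{k}"] = (dpre * zhat).sum(axis=0)
            grads[f"beta{k}"] = dpre.sum(axis=0)
            dzhat = dpre * p[f"g{k}"]
            inv_std = cache[f"inv_std{k}"]
            # batch-norm backward (batch statistics participate in the graph)
            dz = (inv_std / B) * (
                B * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            h_in = cache[f"h{k}"]
            grads[f"W{k}"] = h_in.T @ dz
            grads[f"b{k}"] = dz.sum(axis=0)
            if k > 0:
                dh = dz @ p[f"W{k}"].T
        return grads

    # -- snapshots ----------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        """Deep copy of all parameters and running statistics."""
        out = {k: v.copy() for k, v in self.params.items()}
        out.update({f"run_{k}": v.copy() for k, v in self.running.items()})
        return out

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        for k in self.running:
            self.running[k] = state[f"run_{k}"].copy()

    def clone(self) -> "QNetwork":
        other = QNetwork(self.input_dim, self.hidden_sizes, self.output_dim,
                         rng=np.random.default_rng(0))
        other.set_state(self.get_state())
        return other


class Adam:
    """Adam optimizer over a parameter dictionary."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            if _HAVE_NUMBA:
                _adam_update(
                    params[k].reshape(-1), np.ascontiguousarray(g, dtype=np.float32).reshape(-1),
                    m.reshape(-1), v.reshape(-1),
                    np.float32(self.lr / b1t), np.float32(1.0 - self.beta1),
                    np.float32(1.0 - self.beta2), np.float32(np.sqrt(b2t)),
                    np.float32(self.eps),
                )
            else:
                m += (1.0 - self.beta1) * (g - m)
                v += (1.0 - self.beta2) * (g * g - v)
                params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
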