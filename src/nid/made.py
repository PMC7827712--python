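"""Masked autoregressive density baselines (MADE, MADE-S, sliding window).

A single feedforward network whose weight masks enforce an autoregressive
factorization p(X) = prod_i p(X_i | predecessors) for a variable ordering.
Variants:

* ``made_nll`` — one fixed ordering (classic MADE with categorical heads).
* ``made_s``  — one network shared across a pool of random orderings,
  resampled per minibatch; evaluation averages over the pool.
* window size ``k`` — restricts each variable's predecessors to the k
  immediately preceding positions, the subset-subsampling baseline in which
  only a linear number of size-k contexts is modeled.

Inputs are one-hot encoded; masks operate at variable granularity, so the
connectivity audit (no gradient path from non-predecessors) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Adam, Parameter, Tensor, cross_entropy_sum, nll_matrix, relu
from .datasets import SampleMatrix

__all__ = ["MADEConfig", "MADEModel", "MADEResult", "made_nll", "made_s"]

_NEG_INF = -1e9


@dataclass
class MADEConfig:
    n_vars: int
    supports: tuple[int, ...]
    hidden_dims: tuple[int, ...] = (64, 64)
    n_orderings: int = 1
    window: int | None = None  # restrict contexts to the k previous positions
    lr: float = 5e-3
    epochs: int = 100
    batch_size: int = 512
    seed: int = 0
    clip_norm: float = 5.0
    patience: int = 25

    def __post_init__(self) -> None:
        self.supports = tuple(int(q) for q in self.supports)
        if len(self.supports) != self.n_vars:
            raise ValueError("supports length must match n_vars")
        if self.window is not None and not 1 <= self.window <= self.n_vars:
            raise ValueError("window must lie in 1..n_vars")
        if self.n_orderings < 1:
            raise ValueError("need at least one ordering")


@dataclass
class MADEResult:
    """Validation NLLs in nats, per variable in *input* (not ordering) order."""

    per_variable: np.ndarray
    orderings: list[np.ndarray]
    last_variable_nll: float  # NLL of the final position, averaged over orderings


class MADEModel:
    """Masked feedforward network with per-ordering connectivity masks."""

    def __init__(self, config: MADEConfig):
        self.config = config
        n = config.n_vars
        self.q_max = max(config.supports)
        rng = np.random.default_rng(config.seed)
        dims = [n * self.q_max, *config.hidden_dims, n * self.q_max]
        self.weights, self.biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.weights.append(
                Parameter(rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_in, d_out)))
            )
            self.biases.append(Parameter(np.zeros(d_out)))
        # hidden-unit degrees, resampled once; valid for every ordering
        self.hidden_degrees = [
            rng.integers(0, n - 1, size=d) for d in config.hidden_dims
        ]
        mask = np.zeros((n, self.q_max))
        for i, qi in enumerate(config.supports):
            mask[i, qi:] = _NEG_INF
        self._class_mask = mask.reshape(1, n, self.q_max)
        self.orderings = [
            rng.permutation(n) if (k or config.n_orderings > 1) else np.arange(n)
            for k in range(config.n_orderings)
        ]

    def parameters(self) -> list[Parameter]:
        return [*self.weights, *self.biases]

    # ------------------------------------------------------------------
    def masks(self, ordering: np.ndarray) -> list[np.ndarray]:
        """Connectivity masks for one ordering (optionally windowed)."""
        cfg = self.config
        n, q, w = cfg.n_vars, self.q_max, cfg.window
        position = np.empty(n, dtype=np.int64)
        position[ordering] = np.arange(n)
        in_deg = np.repeat(position, q)
        out_deg = np.repeat(position, q)
        if w is None:
            degs = [in_deg, *self.hidden_degrees, out_deg]
            out = []
            for a, (da, db) in enumerate(zip(degs[:-1], degs[1:])):
                if a == len(degs) - 2:
                    out.append((db[None, :] > da[:, None]).astype(float))
                else:
                    out.append((db[None, :] >= da[:, None]).astype(float))
            return out
        # sliding window: dedicate hidden blocks to output positions and
        # allow only the w immediately preceding positions as inputs
        masks = []
        blocks = [np.mod(np.arange(d), n) for d in cfg.hidden_dims]
        lo = np.maximum(blocks[0][None, :] - w, 0)
        first = (in_deg[:, None] >= lo) & (in_deg[:, None] < blocks[0][None, :])
        masks.append(first.astype(float))
        for prev, cur in zip(blocks[:-1], blocks[1:]):
            masks.append((prev[:, None] == cur[None, :]).astype(float))
        masks.append((blocks[-1][:, None] == out_deg[None, :]).astype(float))
        return masks

    def forward(self, X: np.ndarray, ordering: np.ndarray) -> Tensor:
        """Logits (B, n, q_max) under the autoregressive masks of ``ordering``."""
        cfg = self.config
        n, q = cfg.n_vars, self.q_max
        B = X.shape[0]
        onehot = np.zeros((B, n, q))
        np.put_along_axis(onehot, np.asarray(X)[..., None], 1.0, axis=-1)
        h = Tensor(onehot.reshape(B, n * q))
        masks = self.masks(ordering)
        for idx, (W, b, M) in enumerate(zip(self.weights, self.biases, masks)):
            h = h @ (W * Tensor(M)) + b
            if idx < len(self.weights) - 1:
                h = relu(h)
        logits = h.reshape(B, n, q) + Tensor(self._class_mask)
        return logits

    def evaluate(self, X: np.ndarray) -> MADEResult:
        """Validation NLL per variable, averaged over the ordering pool."""
        uniq, counts = np.unique(np.asarray(X, dtype=np.int64), axis=0, return_counts=True)
        w = counts / counts.sum()
        per_var = np.zeros(self.config.n_vars)
        last = 0.0
        for ordering in self.orderings:
            logits = self.forward(uniq, ordering).data
            nll = (nll_matrix(logits, uniq) * w[:, None]).sum(axis=0)
            per_var += nll / len(self.orderings)
            last += nll[ordering[-1]] / len(self.orderings)
        return MADEResult(
            per_variable=per_var, orderings=self.orderings, last_variable_nll=float(last)
        )

    def connectivity_audit(self, rng: np.random.Generator | None = None) -> None:
        """Verify output i is insensitive to non-predecessor inputs."""
        cfg = self.config
        rng = rng or np.random.default_rng(0)
        X = np.stack(
            [rng.integers(0, q, size=32) for q in cfg.supports], axis=1
        )
        for ordering in self.orderings:
            base = self.forward(X, ordering).data
            position = np.empty(cfg.n_vars, dtype=np.int64)
            position[ordering] = np.arange(cfg.n_vars)
            for j in range(cfg.n_vars):
                mutated = X.copy()
                mutated[:, j] = (mutated[:, j] + 1) % cfg.supports[j]
                out = self.forward(mutated, ordering).data
                changed = ~np.isclose(out, base).all(axis=(0, 2))
                for i in np.nonzero(changed)[0]:
                    lo = position[i] - (cfg.window or cfg.n_vars)
                    if not lo <= position[j] < position[i]:
                        raise AssertionError(
                            f"mask violation: output {i} depends on variable {j}"
                        )


def _train(model: MADEModel, samples: SampleMatrix) -> MADEResult:
    cfg = model.config
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed + 1)
    Xtr, Xval = samples.train, samples.val
    best, best_state, stale = np.inf, None, 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), cfg.batch_size):
            batch = Xtr[perm[start : start + cfg.batch_size]]
            uniq, counts = np.unique(batch, axis=0, return_counts=True)
            ordering = model.orderings[rng.integers(len(model.orderings))]
            logits = model.forward(uniq, ordering)
            loss = cross_entropy_sum(
                logits, uniq, (counts / counts.sum())[:, None]
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        report = model.evaluate(Xval)
        score = report.last_variable_nll
        if score < best - 1e-4:
            best, stale = score, 0
            best_state = [p.data.copy() for p in model.parameters()]
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        for p, d in zip(model.parameters(), best_state):
            p.data = d
    return model.evaluate(Xval)


def made_nll(config: MADEConfig, samples: SampleMatrix) -> tuple[MADEModel, MADEResult]:
    """Train classic MADE with a single fixed ordering."""
    if config.n_orderings != 1:
        raise ValueError("made_nll uses a single ordering; use made_s otherwise")
    model = MADEModel(config)
    model.connectivity_audit()
    return model, _train(model, samples)


def made_s(config: MADEConfig, samples: SampleMatrix) -> tuple[MADEModel, MADEResult]:
    """Train one MADE shared across a pool of random orderings."""
    model = MADEModel(config)
    model.connectivity_audit()
    return model, _train(model, samples)
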