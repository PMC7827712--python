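"""Benchmark distributions with purely higher-order structure.

Three families, each available both as an exact :class:`~nid.joint.JointTable`
and as a seeded sample generator:

* **parity** — n-1 iid uniform bits plus their XOR.  Every proper-subset
  marginal is uniform, so all dependence lives at order n.
* **MDS codes** — uniform draws from a Reed-Solomon code of length n and
  message dimension k over a prime field of size q.  Any k symbols are
  jointly uniform and independent, and any k symbols determine the rest
  (the maximum-distance-separable property), so subset entropies are
  exactly min(m, k) * ln q.
* **canonical gates** — the small source/target circuits (XOR, AND,
  Redundant, Sum, Copy) used throughout the information-decomposition
  literature, with the target variable designated for directed measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .joint import JointTable

__all__ = [
    "SampleMatrix",
    "DatasetSpec",
    "gen_parity",
    "parity_joint",
    "gen_mds",
    "mds_joint",
    "gate_joint",
    "analytic_ground_truth",
    "GATE_NAMES",
]

TRAIN_FRACTION = 0.7
DEFAULT_M = 100_000


@dataclass
class SampleMatrix:
    """M x n integer observation matrix with a deterministic 70/30 split."""

    data: np.ndarray
    supports: tuple[int, ...]
    seed: int | None = None
    train_idx: np.ndarray = field(default=None, repr=False)
    val_idx: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] == 0:
            raise ValueError("data must be a non-empty (M, n) matrix")
        self.supports = tuple(int(q) for q in self.supports)
        if len(self.supports) != self.data.shape[1]:
            raise ValueError("supports length must match number of columns")
        for i, q in enumerate(self.supports):
            col = self.data[:, i]
            if col.min() < 0 or col.max() >= q:
                raise ValueError(f"column {i} has entries outside [0, {q})")
        if self.train_idx is None or self.val_idx is None:
            self._make_split()
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.val_idx = np.asarray(self.val_idx, dtype=np.int64)
        both = np.concatenate([self.train_idx, self.val_idx])
        if len(np.unique(both)) != self.n_samples or len(both) != self.n_samples:
            raise ValueError("train/validation split must be disjoint and exhaustive")

    def _make_split(self) -> None:
        rng = np.random.default_rng(None if self.seed is None else self.seed + 1)
        perm = rng.permutation(self.n_samples)
        cut = int(round(TRAIN_FRACTION * self.n_samples))
        self.train_idx, self.val_idx = perm[:cut], perm[cut:]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_vars(self) -> int:
        return self.data.shape[1]

    @property
    def train(self) -> np.ndarray:
        return self.data[self.train_idx]

    @property
    def val(self) -> np.ndarray:
        return self.data[self.val_idx]


@dataclass
class DatasetSpec:
    """Recipe for one benchmark dataset."""

    family: str  # parity | mds | gate
    n: int | None = None
    k: int | None = None
    q: int | None = None
    gate: str | None = None
    M: int = DEFAULT_M
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("parity", "mds", "gate"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "parity" and (self.n is None or self.n < 2):
            raise ValueError("parity requires n >= 2")
        if self.family == "mds":
            q = self.q if self.q is not None else self.n
            if self.n is None or self.k is None or not 1 <= self.k < self.n:
                raise ValueError("mds requires 1 <= k < n")
            if q < self.n or not _is_prime(q):
                raise ValueError("mds requires a prime field size q >= n")
        if self.family == "gate" and self.gate not in GATE_NAMES:
            raise ValueError(f"unknown gate {self.gate!r}; choose from {GATE_NAMES}")

    def generate(self) -> SampleMatrix:
        if self.family == "parity":
            return gen_parity(self.n, self.M, self.seed)
        if self.family == "mds":
            return gen_mds(self.n, self.k, self.M, self.seed, q=self.q)
        return gen_gate(self.gate, self.M, self.seed)

    def joint(self) -> JointTable:
        if self.family == "parity":
            return parity_joint(self.n)
        if self.family == "mds":
            return mds_joint(self.n, self.k, q=self.q)
        return gate_joint(self.gate)


# ----------------------------------------------------------------------
# parity


def gen_parity(n: int, M: int, seed: int | None = None) -> SampleMatrix:
    """M samples of n-1 iid uniform bits plus their XOR in the last column."""
    if n < 2 or M < 1:
        raise ValueError("parity requires n >= 2 and M >= 1")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(M, n - 1))
    data = np.concatenate([bits, bits.sum(axis=1, keepdims=True) % 2], axis=1)
    return SampleMatrix(data=data, supports=(2,) * n, seed=seed)


def parity_joint(n: int) -> JointTable:
    """Uniform mass 2^-(n-1) on the 2^(n-1) even-parity states."""
    if n < 2:
        raise ValueError("parity requires n >= 2")
    free = np.array(list(product((0, 1), repeat=n - 1)), dtype=np.int64)
    states = np.concatenate([free, free.sum(axis=1, keepdims=True) % 2], axis=1)
    probs = np.full(len(states), 2.0 ** -(n - 1))
    return JointTable(states, probs, (2,) * n)


# ----------------------------------------------------------------------
# MDS / Reed-Solomon codes


def _is_prime(q: int) -> bool:
    if q < 2:
        return False
    return all(q % d for d in range(2, int(math.isqrt(q)) + 1))


def _rs_matrix(n: int, k: int, q: int) -> np.ndarray:
    """Vandermonde generator matrix: entry [m, t] = t^m mod q, t = 0..n-1."""
    t = np.arange(n, dtype=np.int64)
    return np.array([pow(int(x), m, q) for m in range(k) for x in t]).reshape(k, n)


def _check_mds_params(n: int, k: int, q: int | None) -> int:
    q = n if q is None else q
    if not 1 <= k < n:
        raise ValueError("mds requires 1 <= k < n")
    if q < n or not _is_prime(q):
        raise ValueError(f"field size q={q} must be prime and >= n={n}")
    return q


def gen_mds(
    n: int, k: int, M: int, seed: int | None = None, q: int | None = None
) -> SampleMatrix:
    """M uniform draws from the length-n Reed-Solomon code of dimension k.

    Each sample draws k coefficients uniformly over the field of size q and
    evaluates the degree-(k-1) polynomial at the points 0..n-1; the induced
    distribution is uniform over the q^k codewords.
    """
    q = _check_mds_params(n, k, q)
    rng = np.random.default_rng(seed)
    coeffs = rng.integers(0, q, size=(M, k))
    data = coeffs @ _rs_matrix(n, k, q) % q
    return SampleMatrix(data=data, supports=(q,) * n, seed=seed)


def mds_joint(n: int, k: int, q: int | None = None) -> JointTable:
    """Exact joint: equal mass on all q^k Reed-Solomon codewords."""
    q = _check_mds_params(n, k, q)
    coeffs = np.array(list(product(range(q), repeat=k)), dtype=np.int64)
    states = coeffs @ _rs_matrix(n, k, q) % q
    probs = np.full(len(states), float(q) ** -k)
    return JointTable(states, probs, (q,) * n)


# ----------------------------------------------------------------------
# canonical gates

GATE_NAMES = ("XOR2", "AND2", "RDN2", "XOR3", "AND3", "RDN3", "SUM3", "COPY3")


def _gate_states(name: str) -> tuple[np.ndarray, tuple[int, ...]]:
    if name not in GATE_NAMES:
        raise ValueError(f"unknown gate {name!r}; choose from {GATE_NAMES}")
    if name in ("RDN2", "RDN3"):
        # one uniform bit copied to every source and to Y
        n_src = 2 if name == "RDN2" else 3
        rows = [[b] * (n_src + 1) for b in (0, 1)]
        return np.array(rows, dtype=np.int64), (2,) * (n_src + 1)
    n_src = 2 if name.endswith("2") else 3
    rows, y_support = [], 2
    for bits in product((0, 1), repeat=n_src):
        if name.startswith("XOR"):
            y = sum(bits) % 2
        elif name.startswith("AND"):
            y = int(all(bits))
        elif name == "SUM3":
            y = sum(bits)
            y_support = 4
        elif name == "COPY3":
            # the three pairwise copies jointly determine the full source
            # state, so Y is an 8-letter categorical relabeling of it
            y = bits[0] * 4 + bits[1] * 2 + bits[2]
            y_support = 8
        rows.append(list(bits) + [y])
    return np.array(rows, dtype=np.int64), (2,) * n_src + (y_support,)


def gate_joint(name: str) -> JointTable:
    """Exact joint of a canonical gate; the last variable is the target Y."""
    states, supports = _gate_states(name)
    probs = np.full(len(states), 1.0 / len(states))
    return JointTable(states, probs, supports, target_index=len(supports) - 1)


def gen_gate(name: str, M: int, seed: int | None = None) -> SampleMatrix:
    """Seeded samples from a canonical gate joint."""
    states, supports = _gate_states(name)
    rng = np.random.default_rng(seed)
    data = states[rng.integers(0, len(states), size=M)]
    return SampleMatrix(data=data, supports=supports, seed=seed)


# ----------------------------------------------------------------------
# analytic ground truth


def analytic_ground_truth(spec: DatasetSpec, unit: str = "nats"):
    """Closed-form Cohesion profile for parity and MDS, bypassing enumeration.

    Uses the analytic subset entropies:  m * ln 2  for any proper subset of a
    parity distribution, and  min(m, k) * ln q  for an MDS code.
    """
    from .exact import UndirectedProfile
    from .joint import convert_unit

    if spec.family == "parity":
        n = spec.n

        def h(m: int) -> float:  # subset entropy, nats
            return min(m, n - 1) * math.log(2.0)

    elif spec.family == "mds":
        n, kk = spec.n, spec.k
        q = spec.q if spec.q is not None else spec.n

        def h(m: int) -> float:
            return min(m, kk) * math.log(q)

    else:
        raise ValueError("analytic ground truth exists only for parity and mds")

    total = h(n)
    coh = [
        math.comb(n, j) * h(j) / math.comb(n - 1, j - 1) - total
        for j in range(1, n + 1)
    ]
    coh = [convert_unit(c, unit) for c in coh]
    diffs = [coh[j - 1] - coh[j] for j in range(1, n)]
    return UndirectedProfile(unit=unit, cohesion=coh, local_diffs=diffs)
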