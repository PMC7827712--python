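"""Discrete joint distributions and cached subset entropies.

A :class:`JointTable` holds an explicit probability table over ``n`` discrete
variables, the object on which every exact dependence measure in this package
is computed.  Entropies of variable subsets are memoized in an
:class:`EntropyCache` because the decomposition measures re-use the same
marginals across many orders ``k``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import entr

__all__ = ["JointTable", "EntropyCache", "LN2", "convert_unit"]

LN2 = math.log(2.0)

#: probabilities below this are treated as exact zeros before taking logs
_ZERO_TOL = 1e-15
_NORM_TOL = 1e-9

#: hard cap on the number of states in a full table (guards subset enumeration)
DEFAULT_STATE_CAP = 2 ** 24
#: hard cap on the number of variables (guards combinatorial blowup)
DEFAULT_NVARS_CAP = 20


def convert_unit(value_nats: float, unit: str) -> float:
    """Convert an information value from nats to the requested unit."""
    if unit == "nats":
        return value_nats
    if unit == "bits":
        return value_nats / LN2
    raise ValueError(f"unknown unit {unit!r}; expected 'nats' or 'bits'")


@dataclass
class EntropyCache:
    """Memo of subset entropies, keyed by canonical (sorted) index tuples.

    Entries are stored in nats; conversion happens at the reporting surface.
    """

    entries: dict[tuple[int, ...], float] = field(default_factory=dict)

    def get(self, subset: tuple[int, ...]) -> float | None:
        return self.entries.get(subset)

    def put(self, subset: tuple[int, ...], value: float) -> None:
        self.entries[subset] = value


class JointTable:
    """Explicit discrete joint distribution over ``n_vars`` variables.

    Parameters
    ----------
    states
        Integer array of shape ``(S, n_vars)`` listing the support states.
        States not listed carry zero mass.
    probs
        Probability mass for each listed state; must sum to 1 within 1e-9.
    supports
        Per-variable alphabet sizes ``q_i >= 2``.
    target_index
        Optional index of a designated target variable ``Y`` for the
        directed measures.
    """

    def __init__(
        self,
        states: np.ndarray,
        probs: np.ndarray,
        supports: Sequence[int],
        target_index: int | None = None,
        state_cap: int = DEFAULT_STATE_CAP,
        nvars_cap: int = DEFAULT_NVARS_CAP,
    ) -> None:
        states = np.asarray(states, dtype=np.int64)
        probs = np.asarray(probs, dtype=np.float64)
        if states.ndim != 2:
            raise ValueError("states must be a 2-D array of shape (S, n_vars)")
        supports = tuple(int(q) for q in supports)
        n = states.shape[1]
        if len(supports) != n:
            raise ValueError("supports length must match number of variables")
        if any(q < 2 for q in supports):
            raise ValueError("every alphabet size must be >= 2")
        if n > nvars_cap:
            raise ValueError(
                f"n_vars={n} exceeds the cap of {nvars_cap} variables"
            )
        total_states = 1
        for q in supports:
            total_states *= q
            if total_states > state_cap:
                raise ValueError(
                    f"full table size prod(q_i) exceeds the cap of {state_cap} states"
                )
        if probs.shape != (states.shape[0],):
            raise ValueError("probs must be 1-D and match the number of states")
        if np.any(probs < -_ZERO_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"probabilities sum to {probs.sum():.12f}, not 1 within {_NORM_TOL}"
            )
        for i, q in enumerate(supports):
            col = states[:, i]
            if col.min(initial=0) < 0 or col.max(initial=0) >= q:
                raise ValueError(f"state values of variable {i} fall outside [0, {q})")
        if target_index is not None and not (0 <= target_index < n):
            raise ValueError("target_index out of range")

        # collapse duplicate states and drop zero-mass entries
        keep = probs > _ZERO_TOL
        states, probs = states[keep], probs[keep]
        uniq, inv = np.unique(states, axis=0, return_inverse=True)
        mass = np.bincount(inv, weights=probs, minlength=len(uniq))
        self.states = uniq
        self.probs = mass / mass.sum()
        self.supports = supports
        self.target_index = target_index
        self.cache = EntropyCache()

    # ------------------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_mapping(
        cls,
        probs: Mapping[tuple[int, ...], float],
        supports: Sequence[int],
        target_index: int | None = None,
    ) -> "JointTable":
        states = np.array(list(probs.keys()), dtype=np.int64)
        mass = np.array(list(probs.values()), dtype=np.float64)
        return cls(states, mass, supports, target_index)

    @classmethod
    def from_samples(
        cls,
        data: np.ndarray,
        supports: Sequence[int] | None = None,
        target_index: int | None = None,
    ) -> "JointTable":
        """Plug-in (empirical frequency) estimate of a joint table.

        This is a raw maximum-likelihood estimate with no bias correction;
        entropies of plug-in tables are downward-biased at small sample size.
        """
        data = np.asarray(data, dtype=np.int64)
        if data.ndim != 2 or data.shape[0] == 0:
            raise ValueError("data must be a non-empty (M, n) integer matrix")
        if np.any(data < 0):
            raise ValueError("sample entries must be non-negative")
        if supports is None:
            supports = tuple(int(v) + 1 for v in data.max(axis=0))
            supports = tuple(max(q, 2) for q in supports)
        uniq, counts = np.unique(data, axis=0, return_counts=True)
        probs = counts / counts.sum()
        table = cls(uniq, probs, supports, target_index)
        table.is_plugin_estimate = True
        return table

    # ------------------------------------------------------------------
    def marginal(self, subset: Iterable[int]) -> np.ndarray:
        """Probability masses of the marginal over ``subset`` (order ignored)."""
        idx = self._canonical(subset)
        sub = self.states[:, idx]
        _, inv = np.unique(sub, axis=0, return_inverse=True)
        return np.bincount(inv, weights=self.probs)

    def subset_entropy(self, subset: Iterable[int], unit: str = "nats") -> float:
        """Shannon entropy of the marginal over ``subset`` (0 log 0 = 0)."""
        idx = self._canonical(subset)
        if idx == ():
            return 0.0
        cached = self.cache.get(idx)
        if cached is None:
            p = self.marginal(idx)
            p = p[p > _ZERO_TOL]
            cached = float(entr(p).sum())
            self.cache.put(idx, cached)
        return convert_unit(cached, unit)

    def conditional_entropy(
        self, target: int, given: Iterable[int], unit: str = "nats"
    ) -> float:
        """H(X_target | X_given) via the chain rule on cached entropies."""
        given = self._canonical(given)
        if target in given:
            raise ValueError("target variable cannot appear in the conditioning set")
        joint = self.subset_entropy(given + (target,))
        return convert_unit(joint - self.subset_entropy(given), unit)

    def _canonical(self, subset: Iterable[int]) -> tuple[int, ...]:
        idx = tuple(sorted(set(int(i) for i in subset)))
        if idx and (idx[0] < 0 or idx[-1] >= self.n_vars):
            raise ValueError(f"subset indices {idx} out of range for n={self.n_vars}")
        return idx

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "supports": list(self.supports),
            "states": [list(map(int, s)) for s in self.states],
            "probs": [float(p) for p in self.probs],
            "target_index": self.target_index,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "JointTable":
        payload = json.loads(text)
        return cls(
            np.array(payload["states"], dtype=np.int64),
            np.array(payload["probs"], dtype=np.float64),
            payload["supports"],
            payload.get("target_index"),
        )

    def __repr__(self) -> str:  # pragma: no cover
        tgt = f", target={self.target_index}" if self.target_index is not None else ""
        return (
            f"JointTable(n_vars={self.n_vars}, support_states={len(self.states)}{tgt})"
        )
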