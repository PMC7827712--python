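"""Exact order-by-order decomposition of multivariate dependence.

Undirected side: the Cohesion family

    C(k) = binom(n-1, k-1)^{-1} * sum_{|A|=k} H(X_A)  -  H(X_{1:n}),

whose k = 1 member is the total correlation.  C(k) is monotone decreasing in
k, so the local differences C(k-1||k) = C(k-1) - C(k) are non-negative and
attribute the total correlation to successive interaction orders.

Directed side: for a designated target Y with n source variables,

    C_Y(k-1||k) = binom(n, k-1)^{-1} sum_{|B|=k-1} H(Y|X_B)
                - binom(n, k)^{-1}   sum_{|A|=k}   H(Y|X_A),

the average reduction in uncertainty about Y when source contexts grow from
size k-1 to k.  Summed over k = 1..n these recover I(Y : X_{1:n}) exactly.

All sums enumerate subsets exhaustively with memoized marginal entropies;
table-size and variable-count caps in :class:`~nid.joint.JointTable` guard
the combinatorics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .joint import JointTable, convert_unit

__all__ = [
    "subset_entropy",
    "cohesion",
    "local_difference",
    "local_difference_conditional_form",
    "cumulative_differences",
    "directed_local_difference",
    "mi_decomposition",
    "decompose_undirected",
    "UndirectedProfile",
    "DirectedProfile",
]

_TOL = 1e-9


# ----------------------------------------------------------------------
# profiles


@dataclass
class UndirectedProfile:
    """Cohesion values C(k) and local differences C(k||k+1) for one joint."""

    unit: str
    cohesion: list[float]  # C(k), k = 1..n
    local_diffs: list[float]  # C(k||k+1), k = 1..n-1

    @property
    def n_vars(self) -> int:
        return len(self.cohesion)

    @property
    def total_correlation(self) -> float:
        return self.cohesion[0]

    def rows(self) -> list[dict]:
        out = [
            {"k": k + 1, "measure": f"C({k + 1})", "value": v, "unit": self.unit}
            for k, v in enumerate(self.cohesion)
        ]
        out += [
            {
                "k": k + 1,
                "measure": f"C({k + 1}||{k + 2})",
                "value": v,
                "unit": self.unit,
            }
            for k, v in enumerate(self.local_diffs)
        ]
        return out


@dataclass
class DirectedProfile:
    """Directed local differences C_Y(k-1||k), k = 1..n, and the total MI."""

    unit: str
    cy_local_diffs: list[float]
    total_mi: float

    @property
    def n_sources(self) -> int:
        return len(self.cy_local_diffs)

    def rows(self) -> list[dict]:
        out = [
            {
                "k": k + 1,
                "measure": f"CY({k}||{k + 1})",
                "value": v,
                "unit": self.unit,
            }
            for k, v in enumerate(self.cy_local_diffs)
        ]
        out.append(
            {"k": None, "measure": "I(Y:X)", "value": self.total_mi, "unit": self.unit}
        )
        return out


# ----------------------------------------------------------------------
# undirected measures


def subset_entropy(joint: JointTable, subset, unit: str = "nats") -> float:
    """Shannon entropy of the marginal of ``joint`` over ``subset``."""
    return joint.subset_entropy(subset, unit)


def _mean_subset_entropy(joint: JointTable, size: int, variables=None) -> float:
    """binom(n-1, size-1)^{-1} * sum over size-``size`` subsets of H(X_A), nats."""
    if variables is None:
        variables = range(joint.n_vars)
    variables = tuple(variables)
    n = len(variables)
    total = sum(
        joint.subset_entropy(A) for A in combinations(variables, size)
    )
    return total / comb(n - 1, size - 1)


def cohesion(joint: JointTable, k: int, unit: str = "nats") -> float:
    """Cohesion C(k); equals the total correlation at k = 1 and 0 at k = n."""
    n = joint.n_vars
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    value = _mean_subset_entropy(joint, k) - joint.subset_entropy(range(n))
    return convert_unit(value, unit)


def local_difference(joint: JointTable, k: int, unit: str = "nats") -> float:
    """Local difference C(k-1||k) = C(k-1) - C(k), non-negative."""
    n = joint.n_vars
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range 2..{n}")
    return cohesion(joint, k - 1, unit) - cohesion(joint, k, unit)


def local_difference_conditional_form(
    joint: JointTable, k: int, unit: str = "nats"
) -> float:
    """C(k-1||k) written as averaged conditional entropies.

    C(k-1||k) = (1/k) binom(n-1,k-2)^{-1} sum_{|B|=k-1} H(X_B)
              - (1/k) binom(n-1,k-1)^{-1} sum_i sum_{|B|=k-1, i not in B} H(X_i|X_B)

    Algebraically identical to :func:`local_difference`; implemented from the
    conditional-entropy terms as an independent cross-check of that identity.
    """
    n = joint.n_vars
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range 2..{n}")
    variables = range(n)
    first = sum(joint.subset_entropy(B) for B in combinations(variables, k - 1))
    first /= comb(n - 1, k - 2)
    second = 0.0
    for B in combinations(variables, k - 1):
        sB = set(B)
        for i in variables:
            if i not in sB:
                second += joint.conditional_entropy(i, B)
    second /= comb(n - 1, k - 1)
    return convert_unit((first - second) / k, unit)


def cumulative_differences(joint: JointTable, k: int, unit: str = "nats") -> float:
    """Partial sum sum_{l=1}^{k} C(l||l+1), from its conditional-entropy form.

    Derived by unrolling the chain rule over growing contexts:

        sum_{l=1}^{k} C(l||l+1)
            = (k/(k+1)) sum_i H(X_i)
            - (1/(k+1)) sum_{l=2}^{k+1} binom(n-1,l-1)^{-1}
                          sum_i sum_{|C|=l-1, i not in C} H(X_i | X_C)

    and equal to C(1) - C(k+1) by telescoping.  Computed here from the
    right-hand side so tests can check the telescoping identity against
    :func:`cohesion` independently.
    """
    n = joint.n_vars
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range 1..{n - 1}")
    variables = range(n)
    marg = sum(joint.subset_entropy((i,)) for i in variables)
    acc = (k / (k + 1)) * marg
    for l in range(2, k + 2):
        inner = 0.0
        for C in combinations(variables, l - 1):
            sC = set(C)
            for i in variables:
                if i not in sC:
                    inner += joint.conditional_entropy(i, C)
        acc -= inner / ((k + 1) * comb(n - 1, l - 1))
    return convert_unit(acc, unit)


def decompose_undirected(joint: JointTable, unit: str = "nats") -> UndirectedProfile:
    """Full Cohesion profile: C(k) for k = 1..n and all local differences."""
    n = joint.n_vars
    coh = [cohesion(joint, k, unit) for k in range(1, n + 1)]
    diffs = [coh[k - 1] - coh[k] for k in range(1, n)]
    return UndirectedProfile(unit=unit, cohesion=coh, local_diffs=diffs)


# ----------------------------------------------------------------------
# directed measures


def _sources(joint: JointTable) -> tuple[int, ...]:
    if joint.target_index is None:
        raise ValueError("no target variable designated on this joint table")
    return tuple(i for i in range(joint.n_vars) if i != joint.target_index)


def directed_local_difference(joint: JointTable, k: int, unit: str = "nats") -> float:
    """Directed local difference C_Y(k-1||k) for the designated target.

    ``k`` ranges over 1..n where n counts *source* variables; k = 1 gives
    H(Y) minus the mean over single sources of H(Y|X_i), i.e., the average
    single-source mutual information about Y.
    """
    sources = _sources(joint)
    y = joint.target_index
    n = len(sources)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n} source variables")
    first = sum(
        joint.conditional_entropy(y, B) for B in combinations(sources, k - 1)
    ) / comb(n, k - 1)
    second = sum(
        joint.conditional_entropy(y, A) for A in combinations(sources, k)
    ) / comb(n, k)
    return convert_unit(first - second, unit)


def mi_decomposition(joint: JointTable, unit: str = "nats") -> DirectedProfile:
    """Order-k decomposition of I(Y : X) for the designated target.

    The local differences sum exactly to the mutual information because the
    average conditional entropy at each subset size telescopes between
    consecutive orders.
    """
    sources = _sources(joint)
    y = joint.target_index
    n = len(sources)
    diffs = [directed_local_difference(joint, k, unit) for k in range(1, n + 1)]
    total = joint.subset_entropy((y,)) - joint.conditional_entropy(y, sources)
    return DirectedProfile(
        unit=unit, cy_local_diffs=diffs, total_mi=convert_unit(total, unit)
    )
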