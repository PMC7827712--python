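"""Exact decomposition: frozen values, algebraic identities, invariants."""

import math

import numpy as np
import pytest

from nid.datasets import gate_joint, mds_joint, parity_joint
from nid.exact import (
    cohesion,
    cumulative_differences,
    decompose_undirected,
    directed_local_difference,
    local_difference,
    local_difference_conditional_form,
    mi_decomposition,
    subset_entropy,
)
from conftest import random_joint

LN2 = math.log(2)


class TestSubsetEntropy:
    def test_and3_target_marginal_bits(self):
        # H(Y) for Y = AND of three uniform bits: -(7/8)lg(7/8) - (1/8)lg(1/8)
        joint = gate_joint("AND3")
        expected = -(7 / 8) * math.log2(7 / 8) - (1 / 8) * math.log2(1 / 8)
        assert subset_entropy(joint, [3], unit="bits") == pytest.approx(
            expected, abs=1e-12
        )

    def test_independent_uniform_pair(self):
        joint = parity_joint(3)  # any 2 of 3 parity variables are iid uniform
        assert subset_entropy(joint, [0, 1]) == pytest.approx(2 * LN2, abs=1e-12)


class TestCohesion:
    def test_independent_variables_zero(self, rng):
        # product of independent marginals: every C(k) vanishes
        p = rng.dirichlet([1, 1])
        q = rng.dirichlet([1, 1, 1])
        states = np.array([(a, b) for a in range(2) for b in range(3)])
        probs = np.array([p[a] * q[b] for a, b in states])
        from nid.joint import JointTable

        jt = JointTable(states, probs, (2, 3))
        for k in (1, 2):
            assert cohesion(jt, k) == pytest.approx(0.0, abs=1e-9)

    def test_parity5_k4(self):
        assert cohesion(parity_joint(5), 4) == pytest.approx(LN2, abs=1e-9)

    def test_mds73_k3_analytic(self):
        assert cohesion(mds_joint(7, 3), 3) == pytest.approx(
            4 * math.log(7), abs=1e-9
        )

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            cohesion(parity_joint(3), 4)

    def test_total_correlation_at_k1(self, rng):
        jt = random_joint(rng, 4, 2)
        tc = sum(jt.subset_entropy([i]) for i in range(4)) - jt.subset_entropy(
            range(4)
        )
        assert cohesion(jt, 1) == pytest.approx(tc, abs=1e-12)


class TestLocalDifferences:
    @pytest.mark.parametrize(
        "k,expected", [(2, 0.0), (3, 0.0), (4, 0.0), (5, LN2)]
    )
    def test_parity5_profile(self, k, expected):
        assert local_difference(parity_joint(5), k) == pytest.approx(
            expected, abs=1e-9
        )

    def test_mds73_c34(self):
        # analytic value 1.75 ln 7, printed as 3.4
        assert local_difference(mds_joint(7, 3), 4) == pytest.approx(
            1.75 * math.log(7), abs=1e-9
        )

    def test_conditional_form_identity(self, random_joint_suite):
        # chain-rule rewrite must agree with the difference of Cohesions
        for jt in random_joint_suite[:20]:
            for k in range(2, jt.n_vars + 1):
                assert local_difference_conditional_form(jt, k) == pytest.approx(
                    local_difference(jt, k), abs=1e-9
                )

    def test_parity5_conditional_form_k5(self):
        assert local_difference_conditional_form(parity_joint(5), 5) == pytest.approx(
            LN2, abs=1e-9
        )

    def test_cumulative_equals_cohesion_gap(self, random_joint_suite):
        for jt in random_joint_suite[:20]:
            for k in range(1, jt.n_vars):
                assert cumulative_differences(jt, k) == pytest.approx(
                    cohesion(jt, 1) - cohesion(jt, k + 1), abs=1e-9
                )

    def test_cumulative_total_on_parity(self):
        # summing every local difference recovers the total correlation
        jt = parity_joint(5)
        tc = sum(jt.subset_entropy([i]) for i in range(5)) - jt.subset_entropy(
            range(5)
        )
        assert cumulative_differences(jt, 4) == pytest.approx(tc, abs=1e-9)
        assert tc == pytest.approx(LN2, abs=1e-12)


class TestUndirectedProfile:
    def test_parity_and_mds_profiles(self):
        up = decompose_undirected(parity_joint(5))
        np.testing.assert_allclose(up.local_diffs, [0, 0, 0, LN2], atol=1e-9)
        um = decompose_undirected(mds_joint(7, 3))
        np.testing.assert_allclose(
            um.local_diffs[:4],
            [0, 0, 1.75 * math.log(7), 1.05 * math.log(7)],
            atol=1e-9,
        )

    def test_invariants_on_random_joints(self, random_joint_suite):
        for jt in random_joint_suite:
            up = decompose_undirected(jt)
            n = jt.n_vars
            # monotone decrease and final zero
            assert all(d >= -1e-9 for d in up.local_diffs)
            assert up.cohesion[-1] == pytest.approx(0.0, abs=1e-9)
            # telescoping: C(k) = sum_{l=k}^{n-2} C(l||l+1) + C(n-1)
            for k in range(1, n):
                tail = sum(up.local_diffs[k - 1 : n - 2]) + up.cohesion[n - 2]
                assert up.cohesion[k - 1] == pytest.approx(tail, abs=1e-9)

    def test_unit_coherence(self, random_joint_suite):
        jt = random_joint_suite[0]
        nats = decompose_undirected(jt, "nats")
        bits = decompose_undirected(jt, "bits")
        for a, b in zip(nats.cohesion, bits.cohesion):
            assert b * LN2 == pytest.approx(a, abs=1e-12)


class TestDirected:
    def test_requires_target(self):
        with pytest.raises(ValueError, match="target"):
            directed_local_difference(parity_joint(3), 1)

    def test_and2_first_difference_bits(self):
        assert directed_local_difference(
            gate_joint("AND2"), 1, unit="bits"
        ) == pytest.approx(0.311, abs=5e-4)

    def test_xor2_no_first_order_information(self):
        assert directed_local_difference(
            gate_joint("XOR2"), 1, unit="bits"
        ) == pytest.approx(0.0, abs=1e-9)

    def test_and3_second_difference_bits(self):
        assert directed_local_difference(
            gate_joint("AND3"), 2, unit="bits"
        ) == pytest.approx(0.1556, abs=5e-5)

    def test_copy_gate_first_difference(self):
        assert directed_local_difference(
            gate_joint("COPY3"), 1, unit="bits"
        ) == pytest.approx(1.0, abs=1e-9)

    def test_mi_conservation_and_nonnegativity(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 5))
            jt = random_joint(rng, n, 2, target=n - 1)
            prof = mi_decomposition(jt)
            assert all(d >= -1e-9 for d in prof.cy_local_diffs)
            assert sum(prof.cy_local_diffs) == pytest.approx(
                prof.total_mi, abs=1e-9
            )

    def test_first_difference_is_mean_pairwise_mi(self, rng):
        jt = random_joint(rng, 4, 2, target=3)
        y = 3
        mis = [
            jt.subset_entropy([y]) - jt.conditional_entropy(y, [i])
            for i in range(3)
        ]
        assert directed_local_difference(jt, 1) == pytest.approx(
            np.mean(mis), abs=1e-9
        )

    def test_independent_target_all_zero(self, rng):
        # Y independent of the sources: no information at any order
        from itertools import product
        from nid.joint import JointTable

        src = np.array(list(product((0, 1), repeat=2)))
        rows, probs = [], []
        py = rng.dirichlet([1, 1])
        for s in src:
            for yv in (0, 1):
                rows.append([*s, yv])
                probs.append(0.25 * py[yv])
        jt = JointTable(np.array(rows), np.array(probs), (2, 2, 2), target_index=2)
        prof = mi_decomposition(jt)
        np.testing.assert_allclose(prof.cy_local_diffs, 0.0, atol=1e-9)
        assert prof.total_mi == pytest.approx(0.0, abs=1e-9)
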