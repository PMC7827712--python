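"""Generators: construction invariants, reproducibility, analytic agreement."""

import math

import numpy as np
import pytest

from nid.datasets import (
    DatasetSpec,
    SampleMatrix,
    analytic_ground_truth,
    gate_joint,
    gen_mds,
    gen_parity,
    mds_joint,
    parity_joint,
)
from nid.exact import decompose_undirected
from nid.joint import JointTable


def plugin_entropy(cols: np.ndarray) -> float:
    _, counts = np.unique(cols, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


class TestParity:
    def test_rows_have_even_parity(self):
        sm = gen_parity(6, 500, seed=3)
        assert np.all(sm.data.sum(axis=1) % 2 == 0)

    def test_bit_reproducible(self):
        a, b = gen_parity(5, 1000, seed=9), gen_parity(5, 1000, seed=9)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_split_disjoint_exhaustive(self):
        sm = gen_parity(4, 1001, seed=0)
        both = np.concatenate([sm.train_idx, sm.val_idx])
        assert len(np.unique(both)) == 1001
        assert len(sm.train_idx) == round(0.7 * 1001)

    def test_joint_small_cases(self):
        jt = parity_joint(2)
        assert {tuple(s) for s in jt.states} == {(0, 0), (1, 1)}
        jt5 = parity_joint(5)
        assert jt5.subset_entropy(range(5)) == pytest.approx(
            4 * math.log(2), abs=1e-12
        )

    def test_proper_subset_marginals_uniform(self):
        jt = parity_joint(4)
        for subset in ([0], [3], [0, 3], [1, 2, 3]):
            m = jt.marginal(subset)
            np.testing.assert_allclose(m, 1.0 / len(m), atol=1e-12)

    def test_plugin_entropy_within_three_se(self):
        # subset entropies of sampled parity data vs the analytic m*ln2
        sm = gen_parity(5, 100_000, seed=1)
        for subset in ([0, 1], [1, 2, 3, 4]):
            h = plugin_entropy(sm.data[:, subset])
            # multinomial SE of the plug-in entropy via delta method
            _, counts = np.unique(sm.data[:, subset], axis=0, return_counts=True)
            p = counts / counts.sum()
            se = np.sqrt(((p * np.log(p) ** 2).sum() - h**2) / len(sm.data))
            se = max(se, (len(p) - 1) / (2 * len(sm.data)))  # bias floor
            assert abs(h - len(subset) * math.log(2)) < 3 * se + (len(p) - 1) / len(sm.data)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_parity(1, 10)


class TestMDS:
    def test_any_k_columns_uniform_and_determine_row(self):
        jt = mds_joint(5, 2)
        # any 2 columns jointly uniform
        for cols in ([0, 1], [2, 4]):
            m = jt.marginal(cols)
            assert len(m) == 25
            np.testing.assert_allclose(m, 1 / 25, atol=1e-12)
        # any 2 entries determine the codeword
        seen = {}
        for s in jt.states:
            key = (s[0], s[3])
            assert key not in seen
            seen[key] = s

    def test_subset_entropy_min_m_k(self):
        jt = mds_joint(7, 3)
        for subset in ([0], [1, 5], [0, 2, 4], [0, 1, 2, 3], list(range(6))):
            expected = min(len(subset), 3) * math.log(7)
            assert jt.subset_entropy(subset) == pytest.approx(expected, abs=1e-9)

    def test_samples_are_codewords(self):
        sm = gen_mds(7, 3, 300, seed=4)
        codewords = {tuple(s) for s in mds_joint(7, 3).states}
        assert all(tuple(row) in codewords for row in sm.data)

    def test_plugin_entropy_within_three_se(self):
        sm = gen_mds(7, 3, 100_000, seed=2)
        h = plugin_entropy(sm.data[:, [0, 3, 6]])
        _, counts = np.unique(sm.data[:, [0, 3, 6]], axis=0, return_counts=True)
        p = counts / counts.sum()
        se = np.sqrt(((p * np.log(p) ** 2).sum() - h**2) / len(sm.data))
        bias = (len(p) - 1) / (2 * len(sm.data))
        assert abs(h - 3 * math.log(7)) < 3 * max(se, bias) + 2 * bias

    def test_rejects_nonprime_field(self):
        with pytest.raises(ValueError, match="prime"):
            gen_mds(8, 3, 10)


class TestGates:
    def test_catalogue_and_unknown_name(self):
        for name in ("XOR2", "SUM3", "COPY3"):
            jt = gate_joint(name)
            assert jt.target_index == jt.n_vars - 1
        with pytest.raises(ValueError, match="unknown gate"):
            gate_joint("RED_XOR")

    def test_copy_gate_target_is_full_state(self):
        jt = gate_joint("COPY3")
        assert jt.supports == (2, 2, 2, 8)
        # Y bijective with the source triple
        assert jt.subset_entropy([3]) == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_redundant_gate_sources_are_copies(self):
        jt = gate_joint("RDN3")
        assert len(jt.states) == 2


class TestSpecAndAnalytic:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DatasetSpec("mds", n=7, k=9)
        with pytest.raises(ValueError):
            DatasetSpec("gate", gate="NAND")

    @pytest.mark.parametrize(
        "spec",
        [
            DatasetSpec("parity", n=5),
            DatasetSpec("parity", n=8),
            DatasetSpec("mds", n=7, k=3),
            DatasetSpec("mds", n=5, k=2),
        ],
        ids=["parity5", "parity8", "mds73", "mds52"],
    )
    def test_analytic_matches_enumeration(self, spec):
        analytic = analytic_ground_truth(spec)
        enumerated = decompose_undirected(spec.joint())
        np.testing.assert_allclose(
            analytic.cohesion, enumerated.cohesion, atol=1e-9
        )
        np.testing.assert_allclose(
            analytic.local_diffs, enumerated.local_diffs, atol=1e-9
        )

    def test_analytic_unsupported_family(self):
        with pytest.raises(ValueError):
            analytic_ground_truth(DatasetSpec("gate", gate="AND2"))


class TestSampleMatrix:
    def test_rejects_out_of_support(self):
        with pytest.raises(ValueError, match="outside"):
            SampleMatrix(data=np.array([[0, 3]]), supports=(2, 2))

    def test_rejects_bad_split(self):
        with pytest.raises(ValueError, match="disjoint"):
            SampleMatrix(
                data=np.zeros((4, 2), dtype=int),
                supports=(2, 2),
                train_idx=np.array([0, 1]),
                val_idx=np.array([1, 2]),
            )
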