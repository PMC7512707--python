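"""Lloyd-Max quantization and plug-in information estimates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import banzhafselect as bs
from banzhafselect.infotheory import interdependency_matrix, joint_entropy


class TestLloydQuantize:
    def test_five_distinct_values_recovered_exactly(self):
        v = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 20)
        q = bs.lloyd_quantize(v, n_levels=5)
        np.testing.assert_allclose(np.sort(q.levels), [1, 2, 3, 4, 5], atol=1e-12)
        assert np.mean((q.decode(q.encode(v)) - v) ** 2) == pytest.approx(0.0, abs=1e-24)

    def test_uniform_source_codebook(self):
        v = np.random.default_rng(3).random(100_000)
        q = bs.lloyd_quantize(v, n_levels=5)
        np.testing.assert_allclose(q.levels, [0.1, 0.3, 0.5, 0.7, 0.9], atol=0.01)

    def test_constant_input_single_effective_level(self):
        q = bs.lloyd_quantize(np.full(10, 3.5), n_levels=5)
        assert q.n_levels == 1
        assert np.all(q.encode([3.5, 0.0, 100.0]) == 0)

    def test_boundary_ties_go_to_lower_level(self):
        q = bs.Quantizer(levels=np.array([0.0, 1.0]), boundaries=np.array([0.5]))
        assert q.encode([0.5])[0] == 0
        assert q.encode([0.5000001])[0] == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bs.lloyd_quantize([], 5)
        with pytest.raises(ValueError):
            bs.lloyd_quantize([1.0], 0)


class TestDiscretizeTable:
    def test_default_is_five_levels(self, benchmark_table):
        table, _ = benchmark_table
        dt = bs.discretize_table(table)
        assert all(dt.quantizers[c].n_levels <= 5 for c in dt.feature_names)
        assert int(dt.codes.to_numpy().max()) == 4

    def test_integer_column_relabeling_preserves_equality_structure(self):
        col = np.array([0, 1, 2, 3, 4] * 30)
        table = pd.DataFrame({"f": col.astype(float), "label": (col % 2)})
        dt = bs.discretize_table(table, n_levels=5)
        codes = dt.codes["f"].to_numpy()
        for a in range(5):
            assert np.unique(codes[col == a]).size == 1
        assert np.unique(codes).size == 5

    def test_identical_columns_identical_codes(self, benchmark_table):
        table, _ = benchmark_table
        t = table[["marginal_0", "label"]].copy()
        t["twin"] = t["marginal_0"]
        dt = bs.discretize_table(t)
        np.testing.assert_array_equal(dt.codes["marginal_0"], dt.codes["twin"])

    def test_label_column_untouched(self, benchmark_table):
        table, _ = benchmark_table
        dt = bs.discretize_table(table)
        np.testing.assert_array_equal(dt.label.to_numpy(), table["label"].to_numpy())


class TestEntropyAndMI:
    def test_entropy_examples(self):
        assert bs.entropy([0, 1] * 50) == pytest.approx(1.0)
        assert bs.entropy([7] * 10) == 0.0
        codes = [0] * 2 + [1] * 3 + [2] * 5
        expected = -sum((c / 10) * np.log2(c / 10) for c in (2, 3, 5))
        assert bs.entropy(codes) == pytest.approx(expected, abs=1e-12)

    def test_mi_constant_and_identity(self):
        c = np.array([0, 1] * 50)
        assert bs.mutual_information(np.zeros(100, int), c) == 0.0
        assert bs.mutual_information(c, c) == pytest.approx(1.0)

    def test_mi_printed_contingency_table(self):
        # joint counts [[40,10],[10,40]] over 100 samples
        x = np.repeat([0, 0, 1, 1], [40, 10, 10, 40])
        c = np.repeat([0, 1, 0, 1], [40, 10, 10, 40])
        pj = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            pj[i, j] * np.log2(pj[i, j] / (pj[i].sum() * pj[:, j].sum()))
            for i in range(2)
            for j in range(2)
        )
        assert bs.mutual_information(x, c) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bs.mutual_information([0, 1], [0])
        with pytest.raises(ValueError):
            bs.conditional_mutual_information([0, 1], [0, 1], [0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mi_nonnegative_symmetric_bounded(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, 200)
        c = r.integers(0, 3, 200)
        mi = bs.mutual_information(x, c)
        assert mi >= 0.0
        assert mi == bs.mutual_information(c, x)
        assert mi <= min(bs.entropy(x), bs.entropy(c)) + 1e-12


class TestConditionalMI:
    def test_fully_explained_is_zero(self):
        x = np.array([0, 1, 0, 1] * 10)
        assert bs.conditional_mutual_information(x, x, x) == 0.0

    def test_irrelevant_conditioning_approximates_mi(self):
        r = np.random.default_rng(4)
        x = r.integers(0, 2, 10_000)
        c = np.where(r.random(10_000) < 0.8, x, 1 - x)
        z = r.integers(0, 2, 10_000)
        mi = bs.mutual_information(x, c)
        cmi = bs.conditional_mutual_information(x, c, z)
        assert abs(cmi - mi) < 0.02

    def test_xor_identity_on_exact_joint(self):
        x = np.array([0, 0, 1, 1])
        z = np.array([0, 1, 0, 1])
        c = x ^ z
        assert bs.mutual_information(x, c) == 0.0
        assert bs.conditional_mutual_information(x, c, z) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_chain_identity(self, seed):
        # I(X;C|Z) = I(XZ;C) - I(Z;C) for the plug-in estimator
        r = np.random.default_rng(seed)
        x = r.integers(0, 3, 300)
        c = r.integers(0, 2, 300)
        z = r.integers(0, 3, 300)
        xz = x * 3 + z
        lhs = bs.conditional_mutual_information(x, c, z)
        rhs = bs.mutual_information(xz, c) - bs.mutual_information(z, c)
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestInterdependencyMatrix:
    @staticmethod
    def _dtable(frame: pd.DataFrame) -> bs.DiscretizedFeatureTable:
        return bs.discretize_table(frame, n_levels=5)

    def test_xor_pair_on_exact_joint(self):
        x = np.array([0, 0, 1, 1], dtype=float)
        z = np.array([0, 1, 0, 1], dtype=float)
        frame = pd.DataFrame({"a": x, "b": z, "label": (x.astype(int) ^ z.astype(int))})
        r, D = interdependency_matrix(bs.discretize_table(frame, n_levels=2))
        np.testing.assert_allclose(r, [0.0, 0.0], atol=1e-12)
        assert D[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert D[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_exact_duplicate_is_fully_redundant(self):
        rng = np.random.default_rng(5)
        c = rng.integers(0, 2, 2000)
        f = c + rng.normal(0, 1, 2000)
        frame = pd.DataFrame({"f1": f, "f2": f, "label": c})
        r, D = interdependency_matrix(self._dtable(frame))
        assert r[0] > 0
        assert D[0, 1] == pytest.approx(-r[1], abs=1e-12)
        assert D[1, 0] == pytest.approx(-r[0], abs=1e-12)

    def test_matches_naive_definition_oracle(self):
        rng = np.random.default_rng(6)
        c = rng.integers(0, 2, 400)
        frame = pd.DataFrame({f"f{j}": rng.normal(c * (j % 3), 1.0, 400) for j in range(6)})
        frame["label"] = c
        dt = self._dtable(frame)
        r, D = interdependency_matrix(dt)
        lab = dt.label.to_numpy()
        for i, fi in enumerate(dt.feature_names):
            assert r[i] == pytest.approx(
                bs.mutual_information(dt.codes[fi], lab), abs=1e-12
            )
            for j, fj in enumerate(dt.feature_names):
                if i == j:
                    assert D[i, j] == 0.0
                    continue
                expected = bs.conditional_mutual_information(
                    dt.codes[fj], lab, dt.codes[fi]
                ) - bs.mutual_information(dt.codes[fj], lab)
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_row_permutation_invariance(self, benchmark_table):
        table, _ = benchmark_table
        small = table.iloc[:500, [0, 1, 2, -1]]
        r1, D1 = interdependency_matrix(self._dtable(small))
        shuffled = small.sample(frac=1.0, random_state=9)
        r2, D2 = interdependency_matrix(self._dtable(shuffled))
        np.testing.assert_allclose(r1, r2, atol=1e-12)
        np.testing.assert_allclose(D1, D2, atol=1e-12)

    def test_requires_two_features(self):
        frame = pd.DataFrame({"f": [1.0, 2.0], "label": [0, 1]})
        with pytest.raises(ValueError, match="at least 2"):
            interdependency_matrix(self._dtable(frame))

    def test_zero_variance_feature_is_inert(self):
        rng = np.random.default_rng(8)
        c = rng.integers(0, 2, 500)
        frame = pd.DataFrame(
            {"flat": np.ones(500), "sig": c + rng.normal(0, 1, 500), "label": c}
        )
        r, D = interdependency_matrix(self._dtable(frame))
        assert r[0] == 0.0
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_joint_entropy_additive_for_independent_blocks(self):
        x = np.repeat([0, 1], 8)
        y = np.tile([0, 1], 8)
        assert joint_entropy(x, y) == pytest.approx(bs.entropy(x) + bs.entropy(y), abs=1e-12)
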