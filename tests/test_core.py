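"""Model fitting, reference-aligned adjustment and rank-k reconstruction.

The independent oracle throughout is an eigendecomposition of the Gram
matrix X0^T X0: its eigenvectors give the right singular vectors and its
eigenvalues the squared singular values, without touching the SVD code path
under test.
"""

import numpy as np
import pandas as pd
import pytest

from bara import (
    BaraTransformer,
    GeneSpaceError,
    ParameterError,
    ReferenceLookupError,
    ValidationError,
    ZeroVarianceError,
    as_expression_matrix,
    fit_bara,
    select_k,
)


def eigen_rank_k(values, k):
    """Rank-k approximation of the centered matrix via the Gram-matrix
    eigendecomposition (oracle independent of np.linalg.svd)."""
    centered = values - values.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    order = np.argsort(evals)[::-1]
    v = evecs[:, order[:k]]
    return centered @ v @ v.T + values.mean(axis=0)


class TestFit:
    def test_toy_example(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        assert model.gene_means_.tolist() == [2.0, 0.0]
        np.testing.assert_allclose(model.singular_values_, [np.sqrt(8), np.sqrt(2)])
        frac = model.singular_values_**2 / np.sum(model.singular_values_**2)
        np.testing.assert_allclose(frac, [0.8, 0.2])
        assert model.k_ == 1
        np.testing.assert_allclose(model.basis_, [[0.0], [1.0]], atol=1e-12)
        np.testing.assert_allclose(
            model.compressed_train_.to_numpy().ravel(), [0.0, 0.0, 2.0, -2.0], atol=1e-12
        )
        assert model.variance_retained_ == pytest.approx(0.8)

    def test_toy_example_low_loss_keeps_both_dimensions(self, toy_train):
        model = fit_bara(toy_train, loss=0.10)
        assert model.k_ == 2
        assert model.variance_retained_ == pytest.approx(1.0)

    def test_zero_variance_training_set_rejected(self):
        with pytest.raises(ZeroVarianceError, match="zero-variance training set"):
            fit_bara([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])

    def test_k_override_beyond_rank_rejected(self, toy_train):
        with pytest.raises(ParameterError):
            fit_bara(toy_train, k_override=3)

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_bara([[1.0, np.nan], [2.0, 3.0]])

    def test_sign_convention_and_determinism(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=(15, 30))
        a = fit_bara(values, loss=0.1)
        b = fit_bara(values.copy(), loss=0.1)
        # bit-identical refits
        assert (a.basis_ == b.basis_).all()
        assert (a.compressed_train_.to_numpy() == b.compressed_train_.to_numpy()).all()
        # largest-magnitude entry of every basis column is positive
        peaks = a.basis_[np.argmax(np.abs(a.basis_), axis=0), np.arange(a.k_)]
        assert (peaks > 0).all()

    def test_basis_orthonormal(self):
        rng = np.random.default_rng(3)
        model = fit_bara(rng.normal(size=(20, 40)), loss=0.0)
        gram = model.basis_.T @ model.basis_
        np.testing.assert_allclose(gram, np.eye(model.k_), atol=1e-8)


class TestSelectK:
    @pytest.mark.parametrize(
        "s, loss, expected",
        [
            ((np.sqrt(8), np.sqrt(2)), 0.10, 2),
            ((np.sqrt(8), np.sqrt(2)), 0.25, 1),
            ((3.0, 2.0, 1.0), 0.0, 3),
            ((5.0, 0.0), 0.0, 1),
        ],
    )
    def test_smallest_k_retaining_variance(self, s, loss, expected):
        assert select_k(np.asarray(s), loss) == expected

    def test_all_zero_singular_values_rejected(self):
        with pytest.raises(ZeroVarianceError):
            select_k(np.zeros(3), 0.1)

    def test_variance_retention_bound_and_minimality(self):
        rng = np.random.default_rng(11)
        for loss in (0.0, 0.05, 0.10, 0.25):
            for _ in range(10):
                m, n = rng.integers(4, 30), rng.integers(5, 40)
                model = fit_bara(rng.normal(size=(m, n)), loss=loss)
                assert model.variance_retained_ >= 1 - loss - 1e-12
                if model.k_ > 1:
                    s2 = model.singular_values_ ** 2
                    below = np.sum(s2[: model.k_ - 1]) / np.sum(s2)
                    assert below < 1 - loss


class TestAdjust:
    def test_toy_adjustment(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        test = as_expression_matrix([[2.0, 5.0], [2.0, 1.0]], sample_ids=["t0", "t1"])
        res = model.adjust(test, ref_train=["s2", "s3"], ref_test=["t0", "t1"])
        np.testing.assert_allclose(res.adjustment_factors, [3.0], atol=1e-12)
        np.testing.assert_allclose(
            res.adjusted_test.to_numpy(), [[2.0, 2.0], [2.0, -2.0]], atol=1e-12
        )
        assert list(res.adjusted_test.index) == ["t0", "t1"]
        assert list(res.adjusted_test.columns) == list(toy_train.columns)

    def test_identical_references_give_zero_adjustment(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        res = model.adjust(toy_train, ref_train=["s2", "s3"], ref_test=["s2", "s3"])
        np.testing.assert_allclose(res.adjustment_factors, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            res.adjusted_test.to_numpy(), model.reconstruct_train().to_numpy(), atol=1e-12
        )

    def test_constant_shift_is_removed(self):
        rng = np.random.default_rng(8)
        train = as_expression_matrix(rng.normal(size=(12, 25)))
        model = fit_bara(train, loss=0.1)
        shift = 4.7
        shifted = train + shift
        refs = list(train.index[:3])
        res = model.adjust(shifted, ref_train=refs, ref_test=refs)
        # a_j = c * column sums of the basis
        np.testing.assert_allclose(
            res.adjustment_factors, shift * model.basis_.sum(axis=0), atol=1e-8
        )
        np.testing.assert_allclose(
            res.adjusted_test.to_numpy(), model.reconstruct_train().to_numpy(), atol=1e-8
        )

    def test_reference_alignment_is_exact(self):
        rng = np.random.default_rng(21)
        train = as_expression_matrix(rng.normal(size=(15, 40)))
        test = as_expression_matrix(
            rng.normal(size=(9, 40)) + 5, sample_ids=[f"t{i}" for i in range(9)]
        )
        model = fit_bara(train, loss=0.1)
        res = model.adjust(test, ref_train=list(train.index[:4]), ref_test=["t0", "t1", "t2"])
        gap = res.compressed_test.loc[["t0", "t1", "t2"]].mean() - model.compressed_train_.loc[
            list(train.index[:4])
        ].mean()
        np.testing.assert_allclose(gap.to_numpy(), 0.0, atol=1e-8)

    def test_rows_adjust_independently(self):
        """Same references -> adjusting rows one at a time equals joint run."""
        rng = np.random.default_rng(31)
        train = as_expression_matrix(rng.normal(size=(10, 20)))
        test = as_expression_matrix(
            rng.normal(size=(6, 20)), sample_ids=[f"t{i}" for i in range(6)]
        )
        model = fit_bara(train, loss=0.1)
        refs_tr = list(train.index[:3])
        refs_te = ["t0", "t1"]
        joint = model.adjust(test, refs_tr, refs_te).adjusted_test
        for sid in test.index:
            single = model.adjust(
                test.loc[sorted({sid, *refs_te})], refs_tr, refs_te
            ).adjusted_test
            np.testing.assert_allclose(
                single.loc[sid].to_numpy(), joint.loc[sid].to_numpy(), atol=1e-10
            )

    def test_gene_mismatch_rejected(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        bad = as_expression_matrix([[1.0, 2.0]], gene_ids=["g0", "other"])
        with pytest.raises(GeneSpaceError, match="incompatible gene space"):
            model.adjust(bad, ["s2"], [bad.index[0]])

    def test_gene_reordering_allowed(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        test = as_expression_matrix(
            [[5.0, 2.0], [1.0, 2.0]], sample_ids=["t0", "t1"], gene_ids=["g1", "g0"]
        )
        res = model.adjust(test, ["s2", "s3"], ["t0", "t1"])
        np.testing.assert_allclose(
            res.adjusted_test.to_numpy(), [[2.0, 2.0], [2.0, -2.0]], atol=1e-12
        )

    def test_reference_errors(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        with pytest.raises(ParameterError):
            model.adjust(toy_train, [], ["s0"])
        with pytest.raises(ReferenceLookupError):
            model.adjust(toy_train, ["nope"], ["s0"])
        with pytest.raises(ReferenceLookupError):
            model.adjust(toy_train, ["s0"], ["nope"])


class TestReconstruct:
    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(5)
        train = as_expression_matrix(rng.normal(size=(8, 5)))
        model = fit_bara(train, loss=0.0)
        np.testing.assert_allclose(
            model.reconstruct_train().to_numpy(), train.to_numpy(), atol=1e-8
        )

    def test_toy_rank_one_truncation(self, toy_train):
        model = fit_bara(toy_train, loss=0.25)
        np.testing.assert_allclose(
            model.reconstruct_train().to_numpy(),
            [[2.0, 0.0], [2.0, 0.0], [2.0, 2.0], [2.0, -2.0]],
            atol=1e-12,
        )

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            values = rng.normal(size=(20, 50))
            model = fit_bara(values, loss=0.1)
            oracle = eigen_rank_k(values, model.k_)
            rel = np.linalg.norm(model.reconstruct_train().to_numpy() - oracle) / np.linalg.norm(
                oracle
            )
            assert rel <= 1e-6

    def test_frobenius_error_equals_discarded_singular_values(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(12, 30))
        model = fit_bara(values, loss=0.3)
        err = np.linalg.norm(values - model.reconstruct_train().to_numpy()) ** 2
        tail = np.sum(model.singular_values_[model.k_ :] ** 2)
        assert err == pytest.approx(tail, rel=1e-8)


class TestSklearnSurface:
    def test_get_set_params_roundtrip(self):
        model = BaraTransformer(loss=0.2, k=3)
        params = model.get_params()
        assert params == {"loss": 0.2, "k": 3}
        model.set_params(loss=0.1, k=None)
        assert model.loss == 0.1 and model.k is None

    def test_transform_without_references_is_rank_k_smoothing(self, toy_train):
        model = BaraTransformer(loss=0.25).fit(toy_train)
        out = model.transform(toy_train)
        np.testing.assert_allclose(
            out.to_numpy(), model.reconstruct_train().to_numpy(), atol=1e-12
        )


class TestSelectKProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12),
        st.floats(0.0, 0.9),
    )
    def test_bound_and_minimality(self, values, loss):
        s = np.sort(np.asarray(values))[::-1]
        k = select_k(s, loss)
        frac = np.cumsum(s**2) / np.sum(s**2)
        assert 1 <= k <= s.size
        assert frac[k - 1] >= 1 - loss - 1e-9
        if k > 1:
            assert frac[k - 2] < 1 - loss
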