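"""Reference-aligned batch adjustment in an SVD-compressed space.

The method fits on a fixed training set X (m samples x n genes): genes are
centered by their training means, X0 = X - x_bar, and the centered matrix is
decomposed as X0 = U S V^T.  The smallest number k of right singular vectors
whose squared singular values retain at least a (1 - loss) fraction of the
total variance is kept; the training set is compressed as X' = X0 V[:, :k].

A test set Z is centered with the *training* means, projected onto the same
basis (Z' = (Z - x_bar) V[:, :k]) and aligned to the training set through
reference samples measured in both batches: per retained dimension j the
adjustment factor a_j is the difference between the mean projected reference
value in the test set and in the training set, and is subtracted from every
projected test sample.  Both sets are reconstructed to gene space by
right-multiplying with V[:, :k]^T and adding back the training means, giving
X^k (rank-k training reconstruction, what a downstream classifier is fitted
on) and Z^k (the adjusted test set, what it predicts on).

Because only k per-dimension means are estimated from the references, a
handful of reference samples suffices, and the training set is never altered
by the arrival of a new test batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    GeneSpaceError,
    ParameterError,
    ReferenceLookupError,
    ValidationError,
    ZeroVarianceError,
)
from .matrix import as_expression_matrix

# singular values below this fraction of the largest are treated as zero
# (centering always removes one rank; anything at this level is noise)
_RANK_TOL = 1e-10

DEFAULT_LOSS = 0.10


def select_k(singular_values, loss: float) -> int:
    """Smallest k whose leading squared singular values retain >= 1 - loss
    of the total variance.

    Parameters
    ----------
    singular_values : array-like
        Nonincreasing, nonnegative singular values of the centered training
        matrix.
    loss : float
        Acceptable fraction of training variance to discard, in [0, 1).
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0 or not (s > 0).any():
        raise ZeroVarianceError("all singular values are zero")
    if np.any(np.diff(s) > 1e-12 * s[0]):
        raise ParameterError("singular values must be nonincreasing")
    if not 0 <= loss < 1:
        raise ParameterError(f"loss must be in [0, 1), got {loss}")
    s = s[s > 0]
    frac = np.cumsum(s**2) / np.sum(s**2)
    target = 1.0 - loss
    # tiny slack so loss=0 is reachable despite rounding in the cumsum
    k = int(np.searchsorted(frac, target - 1e-12) + 1)
    return min(k, s.size)


@dataclass
class AdjustmentResult:
    """Output of a reference-aligned test-set adjustment.

    Attributes
    ----------
    adjustment_factors : ndarray, shape (k,)
        Per-dimension difference between test- and training-reference means
        in the compressed space (subtracted from the projected test set).
    compressed_test : DataFrame, shape (p, k)
        Projected test samples *after* adjustment.
    adjusted_test : DataFrame, shape (p, n)
        The reconstructed, adjusted test set Z^k (training gene order).
    """

    adjustment_factors: np.ndarray
    compressed_test: pd.DataFrame
    adjusted_test: pd.DataFrame
    reference_ids_train: list = field(default_factory=list)
    reference_ids_test: list = field(default_factory=list)


class BaraTransformer(BaseEstimator, TransformerMixin):
    """Batch adjustment by reference alignment.

    Parameters
    ----------
    loss : float, default 0.10
        Maximum fraction of training variance discarded when choosing the
        number of retained dimensions.
    k : int or None
        Explicit number of dimensions; overrides loss-based selection.

    Attributes (after ``fit``)
    --------------------------
    gene_means_ : Series (n,) — training column means x_bar.
    basis_ : ndarray (n, k) — retained right singular vectors V[:, :k],
        sign-fixed so each column's largest-magnitude entry is positive.
    singular_values_ : ndarray (r,) — positive singular values, nonincreasing.
    k_ : int — retained dimensions.
    variance_retained_ : float — sum of the leading k squared singular values
        over the total, always >= 1 - loss.
    compressed_train_ : DataFrame (m, k) — X' = X0 V[:, :k].
    train_gene_ids_, train_sample_ids_ : label lists.
    """

    def __init__(self, loss: float = DEFAULT_LOSS, k: int | None = None):
        self.loss = loss
        self.k = k

    def fit(self, X, y=None):
        train = as_expression_matrix(X)
        if train.shape[0] < 2:
            raise ValidationError("training set needs at least 2 samples")
        if not 0 <= self.loss < 1:
            raise ParameterError(f"loss must be in [0, 1), got {self.loss}")

        values = train.to_numpy()
        means = values.mean(axis=0)
        centered = values - means

        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        keep = s > _RANK_TOL * (s[0] if s.size else 0.0)
        if not keep.any():
            raise ZeroVarianceError("zero-variance training set")
        s = s[keep]
        vt = vt[keep]

        # deterministic sign convention: largest-magnitude entry of each
        # basis column is positive
        flip = vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)] < 0
        vt[flip] *= -1.0

        rank = s.size
        if self.k is not None:
            if not 1 <= self.k <= rank:
                raise ParameterError(f"k={self.k} outside [1, rank={rank}]")
            k = int(self.k)
        else:
            k = select_k(s, self.loss)

        basis = vt[:k].T  # n x k
        self.gene_means_ = pd.Series(means, index=train.columns)
        self.basis_ = basis
        self.singular_values_ = s
        self.k_ = k
        self.variance_retained_ = float(np.sum(s[:k] ** 2) / np.sum(s**2))
        self.compressed_train_ = pd.DataFrame(centered @ basis, index=train.index)
        self.train_gene_ids_ = list(train.columns)
        self.train_sample_ids_ = list(train.index)
        return self

    def _check_fitted(self):
        if not hasattr(self, "basis_"):
            raise ValidationError("model is not fitted")

    def _align_genes(self, test: pd.DataFrame) -> pd.DataFrame:
        if set(test.columns) != set(self.train_gene_ids_):
            missing = sorted(set(self.train_gene_ids_) - set(test.columns))[:5]
            extra = sorted(set(test.columns) - set(self.train_gene_ids_))[:5]
            raise GeneSpaceError(
                f"incompatible gene space (missing from test: {missing}, "
                f"unknown in test: {extra})"
            )
        return test[self.train_gene_ids_]

    def adjust(self, test, ref_train, ref_test) -> AdjustmentResult:
        """Align a test set to the training set via shared-batch references.

        ``ref_train`` are sample ids of the fitted training set; ``ref_test``
        sample ids of ``test``.  All test rows, references included, are
        adjusted and returned.
        """
        self._check_fitted()
        test = self._align_genes(as_expression_matrix(test))
        ref_train = list(ref_train)
        ref_test = list(ref_test)
        if not ref_train or not ref_test:
            raise ParameterError("reference sample lists must be non-empty")
        missing_train = [r for r in ref_train if r not in self.compressed_train_.index]
        if missing_train:
            raise ReferenceLookupError(f"training reference ids not found: {missing_train}")
        missing_test = [r for r in ref_test if r not in test.index]
        if missing_test:
            raise ReferenceLookupError(f"test reference ids not found: {missing_test}")

        centered = test.to_numpy() - self.gene_means_.to_numpy()
        projected = pd.DataFrame(centered @ self.basis_, index=test.index)
        a = (
            projected.loc[ref_test].mean(axis=0).to_numpy()
            - self.compressed_train_.loc[ref_train].mean(axis=0).to_numpy()
        )
        adjusted_proj = projected - a
        reconstructed = adjusted_proj.to_numpy() @ self.basis_.T + self.gene_means_.to_numpy()
        adjusted = pd.DataFrame(reconstructed, index=test.index, columns=self.train_gene_ids_)
        return AdjustmentResult(
            adjustment_factors=a,
            compressed_test=adjusted_proj,
            adjusted_test=adjusted,
            reference_ids_train=ref_train,
            reference_ids_test=ref_test,
        )

    def transform(self, X, ref_train=None, ref_test=None) -> pd.DataFrame:
        """Adjusted test set Z^k; without references, the plain rank-k
        compress-reconstruct of X under the training model."""
        self._check_fitted()
        if ref_train is None and ref_test is None:
            test = self._align_genes(as_expression_matrix(X))
            centered = test.to_numpy() - self.gene_means_.to_numpy()
            recon = centered @ self.basis_ @ self.basis_.T + self.gene_means_.to_numpy()
            return pd.DataFrame(recon, index=test.index, columns=self.train_gene_ids_)
        if ref_train is None or ref_test is None:
            raise ParameterError("provide both ref_train and ref_test, or neither")
        return self.adjust(X, ref_train, ref_test).adjusted_test

    def reconstruct_train(self) -> pd.DataFrame:
        """Rank-k reconstruction X^k = X' V[:, :k]^T + x_bar.

        This — not the raw training matrix — is what downstream prediction
        models are fitted on.
        """
        self._check_fitted()
        recon = self.compressed_train_.to_numpy() @ self.basis_.T + self.gene_means_.to_numpy()
        return pd.DataFrame(recon, index=self.train_sample_ids_, columns=self.train_gene_ids_)


def fit_bara(train, loss: float = DEFAULT_LOSS, k_override: int | None = None) -> BaraTransformer:
    """Fit the adjustment model on a training expression matrix."""
    return BaraTransformer(loss=loss, k=k_override).fit(train)


def transform_test(model: BaraTransformer, test, ref_train, ref_test) -> AdjustmentResult:
    """Reference-aligned adjustment of a test set under a fitted model."""
    return model.adjust(test, ref_train, ref_test)


def reconstruct_train(model: BaraTransformer) -> pd.DataFrame:
    """Rank-k reconstruction of the fitted training set."""
    return model.reconstruct_train()
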