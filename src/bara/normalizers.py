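"""Pluggable normalizer contract for the cross-study harness.

Every normalizer exposes two phases mirroring the predictive-modelling
setting: ``fit`` consumes the training matrix (and, for reference-based
methods, the training reference ids) and returns the matrix the classifier
is trained on; ``transform`` maps each incoming test set, given that
iteration's test reference ids, to the matrix the classifier predicts on.

Reference-based methods (``bara``, ``ref_center``, ``ref_ratio``) use only
the reference samples of the test set; batchwise methods (``mean_center``,
``ratio``, ``standardize``) use all test samples, references included, with
the training set as one batch and each test set as another.  External
methods (e.g. ComBat or frozen SVA from other toolkits) can be attached via
:func:`register_normalizer` without touching the harness.
"""

from __future__ import annotations

import abc

import pandas as pd

from . import baselines
from .core import DEFAULT_LOSS, BaraTransformer
from .errors import ParameterError


class Normalizer(abc.ABC):
    """Two-phase train/test normalization contract."""

    name: str = "abstract"
    uses_references: bool = False

    @abc.abstractmethod
    def fit(self, train: pd.DataFrame, ref_train) -> pd.DataFrame:
        """Normalize the training set; returns the classifier's design matrix."""

    @abc.abstractmethod
    def transform(self, test: pd.DataFrame, ref_test) -> pd.DataFrame:
        """Normalize one test set for prediction."""


class IdentityNormalizer(Normalizer):
    name = "none"

    def fit(self, train, ref_train):
        return train

    def transform(self, test, ref_test):
        return test


class BaraNormalizer(Normalizer):
    """SVD-compressed reference alignment; training output is the rank-k
    reconstruction X^k, test output the adjusted Z^k."""

    name = "bara"
    uses_references = True

    def __init__(self, loss: float = DEFAULT_LOSS, k: int | None = None):
        self.loss = loss
        self.k = k

    def fit(self, train, ref_train):
        self.model_ = BaraTransformer(loss=self.loss, k=self.k).fit(train)
        self.ref_train_ = list(ref_train)
        return self.model_.reconstruct_train()

    def transform(self, test, ref_test):
        return self.model_.adjust(test, self.ref_train_, ref_test).adjusted_test


class _BatchwiseNormalizer(Normalizer):
    """Applies a batchwise operation with each matrix as its own batch."""

    _op = None

    def fit(self, train, ref_train):
        return self._apply(train, "train")

    def transform(self, test, ref_test):
        return self._apply(test, "test")

    def _apply(self, matrix, label):
        batches = pd.Series(label, index=matrix.index)
        return type(self)._op(matrix, batches)


class MeanCenterNormalizer(_BatchwiseNormalizer):
    name = "mean_center"
    _op = staticmethod(baselines.mean_center)


class RatioNormalizer(_BatchwiseNormalizer):
    name = "ratio"
    _op = staticmethod(baselines.ratio_scale)


class StandardizeNormalizer(_BatchwiseNormalizer):
    name = "standardize"
    _op = staticmethod(baselines.standardize)


class ReferenceCenterNormalizer(Normalizer):
    name = "ref_center"
    uses_references = True

    def fit(self, train, ref_train):
        return train - baselines._reference_mean(train, ref_train)

    def transform(self, test, ref_test):
        return test - baselines._reference_mean(test, ref_test)


class ReferenceRatioNormalizer(Normalizer):
    name = "ref_ratio"
    uses_references = True

    def fit(self, train, ref_train):
        train_out, _ = baselines.reference_ratio(train, train, ref_train, ref_train)
        return train_out

    def transform(self, test, ref_test):
        _, test_out = baselines.reference_ratio(test, test, ref_test, ref_test)
        return test_out


_REGISTRY: dict[str, type | object] = {
    "none": IdentityNormalizer,
    "bara": BaraNormalizer,
    "mean_center": MeanCenterNormalizer,
    "ratio": RatioNormalizer,
    "standardize": StandardizeNormalizer,
    "ref_center": ReferenceCenterNormalizer,
    "ref_ratio": ReferenceRatioNormalizer,
}


def register_normalizer(name: str, factory) -> None:
    """Attach an external normalizer factory under ``name``."""
    _REGISTRY[name] = factory


def available_normalizers() -> list[str]:
    return sorted(_REGISTRY)


def make_normalizer(name: str, loss: float = DEFAULT_LOSS, k: int | None = None) -> Normalizer:
    """Instantiate a normalizer by registry name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown normalizer {name!r}; available: {available_normalizers()}"
        ) from None
    if factory is BaraNormalizer:
        return BaraNormalizer(loss=loss, k=k)
    return factory()
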