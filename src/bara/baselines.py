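"""Simple comparator normalizations: batchwise centering, scaling,
standardization, and the two reference-based variants.

Batches are the operating unit: each method removes (or divides out) a
per-gene location or scale statistic estimated within each batch.  In the
cross-study setting the training set is treated as one batch and each test
set as another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateBatchError, ReferenceLookupError, ValidationError
from .matrix import validate_expression_matrix


def _batch_series(matrix: pd.DataFrame, batches) -> pd.Series:
    if isinstance(batches, pd.Series):
        b = batches
    else:
        b = pd.Series(dict(batches))
    missing = [s for s in matrix.index if s not in b.index]
    if missing:
        raise ValidationError(f"samples without batch assignment: {missing}")
    return b.loc[matrix.index]


def mean_center(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Subtract each gene's batch mean within every batch."""
    matrix = validate_expression_matrix(matrix)
    b = _batch_series(matrix, batches)
    return matrix - matrix.groupby(b).transform("mean")


def ratio_scale(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Divide each gene by its batch arithmetic mean within every batch."""
    matrix = validate_expression_matrix(matrix)
    b = _batch_series(matrix, batches)
    means = matrix.groupby(b).transform("mean")
    zero = means == 0
    if zero.to_numpy().any():
        loc = np.argwhere(zero.to_numpy())[0]
        raise DegenerateBatchError(
            f"zero batch mean for gene {matrix.columns[loc[1]]!r} "
            f"in batch {b.iloc[loc[0]]!r}"
        )
    return matrix / means


def standardize(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Per batch and gene: subtract the mean, divide by the sample standard
    deviation (n-1 denominator).  Every batch needs >= 2 samples."""
    matrix = validate_expression_matrix(matrix)
    b = _batch_series(matrix, batches)
    sizes = b.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValidationError(f"standardization needs >= 2 samples per batch; got {dict(small)}")
    means = matrix.groupby(b).transform("mean")
    sds = matrix.groupby(b).transform("std")  # ddof=1
    zero = sds == 0
    if zero.to_numpy().any():
        loc = np.argwhere(zero.to_numpy())[0]
        raise DegenerateBatchError(
            f"zero within-batch variance for gene {matrix.columns[loc[1]]!r} "
            f"in batch {b.iloc[loc[0]]!r}"
        )
    return (matrix - means) / sds


def _reference_mean(matrix: pd.DataFrame, refs) -> pd.Series:
    refs = list(refs)
    if not refs:
        raise ValidationError("reference list must be non-empty")
    missing = [r for r in refs if r not in matrix.index]
    if missing:
        raise ReferenceLookupError(f"reference ids not found: {missing}")
    return matrix.loc[refs].mean(axis=0)


def reference_center(train, test, ref_train, ref_test):
    """Subtract each matrix's own reference-sample gene means from all of
    its samples; returns the (train, test) pair."""
    train = validate_expression_matrix(train)
    test = validate_expression_matrix(test)
    return train - _reference_mean(train, ref_train), test - _reference_mean(test, ref_test)


def reference_ratio(train, test, ref_train, ref_test):
    """Divide each matrix gene-wise by its own reference-sample means."""
    train = validate_expression_matrix(train)
    test = validate_expression_matrix(test)
    out = []
    for mat, refs in ((train, ref_train), (test, ref_test)):
        mean = _reference_mean(mat, refs)
        zero = mean[mean == 0]
        if not zero.empty:
            raise DegenerateBatchError(f"zero reference mean for genes {list(zero.index)[:5]}")
        out.append(mat / mean)
    return tuple(out)
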