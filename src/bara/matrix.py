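"""Expression-matrix and sample-annotation containers.

The universal carrier is a :class:`pandas.DataFrame` with samples in rows and
genes in columns; row index = sample ids, column index = gene ids.  The
helpers here validate the invariants every operation relies on: unique
labels, a numeric body, and finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

REQUIRED_ANNOTATION_COLUMNS = ("group",)
DEFAULT_BATCH = "batch0"


def as_expression_matrix(data, sample_ids=None, gene_ids=None) -> pd.DataFrame:
    """Coerce array-like input to a validated samples x genes DataFrame.

    Plain arrays get generated labels (``s0, s1, ...`` / ``g0, g1, ...``).
    """
    if isinstance(data, pd.DataFrame):
        df = data.copy()
        if sample_ids is not None:
            df.index = pd.Index(sample_ids)
        if gene_ids is not None:
            df.columns = pd.Index(gene_ids)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(f"expression matrix must be 2-dimensional, got shape {arr.shape}")
        m, n = arr.shape
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(m)]
        if gene_ids is None:
            gene_ids = [f"g{j}" for j in range(n)]
        df = pd.DataFrame(arr, index=pd.Index(sample_ids), columns=pd.Index(gene_ids))
    return validate_expression_matrix(df)


def validate_expression_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check label uniqueness and numeric, finite values; return float frame."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric values in expression matrix: {exc}") from exc
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            "non-finite value at sample "
            f"{df.index[bad[0]]!r}, gene {df.columns[bad[1]]!r}"
        )
    return df.astype(float)


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table (index = sample id).

    Required column: ``group``.  Optional columns ``batch`` and
    ``is_reference`` are filled with defaults (a single batch; no references).
    Extra columns are preserved untouched.
    """
    ann = annotations.copy()
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in annotations: {dup}")
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValidationError(f"annotations missing required column {col!r}")
    if "batch" not in ann.columns:
        ann["batch"] = DEFAULT_BATCH
    if "is_reference" in ann.columns:
        ann["is_reference"] = ann["is_reference"].astype(bool)
    else:
        ann["is_reference"] = False
    return ann


@dataclass
class Dataset:
    """An expression matrix joined with its per-sample annotations."""

    name: str
    matrix: pd.DataFrame
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.matrix = validate_expression_matrix(self.matrix)
        self.annotations = validate_annotations(self.annotations)
        mat_ids = set(self.matrix.index)
        ann_ids = set(self.annotations.index)
        if mat_ids != ann_ids:
            missing = sorted(mat_ids - ann_ids)
            extra = sorted(ann_ids - mat_ids)
            raise ValidationError(
                f"dataset {self.name!r}: annotation/matrix mismatch; "
                f"unannotated samples: {missing}; annotation-only samples: {extra}"
            )
        # keep annotation rows in matrix order
        self.annotations = self.annotations.loc[self.matrix.index]

    @property
    def sample_ids(self) -> list:
        return list(self.matrix.index)

    @property
    def gene_ids(self) -> list:
        return list(self.matrix.columns)

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    def samples_in_group(self, group) -> list:
        return sorted(self.annotations.index[self.annotations["group"] == group])
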