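"""Readers and writers: TSV expression matrices and annotations, the
serialized model container, and evaluation configs.

Canonical on-disk matrix layout: tab-separated text, first row gene ids,
first column sample ids, samples in rows.  The transposed (genes-in-rows)
dialect common for distributed expression tables is accepted via a flag and
transposed on read.  Models are stored as versioned JSON; floats survive the
round trip exactly (shortest-repr encoding).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BaraTransformer
from .errors import ParameterError, ValidationError
from .evaluation import EvaluationConfig
from .matrix import Dataset, validate_annotations, validate_expression_matrix

MODEL_FORMAT_VERSION = 1


def read_matrix(path, genes_in_rows: bool = False) -> pd.DataFrame:
    """Read a labelled expression matrix from TSV (samples in rows unless
    ``genes_in_rows``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table: {exc}") from exc
    if genes_in_rows:
        df = df.T
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    for axis_name, labels in (("sample", df.index), ("gene", df.columns)):
        if labels.has_duplicates:
            dup = labels[labels.duplicated()].unique().tolist()
            raise ValidationError(f"{path}: duplicate {axis_name} ids: {dup}")
    non_numeric = df.columns[[df[c].dtype == object for c in df.columns]].tolist()
    if non_numeric:
        raise ValidationError(f"{path}: non-numeric values in columns {non_numeric[:5]}")
    return validate_expression_matrix(df)


def write_matrix(matrix: pd.DataFrame, path, genes_in_rows: bool = False) -> None:
    out = matrix.T if genes_in_rows else matrix
    out.to_csv(path, sep="\t", index_label="sample_id" if not genes_in_rows else "gene_id")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample-annotation TSV (columns: sample_id, group[, batch,
    is_reference, ...])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    if "group" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'group'")
    df = df.set_index("sample_id")
    if "is_reference" in df.columns:
        df["is_reference"] = (
            df["is_reference"].str.lower().map({"true": True, "1": True, "false": False, "0": False})
        )
        if df["is_reference"].isna().any():
            raise ValidationError(f"{path}: is_reference must be boolean (true/false/1/0)")
    return validate_annotations(df)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id")


def read_dataset(matrix_path, annotations_path, name: str | None = None, genes_in_rows=False) -> Dataset:
    matrix = read_matrix(matrix_path, genes_in_rows=genes_in_rows)
    annotations = read_annotations(annotations_path)
    return Dataset(name=name or Path(matrix_path).stem, matrix=matrix, annotations=annotations)


def save_model(model: BaraTransformer, path) -> None:
    """Serialize a fitted model to versioned JSON (lossless float round-trip)."""
    if not hasattr(model, "basis_"):
        raise ValidationError("cannot save an unfitted model")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "loss": model.loss,
        "k": model.k_,
        "variance_retained": model.variance_retained_,
        "gene_ids": [str(g) for g in model.train_gene_ids_],
        "sample_ids": [str(s) for s in model.train_sample_ids_],
        "gene_means": model.gene_means_.to_numpy().tolist(),
        "singular_values": model.singular_values_.tolist(),
        "basis": model.basis_.tolist(),
        "compressed_train": model.compressed_train_.to_numpy().tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> BaraTransformer:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {version!r} (expected {MODEL_FORMAT_VERSION})"
        )
    model = BaraTransformer(loss=payload["loss"], k=None)
    model.k_ = int(payload["k"])
    model.variance_retained_ = float(payload["variance_retained"])
    model.train_gene_ids_ = list(payload["gene_ids"])
    model.train_sample_ids_ = list(payload["sample_ids"])
    model.gene_means_ = pd.Series(payload["gene_means"], index=model.train_gene_ids_, dtype=float)
    model.singular_values_ = np.asarray(payload["singular_values"], dtype=float)
    model.basis_ = np.asarray(payload["basis"], dtype=float)
    model.compressed_train_ = pd.DataFrame(
        np.asarray(payload["compressed_train"], dtype=float), index=model.train_sample_ids_
    )
    return model


def load_config(path) -> EvaluationConfig:
    """Read an EvaluationConfig from a YAML mapping; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(EvaluationConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ParameterError(f"{path}: unknown config keys {unknown}")
    return EvaluationConfig(**data)


def write_results(result, out_dir, prefix: str = "cross_study") -> None:
    """Write the tidy long table and the per-train/overall summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.raw.to_csv(out_dir / f"{prefix}_raw.tsv", sep="\t", index=False)
    per_train = result.per_train
    summary = per_train.rename("mean_mcc").to_frame()
    summary.to_csv(out_dir / f"{prefix}_summary.tsv", sep="\t", index_label="train_id")
    overall = pd.DataFrame(
        [{"overall_mean_mcc": result.overall, "sd": float(per_train.std(ddof=1)) if len(per_train) > 1 else 0.0}]
    )
    overall.to_csv(out_dir / f"{prefix}_overall.tsv", sep="\t", index=False)
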