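"""Cross-study prediction protocol.

Each dataset in a collection is used in turn as the fixed training set:
reference samples are drawn once from a designated biological group, the
most differentially expressed genes are selected, the training set is
normalized, and a classifier is tuned by repeated stratified
cross-validation maximizing the Matthews correlation coefficient (MCC).
Every other dataset then plays external test set: over several iterations,
test-side reference samples are redrawn, the test set is normalized, the
references are removed, and the remaining samples are classified.  The
per-pair score is the median MCC over iterations; per-train scores average
over test sets, and the overall score averages over training sets.

All randomness descends from a single seed: per-(train, test, iteration)
streams are derived from (seed, train id, test id, iteration), so any pair
is reproducible in isolation and results are independent of execution order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .classifiers import default_grid, make_classifier
from .core import DEFAULT_LOSS
from .errors import BaraError, GeneSpaceError, ParameterError, ValidationError
from .matrix import Dataset
from .normalizers import Normalizer, make_normalizer

logger = logging.getLogger("bara")

_SEED_MASK = 2**31 - 1


def _label_entropy(label: str) -> int:
    return zlib.crc32(str(label).encode("utf-8"))


def derive_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic child RNG for a (seed, labels...) coordinate."""
    entropy = [int(seed) & _SEED_MASK] + [
        _label_entropy(l) if isinstance(l, str) else int(l) for l in labels
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def mcc(labels_true, labels_pred) -> float:
    """Matthews correlation coefficient for binary labels.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0 when
    any factor of the denominator vanishes (degenerate confusion table).
    """
    y_true = np.asarray(labels_true)
    y_pred = np.asarray(labels_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValidationError("label vectors must be equal-length, non-empty, 1-D")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if classes.size > 2:
        raise ValidationError(f"more than two classes: {classes.tolist()}")
    pos = classes[-1]
    t = y_true == pos
    p = y_pred == pos
    tp = float(np.sum(t & p))
    tn = float(np.sum(~t & ~p))
    fp = float(np.sum(~t & p))
    fn = float(np.sum(t & ~p))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def rank_genes(train: pd.DataFrame, groups, n_top: int | None = None) -> list:
    """Genes ordered by decreasing |pooled-variance two-sample t statistic|.

    Ties (including zero-variance genes, whose statistic is taken as 0) are
    broken by gene id, so the ranking is fully deterministic.
    """
    groups = pd.Series(np.asarray(groups), index=train.index) if not isinstance(groups, pd.Series) else groups.loc[train.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"gene ranking needs exactly two groups, got {labels}")
    a = train.loc[groups == labels[0]].to_numpy()
    b = train.loc[groups == labels[1]].to_numpy()
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs >= 2 samples for the t statistic")
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / se
    t = np.where(np.isfinite(t), t, 0.0)
    order = sorted(range(train.shape[1]), key=lambda j: (-abs(t[j]), str(train.columns[j])))
    if n_top is None:
        n_top = train.shape[1]
    if n_top > train.shape[1]:
        raise ParameterError(f"n_top={n_top} exceeds the {train.shape[1]} available genes")
    return [train.columns[j] for j in order[:n_top]]


def tune_classifier(
    train: pd.DataFrame,
    groups,
    classifier: str = "knn",
    grid: list[dict] | None = None,
    cv_repeats: int = 3,
    cv_folds: int = 10,
    rng_seed: int = 0,
):
    """Pick the grid point maximizing mean cross-validated MCC.

    Folds are stratified by class and fully determined by ``rng_seed``.  If
    the minority class is smaller than ``cv_folds`` the fold count is reduced
    to the minority size (warning logged).  Ties go to the earliest grid
    entry, i.e. the simplest parameter value.

    Returns ``(best_params, best_score, table)`` where ``table`` lists the
    mean MCC per grid point.
    """
    y = np.asarray(groups)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("tuning needs two classes in the training labels")
    if grid is None:
        grid = default_grid(classifier)
    if not grid:
        raise ParameterError("empty tuning grid")
    n_folds = int(min(cv_folds, counts.min()))
    if n_folds < 2:
        raise ValidationError("minority class too small for cross-validation")
    if n_folds < cv_folds:
        logger.warning("reducing cv folds from %d to %d (minority class size)", cv_folds, n_folds)

    X = train.to_numpy()
    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=cv_repeats, random_state=int(rng_seed) & _SEED_MASK
    )
    splits = list(cv.split(X, y))
    table = []
    for params in grid:
        scores = []
        for train_idx, test_idx in splits:
            clf = make_classifier(classifier, params, random_state=int(rng_seed) & _SEED_MASK)
            clf.fit(X[train_idx], y[train_idx])
            scores.append(mcc(y[test_idx], clf.predict(X[test_idx])))
        table.append({**params, "mean_mcc": float(np.mean(scores))})
    best_idx = int(np.argmax([row["mean_mcc"] for row in table]))
    best = dict(grid[best_idx])
    return best, table[best_idx]["mean_mcc"], table


@dataclass
class EvaluationConfig:
    """Settings of the cross-study protocol (defaults = standard settings:
    500 genes, 3 references, 10 iterations, 3x10 repeated CV, loss 10%)."""

    n_top_genes: int = 500
    n_references: int = 3
    n_iterations: int = 10
    cv_repeats: int = 3
    cv_folds: int = 10
    loss: float = DEFAULT_LOSS
    classifier: str = "knn"
    classifier_grid: list | None = None
    normalizer: str = "bara"
    reference_group: str | None = None
    rng_seed: int = 0
    # test-side reference count; None -> same as n_references.  The
    # reference-count sweep varies this while the training-side references
    # stay part of the fixed trained pipeline.
    n_test_references: int | None = None

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        for name in ("n_top_genes", "n_references", "n_iterations", "cv_repeats"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0 <= self.loss < 1:
            raise ParameterError("loss must be in [0, 1)")
        if self.classifier_grid is not None and not self.classifier_grid:
            raise ParameterError("classifier_grid must be non-empty when given")
        if self.n_test_references is not None and self.n_test_references < 1:
            raise ParameterError("n_test_references must be >= 1")


@dataclass
class TrainedPipeline:
    """Artifacts built from a training set only: drawn references, selected
    genes, fitted normalizer and tuned, fitted classifier."""

    train_id: str
    reference_group: str
    ref_train: list
    gene_list: list
    normalizer: Normalizer
    classifier: object
    best_params: dict
    cv_score: float
    config: EvaluationConfig


@dataclass
class PairResult:
    train_id: str
    test_id: str
    mccs: np.ndarray
    reference_draws: list = field(repr=False, default_factory=list)
    predicted_ids: list = field(repr=False, default_factory=list)

    @property
    def median_mcc(self) -> float:
        return float(np.median(self.mccs))


def _draw_references(candidates: list, n: int, rng: np.random.Generator, where: str) -> list:
    if len(candidates) < n:
        raise ParameterError(
            f"reference group has {len(candidates)} samples in the {where} set; "
            f"{n} references requested"
        )
    picked = rng.choice(np.asarray(candidates, dtype=object), size=n, replace=False)
    return sorted(picked.tolist())


def build_training_artifacts(train: Dataset, config: EvaluationConfig) -> TrainedPipeline:
    """Draw training references, rank genes, normalize and tune — using the
    training set only."""
    groups = train.groups
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"dataset {train.name!r} must contain exactly two groups, got {labels}")
    ref_group = config.reference_group if config.reference_group is not None else labels[0]
    if ref_group not in labels:
        raise ParameterError(f"reference group {ref_group!r} absent from dataset {train.name!r}")

    rng = derive_rng(config.rng_seed, train.name, "train-references")
    ref_train = _draw_references(
        train.samples_in_group(ref_group), config.n_references, rng, "training"
    )

    gene_list = rank_genes(train.matrix, groups, config.n_top_genes)
    sub = train.matrix[gene_list]
    normalizer = make_normalizer(config.normalizer, loss=config.loss)
    train_norm = normalizer.fit(sub, ref_train)

    tune_seed = int(derive_rng(config.rng_seed, train.name, "tuning").integers(_SEED_MASK))
    best_params, cv_score, _ = tune_classifier(
        train_norm,
        groups,
        classifier=config.classifier,
        grid=config.classifier_grid,
        cv_repeats=config.cv_repeats,
        cv_folds=config.cv_folds,
        rng_seed=tune_seed,
    )
    clf = make_classifier(config.classifier, best_params, random_state=tune_seed)
    clf.fit(train_norm.to_numpy(), groups.to_numpy())
    logger.info(
        "train=%s refs=%s params=%s cv_mcc=%.3f%s",
        train.name,
        ref_train,
        best_params,
        cv_score,
        (
            f" k={normalizer.model_.k_} var_retained={normalizer.model_.variance_retained_:.3f}"
            if hasattr(normalizer, "model_")
            else ""
        ),
    )
    return TrainedPipeline(
        train_id=train.name,
        reference_group=ref_group,
        ref_train=ref_train,
        gene_list=gene_list,
        normalizer=normalizer,
        classifier=clf,
        best_params=best_params,
        cv_score=cv_score,
        config=config,
    )


def evaluate_pair(trained, test: Dataset, config: EvaluationConfig | None = None) -> PairResult:
    """Score one (train, test) pair over reference-resampling iterations.

    ``trained`` is a :class:`TrainedPipeline` or a :class:`Dataset` (built on
    the fly).  Per iteration: draw ``n_references`` test samples from the
    reference group, normalize the test set, drop the references, predict,
    and record the MCC on the remaining samples.
    """
    if isinstance(trained, Dataset):
        if config is None:
            raise ParameterError("config required when passing a raw training dataset")
        trained = build_training_artifacts(trained, config)
    config = trained.config

    missing = [g for g in trained.gene_list if g not in test.matrix.columns]
    if missing:
        raise GeneSpaceError(
            f"test set {test.name!r} lacks {len(missing)} selected genes, e.g. {missing[:5]}"
        )
    test_sub = test.matrix[trained.gene_list]
    candidates = test.samples_in_group(trained.reference_group)

    n_test_refs = (
        config.n_test_references if config.n_test_references is not None else config.n_references
    )
    mccs = []
    draws = []
    predicted = []
    for it in range(config.n_iterations):
        rng = derive_rng(config.rng_seed, trained.train_id, test.name, it)
        ref_test = _draw_references(candidates, n_test_refs, rng, "test")
        normalized = trained.normalizer.transform(test_sub, ref_test)
        predict_ids = [s for s in normalized.index if s not in set(ref_test)]
        overlap = set(predict_ids) & set(ref_test)
        if overlap:  # protocol guarantee: references are never predicted
            raise AssertionError(f"reference samples among predicted samples: {sorted(overlap)}")
        y_true = test.groups.loc[predict_ids].to_numpy()
        y_pred = trained.classifier.predict(normalized.loc[predict_ids].to_numpy())
        mccs.append(mcc(y_true, y_pred))
        draws.append(ref_test)
        predicted.append(predict_ids)
    result = PairResult(
        train_id=trained.train_id,
        test_id=test.name,
        mccs=np.asarray(mccs),
        reference_draws=draws,
        predicted_ids=predicted,
    )
    logger.info(
        "pair train=%s test=%s median_mcc=%.3f", trained.train_id, test.name, result.median_mcc
    )
    return result


@dataclass
class CrossStudyResult:
    """Raw per-iteration MCCs plus their aggregations.

    ``raw`` is a tidy long table (train_id, test_id, iteration, mcc); all
    aggregate fields are recomputable from it.
    """

    raw: pd.DataFrame
    chosen_params: dict
    gene_lists: dict = field(repr=False)
    failures: list = field(default_factory=list)

    @property
    def pair_medians(self) -> pd.Series:
        return self.raw.groupby(["train_id", "test_id"])["mcc"].median()

    @property
    def per_train(self) -> pd.Series:
        return self.pair_medians.groupby("train_id").mean()

    @property
    def overall(self) -> float:
        return float(self.per_train.mean())


def cross_study(datasets: list[Dataset], config: EvaluationConfig) -> CrossStudyResult:
    """Full leave-one-dataset-as-training protocol over a collection."""
    if len(datasets) < 2:
        raise ParameterError("cross-study evaluation needs at least 2 datasets")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate dataset names: {names}")

    rows = []
    chosen_params = {}
    gene_lists = {}
    failures = []
    for train in datasets:
        try:
            trained = build_training_artifacts(train, config)
        except BaraError as exc:
            failures.append({"train_id": train.name, "test_id": None, "error": str(exc)})
            continue
        chosen_params[train.name] = trained.best_params
        gene_lists[train.name] = trained.gene_list
        for test in datasets:
            if test.name == train.name:
                continue
            try:
                pair = evaluate_pair(trained, test)
            except BaraError as exc:
                failures.append(
                    {"train_id": train.name, "test_id": test.name, "error": str(exc)}
                )
                continue
            for it, value in enumerate(pair.mccs):
                rows.append(
                    {
                        "train_id": train.name,
                        "test_id": test.name,
                        "iteration": it,
                        "mcc": float(value),
                    }
                )
    raw = pd.DataFrame(rows, columns=["train_id", "test_id", "iteration", "mcc"])
    return CrossStudyResult(
        raw=raw, chosen_params=chosen_params, gene_lists=gene_lists, failures=failures
    )


def reference_sweep(
    datasets: list[Dataset], config: EvaluationConfig, n_ref_values: list[int]
) -> "SweepResult":
    """Repeat the cross-study protocol for each test-side reference count.

    The trained pipelines — including the training-side references, drawn
    once per training set — are part of the fixed protocol, so the sweep
    varies only the number of references drawn from each test set.
    Summarizes each run by the mean and standard deviation of the per-train
    MCCs (the points and bars of a reference-count robustness plot).
    """
    if not n_ref_values:
        raise ParameterError("n_ref_values must be non-empty")
    runs = {}
    rows = []
    for n in n_ref_values:
        res = cross_study(datasets, replace(config, n_test_references=int(n)))
        runs[int(n)] = res
        per_train = res.per_train
        rows.append(
            {
                "n_references": int(n),
                "mean_mcc": float(per_train.mean()),
                "sd_mcc": float(per_train.std(ddof=1)) if len(per_train) > 1 else 0.0,
            }
        )
    return SweepResult(summary=pd.DataFrame(rows), runs=runs)


@dataclass
class SweepResult:
    summary: pd.DataFrame
    runs: dict = field(repr=False)
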