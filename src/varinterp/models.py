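"""Per-reference-amino-acid subset classifiers and their evaluation.

Variants are split into 18 subsets by reference amino acid (tryptophan,
tyrosine and phenylalanine merged into one ``WYF`` subset because they are
individually too small to train on).  Each subset gets its own
maximum-margin classifier — linear kernel, C=0.1, by default — with Platt
probability outputs so that predictions from different subset classifiers
live on a common scale and can be pooled into one ROC curve (the C_S
protocol).  A single classifier trained on all variants (C_E) is the
comparison; its score is the mean AUC over the ten CV folds.

The linear models are trained with scikit-learn's libsvm binding; weight
interpretation lives in :mod:`varinterp.interpret`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    FeatureMatrix,
    Resources,
    Scaler,
    apply_scaler,
    assemble,
    drop_constant_columns,
    standardize,
)
from .genetic_code import AMINO_ACIDS, standard_reachability
from .io import VariantRecord

MERGED_KEY = "WYF"
SUBSET_KEYS: tuple[str, ...] = tuple(
    sorted(set(AMINO_ACIDS) - set(MERGED_KEY))
) + (MERGED_KEY,)
"""The 18 subset keys: 17 single reference amino acids plus the WYF merge."""


def subset_of(ref_aa: str) -> str:
    """The subset key a reference amino acid belongs to."""
    if ref_aa not in AMINO_ACIDS:
        raise ValueError(f"not a standard amino acid: {ref_aa!r}")
    return MERGED_KEY if ref_aa in MERGED_KEY else ref_aa


@dataclass(frozen=True)
class TrainingConfig:
    kernel: str = "linear"
    C: float = 0.1
    gamma: float = 0.01  # rbf only
    n_folds: int = 10
    seed: int = 0
    probability: bool = True
    class_weight: str | None = None  # "balanced" enables inverse-frequency weights
    min_size: int = 500

    def with_seed(self, seed: int) -> "TrainingConfig":
        return replace(self, seed=seed)

    @classmethod
    def rbf(cls, **kw) -> "TrainingConfig":
        kw.setdefault("C", 1.0)
        return cls(kernel="rbf", **kw)


def split_subsets(
    variants: list[VariantRecord],
    min_size: int = 500,
    merge_all: bool = False,
) -> dict[str, list[VariantRecord]]:
    """Group labeled variants by reference amino acid, merging W/Y/F.

    ``merge_all`` collapses everything into a single ``ALL`` subset (the
    C_E protocol).  Subsets smaller than ``min_size`` draw a warning; ones
    missing a class entirely are flagged untrainable (warned and kept, so
    the caller decides).
    """
    if merge_all:
        return {"ALL": list(variants)}
    groups: dict[str, list[VariantRecord]] = {}
    for v in variants:
        groups.setdefault(subset_of(v.ref_aa), []).append(v)
    for key, members in groups.items():
        labels = {v.label for v in members}
        if len(labels) < 2:
            warnings.warn(f"subset {key}: only one class present; untrainable")
        elif len(members) < min_size:
            warnings.warn(f"subset {key}: only {len(members)} variants (< {min_size})")
    return {k: groups[k] for k in SUBSET_KEYS if k in groups}


@dataclass
class SubsetModel:
    """A trained classifier for one reference-amino-acid subset.

    ``svc`` is the maximum-margin classifier fitted on the full
    (standardized) subset; when probability output was requested,
    ``calibrated`` wraps it with a Platt sigmoid fitted on 5-fold
    cross-validated decision values, so P(disease) = expit(-(a f + b))
    with f the decision value.
    """

    key: str
    svc: SVC
    calibrated: CalibratedClassifierCV | None
    retained_features: list[tuple[str, str]]
    dropped_features: list[tuple[str, str]]
    scaler: Scaler
    n_training: int

    @property
    def kernel(self) -> str:
        return self.svc.kernel

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    @property
    def support_coefficients(self) -> np.ndarray:
        """alpha_i * y_i for the support vectors (libsvm dual coefficients)."""
        return self.svc.dual_coef_[0]

    @property
    def calibration(self) -> tuple[float, float]:
        """Platt sigmoid parameters (a, b)."""
        if self.calibrated is None:
            raise ValueError(f"subset {self.key}: trained without calibration")
        cal = self.calibrated.calibrated_classifiers_[0].calibrators[0]
        return float(cal.a_), float(cal.b_)

    def prepare(self, M: FeatureMatrix) -> FeatureMatrix:
        """Align a raw feature matrix to the training columns and scaling."""
        aligned = FeatureMatrix(M.df.loc[:, self.retained_features])
        return apply_scaler(aligned, self.scaler)

    def decision_values(self, M: FeatureMatrix, prepared: bool = False) -> np.ndarray:
        X = (M if prepared else self.prepare(M)).values
        return self.svc.decision_function(X)

    def predict_proba(self, M: FeatureMatrix, prepared: bool = False) -> np.ndarray:
        """Calibrated P(disease) per row of ``M``."""
        a, b = self.calibration
        return expit(-(a * self.decision_values(M, prepared) + b))

    def score(self, M: FeatureMatrix) -> np.ndarray:
        """Calibrated probability when available, else the raw decision
        value (a monotone surrogate: identical ranking, hence identical
        AUC, but not poolable across different subset classifiers)."""
        if self.calibrated is not None:
            return self.predict_proba(M)
        return self.decision_values(M)


def train_subset(
    M: FeatureMatrix, labels: np.ndarray, cfg: TrainingConfig, key: str = "ALL"
) -> SubsetModel:
    """Drop constant columns, standardize, and fit one subset classifier.

    ``labels`` are {0 neutral, 1 disease}; the libsvm solver maps them to
    the internal {-1, +1} convention, so positive decision values (and
    positive weights, for the linear kernel) point at disease.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"subset {key}: single-class input")
    if counts.min() < 2:
        raise ValueError(f"subset {key}: fewer than 2 variants in a class")
    reduced, dropped = drop_constant_columns(M)
    scaled, scaler = standardize(reduced)
    svc = SVC(
        kernel=cfg.kernel,
        C=cfg.C,
        gamma=cfg.gamma if cfg.kernel == "rbf" else "scale",
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
    )
    calibrated = None
    if cfg.probability:
        calibrated = CalibratedClassifierCV(
            svc, method="sigmoid", cv=min(5, int(counts.min())), ensemble=False
        )
        calibrated.fit(scaled.values, labels)
        svc = calibrated.calibrated_classifiers_[0].estimator
    else:
        svc.fit(scaled.values, labels)
    return SubsetModel(
        key=key,
        svc=svc,
        calibrated=calibrated,
        retained_features=list(reduced.df.columns),
        dropped_features=dropped,
        scaler=scaler,
        n_training=len(labels),
    )


def train_all_subsets(
    subset_data: dict[str, tuple[FeatureMatrix, np.ndarray]], cfg: TrainingConfig
) -> dict[str, SubsetModel]:
    """Train one model per subset on its full data (used for weight
    extraction after cross-validation).  Untrainable subsets (a class
    missing or nearly empty) are skipped with a warning."""
    models = {}
    for i, (key, (M, labels)) in enumerate(sorted(subset_data.items())):
        try:
            models[key] = train_subset(M, labels, cfg.with_seed(cfg.seed + i), key=key)
        except ValueError as exc:
            warnings.warn(f"skipping subset {key}: {exc}")
    return models


@dataclass
class EvaluationResult:
    """Cross-validation outcome: per-subset and pooled scores."""

    per_subset_auc: dict[str, float]
    per_fold_auc: dict[str, list[float]]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fold_assignments: dict[str, np.ndarray]
    untrainable: list[str] = field(default_factory=list)

    @property
    def pooled_auc(self) -> float:
        return float(roc_auc_score(self.pooled_labels, self.pooled_scores))

    @property
    def mean_fold_auc(self) -> float:
        """Mean per-fold AUC over all subsets' folds (the C_E score when
        evaluated on a single ALL subset)."""
        folds = [a for aucs in self.per_fold_auc.values() for a in aucs]
        return float(np.mean(folds))

    def roc_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pooled ROC curve (fpr, tpr, thresholds), decreasing thresholds."""
        return roc_curve(self.pooled_labels, self.pooled_scores)


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    if len(np.unique(labels)) < 2:
        raise ValueError("cannot stratify: single class")
    n_min = int(np.bincount(labels).min())
    if n_min < 3:
        # with fewer, some training fold would see < 2 minority examples
        raise ValueError("cannot stratify: minority class has fewer than 3 members")
    n_folds = min(n_folds, n_min)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_validate(
    subset_data: dict[str, tuple[FeatureMatrix, np.ndarray]],
    cfg: TrainingConfig,
) -> EvaluationResult:
    """Stratified k-fold CV per subset; out-of-fold probabilities pooled.

    Constant-column removal and feature scaling are re-fitted inside every
    training fold and applied verbatim to its test fold, so no test
    information leaks into scaling.  Subsets that cannot be stratified
    (a class with < 2 members) are recorded as untrainable and excluded
    from pooling.
    """
    per_subset_auc: dict[str, float] = {}
    per_fold_auc: dict[str, list[float]] = {}
    fold_assignments: dict[str, np.ndarray] = {}
    untrainable: list[str] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for i, (key, (M, labels)) in enumerate(sorted(subset_data.items())):
        labels = np.asarray(labels)
        subset_seed = cfg.seed + 1000 * (i + 1)
        try:
            folds = _stratified_folds(labels, cfg.n_folds, subset_seed)
        except ValueError:
            untrainable.append(key)
            continue
        scores = np.full(len(labels), np.nan)
        assignment = np.full(len(labels), -1)
        fold_aucs: list[float] = []
        for f, (train_idx, test_idx) in enumerate(folds):
            model = train_subset(
                FeatureMatrix(M.df.iloc[train_idx]),
                labels[train_idx],
                cfg.with_seed(subset_seed + f),
                key=key,
            )
            scores[test_idx] = model.score(FeatureMatrix(M.df.iloc[test_idx]))
            assignment[test_idx] = f
            if len(np.unique(labels[test_idx])) == 2:
                fold_aucs.append(float(roc_auc_score(labels[test_idx], scores[test_idx])))
        per_subset_auc[key] = float(roc_auc_score(labels, scores))
        per_fold_auc[key] = fold_aucs
        fold_assignments[key] = assignment
        pooled_scores.append(scores)
        pooled_labels.append(labels)

    if not pooled_scores:
        raise ValueError("no trainable subset")
    return EvaluationResult(
        per_subset_auc=per_subset_auc,
        per_fold_auc=per_fold_auc,
        pooled_scores=np.concatenate(pooled_scores),
        pooled_labels=np.concatenate(pooled_labels),
        fold_assignments=fold_assignments,
        untrainable=untrainable,
    )


def build_subset_data(
    variants: list[VariantRecord],
    resources: Resources,
    categories: tuple[str, ...] | None = None,
    min_size: int = 500,
    merge_all: bool = False,
) -> tuple[dict[str, tuple[FeatureMatrix, np.ndarray]], list[str]]:
    """Featurize variants and group by subset; returns data and exclusions."""
    from .features import CATEGORIES

    categories = categories or CATEGORIES
    subsets = split_subsets(variants, min_size=min_size, merge_all=merge_all)
    data = {}
    all_excluded: list[str] = []
    for key, members in subsets.items():
        M, excluded = assemble(members, resources, categories)
        all_excluded.extend(excluded)
        kept_ids = set(M.df.index)
        labels = np.array([v.label for v in members if v.variant_id in kept_ids])
        if len(labels):
            data[key] = (M, labels)
    return data, all_excluded


def predict(
    v: VariantRecord,
    models: dict[str, SubsetModel],
    resources: Resources,
) -> float:
    """Probability that variant ``v`` is disease-associated.

    The variant is routed to the subset model of its reference amino acid;
    features are built with that model's retained columns and scaler.
    """
    key = subset_of(v.ref_aa)
    if key not in models:
        raise KeyError(f"no trained model for subset {key}")
    if not standard_reachability()[v.ref_aa, v.mut_aa]:
        warnings.warn(
            f"{v.variant_id}: substitution needs more than one codon mutation; "
            "the model was not trained on such variants"
        )
    model = models[key]
    categories = tuple(dict.fromkeys(c for c, _ in model.retained_features + model.dropped_features))
    M, excluded = assemble([v], resources, categories)
    if excluded:
        raise ValueError(excluded[0])
    return float(model.predict_proba(M)[0])
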