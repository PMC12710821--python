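"""Cross-validated hemisphere/handedness classification and MCC scoring.

Experiments are organised around subject-level, handedness-stratified
folds (default 5): both hemisphere samples of a subject always share a
fold, so no subject contributes to both the training and test side of any
split.  Three classifier families are supported — linear discriminant
analysis (LDA), linear-kernel support vector classification (SVC) and a
single-hidden-layer neural net (NN) — with per-feature standardization
fitted on the training folds for SVC/NN and raw features for LDA (keeping
its scalings interpretable).

Performance is summarised by the Matthews correlation coefficient (MCC),
which lies on [-1, 1] and equals 0 whenever any class is assigned at
chance (in particular for the all-majority classifier on an imbalanced
sample, where raw accuracy would equal the majority fraction).  Point
estimates and 95% confidence intervals come from jointly resampling
(truth, prediction) pairs with replacement, 1,000 replicates, taking the
distribution mean and its 2.5th/97.5th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FoldPlan",
    "ClassificationRun",
    "MODEL_KINDS",
    "make_folds",
    "build_model",
    "train_and_predict",
    "fit_oriented_lda",
    "confusion",
    "mcc",
    "accuracy",
    "per_class_accuracy",
    "bootstrap_mcc_ci",
    "mcc_accuracy_calibration",
    "oversample_minority",
    "subsample_training",
    "fourway_label",
    "decompose_fourway",
    "compare_mcc_paired",
    "cross_validated_run",
]

MODEL_KINDS = ("LDA", "SVC", "NN")

_FOURWAY = {
    ("LH", "dextral"): "rightyLH",
    ("RH", "dextral"): "rightyRH",
    ("LH", "sinistral"): "leftyLH",
    ("RH", "sinistral"): "leftyRH",
}
_FOURWAY_INV = {v: k for k, v in _FOURWAY.items()}


@dataclass(frozen=True)
class FoldPlan:
    """Subject -> fold assignment, stratified on handedness."""

    n_folds: int
    assignment: Mapping[str, int]

    def test_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]


@dataclass
class ClassificationRun:
    """Results of one cross-validated classification experiment."""

    model_kind: str
    input_kind: str
    outcome: str
    classes: tuple[str, ...]
    fold_confusions: list[np.ndarray]
    fold_mcc: list[float]
    y_true: np.ndarray
    y_pred: np.ndarray
    mcc_point: float = field(default=np.nan)
    mcc_ci_low: float = field(default=np.nan)
    mcc_ci_high: float = field(default=np.nan)

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)

    @property
    def fold_per_class_accuracy(self) -> list[np.ndarray]:
        return [per_class_accuracy(cm) for cm in self.fold_confusions]

    @property
    def min_per_class_accuracy(self) -> float:
        return float(min(acc.min() for acc in self.fold_per_class_accuracy))

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "input_kind": self.input_kind,
            "outcome": self.outcome,
            "classes": list(self.classes),
            "fold_confusions": [cm.tolist() for cm in self.fold_confusions],
            "fold_mcc": [float(m) for m in self.fold_mcc],
            "mcc_point": float(self.mcc_point),
            "mcc_ci_low": float(self.mcc_ci_low),
            "mcc_ci_high": float(self.mcc_ci_high),
            "min_per_class_accuracy": self.min_per_class_accuracy,
        }


def make_folds(
    subject_ids: Sequence[str],
    handedness: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Handedness-stratified subject-level fold assignment.

    Per-fold class proportions differ from the global ones by at most one
    subject per class (sklearn's stratified splitter guarantee).
    """
    subject_ids = list(subject_ids)
    handedness = np.asarray(handedness)
    if len(subject_ids) != len(handedness):
        raise ValueError("subject_ids and handedness must be equal length")
    _, counts = np.unique(handedness, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest handedness class ({counts.min()}) has fewer subjects "
            f"than folds ({n_folds})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(subject_ids)), handedness)):
        for i in test_idx:
            assignment[subject_ids[i]] = fold
    return FoldPlan(n_folds=n_folds, assignment=assignment)


def build_model(model_kind: str, seed: int | None = 0):
    """Instantiate one of the three classifier families."""
    if model_kind == "LDA":
        return LinearDiscriminantAnalysis()
    if model_kind == "SVC":
        return make_pipeline(StandardScaler(), SVC(kernel="linear"))
    if model_kind == "NN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(100,), max_iter=500, random_state=seed),
        )
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def train_and_predict(
    train_X: np.ndarray,
    train_y: Sequence[str],
    test_X: np.ndarray,
    model_kind: str = "LDA",
    seed: int | None = 0,
):
    """Fit one classifier and predict test labels.

    Returns ``(predictions, fitted_model)``; for LDA the fitted model
    exposes per-feature ``scalings_`` and discriminant scores via
    ``transform``.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    model = build_model(model_kind, seed=seed)
    model.fit(train_X, train_y)
    return model.predict(test_X), model


def fit_oriented_lda(
    X: np.ndarray, y: Sequence[str], negative_class: str = "LH"
) -> tuple[LinearDiscriminantAnalysis, float]:
    """Fit an LDA and resolve the arbitrary LD1 sign.

    Returns ``(model, sign)`` with ``sign`` in {-1, +1} chosen so the mean
    LD1 score of ``negative_class`` is negative.  Multiply ``scalings_[:, 0]``
    and ``transform(...)[:, 0]`` by ``sign`` to obtain oriented values.
    """
    y = np.asarray(y)
    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    scores = lda.transform(X)[:, 0]
    mean_neg = scores[y == negative_class].mean()
    sign = -1.0 if mean_neg > 0 else 1.0
    return lda, sign


def confusion(
    y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None
) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    k = len(classes)
    lookup = {c: i for i, c in enumerate(classes.tolist())}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        cm[lookup[t], lookup[p]] += 1
    return cm


def _mcc_batch(cms: np.ndarray) -> np.ndarray:
    """Generalized (multiclass) MCC for a batch of confusion matrices.

    Uses the covariance form: for binary matrices this reduces to the
    textbook (TP*TN - FP*FN) / sqrt(...) formula.  Any zero denominator
    factor (a class absent from truth or predictions, or one-class
    output) yields MCC = 0.
    """
    cms = np.asarray(cms, dtype=float)
    t = cms.sum(axis=-1)  # true class totals
    p = cms.sum(axis=-2)  # predicted class totals
    s = t.sum(axis=-1)
    c = np.trace(cms, axis1=-2, axis2=-1)
    num = c * s - (t * p).sum(axis=-1)
    d1 = s**2 - (p**2).sum(axis=-1)
    d2 = s**2 - (t**2).sum(axis=-1)
    denom = np.sqrt(d1 * d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def mcc(confusion_matrix: np.ndarray) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Binary matrices use the standard formula with the convention that any
    zero denominator factor gives 0; larger matrices use the generalized
    multiclass (Gorodkin) form, which shares that convention.
    """
    cm = np.asarray(confusion_matrix)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return float(_mcc_batch(cm))


def accuracy(confusion_matrix: np.ndarray) -> float:
    """Overall accuracy: trace / total."""
    cm = np.asarray(confusion_matrix, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm) / total)


def per_class_accuracy(confusion_matrix: np.ndarray) -> np.ndarray:
    """Within-class accuracy (recall) for each true class."""
    cm = np.asarray(confusion_matrix, dtype=float)
    totals = cm.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a class has no samples in the confusion matrix")
    return np.diag(cm) / totals


def bootstrap_mcc_ci(
    y_true: Sequence,
    y_pred: Sequence,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap (mean, 2.5th pct, 97.5th pct) of MCC.

    (truth, prediction) pairs are resampled jointly with replacement;
    replicates with a degenerate confusion matrix score 0 by the MCC
    convention rather than being dropped.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes.tolist())}
    ti = np.array([lut[v] for v in y_true.tolist()])
    pi = np.array([lut[v] for v in y_pred.tolist()])
    n = len(ti)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    codes = ti[idx] * k + pi[idx]
    offsets = (np.arange(reps) * k * k)[:, None]
    cms = np.bincount((codes + offsets).ravel(), minlength=reps * k * k).reshape(reps, k, k)
    vals = _mcc_batch(cms)
    return (
        float(vals.mean()),
        float(np.percentile(vals, 2.5)),
        float(np.percentile(vals, 97.5)),
    )


def mcc_accuracy_calibration(
    class_sizes: Sequence[int],
    per_class_acc: float,
    reps: int = 1000,
    seed: int = 0,
    error_allocation: str = "uniform",
) -> dict[str, float]:
    """Simulate the MCC implied by a fixed per-class accuracy.

    For each replicate and class, the number of correct predictions is
    Binomial(n_class, per_class_acc) and misclassifications are spread
    over the other classes (uniformly by default).  Summarises the MCC
    distribution — used to motivate critical values such as MCC 0.4/0.6
    corresponding to roughly 80%/90% per-class accuracy.
    """
    sizes = np.asarray(class_sizes, dtype=int)
    if np.any(sizes <= 0):
        raise ValueError("class sizes must be positive")
    if not 0 < per_class_acc <= 1:
        raise ValueError("per-class accuracy must lie in (0, 1]")
    if error_allocation != "uniform":
        raise ValueError("only uniform error allocation is implemented")
    k = len(sizes)
    rng = np.random.default_rng(seed)
    cms = np.zeros((reps, k, k))
    for c in range(k):
        correct = rng.binomial(sizes[c], per_class_acc, size=reps)
        cms[:, c, c] = correct
        wrong = sizes[c] - correct
        if k > 1:
            others = [j for j in range(k) if j != c]
            alloc = np.array(
                [rng.multinomial(w, np.full(k - 1, 1.0 / (k - 1))) for w in wrong]
            )
            cms[:, c, others] = alloc
    vals = _mcc_batch(cms)
    return {
        "mean": float(vals.mean()),
        "p2.5": float(np.percentile(vals, 2.5)),
        "p97.5": float(np.percentile(vals, 97.5)),
    }


def oversample_minority(
    X: np.ndarray, y: Sequence, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random oversampling: duplicate minority rows until all classes match
    the majority count.  Majority rows are untouched; every added row is an
    exact copy of an existing row of its class."""
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires at least two classes")
    target = counts.max()
    rng = np.random.default_rng(seed)
    extra_idx: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        if count < target:
            rows = np.flatnonzero(y == cls)
            extra_idx.append(rng.choice(rows, size=target - count, replace=True))
    if not extra_idx:
        return X, y
    add = np.concatenate(extra_idx)
    return np.vstack([X, X[add]]), np.concatenate([y, y[add]])


def subsample_training(
    train_subjects: Sequence[str], target_n: int = 74, seed: int = 0
) -> list[str]:
    """Uniform subject subsample without replacement (size-matched control).

    The default target of 74 is four fifths of a 92-subject minority
    cohort — the size of its training portion under 5-fold CV.
    """
    subjects = list(train_subjects)
    if target_n > len(subjects):
        raise ValueError(
            f"requested {target_n} subjects but only {len(subjects)} available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(subjects), size=target_n, replace=False)
    return [subjects[i] for i in sorted(picked)]


def default_subsample_target(minority_cohort_size: int) -> int:
    """Training-portion size of the minority cohort under 5-fold CV."""
    return round(0.8 * minority_cohort_size)


def fourway_label(hemi: str, handedness: str) -> str:
    """Combined chirality x handedness label, e.g. (LH, dextral) -> 'rightyLH'."""
    try:
        return _FOURWAY[(hemi, handedness)]
    except KeyError:
        raise ValueError(f"unknown (hemi, handedness) combination ({hemi!r}, {handedness!r})")


def decompose_fourway(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Split four-way labels back into (chirality, handedness) components."""
    hemi, hand = [], []
    for lbl in labels:
        try:
            h, d = _FOURWAY_INV[lbl]
        except KeyError:
            raise ValueError(f"unknown four-way label {lbl!r}")
        hemi.append(h)
        hand.append(d)
    return np.array(hemi), np.array(hand)


def compare_mcc_paired(
    mcc_a: Sequence[float], mcc_b: Sequence[float]
) -> dict[str, float]:
    """Paired t-test between two matched lists of MCC values.

    Returns mean difference (a - b), t, df, two-sided p, and Cohen's d of
    the differences.  Identical lists return t = 0, p = 1; a constant
    nonzero difference has no defined t and raises.
    """
    a = np.asarray(mcc_a, dtype=float)
    b = np.asarray(mcc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two matched 1-D lists of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return {"mean_diff": 0.0, "t": 0.0, "df": len(a) - 1, "p": 1.0, "d": 0.0}
        raise ValueError("paired differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return {
        "mean_diff": float(diff.mean()),
        "t": float(t),
        "df": len(a) - 1,
        "p": float(p),
        "d": float(diff.mean() / sd),
    }


def cross_validated_run(
    X: np.ndarray,
    y: Sequence[str],
    sample_subjects: Sequence[str],
    subject_handedness: Mapping[str, str],
    model_kind: str = "LDA",
    input_kind: str = "HC",
    outcome: str = "chirality",
    n_folds: int = 5,
    seed: int = 0,
    oversample: bool = False,
    subsample_train: int | None = None,
    bootstrap_reps: int = 1000,
) -> ClassificationRun:
    """Run one full stratified cross-validated classification experiment.

    ``sample_subjects`` maps each row of ``X`` to its subject; folds are
    built over unique subjects stratified on handedness, so all samples of
    a subject stay on one side of every split.  Optional minority
    oversampling and training-set subject subsampling apply to the
    training side only.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    sample_subjects = np.asarray(sample_subjects)
    unique_subjects = list(dict.fromkeys(sample_subjects.tolist()))
    hands = [subject_handedness[s] for s in unique_subjects]
    plan = make_folds(unique_subjects, hands, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]).generate_state(1)[0])

    classes = tuple(np.unique(y).tolist())
    fold_confusions, fold_mcc = [], []
    all_true, all_pred = [], []
    for fold in range(n_folds):
        train_subj = plan.train_subjects(fold)
        if subsample_train is not None:
            train_subj = subsample_training(
                train_subj, target_n=subsample_train,
                seed=int(rng.integers(2**31 - 1)),
            )
        train_set = set(train_subj)
        test_set = set(plan.test_subjects(fold))
        if train_set & test_set:
            raise RuntimeError("fold hygiene violated: subject in train and test")
        train_rows = np.isin(sample_subjects, list(train_set))
        test_rows = np.isin(sample_subjects, list(test_set))
        tr_X, tr_y = X[train_rows], y[train_rows]
        if oversample:
            tr_X, tr_y = oversample_minority(
                tr_X, tr_y, seed=int(rng.integers(2**31 - 1))
            )
        preds, _ = train_and_predict(
            tr_X, tr_y, X[test_rows], model_kind=model_kind,
            seed=int(rng.integers(2**31 - 1)),
        )
        cm = confusion(y[test_rows], preds, classes=classes)
        fold_confusions.append(cm)
        fold_mcc.append(mcc(cm))
        all_true.append(y[test_rows])
        all_pred.append(preds)

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    point, lo, hi = bootstrap_mcc_ci(
        y_true, y_pred, reps=bootstrap_reps,
        seed=int(rng.integers(2**31 - 1)),
    )
    return ClassificationRun(
        model_kind=model_kind,
        input_kind=input_kind,
        outcome=outcome,
        classes=classes,
        fold_confusions=fold_confusions,
        fold_mcc=fold_mcc,
        y_true=y_true,
        y_pred=y_pred,
        mcc_point=point,
        mcc_ci_low=lo,
        mcc_ci_high=hi,
    )
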