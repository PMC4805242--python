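"""Max-margin classification of comparison scores.

Each subject contributes one point in score space (a single EMD value, an
MFI delta, or a small vector of measures), labelled with one of two classes.
A linear support vector machine (scikit-learn SVC, linear kernel, no feature
normalization) finds the maximal gap between the classes; hard margins
(C = 1e5) suit separable scores, soft margins (C = 1) tolerate overlap.
Validation is repeated sub-sampling: split each class into train/held-out,
fit on train, count held-out misclassifications, either exhaustively over
all splits or randomly with a guarantee that every subject is held out at
least once.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .alt_metrics import chi_square, mahalanobis, mfi_delta, pb_statistic
from .emd_core import emd_samples
from .errors import DegenerateInputError, ParameterError
from .flow_io import EventMatrix

__all__ = [
    "ScoredCohort",
    "LinearSeparator",
    "SplitRecord",
    "ClassifierResult",
    "fit_linear_svm",
    "repeated_subsample_validate",
    "score_cohort",
    "emd_measure",
    "pb_measure",
    "chs_measure",
    "md_measure",
    "mfi_measure",
]

HARD_MARGIN_C = 1e5
SOFT_MARGIN_C = 1.0


@dataclass(frozen=True)
class ScoredCohort:
    """Per-subject scores and class labels (exactly two classes)."""

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]
    scores: np.ndarray  # (n_subjects, n_measures)
    measure_names: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if scores.shape[0] != len(self.subject_ids):
            scores = scores.T
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.subject_ids)
        if scores.shape != (n, len(self.measure_names)):
            raise ParameterError(
                f"scores shape {scores.shape} does not match "
                f"{n} subjects x {len(self.measure_names)} measures"
            )
        if len(self.labels) != n:
            raise ParameterError("one label per subject required")
        if not np.all(np.isfinite(scores)):
            raise DegenerateInputError("cohort contains non-finite scores")
        if len(set(self.labels)) != 2:
            raise DegenerateInputError(
                f"exactly two class labels required, got {sorted(set(self.labels))}"
            )

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(set(self.labels)))

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)

    def subset(self, measures: Sequence[str]) -> "ScoredCohort":
        idx = [self.measure_names.index(m) for m in measures]
        return ScoredCohort(
            self.subject_ids, self.labels, self.scores[:, idx], tuple(measures)
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.scores, columns=list(self.measure_names))
        frame.insert(0, "label", list(self.labels))
        frame.insert(0, "subject", list(self.subject_ids))
        return frame

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ScoredCohort":
        measures = [c for c in frame.columns if c not in ("subject", "label")]
        return cls(
            tuple(str(s) for s in frame["subject"]),
            tuple(str(l) for l in frame["label"]),
            frame[measures].to_numpy(dtype=float),
            tuple(measures),
        )


@dataclass(frozen=True)
class LinearSeparator:
    """Hyperplane w.x + b = 0; x with w.x + b >= 0 goes to ``positive_class``.

    Ties exactly on the boundary are assigned to the positive side.
    """

    weights: np.ndarray
    intercept: float
    negative_class: str
    positive_class: str
    C: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        side = self.decision(X) >= 0
        return np.where(side, self.positive_class, self.negative_class)

    @property
    def threshold(self) -> float:
        """Decision boundary for 1-D scores: -b / w."""
        if self.weights.shape[0] != 1:
            raise ParameterError("threshold is defined for 1-D score spaces only")
        return float(-self.intercept / self.weights[0])


def fit_linear_svm(
    cohort: ScoredCohort,
    C: float = HARD_MARGIN_C,
    measures: Sequence[str] | None = None,
    indices: np.ndarray | None = None,
) -> LinearSeparator:
    """Fit a linear max-margin separator on the (unnormalized) score space.

    For separable 1-D scores with a hard margin the resulting threshold is
    the midpoint between the closest opposing scores.
    """
    if C <= 0:
        raise ParameterError(f"regularization C must be positive, got {C}")
    work = cohort if measures is None else cohort.subset(measures)
    X = work.scores
    y = np.asarray(work.labels)
    if indices is not None:
        X, y = X[indices], y[indices]
    if len(set(y)) < 2:
        raise DegenerateInputError("training data contains a single class")
    model = SVC(kernel="linear", C=C)
    model.fit(X, y)
    return LinearSeparator(
        weights=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        negative_class=str(model.classes_[0]),
        positive_class=str(model.classes_[1]),
        C=C,
    )


@dataclass(frozen=True)
class SplitRecord:
    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    train_errors: int
    validation_errors: int
    validation_size: int


@dataclass(frozen=True)
class ClassifierResult:
    """Separator fit on the full cohort plus per-split validation counts."""

    separator: LinearSeparator
    C: float
    splits: tuple[SplitRecord, ...]
    best_validation_errors: int
    mean_validation_error_rate: float
    validation_size: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "C": self.C,
                "weights": self.separator.weights.tolist(),
                "intercept": self.separator.intercept,
                "classes": [self.separator.negative_class, self.separator.positive_class],
                "n_splits": len(self.splits),
                "best_validation_errors": self.best_validation_errors,
                "validation_size": self.validation_size,
                "mean_validation_error_rate": self.mean_validation_error_rate,
                "splits": [
                    {
                        "train": list(s.train_indices),
                        "validation": list(s.validation_indices),
                        "train_errors": s.train_errors,
                        "validation_errors": s.validation_errors,
                    }
                    for s in self.splits
                ],
            }
        )


def _evaluate_split(
    cohort: ScoredCohort, train_idx: np.ndarray, C: float
) -> SplitRecord:
    sep = fit_linear_svm(cohort, C=C, indices=train_idx)
    labels = np.asarray(cohort.labels)
    val_idx = np.setdiff1d(np.arange(len(labels)), train_idx)
    train_err = int((sep.predict(cohort.scores[train_idx]) != labels[train_idx]).sum())
    val_err = int((sep.predict(cohort.scores[val_idx]) != labels[val_idx]).sum())
    return SplitRecord(
        tuple(int(i) for i in train_idx),
        tuple(int(i) for i in val_idx),
        train_err,
        val_err,
        val_idx.size,
    )


def repeated_subsample_validate(
    cohort: ScoredCohort,
    train_per_class: int,
    C: float = HARD_MARGIN_C,
    mode: str = "exhaustive",
    n_reps: int = 200,
    seed: int | None = None,
    max_exhaustive: int = 200_000,
) -> ClassifierResult:
    """Repeated sub-sampling validation of the linear SVM.

    ``mode="exhaustive"`` evaluates every combination of ``train_per_class``
    training subjects from each class (C(n_a, k) * C(n_b, k) splits);
    ``mode="random"`` draws ``n_reps`` random splits and then appends
    targeted splits so that every subject is held out at least once.  The
    headline number is the minimum validation error over splits (the "best
    classification"), which is optimistic, so the mean error rate is
    reported alongside.
    """
    label_a, label_b = cohort.classes
    idx_a = cohort.class_indices(label_a)
    idx_b = cohort.class_indices(label_b)
    if not (0 < train_per_class < min(idx_a.size, idx_b.size)):
        raise ParameterError(
            f"train_per_class={train_per_class} infeasible for class sizes "
            f"{idx_a.size} and {idx_b.size}"
        )

    splits: list[np.ndarray] = []
    if mode == "exhaustive":
        n_comb = math.comb(idx_a.size, train_per_class) * math.comb(
            idx_b.size, train_per_class
        )
        if n_comb > max_exhaustive:
            raise ParameterError(
                f"{n_comb} exhaustive splits exceed the cap {max_exhaustive}; "
                "use mode='random'"
            )
        for comb_a in itertools.combinations(idx_a, train_per_class):
            for comb_b in itertools.combinations(idx_b, train_per_class):
                splits.append(np.array(comb_a + comb_b))
    elif mode == "random":
        if seed is None:
            raise ParameterError("random mode requires an explicit seed")
        rng = np.random.default_rng(seed)
        for _ in range(n_reps):
            train_a = rng.choice(idx_a, train_per_class, replace=False)
            train_b = rng.choice(idx_b, train_per_class, replace=False)
            splits.append(np.concatenate([train_a, train_b]))
        # coverage guarantee: every subject held out at least once
        held_out = set()
        n = len(cohort.subject_ids)
        for s in splits:
            held_out.update(np.setdiff1d(np.arange(n), s).tolist())
        for subject in range(n):
            if subject in held_out:
                continue
            own, other = (idx_a, idx_b) if subject in idx_a else (idx_b, idx_a)
            pool = own[own != subject]
            train_own = rng.choice(pool, train_per_class, replace=False)
            train_other = rng.choice(other, train_per_class, replace=False)
            splits.append(np.concatenate([train_own, train_other]))
    else:
        raise ParameterError(f"mode must be 'exhaustive' or 'random', got {mode!r}")

    records = tuple(_evaluate_split(cohort, s, C) for s in splits)
    best = min(r.validation_errors for r in records)
    mean_rate = float(
        np.mean([r.validation_errors / r.validation_size for r in records])
    )
    full = fit_linear_svm(cohort, C=C)
    return ClassifierResult(
        separator=full,
        C=C,
        splits=records,
        best_validation_errors=best,
        mean_validation_error_rate=mean_rate,
        validation_size=records[0].validation_size,
    )


# ---------------------------------------------------------------------------
# measure factories: (control, stimulated) -> score


Measure = Callable[[EventMatrix, EventMatrix], float]


def emd_measure(stop_threshold: float | str = "auto") -> Measure:
    """EMD between per-sample auto-binned signatures."""
    return lambda control, test: emd_samples(control, test, stop_threshold)


def pb_measure() -> Measure:
    return lambda control, test: pb_statistic(control, test, "auto")


def chs_measure() -> Measure:
    return lambda control, test: chi_square(control, test, "auto")


def md_measure() -> Measure:
    return lambda control, test: mahalanobis(control, test)


def mfi_measure(
    channel: str, subsample: int | None = None, seed: int | None = None
) -> Measure:
    """MFI delta on one channel; ``subsample`` draws that many events first.

    Sub-sampling deliberately degrades the readout (median sampling noise
    grows as 1/sqrt(n)), emulating a low-information single-channel assay.
    """

    def measure(control: EventMatrix, test: EventMatrix) -> float:
        c, t = control, test
        if subsample is not None:
            rng = np.random.default_rng(seed)
            keep_c = rng.choice(c.n_events, min(subsample, c.n_events), replace=False)
            keep_t = rng.choice(t.n_events, min(subsample, t.n_events), replace=False)
            c = EventMatrix(c.values[keep_c], c.channels, c.transform_tag)
            t = EventMatrix(t.values[keep_t], t.channels, t.transform_tag)
        return mfi_delta(c, t, channel)

    return measure


def score_cohort(subjects: Sequence, measures: Mapping[str, Measure]) -> ScoredCohort:
    """Score every subject's (control, stimulated) pair with each measure.

    ``subjects`` is any sequence of objects exposing ``subject_id``,
    ``label``, ``control`` and ``stimulated`` (see synthetic_data.Subject).
    """
    names = tuple(measures)
    scores = np.array(
        [[measures[m](s.control, s.stimulated) for m in names] for s in subjects]
    )
    return ScoredCohort(
        tuple(s.subject_id for s in subjects),
        tuple(s.label for s in subjects),
        scores,
        names,
    )
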