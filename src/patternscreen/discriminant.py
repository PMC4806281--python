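"""Linear discriminant classification and 12-way misclassification typing.

The physician-assigned pattern is treated as the response and the raw
clinical indices (not the aggregated upper-class scores) as predictors.  A
classical linear discriminant — per-class means, pooled within-class
covariance, priors proportional to class frequencies — is fitted and the
cohort is classified by resubstitution.  Each patient then gets a
classification type code: the pattern label itself when physician and model
agree ("QD"), or the concatenation physician+predicted when they disagree
("DPFH" = physician said Dampness-phlegm, model said Fire-heat).  With four
patterns there are exactly 12 such misclassification codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PATTERNS, DataError


class FittingError(ValueError):
    """Raised when the discriminant cannot be fitted on the given cohort."""


@dataclass(frozen=True)
class LdaModel:
    """Pooled-covariance linear discriminant over the four patterns.

    The discriminant score of class k at x is
    ``delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k`` with S the
    (ridge-regularized) pooled within-class covariance.  ``coef`` and
    ``intercept`` cache ``S^-1 mu_k`` and the constant term per class.
    """

    classes: tuple[str, ...]
    means: np.ndarray        # (k, p)
    covariance: np.ndarray   # (p, p), after regularization
    priors: np.ndarray       # (k,)
    coef: np.ndarray         # (k, p)
    intercept: np.ndarray    # (k,)
    regularization: float

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float | None = None,
) -> LdaModel:
    """Fit the pooled-covariance linear discriminant.

    Priors are proportional to class frequencies; classes absent from
    ``labels`` are dropped (at least two must remain, each with at least two
    members, or the pooled covariance is undefined).  ``regularization`` is a
    ridge term added to the covariance diagonal; the default
    ``1e-6 * trace(S)/p`` guarantees invertibility on small cohorts without
    perturbing a well-conditioned fit.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError(
            f"feature matrix {X.shape} does not align with {y.shape[0]} labels"
        )
    present = [c for c in PATTERNS if np.any(y == c)]
    if len(present) < 2:
        raise FittingError(
            f"need at least two classes to discriminate, found {present}"
        )
    n, p = X.shape
    counts = {}
    means = []
    pooled = np.zeros((p, p))
    for c in present:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise FittingError(
                f"class {c} has {Xc.shape[0]} member(s); at least 2 required"
            )
        counts[c] = Xc.shape[0]
        mu = Xc.mean(axis=0)
        means.append(mu)
        dev = Xc - mu
        pooled += dev.T @ dev
    k = len(present)
    pooled /= n - k
    if regularization is None:
        regularization = 1e-6 * np.trace(pooled) / p
    if regularization < 0:
        raise FittingError("regularization must be nonnegative")
    cov = pooled + regularization * np.eye(p)

    means_arr = np.vstack(means)
    priors = np.array([counts[c] / n for c in present])
    try:
        coef = np.linalg.solve(cov, means_arr.T).T  # rows: S^-1 mu_k
    except np.linalg.LinAlgError as exc:
        raise FittingError(
            f"pooled covariance singular even after ridge {regularization:g}"
        ) from exc
    intercept = -0.5 * np.einsum("kp,kp->k", means_arr, coef) + np.log(priors)
    return LdaModel(
        classes=tuple(present),
        means=means_arr,
        covariance=cov,
        priors=priors,
        coef=coef,
        intercept=intercept,
        regularization=float(regularization),
    )


def discriminant_scores(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """(n, k) matrix of delta_k(x) values."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise DataError(
            f"record has {X.shape[1]} features, model expects {model.n_features}"
        )
    return X @ model.coef.T + model.intercept


def classify(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Predicted pattern labels; ties go to the first class in QD, DP, YD, FH order.

    ``model.classes`` preserves that fixed order, and ``argmax`` returns the
    first maximizer, so the tie-break is deterministic.
    """
    scores = discriminant_scores(model, features)
    idx = np.argmax(scores, axis=1)
    return np.asarray([model.classes[i] for i in idx], dtype=object)


def type_code(physician: str, predicted: str) -> str:
    """Classification type code: the label itself if correct, else physician+predicted."""
    for lab in (physician, predicted):
        if lab not in PATTERNS:
            raise DataError(f"unknown pattern label {lab!r}")
    return physician if physician == predicted else physician + predicted


MISCLASSIFICATION_CODES: tuple[str, ...] = tuple(
    a + b for a in PATTERNS for b in PATTERNS if a != b
)


def outcome_table(
    patient_ids: list[str],
    physician: np.ndarray,
    predicted: np.ndarray,
) -> pd.DataFrame:
    """Per-patient classification outcomes.

    Columns: patient_id, physician_pattern, predicted_pattern, correct,
    type_code.
    """
    rows = []
    for pid, phys, pred in zip(patient_ids, physician, predicted):
        rows.append(
            {
                "patient_id": pid,
                "physician_pattern": phys,
                "predicted_pattern": pred,
                "correct": phys == pred,
                "type_code": type_code(phys, pred),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfusionSummary:
    """4x4 confusion counts (rows physician, columns predicted) with rates."""

    matrix: pd.DataFrame          # counts, index/columns = PATTERNS
    row_totals: pd.Series
    col_totals: pd.Series
    n_total: int
    n_correct: int
    n_misclassified: int
    overall_rate: float           # percent correct
    per_class_rate: pd.Series     # percent correct per physician pattern

    def to_report(self) -> pd.DataFrame:
        """Counts with row percentages in parentheses, plus totals."""
        cells = {}
        for r in PATTERNS:
            row = {}
            for c in PATTERNS:
                cnt = int(self.matrix.loc[r, c])
                pct = 100.0 * cnt / self.row_totals[r] if self.row_totals[r] else 0.0
                row[c] = f"{cnt} ({pct:.2f})"
            row["Total"] = f"{int(self.row_totals[r])} ({100.0 * self.row_totals[r] / self.n_total:.2f})"
            cells[r] = row
        total_row = {
            c: f"{int(self.col_totals[c])} ({100.0 * self.col_totals[c] / self.n_total:.2f})"
            for c in PATTERNS
        }
        total_row["Total"] = f"{self.n_total} (100.00)"
        cells["Total"] = total_row
        return pd.DataFrame(cells).T[list(PATTERNS) + ["Total"]]


def confusion(outcomes: pd.DataFrame) -> ConfusionSummary:
    """Tabulate physician-vs-predicted counts and correct-classification rates."""
    if len(outcomes) == 0:
        raise DataError("empty outcome list")
    matrix = pd.crosstab(
        outcomes["physician_pattern"], outcomes["predicted_pattern"]
    ).reindex(index=PATTERNS, columns=PATTERNS, fill_value=0)
    matrix.index.name = "physician"
    matrix.columns.name = "predicted"
    row_totals = matrix.sum(axis=1)
    col_totals = matrix.sum(axis=0)
    n_total = int(matrix.values.sum())
    n_correct = int(np.trace(matrix.values))
    per_class = pd.Series(
        {
            c: 100.0 * matrix.loc[c, c] / row_totals[c] if row_totals[c] else np.nan
            for c in PATTERNS
        }
    )
    return ConfusionSummary(
        matrix=matrix,
        row_totals=row_totals,
        col_totals=col_totals,
        n_total=n_total,
        n_correct=n_correct,
        n_misclassified=n_total - n_correct,
        overall_rate=100.0 * n_correct / n_total,
        per_class_rate=per_class,
    )
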