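"""Upper-class pattern scores, ordered profiles and the D/R/S/C criteria.

The 44 clinical indices are grouped into four pattern blocks and aggregated
into one upper-class variable per pattern; each upper-class variable is then
standardized across the cohort (z-scores).  Sorting a patient's four
standardized scores in descending order gives the order statistics
Z(1) >= Z(2) >= Z(3) >= Z(4), from which four profile-shape criteria are
derived:

    D = Z(1) - Z(2)          dominance of the top pattern
    R = Z(1) - Z(4)          range of the profile
    S = Z(2)                 strength of the runner-up pattern
    C = (Z(1)+Z(2)) - (Z(3)+Z(4))   two-high-two-low contrast

A U-shaped ("bathtub") profile — two high and two low scores — signals a
patient torn between two patterns and hence at risk of misclassification;
an L-shaped profile (one dominant score) signals a clear-cut case.

C has an equivalent reading as curvature: place the four scores at abscissae
x = 1..4 with Z(1) at x=1, Z(3) at x=2, Z(4) at x=3 and Z(2) at x=4, fit the
least-squares parabola y = b0 + b1 x + b2 x^2, and the quadratic coefficient
satisfies b2 = C/4 identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PATTERNS, DataError, PatientRecord

__all__ = [
    "StandardizedScores",
    "OrderedProfile",
    "ScoreQuartet",
    "Standardizer",
    "CURVATURE_NORMAL_MATRIX",
    "aggregate_blocks",
    "aggregate_cohort",
    "fit_standardizer",
    "order_profile",
    "compute_scores",
    "fit_curvature",
    "score_table",
]


class DegenerateCohortError(ValueError):
    """A cohort on which standardization cannot be fitted."""


@dataclass(frozen=True)
class StandardizedScores:
    """The four cohort-standardized upper-class scores of one patient."""

    z_qd: float
    z_dp: float
    z_yd: float
    z_fh: float

    def as_array(self) -> np.ndarray:
        return np.array([self.z_qd, self.z_dp, self.z_yd, self.z_fh])


@dataclass(frozen=True)
class OrderedProfile:
    """Descending order statistics of the four standardized scores.

    ``perm`` holds the pattern labels in descending-score order; ties are
    broken by the fixed pattern order QD, DP, YD, FH.
    """

    z1: float
    z2: float
    z3: float
    z4: float
    perm: tuple[str, str, str, str]

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3, self.z4])


@dataclass(frozen=True)
class ScoreQuartet:
    """The four profile-shape criteria plus the quadratic curvature b2 = c/4."""

    d: float
    r: float
    s: float
    c: float
    b2: float


# --------------------------------------------------------------------------
# Aggregation


def aggregate_blocks(
    record: PatientRecord,
    block_sizes: tuple[int, ...],
    how: str = "sum",
) -> np.ndarray:
    """Collapse a patient's index values into four upper-class raw scores.

    ``how`` is ``"sum"`` (default) or ``"mean"``; with fixed block sizes the
    two differ by a per-block affine factor that cohort standardization
    removes, so downstream z-scores are identical.
    """
    values = record.index_values
    if values.size != sum(block_sizes):
        raise DataError(
            f"patient {record.patient_id!r}: {values.size} index values, "
            f"expected {int(sum(block_sizes))}"
        )
    out = np.empty(4)
    start = 0
    for k, size in enumerate(block_sizes):
        block = values[start : start + size]
        out[k] = block.sum() if how == "sum" else block.mean()
        start += size
    return out


def aggregate_cohort(
    records: list[PatientRecord],
    block_sizes: tuple[int, ...],
    how: str = "sum",
) -> np.ndarray:
    """(n_patients, 4) array of raw upper-class scores, order QD, DP, YD, FH."""
    return np.vstack([aggregate_blocks(r, block_sizes, how=how) for r in records])


# --------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class Standardizer:
    """Per-component mean and standard deviation fitted on a cohort."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        """z = (x - mean) / sd, broadcast over rows."""
        return (np.asarray(raw, dtype=float) - self.mean) / self.sd


def fit_standardizer(raw: np.ndarray, ddof: int = 1) -> Standardizer:
    """Fit per-component mean and sd over the cohort.

    Uses the sample standard deviation (``ddof=1``) by default.  A component
    with zero variance cannot be standardized and raises, naming the
    offending pattern.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 4:
        raise DataError(f"expected an (n, 4) raw-score array, got shape {raw.shape}")
    if raw.shape[0] < 2:
        raise DegenerateCohortError("standardization needs a cohort of at least 2")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=ddof)
    for k, s in enumerate(sd):
        if s == 0.0 or not np.isfinite(s):
            raise DegenerateCohortError(
                f"upper-class variable {PATTERNS[k]} has zero variance; "
                "cohort is degenerate"
            )
    return Standardizer(mean=mean, sd=sd)


def standardize_cohort(raw: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Fit-and-apply convenience: cohort z-score matrix (n, 4)."""
    return fit_standardizer(raw, ddof=ddof).apply(raw)


# --------------------------------------------------------------------------
# Ordered profiles and criteria


def order_profile(scores: StandardizedScores | np.ndarray) -> OrderedProfile:
    """Sort the four standardized scores in descending order.

    Ties are broken by the fixed pattern order QD, DP, YD, FH (stable sort on
    the negated scores).
    """
    z = scores.as_array() if isinstance(scores, StandardizedScores) else np.asarray(scores, dtype=float)
    if z.shape != (4,):
        raise DataError(f"expected four scores, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise DataError(f"non-finite standardized scores: {z!r}")
    order = np.argsort(-z, kind="stable")
    zs = z[order]
    return OrderedProfile(
        z1=float(zs[0]),
        z2=float(zs[1]),
        z3=float(zs[2]),
        z4=float(zs[3]),
        perm=tuple(PATTERNS[i] for i in order),
    )


def compute_scores(profile: OrderedProfile) -> ScoreQuartet:
    """Derive the D, R, S, C criteria (and curvature b2) from a profile."""
    d = profile.z1 - profile.z2
    r = profile.z1 - profile.z4
    s = profile.z2
    c = (profile.z1 + profile.z2) - (profile.z3 + profile.z4)
    _, _, b2 = fit_curvature(profile)
    return ScoreQuartet(d=d, r=r, s=s, c=c, b2=b2)


# --------------------------------------------------------------------------
# Quadratic curvature

#: Cross-product matrix X'X of the quadratic design on x = 1..4
#: (columns 1, x, x^2).  Row three reads S3 = 30 b0 + 100 b1 + 354 b2.
CURVATURE_NORMAL_MATRIX = np.array(
    [
        [4.0, 10.0, 30.0],
        [10.0, 30.0, 100.0],
        [30.0, 100.0, 354.0],
    ]
)

# Design matrix of the parabola through (1, z1), (2, z3), (3, z4), (4, z2).
_CURVATURE_DESIGN = np.array(
    [[1.0, x, x * x] for x in (1.0, 2.0, 3.0, 4.0)]
)


def fit_curvature(profile: OrderedProfile) -> tuple[float, float, float]:
    """Least-squares parabola through the rearranged profile points.

    The largest score sits at x=1, the second-largest at x=4, the third at
    x=2 and the smallest at x=3, so a U-shaped profile opens the parabola
    upward.  Solves the normal equations X'X b = X'y; the system always has
    full column rank.  Returns (b0, b1, b2); only b2 carries meaning (it
    equals C/4), b0 and b1 are exposed for verification.
    """
    y = np.array([profile.z1, profile.z3, profile.z4, profile.z2])
    b = np.linalg.solve(CURVATURE_NORMAL_MATRIX, _CURVATURE_DESIGN.T @ y)
    return float(b[0]), float(b[1]), float(b[2])


# --------------------------------------------------------------------------
# Per-patient score table


def score_table(
    records: list[PatientRecord],
    block_sizes: tuple[int, ...],
    how: str = "sum",
    ddof: int = 1,
) -> pd.DataFrame:
    """Full per-patient score table for a cohort.

    Standardization is fitted on this cohort (resubstitution framing);
    downstream subset analyses reuse these scores without refitting, so a
    patient's scores travel unchanged through every filtering step.

    Columns: patient_id, physician_pattern, z_qd, z_dp, z_yd, z_fh,
    z1..z4, perm (dash-joined), d, r, s, c, b2.
    """
    raw = aggregate_cohort(records, block_sizes, how=how)
    z = fit_standardizer(raw, ddof=ddof).apply(raw)
    rows = []
    for rec, zrow in zip(records, z):
        prof = order_profile(zrow)
        q = compute_scores(prof)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "physician_pattern": rec.physician_pattern,
                "z_qd": zrow[0],
                "z_dp": zrow[1],
                "z_yd": zrow[2],
                "z_fh": zrow[3],
                "z1": prof.z1,
                "z2": prof.z2,
                "z3": prof.z3,
                "z4": prof.z4,
                "perm": "-".join(prof.perm),
                "d": q.d,
                "r": q.r,
                "s": q.s,
                "c": q.c,
                "b2": q.b2,
            }
        )
    return pd.DataFrame(rows)
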