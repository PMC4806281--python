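"""Decile filtering/selection screens and discrimination-rate gains.

Each profile criterion (D, R, S, C) is evaluated as a misclassification
screen: the cohort is sorted so that hypothesized-misclassified patients
come first, the most-suspect fraction ("filtered" data) and the equally
sized most-reliable fraction ("selected" data) are taken at 10% steps, and
each subset's misclassification count, rate and group score means are
tabulated.  Retained (selected) subsets are additionally used to refit the
discriminant and measure how much the resubstitution discrimination rate
improves as suspect patients are excluded.

Screen directions
-----------------
A patient is ranked suspect when the score points toward a U-shaped
(two-pattern) profile.  The operational defaults are

    D: suspect_low   (top two scores close together)
    R: suspect_low   (flat profile, small range)
    S: suspect_high  (strong runner-up pattern)
    C: suspect_low

For C the direction is genuinely ambiguous: a large two-high-two-low
contrast is the U-shape hypothesis, yet the clinical screening tables place
the small-C tail in the filtered (suspect) fraction and that tail carries
the highest misclassification rate — a flat, low-contrast profile marks a
patient with no clear pattern at all.  The default follows the tabulated
record; every direction can be overridden per score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PATTERNS, ConfigurationError, DataError
from .discriminant import classify, fit_lda, FittingError

SCORE_NAMES: tuple[str, ...] = ("D", "R", "S", "C")

#: Column in the per-patient score table holding each criterion.
SCORE_COLUMNS: dict[str, str] = {"D": "d", "R": "r", "S": "s", "C": "c"}

#: Default screen direction per criterion (see module docstring).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "D": "suspect_low",
    "R": "suspect_low",
    "S": "suspect_high",
    "C": "suspect_low",
}

DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


def subset_size(n: int, fraction: float) -> int:
    """Patients in a ``fraction`` subset of ``n``: round half away from zero, min 1."""
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must lie in (0, 1], got {fraction!r}")
    return max(1, int(math.floor(n * fraction + 0.5)))


def _resolve(score_name: str, direction: str | None) -> tuple[str, str]:
    if score_name not in SCORE_COLUMNS:
        raise ConfigurationError(
            f"unknown score {score_name!r}; expected one of {SCORE_NAMES}"
        )
    direction = direction or DEFAULT_DIRECTIONS[score_name]
    if direction not in ("suspect_low", "suspect_high"):
        raise ConfigurationError(
            f"direction must be 'suspect_low' or 'suspect_high', got {direction!r}"
        )
    return SCORE_COLUMNS[score_name], direction


def filter_rank(
    scores: pd.DataFrame,
    score_name: str,
    direction: str | None = None,
) -> pd.DataFrame:
    """Order patients most-suspect-first by one criterion.

    ``suspect_low`` sorts ascending (small values filtered first),
    ``suspect_high`` descending.  Ties are broken by ``patient_id`` so the
    ranking is a deterministic total order regardless of input row order.
    """
    col, direction = _resolve(score_name, direction)
    ascending = direction == "suspect_low"
    return scores.sort_values(
        [col, "patient_id"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ScreeningRow:
    """One fraction of one screen: counts, misclassification rate, score means."""

    side: str        # "filtered" (suspect) or "selected" (reliable)
    fraction: float
    n_t: int
    n_m: int
    n_c: int
    rate_m: float    # percent misclassified in the subset
    mean_m: float
    mean_c: float
    mean_t: float


def _summarize(sub: pd.DataFrame, col: str, side: str, fraction: float) -> ScreeningRow:
    n_t = len(sub)
    mis = sub[~sub["correct"]]
    cor = sub[sub["correct"]]
    return ScreeningRow(
        side=side,
        fraction=fraction,
        n_t=n_t,
        n_m=len(mis),
        n_c=len(cor),
        rate_m=100.0 * len(mis) / n_t,
        mean_m=float(mis[col].mean()) if len(mis) else float("nan"),
        mean_c=float(cor[col].mean()) if len(cor) else float("nan"),
        mean_t=float(sub[col].mean()),
    )


def screening_table(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    score_name: str,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    direction: str | None = None,
) -> pd.DataFrame:
    """Filtered/selected screening rows for one criterion.

    For each fraction f the *filtered* subset is the first
    ``subset_size(n, f)`` patients of the suspect-first ranking and the
    *selected* subset is the same count taken from the opposite (reliable)
    end.  Rows report subset counts, the misclassification rate, and the
    criterion's mean within the misclassified, correct and total groups.
    """
    col, direction = _resolve(score_name, direction)
    merged = outcomes.merge(scores, on="patient_id", how="inner", suffixes=("", "_s"))
    if len(merged) != len(outcomes) or len(merged) != len(scores):
        raise DataError(
            "outcomes and scores are not aligned: "
            f"{len(outcomes)} outcomes, {len(scores)} scores, {len(merged)} matched"
        )
    ranked = filter_rank(merged, score_name, direction)
    n = len(ranked)
    rows = []
    for f in fractions:
        k = subset_size(n, f)
        rows.append(_summarize(ranked.head(k), col, "filtered", f))
        rows.append(_summarize(ranked.tail(k), col, "selected", f))
    return pd.DataFrame([vars(r) for r in rows])


def selected_ids(
    scores: pd.DataFrame,
    score_name: str,
    fraction: float,
    direction: str | None = None,
) -> list[str]:
    """Patient ids of the retained (most reliable) ``fraction`` of the cohort."""
    ranked = filter_rank(scores, score_name, direction)
    k = subset_size(len(ranked), fraction)
    return ranked["patient_id"].tail(k).tolist()


def discrimination_gain(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids: list[str],
    scores: pd.DataFrame,
    score_name: str,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    direction: str | None = None,
    regularization: float | None = None,
) -> pd.DataFrame:
    """Discrimination rate on selected subsets, refit at each retention level.

    Rows run from retention 1.0 (the baseline fit on the whole cohort) down
    through the given fractions in decreasing order.  At each level the
    discriminant is refitted on the selected subset only and evaluated on it
    by resubstitution; ``gain`` is the rate difference from the next-larger
    retention level.  Subsets on which the discriminant cannot be fitted
    (fewer than two classes, or a class with a single member) are flagged
    ``evaluable=False`` rather than dropped.
    """
    ids = list(patient_ids)
    pos = {pid: i for i, pid in enumerate(ids)}
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)

    levels = [1.0] + sorted((f for f in fractions if f < 1.0), reverse=True)
    rows = []
    prev_rate = float("nan")
    for f in levels:
        if f == 1.0:
            keep = ids
        else:
            keep = selected_ids(scores, score_name, f, direction)
        idx = np.asarray([pos[pid] for pid in keep])
        try:
            model = fit_lda(X[idx], y[idx], regularization=regularization)
            pred = classify(model, X[idx])
            rate = 100.0 * float(np.mean(pred == y[idx]))
            evaluable = True
        except FittingError:
            rate = float("nan")
            evaluable = False
        gain = rate - prev_rate if rows and evaluable and not math.isnan(prev_rate) else float("nan")
        rows.append(
            {
                "retention": f,
                "n": len(idx),
                "rate": rate,
                "gain": gain,
                "evaluable": evaluable,
            }
        )
        if evaluable:
            prev_rate = rate
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Profile-group summaries

Z_COLUMNS: tuple[str, ...] = ("z_qd", "z_dp", "z_yd", "z_fh")


def profile_arrangement(pattern_pair: tuple[str, str]) -> list[str]:
    """Plotting order for a pattern pair: own patterns on the edges, others inside.

    For the pair (A, B) the arrangement is [A, inner1, inner2, B] with the
    inner patterns in the fixed order QD, DP, YD, FH.  A correct-A patient
    then shows a flipped-L shape, a correct-B patient an L shape, and a
    patient torn between A and B a U shape.
    """
    a, b = pattern_pair
    inner = [p for p in PATTERNS if p not in (a, b)]
    return [a, *inner, b]


def profile_group_summary(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    pattern_pair: tuple[str, str],
) -> pd.DataFrame:
    """Mean +/- SE of the standardized scores for one pattern pair's groups.

    Groups are OK(A) and OK(B) (physician and model agree) and the two
    misclassification types AB and BA (physician first, model second), plus
    a Total row over all four groups.  Empty groups appear with n=0 and NaN
    means; singleton groups have NaN standard errors.  The ``flag`` column
    marks both conditions explicitly.
    """
    a, b = pattern_pair
    if a == b or a not in PATTERNS or b not in PATTERNS:
        raise ConfigurationError(
            f"pattern_pair must be two distinct patterns, got {pattern_pair!r}"
        )
    merged = outcomes.merge(scores, on="patient_id", how="inner", suffixes=("", "_s"))
    phys = merged["physician_pattern"]
    pred = merged["predicted_pattern"]

    groups = {
        a + b: merged[(phys == a) & (pred == b)],
        f"OK({a})": merged[(phys == a) & (pred == a)],
        f"OK({b})": merged[(phys == b) & (pred == b)],
        b + a: merged[(phys == b) & (pred == a)],
    }
    groups["Total"] = pd.concat(list(groups.values()))

    rows = []
    for name, sub in groups.items():
        n = len(sub)
        row: dict[str, object] = {"group": name, "n": n}
        for col in Z_COLUMNS:
            if n == 0:
                mean, se = float("nan"), float("nan")
            else:
                mean = float(sub[col].mean())
                se = float(sub[col].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            row[f"mean_{col}"] = mean
            row[f"se_{col}"] = se
        row["flag"] = "empty" if n == 0 else ("se_undefined" if n == 1 else "")
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["profile_order"] = profile_arrangement(pattern_pair)
    return out


def rate_matrix(tables: dict[str, pd.DataFrame], side: str = "filtered") -> pd.DataFrame:
    """Fraction x score matrix of misclassification rates (one screening table per score)."""
    cols = {}
    for name, tab in tables.items():
        sub = tab[tab["side"] == side].set_index("fraction")
        cols[name] = sub["rate_m"]
    out = pd.DataFrame(cols)
    out.insert(0, "n", tables[next(iter(tables))].loc[lambda t: t["side"] == side].set_index("fraction")["n_t"])
    return out


def gain_matrix(gains: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Retention x score matrix of discrimination rates with gains in parentheses."""
    first = gains[next(iter(gains))]
    out = pd.DataFrame({"retention": first["retention"], "n": first["n"]})
    for name, tab in gains.items():
        cells = []
        for _, row in tab.iterrows():
            if not row["evaluable"]:
                cells.append("NE")
            elif math.isnan(row["gain"]):
                cells.append(f"{row['rate']:.2f}")
            else:
                cells.append(f"{row['rate']:.2f} ({row['gain']:+.2f})")
        out[name] = cells
    return out
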