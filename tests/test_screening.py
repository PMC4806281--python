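"""Decile filtering/selection screens, retention gains, profile summaries."""

import math

import numpy as np
import pandas as pd
import pytest

import patternscreen as ps
from patternscreen.cohort import ConfigurationError


# --------------------------------------------------------------------------
# Subset sizing


@pytest.mark.parametrize(
    "n, fraction, expected",
    [
        (3306, 0.10, 331),
        (3306, 0.50, 1653),
        (3306, 0.90, 2975),
        (10, 0.10, 1),
        (5, 0.10, 1),
        (4, 0.375, 2),  # 1.5 rounds half away from zero
        (100, 1.0, 100),
    ],
)
def test_subset_size(n, fraction, expected):
    assert ps.subset_size(n, fraction) == expected


@pytest.mark.parametrize("fraction", [0.0, -0.1, 1.2])
def test_subset_size_rejects_bad_fraction(fraction):
    with pytest.raises(ConfigurationError):
        ps.subset_size(100, fraction)


# --------------------------------------------------------------------------
# Ranking


def _scores_df(values, ids=None):
    ids = ids or [f"P{i + 1}" for i in range(len(values))]
    return pd.DataFrame({"patient_id": ids, "d": values, "r": values, "s": values, "c": values})


def test_filter_rank_forced_order():
    ranked = ps.filter_rank(_scores_df([0.1, 2.0, 0.5]), "D")
    assert ranked["patient_id"].tolist() == ["P1", "P3", "P2"]


def test_reversing_direction_reverses_order():
    df = _scores_df([0.3, 1.1, 0.7, 2.0])
    low = ps.filter_rank(df, "D", "suspect_low")["patient_id"].tolist()
    high = ps.filter_rank(df, "D", "suspect_high")["patient_id"].tolist()
    assert high == low[::-1]


def test_ties_broken_by_patient_id():
    df = _scores_df([1.0, 1.0, 0.5], ids=["Pb", "Pa", "Pc"])
    ranked = ps.filter_rank(df, "D")
    assert ranked["patient_id"].tolist() == ["Pc", "Pa", "Pb"]


def test_filtered_set_matches_brute_force_extremes():
    rng = np.random.default_rng(0)
    values = rng.normal(size=40)
    df = _scores_df(values)
    for k in (1, 5, 17):
        got = set(ps.filter_rank(df, "S").head(k)["patient_id"])  # suspect_high
        expected = set(
            df.sort_values(["s", "patient_id"], ascending=[False, True])
            .head(k)["patient_id"]
        )
        assert got == expected


def test_unknown_score_rejected():
    with pytest.raises(ConfigurationError, match="X"):
        ps.filter_rank(_scores_df([1.0]), "X")


# --------------------------------------------------------------------------
# Screening tables


def _toy_outcomes(correct_flags, ids=None):
    n = len(correct_flags)
    ids = ids or [f"P{i + 1}" for i in range(n)]
    phys = np.asarray(["QD"] * n, dtype=object)
    pred = np.asarray(["QD" if c else "DP" for c in correct_flags], dtype=object)
    return ps.outcome_table(ids, phys, pred)


def test_whole_cohort_fraction_recovers_overall_rate():
    rng = np.random.default_rng(1)
    flags = rng.random(57) < 0.6
    out = _toy_outcomes(flags)
    tab = ps.screening_table(out, _scores_df(rng.normal(size=57)), "D", fractions=(1.0,))
    row = tab[tab["side"] == "filtered"].iloc[0]
    assert row["n_t"] == 57
    assert row["rate_m"] == pytest.approx(100.0 * (~flags).mean())


def test_filtered_and_selected_counts_and_identities(calibrated_bundle):
    tab = ps.screening_table(
        calibrated_bundle["outcomes"], calibrated_bundle["scores"], "D"
    )
    n = len(calibrated_bundle["outcomes"])
    for _, row in tab.iterrows():
        assert row["n_m"] + row["n_c"] == row["n_t"]
        assert row["rate_m"] == pytest.approx(100.0 * row["n_m"] / row["n_t"])
        assert row["n_t"] == ps.subset_size(n, row["fraction"])


def test_filtered_selected_disjoint_and_partition_at_half():
    rng = np.random.default_rng(2)
    n = 100
    out = _toy_outcomes(rng.random(n) < 0.6)
    scores = _scores_df(rng.normal(size=n))
    ranked = ps.filter_rank(scores, "D")
    for f in (0.1, 0.3, 0.5):
        k = ps.subset_size(n, f)
        filtered = set(ranked.head(k)["patient_id"])
        selected = set(ranked.tail(k)["patient_id"])
        assert not filtered & selected
        if f == 0.5:
            assert filtered | selected == set(scores["patient_id"])


def test_report_invariant_to_input_row_order():
    rng = np.random.default_rng(3)
    n = 80
    out = _toy_outcomes(rng.random(n) < 0.6)
    scores = _scores_df(rng.normal(size=n))
    a = ps.screening_table(out, scores, "C")
    shuffled = scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
    b = ps.screening_table(out.sample(frac=1.0, random_state=2), shuffled, "C")
    pd.testing.assert_frame_equal(a, b)


def test_permutation_null_rates_match_base_rate(calibrated_bundle):
    """A score independent of correctness shows no enrichment beyond noise."""
    out = calibrated_bundle["outcomes"].copy()
    rng = np.random.default_rng(7)
    out["correct"] = rng.permutation(out["correct"].to_numpy())
    base = 100.0 * (~out["correct"]).mean()
    tab = ps.screening_table(out, calibrated_bundle["scores"], "D")
    p = (~out["correct"]).mean()
    for _, row in tab[tab["side"] == "filtered"].iterrows():
        se = 100.0 * math.sqrt(p * (1 - p) / row["n_t"])
        assert abs(row["rate_m"] - base) <= 3 * se, (row["fraction"], row["rate_m"], base)


def test_calibrated_screens_enrich_filtered_decile(calibrated_bundle):
    """At calibrated defaults every screen's suspect decile beats the base rate."""
    out = calibrated_bundle["outcomes"]
    base = 100.0 * (~out["correct"]).mean()
    for name in ps.SCORE_NAMES:
        tab = ps.screening_table(out, calibrated_bundle["scores"], name)
        first = tab[tab["side"] == "filtered"].iloc[0]
        assert first["rate_m"] >= base, (name, first["rate_m"], base)


# --------------------------------------------------------------------------
# Discrimination gains


def test_full_retention_equals_baseline(calibrated_bundle):
    b = calibrated_bundle
    gains = ps.discrimination_gain(
        b["X"], b["y"], b["ids"], b["scores"], "D", fractions=(0.5, 0.9)
    )
    baseline = 100.0 * b["outcomes"]["correct"].mean()
    row = gains[gains["retention"] == 1.0].iloc[0]
    assert row["rate"] == pytest.approx(baseline)
    assert row["n"] == len(b["ids"])
    assert math.isnan(row["gain"])


def test_perfectly_separable_cohort_stays_at_100():
    cfg = ps.CohortConfig(
        n_patients=300, contamination_rate=0.0, signal_mean=5.0, noise_sd=0.1, seed=9
    )
    records = ps.generate_cohort(cfg)
    X = ps.feature_matrix(records, cfg.block_sizes)
    y = ps.labels_array(records)
    scores = ps.score_table(records, cfg.block_sizes)
    ids = [r.patient_id for r in records]
    gains = ps.discrimination_gain(X, y, ids, scores, "D", fractions=(0.3, 0.6, 0.9))
    assert np.allclose(gains["rate"], 100.0)


def test_purging_known_misclassifications_raises_rate(calibrated_bundle):
    """Ranking by the true correctness flag (an oracle screen) improves the refit."""
    b = calibrated_bundle
    cheat = b["scores"][["patient_id"]].copy()
    flag = b["outcomes"].set_index("patient_id")["correct"]
    for col in ("d", "r", "s", "c"):
        cheat[col] = flag.loc[cheat["patient_id"]].to_numpy().astype(float)
    gains = ps.discrimination_gain(
        b["X"], b["y"], b["ids"], cheat, "D", fractions=(0.9,)
    )
    baseline = gains[gains["retention"] == 1.0].iloc[0]["rate"]
    at90 = gains[gains["retention"] == 0.9].iloc[0]["rate"]
    assert at90 >= baseline


def test_unfittable_subsets_are_flagged_not_dropped():
    rng = np.random.default_rng(10)
    n = 12
    X = rng.normal(size=(n, 3))
    y = np.asarray([p for p in ps.PATTERNS for _ in range(3)], dtype=object)
    ids = [f"P{i + 1:02d}" for i in range(n)]
    scores = pd.DataFrame(
        {"patient_id": ids, "d": np.arange(n, dtype=float),
         "r": 0.0, "s": 0.0, "c": 0.0}
    )
    gains = ps.discrimination_gain(X, y, ids, scores, "D", fractions=(0.17, 0.9))
    tiny = gains[gains["retention"] == 0.17].iloc[0]
    assert not tiny["evaluable"]
    assert math.isnan(tiny["rate"])
    assert len(gains) == 3  # 1.0, 0.9, 0.17 all present


# --------------------------------------------------------------------------
# Profile-group summaries


def test_profile_groups_match_two_pass_oracle(calibrated_bundle):
    b = calibrated_bundle
    summ = ps.profile_group_summary(b["outcomes"], b["scores"], ("FH", "QD"))
    merged = b["outcomes"].merge(b["scores"], on="patient_id", suffixes=("", "_s"))
    fhqd = merged[(merged["physician_pattern"] == "FH") & (merged["predicted_pattern"] == "QD")]
    row = summ[summ["group"] == "FHQD"].iloc[0]
    assert row["n"] == len(fhqd)
    for col in ("z_qd", "z_dp", "z_yd", "z_fh"):
        vals = fhqd[col].to_numpy()
        assert row[f"mean_{col}"] == pytest.approx(vals.mean(), abs=1e-12)
        assert row[f"se_{col}"] == pytest.approx(
            vals.std(ddof=1) / math.sqrt(len(vals)), abs=1e-12
        )
    assert summ.attrs["profile_order"] == ["FH", "DP", "YD", "QD"]


def test_profile_arrangement_places_pair_on_edges():
    assert ps.profile_arrangement(("FH", "QD")) == ["FH", "DP", "YD", "QD"]
    assert ps.profile_arrangement(("QD", "DP")) == ["QD", "YD", "FH", "DP"]


def test_all_pairs_cover_every_within_pair_outcome(calibrated_bundle):
    b = calibrated_bundle
    pairs = [(a, c) for i, a in enumerate(ps.PATTERNS) for c in ps.PATTERNS[i + 1:]]
    total = 0
    for pair in pairs:
        summ = ps.profile_group_summary(b["outcomes"], b["scores"], pair)
        n_pair = summ[summ["group"] == "Total"].iloc[0]["n"]
        out = b["outcomes"]
        mask = out["physician_pattern"].isin(pair) & out["predicted_pattern"].isin(pair)
        assert n_pair == int(mask.sum())
        total += n_pair
    # every patient with both labels in some pair is covered at least once
    assert total >= len(b["outcomes"])


def test_singleton_and_empty_groups_flagged():
    ids = ["P1", "P2", "P3"]
    phys = np.asarray(["QD", "QD", "DP"], dtype=object)
    pred = np.asarray(["DP", "QD", "DP"], dtype=object)
    out = ps.outcome_table(ids, phys, pred)
    scores = pd.DataFrame(
        {"patient_id": ids, "z_qd": [0.1, 0.2, 0.3], "z_dp": [0.0, 0.1, 0.2],
         "z_yd": [1.0, 2.0, 3.0], "z_fh": [0.5, 0.5, 0.5]}
    )
    summ = ps.profile_group_summary(out, scores, ("QD", "DP")).set_index("group")
    assert summ.loc["QDDP", "flag"] == "se_undefined"
    assert summ.loc["QDDP", "mean_z_qd"] == pytest.approx(0.1)
    assert math.isnan(summ.loc["QDDP", "se_z_qd"])
    assert summ.loc["DPQD", "n"] == 0
    assert summ.loc["DPQD", "flag"] == "empty"
    assert math.isnan(summ.loc["DPQD", "mean_z_qd"])
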