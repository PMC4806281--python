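"""Cohort readers/writers, run configuration and the end-to-end pipeline.

Cohorts travel as comma-separated text (header: patient_id,
physician_pattern, then one column per clinical index); reports are written
as tab-separated text.  ``run_pipeline`` wires the stages together:
simulate or read a cohort, compute scores, fit and apply the discriminant,
run every screening table and the retention/gain analysis, and write the
report bundle plus a manifest.  The same configuration and seed always
reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_BLOCK_SIZES,
    PATTERNS,
    CohortConfig,
    ConfigurationError,
    DataError,
    PatientRecord,
    cohort_to_frame,
    feature_matrix,
    index_columns,
    labels_array,
)
from .discriminant import classify, confusion, fit_lda, outcome_table
from .scores import score_table
from .screening import (
    DEFAULT_FRACTIONS,
    SCORE_NAMES,
    discrimination_gain,
    gain_matrix,
    profile_group_summary,
    rate_matrix,
    screening_table,
)

logger = logging.getLogger("patternscreen")


def write_cohort(
    records: list[PatientRecord],
    path: str | Path,
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES,
) -> None:
    """Write a cohort as comma-separated text (full float precision)."""
    frame = cohort_to_frame(records, block_sizes)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_cohort(
    path: str | Path,
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES,
) -> list[PatientRecord]:
    """Read and validate a cohort written by :func:`write_cohort`.

    Malformed rows are reported with their line number (header = line 1).
    """
    expected = ["patient_id", "physician_pattern", *index_columns(block_sizes)]
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file, no cohort to read") from exc
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise DataError(f"{path}: header only, empty cohort")

    idx_cols = expected[2:]
    records = []
    for row_no, (_, row) in enumerate(frame.iterrows(), start=2):
        label = row["physician_pattern"]
        if label not in PATTERNS:
            raise DataError(
                f"{path}, line {row_no}: unknown pattern label {label!r}"
            )
        values = pd.to_numeric(row[idx_cols], errors="coerce").to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = [c for c, v in zip(idx_cols, values) if np.isnan(v)]
            raise DataError(
                f"{path}, line {row_no}: non-numeric index values in {bad[:3]}"
            )
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                physician_pattern=label,
                index_values=values,
            )
        )
    return records


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``input_path`` names a cohort file or ``simulate`` is true and
    ``cohort`` parameterizes the generator.  ``directions`` overrides the
    default screen direction per score name.
    """

    simulate: bool = True
    input_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    score_names: tuple[str, ...] = SCORE_NAMES
    directions: dict[str, str] = field(default_factory=dict)
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    regularization: float | None = None
    output_dir: str = "patternscreen_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.simulate and not self.input_path:
            raise ConfigurationError("either simulate=True or input_path is required")
        fr = tuple(float(f) for f in self.fractions)
        if any(not 0.0 < f <= 1.0 for f in fr) or list(fr) != sorted(set(fr)):
            raise ConfigurationError(
                "fractions must be strictly increasing within (0, 1]"
            )
        unknown = [s for s in self.score_names if s not in SCORE_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown score names {unknown}")
        object.__setattr__(self, "fractions", fr)


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run cohort -> scores -> discriminant -> screening and write all reports.

    Returns the in-memory bundle (cohort records, score table, outcomes,
    confusion summary, screening and gain tables) so callers can continue
    computing without re-reading the files.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        cohort_cfg = config.cohort.with_(
            seed=config.seed, block_sizes=config.block_sizes
        )
        from .cohort import generate_cohort

        records = generate_cohort(cohort_cfg)
        write_cohort(records, out / "cohort.csv", config.block_sizes)
        logger.info("simulated cohort: %d patients", len(records))
    else:
        records = read_cohort(config.input_path, config.block_sizes)
        logger.info("read cohort: %d patients from %s", len(records), config.input_path)

    scores = score_table(records, config.block_sizes)
    _write_tsv(scores, out / "scores.tsv", float_format="%.10g")

    X = feature_matrix(records, config.block_sizes)
    y = labels_array(records)
    model = fit_lda(X, y, regularization=config.regularization)
    pred = classify(model, X)
    outcomes = outcome_table([r.patient_id for r in records], y, pred)
    _write_tsv(outcomes, out / "outcomes.tsv")
    summary = confusion(outcomes)
    summary.to_report().to_csv(out / "confusion.tsv", sep="\t")
    logger.info(
        "discriminant: %d/%d correct (%.2f%%), %d misclassified",
        summary.n_correct,
        summary.n_total,
        summary.overall_rate,
        summary.n_misclassified,
    )

    screen_tables: dict[str, pd.DataFrame] = {}
    gain_tables: dict[str, pd.DataFrame] = {}
    for name in config.score_names:
        direction = config.directions.get(name)
        tab = screening_table(
            outcomes, scores, name, config.fractions, direction=direction
        )
        screen_tables[name] = tab
        _write_tsv(tab, out / f"screening_{name}.tsv")
        gains = discrimination_gain(
            X,
            y,
            [r.patient_id for r in records],
            scores,
            name,
            config.fractions,
            direction=direction,
            regularization=config.regularization,
        )
        gain_tables[name] = gains
        _write_tsv(gains, out / f"gains_{name}.tsv")
        logger.info(
            "screen %s: filtered-10%% rate %.2f%% (base %.2f%%)",
            name,
            tab[tab["side"] == "filtered"].iloc[0]["rate_m"],
            100.0 - summary.overall_rate,
        )

    rate_matrix(screen_tables).to_csv(out / "filtered_rates.tsv", sep="\t")
    gain_matrix(gain_tables).to_csv(out / "selected_gains.tsv", sep="\t", index=False)

    pairs = [(a, b) for i, a in enumerate(PATTERNS) for b in PATTERNS[i + 1 :]]
    profile_frames = []
    for pair in pairs:
        summ = profile_group_summary(outcomes, scores, pair)
        summ.insert(0, "pair", f"{pair[0]},{pair[1]}")
        profile_frames.append(summ)
    profiles = pd.concat(profile_frames, ignore_index=True)
    _write_tsv(profiles, out / "profile_groups.tsv")

    cfg_json = _jsonable(config)
    cfg_json.pop("output_dir")  # not part of the analysis; keeps manifests comparable
    manifest = {
        "package": "patternscreen",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_json,
        "n_patients": len(records),
        "overall_correct_rate": round(summary.overall_rate, 2),
        "n_misclassified": summary.n_misclassified,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "records": records,
        "scores": scores,
        "model": model,
        "outcomes": outcomes,
        "confusion": summary,
        "screening": screen_tables,
        "gains": gain_tables,
        "profiles": profiles,
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj
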