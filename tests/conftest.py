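import numpy as np
import pytest

import patternscreen as ps


@pytest.fixture(scope="session")
def calibrated_bundle():
    """Full analysis of one default-calibration cohort (n=3306, seed 0)."""
    cfg = ps.CohortConfig(seed=0)
    records = ps.generate_cohort(cfg)
    X = ps.feature_matrix(records, cfg.block_sizes)
    y = ps.labels_array(records)
    model = ps.fit_lda(X, y)
    pred = ps.classify(model, X)
    outcomes = ps.outcome_table([r.patient_id for r in records], y, pred)
    scores = ps.score_table(records, cfg.block_sizes)
    return {
        "config": cfg,
        "records": records,
        "X": X,
        "y": y,
        "model": model,
        "outcomes": outcomes,
        "scores": scores,
        "ids": [r.patient_id for r in records],
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small continuous cohort for unit-level plumbing tests."""
    cfg = ps.CohortConfig(n_patients=120, seed=7)
    return cfg, ps.generate_cohort(cfg)


def random_profile(rng: np.random.Generator) -> ps.OrderedProfile:
    return ps.order_profile(rng.normal(size=4))
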