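"""Shared fixtures: phenotyped synthetic cohorts and the published per-draw table."""

import numpy as np
import pytest

from mrdash import CohortSpec, generate_cohort, phenotype_cohort
from mrdash.association import OrEstimate
from mrdash.score import DrawResult


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (n=3014) with all phenotypes derived."""
    spec = CohortSpec(n_subjects=3014, seed=11)
    phenotyped, excluded = phenotype_cohort(generate_cohort(spec))
    assert not excluded
    return phenotyped


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (n=50,000) for parameter-recovery checks."""
    spec = CohortSpec(n_subjects=50_000, seed=7)
    phenotyped, excluded = phenotype_cohort(generate_cohort(spec))
    assert not excluded
    return phenotyped


def _estimate(factor, odds_ratio, p_value):
    return OrEstimate(
        factor=factor, odds_ratio=odds_ratio, ci_low=odds_ratio / 2,
        ci_high=odds_ratio * 2, p_value=p_value, adjusted=True, n_used=1742,
    )


# Published per-draw odds ratios and p-values of the six-factor silent-AF
# model over the five random splits ("<0.001" entries encoded as 0.0005).
PUBLISHED_DRAW_TABLE = {
    "male": ([2.39, 1.54, 2.13, 1.99, 2.50], [0.020, 0.0005, 0.0005, 0.0005, 0.0005]),
    "ckd": ([1.78, 1.39, 1.31, 1.88, 1.43], [0.002, 0.092, 0.171, 0.001, 0.066]),
    "dm": ([1.34, 1.39, 1.29, 1.37, 1.51], [0.115, 0.093, 0.197, 0.086, 0.030]),
    "age_ge_75": ([2.66, 3.30, 3.10, 2.34, 2.83], [0.0005] * 5),
    "ics_tia": ([1.70, 1.57, 1.94, 1.98, 1.76], [0.025, 0.073, 0.005, 0.003, 0.021]),
    "heart_failure": ([1.63, 2.02, 2.10, 1.85, 1.88],
                      [0.016, 0.001, 0.0005, 0.002, 0.002]),
}


@pytest.fixture(scope="session")
def published_draws():
    """Five DrawResults carrying the published per-draw evidence."""
    draws = []
    n_eligible = 2613
    ids = [f"S{i}" for i in range(n_eligible)]
    for d in range(5):
        rng = np.random.default_rng(d)
        perm = rng.permutation(n_eligible)
        draws.append(DrawResult(
            draw_index=d,
            derivation_ids=[ids[i] for i in perm[:1742]],
            validation_ids=[ids[i] for i in perm[1742:]],
            estimates={
                f: _estimate(f, ors[d], ps[d])
                for f, (ors, ps) in PUBLISHED_DRAW_TABLE.items()
            },
        ))
    return draws
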