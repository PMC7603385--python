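import numpy as np
import pytest

import tsfs
from tsfs.student import StudentSpec
from tsfs.teacher import default_teacher_spec


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny planted-effect cohort: R=10, 3 disjoint pairs, strong effect.

    Nuisance terms are turned down relative to the benchmark defaults so
    that even 30 subjects carry a clear signal; this fixture exercises
    plumbing, not statistical difficulty.
    """
    pairs = tsfs.default_planted_pairs(10, 3, seed=0)
    spec = tsfs.CohortSpec(
        n_per_class=15, R=10, T=120, planted_pairs=pairs, effect=0.7,
        hetero=0.4, background_sd=0.3, seed=0,
    )
    subjects, planted = tsfs.generate_cohort(spec)
    return spec, subjects, planted


@pytest.fixture(scope="session")
def small_design(small_cohort):
    _, subjects, planted = small_cohort
    CONN, labels, sites = tsfs.build_design_matrix(subjects)
    return CONN, labels, sites, planted


@pytest.fixture(scope="session")
def study_cohort():
    """The R=20 / 10 planted pairs / effect 0.6 benchmark cohort, seed 1."""
    pairs = tsfs.default_planted_pairs(20, 10, seed=1)
    spec = tsfs.CohortSpec(
        n_per_class=40, R=20, T=200, planted_pairs=pairs, effect=0.6, seed=1
    )
    subjects, planted = tsfs.generate_cohort(spec)
    CONN, labels, sites = tsfs.build_design_matrix(subjects)
    planted_idx = sorted(
        tsfs.pair_to_feature(j, k, 20) for j, k in planted
    )
    return CONN, labels, sites, planted_idx


@pytest.fixture(scope="session")
def study_ranking(study_cohort):
    """Distillation ranking of the benchmark cohort (reduced teacher)."""
    CONN, labels, _, _ = study_cohort
    tspec = default_teacher_spec(CONN.shape[1], epochs=100, seed=1)
    return tsfs.rank_pipeline(CONN, labels, tspec, StudentSpec(seed=1))
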