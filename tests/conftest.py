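"""Shared fixtures: a desk-scale discrimination study reused across tests.

The reference library (300 pooled replicates per cell) and the error
assessments (300 fresh samples per cell) are built once per session; single-
and double-copy assessments share a seed so their trajectories are identical
and the run-type comparison is paired.
"""

import pytest

from fractionator import (
    DEFAULT_MU_GRID,
    assess_discrimination,
    build_reference,
)

REF_SEED = 20260927
ASSESS_SEED = 914517

STUDY_OMTS = (0.2, 0.3, 0.4, 0.8)
REPLICATES = 300
SAMPLES = 300


@pytest.fixture(scope="session")
def reference_library():
    """15-mu reference cumulatives at N in {100, 200, 300, 900}."""
    return build_reference(
        mus=DEFAULT_MU_GRID,
        n_genes_list=(100, 200, 300, 900),
        one_minus_thetas=STUDY_OMTS,
        replicates=REPLICATES,
        run_type="both",
        seed=REF_SEED,
    )


@pytest.fixture(scope="session")
def assessment_n900_single(reference_library):
    """mu_hat frequencies from single-copy runs at N = 900."""
    return assess_discrimination(
        true_mus=(1.0, 1.2, 1.9),
        n_genes_list=(900,),
        one_minus_thetas=STUDY_OMTS,
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED,
        run_type="single",
    )


@pytest.fixture(scope="session")
def assessment_n900_double(reference_library):
    """Same trajectories as the single-copy assessment, classified on double runs."""
    return assess_discrimination(
        true_mus=(1.0, 1.2, 1.9),
        n_genes_list=(900,),
        one_minus_thetas=STUDY_OMTS,
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED,
        run_type="double",
    )


@pytest.fixture(scope="session")
def assessment_n200_single(reference_library):
    return assess_discrimination(
        true_mus=(1.0, 1.2),
        n_genes_list=(200,),
        one_minus_thetas=(0.2, 0.3, 0.4, 0.8),
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED + 1,
        run_type="single",
    )


@pytest.fixture(scope="session")
def assessment_n200_double(reference_library):
    return assess_discrimination(
        true_mus=(1.0, 1.2),
        n_genes_list=(200,),
        one_minus_thetas=(0.2, 0.3, 0.4, 0.8),
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED + 1,
        run_type="double",
    )


@pytest.fixture(scope="session")
def assessment_mu15_by_n(reference_library):
    """mu = 1.5 classified at every library N; genome-size trend material."""
    return assess_discrimination(
        true_mus=(1.5,),
        n_genes_list=(100, 200, 300, 900),
        one_minus_thetas=(0.2,),
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED + 2,
        run_type="single",
    )


@pytest.fixture(scope="session")
def assessment_mu11_n100(reference_library):
    """mu = 1.1 at N = 100: the regime where the mode collapses to mu_hat = 1."""
    return assess_discrimination(
        true_mus=(1.1,),
        n_genes_list=(100,),
        one_minus_thetas=(0.2,),
        samples_per_cell=SAMPLES,
        library=reference_library,
        seed=ASSESS_SEED + 3,
        run_type="single",
    )
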