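"""Shared fixtures: small synthetic cohorts and heavier session-scoped
study runs reused by the calibration / recovery / ordering tests."""

import numpy as np
import pytest

from marm.cnv import cnv_feature_pipeline
from marm.pipeline import RunConfig, run_study
from marm.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort with CNVs, batch factors and a weak set."""
    cfg = SimulationConfig(
        n_samples=60, n_weak=15, n_bins=120, n_species=40,
        malignant_fraction=0.3, mean_reads_per_bin=400.0, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_pipeline():
    """No-CNV, no-batch cohort pushed through the frozen CNV pipeline.

    200 reference + 100 held-out normals over 500 bins: the Z scores of the
    held-out normals should be approximately standard normal.
    """
    cfg = SimulationConfig(
        n_samples=300, n_bins=500, malignant_fraction=0.0,
        gc_bias_strength=0.0, n_latent_factors=0, seed=101,
    )
    cohort = simulate_cohort(cfg)
    reference_ids = cohort.sample_ids[:200]
    test_ids = cohort.sample_ids[200:]
    result = cnv_feature_pipeline(cohort.bin_counts, cohort.bins, reference_ids)
    return cohort, result, reference_ids, test_ids


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort whose malignant samples all carry one cn=4 segment at bins
    100-119 (tumor fraction 0.4, 500 reads/bin); includes a weak set."""
    cfg = SimulationConfig(
        n_samples=260, n_weak=80, n_bins=500, malignant_fraction=0.25,
        mean_reads_per_bin=500.0, tumor_fraction_range=(0.4, 0.4),
        copy_numbers=(4,), n_cnv_segments=1, segment_length_bins=20,
        segment_positions=(100,), seed=11,
    )
    cohort = simulate_cohort(cfg)
    normals = [s for s in cohort.sample_ids if cohort.labels[s] == "non_malignant"]
    result = cnv_feature_pipeline(cohort.bin_counts, cohort.bins, normals[:100])
    return cohort, result


@pytest.fixture(scope="session")
def ordering_study():
    """End-to-end study on a cohort with CNV-borne signal and
    label-independent microbial noise (18-row comparison table)."""
    sim = SimulationConfig(
        n_samples=240, n_weak=60, n_bins=300, n_species=80,
        malignant_fraction=0.3, mean_reads_per_bin=500.0,
        tumor_fraction_range=(0.4, 0.8), n_cnv_segments=4,
        segment_length_bins=20, species_effect=0.0, seed=5,
    )
    cfg = RunConfig(simulation=sim, baseline_mode="fixed", n_reference=100,
                    n_boot=200, seed=5)
    return run_study(cfg)
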