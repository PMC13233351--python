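"""CNV feature derivation: every arithmetic stage against an independent
naive oracle, boundary semantics, and pipeline-level invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from marm.cnv import (
    BinSet,
    Log2RatioProfile,
    build_reference_baseline,
    compute_log2_ratio,
    compute_z,
    cnv_feature_pipeline,
    correct_gc_mappability,
    count_reads_in_bins,
    define_bins,
    filter_available_bins,
    normalize_counts,
    pca_denoise,
    qc_sample,
)
from marm.errors import InvalidInputError, InvalidParameterError
from marm.simulate import SimulationConfig, simulate_cohort


# ---------------------------------------------------------------- binning
def test_define_bins_single_exact_chromosome():
    b = define_bins({"c": 1_000_000})
    assert len(b) == 1
    assert b.table.iloc[0][["start", "end"]].tolist() == [0, 1_000_000]


def test_define_bins_short_last_bin():
    b = define_bins({"c": 2_345_678})
    assert len(b) == 3
    assert b.table.iloc[-1][["start", "end"]].tolist() == [2_000_000, 2_345_678]


def test_define_bins_matches_ceil_sum_oracle(rng):
    lengths = {f"c{i}": int(rng.integers(1, 5_000_000)) for i in range(20)}
    b = define_bins(lengths, bin_size=700_000)
    assert len(b) == sum(math.ceil(v / 700_000) for v in lengths.values())


def test_define_bins_rejects_bad_sizes():
    with pytest.raises(InvalidParameterError):
        define_bins({"c": 100}, bin_size=0)
    with pytest.raises(InvalidParameterError):
        define_bins({"c": 0})


# ---------------------------------------------------------------- QC gate
@pytest.mark.parametrize(
    "bases,cov,passed,reasons",
    [
        (5e6, 0.05, True, []),               # both thresholds inclusive
        (4.99e6, 0.5, False, ["low_host_bases"]),
        (1e9, 1.0, True, []),
        (1e9, 0.049, False, ["low_coverage"]),
        (0, 0, False, ["low_host_bases", "low_coverage"]),
    ],
)
def test_qc_sample(bases, cov, passed, reasons):
    res = qc_sample(bases, cov)
    assert res.passed is passed
    assert res.reasons == reasons


# ---------------------------------------------------------------- counting
def test_count_reads_empty_input():
    bins = define_bins({"c": 2_000_000})
    counts, unassigned = count_reads_in_bins([], bins)
    assert counts.tolist() == [0, 0] and unassigned == 0


def test_count_reads_half_open_boundary():
    bins = define_bins({"c": 2_000_000})
    reads = [("c", 0), ("c", 999_999), ("c", 1_000_000)]
    counts, _ = count_reads_in_bins(reads, bins)
    assert counts.tolist() == [2, 1]


def test_count_reads_unknown_contig_goes_to_unassigned():
    bins = define_bins({"c": 1_000_000})
    counts, unassigned = count_reads_in_bins([("other", 5), ("c", 5)], bins)
    assert counts.tolist() == [1] and unassigned == 1


def test_count_reads_matches_naive_loop(rng):
    lengths = {"a": 3_200_000, "b": 1_500_000}
    bins = define_bins(lengths)
    reads = []
    for _ in range(500):
        chrom = "a" if rng.random() < 0.6 else "b"
        reads.append((chrom, int(rng.integers(0, lengths[chrom]))))
    counts, _ = count_reads_in_bins(reads, bins)
    oracle = np.zeros(len(bins), dtype=int)
    for chrom, pos in reads:
        for i, (c, s, e) in enumerate(
            bins.table[["chrom", "start", "end"]].itertuples(index=False)
        ):
            if c == chrom and s <= pos < e:
                oracle[i] += 1
    assert counts.tolist() == oracle.tolist()


# ------------------------------------------------------------ normalization
def test_normalize_scale_invariance_and_uniform(rng):
    row = rng.integers(1, 100, size=30).astype(float)
    m = pd.DataFrame([row, 2 * row], index=["a", "b"])
    out = normalize_counts(m)
    np.testing.assert_allclose(out.loc["a"], out.loc["b"], atol=1e-12)
    uniform = normalize_counts(pd.DataFrame([np.full(25, 7.0)]))
    np.testing.assert_allclose(uniform.to_numpy(), 1e6 / 25, atol=1e-9)


def test_normalize_matches_hand_computation(rng):
    row = rng.uniform(0, 50, size=40)
    out = normalize_counts(pd.DataFrame([row]))
    np.testing.assert_allclose(out.to_numpy()[0], row / row.sum() * 1e6, atol=1e-12)


def test_normalize_excludes_zero_samples():
    m = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
    with pytest.warns(UserWarning, match="empty"):
        out = normalize_counts(m)
    assert list(out.index) == ["ok"]


# ------------------------------------------------------------ GC correction
def _bins_with(gc, mappability=None):
    n = len(gc)
    tab = pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "gc": gc,
            "mappability": 1.0 if mappability is None else mappability,
        }
    )
    return BinSet(tab)


def test_gc_correction_is_noop_without_bias(rng):
    gc = rng.uniform(0.3, 0.6, size=400)
    bins = _bins_with(gc)
    vals = rng.uniform(98, 102, size=(3, 400))
    m = pd.DataFrame(vals)
    out, mask = correct_gc_mappability(m, bins)
    rel = np.abs(out.to_numpy() - vals) / vals
    assert mask.all()
    assert rel.max() < 0.02


def test_gc_correction_removes_quadratic_bias(rng):
    n = 2000
    gc = rng.uniform(0.3, 0.6, size=n)
    bins = _bins_with(gc)
    # smooth unimodal curve peaking past the sampled range -> strong trend
    base = 100 * np.exp(-0.8 * ((gc - 0.55) / 0.30) ** 2)
    vals = base * rng.normal(1.0, 0.05, size=(2, n))
    out, _ = correct_gc_mappability(pd.DataFrame(vals), bins)
    for i in range(2):
        r_before = np.corrcoef(vals[i], gc)[0, 1]
        r_after = np.corrcoef(out.to_numpy()[i], gc)[0, 1]
        assert abs(r_before) > 0.5
        assert abs(r_after) < 0.05


def test_low_mappability_bins_are_masked(rng):
    gc = rng.uniform(0.3, 0.6, size=50)
    mapp = np.ones(50)
    mapp[7] = 0.5
    bins = _bins_with(gc, mapp)
    out, mask = correct_gc_mappability(pd.DataFrame([np.full(50, 10.0)]), bins)
    assert not mask[7]
    assert np.isnan(out.iloc[0, 7])


def test_gc_correction_needs_enough_bins(rng):
    bins = _bins_with(rng.uniform(0.3, 0.6, size=5))
    with pytest.raises(InvalidInputError):
        correct_gc_mappability(pd.DataFrame([np.ones(5)]), bins)


# ---------------------------------------------------------------- log2 ratio
def test_log2_ratio_examples(rng):
    base = rng.uniform(10, 20, size=30)
    prof = compute_log2_ratio(base, base)
    np.testing.assert_allclose(prof.x, 0.0, atol=1e-12)
    doubled = base.copy()
    doubled[4] *= 2
    assert compute_log2_ratio(doubled, base).x[4] == pytest.approx(1.0)


def test_log2_ratio_matches_elementwise_oracle(rng):
    s = rng.uniform(0.1, 50, size=40)
    b = rng.uniform(0.1, 50, size=40)
    prof = compute_log2_ratio(s, b)
    np.testing.assert_allclose(prof.x, np.log2(s / b), atol=1e-12)


def test_log2_ratio_masks_zero_bins_and_checks_shape():
    prof = compute_log2_ratio(np.array([0.0, 4.0]), np.array([2.0, 2.0]))
    assert not prof.mask[0] and np.isnan(prof.x[0])
    assert prof.x[1] == pytest.approx(1.0)
    with pytest.raises(InvalidInputError):
        compute_log2_ratio(np.ones(3), np.ones(4))


# ---------------------------------------------------------------- baseline
def test_identical_reference_rows_hit_sigma_floor(rng):
    row = rng.normal(size=50)
    ref = pd.DataFrame([row] * 40)
    with pytest.warns(UserWarning):
        base = build_reference_baseline(pd.DataFrame([row] * 10))
    base = build_reference_baseline(ref)
    np.testing.assert_allclose(base.mu, row, atol=1e-12)
    np.testing.assert_allclose(base.sigma, base.sigma_floor)


def test_k0_baseline_equals_plain_mean_sd(rng):
    ref = pd.DataFrame(rng.normal(size=(40, 30)))
    base = build_reference_baseline(ref, k_components=0)
    np.testing.assert_allclose(base.mu, ref.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(base.sigma, ref.std(axis=0, ddof=1), atol=1e-12)


def test_rank1_factor_is_removed_by_k1_baseline(rng):
    n, p = 60, 80
    loading = rng.normal(size=p)
    scores = rng.normal(size=n) * 2.0
    noise = rng.normal(scale=0.1, size=(n, p))
    ref = pd.DataFrame(np.outer(scores, loading) + noise)
    raw_sd = ref.std(axis=0, ddof=1).to_numpy()
    base = build_reference_baseline(ref, k_components=1)
    assert base.sigma.mean() < 0.25 * raw_sd.mean()


def test_baseline_parameter_validation(rng):
    ref = pd.DataFrame(rng.normal(size=(10, 20)))
    with pytest.raises(InvalidParameterError):
        build_reference_baseline(ref, k_components=10)
    with pytest.raises(InvalidInputError):
        build_reference_baseline(ref.iloc[:1])


# ---------------------------------------------------------------- denoising
def test_denoise_k0_is_identity(rng):
    ref = pd.DataFrame(rng.normal(size=(30, 40)))
    base = build_reference_baseline(ref, k_components=0)
    prof = Log2RatioProfile(rng.normal(size=40), np.ones(40, dtype=bool))
    out = pca_denoise(prof, base)
    np.testing.assert_allclose(out.x, prof.x, atol=1e-12)


def test_profile_in_component_span_is_annihilated(rng):
    ref = pd.DataFrame(rng.normal(size=(50, 60)))
    base = build_reference_baseline(ref, k_components=3)
    coefs = rng.normal(size=3)
    x = base.mu + coefs @ base.components
    out = pca_denoise(Log2RatioProfile(x, np.ones(60, dtype=bool)), base)
    assert np.max(np.abs(out.x - base.mu)) < 1e-10


def test_injected_latent_factor_is_decorrelated(rng):
    n, p = 100, 120
    loading = rng.normal(size=p)
    loading /= np.linalg.norm(loading)
    ref = pd.DataFrame(np.outer(rng.normal(size=n), loading) + rng.normal(scale=0.05, size=(n, p)))
    base = build_reference_baseline(ref, k_components=1)
    x = 3.0 * loading + rng.normal(scale=0.05, size=p)
    out = pca_denoise(Log2RatioProfile(x, np.ones(p, dtype=bool)), base)
    assert abs(np.corrcoef(out.x, loading)[0, 1]) < 0.1


# ---------------------------------------------------------------- Z scores
def test_z_formula(rng):
    p = 30
    mu = rng.normal(size=p)
    sigma = rng.uniform(0.5, 2.0, size=p)
    base = build_reference_baseline(pd.DataFrame(rng.normal(size=(10, p))), 0)
    base.mu, base.sigma = mu, sigma
    z0 = compute_z(Log2RatioProfile(mu.copy(), np.ones(p, bool)), base)
    np.testing.assert_allclose(z0, 0.0, atol=1e-12)
    z2 = compute_z(Log2RatioProfile(mu + 2 * sigma, np.ones(p, bool)), base)
    np.testing.assert_allclose(z2, 2.0, atol=1e-12)
    x = rng.normal(size=p)
    z = compute_z(Log2RatioProfile(x, np.ones(p, bool)), base)
    np.testing.assert_allclose(z, (x - mu) / sigma, atol=1e-12)


def test_masked_bins_get_zero_z(rng):
    p = 10
    base = build_reference_baseline(pd.DataFrame(rng.normal(size=(5, p))), 0)
    mask = np.ones(p, bool)
    mask[3] = False
    x = np.where(mask, rng.normal(size=p), np.nan)
    z = compute_z(Log2RatioProfile(x, mask), base)
    assert z[3] == 0.0


# ---------------------------------------------------- availability filter
def test_availability_inclusive_boundary():
    m = pd.DataFrame([[1, 0], [0, 0], [0, 0], [0, 0]])
    kept = filter_available_bins(m, min_sample_fraction=0.25)
    assert kept.tolist() == [0]  # 1/4 == 0.25 retained (inclusive)


def test_availability_matches_loop_oracle(rng):
    m = pd.DataFrame(rng.integers(0, 3, size=(15, 40)))
    kept = filter_available_bins(m, min_sample_fraction=0.4, min_reads=2)
    oracle = [
        j
        for j in range(40)
        if sum(m.iloc[i, j] >= 2 for i in range(15)) / 15 >= 0.4
    ]
    assert kept.tolist() == oracle


def test_availability_monotone_in_fraction(rng):
    m = pd.DataFrame(rng.integers(0, 2, size=(20, 60)))
    sizes = [
        len(filter_available_bins(m, min_sample_fraction=f))
        for f in (0.05, 0.25, 0.5, 0.9)
    ]
    assert sizes == sorted(sizes, reverse=True)
    with pytest.raises(InvalidInputError):
        filter_available_bins(pd.DataFrame())


# ---------------------------------------------------------------- pipeline
def test_pipeline_scale_invariance(small_cohort):
    cohort = small_cohort
    normals = [s for s in cohort.sample_ids if cohort.labels[s] == "non_malignant"]
    refs = normals[:25]
    target = [s for s in cohort.sample_ids if s not in set(refs)][0]
    res1 = cnv_feature_pipeline(cohort.bin_counts, cohort.bins, refs)
    scaled = cohort.bin_counts.copy()
    scaled.loc[target] = scaled.loc[target] * 7
    res2 = cnv_feature_pipeline(scaled, cohort.bins, refs)
    np.testing.assert_allclose(
        res1.z.loc[target].to_numpy(), res2.z.loc[target].to_numpy(), atol=1e-8
    )


def test_pipeline_reference_self_consistency(null_pipeline):
    """Reference samples scored against their own frozen baseline stay
    near-calibrated: per-bin mean Z around 0, SD inside [0.8, 1.2]."""
    _, result, reference_ids, _ = null_pipeline
    zr = result.z.loc[reference_ids].to_numpy()
    assert np.abs(zr.mean(axis=0)).max() < 0.1
    sd = zr.std(axis=0)
    assert sd.min() > 0.8 and sd.max() < 1.2


def test_pipeline_rejects_unknown_reference(small_cohort):
    with pytest.raises(InvalidInputError):
        cnv_feature_pipeline(
            small_cohort.bin_counts, small_cohort.bins, ["nope"]
        )
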