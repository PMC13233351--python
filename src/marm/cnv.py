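"""Window-level host CNV Z-score features from shallow-coverage bin counts.

The feature derivation follows the standard shallow-WGS recipe: tile the
genome into fixed-size windows, count host reads per window, normalize each
sample to a common library size, correct GC bias with a per-sample local
regression and mask low-mappability windows, express each window as a log2
ratio against the median of a non-malignant reference panel, remove shared
background structure by projecting out the top principal components of the
reference profiles, and standardize each window against the reference
mean/SD to obtain a Z score. Windows covered in too few samples are dropped
from the feature set.

Coordinates are 0-based half-open (BED convention); reads are assigned to
bins by leftmost position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "BinSet",
    "Log2RatioProfile",
    "ReferenceBaseline",
    "QCResult",
    "define_bins",
    "qc_sample",
    "count_reads_in_bins",
    "normalize_counts",
    "correct_gc_mappability",
    "compute_log2_ratio",
    "build_reference_baseline",
    "pca_denoise",
    "compute_z",
    "filter_available_bins",
    "cnv_feature_pipeline",
]

MIN_HOST_BASES = 5e6        # minimum host-derived bases for CNV modeling
MIN_COVERAGE = 0.05         # minimum effective host-genome coverage (fold)
DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class BinSet:
    """Ordered, non-overlapping genome windows with per-bin GC and mappability.

    ``table`` columns: chrom, start, end, gc, mappability. Bins must be
    sorted by (chrom order of first appearance, start) and non-overlapping
    within each chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"bin table missing columns: {sorted(missing)}")
        tab = self.table.reset_index(drop=True).copy()
        if "gc" not in tab.columns:
            tab["gc"] = np.nan
        if "mappability" not in tab.columns:
            tab["mappability"] = 1.0
        for chrom, grp in tab.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                raise InvalidInputError(f"{chrom}: empty or inverted bin")
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
                raise InvalidInputError(f"{chrom}: bins unsorted or overlapping")
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        """Bin identifiers in ``chrom:start-end`` form."""
        t = self.table
        return [f"{c}:{s}-{e}" for c, s, e in zip(t["chrom"], t["start"], t["end"])]

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(dtype=float)

    @property
    def mappability(self) -> np.ndarray:
        return self.table["mappability"].to_numpy(dtype=float)


@dataclass
class Log2RatioProfile:
    """Per-bin log2 coverage ratio with an availability mask.

    ``x`` holds the ratio; positions where ``mask`` is False carry no finite
    value requirement (they are NaN by convention) and are excluded from
    fitting and scoring.
    """

    x: np.ndarray
    mask: np.ndarray  # True = available

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.x.shape != self.mask.shape:
            raise InvalidInputError("profile and mask shapes differ")
        if not np.all(np.isfinite(self.x[self.mask])):
            raise InvalidInputError("unmasked bins must be finite")


@dataclass
class ReferenceBaseline:
    """Frozen per-bin null distribution of log2 ratios plus denoising axes.

    mu/sigma describe the non-malignant background; ``components`` (k x p,
    orthonormal rows) span the shared structure removed before Z scoring.
    """

    mu: np.ndarray
    sigma: np.ndarray
    components: np.ndarray
    k: int
    reference_sample_ids: list[str]
    sigma_floor: float = 1e-4
    bin_ids: list[str] | None = None
    explained_variance: np.ndarray | None = field(default=None, repr=False)


@dataclass
class QCResult:
    passed: bool
    reasons: list[str]


def define_bins(
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
) -> BinSet:
    """Tile chromosomes into non-overlapping fixed-size windows.

    Each chromosome contributes ``ceil(length / bin_size)`` bins; the last
    bin of a chromosome may be shorter. GRCh37 chr1-22,X,Y at 1 Mb yields
    3,113 bins.
    """
    if bin_size <= 0:
        raise InvalidParameterError(f"bin_size must be positive, got {bin_size}")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise InvalidParameterError(f"{chrom}: non-positive length {length}")
        n = math.ceil(length / bin_size)
        for i in range(n):
            rows.append((chrom, i * bin_size, min((i + 1) * bin_size, length)))
    tab = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if gc is not None:
        tab["gc"] = np.asarray(gc, dtype=float)
    if mappability is not None:
        tab["mappability"] = np.asarray(mappability, dtype=float)
    return BinSet(tab)


def qc_sample(host_bases: float, effective_coverage: float) -> QCResult:
    """Sample-level inclusion gate for CNV modeling.

    Passes iff the sample carries at least 5 Mb of host-derived bases and at
    least 0.05x effective host-genome coverage (both thresholds inclusive).
    """
    if host_bases < 0 or effective_coverage < 0:
        raise InvalidParameterError("host_bases and coverage must be non-negative")
    reasons = []
    if host_bases < MIN_HOST_BASES:
        reasons.append("low_host_bases")
    if effective_coverage < MIN_COVERAGE:
        reasons.append("low_coverage")
    return QCResult(passed=not reasons, reasons=reasons)


def _record_chrom_pos(rec) -> tuple[str | None, int, bool]:
    """Extract (chrom, leftmost pos, usable) from a tuple or pysam record."""
    if isinstance(rec, tuple):
        return rec[0], int(rec[1]), True
    # pysam.AlignedSegment
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
        return None, 0, False
    return rec.reference_name, int(rec.reference_start), True


def count_reads_in_bins(alignment_records, bins: BinSet) -> tuple[np.ndarray, int]:
    """Count primary mapped non-duplicate reads per bin by leftmost position.

    ``alignment_records`` is an iterable of ``(chrom, pos)`` tuples or pysam
    ``AlignedSegment`` objects. Returns (per-bin counts, unassigned tally);
    reads on contigs absent from the bin set, or beyond the last bin, go to
    the unassigned tally.
    """
    tab = bins.table
    starts_by_chrom: dict[str, np.ndarray] = {}
    offset_by_chrom: dict[str, int] = {}
    end_by_chrom: dict[str, int] = {}
    for chrom, grp in tab.groupby("chrom", sort=False):
        starts_by_chrom[chrom] = grp["start"].to_numpy()
        offset_by_chrom[chrom] = int(grp.index[0])
        end_by_chrom[chrom] = int(grp["end"].iloc[-1])
    counts = np.zeros(len(tab), dtype=np.int64)
    unassigned = 0
    for rec in alignment_records:
        chrom, pos, usable = _record_chrom_pos(rec)
        if not usable:
            continue
        starts = starts_by_chrom.get(chrom)
        if starts is None or pos < 0 or pos >= end_by_chrom[chrom]:
            unassigned += 1
            continue
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        counts[offset_by_chrom[chrom] + idx] += 1
    return counts, unassigned


def count_sam(path: str, bins: BinSet) -> tuple[np.ndarray, int]:
    """Count reads in bins from a coordinate-sorted SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(path) as fh:
        return count_reads_in_bins(fh, bins)


def normalize_counts(
    matrix: pd.DataFrame,
    mask: np.ndarray | None = None,
    scale: float = 1e6,
) -> pd.DataFrame:
    """Scale each sample so its total over unmasked bins equals ``scale``.

    Per-million scaling makes profiles comparable across library sizes.
    All-zero samples (over unmasked bins) are excluded with a warning rather
    than silently propagated.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InvalidInputError("empty coverage matrix")
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise InvalidInputError("coverage matrix contains negative values")
    if mask is None:
        mask = np.ones(matrix.shape[1], dtype=bool)
    totals = vals[:, mask].sum(axis=1)
    bad = totals <= 0
    if bad.any():
        dropped = list(matrix.index[bad])
        warnings.warn(f"excluding all-zero samples from normalization: {dropped}")
        matrix = matrix.loc[~bad]
        vals = vals[~bad]
        totals = totals[~bad]
    out = vals * (scale / totals)[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _loess_fit(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    """LOESS-style local linear fit of y on x, evaluated at x.

    ``delta`` skips refits at near-identical GC values (linear
    interpolation in between), the standard lowess speedup.
    """
    delta = 0.01 * (x.max() - x.min())
    grid = lowess(y, x, frac=span, delta=delta, return_sorted=True)
    return np.interp(x, grid[:, 0], grid[:, 1])


def correct_gc_mappability(
    matrix: pd.DataFrame,
    bins: BinSet,
    mappability_min: float = 0.8,
    loess_span: float = 0.3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample GC-bias correction plus mappability masking.

    Bins with mappability below ``mappability_min`` are masked (excluded
    from fitting and downstream scoring). For each sample a local regression
    of normalized coverage on bin GC is fit over unmasked bins; each bin is
    divided by the fitted value and the profile is rescaled to preserve the
    sample's pre-correction median. Returns (corrected matrix, mask).
    """
    if matrix.shape[1] != len(bins):
        raise InvalidInputError(
            f"matrix has {matrix.shape[1]} bins, bin set has {len(bins)}"
        )
    mask = bins.mappability >= mappability_min
    gc = bins.gc
    gc_ok = np.isfinite(gc)
    fit_mask = mask & gc_ok
    if fit_mask.sum() < 10:
        raise InvalidInputError("fewer than 10 unmasked bins with GC annotation")
    vals = matrix.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for i in range(vals.shape[0]):
        y = vals[i]
        fitted = _loess_fit(y[fit_mask], gc[fit_mask], loess_span)
        fitted = np.maximum(fitted, 1e-12)
        corr = np.full_like(y, np.nan)
        corr[fit_mask] = y[fit_mask] / fitted
        med_before = np.median(y[fit_mask])
        med_after = np.median(corr[fit_mask])
        if med_after > 0:
            corr[fit_mask] *= med_before / med_after
        out[i] = corr
    out[:, ~fit_mask] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), fit_mask


def compute_log2_ratio(
    sample_row: np.ndarray,
    baseline_median: np.ndarray,
    mask: np.ndarray | None = None,
) -> Log2RatioProfile:
    """log2 of corrected sample coverage over the reference per-bin median.

    Bins where the sample has zero (or masked) coverage, or where the
    reference median is non-positive, are masked for that sample rather
    than clamped.
    """
    sample_row = np.asarray(sample_row, dtype=float)
    baseline_median = np.asarray(baseline_median, dtype=float)
    if sample_row.shape != baseline_median.shape:
        raise InvalidInputError(
            f"sample has {sample_row.shape[0]} bins, baseline {baseline_median.shape[0]}"
        )
    if mask is None:
        mask = np.ones_like(sample_row, dtype=bool)
    ok = (
        np.asarray(mask, dtype=bool)
        & np.isfinite(sample_row)
        & (sample_row > 0)
        & np.isfinite(baseline_median)
        & (baseline_median > 0)
    )
    x = np.full_like(sample_row, np.nan)
    x[ok] = np.log2(sample_row[ok] / baseline_median[ok])
    return Log2RatioProfile(x=x, mask=ok)


def _centered_imputed(ref: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Center reference profiles on mu; missing entries become 0 (the mean)."""
    centered = ref - mu[None, :]
    centered[~np.isfinite(centered)] = 0.0
    return centered


def _top_components(centered: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(k x p orthonormal principal axes, all covariance eigenvalues).

    Works on the n x n Gram matrix when n < p, which is the common shape
    here (a few hundred reference samples over a few thousand bins).
    """
    n, p = centered.shape
    if n < p:
        gram = centered @ centered.T
        w, u = np.linalg.eigh(gram)
        w = np.clip(w[::-1], 0.0, None)
        u = u[:, ::-1]
        eig = w / max(n - 1, 1)
        if k == 0:
            return np.empty((0, p)), eig
        s = np.sqrt(w[:k])
        s = np.where(s > 1e-12, s, 1.0)
        vt = (centered.T @ u[:, :k] / s).T
        return vt, eig
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    return vt[:k], eig


def build_reference_baseline(
    reference_log2: pd.DataFrame,
    k_components: int | str = "auto",
    sigma_floor: float = 1e-4,
) -> ReferenceBaseline:
    """Fit the frozen non-malignant baseline: per-bin mu/sigma + denoising axes.

    PCA is fit on the column-centered reference log2 matrix (missing entries
    imputed at the column mean). ``k_components="auto"`` keeps components
    whose eigenvalue exceeds the mean eigenvalue (Kaiser-type rule), capped
    at 10. mu is the per-bin mean; sigma is the per-bin SD of denoising
    residuals, estimated leave-one-out when k > 0 so that it reflects the
    residual noise of a profile *not* used to fit the components — the same
    situation a test sample is in. With k = 0 sigma is the plain column SD.
    sigma is floored at ``sigma_floor``.
    """
    n_ref, p = reference_log2.shape
    if n_ref < 2:
        raise InvalidInputError("need at least 2 reference samples")
    if n_ref < 30:
        warnings.warn(f"only {n_ref} reference samples; sigma estimates will be noisy")
    ref = reference_log2.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(ref, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    centered = _centered_imputed(ref, mu)

    max_rank = min(n_ref - 1, p)
    if k_components == "auto":
        _, eig = _top_components(centered, 0)
        thresh = eig.mean() if eig.size else 0.0
        k = int(min(10, np.sum(eig > thresh)))
    else:
        k = int(k_components)
        if k < 0:
            raise InvalidParameterError("k_components must be >= 0")
        if k >= n_ref:
            raise InvalidParameterError(
                f"k_components={k} must be < n_reference={n_ref}"
            )
        k = min(k, max_rank)

    components, eig = _top_components(centered, k)

    if k == 0:
        sigma = np.std(centered, axis=0, ddof=1)
    else:
        # Leave-one-out residuals: refit the top-k axes without sample i,
        # then project sample i out. Matches how a held-out sample is scored.
        resid = np.empty_like(centered)
        idx = np.arange(n_ref)
        for i in range(n_ref):
            others = centered[idx != i]
            mu_o = others.mean(axis=0)
            vt_i, _ = _top_components(others - mu_o[None, :], k)
            xc = centered[i] - mu_o
            resid[i] = xc - vt_i.T @ (vt_i @ xc)
        sigma = np.sqrt(np.mean(resid**2, axis=0) * n_ref / max(n_ref - 1, 1))
    sigma = np.maximum(sigma, sigma_floor)
    return ReferenceBaseline(
        mu=mu,
        sigma=sigma,
        components=components,
        k=k,
        reference_sample_ids=list(reference_log2.index),
        sigma_floor=sigma_floor,
        bin_ids=list(reference_log2.columns),
        explained_variance=eig,
    )


def pca_denoise(profile: Log2RatioProfile, baseline: ReferenceBaseline) -> Log2RatioProfile:
    """Remove the component of a profile lying in the reference PC span.

    Returns x - P(x - mu) - projection residual re-offset by mu, i.e. the
    profile with shared background structure subtracted. Masked bins are
    imputed to the baseline mean for the projection only and stay masked.
    """
    if profile.x.shape[0] != baseline.mu.shape[0]:
        raise InvalidInputError("profile/baseline dimension mismatch")
    if baseline.k == 0:
        return Log2RatioProfile(x=profile.x.copy(), mask=profile.mask.copy())
    xc = profile.x - baseline.mu
    xc = np.where(profile.mask & np.isfinite(xc), xc, 0.0)
    v = baseline.components
    resid = xc - v.T @ (v @ xc)
    out = np.full_like(profile.x, np.nan)
    out[profile.mask] = (resid + baseline.mu)[profile.mask]
    return Log2RatioProfile(x=out, mask=profile.mask.copy())


def compute_z(profile: Log2RatioProfile, baseline: ReferenceBaseline) -> np.ndarray:
    """Per-bin Z score: (x - mu) / sigma against the frozen baseline.

    Masked bins yield Z = 0 ("no deviation") so downstream feature matrices
    stay finite; this neutral imputation is documented behavior.
    """
    if profile.x.shape[0] != baseline.mu.shape[0]:
        raise InvalidInputError("profile/baseline dimension mismatch")
    z = np.zeros_like(profile.x)
    m = profile.mask
    z[m] = (profile.x[m] - baseline.mu[m]) / baseline.sigma[m]
    return z


def filter_available_bins(
    raw_counts: pd.DataFrame,
    min_sample_fraction: float = 0.25,
    min_reads: int = 1,
) -> np.ndarray:
    """Indices of bins covered (count >= min_reads) in enough samples.

    A bin is retained iff the fraction of samples in which it is available
    is at least ``min_sample_fraction`` (inclusive). Indices are sorted.
    """
    if raw_counts.shape[0] == 0 or raw_counts.shape[1] == 0:
        raise InvalidInputError("empty count matrix")
    if not 0 < min_sample_fraction <= 1:
        raise InvalidParameterError("min_sample_fraction must be in (0, 1]")
    vals = raw_counts.to_numpy()
    frac = (vals >= min_reads).mean(axis=0)
    return np.flatnonzero(frac >= min_sample_fraction)


@dataclass
class CnvFeatureResult:
    """Output bundle of the CNV feature pipeline."""

    z: pd.DataFrame                  # samples x retained bins
    baseline: ReferenceBaseline
    retained_bins: np.ndarray        # indices into the BinSet
    mask: np.ndarray                 # mappability/GC mask over all bins
    bins: BinSet


def cnv_feature_pipeline(
    raw: pd.DataFrame,
    bins: BinSet,
    reference_ids: list[str],
    k_components: int | str = "auto",
    min_sample_fraction: float = 0.25,
    min_reads: int = 1,
    mappability_min: float = 0.8,
    loess_span: float = 0.3,
    sigma_floor: float = 1e-4,
) -> CnvFeatureResult:
    """Full feature derivation: normalize -> GC/mappability correct ->
    reference baseline -> log2 -> PCA denoise -> Z -> availability filter.

    The baseline (median, mu, sigma, components) is fit ONLY on
    ``reference_ids`` and then frozen; every sample, reference included, is
    scored against it. Returns Z scores restricted to retained bins.
    """
    reference_ids = list(reference_ids)
    missing = [s for s in reference_ids if s not in raw.index]
    if missing:
        raise InvalidInputError(f"reference ids not in matrix: {missing[:5]}")
    if raw.shape[1] != len(bins):
        raise InvalidInputError("count matrix / bin set dimension mismatch")

    map_mask = bins.mappability >= mappability_min
    norm = normalize_counts(raw, mask=map_mask)
    corrected, mask = correct_gc_mappability(
        norm, bins, mappability_min=mappability_min, loess_span=loess_span
    )

    ref_corr = corrected.loc[reference_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        baseline_median = np.nanmedian(ref_corr.to_numpy(), axis=0)

    profiles = {
        sid: compute_log2_ratio(corrected.loc[sid].to_numpy(), baseline_median, mask)
        for sid in corrected.index
    }
    ref_log2 = pd.DataFrame(
        {sid: profiles[sid].x for sid in reference_ids}, index=corrected.columns
    ).T
    baseline = build_reference_baseline(
        ref_log2, k_components=k_components, sigma_floor=sigma_floor
    )

    z_rows = {}
    for sid, prof in profiles.items():
        den = pca_denoise(prof, baseline)
        z_rows[sid] = compute_z(den, baseline)
    z = pd.DataFrame.from_dict(z_rows, orient="index", columns=corrected.columns)
    z = z.loc[corrected.index]

    avail = filter_available_bins(
        raw.loc[corrected.index], min_sample_fraction=min_sample_fraction, min_reads=min_reads
    )
    retained = np.array([i for i in avail if mask[i]], dtype=int)
    z = z.iloc[:, retained]
    return CnvFeatureResult(
        z=z, baseline=baseline, retained_bins=retained, mask=mask, bins=bins
    )
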