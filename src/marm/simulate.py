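"""Synthetic admixed BALF-mNGS-like cohorts with known ground truth.

The generator starts at per-bin host read counts (no read-level
simulation): each sample draws negative-binomial counts around
``mean_reads_per_bin``, modulated by a library-size factor, a unimodal GC
bias curve, a low-rank multiplicative batch term exp(A @ F), and — in
malignant samples — a copy-number multiplier diluted by tumor fraction.
Microbial species counts are sparse and overdispersed: each species has a
random prevalence, present cells are negative-binomial. Weakly labeled
samples carry a hidden true malignancy status (the biology that drives
their counts) plus a noisy clinical flag, so pseudo-label purity is
measurable.

Copy-number dilution: a segment at copy number ``cn`` in a sample with
tumor fraction ``tf`` multiplies expected coverage by
``m = (1 - tf) + tf * cn / 2`` (diploid background mixed with tumor DNA).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import BinSet
from .errors import InvalidParameterError

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "expected_multiplier",
    "simulate_bins",
    "simulate_cohort",
    "simulate_microbiome",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort generator.

    Defaults emulate a shallow (~0.05-1x, 50-bp single-end scale) BALF mNGS
    cohort: ~1000 reads per 1-Mb window (the 0.05x coverage floor at 50 bp),
    mild NB overdispersion,
    a moderate GC bias and weak shared batch structure, CNV gains/losses
    diluted by tumor fraction, and sparse overdispersed species counts.
    """

    n_samples: int = 200
    malignant_fraction: float = 0.3
    n_weak: int = 0
    n_bins: int = 500
    tumor_fraction_range: tuple[float, float] = (0.2, 0.8)
    n_cnv_segments: int = 3
    segment_length_bins: int = 20
    mean_reads_per_bin: float = 1000.0
    library_size_sd: float = 0.2          # lognormal sigma of library-size factor
    gc_bias_strength: float = 0.6
    n_latent_factors: int = 3
    latent_factor_sd: float = 0.05
    nb_dispersion: float = 1000.0          # NB size; inf -> Poisson
    n_species: int = 150
    species_prevalence_range: tuple[float, float] = (0.05, 0.6)
    species_mean_reads: float = 200.0
    species_nb_dispersion: float = 0.5
    species_effect: float = 0.0            # log abundance shift in malignant samples
    n_affected_species: int = 0
    weak_label_noise: float = 0.1
    copy_numbers: tuple[int, ...] = (0, 1, 3, 4)
    segment_positions: tuple[int, ...] | None = None  # fixed start bins, optional
    low_mappability_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("malignant_fraction", "weak_label_noise", "low_mappability_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        for name in ("tumor_fraction_range", "species_prevalence_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise InvalidParameterError(f"{name}=({lo}, {hi}) invalid")
        for name in ("n_samples", "n_weak", "n_bins", "n_cnv_segments",
                     "segment_length_bins", "n_species", "n_affected_species"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        for name in ("mean_reads_per_bin", "nb_dispersion", "species_nb_dispersion",
                     "latent_factor_sd"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if any(cn < 0 for cn in self.copy_numbers):
            raise InvalidParameterError("copy numbers must be non-negative")


@dataclass
class SyntheticCohort:
    """Generated cohort: counts, labels, and the ground truth behind them."""

    bins: BinSet
    bin_counts: pd.DataFrame            # samples x bins, integers
    species_counts: pd.DataFrame        # species x samples, integers
    labels: pd.Series                   # {malignant, non_malignant, weak}
    hidden_truth: pd.Series             # true status of weak samples
    weak_flags: pd.Series               # noisy clinical suspicion flag for weak samples
    truth_segments: pd.DataFrame        # sample, chrom, start_bin, end_bin, copy_number, tumor_fraction
    latent_factors: pd.DataFrame        # samples x factors
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bin_counts.index)

    def write(self, outdir: str | Path) -> None:
        """Write the cohort as diff-able flat files (TSV + JSON config)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bin_counts.to_csv(out / "bin_counts.tsv", sep="\t")
        self.species_counts.to_csv(out / "species_counts.tsv", sep="\t")
        lab = self.labels.rename("label").to_frame()
        lab["hidden_truth"] = self.hidden_truth.reindex(lab.index)
        lab.index.name = "sample_id"
        lab.to_csv(out / "labels.tsv", sep="\t")
        tab = self.bins.table
        seg = self.truth_segments.copy()
        if len(seg):
            seg["start"] = tab["start"].to_numpy()[seg["start_bin"]]
            seg["end"] = tab["end"].to_numpy()[seg["end_bin"] - 1]
        cols = ["chrom", "start", "end", "sample", "copy_number", "tumor_fraction"]
        (seg[cols] if len(seg) else pd.DataFrame(columns=cols)).to_csv(
            out / "truth_segments.tsv", sep="\t", index=False
        )
        tab.to_csv(out / "bins.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list))


def expected_multiplier(copy_number: int, tumor_fraction: float) -> float:
    """Expected coverage multiplier of a CNV segment under admixture dilution.

    m = (1 - tf) + tf * cn / 2: a diploid background mixed with a tumor
    fraction ``tf`` carrying ``cn`` copies. m = 1 whenever cn = 2 or tf = 0.
    """
    if copy_number < 0:
        raise InvalidParameterError(f"copy_number must be >= 0, got {copy_number}")
    if not 0 <= tumor_fraction <= 1:
        raise InvalidParameterError(f"tumor_fraction={tumor_fraction} outside [0, 1]")
    return (1.0 - tumor_fraction) + tumor_fraction * copy_number / 2.0


def simulate_bins(config: SimulationConfig, rng: np.random.Generator) -> BinSet:
    """Synthetic 1-Mb tiling of one chromosome with GC and mappability."""
    n = config.n_bins
    gc = np.clip(rng.normal(0.45, 0.07, size=n), 0.25, 0.70)
    mappability = rng.uniform(0.85, 1.0, size=n)
    n_low = int(round(config.low_mappability_fraction * n))
    if n_low:
        low = rng.choice(n, size=n_low, replace=False)
        mappability[low] = rng.uniform(0.3, 0.79, size=n_low)
    tab = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(n, dtype=np.int64) * 1_000_000,
            "end": (np.arange(n, dtype=np.int64) + 1) * 1_000_000,
            "gc": gc,
            "mappability": mappability,
        }
    )
    return BinSet(tab)


def _gc_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    # unimodal log-quadratic bias centered at GC 0.45; strength 0 -> flat
    return np.exp(-strength * ((gc - 0.45) / 0.15) ** 2)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if not np.isfinite(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, np.clip(p, 1e-12, 1.0))


def _place_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int, int, float]]:
    """Draw (start_bin, end_bin, cn, tf) segments for one malignant sample."""
    L = config.segment_length_bins
    tf = rng.uniform(*config.tumor_fraction_range)
    segs = []
    if config.segment_positions is not None:
        starts = list(config.segment_positions)
    else:
        starts: list[int] = []
        occupied = np.zeros(config.n_bins, dtype=bool)
        for _ in range(config.n_cnv_segments):
            for _attempt in range(50):
                s = int(rng.integers(0, max(config.n_bins - L, 1)))
                if not occupied[s : s + L].any():
                    occupied[s : s + L] = True
                    starts.append(s)
                    break
    for s in starts:
        cn = int(rng.choice(config.copy_numbers))
        segs.append((s, min(s + L, config.n_bins), cn, tf))
    return segs


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort (bin counts, species counts, labels, truth).

    Deterministic: the same config (including seed) reproduces the cohort
    bit for bit. Exactly ``round(n_samples * malignant_fraction)`` of the
    labeled samples are malignant; weak samples draw their hidden status
    from the same malignant fraction.
    """
    config.validate()
    if config.n_samples <= 0 or config.n_bins <= 0:
        raise InvalidParameterError("n_samples and n_bins must be positive")
    rng = np.random.default_rng([config.seed, 0])
    bins = simulate_bins(config, rng)

    n_lab, n_weak = config.n_samples, config.n_weak
    n_total = n_lab + n_weak
    n_mal = int(round(n_lab * config.malignant_fraction))
    labeled_ids = [f"S{i:04d}" for i in range(n_lab)]
    weak_ids = [f"W{i:04d}" for i in range(n_weak)]
    sample_ids = labeled_ids + weak_ids

    status = np.zeros(n_total, dtype=bool)  # True = biologically malignant
    mal_idx = rng.choice(n_lab, size=n_mal, replace=False)
    status[mal_idx] = True
    if n_weak:
        status[n_lab:] = rng.random(n_weak) < config.malignant_fraction

    labels = pd.Series(
        ["malignant" if status[i] else "non_malignant" for i in range(n_lab)]
        + ["weak"] * n_weak,
        index=sample_ids,
        name="label",
    )
    hidden = pd.Series(
        ["malignant" if s else "non_malignant" for s in status[n_lab:]],
        index=weak_ids,
        name="hidden_truth",
        dtype=object,
    )
    flags = hidden.copy().rename("weak_flag")
    if n_weak and config.weak_label_noise > 0:
        flip = rng.random(n_weak) < config.weak_label_noise
        flipped = np.where(
            flip,
            np.where(hidden.to_numpy() == "malignant", "non_malignant", "malignant"),
            hidden.to_numpy(),
        )
        flags = pd.Series(flipped, index=weak_ids, name="weak_flag")

    # expected-count surface
    gc_mult = _gc_curve(bins.gc, config.gc_bias_strength)
    lib = np.exp(
        rng.normal(-config.library_size_sd**2 / 2, config.library_size_sd, size=n_total)
    )
    k = config.n_latent_factors
    if k > 0:
        A = rng.normal(0.0, config.latent_factor_sd, size=(n_total, k))
        F = rng.normal(0.0, 1.0, size=(k, config.n_bins))
        latent_mult = np.exp(A @ F)
        latent = pd.DataFrame(A, index=sample_ids, columns=[f"F{j}" for j in range(k)])
    else:
        latent_mult = np.ones((n_total, config.n_bins))
        latent = pd.DataFrame(index=sample_ids)

    cn_mult = np.ones((n_total, config.n_bins))
    seg_rows = []
    for i in range(n_total):
        if not status[i]:
            continue
        for s, e, cn, tf in _place_segments(config, rng):
            cn_mult[i, s:e] *= expected_multiplier(cn, tf)
            seg_rows.append((sample_ids[i], "chrS", s, e, cn, tf))
    truth = pd.DataFrame(
        seg_rows,
        columns=["sample", "chrom", "start_bin", "end_bin", "copy_number", "tumor_fraction"],
    )

    mean = (
        config.mean_reads_per_bin
        * lib[:, None]
        * gc_mult[None, :]
        * latent_mult
        * cn_mult
    )
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    bin_counts = pd.DataFrame(counts, index=sample_ids, columns=bins.ids)

    species = simulate_microbiome(config, labels=None, _status=status, _ids=sample_ids)

    return SyntheticCohort(
        bins=bins,
        bin_counts=bin_counts,
        species_counts=species,
        labels=labels,
        hidden_truth=hidden,
        weak_flags=flags,
        truth_segments=truth,
        latent_factors=latent,
        config=config,
    )


def simulate_microbiome(
    config: SimulationConfig,
    labels: pd.Series | None = None,
    _status: np.ndarray | None = None,
    _ids: list[str] | None = None,
) -> pd.DataFrame:
    """Species x sample count matrix: random prevalence, NB abundance.

    Each species draws a prevalence from ``species_prevalence_range`` and a
    lognormal mean abundance; present cells are negative-binomial with size
    ``species_nb_dispersion`` (heavily overdispersed by default), absent
    cells are zero. If ``species_effect`` > 0, the first
    ``n_affected_species`` species have their log mean shifted by that
    amount in malignant samples (for power studies); with the default
    effect of 0 the matrix is label-independent.

    Deterministic given the config seed; uses a stream independent of the
    bin-count draw so the same species matrix arises whether called alone
    or from :func:`simulate_cohort`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    if _ids is None:
        n_total = config.n_samples + config.n_weak
        _ids = [f"S{i:04d}" for i in range(config.n_samples)] + [
            f"W{i:04d}" for i in range(config.n_weak)
        ]
    else:
        n_total = len(_ids)
    if _status is None:
        if labels is not None:
            _status = (labels.reindex(_ids).to_numpy() == "malignant")
        else:
            _status = np.zeros(n_total, dtype=bool)

    S = config.n_species
    species_names = [f"species_{j:04d}" for j in range(S)]
    if S == 0:
        return pd.DataFrame(
            np.zeros((0, n_total), dtype=np.int64), index=species_names, columns=_ids
        )
    prev = rng.uniform(*config.species_prevalence_range, size=S)
    log_mean = rng.normal(np.log(config.species_mean_reads), 1.0, size=S)
    present = rng.random((S, n_total)) < prev[:, None]
    mean = np.exp(log_mean)[:, None] * np.ones((S, n_total))
    if config.species_effect > 0 and config.n_affected_species > 0:
        aff = min(config.n_affected_species, S)
        mean[:aff, :] *= np.where(_status[None, :], np.exp(config.species_effect), 1.0)
    counts = _nb_draw(rng, mean, config.species_nb_dispersion)
    counts = np.where(present, counts, 0)
    return pd.DataFrame(counts.astype(np.int64), index=species_names, columns=_ids)
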