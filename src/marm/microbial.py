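"""Species-level microbial feature matrix and diversity summaries.

Consumes Kraken2-style species reports (or a species x sample count
matrix) and applies two rules before modeling: a species counts as
*positively detected* in a sample only when its read count strictly
exceeds a detection minimum (default 2 reads, guarding against background
contamination and read misassignment at shallow depth), and a species is
*retained* as a feature only when it is positive in at least a prevalence
cutoff fraction of samples (default 10%, inclusive). Feature values are
raw read counts; no normalization is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .errors import InvalidInputError, InvalidParameterError, ParseError, UndefinedMetricError

__all__ = [
    "MicrobialFeatureMatrix",
    "parse_species_report",
    "read_reports_dir",
    "detect_positive",
    "prevalence_filter",
    "shannon_index",
    "species_richness",
    "diversity_summary",
]

DETECTION_MIN_READS = 2     # positive iff count strictly exceeds this
PREVALENCE_CUTOFF = 0.10    # retained iff positive in >= this fraction of samples


@dataclass
class MicrobialFeatureMatrix:
    """Retained species x sample read counts plus the filter settings used."""

    counts: pd.DataFrame            # retained species x samples
    prevalence_cutoff: float
    detection_min_reads: int

    @property
    def retained_species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def as_features(self) -> pd.DataFrame:
        """Samples x species orientation for the classifier harness."""
        return self.counts.T


def parse_species_report(report_file: str | Path) -> dict[str, int]:
    """Species-level clade read counts from one Kraken2-style report.

    Expects tab-separated lines: percent, clade_reads, direct_reads,
    [minimizer columns,] rank code, taxid, indented name. Only rank code
    "S" rows are kept; the count is the clade read total (subspecies
    included). Malformed lines raise :class:`ParseError` with the line
    number.
    """
    out: dict[str, int] = {}
    with open(report_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) not in (6, 8):
                raise ParseError(
                    f"expected 6 or 8 tab-separated fields, got {len(fields)}", lineno
                )
            rank = fields[-3].strip()
            try:
                clade_reads = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"non-integer clade read count {fields[1]!r}", lineno) from exc
            if rank == "S":
                out[fields[-1].strip()] = clade_reads
    return out


def read_reports_dir(directory: str | Path, pattern: str = "*.txt") -> pd.DataFrame:
    """Species x sample count matrix from a directory of report files.

    Sample id = file stem; species missing from a report get count 0.
    """
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise InvalidInputError(f"no report files matching {pattern!r} in {directory}")
    per_sample = {f.stem: parse_species_report(f) for f in files}
    table = pd.DataFrame(per_sample).fillna(0).astype(np.int64)
    table.index.name = "species"
    return table.sort_index()


def detect_positive(count: int, min_reads: int = DETECTION_MIN_READS) -> bool:
    """Positive detection iff the read count strictly exceeds ``min_reads``."""
    if count < 0:
        raise InvalidParameterError("read count must be non-negative")
    return count > min_reads


def prevalence_filter(
    table: pd.DataFrame,
    cutoff: float = PREVALENCE_CUTOFF,
    detection_min_reads: int = DETECTION_MIN_READS,
) -> MicrobialFeatureMatrix:
    """Drop species positively detected in fewer than ``cutoff`` of samples.

    ``table`` is species x samples. The retention rule is inclusive:
    positive-fraction >= cutoff keeps the species. Counts pass through
    unchanged, so the filter is idempotent.
    """
    if not 0 < cutoff <= 1:
        raise InvalidParameterError(f"cutoff={cutoff} outside (0, 1]")
    if table.shape[1] < 1:
        raise InvalidInputError("need at least one sample")
    positive = table.to_numpy() > detection_min_reads
    frac = positive.mean(axis=1)
    keep = frac >= cutoff
    return MicrobialFeatureMatrix(
        counts=table.loc[keep].copy(),
        prevalence_cutoff=cutoff,
        detection_min_reads=detection_min_reads,
    )


def shannon_index(sample_counts: np.ndarray | pd.Series, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over species with count > 0.

    Natural log by default (values of ~3-4 over hundreds of species are on
    the nats scale).
    """
    counts = np.asarray(sample_counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0 or counts.sum() <= 0:
        raise UndefinedMetricError("Shannon index undefined for an all-zero sample")
    return float(entropy(counts, base=base))


def species_richness(sample_counts: np.ndarray | pd.Series, min_reads: int = 0) -> int:
    """Number of species with count strictly greater than ``min_reads``."""
    counts = np.asarray(sample_counts)
    return int((counts > min_reads).sum())


def diversity_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index and richness from a species x sample table."""
    rows = {}
    for sid in table.columns:
        col = table[sid].to_numpy()
        h = shannon_index(col) if (col > 0).any() else np.nan
        rows[sid] = {"shannon": h, "richness": species_richness(col)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
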