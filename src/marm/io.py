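"""Flat-file readers/writers: TSV matrices, labels, bins, chromosome lengths.

Canonical tabular dialect: tab-separated, UTF-8, header row, '.' decimal.
All readers validate shape and value constraints and raise
:class:`~marm.errors.SchemaError` with row/column context; writers
round-trip bit-exactly for integer matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import BinSet, ReferenceBaseline
from .errors import InvalidInputError, SchemaError

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_labels",
    "write_labels",
    "read_bins_tsv",
    "write_bins_tsv",
    "read_chrom_lengths",
    "write_baseline",
    "read_baseline",
]


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix (first column = row ids, header = column ids).

    Values must be non-negative numbers; duplicate ids, ragged rows and
    empty files are schema errors with location context.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise InvalidInputError(f"{path}: no data rows")
    if df.index.duplicated().any():
        dup = list(df.index[df.index.duplicated()])
        raise SchemaError(f"{path}: duplicate row ids {dup[:5]}")
    if df.columns.duplicated().any():
        dup = list(df.columns[df.columns.duplicated()])
        raise SchemaError(f"{path}: duplicate column ids {dup[:5]}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        raise SchemaError(f"{path}: non-numeric column {non_numeric[0]!r}")
    if (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise SchemaError(
            f"{path}: negative value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    """Labels TSV: columns sample_id, label (extra columns preserved as attrs)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = list(df["sample_id"][df["sample_id"].duplicated()])
        raise SchemaError(f"{path}: duplicate sample ids {dup[:5]}")
    s = df.set_index("sample_id")["label"]
    s.attrs["extra"] = df.set_index("sample_id").drop(columns="label")
    return s


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("label").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_bins_tsv(path: str | Path) -> BinSet:
    """BED-like bin annotation: chrom, start, end[, gc, mappability]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return BinSet(df)


def write_bins_tsv(bins: BinSet, path: str | Path) -> None:
    bins.table.to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column chrom/length TSV; FASTA .fai (5 columns) also accepted."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                out[fields[0].strip()] = int(fields[1])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-integer length") from exc
    if not out:
        raise InvalidInputError(f"{path}: no chromosomes")
    return out


def write_baseline(baseline: ReferenceBaseline, outdir: str | Path) -> None:
    """Persist a reference baseline as a flat-file bundle (TSV + JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bin_ids = baseline.bin_ids or [str(i) for i in range(len(baseline.mu))]
    pd.DataFrame(
        {"bin_id": bin_ids, "mu": baseline.mu, "sigma": baseline.sigma}
    ).to_csv(out / "baseline_mu_sigma.tsv", sep="\t", index=False)
    comp = pd.DataFrame(
        baseline.components,
        index=[f"PC{i + 1}" for i in range(baseline.k)],
        columns=bin_ids,
    )
    comp.to_csv(out / "baseline_components.tsv", sep="\t")
    meta = {
        "k": baseline.k,
        "sigma_floor": baseline.sigma_floor,
        "reference_sample_ids": baseline.reference_sample_ids,
    }
    (out / "baseline_meta.json").write_text(json.dumps(meta, indent=2))


def read_baseline(outdir: str | Path) -> ReferenceBaseline:
    out = Path(outdir)
    ms = pd.read_csv(out / "baseline_mu_sigma.tsv", sep="\t")
    comp = pd.read_csv(out / "baseline_components.tsv", sep="\t", index_col=0)
    meta = json.loads((out / "baseline_meta.json").read_text())
    return ReferenceBaseline(
        mu=ms["mu"].to_numpy(),
        sigma=ms["sigma"].to_numpy(),
        components=comp.to_numpy(dtype=float).reshape(meta["k"], len(ms)),
        k=meta["k"],
        reference_sample_ids=meta["reference_sample_ids"],
        sigma_floor=meta["sigma_floor"],
        bin_ids=list(ms["bin_id"].astype(str)),
    )
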