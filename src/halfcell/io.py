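"""Reading and validation of abundance tables and half-cell pairing metadata.

Expression values are transcripts per million (TPM) as produced by kallisto's
``abundance.tsv`` (columns ``target_id, length, eff_length, est_counts, tpm``).
Gene identifiers are opaque strings matched exactly; a TPM of 0 is legal and no
pseudo-count is added at I/O time.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "read_kallisto_abundance",
    "write_kallisto_abundance",
    "read_tpm_matrix",
    "read_sample_sheet",
    "assemble_matrix",
    "validate_pairing",
    "write_table",
]

SHEET_COLUMNS = ("sample_id", "pair_id", "half", "condition", "batch")
HALVES = ("A", "P")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Input data violates a structural contract (duplicates, mismatched sets...)."""


def read_kallisto_abundance(path: str | os.PathLike) -> pd.Series:
    """Read one kallisto ``abundance.tsv`` and return TPM keyed by target_id.

    Order of rows is preserved. Raises :class:`FormatError` when a required
    column is missing, and :class:`ValidationError` on non-numeric TPM entries
    (reported with their 1-based line number) or duplicated identifiers.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("target_id", "tpm"):
        if column not in table.columns:
            raise FormatError(
                f"{path}: missing required column {column!r} "
                f"(found {list(table.columns)})"
            )
    tpm = pd.to_numeric(table["tpm"], errors="coerce")
    bad = tpm.index[tpm.isna() & table["tpm"].notna()]
    if len(bad) > 0:
        # +2: one for the header line, one for 1-based numbering.
        line = int(bad[0]) + 2
        raise ValidationError(
            f"{path}: non-numeric tpm value {table['tpm'].iloc[bad[0]]!r} "
            f"on line {line}"
        )
    if table["tpm"].isna().any():
        line = int(table.index[table["tpm"].isna()][0]) + 2
        raise ValidationError(f"{path}: empty tpm value on line {line}")
    ids = table["target_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate target_id values: {dupes[:5]}")
    out = pd.Series(tpm.to_numpy(dtype=float), index=pd.Index(ids, name="target_id"))
    out.name = "tpm"
    return out


def write_kallisto_abundance(
    path: str | os.PathLike, tpm: pd.Series, length: int = 1000
) -> None:
    """Write a TPM vector in the kallisto ``abundance.tsv`` dialect.

    ``length``/``eff_length`` are filler (the pipeline is TPM-based) and
    ``est_counts`` is set proportional to TPM so the file is self-consistent.
    """
    frame = pd.DataFrame(
        {
            "target_id": tpm.index,
            "length": length,
            "eff_length": length,
            "est_counts": tpm.to_numpy(dtype=float),
            "tpm": tpm.to_numpy(dtype=float),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_tpm_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a combined genes x samples TPM matrix (first column = gene id)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene identifiers")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative TPM values")
    matrix.index.name = "gene_id"
    return matrix


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet (TSV or CSV by extension) describing half-samples.

    Required columns: sample_id, pair_id, half, condition. ``batch`` is
    optional and defaults to an empty string.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in SHEET_COLUMNS[:4] if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    if "batch" not in sheet.columns:
        sheet["batch"] = ""
    sheet["batch"] = sheet["batch"].fillna("")
    return sheet[list(SHEET_COLUMNS)]


def validate_pairing(sheet: pd.DataFrame) -> list[str]:
    """Check the anterior/posterior pairing structure of a sample sheet.

    Returns a list of human-readable violations; an empty list means valid.
    Violations are data, not exceptions: every pair_id must have exactly one A
    and one P half, both sharing condition and batch, and sample ids must be
    unique.
    """
    violations: list[str] = []
    if sheet["sample_id"].duplicated().any():
        for sid in sheet["sample_id"][sheet["sample_id"].duplicated()].unique():
            violations.append(f"duplicate sample_id {sid!r}")
    bad_half = sheet.loc[~sheet["half"].isin(HALVES), "sample_id"]
    for sid in bad_half:
        violations.append(f"sample {sid!r}: half must be one of {HALVES}")
    for pair_id, group in sheet.groupby("pair_id", sort=False):
        for half in HALVES:
            n = int((group["half"] == half).sum())
            if n > 1:
                violations.append(f"duplicate half {half} for pair {pair_id!r}")
            elif n == 0:
                other = "posterior" if half == "P" else "anterior"
                violations.append(f"pair {pair_id!r}: missing {other} half")
        if group["condition"].nunique() > 1:
            violations.append(f"pair {pair_id!r}: halves disagree on condition")
        if group["batch"].nunique() > 1:
            violations.append(f"pair {pair_id!r}: halves disagree on batch")
    return violations


def assemble_matrix(
    files: Mapping[str, str | os.PathLike] | Sequence[str | os.PathLike],
    sheet: pd.DataFrame,
    intersect: bool = False,
) -> pd.DataFrame:
    """Assemble per-half-sample abundance files into a genes x samples matrix.

    ``files`` maps sample_id -> abundance.tsv path (or is a sequence aligned
    with the sheet rows). Column order follows the sample sheet, so the result
    is invariant to the order files are supplied in. Gene universes must be
    identical across files unless ``intersect=True``, in which case the common
    gene set is used (in first-file order).
    """
    if not isinstance(files, Mapping):
        files = dict(zip(sheet["sample_id"], files))
    missing = [s for s in sheet["sample_id"] if s not in files]
    if missing:
        raise ValidationError(f"no abundance file for samples {missing}")
    vectors = {sid: read_kallisto_abundance(files[sid]) for sid in sheet["sample_id"]}
    first_sid = sheet["sample_id"].iloc[0]
    reference = vectors[first_sid].index
    common = reference
    for sid, vec in vectors.items():
        if vec.index.equals(reference):
            continue
        if not intersect:
            raise ValidationError(
                f"gene sets differ between {first_sid!r} ({len(reference)} genes) "
                f"and {sid!r} ({len(vec.index)} genes); pass intersect=True to "
                "take the common set"
            )
        common = common.intersection(vec.index, sort=False)
    matrix = pd.DataFrame(
        {sid: vectors[sid].reindex(common) for sid in sheet["sample_id"]}
    )
    matrix.index.name = "gene_id"
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("negative TPM values in assembled matrix")
    return matrix


def write_table(frame: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    """Write a result table as UTF-8 TSV with '.' decimal separator."""
    frame.to_csv(path, sep="\t", index=index, encoding="utf-8")
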