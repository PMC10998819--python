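"""Tabular I/O and design validation for the AMF community pipeline.

The pipeline's central object is a sample-by-OTU table of non-negative
integer read counts.  Sample identity carries the study design factors
(site, tree, month, compartment) and, optionally, the soil chemistry
measured on the paired soil sample.  Everything is exchanged as plain
UTF-8 tab-separated text: samples as rows, ``#`` lines ignored, no
quoting.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical sampling-calendar order (May 2021 through March 2022); the
#: year-round axis deliberately crosses the calendar-year boundary.
MONTH_ORDER: tuple[str, ...] = (
    "May", "July", "September", "November", "January", "March",
)

COMPARTMENTS: tuple[str, str] = ("root", "soil")

METADATA_COLUMNS = ("sample_id", "site", "tree", "month", "compartment")
CHEMISTRY_VARS = ("pH", "TC", "TN", "TP")


class TableFormatError(ValueError):
    """A file could not be parsed into a valid table."""


class DesignError(ValueError):
    """Sample metadata violates the paired root/soil sampling design."""


@dataclasses.dataclass(frozen=True)
class OtuCountTable:
    """Immutable sample-by-OTU count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers; index = sample IDs, columns = OTU IDs.
        Every sample must contain at least one read and identifiers must
        be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample identifiers: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate OTU identifiers: {dup}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise TableFormatError("counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        row_sums = values.sum(axis=1)
        if (row_sums == 0).any():
            empty = df.index[row_sums == 0].tolist()
            raise TableFormatError(f"samples with zero total reads: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuCountTable":
        return OtuCountTable(self.counts.loc[:, list(otu_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuCountTable":
        return OtuCountTable(self.counts.loc[list(sample_ids)])


def read_count_table(path: str | Path, transpose: bool = False) -> OtuCountTable:
    """Load a count TSV (rows = samples unless ``transpose``)."""
    _check_unique_header(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableFormatError(f"cannot read count table {path}: {exc}") from exc
    if transpose:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableFormatError(
            f"non-numeric count {df.iloc[i, j]!r} at sample "
            f"{df.index[i]!r}, OTU {df.columns[j]!r} in {path}"
        )
    if not np.all(np.equal(np.mod(numeric.to_numpy(dtype=float), 1), 0)):
        i, j = np.argwhere(~np.equal(np.mod(numeric.to_numpy(dtype=float), 1), 0))[0]
        raise TableFormatError(
            f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )
    numeric.index.name = "sample_id"
    return OtuCountTable(numeric.astype(np.int64))


def _check_unique_header(path: str | Path) -> None:
    # pandas silently renames duplicate columns, so inspect the raw header
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            names = line.rstrip("\n").split("\t")[1:]
            dup = sorted({n for n in names if names.count(n) > 1})
            if dup:
                raise TableFormatError(f"duplicate OTU identifiers in header: {dup}")
            return


def write_count_table(table: OtuCountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "sample_id"
    write_text_atomic(path, df.to_csv(sep="\t", lineterminator="\n"))


def read_metadata(
    path: str | Path,
    chemistry_path: str | Path | None = None,
    month_order: Sequence[str] = MONTH_ORDER,
) -> pd.DataFrame:
    """Load sample metadata (and optionally join soil chemistry).

    Returns a DataFrame indexed by ``sample_id`` with ``site``, ``tree``,
    ``compartment`` and an ordered-categorical ``month``.  When a
    chemistry table is joined, the carbon-to-nitrogen ratio ``CN`` is
    derived as TC/TN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise DesignError("duplicate sample_id in metadata")
    bad = sorted(set(df["compartment"]) - set(COMPARTMENTS))
    if bad:
        raise DesignError(
            f"unknown compartment level(s) {bad}; expected one of {COMPARTMENTS}"
        )
    bad_months = sorted(set(df["month"]) - set(month_order))
    if bad_months:
        raise DesignError(f"month level(s) {bad_months} not in order {tuple(month_order)}")
    key = df[["site", "tree", "month", "compartment"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].to_dict("records")
        raise DesignError(f"duplicate (site, tree, month, compartment): {dup}")
    df = df.set_index("sample_id")
    df["month"] = pd.Categorical(df["month"], categories=list(month_order), ordered=True)
    if chemistry_path is not None:
        chem = read_chemistry(chemistry_path)
        orphans = sorted(set(df.index) - set(chem.index))
        if orphans:
            raise DesignError(f"samples missing from chemistry table: {orphans}")
        df = df.join(chem, how="left")
    return df


def read_chemistry(path: str | Path) -> pd.DataFrame:
    """Load per-sample soil chemistry; derives CN = TC/TN.

    TC and TN are percent dry mass, TP is mg per kg soil; all three must
    be positive where present.  A supplied ``CN`` column is checked
    against TC/TN to 1e-9.
    """
    chem = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in chem.columns:
        raise TableFormatError("chemistry table missing sample_id column")
    missing = [c for c in CHEMISTRY_VARS if c not in chem.columns]
    if missing:
        raise TableFormatError(f"chemistry table missing columns: {missing}")
    chem = chem.set_index("sample_id")
    for col in ("TC", "TN", "TP"):
        vals = chem[col].astype(float)
        if (vals <= 0).any():
            bad = chem.index[vals <= 0].tolist()
            raise TableFormatError(f"{col} must be > 0; offending samples: {bad}")
    derived = chem["TC"].astype(float) / chem["TN"].astype(float)
    if "CN" in chem.columns:
        given = chem["CN"].astype(float)
        ok = given.isna() | (np.abs(given - derived) <= 1e-9 * np.maximum(1.0, np.abs(derived)))
        if not ok.all():
            raise TableFormatError("CN column inconsistent with TC/TN")
    chem["CN"] = derived
    return chem[["pH", "TC", "TN", "CN", "TP"]].astype(float)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    df = metadata.reset_index() if metadata.index.name == "sample_id" else metadata
    write_text_atomic(path, df.to_csv(sep="\t", index=False, lineterminator="\n"))


def align(table: OtuCountTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check 1:1 correspondence and return metadata in table sample order."""
    t = set(table.sample_ids)
    m = set(metadata.index)
    missing = sorted(t - m)
    if missing:
        raise DesignError(f"samples in counts absent from metadata: {missing}")
    return metadata.loc[table.sample_ids]


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Load a BLAST-tabular-style hit table (qseqid sseqid pident qcovs stitle)."""
    hits = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["qseqid", "sseqid", "pident", "qcovs", "stitle"]
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise TableFormatError(f"hit table missing columns: {missing}")
    for col in ("pident", "qcovs"):
        vals = pd.to_numeric(hits[col], errors="coerce")
        if vals.isna().any():
            bad = hits.loc[vals.isna(), col].iloc[0]
            raise TableFormatError(f"malformed percent value {bad!r} in column {col}")
        if ((vals < 0) | (vals > 100)).any():
            raise TableFormatError(f"column {col} outside [0, 100]")
        hits[col] = vals
    return hits


def write_text_atomic(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so partial output is never observed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)
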