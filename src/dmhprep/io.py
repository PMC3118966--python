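"""Readers and writers for the on-disk formats used by the DMH pipeline.

Two-color feature tables are tab-delimited with a header row (Agilent
Feature Extraction-style column names by default, remappable via a
*dialect* mapping).  Probe annotation is BED6-like: chrom, start, end,
probe_id, island_id ("." for none), promoter flag.  Genomic coordinates
are 0-based half-open throughout the package (BED convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError

#: Default column names for feature tables.  The scanner export column
#: naming is site-specific; remap via the ``dialect`` argument.
DEFAULT_DIALECT: dict[str, str] = {
    "probe_id": "ProbeName",
    "Rf": "rMeanSignal",
    "Gf": "gMeanSignal",
    "Rb": "rBGMeanSignal",
    "Gb": "gBGMeanSignal",
}

INTENSITY_FIELDS = ("Rf", "Gf", "Rb", "Gb")


@dataclasses.dataclass
class TwoColorArray:
    """Raw intensities for one two-color array.

    ``data`` holds one row per probe with columns ``probe_id`` and the
    four channel intensities ``Rf, Gf, Rb, Gb`` (red/green foreground and
    local background, arbitrary units, all >= 0).
    """

    array_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", *INTENSITY_FIELDS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"array {self.array_id!r}: missing column(s) {missing}")
        if self.data["probe_id"].duplicated().any():
            dup = self.data.loc[self.data["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"array {self.array_id!r}: duplicate probe_id {dup!r}")
        vals = self.data[list(INTENSITY_FIELDS)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError(f"array {self.array_id!r}: non-finite intensity values")
        if (vals < 0).any():
            raise FormatError(f"array {self.array_id!r}: negative intensity values")

    @property
    def probe_ids(self) -> pd.Series:
        return self.data["probe_id"]

    def __len__(self) -> int:
        return len(self.data)


@dataclasses.dataclass
class ProbeAnnotation:
    """Genomic annotation of array probes (0-based half-open intervals).

    ``data`` columns: probe_id, chrom, start, end, island_id (pandas NA
    when the probe lies outside any CpG island), in_promoter (bool).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d["probe_id"].duplicated().any():
            dup = d.loc[d["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r} in annotation")
        if (d["start"] >= d["end"]).any():
            bad = d.loc[d["start"] >= d["end"], "probe_id"].iloc[0]
            raise FormatError(f"probe {bad!r}: empty or inverted interval")
        if (d["start"] < 0).any():
            raise FormatError("negative genomic coordinate in annotation")

    @property
    def probe_ids(self) -> pd.Series:
        return self.data["probe_id"]

    def island_probes(self) -> pd.DataFrame:
        """Rows belonging to a CpG island."""
        return self.data[self.data["island_id"].notna()]

    def centers(self) -> pd.Series:
        """Probe centers, floor((start + end) / 2), indexed by probe_id."""
        c = (self.data["start"] + self.data["end"]) // 2
        return pd.Series(c.to_numpy(), index=self.data["probe_id"].to_numpy())

    def __len__(self) -> int:
        return len(self.data)


class GenomeSequences(dict):
    """Mapping chrom -> uppercase DNA sequence (A/C/G/T/N)."""

    _ALPHABET = frozenset("ACGTN")

    def __setitem__(self, key: str, value: str) -> None:
        if not value:
            raise FormatError(f"empty sequence for {key!r}")
        if not self._ALPHABET.issuperset(value):
            bad = sorted(set(value) - self._ALPHABET)
            raise FormatError(f"sequence {key!r} contains invalid characters {bad}")
        super().__setitem__(key, value)


def _numeric_column(raw: pd.Series, name: str, path) -> pd.Series:
    try:
        return pd.to_numeric(raw, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric value in column {name!r}: {exc}") from None


def read_feature_table(path, dialect: Mapping[str, str] | None = None) -> TwoColorArray:
    """Read one tab-delimited feature table into a :class:`TwoColorArray`.

    The array id is the file name without its extension.  Probe order is
    preserved.  Missing columns, duplicate probe ids, and non-numeric or
    negative intensities raise :class:`FormatError`.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for field in ("probe_id", *INTENSITY_FIELDS):
        col = dialect[field]
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    data = pd.DataFrame({"probe_id": raw[dialect["probe_id"]].astype(str)})
    for field in INTENSITY_FIELDS:
        data[field] = _numeric_column(raw[dialect[field]], dialect[field], path)
    return TwoColorArray(array_id=path.stem, data=data)


def read_feature_tables(
    paths: Iterable, dialect: Mapping[str, str] | None = None
) -> list[TwoColorArray]:
    """Read several feature tables; one :class:`TwoColorArray` per file."""
    return [read_feature_table(p, dialect) for p in paths]


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read BED6-like probe annotation.

    Columns: chrom, start, end, probe_id, island_id ("." = none),
    promoter flag (0/1).  Coordinates are interpreted 0-based half-open.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            chrom, start_s, end_s, probe_id, island, promoter = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if promoter not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: promoter flag must be 0 or 1")
            rows.append(
                {
                    "probe_id": probe_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "island_id": None if island == "." else island,
                    "in_promoter": promoter == "1",
                }
            )
    if not rows:
        raise FormatError(f"{path}: no annotation rows")
    data = pd.DataFrame(rows)
    data["island_id"] = data["island_id"].astype("object")
    return ProbeAnnotation(data)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    """Write annotation back out in the BED6-like layout read by
    :func:`read_probe_annotation`."""
    d = annotation.data
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["start"],
            "end": d["end"],
            "probe_id": d["probe_id"],
            "island_id": d["island_id"].fillna("."),
            "promoter": d["in_promoter"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genome_fasta(path) -> GenomeSequences:
    """Read a FASTA file into a :class:`GenomeSequences` mapping.

    Sequences are uppercased.  Empty files and duplicate record names
    raise :class:`FormatError`.
    """
    path = Path(path)
    genome = GenomeSequences()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"{path}: duplicate record name {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_results(table: pd.DataFrame, path, float_fmt: str = "%.10g") -> None:
    """Write a result table (score table, evaluation grid, ...) as TSV.

    Output is long-format, tab-delimited with a header line, and
    round-trips exactly through :func:`read_results` at the written
    precision.
    """
    table.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_results(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
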