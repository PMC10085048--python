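"""Domain records and readers/writers for every external file the pipeline touches.

Coordinate conventions
----------------------
BED inputs are 0-based half-open (the BED standard).  Editing-site lists and
all human-readable outputs are 1-based, matching the ``chr4 57110068`` style
used for known recoding sites in the literature.  The interval
``(start=100, end=101)`` therefore contains exactly the 1-based position 101.

All result tables are written as TSV with a single header row; missing values
are written as ``NA``; reals are written with 12 significant digits so that a
write/read round trip is value-preserving at that precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")
SITE_CLASSES = ("recoding", "synonymous")

__all__ = [
    "AnnotationError",
    "GenomicInterval",
    "EditingSite",
    "ExpressionMatrix",
    "CohortDesign",
    "read_intervals",
    "read_sites",
    "read_expression",
    "read_cohort",
    "write_table",
    "read_table",
]


class AnnotationError(ValueError):
    """An input file or record violates its documented format or invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated reference region (repeat element or 3'UTR).

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.  ``parent``
    optionally names the gene/3'UTR the region belongs to, for containment
    queries.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    parent: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment of ``other`` within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def positions(self) -> np.ndarray:
        """All 1-based reference positions covered by the interval."""
        return np.arange(self.start + 1, self.end + 1, dtype=np.int64)


@dataclass(frozen=True)
class EditingSite:
    """One known editing position (1-based), reference-A on its annotated strand."""

    chrom: str
    pos: int
    strand: str
    gene: str
    klass: str = "recoding"
    label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise AnnotationError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if self.klass not in SITE_CLASSES:
            raise AnnotationError(
                f"site class must be one of {SITE_CLASSES}, got {self.klass!r}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


class ExpressionMatrix:
    """Gene x sample matrix of non-negative TPM values.

    Duplicate gene rows (e.g. transcript-level rows mapping to one gene) are
    collapsed by summation.  Negative entries are rejected.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            data = data.groupby(level=0, sort=False).sum()
        data = data.astype(float)
        if (data.to_numpy() < 0).any():
            bad = data.index[(data < 0).any(axis=1)][0]
            raise AnnotationError(f"negative expression value in gene {bad!r}")
        self.data = data

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "gene", out.index)
        write_table(out, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class CohortDesign:
    """Sample -> group assignment with optional age/sex covariates and tissue label.

    Group level order is preserved as given in the input.  Every sample must
    appear exactly once.
    """

    OPTIONAL = ("age", "sex", "tissue")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        for col in ("sample", "group"):
            if col not in table.columns:
                raise AnnotationError(f"cohort table is missing column {col!r}")
        if table["sample"].duplicated().any():
            dup = table.loc[table["sample"].duplicated(), "sample"].iloc[0]
            raise AnnotationError(f"duplicated sample ID {dup!r}")
        for col in self.OPTIONAL:
            if col not in table.columns:
                table[col] = np.nan
        table["sample"] = table["sample"].astype(str)
        table["group"] = table["group"].astype(str)
        self.table = table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.table["group"]))

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])

    def covariates(self) -> pd.DataFrame:
        return self.table.set_index("sample")[["group", "age", "sex", "tissue"]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortDesign":
        return cls(pd.read_csv(path, sep="\t", na_values="NA"))

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.table, path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortDesign({len(self.samples)} samples, groups={self.groups})"


def read_intervals(path: str | Path, kind: str = "repeat") -> list[GenomicInterval]:
    """Read a BED file into sorted :class:`GenomicInterval` records.

    ``kind="repeat"`` requires the BED strand column (column 6);
    ``kind="utr3"`` tolerates its absence (defaulting to ``+`` — the 3'UTR
    strand is not used by the inverted-pair filter, only containment is).
    Malformed lines raise :class:`AnnotationError` naming the line number.
    """
    if kind not in ("repeat", "utr3"):
        raise ValueError(f"kind must be 'repeat' or 'utr3', got {kind!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated BED columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else None
            if strand is None:
                if kind == "repeat":
                    raise AnnotationError(
                        f"{path}: line {lineno}: strand (column 6) is required "
                        "for repeat intervals"
                    )
                strand = "+"
            try:
                iv = GenomicInterval(fields[0], start, end, strand, name)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
            out.append(iv)
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return out


def read_sites(
    path: str | Path, reference: object | None = None
) -> tuple[list[EditingSite], list[str]]:
    """Read a tab-delimited editing-site list.

    Columns: chrom, pos (1-based), strand, gene, klass[, label].  A header
    line starting with ``chrom`` is skipped.  Sites are deduplicated on
    (chrom, pos, strand).  When an indexed FASTA is supplied, each site's
    stranded reference base is verified to be adenosine (``A`` on ``+``,
    ``T`` on ``-``); failing sites are excluded and reported in the second
    return value.
    """
    fasta = _as_fasta(reference)
    sites: list[EditingSite] = []
    rejected: list[str] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(fields) < 5:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected >= 5 columns "
                    "(chrom, pos, strand, gene, klass)"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer position"
                ) from exc
            label = fields[5] if len(fields) > 5 else ""
            try:
                site = EditingSite(fields[0], pos, fields[2], fields[3], fields[4], label)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
            key = (site.chrom, site.pos, site.strand)
            if key in seen:
                continue
            seen.add(key)
            if fasta is not None:
                base = str(fasta[site.chrom][site.pos - 1 : site.pos]).upper()
                expected = "A" if site.strand == "+" else "T"
                if base != expected:
                    rejected.append(
                        f"{site.site_id} ({site.gene}): reference base {base!r}, "
                        f"expected {expected!r}"
                    )
                    continue
            sites.append(site)
    if rejected:
        warnings.warn(
            f"{len(rejected)} site(s) rejected: reference base is not adenosine "
            "on the annotated strand",
            stacklevel=2,
        )
    return sites, rejected


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header sample IDs)."""
    return ExpressionMatrix.from_tsv(path)


def read_cohort(path: str | Path) -> CohortDesign:
    """Read TSV cohort metadata (columns: sample, group[, age, sex, tissue])."""
    return CohortDesign.from_tsv(path)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: one header row, NA for missing, 12 sig. digits."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=False)


def _as_fasta(reference: object | None):
    if reference is None:
        return None
    if isinstance(reference, (str, Path)):
        from pyfaidx import Fasta

        return Fasta(str(reference))
    return reference
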