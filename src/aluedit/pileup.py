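"""Strand-aware base pileup over targeted intervals and known editing sites.

Converts aligned RNA-seq reads into per-position A/C/G/T counts, applying the
read-level filters used for editing quantification: end trimming in read
coordinates, base- and mapping-quality floors, and exclusion of duplicate /
secondary / supplementary alignments.  "Unique mapping" is enforced via the
mapping-quality floor — an approximation of rerunning the aligner with
multimapper filtering, which is out of scope here.

Only aligned (CIGAR ``M``/``=``/``X``) bases contribute counts; insertions,
deletions and reference skips contribute nothing at skipped positions, and
read bases of ``N`` are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import EditingSite, GenomicInterval, _as_fasta

__all__ = ["PileupError", "ReadFilterPolicy", "PileupTable", "pileup"]

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class PileupError(RuntimeError):
    """Unusable alignment input (e.g. not coordinate-sorted)."""


@dataclass
class ReadFilterPolicy:
    """Read-level filters applied before counting.

    trim_ends:
        bases excluded at *each* end of the read, measured in read
        coordinates (sequenced bases), matching ``-T 5-5`` semantics.
    min_base_quality / min_mapping_quality:
        phred floors; mapping quality stands in for unique-alignment
        enforcement (default 10).
    mate_overlap:
        ``"independent"`` counts each mate of an overlapping pair
        (default); ``"once"`` drops second-mate bases at positions the
        first mate's (approximate) span also covers.
    """

    trim_ends: int = 5
    min_base_quality: int = 20
    min_mapping_quality: int = 10
    exclude_duplicates: bool = True
    exclude_secondary_supplementary: bool = True
    mate_overlap: str = "independent"

    def __post_init__(self) -> None:
        if self.trim_ends < 0:
            raise ValueError("trim_ends must be >= 0")
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.mate_overlap not in ("independent", "once"):
            raise ValueError("mate_overlap must be 'independent' or 'once'")


class PileupTable:
    """Per-position base counts keyed by (chrom, 1-based pos).

    Each position carries its reference base and the strand context of the
    target (interval or site) that requested it.
    """

    def __init__(self) -> None:
        self._chroms: dict[str, dict[str, np.ndarray]] = {}

    # -- construction -----------------------------------------------------
    def _add_chrom(
        self, chrom: str, pos: np.ndarray, ref: np.ndarray, strand: np.ndarray
    ) -> None:
        self._chroms[chrom] = {
            "pos": pos,
            "ref": ref,
            "strand": strand,
            "counts": np.zeros((pos.size, 4), dtype=np.int64),
        }

    # -- access -----------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    @property
    def n_positions(self) -> int:
        return sum(d["pos"].size for d in self._chroms.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]["pos"]

    def counts(self, chrom: str) -> np.ndarray:
        """(n_positions, 4) array of A/C/G/T counts for one chromosome."""
        return self._chroms[chrom]["counts"]

    def ref(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]["ref"]

    def strand(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]["strand"]

    def counts_at(self, chrom: str, pos: int) -> np.ndarray:
        """A/C/G/T counts at one 1-based position (zeros if untargeted)."""
        if chrom not in self._chroms:
            return np.zeros(4, dtype=np.int64)
        d = self._chroms[chrom]
        i = np.searchsorted(d["pos"], pos)
        if i < d["pos"].size and d["pos"][i] == pos:
            return d["counts"][i]
        return np.zeros(4, dtype=np.int64)

    def column(self, chrom: str, pos: int) -> dict:
        c = self.counts_at(chrom, pos)
        return dict(zip(BASES, (int(x) for x in c)))

    def range_index(self, chrom: str, start0: int, end0: int) -> slice:
        """Index slice of positions inside a 0-based half-open interval."""
        d = self._chroms[chrom]
        lo = int(np.searchsorted(d["pos"], start0 + 1, side="left"))
        hi = int(np.searchsorted(d["pos"], end0, side="right"))
        return slice(lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, d in self._chroms.items():
            frame = pd.DataFrame(d["counts"], columns=list(BASES))
            frame.insert(0, "strand", d["strand"])
            frame.insert(0, "ref", d["ref"])
            frame.insert(0, "pos", d["pos"])
            frame.insert(0, "chrom", chrom)
            rows.append(frame)
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "ref", "strand", *BASES])
        return pd.concat(rows, ignore_index=True)


def _resolve_targets(
    targets: Sequence[GenomicInterval | EditingSite], fasta
) -> PileupTable:
    per_chrom: dict[str, dict[int, tuple[str, str]]] = {}
    for t in targets:
        if isinstance(t, EditingSite):
            positions = [t.pos]
            strand = t.strand
            chrom = t.chrom
        else:
            positions = range(t.start + 1, t.end + 1)
            strand = t.strand
            chrom = t.chrom
        store = per_chrom.setdefault(chrom, {})
        refseq = None
        if fasta is not None and isinstance(t, GenomicInterval):
            refseq = str(fasta[chrom][t.start : t.end]).upper()
        for j, p in enumerate(positions):
            if p in store:
                continue  # first-declared target wins on strand context
            if refseq is not None:
                base = refseq[j]
            elif fasta is not None:
                base = str(fasta[chrom][p - 1 : p]).upper()
            else:
                base = "N"
            store[p] = (base, strand)
    table = PileupTable()
    for chrom in sorted(per_chrom):
        items = sorted(per_chrom[chrom].items())
        pos = np.array([p for p, _ in items], dtype=np.int64)
        ref = np.array([v[0] for _, v in items], dtype="<U1")
        strand = np.array([v[1] for _, v in items], dtype="<U1")
        table._add_chrom(chrom, pos, ref, strand)
    return table


def pileup(
    alignments: str | Path | pysam.AlignmentFile,
    targets: Sequence[GenomicInterval | EditingSite],
    policy: ReadFilterPolicy | None = None,
    reference: object | None = None,
) -> PileupTable:
    """Count filtered read bases at every reference position inside ``targets``.

    ``alignments`` may be an indexed BAM or a plain coordinate-sorted SAM
    (the header must declare ``SO:coordinate``).  ``reference`` (FASTA path
    or ``pyfaidx.Fasta``) supplies reference bases for the table; targets on
    chromosomes absent from the alignment header yield zero counts with a
    warning.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    policy = policy or ReadFilterPolicy()
    fasta = _as_fasta(reference)
    table = _resolve_targets(targets, fasta)

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=True)
        if own_handle
        else alignments
    )
    try:
        header = af.header.to_dict()
        if header.get("HD", {}).get("SO") != "coordinate":
            raise PileupError(
                "alignments must be coordinate-sorted (header @HD SO:coordinate)"
            )
        present = set(af.references or ())
        colmaps: dict[str, np.ndarray] = {}
        for chrom in table.chroms:
            if chrom not in present:
                warnings.warn(
                    f"target chromosome {chrom!r} absent from alignment header; "
                    "its counts will be zero",
                    stacklevel=2,
                )
                continue
            pos = table.positions(chrom)
            cm = np.full(int(pos[-1]) + 1, -1, dtype=np.int64)
            cm[pos - 1] = np.arange(pos.size)  # 0-based reference -> column
            colmaps[chrom] = cm

        trim = policy.trim_ends
        minbq = policy.min_base_quality
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_qcfail:
                continue
            if policy.exclude_secondary_supplementary and (
                read.is_secondary or read.is_supplementary
            ):
                continue
            if policy.exclude_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < policy.min_mapping_quality:
                continue
            cm = colmaps.get(read.reference_name)
            if cm is None:
                continue
            seq = read.query_sequence
            if not seq:
                continue
            qlen = len(seq)
            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                # ungapped read: avoid the aligned-pairs round trip
                qpos = np.arange(qlen, dtype=np.int64)
                rpos = read.reference_start + qpos
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
                if not pairs:
                    continue
                arr = np.asarray(pairs, dtype=np.int64)
                qpos, rpos = arr[:, 0], arr[:, 1]
            mask = (qpos >= trim) & (qpos < qlen - trim)
            quals = read.query_qualities
            if quals is not None and minbq > 0:
                mask &= np.asarray(quals, dtype=np.int16)[qpos] >= minbq
            bidx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][qpos]
            mask &= bidx >= 0  # drops N and other ambiguity codes
            if (
                policy.mate_overlap == "once"
                and read.is_paired
                and read.is_read2
                and not read.mate_is_unmapped
                and read.reference_id == read.next_reference_id
            ):
                # approximate the mate span by [mate_start, mate_start + qlen)
                mstart = read.next_reference_start
                mask &= ~((rpos >= mstart) & (rpos < mstart + qlen))
            if not mask.any():
                continue
            rsel = rpos[mask]
            inmap = rsel < cm.size
            col = cm[rsel[inmap]]
            good = col >= 0
            counts = table.counts(read.reference_name)
            np.add.at(counts, (col[good], bidx[mask][inmap][good]), 1)
    finally:
        if own_handle:
            af.close()
    return table
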