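"""Shared fixtures: tiny references, hand-written SAM builders, a random
SAM generator, and an independent naive pileup oracle.

The oracle parses SAM text and walks CIGAR strings by hand — it shares no
code path with the package's pileup engine, so agreement between the two is
a genuine cross-check.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pytest
from pyfaidx import Faidx


@pytest.fixture
def write_fasta(tmp_path):
    def _write(sequences: dict[str, str], name: str = "ref.fa") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, seq in sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        Faidx(str(path))
        return path

    return _write


@pytest.fixture
def write_sam(tmp_path):
    """Write a coordinate-sorted SAM from (qname, flag, chrom, pos1, mapq,
    cigar, seq, qual) tuples; reads are sorted for the caller."""

    def _write(
        reads: list[tuple],
        lengths: dict[str, int],
        name: str = "reads.sam",
        sort: bool = True,
    ) -> Path:
        path = tmp_path / name
        chrom_order = {c: i for i, c in enumerate(lengths)}
        rows = sorted(reads, key=lambda r: (chrom_order[r[2]], r[3])) if sort else reads
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for chrom, ln in lengths.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
            for qname, flag, chrom, pos1, mapq, cigar, seq, qual in rows:
                fh.write(
                    f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t"
                    f"{seq}\t{qual}\n"
                )
        return path

    return _write


def naive_pileup_counts(
    sam_path,
    target_positions: dict[str, set[int]],
    trim_ends: int = 5,
    min_base_quality: int = 20,
    min_mapping_quality: int = 10,
    exclude_duplicates: bool = True,
    exclude_secondary_supplementary: bool = True,
) -> dict[tuple[str, int], dict[str, int]]:
    """Independent per-read, per-base recount from raw SAM text.

    ``target_positions`` maps chrom -> set of 1-based positions.  Returns
    (chrom, pos) -> {A, C, G, T} counts.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {
        (c, p): {b: 0 for b in "ACGT"}
        for c, ps in target_positions.items()
        for p in ps
    }
    cigar_re = re.compile(r"(\d+)([MIDNSHP=X])")
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            chrom, pos1, mapq, cigar, seq, qual = f[2], int(f[3]), int(f[4]), f[5], f[9], f[10]
            if flag & 0x4 or flag & 0x200:  # unmapped / qcfail
                continue
            if exclude_secondary_supplementary and (flag & 0x100 or flag & 0x800):
                continue
            if exclude_duplicates and flag & 0x400:
                continue
            if mapq < min_mapping_quality:
                continue
            if chrom not in target_positions:
                continue
            qlen = len(seq)
            qpos = 0
            rpos = pos1  # 1-based
            for n_str, op in cigar_re.findall(cigar):
                n = int(n_str)
                if op in ("M", "=", "X"):
                    for k in range(n):
                        p, q = rpos + k, qpos + k
                        if p in target_positions[chrom]:
                            if q < trim_ends or q >= qlen - trim_ends:
                                continue
                            if qual != "*" and ord(qual[q]) - 33 < min_base_quality:
                                continue
                            base = seq[q]
                            if base in "ACGT":
                                counts[(chrom, p)][base] += 1
                    rpos += n
                    qpos += n
                elif op in ("D", "N"):
                    rpos += n
                elif op in ("I", "S"):
                    qpos += n
                # H and P consume nothing relevant
    return counts


def random_sam_reads(
    rng: np.random.Generator,
    reference: dict[str, str],
    n_reads: int,
    mismatch_rate: float = 0.05,
    structural_rate: float = 0.3,
):
    """Random reads with occasional soft clips, insertions and deletions,
    random qualities, mapq and duplicate/secondary flags."""
    reads = []
    chroms = list(reference)
    for i in range(n_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        ref = reference[chrom]
        rlen = int(rng.integers(30, 61))
        pos0 = int(rng.integers(0, max(1, len(ref) - rlen - 20)))
        ops = []
        if rng.random() < structural_rate:
            kind = rng.choice(["S", "I", "D"])
            if kind == "S":
                clip = int(rng.integers(2, 6))
                ops = [("S", clip), ("M", rlen)]
            elif kind == "I":
                a = rlen // 2
                ops = [("M", a), ("I", int(rng.integers(1, 4))), ("M", rlen - a)]
            else:
                a = rlen // 2
                ops = [("M", a), ("D", int(rng.integers(1, 5))), ("M", rlen - a)]
        else:
            ops = [("M", rlen)]
        seq_parts = []
        rcur = pos0
        for op, n in ops:
            if op in ("M",):
                chunk = list(ref[rcur : rcur + n])
                for k in range(len(chunk)):
                    if rng.random() < mismatch_rate:
                        chunk[k] = "ACGT"[int(rng.integers(4))]
                seq_parts.append("".join(chunk))
                rcur += n
            elif op == "D":
                rcur += n
            else:  # S or I: inserted/clipped bases not from the reference
                seq_parts.append(
                    "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=n))
                )
        seq = "".join(seq_parts)
        qual = "".join(chr(int(q) + 33) for q in rng.integers(5, 41, size=len(seq)))
        cigar = "".join(f"{n}{op}" for op, n in ops)
        flag = 0
        r = rng.random()
        if r < 0.05:
            flag |= 0x400  # duplicate
        elif r < 0.10:
            flag |= 0x100  # secondary
        mapq = int(rng.integers(0, 61))
        reads.append((f"r{i}", flag, chrom, pos0 + 1, mapq, cigar, seq, qual))
    return reads


@pytest.fixture
def rng():
    return np.random.default_rng(20230410)
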