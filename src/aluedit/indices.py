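"""Editing indices computed from pileups.

The Alu Editing Index (AEI) of a sample is the percentage of
editing-supporting bases among informative bases at reference-adenosine
positions inside Alu repeat regions, pooled over all regions:

    AEI = 100 * sum(G) / sum(A + G)      (on + strand regions)

with the strand-complement arithmetic ``C / (T + C)`` at reference-T
positions of minus-strand regions, since A-to-I editing on the antisense
strand is observed as T->C on the sequenced (reference) strand.

The Coding Editing Index (CEI) pools A->G mismatch counts over a fixed
panel of known exonic editing sites:

    CEI = 100 * sum(edited) / sum(coverage)

which is exactly the coverage-weighted mean of the per-site editing levels.
Per-site analyses additionally apply a >= 10 supporting-read inclusion rule;
the pooled CEI applies no per-site coverage floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import EditingSite, GenomicInterval
from .pileup import PileupTable

__all__ = [
    "IndexResult",
    "compute_aei",
    "compute_cei",
    "site_levels",
    "select_utr3_alus",
    "edited_transcript_counts",
    "centralization",
]

# column order in PileupTable counts
_A, _C, _G, _T = 0, 1, 2, 3

# per-site "detected" flag thresholds (REDItools-style -v/-n); these gate the
# flag only, never the level arithmetic, so levels of exactly 0 stay representable
MIN_VARIANT_READS = 1
MIN_VARIANT_FREQUENCY = 0.001


@dataclass
class IndexResult:
    """Numerator, denominator and percent value of one editing index."""

    sample: str
    region_set: str
    numerator: int
    denominator: int

    @property
    def index_pct(self) -> float:
        """100 * numerator / denominator; NaN when the denominator is zero."""
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.numerator / self.denominator

    def to_row(self) -> dict:
        return {
            "sample": self.sample,
            "region_set": self.region_set,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "index_pct": self.index_pct,
        }


def compute_aei(
    pile: PileupTable,
    regions: Sequence[GenomicInterval],
    sample: str = "",
    region_set: str = "all-Alu",
) -> IndexResult:
    """Pool G/(A+G) (strand-adjusted) over all reference-A positions in ``regions``.

    Regions are assumed disjoint; numerators and denominators add over any
    partition of the region set.  A zero denominator yields a NaN index with
    a warning.
    """
    num = 0
    den = 0
    for region in regions:
        if region.chrom not in pile.chroms:
            continue
        sl = pile.range_index(region.chrom, region.start, region.end)
        ref = pile.ref(region.chrom)[sl]
        counts = pile.counts(region.chrom)[sl]
        if region.strand == "+":
            at = ref == "A"
            num += int(counts[at, _G].sum())
            den += int(counts[at, _A].sum() + counts[at, _G].sum())
        else:
            at = ref == "T"
            num += int(counts[at, _C].sum())
            den += int(counts[at, _T].sum() + counts[at, _C].sum())
    if den == 0:
        warnings.warn(
            f"zero informative bases for {region_set!r}; index undefined",
            stacklevel=2,
        )
    return IndexResult(sample=sample, region_set=region_set, numerator=num, denominator=den)


def site_levels(
    pile: PileupTable,
    sites: Sequence[EditingSite],
    min_reads: int = 10,
    sample: str | None = None,
) -> pd.DataFrame:
    """Per-site editing levels, strand-adjusted, with the >=``min_reads`` flag.

    Returns a table with one row per site: coverage (informative reads,
    A+G on ``+`` / T+C on ``-``), edited count, ``level_pct``, an
    ``included`` flag (coverage >= min_reads) and a ``detected`` flag
    (>= 1 variant read at >= 0.001 frequency).
    """
    rows = []
    for site in sites:
        c = pile.counts_at(site.chrom, site.pos)
        if site.strand == "+":
            edited = int(c[_G])
            coverage = int(c[_A] + c[_G])
        else:
            edited = int(c[_C])
            coverage = int(c[_T] + c[_C])
        level = float("nan") if coverage == 0 else 100.0 * edited / coverage
        detected = (
            edited >= MIN_VARIANT_READS
            and coverage > 0
            and edited / coverage >= MIN_VARIANT_FREQUENCY
        )
        rows.append(
            {
                "site": site.site_id,
                "chrom": site.chrom,
                "pos": site.pos,
                "strand": site.strand,
                "gene": site.gene,
                "klass": site.klass,
                "coverage": coverage,
                "edited": edited,
                "level_pct": level,
                "included": coverage >= min_reads,
                "detected": detected,
            }
        )
    frame = pd.DataFrame(rows)
    if sample is not None:
        frame.insert(0, "sample", sample)
    return frame


def compute_cei(site_table: pd.DataFrame, sample: str = "") -> IndexResult:
    """Pooled coding editing index of one sample's site table (no coverage floor)."""
    num = int(site_table["edited"].sum())
    den = int(site_table["coverage"].sum())
    if den == 0:
        warnings.warn("zero total coverage over coding sites; CEI undefined", stacklevel=2)
    return IndexResult(sample=sample, region_set="coding-sites", numerator=num, denominator=den)


def select_utr3_alus(
    alus: Sequence[GenomicInterval],
    utr3s: Sequence[GenomicInterval],
    min_len: int = 250,
    strict_partner: bool = False,
) -> list[GenomicInterval]:
    """Alu repeats fully contained in a 3'UTR, >= ``min_len`` bases, with an
    oppositely oriented Alu in the same 3'UTR.

    The opposite partner need not meet ``min_len`` itself unless
    ``strict_partner`` is set.  Containment means full containment;
    partial overlaps are excluded.  The result is sorted by coordinate and
    independent of input ordering.
    """
    selected: set[GenomicInterval] = set()
    for utr in utr3s:
        contained = [a for a in alus if utr.contains(a)]
        if len(contained) < 2:
            continue
        for alu in contained:
            if alu.length < min_len:
                continue
            has_partner = any(
                other is not alu
                and other.strand != alu.strand
                and (not strict_partner or other.length >= min_len)
                for other in contained
            )
            if has_partner:
                selected.add(alu)
    return sorted(selected, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))


def edited_transcript_counts(site_table: pd.DataFrame, by: str = "gene") -> pd.Series:
    """Sum edited counts at the requested granularity (site, gene or sample).

    Each edited count is one observed A->G mismatch, i.e. one edited
    transcript copy.  ``by="sample"`` requires a ``sample`` column; dividing
    the result by the number of donors gives per-donor averages.
    """
    if by not in ("site", "gene", "sample"):
        raise ValueError("by must be one of 'site', 'gene', 'sample'")
    if site_table.empty:
        return pd.Series(dtype=np.int64, name="edited")
    if by == "sample" and "sample" not in site_table.columns:
        raise ValueError("site table has no 'sample' column")
    return site_table.groupby(by, sort=True)["edited"].sum()


def centralization(activity: pd.Series | Sequence[float], k: int = 5) -> float:
    """Fraction of total editing activity carried by the top-``k`` sites.

    ``activity`` holds per-site edited counts for one tissue; ties are
    broken deterministically by the (sortable) site index.  Returns NaN when
    total activity is zero.
    """
    s = pd.Series(activity, dtype=float)
    total = s.sum()
    if total == 0 or s.empty or np.isnan(total):
        warnings.warn("all-zero editing activity; centralization undefined", stacklevel=2)
        return float("nan")
    order = s.reset_index(drop=False)
    order.columns = ["key", "value"]
    order = order.sort_values(["value", "key"], ascending=[False, True], kind="mergesort")
    return float(order["value"].head(k).sum() / total)
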