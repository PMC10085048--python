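"""Self-contained synthetic cohort generator with known ground truth.

Emulates the statistical structure of a cardiovascular editing study on a
toy genome: strand-assigned repeat ("Alu-like") regions whose
reference-adenosine positions are read as guanosine at a per-sample rate
epsilon; oppositely oriented repeat pairs planted inside 3'UTRs; a panel of
coding editing sites, a handful of which are highly edited (the named
IGFBP7/FLNA/NEIL1/CCNI/SRP9-like recoding sites are also highly expressed,
producing the centralized recoding activity seen in cardiovascular tissue);
and two cohorts in which the disease group has elevated epsilon, elevated
levels at a few sites, and upregulated interferon-signature expression
correlated with epsilon.  Sequencing error is uniform and strand-symmetric
(an A->G error therefore occurs at rate e/3).

Reads are emitted pre-aligned (correct coordinates and CIGAR, coordinate
sorted) — alignment itself is out of scope.  Identical configuration and
seed yield byte-identical outputs.  Default effect sizes follow the scale
reported for ischemic/dilated cardiomyopathy cohorts: control epsilon
0.56% vs. patient 0.67%, an IGFBP7-like site shifted by +11 percentage
points, and group sizes 14 vs. 13.

A ``reads=False`` mode skips read emission and instead draws the measured
per-sample index counts directly from their exact sampling distributions
(Poisson coverage, binomial mismatches), which is the analytic closure used
for fast statistical calibration work.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    CohortDesign,
    EditingSite,
    ExpressionMatrix,
    GenomicInterval,
    write_table,
)

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "ReferenceBundle",
    "SyntheticCohort",
    "simulate_reference",
    "simulate_sample",
    "simulate_cohort",
    "parse_config_file",
]

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

# named high-interest recoding sites and their baseline editing levels
# (fractions, pre tissue scaling); the first five are also highly expressed
NAMED_SITE_LEVELS = {
    "IGFBP7": 0.16,
    "FLNA": 0.90,
    "NEIL1": 0.85,
    "CCNI": 0.80,
    "SRP9": 0.75,
    "COPA": 0.13,
    "COG3": 0.12,
}
TOP_EXPRESSED_GENES = ("IGFBP7", "FLNA", "NEIL1", "CCNI", "SRP9")
SHIFTED_GENES = ("IGFBP7", "COPA", "COG3")
MARKER_GENES = ("NPPA", "NPPB", "TNNI3", "TNNT2")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, repeat-editing rate and disease effects."""

    name: str
    n: int
    alu_editing_rate: float      # epsilon_g, fraction
    site_level_shift: float = 0.0  # added to shifted sites' levels (fraction)
    isg_log2_shift: float = 0.0    # added to ISG gene log2 expression

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= self.alu_editing_rate <= 1:
            raise ValueError("alu_editing_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    Group sizes and effect magnitudes default to the cardiomyopathy-cohort
    scale (14 controls vs. 13 patients; epsilon 0.0056 vs. 0.0067; an
    IGFBP7-like site shifted +0.11); the site panel has 314 entries.
    """

    seed: int = 0
    # toy genome
    n_chroms: int = 3
    chrom_len: int = 120_000
    n_utr3: int = 24
    alus_per_utr3: tuple[int, int] = (1, 3)
    inverted_pair_fraction: float = 0.7
    n_free_alus: int = 12
    alu_len_range: tuple[int, int] = (150, 350)
    alu_a_fraction: float = 0.35
    # coding site panel
    n_coding_sites: int = 314
    exon_len: int = 160
    site_level_range: tuple[float, float] = (0.15, 0.95)
    background_level_range: tuple[float, float] = (0.02, 0.35)
    top_site_coverage_mult: float = 25.0
    # sequencing
    coverage_mean: float = 50.0
    read_len: int = 100
    seq_error_rate: float = 0.001
    base_quality: int = 37
    # cohort structure
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("control", 14, 0.0056),
        GroupSpec("CMP", 13, 0.0067, site_level_shift=0.11, isg_log2_shift=1.0),
    )
    epsilon_concentration: float = 8000.0
    site_level_concentration: float = 150.0
    coupling: float = 0.5
    isg_sd: float = 0.8
    gene_noise_sd: float = 0.25
    marker_sd: float = 1.0
    marker_log2_shifts: tuple[tuple[str, float], ...] = (
        ("NPPA", 1.0),
        ("NPPB", 1.8),
        ("TNNI3", 2.0),
        ("TNNT2", 0.8),
    )
    n_background_genes: int = 20
    # the default cohort emulates a single-tissue (ventricular) case/control
    # study: tissue labels drive pipeline plumbing and profile pooling, but
    # editing levels are tissue-homogeneous unless scales are overridden
    tissues: tuple[str, ...] = ("aorta", "coronary", "LV")
    tissue_site_scale: tuple[tuple[str, float], ...] = (
        ("aorta", 1.0),
        ("coronary", 1.0),
        ("LV", 1.0),
    )

    def __post_init__(self) -> None:
        for rate in (self.inverted_pair_fraction, self.seq_error_rate, self.coupling):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_chroms < 1 or self.chrom_len < 1000:
            raise ValueError("toy genome too small")

    def tissue_scale(self, tissue: str) -> float:
        return dict(self.tissue_site_scale).get(tissue, 1.0)


@dataclass
class ReferenceBundle:
    """The toy reference: sequences, annotations and planted truth."""

    chrom_names: list[str]
    sequences: dict[str, np.ndarray]          # uint8 base codes 0..3
    alus: list[GenomicInterval]
    utr3s: list[GenomicInterval]
    exons: list[GenomicInterval]              # one per coding site
    sites: list[EditingSite]
    site_base_levels: np.ndarray              # fraction, per site
    site_coverage_mult: np.ndarray            # per site
    edit_plus: dict[str, np.ndarray]          # bool: + strand Alu ref-A positions
    edit_minus: dict[str, np.ndarray]         # bool: - strand Alu ref-T positions

    @property
    def planted_a_count(self) -> int:
        """Number of editable (strand-adjusted adenosine) repeat positions."""
        return int(
            sum(m.sum() for m in self.edit_plus.values())
            + sum(m.sum() for m in self.edit_minus.values())
        )

    def sequence_str(self, chrom: str) -> str:
        return _CODES[self.sequences[chrom]].tobytes().decode("ascii")

    def write(self, out_dir: Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta = out_dir / "reference.fa"
        with open(fasta, "w") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                s = self.sequence_str(chrom)
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")
        from pyfaidx import Faidx

        Faidx(str(fasta))
        paths["reference"] = fasta
        for key, intervals in (("alu", self.alus), ("utr3", self.utr3s)):
            path = out_dir / f"{key}.bed"
            with open(path, "w") as fh:
                for iv in intervals:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
                    )
            paths[key] = path
        sites_path = out_dir / "sites.tsv"
        with open(sites_path, "w") as fh:
            fh.write("chrom\tpos\tstrand\tgene\tklass\n")
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.gene}\t{s.klass}\n")
        paths["sites"] = sites_path
        return paths


@dataclass
class SyntheticCohort:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimulationConfig
    reference: ReferenceBundle
    design: CohortDesign
    expression: ExpressionMatrix
    truth_samples: pd.DataFrame       # sample, group, tissue, epsilon, isg_u, age, sex
    truth_site_levels: pd.DataFrame   # sample, site, gene, true_level
    sam_paths: dict[str, Path] | None = None
    measured_aei: pd.DataFrame | None = None      # counts mode only
    measured_sites: pd.DataFrame | None = None    # counts mode only
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.truth_samples["sample"], self.truth_samples["tissue"]))


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ReferenceBundle:
    """Build the toy genome with planted repeats, 3'UTRs and coding sites."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = {
        c: rng.integers(0, 4, size=config.chrom_len, dtype=np.uint8)
        for c in chrom_names
    }

    # round-robin feature assignment to chromosomes
    features: dict[str, list[tuple[str, int]]] = {c: [] for c in chrom_names}
    for i in range(config.n_utr3):
        features[chrom_names[i % config.n_chroms]].append(("utr3", i))
    for i in range(config.n_coding_sites):
        features[chrom_names[i % config.n_chroms]].append(("exon", i))
    for i in range(config.n_free_alus):
        features[chrom_names[i % config.n_chroms]].append(("alu", i))

    site_genes = _site_gene_names(config.n_coding_sites)
    alus: list[GenomicInterval] = []
    utr3s: list[GenomicInterval] = []
    exon_by_site: dict[int, GenomicInterval] = {}
    site_by_index: dict[int, EditingSite] = {}

    for chrom in chrom_names:
        cursor = 100
        seq = sequences[chrom]
        for kind, idx in features[chrom]:
            cursor += int(rng.integers(50, 200))
            if kind == "utr3":
                n_alus = int(rng.integers(config.alus_per_utr3[0], config.alus_per_utr3[1] + 1))
                lens = rng.integers(
                    config.alu_len_range[0], config.alu_len_range[1] + 1, size=n_alus
                )
                pads = rng.integers(20, 60, size=n_alus + 1)
                inverted = n_alus >= 2 and rng.random() < config.inverted_pair_fraction
                strands = [str(rng.choice(["+", "-"]))] * n_alus
                if inverted:
                    strands[0], strands[1] = "+", "-"
                start = cursor
                pos = start
                utr_alus = []
                for j in range(n_alus):
                    pos += int(pads[j])
                    a_start, a_end = pos, pos + int(lens[j])
                    utr_alus.append((a_start, a_end, strands[j]))
                    pos = a_end
                pos += int(pads[-1])
                end = pos
                _check_fit(chrom, end, config.chrom_len)
                utr_name = f"UTR3_{len(utr3s):03d}"
                utr3s.append(GenomicInterval(chrom, start, end, "+", utr_name))
                for a_start, a_end, strand in utr_alus:
                    _fill_repeat(rng, seq, a_start, a_end, strand, config.alu_a_fraction)
                    alus.append(
                        GenomicInterval(chrom, a_start, a_end, strand,
                                        f"AluSim_{len(alus):03d}", parent=utr_name)
                    )
                cursor = end
            elif kind == "exon":
                start, end = cursor, cursor + config.exon_len
                _check_fit(chrom, end, config.chrom_len)
                strand = str(rng.choice(["+", "-"]))
                site_off = config.exon_len // 2
                pos0 = start + site_off
                seq[pos0] = _A if strand == "+" else _T
                gene = site_genes[idx]
                exon_by_site[idx] = GenomicInterval(chrom, start, end, strand, gene)
                site_by_index[idx] = EditingSite(
                    chrom, pos0 + 1, strand, gene,
                    "recoding" if gene in NAMED_SITE_LEVELS or rng.random() < 0.6
                    else "synonymous",
                )
                cursor = end
            else:  # free repeat outside any UTR
                length = int(rng.integers(config.alu_len_range[0], config.alu_len_range[1] + 1))
                start, end = cursor, cursor + length
                _check_fit(chrom, end, config.chrom_len)
                strand = str(rng.choice(["+", "-"]))
                _fill_repeat(rng, seq, start, end, strand, config.alu_a_fraction)
                alus.append(
                    GenomicInterval(chrom, start, end, strand, f"AluSim_{len(alus):03d}")
                )
                cursor = end

    exons = [exon_by_site[i] for i in range(config.n_coding_sites)]
    sites = [site_by_index[i] for i in range(config.n_coding_sites)]

    base_levels = np.empty(config.n_coding_sites)
    mult = np.ones(config.n_coding_sites)
    lo, hi = config.background_level_range
    for i, site in enumerate(sites):
        if site.gene in NAMED_SITE_LEVELS:
            base_levels[i] = NAMED_SITE_LEVELS[site.gene]
        else:
            base_levels[i] = rng.uniform(lo, hi)
        if site.gene in TOP_EXPRESSED_GENES:
            mult[i] = config.top_site_coverage_mult

    edit_plus = {c: np.zeros(config.chrom_len, dtype=bool) for c in chrom_names}
    edit_minus = {c: np.zeros(config.chrom_len, dtype=bool) for c in chrom_names}
    for alu in alus:
        span = sequences[alu.chrom][alu.start : alu.end]
        if alu.strand == "+":
            edit_plus[alu.chrom][alu.start : alu.end] = span == _A
        else:
            edit_minus[alu.chrom][alu.start : alu.end] = span == _T

    alus.sort(key=lambda iv: (iv.chrom, iv.start))
    utr3s.sort(key=lambda iv: (iv.chrom, iv.start))
    return ReferenceBundle(
        chrom_names=chrom_names,
        sequences=sequences,
        alus=alus,
        utr3s=utr3s,
        exons=exons,
        sites=sites,
        site_base_levels=base_levels,
        site_coverage_mult=mult,
        edit_plus=edit_plus,
        edit_minus=edit_minus,
    )


def _check_fit(chrom: str, end: int, chrom_len: int) -> None:
    if end > chrom_len - 100:
        raise ValueError(
            f"planted features exceed chromosome length on {chrom} "
            f"(need > {end}, have {chrom_len}); enlarge chrom_len or plant fewer features"
        )


def _fill_repeat(rng, seq: np.ndarray, start: int, end: int, strand: str, a_frac: float) -> None:
    rest = (1.0 - a_frac) / 3.0
    if strand == "+":
        probs = [a_frac, rest, rest, rest]
    else:
        probs = [rest, rest, rest, a_frac]
    seq[start:end] = rng.choice(4, size=end - start, p=probs).astype(np.uint8)


def _site_gene_names(n: int) -> list[str]:
    named = list(NAMED_SITE_LEVELS)
    return [named[i] if i < len(named) else f"EDG{i:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _transcribed_regions(ref: ReferenceBundle, config: SimulationConfig):
    """(interval, coverage factor) pairs: UTRs, exons and free repeats."""
    regions: list[tuple[GenomicInterval, float]] = []
    for utr in ref.utr3s:
        regions.append((utr, 1.0))
    for i, exon in enumerate(ref.exons):
        regions.append((exon, float(ref.site_coverage_mult[i])))
    in_utr = {
        (a.chrom, a.start) for a in ref.alus if a.parent is not None
    }
    for alu in ref.alus:
        if (alu.chrom, alu.start) not in in_utr:
            regions.append((alu, 1.0))
    return regions


def simulate_sample(
    config: SimulationConfig,
    ref: ReferenceBundle,
    epsilon: float,
    site_levels: np.ndarray,
    sample_id: str,
    out_path: str | Path,
    rng: np.random.Generator,
) -> Path:
    """Emit one sample's coordinate-sorted SAM with planted editing.

    Reads tile the transcribed regions at Poisson depth; within repeat
    regions each strand-adjusted reference adenosine is emitted edited with
    probability ``epsilon``; each coding site at its own true level; every
    base then suffers a uniform sequencing error at ``seq_error_rate``.
    """
    L = config.read_len
    chrom_idx = {c: k for k, c in enumerate(ref.chrom_names)}
    site_map: dict[str, np.ndarray] = {}
    site_strand_plus = np.array([s.strand == "+" for s in ref.sites])
    for c in ref.chrom_names:
        site_map[c] = np.full(config.chrom_len, -1, dtype=np.int32)
    for i, s in enumerate(ref.sites):
        site_map[s.chrom][s.pos - 1] = i
    edit_base = np.where(site_strand_plus, _G, _C).astype(np.uint8)

    all_chrom: list[np.ndarray] = []
    all_start: list[np.ndarray] = []
    all_reads: list[np.ndarray] = []
    offsets = np.arange(L)
    for region, factor in _transcribed_regions(ref, config):
        seq = ref.sequences[region.chrom]
        lo = max(0, region.start - L + 1)
        hi = min(region.end - 1, config.chrom_len - L)
        if hi < lo:
            continue
        span = hi - lo + 1
        n = int(rng.poisson(config.coverage_mean * factor * span / L))
        if n == 0:
            continue
        starts = lo + rng.integers(0, span, size=n)
        positions = starts[:, None] + offsets
        reads = seq[positions].copy()
        # A-to-I editing inside repeats (strand-adjusted)
        if epsilon > 0:
            hit = ref.edit_plus[region.chrom][positions] & (
                rng.random(positions.shape) < epsilon
            )
            reads[hit] = _G
            hit = ref.edit_minus[region.chrom][positions] & (
                rng.random(positions.shape) < epsilon
            )
            reads[hit] = _C
        # coding-site editing at per-site true levels
        sm = site_map[region.chrom][positions]
        has = sm >= 0
        if has.any():
            idx = sm[has]
            edited = rng.random(idx.shape) < site_levels[idx]
            reads[has] = np.where(edited, edit_base[idx], reads[has])
        # uniform sequencing error, strand symmetric
        if config.seq_error_rate > 0:
            err = rng.random(positions.shape) < config.seq_error_rate
            n_err = int(err.sum())
            if n_err:
                reads[err] = (reads[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
        all_chrom.append(np.full(n, chrom_idx[region.chrom], dtype=np.int32))
        all_start.append(starts)
        all_reads.append(reads)

    out_path = Path(out_path)
    qual = chr(config.base_quality + 33) * L
    with open(out_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in ref.chrom_names:
            fh.write(f"@SQ\tSN:{c}\tLN:{config.chrom_len}\n")
        if all_chrom:
            chroms = np.concatenate(all_chrom)
            starts = np.concatenate(all_start)
            reads = np.concatenate(all_reads)
            order = np.lexsort((starts, chroms))
            for k, j in enumerate(order):
                name = ref.chrom_names[chroms[j]]
                seq_str = _CODES[reads[j]].tobytes().decode("ascii")
                fh.write(
                    f"{sample_id}.{k}\t0\t{name}\t{starts[j] + 1}\t60\t{L}M\t*\t0\t0\t"
                    f"{seq_str}\t{qual}\n"
                )
    return out_path


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    reads: bool = True,
) -> SyntheticCohort:
    """Generate the full synthetic study.

    With ``reads=True`` (requires ``out_dir``) per-sample SAM files are
    written alongside the reference, annotations, expression matrix, cohort
    metadata and truth tables.  With ``reads=False`` measured indices and
    site tables are drawn directly from their exact sampling distributions
    instead (fast path; no files required unless ``out_dir`` is given).
    """
    if reads and out_dir is None:
        raise ValueError("out_dir is required when emitting reads")
    rng = np.random.default_rng(config.seed)
    ref = simulate_reference(config, rng)

    # --- per-sample truth -------------------------------------------------
    conc = config.epsilon_concentration
    rows = []
    sample_names: list[str] = []
    eps_values: list[float] = []
    for group in config.groups:
        for i in range(group.n):
            name = f"{group.name}{i + 1:02d}"
            m = group.alu_editing_rate
            eps = float(rng.beta(m * conc, (1 - m) * conc)) if m > 0 else 0.0
            tissue = config.tissues[len(sample_names) % len(config.tissues)]
            age = int(np.clip(round(rng.normal(60, 10)), 30, 90))
            sex = str(rng.choice(["F", "M"]))
            sample_names.append(name)
            eps_values.append(eps)
            rows.append(
                {"sample": name, "group": group.name, "tissue": tissue,
                 "epsilon": eps, "age": age, "sex": sex}
            )
    truth_samples = pd.DataFrame(rows)
    eps_arr = np.array(eps_values)
    z_eps = (eps_arr - eps_arr.mean()) / (eps_arr.std(ddof=0) or 1.0)
    eta = rng.normal(size=len(sample_names))
    isg_u = config.coupling * z_eps + np.sqrt(1 - config.coupling**2) * eta
    truth_samples["isg_u"] = isg_u

    # --- per-(sample, site) truth ----------------------------------------
    shifted = np.array([s.gene in SHIFTED_GENES for s in ref.sites])
    level_rows = []
    sample_levels: dict[str, np.ndarray] = {}
    sconc = config.site_level_concentration
    group_of = dict(zip(truth_samples["sample"], truth_samples["group"]))
    shift_of = {g.name: g.site_level_shift for g in config.groups}
    for row in truth_samples.itertuples():
        scale = config.tissue_scale(row.tissue)
        mean_levels = np.clip(
            ref.site_base_levels * scale + shifted * shift_of[row.group],
            0.005, 0.99,
        )
        levels = rng.beta(mean_levels * sconc, (1 - mean_levels) * sconc)
        sample_levels[row.sample] = levels
        for i, site in enumerate(ref.sites):
            level_rows.append(
                {"sample": row.sample, "site": site.site_id, "gene": site.gene,
                 "true_level": float(levels[i])}
            )
    truth_site_levels = pd.DataFrame(level_rows)

    # --- expression matrix -------------------------------------------------
    from .expression import ISGSignature

    isg_genes = list(ISGSignature.default().genes)
    marker_shift = dict(config.marker_log2_shifts)
    background = [f"BG{i:03d}" for i in range(config.n_background_genes)]
    genes = isg_genes + ["ADARB1"] + list(MARKER_GENES) + background
    base = rng.uniform(2.0, 9.0, size=len(genes))
    is_case = np.array(
        [config.groups[0].name != group_of[s] for s in sample_names], dtype=float
    )
    isg_shift_of = {g.name: g.isg_log2_shift for g in config.groups}
    sample_isg_shift = np.array([isg_shift_of[group_of[s]] for s in sample_names])
    log2 = np.empty((len(genes), len(sample_names)))
    for gi, gene in enumerate(genes):
        noise = rng.normal(0.0, config.gene_noise_sd, size=len(sample_names))
        if gene in isg_genes:
            log2[gi] = base[gi] + sample_isg_shift + config.isg_sd * isg_u + noise
        elif gene == "ADARB1":
            log2[gi] = base[gi] + noise  # uncoupled, no disease shift
        elif gene in marker_shift:
            log2[gi] = (
                base[gi]
                + marker_shift[gene] * is_case
                + rng.normal(0.0, config.marker_sd, size=len(sample_names))
                + noise
            )
        else:
            log2[gi] = base[gi] + rng.normal(0.0, 0.5, size=len(sample_names)) + noise
    expression = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, log2), index=genes, columns=sample_names)
    )

    design = CohortDesign(
        truth_samples[["sample", "group", "age", "sex", "tissue"]].copy()
    )

    cohort = SyntheticCohort(
        config=config,
        reference=ref,
        design=design,
        expression=expression,
        truth_samples=truth_samples,
        truth_site_levels=truth_site_levels,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.paths = ref.write(out_dir)
        expr_path = out_dir / "expression.tsv"
        expression.to_tsv(expr_path)
        cohort.paths["expression"] = expr_path
        cohort_path = out_dir / "cohort.tsv"
        design.to_tsv(cohort_path)
        cohort.paths["cohort"] = cohort_path
        ts = out_dir / "truth_samples.tsv"
        write_table(truth_samples, ts)
        cohort.paths["truth_samples"] = ts
        tl = out_dir / "truth_site_levels.tsv"
        write_table(truth_site_levels, tl)
        cohort.paths["truth_site_levels"] = tl

    if reads:
        reads_dir = Path(out_dir) / "reads"
        reads_dir.mkdir(exist_ok=True)
        sam_paths = {}
        for name in sample_names:
            sam_paths[name] = simulate_sample(
                config, ref, eps_arr[sample_names.index(name)],
                sample_levels[name], name, reads_dir / f"{name}.sam", rng,
            )
        cohort.sam_paths = sam_paths
    else:
        cohort.measured_aei, cohort.measured_sites = _draw_measurements(
            config, ref, truth_samples, sample_levels, rng
        )
    return cohort


def _draw_measurements(
    config: SimulationConfig,
    ref: ReferenceBundle,
    truth_samples: pd.DataFrame,
    sample_levels: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact sampling-distribution draws of the measured AEI and site tables."""
    e = config.seq_error_rate
    n_a = ref.planted_a_count
    aei_rows = []
    site_rows = []
    for row in truth_samples.itertuples():
        den = int(rng.poisson(n_a * config.coverage_mean))
        p_g = row.epsilon * (1 - e) + (1 - row.epsilon) * e / 3.0
        num = int(rng.binomial(den, p_g)) if den else 0
        aei_rows.append(
            {"sample": row.sample, "region_set": "all-Alu", "numerator": num,
             "denominator": den,
             "index_pct": 100.0 * num / den if den else np.nan}
        )
        levels = sample_levels[row.sample]
        cov = rng.poisson(config.coverage_mean * ref.site_coverage_mult)
        p_obs = levels * (1 - e) + (1 - levels) * e / 3.0
        edited = rng.binomial(cov, p_obs)
        for i, site in enumerate(ref.sites):
            c, ed = int(cov[i]), int(edited[i])
            site_rows.append(
                {"sample": row.sample, "site": site.site_id, "chrom": site.chrom,
                 "pos": site.pos, "strand": site.strand, "gene": site.gene,
                 "klass": site.klass, "coverage": c, "edited": ed,
                 "level_pct": 100.0 * ed / c if c else np.nan,
                 "included": c >= 10, "detected": ed >= 1 and c > 0 and ed / c >= 0.001}
            )
    return pd.DataFrame(aei_rows), pd.DataFrame(site_rows)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def parse_config_file(path: str | Path) -> SimulationConfig:
    """Parse a ``key = value`` configuration file into a SimulationConfig.

    Values are Python literals (``ast.literal_eval``); the ``groups`` key
    takes a list of (name, n, alu_editing_rate[, site_level_shift,
    isg_log2_shift]) tuples.  Unknown keys raise.
    """
    overrides: dict = {}
    valid = set(SimulationConfig.__dataclass_fields__)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            parsed = ast.literal_eval(value.strip())
            if key == "groups":
                parsed = tuple(GroupSpec(*g) for g in parsed)
            overrides[key] = parsed
    return SimulationConfig(**overrides)
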