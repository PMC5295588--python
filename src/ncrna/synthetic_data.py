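"""Synthetic developmental RNA-seq data with the statistical structure the
downstream analyses assume.

The generator emulates a compact AT-rich genome in the style of the
*Dictyostelium discoideum* developmental study: GC-poor intergenic space
(~13% GC) separating GC-richer coding loci (~25% GC in ORFs) and intergenic
lncRNA loci (~17% GC); a 13-point, 2 hr-spaced developmental time course in
two replicates whose transcriptome moves gradually within stages and leaps
at two stage boundaries; strand-specific paired-end alignments including
template strand-switch artifacts that mirror spliced sense fragments onto
the antisense strand; and a multicopy tRNA complement with A-to-G edited
reads at the wobble position of designated alleles.

Reads are emitted directly as SAM alignments (the alignment step itself is
out of scope), which keeps every downstream stage testable and hermetic.
Every emitted read names its source transcript, so parameter-recovery tests
can compare pipeline output to ground truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .genetic_code import (
    SENSE_CODONS,
    anticodon_amino_acid,
    AA_THREE_LETTER,
    reverse_complement,
    to_rna,
)
from .io_formats import GeneModel, GenomeAnnotation, GenomicInterval
from .trna import TRNAComplement, TRNAGene, VariantCall


class CapacityError(ValueError):
    """Requested gene complement does not fit in the requested genome."""


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic study, with study defaults."""

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 2
    chromosome_length_bp: int = 200_000
    n_coding_genes: int = 150
    n_lncrna_loci: int = 50
    n_asrna_loci: int = 10
    median_intergenic_gap: int = 700
    gc_intergenic: float = 0.13
    gc_orf: float = 0.25
    gc_lncrna: float = 0.17
    coding_length_median: int = 1100
    coding_length_sigma: float = 0.35
    coding_length_clip: Tuple[int, int] = (400, 2200)
    lncrna_length_median: int = 628
    lncrna_length_sigma: float = 0.45
    lncrna_length_clip: Tuple[int, int] = (250, 1500)
    exon_count_probs: Tuple[float, ...] = (0.3, 0.5, 0.2)  # P(1, 2, 3 exons)
    intron_range: Tuple[int, int] = (70, 500)
    # expression program
    n_timepoints: int = 13
    time_step_hr: float = 2.0
    replicates: int = 2
    stage_boundaries: Tuple[int, ...] = (6, 9)  # leaps into 12 hr and 18 hr
    bump_width_hr: float = 5.0
    stage_sigma: float = 0.5
    replicate_sigma: float = 0.1
    mrna_rpkm_median: float = 41.0
    mrna_rpkm_sigma: float = 0.8
    lncrna_rpkm_median: float = 1.0
    lncrna_rpkm_sigma: float = 0.6
    asrna_rpkm_median: float = 8.0
    asrna_rpkm_sigma: float = 0.5
    # library
    library_size: int = 5_000_000  # mapped fragments per sample (notional)
    artifact_rate: float = 0.1
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 20.0
    min_artifact_intron_fraction: float = 0.06
    # tRNA complement
    n_trna_families: int = 41  # distinct anticodons; leaves 20 codons uncovered
    trna_copy_max: int = 22
    trna_length_range: Tuple[int, int] = (72, 90)
    trna_wobble_index: int = 33  # 0-based offset of anticodon base 34
    n_edited_families: int = 2
    f_edit: float = 0.4
    trna_error_rate: float = 0.002
    trna_coverage: int = 200
    trna_read_length: int = 35

    def __post_init__(self) -> None:
        for name in ("gc_intergenic", "gc_orf", "gc_lncrna"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if any(not 0 < b < self.n_timepoints for b in self.stage_boundaries):
            raise ValueError("stage_boundaries must be interior time indices")
        if not 0 <= self.f_edit <= 1:
            raise ValueError("f_edit must lie in [0, 1]")

    @property
    def times_hr(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.time_step_hr

    @property
    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for ti, t in enumerate(self.times_hr):
            for rep in range(1, self.replicates + 1):
                rows.append((f"t{int(t):02d}r{rep}", float(t), rep))
        return pd.DataFrame(
            rows, columns=["sample", "time_hr", "replicate"]
        ).set_index("sample")

    def stage_of(self, time_index: int) -> int:
        return int(np.searchsorted(np.asarray(self.stage_boundaries), time_index, "right"))


@dataclass
class GroundTruth:
    """Per-transcript truth that downstream recovery tests compare against."""

    classes: Dict[str, str] = field(default_factory=dict)
    source_gene: Dict[str, str] = field(default_factory=dict)
    artifact_models: List[str] = field(default_factory=list)
    abundance: Optional[AbundanceMatrix] = None
    fragment_counts: Optional[pd.DataFrame] = None


@dataclass
class SimulatedGenome:
    sequences: Dict[str, str]
    reference: GenomeAnnotation  # the "known" gene models (coding only)
    models: GenomeAnnotation  # assembled transcript models, incl. artifacts
    cds_sequences: Dict[str, str]
    truth: GroundTruth
    config: SimulationConfig


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """A stop-free reading frame of ``length`` bp (multiple of 3) at ~``gc``."""
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    weights = np.array(
        [math.prod(base_p[b] for b in codon) for codon in SENSE_CODONS]
    )
    weights /= weights.sum()
    n_codons = length // 3 - 2
    idx = rng.choice(len(SENSE_CODONS), size=max(n_codons, 0), p=weights)
    body = "".join(SENSE_CODONS[i] for i in idx)
    return "ATG" + body + "TAA"


@dataclass
class _Locus:
    locus_id: str
    kind: str  # 'coding' | 'lncRNA'
    strand: str
    exon_lengths: List[int]
    intron_lengths: List[int]

    @property
    def exonic(self) -> int:
        return sum(self.exon_lengths)

    @property
    def span(self) -> int:
        return self.exonic + sum(self.intron_lengths)


def _draw_locus(rng: np.random.Generator, cfg: SimulationConfig, kind: str,
                locus_id: str) -> _Locus:
    if kind == "coding":
        med, sig, clip = (
            cfg.coding_length_median, cfg.coding_length_sigma, cfg.coding_length_clip
        )
        n_exons = 1 + rng.choice(len(cfg.exon_count_probs), p=cfg.exon_count_probs)
    else:
        med, sig, clip = (
            cfg.lncrna_length_median, cfg.lncrna_length_sigma, cfg.lncrna_length_clip
        )
        n_exons = 1 if rng.random() < 0.9 else 2
    exonic = int(np.clip(rng.lognormal(math.log(med), sig), *clip))
    if kind == "coding":
        exonic -= exonic % 3
    cuts = np.sort(rng.choice(np.arange(1, exonic // 50), size=n_exons - 1,
                              replace=False)) * 50 if n_exons > 1 else np.array([], int)
    bounds = [0, *cuts.tolist(), exonic]
    exon_lengths = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1,
                           size=n_exons - 1).tolist()
    strand = "+" if rng.random() < 0.5 else "-"
    return _Locus(locus_id, kind, strand, exon_lengths, introns)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate chromosome sequences, the reference annotation, the assembled
    transcript models (including strand-switch artifact models), and truth.

    Deterministic for a fixed seed. Raises :class:`CapacityError` when the
    requested complement cannot be placed even after compressing intergenic
    gaps to the 100 bp floor.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    contig_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # draw all loci, then deal them round-robin across chromosomes
    loci: List[_Locus] = []
    for i in range(cfg.n_coding_genes):
        loci.append(_draw_locus(rng, cfg, "coding", f"g{i + 1:04d}"))
    for i in range(cfg.n_lncrna_loci):
        loci.append(_draw_locus(rng, cfg, "lncRNA", f"lnc{i + 1:04d}"))
    order = rng.permutation(len(loci))
    per_chrom: List[List[_Locus]] = [[] for _ in contig_names]
    for k, idx in enumerate(order):
        per_chrom[k % cfg.n_chromosomes].append(loci[idx])

    sequences: Dict[str, str] = {}
    ref_genes: List[GeneModel] = []
    model_genes: List[GeneModel] = []
    cds_sequences: Dict[str, str] = {}
    truth = GroundTruth()
    gene_spans: Dict[str, GeneModel] = {}

    for contig, chrom_loci in zip(contig_names, per_chrom):
        L = cfg.chromosome_length_bp
        # one leading gap per locus; trailing space is whatever remains
        gaps = rng.lognormal(
            math.log(cfg.median_intergenic_gap), 0.35, size=len(chrom_loci)
        )
        gaps = np.maximum(gaps, 150.0)
        need = sum(l.span for l in chrom_loci)
        slack = L - need
        min_gap = 100.0
        if slack < min_gap * len(gaps):
            raise CapacityError(
                f"{contig}: {len(chrom_loci)} loci need "
                f"{need + int(min_gap) * len(gaps)} bp but only {L} bp available"
            )
        if gaps.sum() > slack:
            # compress gaps uniformly to fit, waterfilling the 100 bp floor
            free = np.ones(len(gaps), dtype=bool)
            budget = float(slack)
            for _ in range(len(gaps)):
                scaled = gaps[free] * budget / gaps[free].sum()
                if (scaled >= min_gap).all():
                    gaps[free] = scaled
                    break
                newly = free.copy()
                newly[free] = scaled < min_gap
                gaps[newly] = min_gap
                free &= ~newly
                budget = slack - min_gap * (~free).sum()
                if not free.any():
                    break
        gaps = np.floor(gaps).astype(int)
        seq = _random_bases(rng, L, cfg.gc_intergenic).copy()
        cursor = 0
        for gap, locus in zip(gaps, chrom_loci):
            cursor += int(gap)
            exons: List[GenomicInterval] = []
            pos = cursor
            for j, elen in enumerate(locus.exon_lengths):
                exons.append(GenomicInterval(contig, pos, pos + elen, locus.strand))
                pos += elen
                if j < len(locus.intron_lengths):
                    pos += locus.intron_lengths[j]
            if locus.kind == "coding":
                tx_seq = _random_orf(rng, locus.exonic, cfg.gc_orf)
                cds_sequences[locus.locus_id] = tx_seq
            else:
                tx_seq = _random_bases(rng, locus.exonic, cfg.gc_lncrna).tobytes().decode()
            genomic = tx_seq if locus.strand == "+" else reverse_complement(tx_seq)
            off = 0
            for iv in exons:
                seq[iv.start : iv.end] = np.frombuffer(
                    genomic[off : off + len(iv)].encode(), dtype=np.uint8
                )
                off += len(iv)
            if locus.kind == "coding":
                gene = GeneModel(locus.locus_id, tuple(exons), "protein_coding",
                                 cds=tuple(exons))
                ref_genes.append(gene)
                gene_spans[locus.locus_id] = gene
                model_id = f"TM.{locus.locus_id}"
                model_genes.append(GeneModel(model_id, tuple(exons), "other"))
                truth.classes[model_id] = "mRNA"
                truth.source_gene[model_id] = locus.locus_id
            else:
                model_genes.append(GeneModel(locus.locus_id, tuple(exons), "other"))
                truth.classes[locus.locus_id] = "lncRNA"
            cursor = pos
        sequences[contig] = seq.tobytes().decode()

    # true antisense transcripts: contiguous opposite-strand coverage inside genes
    wide = [g for g in ref_genes if len(g.span) >= 500]
    as_genes = rng.choice(len(wide), size=min(cfg.n_asrna_loci, len(wide)),
                          replace=False)
    as_gene_ids = set()
    for k, gi in enumerate(sorted(as_genes)):
        gene = wide[gi]
        span = len(gene.span)
        length = int(min(span - 40, rng.integers(400, 900)))
        start = gene.start + int(rng.integers(0, span - length))
        strand = "-" if gene.strand == "+" else "+"
        model_id = f"AS{k + 1:04d}"
        iv = GenomicInterval(gene.contig, start, start + length, strand)
        model_genes.append(GeneModel(model_id, (iv,), "other"))
        truth.classes[model_id] = "asRNA"
        truth.source_gene[model_id] = gene.gene_id
        as_gene_ids.add(gene.gene_id)

    # strand-switch artifact models mirror the exon chain of spliced genes
    if cfg.artifact_rate > 0:
        for gene in ref_genes:
            if gene.gene_id in as_gene_ids or len(gene.intervals) == 1:
                continue
            intron_fraction = 1 - gene.exonic_length / len(gene.span)
            if intron_fraction <= cfg.min_artifact_intron_fraction:
                continue
            strand = "-" if gene.strand == "+" else "+"
            exons = tuple(
                GenomicInterval(iv.contig, iv.start, iv.end, strand)
                for iv in gene.intervals
            )
            model_id = f"ART.{gene.gene_id}"
            model_genes.append(GeneModel(model_id, exons, "other"))
            truth.classes[model_id] = "artifact"
            truth.source_gene[model_id] = gene.gene_id
            truth.artifact_models.append(model_id)

    contig_lengths = {c: cfg.chromosome_length_bp for c in contig_names}
    return SimulatedGenome(
        sequences=sequences,
        reference=GenomeAnnotation(ref_genes, contig_lengths),
        models=GenomeAnnotation(model_genes, contig_lengths),
        cds_sequences=cds_sequences,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# expression program
# ---------------------------------------------------------------------------

_CLASS_PARAMS = {
    "mRNA": ("mrna_rpkm_median", "mrna_rpkm_sigma"),
    "lncRNA": ("lncrna_rpkm_median", "lncrna_rpkm_sigma"),
    "asRNA": ("asrna_rpkm_median", "asrna_rpkm_sigma"),
}


def simulate_expression(
    genome: SimulatedGenome, config: Optional[SimulationConfig] = None
) -> AbundanceMatrix:
    """Assign every non-artifact transcript a staged temporal program.

    Each transcript follows a Gaussian activation bump (peak time uniform over
    the course, width ``bump_width_hr``) multiplied by per-stage factors that
    are redrawn independently at each stage boundary, so adjacent time points
    decorrelate more across boundaries than within stages. Per-transcript
    maxima are log-normal around the class medians (41 RPKM for mRNA, 1.0 for
    lncRNA). Replicate columns add log-normal measurement noise.
    """
    cfg = config or genome.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    times = cfg.times_hr
    stages = np.array([cfg.stage_of(i) for i in range(cfg.n_timepoints)])
    n_stages = stages.max() + 1

    ids = [m for m, k in genome.truth.classes.items() if k != "artifact"]
    true_profiles = {}
    for mid in ids:
        klass = genome.truth.classes[mid]
        med_name, sig_name = _CLASS_PARAMS[klass]
        peak = rng.lognormal(math.log(getattr(cfg, med_name)), getattr(cfg, sig_name))
        tau = rng.uniform(times[0] - 2, times[-1] + 2)
        shape = np.exp(-((times - tau) ** 2) / (2 * cfg.bump_width_hr**2))
        if cfg.stage_sigma > 0:
            g = np.exp(rng.normal(0, cfg.stage_sigma, size=n_stages))
            shape = shape * g[stages]
        true_profiles[mid] = peak * shape / shape.max()

    meta = cfg.sample_meta
    values = np.empty((len(ids), len(meta)))
    for i, mid in enumerate(ids):
        noise = (
            np.exp(rng.normal(0, cfg.replicate_sigma, size=len(meta)))
            if cfg.replicate_sigma > 0
            else np.ones(len(meta))
        )
        values[i] = np.repeat(true_profiles[mid], cfg.replicates) * noise

    df = pd.DataFrame(values, index=ids, columns=meta.index)
    lengths = pd.Series(
        {mid: genome.models.genes[mid].exonic_length for mid in ids}, name="mappable_length_bp"
    )
    matrix = AbundanceMatrix(values=df, sample_meta=meta, mappable_length=lengths)
    genome.truth.abundance = matrix
    return matrix


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

class _Layout:
    """Transcript-to-genome coordinate mapping for one exon chain."""

    def __init__(self, exons: Sequence[GenomicInterval], strand: str) -> None:
        self.strand = strand
        self.exons = list(exons) if strand == "+" else list(exons)[::-1]
        self.lengths = [len(e) for e in self.exons]
        self.tx_length = sum(self.lengths)
        self.cum = np.concatenate([[0], np.cumsum(self.lengths)])

    def blocks(self, a: int, b: int) -> List[Tuple[int, int]]:
        """Genomic (start, end) blocks covering transcript interval [a, b)."""
        out = []
        for i, exon in enumerate(self.exons):
            ts, te = self.cum[i], self.cum[i + 1]
            o0, o1 = max(a, ts), min(b, te)
            if o1 <= o0:
                continue
            if self.strand == "+":
                g0 = exon.start + (o0 - ts)
                out.append((g0, g0 + (o1 - o0)))
            else:
                g1 = exon.end - (o0 - ts)
                out.append((g1 - (o1 - o0), g1))
        out.sort()
        return out


def _cigar(blocks: List[Tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_reads(
    genome: SimulatedGenome,
    abundance: Optional[AbundanceMatrix],
    config: Optional[SimulationConfig],
    out_sam: str | Path,
) -> pd.DataFrame:
    """Emit strand-specific paired 100 bp alignments to ``out_sam``.

    Fragment counts are Poisson around RPKM x length x library_size / 1e9.
    Spliced fragments carry N CIGAR gaps over introns. At loci designated as
    artifact-prone, a fraction ``artifact_rate`` of spliced sense fragments is
    re-emitted with flipped strand flags (a strand-switch event), so their
    tiling gaps coincide with sense introns. Returns the per-model, per-sample
    emitted fragment counts (ground truth for the counting stage).
    """
    cfg = config or genome.config
    if abundance is None:
        abundance = genome.truth.abundance
    if abundance is None:
        raise ValueError("run simulate_expression first")
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    meta = cfg.sample_meta
    samples = list(meta.index)
    rl = cfg.read_length

    artifact_sources = {
        genome.truth.source_gene[a]: a for a in genome.truth.artifact_models
    }
    model_ids = list(abundance.values.index)
    count_rows = model_ids + genome.truth.artifact_models
    counts = pd.DataFrame(0, index=count_rows, columns=samples, dtype=int)

    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in sorted(genome.sequences):
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(genome.sequences[contig])}\n")
        for s in samples:
            fh.write(f"@RG\tID:{s}\tSM:{s}\n")

        for mid in model_ids:
            model = genome.models.genes[mid]
            layout = _Layout(model.intervals, model.strand)
            T = layout.tx_length
            spliced = len(model.intervals) > 1
            gene_id = genome.truth.source_gene.get(mid)
            art_id = artifact_sources.get(gene_id) if gene_id else None
            lam_scale = T * cfg.library_size / 1e9
            for sample in samples:
                lam = abundance.values.at[mid, sample] * lam_scale
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                flens = np.clip(
                    rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n), rl, T
                ).astype(int)
                starts = rng.integers(0, np.maximum(T - flens, 0) + 1)
                mirrored = (
                    rng.random(n) < cfg.artifact_rate
                    if (spliced and art_id is not None)
                    else np.zeros(n, dtype=bool)
                )
                counts.at[mid, sample] += int(n - mirrored.sum())
                if art_id is not None:
                    counts.at[art_id, sample] += int(mirrored.sum())
                for i in range(n):
                    s, flen = int(starts[i]), int(flens[i])
                    rlen = min(rl, flen)
                    b1 = layout.blocks(s, s + rlen)
                    b2 = layout.blocks(s + flen - rlen, s + flen)
                    sense = model.strand
                    tag = ""
                    if mirrored[i]:
                        sense = "-" if sense == "+" else "+"
                        tag = ".A"
                    name = f"{art_id if mirrored[i] else mid}:{sample}:{i}{tag}"
                    if sense == "+":
                        f1, f2 = 99, 147
                    else:
                        f1, f2 = 83, 163
                    p1, p2 = b1[0][0], b2[0][0]
                    left = min(p1, p2)
                    right = max(b1[-1][1], b2[-1][1])
                    tlen = right - left
                    for flag, pos, blocks, mpos in (
                        (f1, p1, b1, p2),
                        (f2, p2, b2, p1),
                    ):
                        t = tlen if pos == left else -tlen
                        fh.write(
                            f"{name}\t{flag}\t{model.contig}\t{pos + 1}\t50\t"
                            f"{_cigar(blocks)}\t=\t{mpos + 1}\t{t}\t*\t*\t"
                            f"RG:Z:{sample}\tNH:i:1\n"
                        )
    genome.truth.fragment_counts = counts
    return counts


# ---------------------------------------------------------------------------
# tRNA complement
# ---------------------------------------------------------------------------

@dataclass
class TrnaRead:
    contig: str
    start: int
    bases: str


@dataclass
class SimulatedTrna:
    reference: Dict[str, str]  # contig -> sequence (unique tRNA alleles)
    complement: TRNAComplement
    reads: List[TrnaRead]
    pileup: pd.DataFrame  # contig, pos, ref, A, C, G, T
    edited_contigs: Dict[str, float]  # contig -> true edited fraction
    true_family_reads: Dict[str, int]


def _valid_anticodons() -> List[str]:
    return [reverse_complement(c) for c in SENSE_CODONS]


def simulate_trna(config: SimulationConfig) -> SimulatedTrna:
    """Generate a multicopy tRNA complement, reads, and a base-count pileup.

    Families carry 1-2 unique allele sequences; designated alleles show an
    A->G fraction ``f_edit`` at the wobble position (anticodon base 34);
    background sequencing error is positionally i.i.d. at ``trna_error_rate``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 3_000_003)
    anticodons = _valid_anticodons()
    # prefer some A34 anticodons so editing has substrates
    a34 = [a for a in anticodons if a[0] == "A"]
    others = [a for a in anticodons if a[0] != "A"]
    n_a34 = min(max(cfg.n_edited_families * 2, 4), len(a34), cfg.n_trna_families)
    chosen = list(rng.choice(a34, size=n_a34, replace=False)) + list(
        rng.choice(others, size=cfg.n_trna_families - n_a34, replace=False)
    )

    genes: List[TRNAGene] = []
    edited_contigs: Dict[str, float] = {}
    n_edited = 0
    for anticodon in chosen:
        aa3 = AA_THREE_LETTER[anticodon_amino_acid(anticodon)]
        family_id = f"tRNA-{aa3}-{to_rna(anticodon)}"
        n_copies = int(min(1 + rng.poisson(3), cfg.trna_copy_max))
        n_alleles = 1 if n_copies == 1 or rng.random() < 0.6 else 2
        length = int(rng.integers(*cfg.trna_length_range))
        wob = cfg.trna_wobble_index
        base_seq = _random_bases(rng, length, 0.5).tobytes().decode()
        base_seq = base_seq[:wob] + anticodon + base_seq[wob + 3 :]
        allele_seqs = [base_seq]
        if n_alleles == 2:
            mut_pos = int(rng.choice([p for p in range(length) if not wob <= p < wob + 3]))
            alt = "ACGT"[(("ACGT".index(base_seq[mut_pos])) + 1) % 4]
            allele_seqs.append(base_seq[:mut_pos] + alt + base_seq[mut_pos + 1 :])
        per = n_copies // n_alleles
        for ai, seq in enumerate(allele_seqs):
            n_this = per + (1 if ai < n_copies - per * n_alleles else 0)
            if n_this == 0:
                continue
            locations = [
                (f"chr{int(rng.integers(1, 7))}", int(rng.integers(0, 1_000_000)))
                for _ in range(n_this)
            ]
            gene = TRNAGene(
                family_id=family_id,
                anticodon=anticodon,
                sequence=seq,
                copy_locations=locations,
                wobble_index=wob,
            )
            if (
                anticodon[0] == "A"
                and n_edited < cfg.n_edited_families
                and ai == 0
            ):
                edited_contigs[f"{family_id}.{ai + 1}"] = cfg.f_edit
                n_edited += 1
            genes.append(gene)

    from .trna import build_reference  # late import avoids a cycle

    complement = build_reference(genes)
    reference = complement.contig_sequences()

    reads: List[TrnaRead] = []
    pileup_counts: Dict[str, np.ndarray] = {
        c: np.zeros((len(seq), 4), dtype=int) for c, seq in reference.items()
    }
    family_reads: Dict[str, int] = {}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    family_factor = {
        fam: rng.lognormal(0, 0.5) for fam in complement.families()
    }
    rlen = cfg.trna_read_length
    for contig in sorted(reference):
        seq = reference[contig]
        gene = complement.contig_gene(contig)
        lam = cfg.trna_coverage * family_factor[gene.family_id] * len(seq) / rlen
        n_reads = int(rng.poisson(lam))
        family_reads[gene.family_id] = family_reads.get(gene.family_id, 0) + n_reads
        f_edit = edited_contigs.get(contig, 0.0)
        wob = gene.wobble_index
        for _ in range(n_reads):
            start = int(rng.integers(0, len(seq) - rlen + 1))
            bases = list(seq[start : start + rlen])
            if f_edit > 0 and start <= wob < start + rlen and rng.random() < f_edit:
                bases[wob - start] = "G"
            err = rng.random(rlen) < cfg.trna_error_rate
            for j in np.flatnonzero(err):
                choices = [b for b in "ACGT" if b != bases[j]]
                bases[j] = choices[int(rng.integers(0, 3))]
            read = "".join(bases)
            reads.append(TrnaRead(contig, start, read))
            for j, b in enumerate(read):
                pileup_counts[contig][start + j, base_idx[b]] += 1

    rows = []
    for contig in sorted(reference):
        seq = reference[contig]
        for pos in range(len(seq)):
            a, c, g, t = pileup_counts[contig][pos]
            rows.append((contig, pos, seq[pos], a, c, g, t))
    pileup = pd.DataFrame(rows, columns=["contig", "pos", "ref", "A", "C", "G", "T"])
    return SimulatedTrna(
        reference=reference,
        complement=complement,
        reads=reads,
        pileup=pileup,
        edited_contigs=edited_contigs,
        true_family_reads=family_reads,
    )


# ---------------------------------------------------------------------------
# planted editing-compensation design
# ---------------------------------------------------------------------------

def random_complement(
    seed: int, n_families: int = 15, wobble_index: int = 33, length: int = 76
) -> TRNAComplement:
    """A random tRNA complement (distinct anticodons), for property tests."""
    rng = np.random.default_rng(seed)
    anticodons = rng.choice(_valid_anticodons(), size=n_families, replace=False)
    genes = []
    for anticodon in anticodons:
        aa3 = AA_THREE_LETTER[anticodon_amino_acid(anticodon)]
        seq = _random_bases(rng, length, 0.5).tobytes().decode()
        seq = seq[:wobble_index] + anticodon + seq[wobble_index + 3 :]
        genes.append(
            TRNAGene(
                family_id=f"tRNA-{aa3}-{to_rna(anticodon)}",
                anticodon=anticodon,
                sequence=seq,
                copy_locations=[("chr1", int(rng.integers(0, 1_000_000)))],
                wobble_index=wobble_index,
            )
        )
    from .trna import build_reference

    return build_reference(genes)


#: sense codons (DNA) deliberately left without a Watson-Crick cognate:
#: four rescuable by A-to-I editing of an A34 isoacceptor, four not.
PLANTED_EDITING_COVERED = ("TTC", "AAC", "GAC", "CAC")
PLANTED_UNEXPLAINED = ("AAA", "GAA", "CAA", "AGA")


def planted_editing_complement(
    wobble_index: int = 33, length: int = 76
) -> Tuple[TRNAComplement, List[VariantCall]]:
    """A deterministic complement with exactly eight missing codons, four of
    which are rescued by observed A->G variants at the wobble position.

    Every sense codon except the eight planted ones gets its Watson-Crick
    anticodon. The rescuable four are NNC codons whose amino acid's only
    isoacceptor carries A34 (editable to inosine); the unexplained four are
    NNA codons whose only isoacceptor carries C34 (pairs G only, not
    editable).
    """
    from .trna import build_reference

    missing = set(PLANTED_EDITING_COVERED) | set(PLANTED_UNEXPLAINED)
    genes = []
    rng = np.random.default_rng(12345)
    for codon in SENSE_CODONS:
        if codon in missing:
            continue
        anticodon = reverse_complement(codon)
        aa3 = AA_THREE_LETTER[anticodon_amino_acid(anticodon)]
        family_id = f"tRNA-{aa3}-{to_rna(anticodon)}"
        seq = _random_bases(rng, length, 0.5).tobytes().decode()
        seq = seq[:wobble_index] + anticodon + seq[wobble_index + 3 :]
        genes.append(
            TRNAGene(
                family_id=family_id,
                anticodon=anticodon,
                sequence=seq,
                copy_locations=[("chr1", int(rng.integers(0, 1_000_000)))],
                wobble_index=wobble_index,
            )
        )
    complement = build_reference(genes)

    variants = []
    for codon in PLANTED_EDITING_COVERED:
        # the editable isoacceptor reads the NNT codon via its A34 anticodon
        partner = codon[:2] + "T"
        anticodon = reverse_complement(partner)
        assert anticodon[0] == "A"
        aa3 = AA_THREE_LETTER[anticodon_amino_acid(anticodon)]
        contig = f"tRNA-{aa3}-{to_rna(anticodon)}.1"
        variants.append(
            VariantCall(
                contig=contig,
                position=wobble_index,
                ref_base="A",
                alt_base="G",
                ref_count=120,
                alt_count=80,
                p_value=1e-30,
                in_anticodon=True,
                anticodon_offset=0,
            )
        )
    complement.variants = variants
    return complement, variants
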