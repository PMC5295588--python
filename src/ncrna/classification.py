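"""Transcript-model classification and the noncoding filter suite.

Assembled models are first partitioned by overlap with the reference
annotation (same-strand overlap -> mRNA; opposite-strand-only -> asRNA
candidate; no overlap -> lncRNA candidate). lncRNA candidates must be at
least 200 bp, show at least two raw fragments at some time point, have
non-zero abundance, and lack any contiguous tiling path bridging them to a
flanking gene. Antisense candidates are screened for template strand-switch
artifacts: a tiling path built only from properly paired, single-M
("100 M"-style) full-length-match reads whose gaps exceed 5% of the model
span marks the model as an artifact, the gaps typically coinciding with
sense-strand introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ReadTable,
    as_read_table,
)

VALID_CLASSES = ("mRNA", "lncRNA", "asRNA", "rejected")


@dataclass
class TilingPath:
    """Intervals of a region covered by properly paired full-match reads."""

    region: GenomicInterval
    covered: Tuple[Tuple[int, int], ...]
    supporting_read_count: int

    def __post_init__(self) -> None:
        for (s, e) in self.covered:
            if not (self.region.start <= s < e <= self.region.end):
                raise ValueError("covered interval outside region")
        for (a, b) in zip(self.covered, self.covered[1:]):
            if b[0] <= a[1]:
                raise ValueError("covered intervals not disjoint/sorted")

    @property
    def covered_length(self) -> int:
        return sum(e - s for s, e in self.covered)


@dataclass
class ClassifiedModel:
    model: GeneModel
    klass: str
    filter_log: List[Tuple[str, bool]] = field(default_factory=list)
    strand_specificity: Optional[float] = None
    orf_max_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.klass not in VALID_CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass == "rejected" and all(ok for _, ok in self.filter_log):
            raise ValueError("rejected model without a failing filter")


def classify_models(
    models: Iterable[GeneModel], annotation: GenomeAnnotation
) -> Dict[str, str]:
    """Initial class per model from overlap with the reference annotation."""
    out: Dict[str, str] = {}
    known = set(annotation.contigs) | set(annotation.contig_lengths)
    for m in models:
        if known and m.contig not in known:
            raise ValueError(f"model {m.gene_id} on unknown contig {m.contig}")
        same = annotation.overlapping(m.span, strand=m.strand)
        opposite = annotation.overlapping(
            m.span, strand="-" if m.strand == "+" else "+"
        )
        if same:
            out[m.gene_id] = "mRNA"
        elif opposite:
            out[m.gene_id] = "asRNA"
        else:
            out[m.gene_id] = "lncRNA"
    return out


def compute_tiling_path(region: GenomicInterval, alignments) -> TilingPath:
    """Union of reference spans of properly paired, single-M full-match reads
    on the region's strand (any strand when the region is unstranded)."""
    reads = as_read_table(alignments)
    idx = reads.overlapping(region.contig, region.start, region.end)
    keep = reads.properly_paired[idx] & reads.full_match[idx]
    if region.strand != ".":
        keep &= reads.strand[idx] == (1 if region.strand == "+" else -1)
    idx = idx[keep]
    if not len(idx):
        return TilingPath(region, (), 0)
    starts = np.clip(reads.start[idx], region.start, region.end)
    ends = np.clip(reads.end[idx], region.start, region.end)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged: List[Tuple[int, int]] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            if cur_e > cur_s:
                merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
        else:
            cur_e = max(cur_e, int(e))
    if cur_e > cur_s:
        merged.append((cur_s, cur_e))
    return TilingPath(region, tuple(merged), int(len(idx)))


def tiling_gap_fraction(
    path: TilingPath, span: Optional[GenomicInterval] = None
) -> float:
    """(span length - covered length within span) / span length.

    A model is retained iff the fraction does not exceed the configured cut
    (strictly "exceeded" triggers removal, so exactly 5% is retained).
    """
    span = span or path.region
    if len(span) <= 0:
        raise ValueError("zero-length span")
    covered = sum(
        max(0, min(e, span.end) - max(s, span.start)) for s, e in path.covered
    )
    return (len(span) - covered) / len(span)


def composite_region(a, b) -> GenomicInterval:
    """Minimal contiguous interval fully including both spans."""
    ia = a.span if isinstance(a, GeneModel) else a
    ib = b.span if isinstance(b, GeneModel) else b
    if ia.contig != ib.contig:
        raise ValueError(f"spans on different contigs: {ia.contig} vs {ib.contig}")
    return GenomicInterval(
        ia.contig, min(ia.start, ib.start), max(ia.end, ib.end), "."
    )


def strand_specificity(
    region: GenomicInterval, sense_strand: str, alignments
) -> Optional[float]:
    """Fraction of properly paired reads in ``region`` whose fragment strand
    is the sense strand, pooled over all samples; None when no reads."""
    if sense_strand not in ("+", "-"):
        raise ValueError(f"invalid sense strand {sense_strand!r}")
    reads = as_read_table(alignments)
    idx = reads.overlapping(region.contig, region.start, region.end)
    idx = idx[reads.properly_paired[idx]]
    if not len(idx):
        return None
    sense = int((reads.strand[idx] == (1 if sense_strand == "+" else -1)).sum())
    return sense / len(idx)


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def find_orfs(
    transcript_sequence: str, min_len_bp: int = 150
) -> Tuple[List[Dict], bool]:
    """Scan the three forward frames for ATG..stop ORFs of >= ``min_len_bp``
    (length includes the stop codon). The input is the stranded transcript,
    already reverse-complemented for minus-strand models.

    Returns the ORF list (frame, start, end, length_bp) and a coding
    potential flag (any qualifying ORF found).
    """
    seq = transcript_sequence.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN symbols in sequence: {bad}")
    orfs: List[Dict] = []
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if length >= min_len_bp:
                    orfs.append(
                        {"frame": frame, "start": start, "end": i + 3,
                         "length_bp": length}
                    )
                start = None
    orfs.sort(key=lambda o: -o["length_bp"])
    return orfs, bool(orfs)


# ---------------------------------------------------------------------------
# filter suites
# ---------------------------------------------------------------------------

def _pooled_counts(
    counts: pd.DataFrame, sample_meta: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Counts pooled per time point (replicates summed) when metadata given."""
    if sample_meta is None:
        return counts
    groups = sample_meta.loc[list(counts.columns), "time_hr"]
    return counts.T.groupby(groups).sum().T


def filter_lncrna(
    candidates: Sequence[GeneModel],
    raw_counts: pd.DataFrame,
    abundance: pd.DataFrame,
    annotation: GenomeAnnotation,
    alignments,
    min_length: int = 200,
    min_reads: int = 2,
    sample_meta: Optional[pd.DataFrame] = None,
) -> Tuple[List[GeneModel], Dict[str, List[Tuple[str, bool]]]]:
    """Apply the intergenic lncRNA filter suite.

    A candidate survives iff its spliced length is >= ``min_length``, it has
    >= ``min_reads`` raw fragments at some time point, non-zero abundance at
    some time point, and no tiling path of contiguous read coverage bridges
    the gap between it and either flanking gene on its strand.
    """
    reads = as_read_table(alignments)
    pooled = _pooled_counts(raw_counts, sample_meta)
    survivors, logs = [], {}
    for cand in candidates:
        if cand.gene_id not in raw_counts.index:
            raise KeyError(f"no count row for candidate {cand.gene_id}")
        log: List[Tuple[str, bool]] = []
        log.append(("min_length_200", cand.exonic_length >= min_length))
        log.append(
            ("min_raw_reads_any_timepoint",
             int(pooled.loc[cand.gene_id].max()) >= min_reads)
        )
        log.append(
            ("expression_gt_zero", float(abundance.loc[cand.gene_id].max()) > 0)
        )
        bridged = False
        left, right = annotation.neighbors(cand.span)
        for neighbor, gap in (
            (left, (left.end, cand.start) if left else None),
            (right, (cand.end, right.start) if right else None),
        ):
            if neighbor is None:
                continue
            if gap[1] <= gap[0]:  # zero-length gap: candidate abuts the gene
                bridged = True
                continue
            region = GenomicInterval(cand.contig, gap[0], gap[1], cand.strand)
            path = compute_tiling_path(region, reads)
            if path.covered_length == len(region):
                bridged = True
        log.append(("no_tiling_path_to_neighbor", not bridged))
        logs[cand.gene_id] = log
        if all(ok for _, ok in log):
            survivors.append(cand)
    return survivors, logs


def filter_asrna(
    candidates: Sequence[GeneModel],
    raw_counts: pd.DataFrame,
    abundance: pd.DataFrame,
    annotation: Optional[GenomeAnnotation],
    alignments,
    min_length: int = 200,
    min_reads: int = 2,
    max_gap_fraction: float = 0.05,
    sample_meta: Optional[pd.DataFrame] = None,
) -> Tuple[List[GeneModel], Dict[str, List[Tuple[str, bool]]], Dict[str, Optional[float]]]:
    """Antisense filter suite: length/coverage rules plus the strand-switch
    artifact screen (tiling gaps must not exceed ``max_gap_fraction`` of the
    model span). Also reports strand specificity over the composite region
    with the sense gene when an annotation is supplied.
    """
    reads = as_read_table(alignments)
    pooled = _pooled_counts(raw_counts, sample_meta)
    survivors, logs, specificity = [], {}, {}
    for cand in candidates:
        if cand.gene_id not in raw_counts.index:
            raise KeyError(f"no count row for candidate {cand.gene_id}")
        log: List[Tuple[str, bool]] = []
        log.append(("min_length_200", cand.exonic_length >= min_length))
        log.append(
            ("min_raw_reads_any_timepoint",
             int(pooled.loc[cand.gene_id].max()) >= min_reads)
        )
        log.append(
            ("expression_gt_zero", float(abundance.loc[cand.gene_id].max()) > 0)
        )
        path = compute_tiling_path(cand.span, reads)
        gap = tiling_gap_fraction(path)
        log.append(("tiling_gap_le_5pct", gap <= max_gap_fraction))
        logs[cand.gene_id] = log
        specificity[cand.gene_id] = None
        if annotation is not None:
            sense_strand = "-" if cand.strand == "+" else "+"
            partners = annotation.overlapping(cand.span, strand=sense_strand)
            if partners:
                partner = max(
                    partners,
                    key=lambda g: min(g.end, cand.end) - max(g.start, cand.start),
                )
                region = composite_region(partner, cand)
                specificity[cand.gene_id] = strand_specificity(
                    region, sense_strand, reads
                )
        if all(ok for _, ok in log):
            survivors.append(cand)
    return survivors, logs, specificity


def classify_pipeline(
    models: GenomeAnnotation | Sequence[GeneModel],
    annotation: GenomeAnnotation,
    alignments,
    raw_counts: pd.DataFrame,
    abundance: pd.DataFrame,
    sample_meta: Optional[pd.DataFrame] = None,
    genome: Optional[Mapping[str, str]] = None,
    min_orf_bp: int = 150,
) -> Dict[str, ClassifiedModel]:
    """Run initial classification and both filter suites over all models."""
    models = list(models)
    reads = as_read_table(alignments)
    initial = classify_models(models, annotation)
    by_id = {m.gene_id: m for m in models}
    lnc = [by_id[i] for i, k in initial.items() if k == "lncRNA"]
    asr = [by_id[i] for i, k in initial.items() if k == "asRNA"]
    lnc_ok, lnc_logs = filter_lncrna(
        lnc, raw_counts, abundance, annotation, reads, sample_meta=sample_meta
    )
    asr_ok, asr_logs, asr_ss = filter_asrna(
        asr, raw_counts, abundance, annotation, reads, sample_meta=sample_meta
    )
    lnc_pass = {m.gene_id for m in lnc_ok}
    asr_pass = {m.gene_id for m in asr_ok}

    out: Dict[str, ClassifiedModel] = {}
    for m in models:
        klass = initial[m.gene_id]
        log = []
        ss = None
        if klass == "lncRNA":
            log = lnc_logs[m.gene_id]
            if m.gene_id not in lnc_pass:
                klass = "rejected"
        elif klass == "asRNA":
            log = asr_logs[m.gene_id]
            ss = asr_ss[m.gene_id]
            if m.gene_id not in asr_pass:
                klass = "rejected"
        orf_max = None
        if genome is not None and klass in ("lncRNA", "asRNA"):
            orfs, _ = find_orfs(m.transcript_sequence(genome), min_orf_bp)
            orf_max = orfs[0]["length_bp"] if orfs else 0
        out[m.gene_id] = ClassifiedModel(
            model=m, klass=klass, filter_log=list(log),
            strand_specificity=ss, orf_max_bp=orf_max,
        )
    return out


def classification_table(results: Mapping[str, ClassifiedModel]) -> pd.DataFrame:
    """Flatten pipeline results to the model/class/filter-verdict table."""
    rows = []
    for mid, r in results.items():
        row = {"model_id": mid, "class": r.klass,
               "strand_specificity": r.strand_specificity,
               "orf_max_bp": r.orf_max_bp}
        for rule, ok in r.filter_log:
            row[rule] = ok
        rows.append(row)
    return pd.DataFrame(rows).set_index("model_id")
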