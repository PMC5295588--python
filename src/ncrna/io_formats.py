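"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; GFF3/GTF I/O
converts from/to the 1-based closed convention at the boundary. SAM parsing
goes through :mod:`pysam`, FASTA through Biopython, tabular matrices through
pandas. Only the fields the pipeline uses are modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "tRNA", "ncRNA", "other")

#: maps transcript-level GFF/GTF feature types to biotypes
_FEATURE_BIOTYPE = {
    "mRNA": "protein_coding",
    "CDS": "protein_coding",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
    "lnc_RNA": "ncRNA",
    "lncRNA": "ncRNA",
    "antisense_RNA": "ncRNA",
}
_BIOTYPE_FEATURE = {
    "protein_coding": "mRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
    "other": "transcript",
}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A transcript/gene model: ordered exons on one contig and strand."""

    gene_id: str
    intervals: Tuple[GenomicInterval, ...]
    biotype: str = "other"
    cds: Optional[Tuple[GenomicInterval, ...]] = None
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise AnnotationError(f"{self.gene_id}: gene model without exons")
        self.intervals = tuple(sorted(self.intervals, key=lambda i: i.start))
        contigs = {i.contig for i in self.intervals}
        strands = {i.strand for i in self.intervals}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{self.gene_id}: exons span multiple contigs/strands"
            )
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"{self.gene_id}: unknown biotype {self.biotype}")
        if self.anticodon is not None and self.biotype != "tRNA":
            raise AnnotationError(
                f"{self.gene_id}: anticodon given for non-tRNA biotype"
            )

    @property
    def contig(self) -> str:
        return self.intervals[0].contig

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def start(self) -> int:
        return self.intervals[0].start

    @property
    def end(self) -> int:
        return self.intervals[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(i) for i in self.intervals)

    def transcript_sequence(self, genome: Dict[str, str]) -> str:
        """Stranded transcript sequence (reverse-complemented on minus)."""
        seq = "".join(genome[self.contig][i.start : i.end] for i in self.intervals)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


class GenomeAnnotation:
    """Indexed collection of gene models with interval and neighbour queries."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        contig_lengths: Optional[Dict[str, int]] = None,
    ) -> None:
        self.genes: Dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.contig_lengths = dict(contig_lengths or {})
        for g in self.genes.values():
            limit = self.contig_lengths.get(g.contig)
            if limit is not None and g.end > limit:
                raise AnnotationError(
                    f"{g.gene_id}: exon beyond declared contig length of {g.contig}"
                )
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]] = {}
        by_contig: Dict[str, List[GeneModel]] = {}
        for g in self.genes.values():
            by_contig.setdefault(g.contig, []).append(g)
        for contig, models in by_contig.items():
            models.sort(key=lambda m: (m.start, m.end))
            starts = np.array([m.start for m in models], dtype=np.int64)
            ends = np.array([m.end for m in models], dtype=np.int64)
            self._index[contig] = (starts, ends, [m.gene_id for m in models])

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    @property
    def contigs(self) -> List[str]:
        return sorted(self._index)

    def genes_on(self, contig: str) -> List[GeneModel]:
        if contig not in self._index:
            return []
        return [self.genes[g] for g in self._index[contig][2]]

    def overlapping(
        self, interval: GenomicInterval, strand: Optional[str] = None
    ) -> List[GeneModel]:
        """Gene models whose span overlaps ``interval`` (optionally by strand)."""
        if interval.contig not in self._index:
            return []
        starts, ends, ids = self._index[interval.contig]
        hit = (starts < interval.end) & (ends > interval.start)
        out = [self.genes[ids[i]] for i in np.flatnonzero(hit)]
        if strand is not None:
            out = [g for g in out if g.strand == strand]
        return out

    def neighbors(
        self, interval: GenomicInterval
    ) -> Tuple[Optional[GeneModel], Optional[GeneModel]]:
        """Nearest non-overlapping gene on the left and right of ``interval``."""
        if interval.contig not in self._index:
            return None, None
        left = right = None
        for g in self.genes_on(interval.contig):
            if g.end <= interval.start:
                if left is None or g.end > left.end:
                    left = g
            elif g.start >= interval.end and right is None:
                right = g
                break
        return left, right

    def intergenic_regions(self, contig: str) -> List[Tuple[int, int]]:
        """Maximal gaps not covered by any gene span (needs contig lengths)."""
        if contig not in self.contig_lengths:
            raise AnnotationError(f"no declared length for contig {contig}")
        length = self.contig_lengths[contig]
        gaps, cursor = [], 0
        if contig in self._index:
            starts, ends, _ = self._index[contig]
            for s, e in zip(starts, ends):
                if s > cursor:
                    gaps.append((cursor, int(s)))
                cursor = max(cursor, int(e))
        if cursor < length:
            gaps.append((cursor, length))
        return gaps


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(col9: str, lineno: int) -> Dict[str, str]:
    col9 = col9.strip()
    if not col9 or col9 == ".":
        return {}
    # GTF uses `key "value";`, GFF3 uses `key=value;`
    if '"' in col9 and "=" not in col9.split('"', 1)[0]:
        return dict(_GTF_ATTR.findall(col9))
    attrs = {}
    for chunk in col9.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise AnnotationError(f"line {lineno}: malformed attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 or GTF file (dialect auto-detected) into an annotation.

    1-based closed coordinates are converted to 0-based half-open. Exon and
    CDS features are grouped per transcript; a transcript-level feature with
    no exon children defines a single-exon model.
    """
    contig_lengths: Dict[str, int] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start, end, _score, strand, _frame, col9 = cols
            try:
                iv = GenomicInterval(contig, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
            attrs = _parse_attributes(col9, lineno)
            tid = (
                attrs.get("transcript_id")
                or attrs.get("Parent")
                or attrs.get("ID")
                or attrs.get("gene_id")
            )
            if tid is None:
                raise AnnotationError(f"line {lineno}: no transcript identifier")
            if ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif ftype == "CDS":
                cds.setdefault(tid, []).append(iv)
            else:
                # transcript-level feature: remember metadata and its own span
                tid = attrs.get("transcript_id") or attrs.get("ID") or tid
                record = meta.setdefault(tid, {})
                record.setdefault("_span", f"{contig}:{iv.start}-{iv.end}:{strand}")
                record["_iv"] = iv  # type: ignore[assignment]
                for key in ("biotype", "gene_biotype", "anticodon"):
                    if key in attrs:
                        record[key] = attrs[key]
                record.setdefault("_ftype", ftype)
            if tid not in order:
                order.append(tid)

    genes = []
    for tid in order:
        info = meta.get(tid, {})
        ivs = exons.get(tid)
        if not ivs:
            iv = info.get("_iv")
            if iv is None:
                continue
            ivs = [iv]
        biotype = info.get("biotype") or info.get("gene_biotype")
        if biotype is None:
            biotype = _FEATURE_BIOTYPE.get(info.get("_ftype", ""), None)
        if biotype is None:
            biotype = "protein_coding" if tid in cds else "other"
        if biotype not in BIOTYPES:
            biotype = "other"
        genes.append(
            GeneModel(
                gene_id=tid,
                intervals=tuple(ivs),
                biotype=biotype,
                cds=tuple(sorted(cds[tid], key=lambda i: i.start)) if tid in cds else None,
                anticodon=info.get("anticodon"),
            )
        )
    return GenomeAnnotation(genes, contig_lengths or None)


def write_annotation(
    annotation: GenomeAnnotation, path: str | Path, dialect: str = "gff3"
) -> None:
    """Write an annotation as GFF3 (default) or GTF; inverse of read_annotation."""
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for contig in sorted(annotation.contig_lengths):
                fh.write(
                    f"##sequence-region {contig} 1 "
                    f"{annotation.contig_lengths[contig]}\n"
                )
        for g in annotation.genes.values():
            ftype = _BIOTYPE_FEATURE[g.biotype]
            if dialect == "gff3":
                attrs = f"ID={g.gene_id};biotype={g.biotype}"
                if g.anticodon:
                    attrs += f";anticodon={g.anticodon}"
                child = f"Parent={g.gene_id}"
            else:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}"; '
                    f'biotype "{g.biotype}";'
                )
                if g.anticodon:
                    attrs += f' anticodon "{g.anticodon}";'
                child = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\tncrna\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for iv in g.intervals:
                fh.write(
                    f"{g.contig}\tncrna\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{child}\n"
                )
            for iv in g.cds or ():
                fh.write(
                    f"{g.contig}\tncrna\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t0\t{child}\n"
                )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One SAM record, restricted to the fields the pipeline uses."""

    read_id: str
    contig: str
    pos: int
    cigar: Tuple[Tuple[str, int], ...]
    mate_pos: int
    properly_paired: bool
    first_in_pair: bool
    reverse_complemented: bool
    unique: bool
    mapq: int
    end: int
    sample: Optional[str] = None

    @property
    def full_length_match(self) -> bool:
        """True for a single-operation all-M CIGAR (no indels/splices/clips)."""
        return len(self.cigar) == 1 and self.cigar[0][0] == "M"


_CIGAR_OPS = "MIDNSHP=X"


def fragment_strand(first_in_pair: bool, reverse: bool, protocol: str = "forward") -> str:
    """Strand of the sequenced fragment under a stranded library protocol.

    ``forward``: the first-in-pair read aligns to the transcribed strand;
    ``reverse``: the second-in-pair read does.
    """
    if protocol not in ("forward", "reverse"):
        raise ValueError(f"unknown strand protocol {protocol!r}")
    sense = (first_in_pair and not reverse) or (not first_in_pair and reverse)
    if protocol == "reverse":
        sense = not sense
    return "+" if sense else "-"


def read_alignments(
    path: str | Path,
    require_unique: bool = True,
    min_mapq: int = 1,
    protocol: str = "forward",
) -> Iterator[AlignmentRecord]:
    """Stream mapped SAM records, excluding secondary/supplementary alignments.

    With ``require_unique`` (the default) only primary alignments with a
    single reported placement (NH tag absent or 1) and MAPQ >= ``min_mapq``
    are emitted.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        known = set(sam.references)
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in known:
                raise AlignmentError(
                    f"record {rec.query_name}: unknown contig {rec.reference_name}"
                )
            if rec.cigartuples is None:
                raise AlignmentError(f"record {rec.query_name}: missing CIGAR")
            unique = (not rec.has_tag("NH") or rec.get_tag("NH") == 1) and (
                rec.mapping_quality >= min_mapq
            )
            if require_unique and not unique:
                continue
            yield AlignmentRecord(
                read_id=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start,
                cigar=tuple((_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples),
                mate_pos=rec.next_reference_start,
                properly_paired=rec.is_proper_pair,
                first_in_pair=not rec.is_read2,
                reverse_complemented=rec.is_reverse,
                unique=unique,
                mapq=rec.mapping_quality,
                end=rec.reference_end,
                sample=rec.get_tag("RG") if rec.has_tag("RG") else None,
            )


class ReadTable:
    """Column-oriented store of mapped reads for vectorised interval work.

    Holds, per read: contig, reference start/end, fragment strand (resolved
    under the configured protocol), properly-paired and full-length-match
    flags, sample label, and a fragment identifier shared by mates.
    """

    COLUMNS = ("contig", "start", "end", "strand", "properly_paired",
               "full_match", "first_in_pair", "sample", "frag_uid")

    def __init__(self, contigs, samples, arrays):
        self.contigs: List[str] = list(contigs)
        self.samples: List[str] = list(samples)
        self.contig_code = arrays["contig"]
        self.start = arrays["start"]
        self.end = arrays["end"]
        self.strand = arrays["strand"]  # +1 / -1
        self.properly_paired = arrays["properly_paired"]
        self.full_match = arrays["full_match"]
        self.first_in_pair = arrays["first_in_pair"]
        self.sample_code = arrays["sample"]
        self.frag_uid = arrays["frag_uid"]
        self._per_contig: Dict[int, Tuple[np.ndarray, int]] = {}

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_sam(
        cls,
        path: str | Path,
        require_unique: bool = True,
        min_mapq: int = 1,
        protocol: str = "forward",
    ) -> "ReadTable":
        contig_ids: Dict[str, int] = {}
        sample_ids: Dict[str, int] = {}
        frag_ids: Dict[str, int] = {}
        cols: Dict[str, list] = {c: [] for c in cls.COLUMNS}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if require_unique:
                    if rec.mapping_quality < min_mapq:
                        continue
                    if rec.has_tag("NH") and rec.get_tag("NH") != 1:
                        continue
                cols["contig"].append(
                    contig_ids.setdefault(rec.reference_name, len(contig_ids))
                )
                cols["start"].append(rec.reference_start)
                cols["end"].append(rec.reference_end)
                strand = fragment_strand(not rec.is_read2, rec.is_reverse, protocol)
                cols["strand"].append(1 if strand == "+" else -1)
                cols["properly_paired"].append(rec.is_proper_pair)
                ct = rec.cigartuples or ()
                cols["full_match"].append(len(ct) == 1 and ct[0][0] == 0)
                cols["first_in_pair"].append(not rec.is_read2)
                sample = rec.get_tag("RG") if rec.has_tag("RG") else ""
                cols["sample"].append(sample_ids.setdefault(sample, len(sample_ids)))
                cols["frag_uid"].append(
                    frag_ids.setdefault(rec.query_name, len(frag_ids))
                )
        arrays = {
            "contig": np.asarray(cols["contig"], dtype=np.int32),
            "start": np.asarray(cols["start"], dtype=np.int64),
            "end": np.asarray(cols["end"], dtype=np.int64),
            "strand": np.asarray(cols["strand"], dtype=np.int8),
            "properly_paired": np.asarray(cols["properly_paired"], dtype=bool),
            "full_match": np.asarray(cols["full_match"], dtype=bool),
            "first_in_pair": np.asarray(cols["first_in_pair"], dtype=bool),
            "sample": np.asarray(cols["sample"], dtype=np.int32),
            "frag_uid": np.asarray(cols["frag_uid"], dtype=np.int64),
        }
        return cls(list(contig_ids), list(sample_ids), arrays)

    @classmethod
    def from_records(
        cls, records: Iterable[AlignmentRecord], protocol: str = "forward"
    ) -> "ReadTable":
        contig_ids: Dict[str, int] = {}
        sample_ids: Dict[str, int] = {}
        frag_ids: Dict[str, int] = {}
        cols: Dict[str, list] = {c: [] for c in cls.COLUMNS}
        for r in records:
            cols["contig"].append(contig_ids.setdefault(r.contig, len(contig_ids)))
            cols["start"].append(r.pos)
            cols["end"].append(r.end)
            strand = fragment_strand(r.first_in_pair, r.reverse_complemented, protocol)
            cols["strand"].append(1 if strand == "+" else -1)
            cols["properly_paired"].append(r.properly_paired)
            cols["full_match"].append(r.full_length_match)
            cols["first_in_pair"].append(r.first_in_pair)
            cols["sample"].append(sample_ids.setdefault(r.sample or "", len(sample_ids)))
            cols["frag_uid"].append(frag_ids.setdefault(r.read_id, len(frag_ids)))
        arrays = {
            "contig": np.asarray(cols["contig"], dtype=np.int32),
            "start": np.asarray(cols["start"], dtype=np.int64),
            "end": np.asarray(cols["end"], dtype=np.int64),
            "strand": np.asarray(cols["strand"], dtype=np.int8),
            "properly_paired": np.asarray(cols["properly_paired"], dtype=bool),
            "full_match": np.asarray(cols["full_match"], dtype=bool),
            "first_in_pair": np.asarray(cols["first_in_pair"], dtype=bool),
            "sample": np.asarray(cols["sample"], dtype=np.int32),
            "frag_uid": np.asarray(cols["frag_uid"], dtype=np.int64),
        }
        return cls(list(contig_ids), list(sample_ids), arrays)

    # -- queries ------------------------------------------------------------

    def _contig_order(self, code: int) -> Tuple[np.ndarray, int]:
        if code not in self._per_contig:
            idx = np.flatnonzero(self.contig_code == code)
            idx = idx[np.argsort(self.start[idx], kind="stable")]
            span = int((self.end[idx] - self.start[idx]).max()) if len(idx) else 0
            self._per_contig[code] = (idx, span)
        return self._per_contig[code]

    def overlapping(self, contig: str, start: int, end: int) -> np.ndarray:
        """Indices of reads overlapping [start, end) on ``contig``."""
        if contig not in self.contigs:
            return np.empty(0, dtype=np.int64)
        code = self.contigs.index(contig)
        idx, span = self._contig_order(code)
        if not len(idx):
            return idx
        starts = self.start[idx]
        lo = np.searchsorted(starts, start - span, side="left")
        hi = np.searchsorted(starts, end, side="left")
        cand = idx[lo:hi]
        return cand[self.end[cand] > start]

    def library_sizes(
        self, exclude_contigs: Sequence[str] = ()
    ) -> Dict[str, int]:
        """Unique mapped fragments per sample, optionally excluding contigs."""
        mask = np.ones(len(self), dtype=bool)
        for contig in exclude_contigs:
            if contig in self.contigs:
                mask &= self.contig_code != self.contigs.index(contig)
        pairs = np.unique(
            np.stack(
                [self.sample_code[mask], self.frag_uid[mask]], axis=1
            ),
            axis=0,
        )
        counts = np.bincount(pairs[:, 0], minlength=len(self.samples))
        return {s: int(counts[i]) for i, s in enumerate(self.samples)}


def as_read_table(alignments, protocol: str = "forward") -> ReadTable:
    """Coerce a SAM path, record iterable, or ReadTable into a ReadTable."""
    if isinstance(alignments, ReadTable):
        return alignments
    if isinstance(alignments, (str, Path)):
        return ReadTable.from_sam(alignments, protocol=protocol)
    return ReadTable.from_records(alignments, protocol=protocol)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read FASTA into an ordered {id: upper-case sequence} map.

    Identifiers are the first whitespace-delimited token; duplicates error.
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix (first column row labels, header of sample labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = df[col].isna() | ~df[col].map(np.isreal)
        if not np.issubdtype(df[col].dtype, np.number) or bad.any():
            row = df.index[np.flatnonzero(bad)[0]] if bad.any() else "?"
            raise ValueError(f"non-numeric or missing cell at row {row!r}, column {col!r}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV with 6-decimal values (read_matrix inverse)."""
    df.to_csv(path, sep="\t", float_format="%.6f")
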