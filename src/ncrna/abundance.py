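"""Read counting, RPKM standardisation, and descriptive transcript statistics.

Counting is at the fragment (read-pair) level: a fragment contributes at most
once to a model, and only when it overlaps the model's exons on the model's
strand (for stranded libraries). RPKM standardises by exonic ("mappable")
length and the per-sample total of mapped fragments excluding the ribosomal
palindrome contig chrR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ReadTable,
    as_read_table,
)

#: the ribosomal palindrome contig excluded from library totals
CHR_R = "chrR"


@dataclass
class AbundanceMatrix:
    """Transcripts x samples standardised abundance with sample metadata.

    ``values`` holds RPKM, ``raw_counts`` (optional) the fragment counts of
    the same shape, ``sample_meta`` time and replicate per sample column,
    ``mappable_length`` the exonic length per row. Columns are ordered by
    time then replicate.
    """

    values: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None
    raw_counts: Optional[pd.DataFrame] = None
    mappable_length: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")
            order = self.sample_meta.loc[list(self.values.columns)].sort_values(
                ["time_hr", "replicate"]
            ).index
            self.values = self.values[order]
            if self.raw_counts is not None:
                self.raw_counts = self.raw_counts[order]
        if self.raw_counts is not None:
            if not self.raw_counts.shape == self.values.shape:
                raise ValueError("raw_counts shape mismatch")
            if ((self.raw_counts.values == 0) & (self.values.values > 0)).any():
                raise ValueError("non-zero abundance where raw count is zero")

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def transcripts(self) -> List[str]:
        return list(self.values.index)

    def timepoint_mean(self) -> pd.DataFrame:
        """Replicate-averaged values, one column per time point (hr)."""
        if self.sample_meta is None:
            return self.values.copy()
        groups = self.sample_meta.loc[self.samples, "time_hr"]
        out = self.values.T.groupby(groups).mean().T
        return out[sorted(out.columns)]

    def timepoint_counts(self, counts: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Raw counts pooled over replicates per time point."""
        counts = counts if counts is not None else self.raw_counts
        if counts is None:
            raise ValueError("no raw counts available")
        if self.sample_meta is None:
            return counts.copy()
        groups = self.sample_meta.loc[list(counts.columns), "time_hr"]
        out = counts.T.groupby(groups).sum().T
        return out[sorted(out.columns)]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _exon_atoms(
    models: Sequence[GeneModel],
) -> Dict[Tuple[str, int], Tuple[np.ndarray, np.ndarray, List[List[int]]]]:
    """Disjoint exonic segments per (contig, strand), each mapped to the
    model indices overlapping it (handles same-strand model overlap)."""
    by_key: Dict[Tuple[str, int], List[Tuple[int, int, int]]] = {}
    for mi, m in enumerate(models):
        key = (m.contig, 1 if m.strand == "+" else -1)
        for iv in m.intervals:
            by_key.setdefault(key, []).append((iv.start, iv.end, mi))
    out = {}
    for key, ivs in by_key.items():
        edges = sorted({p for s, e, _ in ivs for p in (s, e)})
        starts, ends, owners = [], [], []
        ivs.sort()
        for a, b in zip(edges, edges[1:]):
            here = [mi for s, e, mi in ivs if s < b and e > a]
            if here:
                starts.append(a)
                ends.append(b)
                owners.append(here)
        out[key] = (np.array(starts), np.array(ends), owners)
    return out


def count_reads(
    models: GenomeAnnotation | Sequence[GeneModel],
    alignments,
    stranded: bool = True,
) -> pd.DataFrame:
    """Fragment counts per model per sample.

    A fragment counts toward a model iff any of its reads overlaps the
    model's exons (on the model's strand when ``stranded``); each fragment
    counts at most once per model even when it overlaps several exons.
    """
    models = list(models) if not isinstance(models, GenomeAnnotation) else list(models)
    reads = as_read_table(alignments)
    atoms = _exon_atoms(models)
    n_samples = len(reads.samples)
    chunks: List[np.ndarray] = []
    for (contig, strand), (astarts, aends, owners) in atoms.items():
        if contig not in reads.contigs:
            continue
        code = reads.contigs.index(contig)
        sel = reads.contig_code == code
        if stranded:
            sel &= reads.strand == strand
        idx = np.flatnonzero(sel)
        if not len(idx):
            continue
        # atoms are disjoint & sorted, so overlaps form a contiguous range
        lo = np.searchsorted(aends, reads.start[idx], side="right")
        hi = np.searchsorted(astarts, reads.end[idx], side="left")
        hit = hi > lo
        idx, lo, hi = idx[hit], lo[hit], hi[hit]
        if not len(idx):
            continue
        # explode (read, atom) pairs fully vectorised
        d = hi - lo
        total = int(d.sum())
        read_rep = np.repeat(np.arange(len(idx)), d)
        offsets = np.concatenate([[0], np.cumsum(d)[:-1]])
        atom_flat = np.arange(total) - offsets[read_rep] + lo[read_rep]
        single = np.array(
            [o[0] if len(o) == 1 else -1 for o in owners], dtype=np.int64
        )
        model_flat = single[atom_flat]
        samp_flat = reads.sample_code[idx][read_rep].astype(np.int64)
        frag_flat = reads.frag_uid[idx][read_rep]
        ok = model_flat >= 0
        chunks.append(
            np.stack([model_flat[ok], samp_flat[ok], frag_flat[ok]], axis=1)
        )
        if not ok.all():  # atoms shared by several models: rare, explicit loop
            extra = []
            for j in np.flatnonzero(~ok):
                for mi in owners[atom_flat[j]]:
                    extra.append((mi, samp_flat[j], frag_flat[j]))
            chunks.append(np.array(extra, dtype=np.int64))
    counts = np.zeros((len(models), n_samples), dtype=int)
    if chunks:
        arr = np.unique(np.vstack(chunks), axis=0)
        np.add.at(counts, (arr[:, 0], arr[:, 1]), 1)
    return pd.DataFrame(
        counts, index=[m.gene_id for m in models], columns=list(reads.samples)
    )


def rpkm(
    raw_counts: pd.DataFrame,
    mappable_lengths: Mapping[str, int] | pd.Series,
    sample_totals: Mapping[str, int] | pd.Series,
    sample_meta: Optional[pd.DataFrame] = None,
) -> AbundanceMatrix:
    """Standardise counts to reads per kb per million mapped reads.

    value = count * 1e9 / (length_bp * total_mapped_excluding_chrR).
    """
    lengths = pd.Series(mappable_lengths).reindex(raw_counts.index)
    totals = pd.Series(sample_totals).reindex(raw_counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()][0]
        raise ValueError(f"non-positive or missing mappable length for {bad!r}")
    if (totals <= 0).any() or totals.isna().any():
        bad = totals.index[(totals <= 0) | totals.isna()][0]
        raise ValueError(f"non-positive or missing library total for {bad!r}")
    values = raw_counts * 1e9
    values = values.div(lengths, axis=0).div(totals, axis=1)
    return AbundanceMatrix(
        values=values,
        sample_meta=sample_meta,
        raw_counts=raw_counts,
        mappable_length=lengths,
    )


def max_abundance(matrix: AbundanceMatrix | pd.DataFrame) -> pd.Series:
    """Per-transcript maximum abundance across all samples."""
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty abundance matrix")
    return values.max(axis=1)


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator; NaN if empty."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return float("nan")
    return gc / denom


def sample_intergenic(
    annotation: GenomeAnnotation,
    n_per_contig: int = 1000,
    length_sampler=None,
    seed: int = 0,
) -> List[GenomicInterval]:
    """Random intergenic regions per contig, none overlapping any model.

    ``length_sampler(rng)`` draws a region length (default: 628 bp, the
    median lncRNA length, resample-style use passes observed lengths).
    Deterministic per seed; errors if 10x the requested count of attempts
    cannot place enough regions.
    """
    rng = np.random.default_rng(seed)
    if length_sampler is None:
        length_sampler = lambda r: 628  # noqa: E731
    out: List[GenomicInterval] = []
    for contig in annotation.contigs:
        gaps = annotation.intergenic_regions(contig)
        if not gaps:
            raise ValueError(f"no intergenic space on {contig}")
        gap_starts = np.array([g[0] for g in gaps])
        gap_ends = np.array([g[1] for g in gaps])
        placed = 0
        for _ in range(10 * n_per_contig):
            if placed == n_per_contig:
                break
            length = int(length_sampler(rng))
            gi = int(rng.integers(0, len(gaps)))
            lo, hi = int(gap_starts[gi]), int(gap_ends[gi])
            if hi - lo < length:
                continue
            start = int(rng.integers(lo, hi - length + 1))
            out.append(GenomicInterval(contig, start, start + length, "."))
            placed += 1
        if placed < n_per_contig:
            raise ValueError(
                f"{contig}: placed only {placed} of {n_per_contig} intergenic regions"
            )
    return out


def window_coverage(
    alignments,
    contig: str,
    contig_length: int,
    window_bp: int = 100,
    step: Optional[int] = None,
) -> pd.DataFrame:
    """Median per-base read coverage in sliding windows, log2(x+1) transformed.

    The +1 pseudocount maps zero-coverage windows to 0. A window longer than
    the contig degrades to a single whole-contig window.
    """
    reads = as_read_table(alignments)
    step = step or window_bp
    depth = np.zeros(contig_length + 1, dtype=np.int64)
    idx = reads.overlapping(contig, 0, contig_length)
    np.add.at(depth, np.clip(reads.start[idx], 0, contig_length), 1)
    np.add.at(depth, np.clip(reads.end[idx], 0, contig_length), -1)
    depth = np.cumsum(depth)[:contig_length]
    if window_bp >= contig_length:
        starts = np.array([0])
        medians = np.array([np.median(depth)])
    else:
        starts = np.arange(0, contig_length - window_bp + 1, step)
        medians = np.array(
            [np.median(depth[s : s + window_bp]) for s in starts]
        )
    return pd.DataFrame(
        {
            "window_start": starts,
            "median_coverage": medians,
            "log2_coverage": np.log2(medians + 1),
        }
    )


def length_and_class_stats(
    classes: Mapping[str, str],
    matrix: AbundanceMatrix | pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    sequences: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Per-class distribution summaries plus pairwise Mann-Whitney U tests.

    Returns a summary table (median and quartiles of max abundance, length,
    and GC per class) and, per metric, a class x class matrix of two-sided
    tie-corrected Mann-Whitney p-values (NaN where a class has < 2 members).
    """
    maxab = max_abundance(matrix)
    lengths = pd.Series(lengths)
    metrics: Dict[str, Dict[str, List[float]]] = {"max_abundance": {}, "length": {}}
    if sequences is not None:
        metrics["gc"] = {}
    for tid, klass in classes.items():
        if tid in maxab.index:
            metrics["max_abundance"].setdefault(klass, []).append(float(maxab[tid]))
        if tid in lengths.index:
            metrics["length"].setdefault(klass, []).append(float(lengths[tid]))
        if sequences is not None and tid in sequences:
            metrics["gc"].setdefault(klass, []).append(gc_content(sequences[tid]))

    rows = []
    for metric, groups in metrics.items():
        for klass, vals in groups.items():
            q1, med, q3 = np.percentile(vals, [25, 50, 75]) if vals else (np.nan,) * 3
            rows.append((metric, klass, len(vals), q1, med, q3))
    summary = pd.DataFrame(
        rows, columns=["metric", "class", "n", "q1", "median", "q3"]
    )

    pvalues: Dict[str, pd.DataFrame] = {}
    for metric, groups in metrics.items():
        names = sorted(groups)
        pmat = pd.DataFrame(np.nan, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(groups[a]) < 2 or len(groups[b]) < 2:
                    continue  # statistics reported, test skipped
                stat = stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                )
                pmat.at[a, b] = pmat.at[b, a] = stat.pvalue
        pvalues[metric] = pmat
    return summary, pvalues
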