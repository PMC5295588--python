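#!/usr/bin/env python
"""Descriptive contrasts between RNA classes.

Per-class distributions of maximum abundance, transcript length, and GC
content (mRNA vs lncRNA vs sampled non-transcribed intergenic regions), with
pairwise Mann-Whitney U tests; plus a sliding-window coverage profile.
"""

from pathlib import Path

import pandas as pd

from ncrna.abundance import (
    gc_content,
    length_and_class_stats,
    sample_intergenic,
    window_coverage,
)
from ncrna.io_formats import ReadTable, read_annotation, read_fasta, read_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    genome = read_fasta(DATA / "genome.fa")
    models = read_annotation(DATA / "models.gtf")
    models.contig_lengths.update({c: len(s) for c, s in genome.items()})
    classified = pd.read_csv(BASE / "classification.tsv", sep="\t", index_col=0)
    matrix = read_matrix(BASE / "rpkm.tsv")

    keep = classified[classified["class"].isin(["mRNA", "lncRNA", "asRNA"])]
    classes = keep["class"].to_dict()
    lengths = {mid: models.genes[mid].exonic_length for mid in classes}
    sequences = {
        mid: models.genes[mid].transcript_sequence(genome) for mid in classes
    }
    summary, pvals = length_and_class_stats(classes, matrix, lengths, sequences)

    # non-transcribed intergenic background, resampling lncRNA-scale lengths
    regions = sample_intergenic(
        models, n_per_contig=1000,
        length_sampler=lambda rng: int(rng.integers(250, 900)), seed=1,
    )
    inter_gc = pd.Series(
        [gc_content(genome[r.contig][r.start : r.end]) for r in regions]
    )
    summary = pd.concat(
        [summary, pd.DataFrame([{
            "metric": "gc", "class": "intergenic", "n": len(regions),
            "q1": inter_gc.quantile(0.25), "median": inter_gc.median(),
            "q3": inter_gc.quantile(0.75),
        }])],
        ignore_index=True,
    )
    summary.to_csv(BASE / "class_stats.tsv", sep="\t", index=False)
    for metric, mat in pvals.items():
        mat.to_csv(BASE / f"class_stats_pvalues_{metric}.tsv", sep="\t")

    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print("\nsampled intergenic regions:", len(regions),
          f"(median GC {inter_gc.median():.3f})")

    reads = ReadTable.from_sam(DATA / "alignments.sam")
    contig = models.contigs[0]
    cov = window_coverage(reads, contig, 200_000, window_bp=100)
    cov.to_csv(BASE / f"window_coverage_{contig}.tsv", sep="\t", index=False)
    print(f"{contig}: median log2 window coverage "
          f"{cov['log2_coverage'].median():.2f} over {len(cov)} windows")


if __name__ == "__main__":
    main()
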