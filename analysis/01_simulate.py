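#!/usr/bin/env python
"""Generate the default synthetic developmental study.

Writes the genome, reference annotation, assembled transcript models
(including strand-switch artifact models), stranded paired-end alignments,
true abundances, and ground truth to results/data/.
"""

import json
from pathlib import Path

from ncrna import SimulationConfig, simulate_expression, simulate_genome, simulate_reads
from ncrna.io_formats import write_annotation, write_fasta, write_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    genome = simulate_genome(cfg)
    matrix = simulate_expression(genome)
    counts = simulate_reads(genome, matrix, cfg, OUT / "alignments.sam")

    write_fasta(genome.sequences, OUT / "genome.fa")
    write_fasta(genome.cds_sequences, OUT / "cds.fa")
    write_annotation(genome.reference, OUT / "reference.gff3")
    write_annotation(genome.models, OUT / "models.gtf", dialect="gtf")
    write_matrix(matrix.values, OUT / "true_abundance.tsv")
    cfg.sample_meta.to_csv(OUT / "samples.tsv", sep="\t")
    (OUT / "ground_truth.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "library_size": cfg.library_size,
                "classes": genome.truth.classes,
                "source_gene": genome.truth.source_gene,
                "artifact_models": genome.truth.artifact_models,
            },
            indent=2,
        )
    )

    n = {}
    for k in genome.truth.classes.values():
        n[k] = n.get(k, 0) + 1
    print(f"simulated {sum(len(s) for s in genome.sequences.values())/1e3:.0f} kb genome")
    print(f"transcript models: {n}")
    print(f"emitted fragments: {counts.values.sum():,} across {len(matrix.samples)} samples")


if __name__ == "__main__":
    main()
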