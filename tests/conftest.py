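"""Shared fixtures: a compact synthetic study and hand-built SAM helpers."""

from pathlib import Path

import pandas as pd
import pytest

from ncrna import SimulationConfig, simulate_expression, simulate_genome, simulate_reads
from ncrna.abundance import count_reads, rpkm
from ncrna.io_formats import ReadTable


def tiny_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A small study: one 60 kb chromosome, 18 genes, 8 lncRNAs, 3 asRNAs."""
    defaults = dict(
        seed=seed,
        n_chromosomes=1,
        chromosome_length_bp=60_000,
        n_coding_genes=18,
        n_lncrna_loci=8,
        n_asrna_loci=3,
        n_timepoints=5,
        replicates=2,
        stage_boundaries=(2,),
        library_size=2_000_000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """Genome + expression + SAM + counts + RPKM for the tiny configuration."""
    cfg = tiny_config()
    genome = simulate_genome(cfg)
    matrix = simulate_expression(genome)
    sam = tmp_path_factory.mktemp("tiny") / "alignments.sam"
    simulate_reads(genome, matrix, cfg, sam)
    reads = ReadTable.from_sam(sam)
    counts = count_reads(genome.models, reads)
    lengths = pd.Series({m.gene_id: m.exonic_length for m in genome.models})
    abundance = rpkm(
        counts,
        lengths,
        {s: cfg.library_size for s in counts.columns},
        sample_meta=cfg.sample_meta,
    )
    return {
        "config": cfg,
        "genome": genome,
        "matrix": matrix,
        "sam": sam,
        "reads": reads,
        "counts": counts,
        "abundance": abundance,
    }


def write_sam(path: Path, records, contigs=None, samples=()) -> Path:
    """Write hand-built SAM records.

    Each record: (qname, flag, contig, pos0, mapq, cigar, rg) with pos
    0-based (converted to SAM's 1-based on write).
    """
    contigs = contigs or {"chr1": 100_000, "chrR": 50_000}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for s in samples:
            fh.write(f"@RG\tID:{s}\tSM:{s}\n")
        for qname, flag, contig, pos, mapq, cigar, rg in records:
            tags = f"\tRG:Z:{rg}" if rg else ""
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos + 1}\t{mapq}\t{cigar}\t"
                f"*\t0\t0\t*\t*{tags}\tNH:i:1\n"
            )
    return path


def proper_pair_read(
    qname, contig, pos, cigar="100M", strand="+", first=True, rg=None, mapq=50
):
    """Flags for one mate of a properly paired fragment on ``strand``
    under the forward protocol (read1 on the transcribed strand)."""
    flag = 1 | 2
    reverse = (strand == "-") == first  # read1 reversed iff fragment on '-'
    if reverse:
        flag |= 16
    else:
        flag |= 32
    flag |= 64 if first else 128
    return (qname, flag, contig, pos, mapq, cigar, rg)
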