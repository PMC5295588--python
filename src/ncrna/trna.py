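"""tRNA complement analysis: deduplicated reference, pileup variant scan,
family abundance, codon usage, wobble decoding, and A-to-I editing inference.

Multicopy tRNA families are collapsed to unique allele sequences, each a
separate contig. Variants are scored against a fixed sequencing-error rate
with a one-sided binomial tail. Decoding questions run in the RNA alphabet:
the anticodon is read 5'->3' with its first base (position 34, the wobble
base) pairing the codon's third position under relaxed rules — and under
inosine rules (pairs U, C, or A) when an observed A->G wobble variant marks
the family as edited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    SENSE_CODONS,
    anticodon_amino_acid,
    codon_amino_acid,
    reverse_complement,
    to_dna,
    to_rna,
)

#: canonical wobble pairing: anticodon base 34 -> permitted codon third bases
#: (RNA alphabet; I is inosine)
CANONICAL_WOBBLE: Dict[str, Set[str]] = {
    "G": {"C", "U"},
    "U": {"A", "G"},
    "A": {"U"},
    "C": {"G"},
    "I": {"U", "C", "A"},
}

#: strict Watson-Crick pairs used at anticodon positions 35 and 36
_WC_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class TRNAGene:
    """One unique tRNA allele sequence with all its genomic copies."""

    family_id: str  # e.g. "tRNA-Leu-AAG" (amino acid + anticodon 5'->3')
    anticodon: str  # 3-mer, 5'->3', stored as DNA
    sequence: str  # allele sequence, DNA
    copy_locations: List[Tuple[str, int]]
    wobble_index: int  # 0-based offset of the anticodon's 5' base (base 34)

    def __post_init__(self) -> None:
        self.anticodon = to_dna(self.anticodon)
        self.sequence = to_dna(self.sequence)
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT"):
            raise ValueError(f"invalid anticodon {self.anticodon!r}")
        if not 60 <= len(self.sequence) <= 120:
            raise ValueError(
                f"{self.family_id}: implausible tRNA length {len(self.sequence)}"
            )
        embedded = self.sequence[self.wobble_index : self.wobble_index + 3]
        if embedded != self.anticodon:
            raise ValueError(
                f"{self.family_id}: sequence at wobble_index is {embedded!r}, "
                f"not the anticodon {self.anticodon!r}"
            )

    @property
    def amino_acid(self) -> str:
        return anticodon_amino_acid(self.anticodon)

    @property
    def copy_count(self) -> int:
        return len(self.copy_locations)


@dataclass
class VariantCall:
    contig: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    p_value: float
    in_anticodon: bool = False
    anticodon_offset: Optional[int] = None  # 0 = wobble base 34

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("negative counts")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.in_anticodon != (self.anticodon_offset is not None):
            raise ValueError("in_anticodon inconsistent with anticodon_offset")


class TRNAComplement:
    """Unique-sequence tRNA reference: contigs, family map, pileup, variants."""

    def __init__(self, alleles: Mapping[str, TRNAGene]) -> None:
        self._alleles: Dict[str, TRNAGene] = dict(alleles)  # contig -> allele
        self.variants: List[VariantCall] = []

    def __len__(self) -> int:
        return len(self._alleles)

    @property
    def contigs(self) -> List[str]:
        return list(self._alleles)

    def contig_gene(self, contig: str) -> TRNAGene:
        return self._alleles[contig]

    def contig_sequences(self) -> Dict[str, str]:
        return {c: g.sequence for c, g in self._alleles.items()}

    def families(self) -> Dict[str, List[str]]:
        """family_id -> contigs carrying that family's alleles."""
        fam: Dict[str, List[str]] = {}
        for contig, gene in self._alleles.items():
            fam.setdefault(gene.family_id, []).append(contig)
        return fam

    def anticodons(self) -> Dict[str, List[str]]:
        """anticodon (DNA) -> family ids carrying it."""
        out: Dict[str, List[str]] = {}
        for gene in self._alleles.values():
            out.setdefault(gene.anticodon, [])
            if gene.family_id not in out[gene.anticodon]:
                out[gene.anticodon].append(gene.family_id)
        return out

    def edited_families(
        self, variants: Optional[Sequence[VariantCall]] = None
    ) -> Set[str]:
        """Families with an observed A->G variant at the wobble position."""
        variants = self.variants if variants is None else variants
        out = set()
        for v in variants:
            if (
                v.in_anticodon
                and v.anticodon_offset == 0
                and v.ref_base == "A"
                and v.alt_base == "G"
                and v.contig in self._alleles
            ):
                out.add(self._alleles[v.contig].family_id)
        return out


def build_reference(genes: Iterable[TRNAGene]) -> TRNAComplement:
    """Collapse identical sequences to one contig each; keep all copy records.

    Contigs are named ``<family_id>.<i>`` in first-seen order within family.
    """
    by_seq: Dict[Tuple[str, str], TRNAGene] = {}
    order: List[Tuple[str, str]] = []
    for gene in genes:
        key = (gene.family_id, gene.sequence)
        if key in by_seq:
            by_seq[key].copy_locations.extend(gene.copy_locations)
        else:
            by_seq[key] = TRNAGene(
                gene.family_id,
                gene.anticodon,
                gene.sequence,
                list(gene.copy_locations),
                gene.wobble_index,
            )
            order.append(key)
    alleles: Dict[str, TRNAGene] = {}
    counter: Dict[str, int] = {}
    for key in order:
        fam = key[0]
        counter[fam] = counter.get(fam, 0) + 1
        alleles[f"{fam}.{counter[fam]}"] = by_seq[key]
    return TRNAComplement(alleles)


def trim_reads(
    reads: Iterable[Tuple[str, str]], trim_3prime: int = 65
) -> List[Tuple[str, str]]:
    """Truncate each read by ``trim_3prime`` bases from its 3' end and
    dissolve pairs into independent single-end reads.

    100 bp reads become 35 bp prefixes; reads already at or below the target
    length are kept whole with a warning.
    """
    out = []
    for name, seq in reads:
        keep = len(seq) - trim_3prime
        if keep <= 0:
            warnings.warn(
                f"read {name}: length {len(seq)} <= trim of {trim_3prime}; kept whole"
            )
            out.append((name, seq))
        else:
            out.append((name, seq[:keep]))
    return out


def aggregate_pileup(reads: Iterable, reference: Mapping[str, str]) -> pd.DataFrame:
    """Pool per-position A/C/G/T counts across all reads and samples.

    ``reads`` yield objects with ``contig``, ``start`` (0-based) and
    ``bases`` attributes (as produced by the synthetic tRNA generator or an
    equivalent SAM conversion).
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    counts = {c: np.zeros((len(seq), 4), dtype=int) for c, seq in reference.items()}
    for read in reads:
        table = counts[read.contig]
        for j, b in enumerate(read.bases):
            if b in base_idx:
                table[read.start + j, base_idx[b]] += 1
    rows = []
    for contig in sorted(reference):
        seq = reference[contig]
        for pos in range(len(seq)):
            a, c, g, t = counts[contig][pos]
            rows.append((contig, pos, seq[pos], a, c, g, t))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "A", "C", "G", "T"])


def call_variants(
    pileup: pd.DataFrame,
    complement: Optional[TRNAComplement] = None,
    p_threshold: float = 0.25,
    min_alt_reads: int = 2,
    min_coverage: int = 8,
    error_rate: float = 0.002,
) -> List[VariantCall]:
    """Scan a pileup for positions where the most frequent non-reference base
    exceeds the sequencing-error expectation.

    p = one-sided binomial tail P(X >= alt | n = coverage, p = error_rate);
    a variant is called iff coverage >= ``min_coverage``, the alt count is
    >= ``min_alt_reads`` and p < ``p_threshold``. Anticodon flags are set
    from gene metadata when a complement is supplied.
    """
    base_cols = ["A", "C", "G", "T"]
    cov = pileup[base_cols].sum(axis=1).to_numpy()
    refs = pileup["ref"].to_numpy()
    counts = pileup[base_cols].to_numpy()
    calls: List[VariantCall] = []
    for i in range(len(pileup)):
        if cov[i] < min_coverage:
            continue
        ref = refs[i]
        alt_counts = [
            (counts[i][j], b) for j, b in enumerate(base_cols) if b != ref
        ]
        alt_count, alt_base = max(alt_counts)
        if alt_count < min_alt_reads:
            continue
        p = float(stats.binom.sf(alt_count - 1, int(cov[i]), error_rate))
        if p >= p_threshold:
            continue
        contig = pileup["contig"].iat[i]
        pos = int(pileup["pos"].iat[i])
        in_ac, offset = False, None
        if complement is not None and contig in complement.contigs:
            wob = complement.contig_gene(contig).wobble_index
            if wob <= pos < wob + 3:
                in_ac, offset = True, pos - wob
        calls.append(
            VariantCall(
                contig=contig,
                position=pos,
                ref_base=ref,
                alt_base=alt_base,
                ref_count=int(counts[i][base_cols.index(ref)]),
                alt_count=int(alt_count),
                p_value=p,
                in_anticodon=in_ac,
                anticodon_offset=offset,
            )
        )
    return calls


def family_abundance(
    contig_counts: Mapping[str, float], complement: TRNAComplement
) -> pd.Series:
    """Cumulative abundance per tRNA family (sum over its allele contigs)."""
    fam_of = {c: complement.contig_gene(c).family_id for c in complement.contigs}
    out: Dict[str, float] = {f: 0.0 for f in complement.families()}
    for contig, n in contig_counts.items():
        if contig not in fam_of:
            raise ValueError(f"contig {contig!r} has no tRNA family")
        out[fam_of[contig]] += n
    return pd.Series(out).sort_index()


def codon_frequency(cds_sequences: Iterable[str]) -> pd.Series:
    """Frequencies over the 61 sense codons, normalised to sum to 1.

    Stop codons are excluded from numerator and denominator. Sequences whose
    length is not a multiple of 3 or that do not start with ATG are skipped
    with a warning.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    used = 0
    for k, seq in enumerate(cds_sequences):
        seq = to_dna(seq)
        if len(seq) % 3 or not seq.startswith("ATG"):
            warnings.warn(f"CDS #{k} skipped: not an ATG-initiated triplet sequence")
            continue
        used += 1
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    if used == 0:
        raise ValueError("no usable CDS sequences")
    total = sum(counts.values())
    return pd.Series({to_rna(c): n / total for c, n in counts.items()}).sort_index()


def abundance_codon_rank_correlation(
    fam_abundance: Mapping[str, float] | pd.Series,
    codon_freq: pd.Series,
    complement: TRNAComplement,
) -> float:
    """Spearman correlation of tRNA family abundance against codon frequency
    over all 61 sense codons, average ranks on ties.

    Codons without a cognate tRNA receive abundance 0 (tied bottom ranks).
    """
    fam_abundance = pd.Series(fam_abundance)
    by_anticodon: Dict[str, float] = {}
    for contig in complement.contigs:
        gene = complement.contig_gene(contig)
        by_anticodon[gene.anticodon] = by_anticodon.get(gene.anticodon, 0.0) + (
            float(fam_abundance.get(gene.family_id, 0.0)) / len(
                complement.families()[gene.family_id]
            )
        )
    codons = sorted(codon_freq.index)
    abund = np.array(
        [by_anticodon.get(reverse_complement(c), 0.0) for c in codons]
    )
    freq = codon_freq.loc[codons].to_numpy()
    rho = stats.spearmanr(abund, freq).statistic
    return float(rho)


def missing_codons(complement: TRNAComplement) -> Set[str]:
    """Sense codons (RNA) with no exact Watson-Crick cognate anticodon."""
    present = set(complement.anticodons())
    return {
        to_rna(c) for c in SENSE_CODONS if reverse_complement(c) not in present
    }


def wobble_decodable(
    codon: str,
    complement: TRNAComplement,
    decoding_table: Optional[Mapping[str, Set[str]]] = None,
    allow_editing: bool = False,
    variants: Optional[Sequence[VariantCall]] = None,
) -> Tuple[bool, List[str]]:
    """Whether any isoacceptor can read ``codon`` under wobble rules.

    Requires strict Watson-Crick pairing of anticodon bases 35/36 against
    codon positions 2/1, a decoding-table match of the wobble base (34)
    against codon position 3, and identical amino-acid specificity. With
    ``allow_editing``, an anticodon A34 is treated as inosine when the family
    has an observed A->G wobble-position variant.
    """
    table = decoding_table or CANONICAL_WOBBLE
    codon_rna = to_rna(codon)
    if len(codon_rna) != 3 or set(codon_rna) - set("ACGU"):
        raise ValueError(f"invalid codon {codon!r}")
    if to_dna(codon_rna) not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = codon_amino_acid(codon_rna)
    edited = complement.edited_families(variants) if allow_editing else set()

    decoders: List[str] = []
    seen = set()
    for contig in complement.contigs:
        gene = complement.contig_gene(contig)
        if gene.family_id in seen:
            continue
        seen.add(gene.family_id)
        if gene.amino_acid != aa:
            continue
        ac = to_rna(gene.anticodon)
        if _WC_PAIR[ac[1]] != codon_rna[1] or _WC_PAIR[ac[2]] != codon_rna[0]:
            continue
        wobble_base = ac[0]
        if allow_editing and wobble_base == "A" and gene.family_id in edited:
            wobble_base = "I"
        if codon_rna[2] in table.get(wobble_base, set()):
            decoders.append(gene.family_id)
    return bool(decoders), decoders


def editing_compensation(
    missing: Iterable[str],
    variants: Sequence[VariantCall],
    complement: TRNAComplement,
    decoding_table: Optional[Mapping[str, Set[str]]] = None,
) -> Dict[str, Dict]:
    """Partition codons without cognate tRNAs into wobble-covered,
    editing-covered (A->G wobble variants read as A->I deamination), and
    unexplained; catalogue non-anticodon variants separately.
    """
    report: Dict[str, Dict] = {"codons": {}, "other_variants": []}
    for codon in sorted(to_rna(c) for c in missing):
        wob_ok, wob_families = wobble_decodable(
            codon, complement, decoding_table, allow_editing=False
        )
        edit_ok, edit_families = (False, [])
        if not wob_ok:
            edit_ok, edit_families = wobble_decodable(
                codon, complement, decoding_table,
                allow_editing=True, variants=variants,
            )
        report["codons"][codon] = {
            "watson_crick": False,
            "wobble": wob_ok,
            "editing": bool(edit_ok and not wob_ok),
            "supporting_families": wob_families or edit_families,
            "status": (
                "wobble" if wob_ok else ("editing" if edit_ok else "unexplained")
            ),
        }
    report["other_variants"] = [v for v in variants if not v.in_anticodon]
    report["n_wobble"] = sum(
        1 for v in report["codons"].values() if v["status"] == "wobble"
    )
    report["n_editing"] = sum(
        1 for v in report["codons"].values() if v["status"] == "editing"
    )
    report["n_unexplained"] = sum(
        1 for v in report["codons"].values() if v["status"] == "unexplained"
    )
    return report
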