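"""tRNA reference handling, variant calling, codon usage, wobble decoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncrna.genetic_code import SENSE_CODONS, reverse_complement, to_rna
from ncrna.trna import (
    CANONICAL_WOBBLE,
    TRNAGene,
    VariantCall,
    abundance_codon_rank_correlation,
    aggregate_pileup,
    build_reference,
    call_variants,
    codon_frequency,
    editing_compensation,
    family_abundance,
    missing_codons,
    trim_reads,
    wobble_decodable,
)


def make_gene(anticodon, family=None, wobble=33, length=76, mutate_at=None):
    seq = ("ACGTAGGTCA" * 8)[:length]
    seq = seq[:wobble] + anticodon + seq[wobble + 3 :]
    if mutate_at is not None:
        alt = "ACGT"[("ACGT".index(seq[mutate_at]) + 1) % 4]
        seq = seq[:mutate_at] + alt + seq[mutate_at + 1 :]
    from ncrna.genetic_code import AA_THREE_LETTER, anticodon_amino_acid

    family = family or f"tRNA-{AA_THREE_LETTER[anticodon_amino_acid(anticodon)]}-{to_rna(anticodon)}"
    return TRNAGene(family, anticodon, seq, [("chr1", 0)], wobble)


class TestReference:
    def test_identical_copies_collapse(self):
        genes = [make_gene("AAG") for _ in range(22)]
        comp = build_reference(genes)
        assert len(comp) == 1
        assert comp.contig_gene(comp.contigs[0]).copy_count == 22

    def test_one_base_difference_keeps_two_contigs(self):
        comp = build_reference([make_gene("AAG"), make_gene("AAG", mutate_at=10)])
        assert len(comp) == 2

    def test_empty_input_is_empty_reference(self):
        assert len(build_reference([])) == 0

    def test_sequence_anticodon_consistency_enforced(self):
        with pytest.raises(ValueError, match="wobble_index"):
            TRNAGene("tRNA-Leu-AAG", "AAG", "A" * 76, [("chr1", 0)], 33)


class TestTrimReads:
    def test_100bp_read_becomes_35bp_prefix(self):
        out = trim_reads([("r1", "A" * 35 + "C" * 65)])
        assert out == [("r1", "A" * 35)]

    def test_short_read_kept_whole_with_warning(self):
        with pytest.warns(UserWarning, match="kept whole"):
            out = trim_reads([("r1", "A" * 30)])
        assert len(out[0][1]) == 30

    def test_pairs_dissolve_to_singletons(self):
        out = trim_reads([("p/1", "A" * 100), ("p/2", "G" * 100)])
        assert len(out) == 2 and all(len(s) == 35 for _, s in out)


class TestPileupAndVariants:
    def test_single_read_pileup(self):
        class Read:
            contig, start, bases = "c1", 0, "ACG"

        ref = {"c1": "ACGT"}
        out = aggregate_pileup([Read()], ref)
        assert out.loc[0, "A"] == 1 and out.loc[1, "C"] == 1 and out.loc[2, "G"] == 1
        assert out.loc[3, list("ACGT")].sum() == 0

    def test_empty_alignments_give_zero_table(self):
        out = aggregate_pileup([], {"c1": "ACGT"})
        assert (out[list("ACGT")].to_numpy() == 0).all()

    def _pileup_row(self, ref="A", alt="G", cov=100, alt_n=0, contig="c1", pos=0):
        row = {"contig": contig, "pos": pos, "ref": ref, "A": 0, "C": 0, "G": 0, "T": 0}
        row[ref] = cov - alt_n
        row[alt] += alt_n
        return row

    def test_zero_alt_reads_never_called(self):
        pileup = pd.DataFrame([self._pileup_row(alt_n=0)])
        assert call_variants(pileup) == []

    def test_strong_variant_called_with_tiny_p(self):
        pileup = pd.DataFrame([self._pileup_row(alt_n=40)])
        calls = call_variants(pileup)
        assert len(calls) == 1 and calls[0].p_value < 1e-10
        assert calls[0].alt_base == "G" and calls[0].alt_count == 40

    def test_min_alt_reads_threshold(self):
        pileup = pd.DataFrame([self._pileup_row(alt_n=1)])
        assert call_variants(pileup) == []

    def test_p_value_matches_binomial_tail(self):
        pileup = pd.DataFrame([self._pileup_row(alt_n=3, cov=50)])
        calls = call_variants(pileup, error_rate=0.002)
        expected = stats.binom.sf(2, 50, 0.002)
        assert calls[0].p_value == pytest.approx(expected)

    def test_planted_variants_detected_above_20pct_at_cov_50(self):
        rng = np.random.default_rng(0)
        rows = [
            self._pileup_row(alt_n=int(rng.binomial(50, 0.2)), cov=50, pos=i)
            for i in range(200)
        ]
        pileup = pd.DataFrame(rows)
        called = {c.position for c in call_variants(pileup)}
        alt_n = {i: rows[i]["G"] for i in range(200)}
        should = {i for i, n in alt_n.items() if n >= 2}
        detected = len(called & should) / max(len(should), 1)
        assert detected > 0.99


class TestCodonUsage:
    def test_single_cds_frequencies(self):
        freq = codon_frequency(["ATGAAATAA"])
        assert freq["AUG"] == pytest.approx(0.5)
        assert freq["AAA"] == pytest.approx(0.5)
        assert freq.sum() == pytest.approx(1.0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(2)
        cds = []
        for _ in range(100):
            n = int(rng.integers(10, 60))
            body = "".join(
                SENSE_CODONS[i] for i in rng.integers(0, 61, size=n)
            )
            cds.append("ATG" + body + "TAA")
        freq = codon_frequency(cds)
        tally = {c: 0 for c in SENSE_CODONS}
        for s in cds:
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if codon in tally:
                    tally[codon] += 1
        total = sum(tally.values())
        for codon, n in tally.items():
            assert freq[to_rna(codon)] == pytest.approx(n / total)

    def test_bad_cds_skipped_with_warning_and_all_bad_errors(self):
        with pytest.warns(UserWarning):
            freq = codon_frequency(["ATGAAATAA", "CCCC"])
        assert freq.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="no usable CDS"):
            with pytest.warns(UserWarning):
                codon_frequency(["CCCC"])


class TestRankCorrelation:
    def _full_complement(self):
        return build_reference([make_gene(reverse_complement(c)) for c in SENSE_CODONS])

    def test_proportional_abundance_gives_unit_correlation(self):
        comp = self._full_complement()
        freq = pd.Series(
            np.linspace(1, 61, 61) / np.sum(np.linspace(1, 61, 61)),
            index=sorted(to_rna(c) for c in SENSE_CODONS),
        )
        fam_ab = {}
        for contig in comp.contigs:
            g = comp.contig_gene(contig)
            codon = to_rna(reverse_complement(g.anticodon))
            fam_ab[g.family_id] = 1000 * freq[codon]
        sc = abundance_codon_rank_correlation(fam_ab, freq, comp)
        assert sc == pytest.approx(1.0)

    def test_uncovered_codons_share_tied_bottom_ranks(self):
        # 20 codons with no cognate tRNA -> abundance 0, average rank 10.5
        missing = set(SENSE_CODONS[:20])
        comp = build_reference(
            [make_gene(reverse_complement(c)) for c in SENSE_CODONS if c not in missing]
        )
        rng = np.random.default_rng(1)
        freq = pd.Series(
            rng.dirichlet(np.ones(61)), index=sorted(to_rna(c) for c in SENSE_CODONS)
        )
        fam_ab = {
            comp.contig_gene(c).family_id: float(rng.uniform(1, 100))
            for c in comp.contigs
        }
        sc = abundance_codon_rank_correlation(fam_ab, freq, comp)
        codons = sorted(freq.index)
        # independent check via scipy with explicit zero-padding
        by_anticodon = {
            comp.contig_gene(ct).anticodon: fam_ab[comp.contig_gene(ct).family_id]
            for ct in comp.contigs
        }
        vec = np.array(
            [by_anticodon.get(reverse_complement(c), 0.0) for c in codons]
        )
        ranks = stats.rankdata(vec)
        assert ranks[vec == 0].mean() == pytest.approx(10.5)
        expected = stats.spearmanr(vec, freq.loc[codons]).statistic
        assert sc == pytest.approx(expected)

    def test_permuted_abundance_centers_at_zero(self):
        comp = self._full_complement()
        rng = np.random.default_rng(3)
        freq = pd.Series(
            rng.dirichlet(np.ones(61)), index=sorted(to_rna(c) for c in SENSE_CODONS)
        )
        fams = [comp.contig_gene(c).family_id for c in comp.contigs]
        scs = []
        for _ in range(300):
            vals = rng.permutation(np.arange(1.0, 62.0))
            scs.append(
                abundance_codon_rank_correlation(dict(zip(fams, vals)), freq, comp)
            )
        assert abs(np.mean(scs)) < 0.03


class TestWobbleDecoding:
    def test_missing_codons_extremes(self):
        full = build_reference(
            [make_gene(reverse_complement(c)) for c in SENSE_CODONS]
        )
        assert missing_codons(full) == set()
        empty = build_reference([])
        assert len(missing_codons(empty)) == 61

    def test_single_absent_anticodon_maps_to_its_codon(self):
        comp = build_reference(
            [make_gene(reverse_complement(c)) for c in SENSE_CODONS if c != "CTC"]
        )
        assert missing_codons(comp) == {"CUC"}

    def test_gu_wobble_reads_uuu_with_gaa_anticodon(self):
        comp = build_reference([make_gene("GAA")])  # Phe anticodon
        ok, families = wobble_decodable("UUU", comp)
        assert ok and families == ["tRNA-Phe-GAA"]

    def test_editing_rescues_cuc_only_with_observed_variant(self):
        comp = build_reference([make_gene("AAG")])  # Leu-AAG
        assert not wobble_decodable("CUC", comp, allow_editing=False)[0]
        assert not wobble_decodable("CUC", comp, allow_editing=True, variants=[])[0]
        variant = VariantCall(
            contig=comp.contigs[0], position=33, ref_base="A", alt_base="G",
            ref_count=60, alt_count=40, p_value=1e-20,
            in_anticodon=True, anticodon_offset=0,
        )
        ok, fams = wobble_decodable("CUC", comp, allow_editing=True, variants=[variant])
        assert ok and fams == ["tRNA-Leu-AAG"]

    def test_inosine_does_not_pair_g(self):
        comp = build_reference([make_gene("ACG")])  # Arg-ACG
        variant = VariantCall(
            contig=comp.contigs[0], position=33, ref_base="A", alt_base="G",
            ref_count=60, alt_count=40, p_value=1e-20,
            in_anticodon=True, anticodon_offset=0,
        )
        assert not wobble_decodable("CGG", comp, allow_editing=True, variants=[variant])[0]

    def test_non_a_to_g_variant_is_not_editing_evidence(self):
        comp = build_reference([make_gene("CAG")])  # Leu-CAG, C34
        variant = VariantCall(
            contig=comp.contigs[0], position=33, ref_base="C", alt_base="T",
            ref_count=60, alt_count=40, p_value=1e-20,
            in_anticodon=True, anticodon_offset=0,
        )
        assert comp.edited_families([variant]) == set()
        report = editing_compensation(["CUC"], [variant], comp)
        assert report["codons"]["CUC"]["status"] == "unexplained"

    def test_invalid_codon_rejected(self):
        comp = build_reference([make_gene("AAG")])
        with pytest.raises(ValueError):
            wobble_decodable("UAA", comp)  # stop codon
        with pytest.raises(ValueError):
            wobble_decodable("AXG", comp)
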