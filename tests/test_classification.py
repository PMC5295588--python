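"""Classification rules, tiling paths, strand specificity, ORF scanning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncrna.classification import (
    classify_models,
    composite_region,
    compute_tiling_path,
    filter_lncrna,
    find_orfs,
    strand_specificity,
    tiling_gap_fraction,
    TilingPath,
)
from ncrna.io_formats import (
    AlignmentRecord,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    ReadTable,
)


def iv(start, end, strand="+", contig="chr1"):
    return GenomicInterval(contig, start, end, strand)


def gene(gid, *ivs, biotype="protein_coding"):
    return GeneModel(gid, tuple(ivs), biotype)


def pair_records(qname, contig, pos, cigar="100M", strand="+", end=None):
    """Two mates of one properly paired fragment (forward protocol)."""
    length = sum(
        int(n) for n, op in _cigar_items(cigar) if op in "MDN=X"
    )
    recs = []
    for first, p in ((True, pos), (False, pos if end is None else end)):
        reverse = (strand == "-") == first
        recs.append(
            AlignmentRecord(
                read_id=qname, contig=contig, pos=p,
                cigar=tuple((op, int(n)) for n, op in _cigar_items(cigar)),
                mate_pos=pos, properly_paired=True, first_in_pair=first,
                reverse_complemented=reverse, unique=True, mapq=50,
                end=p + length, sample="s1",
            )
        )
    return recs


def _cigar_items(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


class TestClassifyModels:
    def setup_method(self):
        self.ann = GenomeAnnotation(
            [gene("gA", iv(1000, 2000)), gene("gB", iv(5000, 6000, "-"))],
            {"chr1": 10_000},
        )

    def test_model_matching_reference_is_mrna(self):
        m = gene("m1", iv(1000, 2000))
        assert classify_models([m], self.ann)["m1"] == "mRNA"

    def test_model_between_genes_is_lncrna_candidate(self):
        m = gene("m2", iv(3000, 3600))
        assert classify_models([m], self.ann)["m2"] == "lncRNA"

    def test_opposite_strand_overlap_is_asrna_candidate(self):
        m = gene("m3", iv(1950, 2400, "-"))
        assert classify_models([m], self.ann)["m3"] == "asRNA"

    def test_partition_is_exhaustive_and_exclusive(self):
        models = [gene(f"m{i}", iv(100 + 900 * i, 600 + 900 * i)) for i in range(8)]
        classes = classify_models(models, self.ann)
        assert set(classes) == {m.gene_id for m in models}
        assert set(classes.values()) <= {"mRNA", "lncRNA", "asRNA"}

    def test_unknown_contig_is_an_error(self):
        with pytest.raises(ValueError, match="unknown contig"):
            classify_models([gene("mX", iv(0, 100, contig="chr9"))], self.ann)


class TestTilingPath:
    def test_no_qualifying_reads_gives_empty_cover(self):
        region = iv(0, 1000)
        path = compute_tiling_path(region, ReadTable.from_records([]))
        assert path.covered == () and path.supporting_read_count == 0

    def test_two_overlapping_full_match_reads_union(self):
        reads = pair_records("a", "chr1", 0) + pair_records("b", "chr1", 50)
        path = compute_tiling_path(iv(0, 1000), ReadTable.from_records(reads))
        assert path.covered == ((0, 150),)

    def test_spliced_reads_do_not_contribute(self):
        reads = (
            pair_records("a", "chr1", 0)
            + pair_records("b", "chr1", 200, cigar="40M20N40M")
        )
        path = compute_tiling_path(iv(0, 1000), ReadTable.from_records(reads))
        assert path.covered == ((0, 100),)

    def test_gap_fraction_arithmetic_and_strictness(self):
        region = iv(0, 100)
        full = TilingPath(region, ((0, 100),), 10)
        assert tiling_gap_fraction(full) == 0.0
        partial94 = TilingPath(region, ((0, 94),), 10)
        assert tiling_gap_fraction(partial94) == pytest.approx(0.06)
        partial95 = TilingPath(region, ((0, 95),), 10)
        assert tiling_gap_fraction(partial95) == pytest.approx(0.05)
        # the rule removes only when the gap strictly exceeds 5%
        assert tiling_gap_fraction(partial95) <= 0.05
        assert tiling_gap_fraction(partial94) > 0.05


class TestCompositeRegion:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (150, 300), (100, 300)),
            ((0, 500), (100, 200), (0, 500)),
            ((0, 100), (300, 400), (0, 400)),
        ],
    )
    def test_minimal_contiguous_cover(self, a, b, expected):
        region = composite_region(iv(*a), iv(*b, "-"))
        assert (region.start, region.end) == expected

    def test_different_contigs_rejected(self):
        with pytest.raises(ValueError, match="different contigs"):
            composite_region(iv(0, 10), iv(0, 10, "+", "chr2"))


class TestStrandSpecificity:
    def test_direct_ratio(self):
        reads = []
        for i in range(79):
            reads += pair_records(f"s{i}", "chr1", 100 + i, strand="+")
        for i in range(21):
            reads += pair_records(f"a{i}", "chr1", 100 + i, strand="-")
        ss = strand_specificity(iv(0, 1000), "+", ReadTable.from_records(reads))
        assert ss == pytest.approx(0.79)

    def test_all_sense_gives_exactly_one(self):
        reads = [r for i in range(10) for r in pair_records(f"x{i}", "chr1", i * 5)]
        assert strand_specificity(iv(0, 1000), "+", ReadTable.from_records(reads)) == 1.0

    def test_zero_reads_reported_missing(self):
        assert strand_specificity(iv(0, 10), "+", ReadTable.from_records([])) is None

    def test_binomial_sampling_recovers_antisense_fraction(self):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(1000):
            strand = "-" if rng.random() < 0.3 else "+"
            reads += pair_records(f"f{i}", "chr1", int(rng.integers(0, 500)), strand=strand)
        ss = strand_specificity(iv(0, 1000), "+", ReadTable.from_records(reads))
        assert ss == pytest.approx(0.70, abs=0.03)


class TestFindOrfs:
    def test_minimal_150bp_orf_at_threshold(self):
        seq = "ATG" + "CCA" * 48 + "TAA"
        assert len(seq) == 150
        orfs, flag = find_orfs(seq, 150)
        assert flag and orfs[0]["length_bp"] == 150

    def test_no_start_codon_means_no_orfs(self):
        orfs, flag = find_orfs("CCTCCTCCTTAA" * 20, 30)
        assert orfs == [] and not flag

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            find_orfs("ATGXXXTAA")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_three_frame_brute_force_on_at_rich_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), p=[0.415, 0.085, 0.085, 0.415], size=628))
        orfs, flag = find_orfs(seq, 150)
        expected = set()
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
            start = None
            for k, c in enumerate(codons):
                if start is None and c == "ATG":
                    start = k
                elif start is not None and c in ("TAA", "TAG", "TGA"):
                    length = (k - start + 1) * 3
                    if length >= 150:
                        expected.add((frame, frame + start * 3, length))
                    start = None
        got = {(o["frame"], o["start"], o["length_bp"]) for o in orfs}
        assert got == expected and flag == bool(expected)


class TestLncrnaFilter:
    def _setup(self, cand_span=(3000, 3300)):
        ann = GenomeAnnotation(
            [gene("gL", iv(1000, 2000)), gene("gR", iv(5000, 6000))],
            {"chr1": 10_000},
        )
        cand = gene("c1", iv(*cand_span), biotype="other")
        return ann, cand

    def _frames(self, counts_row, n_samples=4):
        counts = pd.DataFrame(
            [counts_row], index=["c1"], columns=[f"s{j}" for j in range(n_samples)]
        )
        rpkm = counts * 1.0
        return counts, rpkm

    def test_short_candidate_rejected_by_length_rule(self):
        ann, _ = self._setup()
        cand = gene("c1", iv(3000, 3199))
        counts, ab = self._frames([5, 5, 5, 5])
        ok, logs = filter_lncrna([cand], counts, ab, ann, ReadTable.from_records([]))
        assert ok == [] and ("min_length_200", False) in logs["c1"]

    def test_low_raw_counts_rejected(self):
        ann, cand = self._setup()
        counts, ab = self._frames([1, 1, 1, 0])
        ok, logs = filter_lncrna([cand], counts, ab, ann, ReadTable.from_records([]))
        assert ok == [] and ("min_raw_reads_any_timepoint", False) in logs["c1"]

    def test_bridge_to_neighbor_rejects_and_gap_retains(self):
        ann, cand = self._setup()
        counts, ab = self._frames([4, 0, 0, 0])
        # continuous coverage over the left flank gap [2000, 3000)
        bridge = []
        for i, pos in enumerate(range(2000, 3000, 80)):
            bridge += pair_records(f"b{i}", "chr1", pos)
        ok, logs = filter_lncrna(
            [cand], counts, ab, ann, ReadTable.from_records(bridge)
        )
        assert ok == [] and ("no_tiling_path_to_neighbor", False) in logs["c1"]
        # removing one read opens a >= 1 bp hole on that flank
        broken = ReadTable.from_records(bridge[2:])
        ok2, logs2 = filter_lncrna([cand], counts, ab, ann, broken)
        assert [m.gene_id for m in ok2] == ["c1"]

    def test_missing_count_row_is_an_error(self):
        ann, cand = self._setup()
        counts, ab = self._frames([4, 0, 0, 0])
        counts.index = ["other"]
        ab.index = ["other"]
        with pytest.raises(KeyError, match="c1"):
            filter_lncrna([cand], counts, ab, ann, ReadTable.from_records([]))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(200, 400), st.integers(2, 6))
    def test_filter_monotone_in_thresholds(self, min_len, min_reads):
        ann, _ = self._setup()
        rng = np.random.default_rng(min_len * 7 + min_reads)
        cands, counts_rows = [], []
        for i in range(8):
            length = int(rng.integers(150, 500))
            start = 2500 + i * 20  # overlapping is fine for this property
            cands.append(gene(f"c{i}", iv(start, start + length)))
            counts_rows.append(rng.integers(0, 6, size=4))
        counts = pd.DataFrame(
            counts_rows, index=[c.gene_id for c in cands],
            columns=[f"s{j}" for j in range(4)],
        )
        ab = counts * 1.0
        empty = ReadTable.from_records([])
        base, _ = filter_lncrna(
            cands, counts, ab, ann, empty, min_length=min_len, min_reads=min_reads
        )
        stricter, _ = filter_lncrna(
            cands, counts, ab, ann, empty,
            min_length=min_len + 50, min_reads=min_reads + 1,
        )
        assert {m.gene_id for m in stricter} <= {m.gene_id for m in base}
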