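"""Tests for intron extraction, combination classification and shift detection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from splicesurvey.genome_io import GenomeAssembly, TranscriptModel
from splicesurvey.splice_sites import (
    ALL_COMBOS,
    CANONICAL,
    Intron,
    SpliceClass,
    build_profile,
    classify_combo,
    closest_reference,
    detect_shift_equivalence,
    extract_introns,
    hamming_distance,
    is_ambiguous,
    read_profile,
    reverse_complement,
    write_profile,
)


def make_intron(seq_name, start, end, strand="+", combo="GTAG", length=None, tid="t", idx=0):
    return Intron(seq_name, start, end, strand, combo, tid, idx)


class TestExtractIntrons:
    def test_plus_strand_borders(self, toy_assembly):
        tr = TranscriptModel("t", "chr1", "+", [(0, 3), (23, 26)])
        (intron,) = extract_introns(tr, toy_assembly)
        assert (intron.start, intron.end) == (3, 23)
        assert intron.length == 20
        assert intron.combo == "GTAG"

    def test_minus_strand_is_strand_invariant(self, toy_assembly):
        seq = toy_assembly.sequences["chr1"]
        mirrored = GenomeAssembly({"chr1": reverse_complement(seq)})
        n = len(seq)
        segments = sorted((n - e, n - s) for s, e in [(0, 3), (23, 26)])
        tr = TranscriptModel("t", "chr1", "-", segments)
        (intron,) = extract_introns(tr, mirrored)
        assert intron.combo == "GTAG"
        assert intron.length == 20

    def test_single_cds_yields_nothing(self, toy_assembly):
        tr = TranscriptModel("t", "chr1", "+", [(0, 26)])
        assert extract_introns(tr, toy_assembly) == []

    def test_minus_strand_index_is_biological(self):
        # two introns; on the minus strand the genomically-right one is 5'
        seq = "CCC" + "GTTTTTTTTTTTTTTTTTAG" + "CCC" + "GCTTTTTTTTTTTTTTTTAG" + "CCC"
        assembly = GenomeAssembly({"c": reverse_complement(seq)})
        n = len(seq)
        fwd_segments = [(0, 3), (23, 26), (46, 49)]
        segments = sorted((n - e, n - s) for s, e in fwd_segments)
        tr = TranscriptModel("t", "c", "-", segments)
        introns = extract_introns(tr, assembly)
        assert [i.combo for i in introns] == ["GTAG", "GCAG"]
        assert [i.index for i in introns] == [0, 1]


class TestClassification:
    @pytest.mark.parametrize(
        "combo,expected",
        [
            ("GTAG", SpliceClass.CANONICAL),
            ("GCAG", SpliceClass.MAJOR_GC_AG),
            ("ATAC", SpliceClass.MAJOR_AT_AC),
            ("CAGG", SpliceClass.MINOR),
            ("GNAG", SpliceClass.AMBIGUOUS),
        ],
    )
    def test_examples(self, combo, expected):
        assert classify_combo(combo) is expected

    def test_length_guard(self):
        with pytest.raises(ValueError):
            classify_combo("GTAGG")

    def test_partition_of_256(self):
        classes = [classify_combo(c) for c in ALL_COMBOS]
        assert classes.count(SpliceClass.CANONICAL) == 1
        assert classes.count(SpliceClass.MAJOR_GC_AG) == 1
        assert classes.count(SpliceClass.MAJOR_AT_AC) == 1
        assert classes.count(SpliceClass.MINOR) == 253
        assert SpliceClass.AMBIGUOUS not in classes


class TestHamming:
    def test_examples(self):
        assert hamming_distance("GTAG", "GTAG") == 0
        assert hamming_distance("CAGG", "GTAG") == 3

    def test_histogram_to_canonical(self):
        # closed form: C(4,d) * 3^d
        histogram = {d: 0 for d in range(5)}
        for combo in ALL_COMBOS:
            histogram[hamming_distance(combo, CANONICAL)] += 1
        assert histogram == {0: 1, 1: 12, 2: 54, 3: 108, 4: 81}

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("GNAG", "GTAG")


class TestClosestReference:
    @pytest.mark.parametrize(
        "combo,expected_ref,expected_subs",
        [
            ("GCAC", "GCAG", [(4, "G", "C")]),
            ("CAGG", "GTAG", [(1, "G", "C"), (2, "T", "A"), (3, "A", "G")]),
            ("GTAC", "GTAG", [(4, "G", "C")]),  # tie with ATAC -> GTAG
        ],
    )
    def test_examples(self, combo, expected_ref, expected_subs):
        ref, subs = closest_reference(combo)
        assert ref == expected_ref
        assert subs == expected_subs

    def test_canonical_and_major_rejected(self):
        for combo in ("GTAG", "GCAG", "ATAC"):
            with pytest.raises(ValueError):
                closest_reference(combo)

    def test_minimality_over_all_minors(self):
        for combo in ALL_COMBOS:
            if classify_combo(combo) is not SpliceClass.MINOR:
                continue
            ref, subs = closest_reference(combo)
            d = hamming_distance(combo, ref)
            assert d == len(subs)
            assert d <= hamming_distance(combo, CANONICAL)
            assert d == min(
                hamming_distance(combo, r) for r in ("GTAG", "GCAG", "ATAC")
            )


class TestBuildProfile:
    def test_counts_masking_and_total(self):
        combos = ["GTAG", "GTAG", "GTAG", "GCAG", "GNAG"]
        introns = [
            make_intron("c", 0, 30, combo=combo, idx=i) for i, combo in enumerate(combos)
        ]
        profile = build_profile(introns, min_length=20)
        assert profile.counts == {"GTAG": 3, "GCAG": 1}
        assert profile.ambiguous_masked == 1
        assert profile.total_introns == 5
        assert sum(profile.counts.values()) + profile.ambiguous_masked == 5

    def test_short_introns_excluded(self):
        intron = make_intron("c", 0, 19)
        profile = build_profile([intron], min_length=20)
        assert profile.total_introns == 0
        assert profile.counts == {}

    def test_empty_input(self):
        profile = build_profile([], min_length=20)
        assert profile.total_introns == 0
        assert profile.vector() == [0] * 256

    def test_tsv_roundtrip(self, tmp_path):
        introns = [make_intron("c", 0, 30, combo="GTAG"), make_intron("c", 0, 30, combo="GNAG")]
        profile = build_profile(introns, species="sp1")
        path = tmp_path / "p.tsv"
        write_profile(profile, path)
        again = read_profile(path)
        assert again.species == "sp1"
        assert again.counts == profile.counts
        assert again.ambiguous_masked == 1


def respliced(seq, start, end):
    """Mature mRNA after removing [start, end) — the independent oracle."""
    return seq[:start] + seq[end:]


class TestShiftEquivalence:
    def test_cagg_example_diagnoses_gcag(self):
        seq = "ATGGCAAATTAGGTTT"
        assembly = GenomeAssembly({"s": seq})
        intron = make_intron("s", 4, 13, combo="CAGG")
        placements = detect_shift_equivalence(intron, assembly, max_shift=3)
        by_shift = {p.shift: p for p in placements}
        assert -1 in by_shift and by_shift[-1].combo == "GCAG"
        # the -1 shift is the only alternative with canonical/major class
        majors = [
            p for p in placements if p.splice_class is not SpliceClass.MINOR
        ]
        assert [p.shift for p in majors] == [-1]
        for p in placements:
            assert respliced(seq, p.start, p.end) == respliced(seq, 4, 13)

    def test_matches_brute_force_oracle(self):
        seq = "ATGGCAAATTAGGTTT"
        assembly = GenomeAssembly({"s": seq})
        intron = make_intron("s", 4, 13, combo="CAGG")
        found = {p.shift for p in detect_shift_equivalence(intron, assembly, 3)}
        oracle = {
            s
            for s in range(-3, 4)
            if s != 0
            and 0 <= 4 + s
            and 13 + s <= len(seq)
            and respliced(seq, 4 + s, 13 + s) == respliced(seq, 4, 13)
        }
        assert found == oracle

    def test_broken_context_yields_nothing(self):
        # changing the base after the intron breaks every equivalence
        seq = "ATGGCAAATTAGATTT"
        assembly = GenomeAssembly({"s": seq})
        intron = make_intron("s", 4, 13, combo="CAGG")
        assert detect_shift_equivalence(intron, assembly, 3) == []

    def test_canonical_nonrepeating_context(self):
        seq = "CAT" + "GTAAATTTCCCCCCCTAG" + "CCA"
        assembly = GenomeAssembly({"s": seq})
        intron = make_intron("s", 3, 21, combo="GTAG")
        assert detect_shift_equivalence(intron, assembly, 3) == []

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=60), st.data())
    def test_all_placements_preserve_mrna(self, seq, data):
        start = data.draw(st.integers(min_value=4, max_value=len(seq) - 25))
        end = start + 20
        assembly = GenomeAssembly({"s": seq})
        intron = make_intron("s", start, end, combo=seq[start : start + 2] + seq[end - 2 : end])
        for p in detect_shift_equivalence(intron, assembly, 3):
            assert respliced(seq, p.start, p.end) == respliced(seq, start, end)
            assert p.combo == seq[p.start : p.start + 2] + seq[p.end - 2 : p.end]


class TestStrandInvarianceOfProfiles:
    def test_mirrored_genome_gives_identical_profile(self, small_synthetic):
        from splicesurvey.genome_io import read_annotation, read_genome, filter_genes, select_representative_transcript

        assembly = read_genome(small_synthetic["fasta"])
        annotation = read_annotation(small_synthetic["gff3"], assembly)
        mirrored = GenomeAssembly(
            {n: reverse_complement(s) for n, s in assembly.sequences.items()}
        )
        flipped_genes = []
        for gene in annotation.genes:
            n = len(assembly.sequences[gene.seq_name])
            flipped = []
            for tr in gene.transcripts:
                segments = sorted((n - e, n - s) for s, e in tr.cds_segments)
                flipped.append(
                    TranscriptModel(
                        tr.transcript_id,
                        tr.seq_name,
                        "-" if tr.strand == "+" else "+",
                        segments,
                    )
                )
            gene_copy = type(gene)(
                gene.gene_id,
                gene.seq_name,
                "-" if gene.strand == "+" else "+",
                flipped,
            )
            flipped_genes.append(gene_copy)

        def profile_of(asm, genes):
            introns = []
            for gene in genes:
                tr = select_representative_transcript(gene)
                introns.extend(extract_introns(tr, asm))
            return build_profile(introns)

        original = profile_of(assembly, annotation.genes)
        flipped = profile_of(mirrored, flipped_genes)
        assert original.counts == flipped.counts
        assert original.ambiguous_masked == flipped.ambiguous_masked
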