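"""Composition, codon usage, ORF discovery, repeats, quadripartite layout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidkit.genomestats import (FrameError, UndefinedValueError,
                                    codon_position_gc, detect_quadripartite,
                                    find_orfs, find_repeats, gc_content,
                                    gene_content_table, gene_counts,
                                    percent_identity, rscu)
from plastidkit.seqio import Feature, GenomeRecord, reverse_complement
from plastidkit.synthetic_data import PlastomeSimConfig, simulate_plastome

from conftest import substitute


class TestGCContent:
    @pytest.mark.parametrize("seq, expected", [
        ("ATGC", 0.5),
        ("AAAA", 0.0),
        ("GGCC", 1.0),
        ("ANGN", 0.5),   # N excluded from the denominator
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            gc_content("NNNN")

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_reverse_complement_invariant(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestCodonPositionGC:
    def test_single_codon_pair(self):
        prof = codon_position_gc(["ATGGCA"])
        assert (prof.gc1, prof.gc2, prof.gc3) == (0.5, 0.5, 0.5)

    def test_at_only(self):
        prof = codon_position_gc(["AAAAAA"])
        assert (prof.gc1, prof.gc2, prof.gc3) == (0.0, 0.0, 0.0)

    def test_total_is_length_weighted_mean(self):
        prof = codon_position_gc(["GGGGGG", "ATA"])
        assert prof.gc_total == pytest.approx(6 / 9)

    def test_out_of_frame_cds_names_the_gene(self):
        with pytest.raises(FrameError, match="rps4"):
            codon_position_gc(["ATGG"], names=["rps4"])


class TestRSCU:
    def test_uniform_family_gives_one(self):
        # all four Ala codons once each
        table = rscu(["GCTGCCGCAGCG"])
        for codon in ("GCT", "GCC", "GCA", "GCG"):
            assert table[codon] == pytest.approx(1.0)

    def test_single_codon_family_concentration(self):
        table = rscu(["GCAGCAGCAGCA"])
        assert table["GCA"] == pytest.approx(4.0)
        assert table["GCC"] == table["GCG"] == table["GCT"] == 0.0

    def test_six_codon_leucine_family(self):
        table = rscu(["TTA" * 3 + "TTG" * 3])
        assert table["TTA"] == pytest.approx(3.0)
        assert table["CTG"] == 0.0

    def test_absent_amino_acid_reported_missing_not_zero(self):
        table = rscu(["TTATTG"])  # leucine only
        assert table["GCA"] is None

    def test_observed_families_average_to_one(self):
        rng = np.random.default_rng(3)
        from plastidkit.codonmodel import SENSE_CODONS
        cds = "".join(rng.choice(SENSE_CODONS, 300))
        table = rscu([cds])
        from plastidkit.codonmodel import CODON_AA
        by_aa = {}
        for codon, aa in zip(SENSE_CODONS, CODON_AA):
            by_aa.setdefault(aa, []).append(table[codon])
        for aa, vals in by_aa.items():
            if all(v is not None for v in vals):
                assert np.mean(vals) == pytest.approx(1.0)


class TestPercentIdentity:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACGT", "ACGT", 1.0),
        ("ACGT", "ACGA", 0.75),
        ("AC-T", "ACGT", 1.0),   # gap columns excluded
    ])
    def test_values(self, a, b, expected):
        assert percent_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity("ACG", "AC")


class TestFindOrfs:
    def test_length_filter(self):
        rec = GenomeRecord(id="r", sequence="ATGAAATAA")
        assert find_orfs(rec, min_len_bp=90) == []

    def test_minimal_orf(self):
        rec = GenomeRecord(id="r", sequence="ATGAAATAA")
        calls = find_orfs(rec, min_len_bp=9)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end, calls[0].strand,
                calls[0].length) == (0, 9, "+", 9)

    def test_earliest_qualifying_start_is_reported(self):
        # TTG ... ATG ... TAA: maximal ORF anchors at the TTG
        rec = GenomeRecord(id="r", sequence="TTGAAAATGAAATAA")
        calls = find_orfs(rec, min_len_bp=9)
        assert calls[0].length == 15
        assert calls[0].sequence.startswith("TTG")

    def test_circular_wrap(self):
        seq = "AAATAG" + "C" * 30 + "ATGCCCAAA"
        rec = GenomeRecord(id="c", sequence=seq, circular=True)
        calls = find_orfs(rec, min_len_bp=9, start_codons=frozenset({"ATG"}))
        assert [(c.start, c.length, c.sequence) for c in calls] == \
            [(36, 15, "ATGCCCAAAAAATAG")]

    def test_minus_strand_coordinates(self):
        orf = "ATGAAACCCTAA"
        seq = "GG" + reverse_complement(orf) + "GG"
        rec = GenomeRecord(id="r", sequence=seq)
        calls = find_orfs(rec, min_len_bp=12, start_codons=frozenset({"ATG"}))
        assert len(calls) == 1
        c = calls[0]
        assert c.strand == "-"
        assert reverse_complement(rec.sequence[c.start:c.end]) == orf

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=400),
           st.booleans())
    def test_every_reported_orf_validates_its_invariants(self, seq, circular):
        rec = GenomeRecord(id="r", sequence=seq, circular=circular)
        for call in find_orfs(rec, min_len_bp=9):
            call.validate()
            assert call.length <= len(seq)


class TestFindRepeats:
    def test_planted_exact_direct_duplicate(self, random_seq):
        s = list(random_seq(10_000, seed=42))
        s[7000:7030] = s[2000:2030]
        rec = GenomeRecord(id="r", sequence="".join(s))
        direct = [h for h in find_repeats(rec) if h.orientation == "direct"]
        assert len(direct) == 1
        hit = direct[0]
        assert hit.identity == 1.0
        assert hit.length >= 30
        assert hit.pos_a < hit.pos_b

    def test_planted_inverted_copy(self, random_seq):
        s = list(random_seq(10_000, seed=43))
        s[6000:6025] = list(reverse_complement("".join(s[4000:4025])))
        rec = GenomeRecord(id="r", sequence="".join(s))
        inverted = [h for h in find_repeats(rec) if h.orientation == "inverted"]
        assert len(inverted) == 1
        assert inverted[0].length >= 25

    def test_identity_threshold_two_vs_five_substitutions(self, random_seq):
        base = random_seq(10_000, seed=44)
        unit = base[3000:3040]
        # two substitutions: 38/40 = 95% -> reported
        copy2 = substitute(substitute(unit, 13), 27)
        rec = GenomeRecord(id="r", sequence=base[:8000] + copy2 + base[8040:])
        hits = [h for h in find_repeats(rec) if h.orientation == "direct"]
        assert any(h.length >= 40 and h.identity >= 0.95 for h in hits)
        # five evenly spread substitutions: every 20-bp window has >= 2 -> absent
        copy5 = unit
        for pos in (4, 12, 20, 28, 36):
            copy5 = substitute(copy5, pos)
        rec5 = GenomeRecord(id="r", sequence=base[:8000] + copy5 + base[8040:])
        assert [h for h in find_repeats(rec5) if h.orientation == "direct"] == []

    def test_unique_kmers_give_no_hits(self):
        # de Bruijn-free short sequence: all 9-mers unique in a random draw
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        rec = GenomeRecord(id="r", sequence=seq)
        assert [h for h in find_repeats(rec) if h.orientation == "direct"] == []

    def test_doubled_sequence_reports_full_length_direct_hit(self, random_seq):
        s = random_seq(3000, seed=45)
        rec = GenomeRecord(id="r", sequence=s + s)
        direct = [h for h in find_repeats(rec) if h.orientation == "direct"]
        assert direct
        assert max(h.length for h in direct) >= len(s) - 9


class TestDetectQuadripartite:
    def test_planted_ir_recovered_exactly(self):
        rec, truth = simulate_plastome(PlastomeSimConfig(
            total_length=50_000, ir_length=5_000, ssc_length=8_000, seed=1))
        layout = detect_quadripartite(rec)
        assert layout is not None
        assert layout.ir_length == 5_000
        assert layout.ira == truth["ira"]
        assert layout.irb == truth["irb"]
        assert (layout.ssc[1] - layout.ssc[0]) == 8_000

    def test_no_ir_returns_none(self):
        rec, _ = simulate_plastome(PlastomeSimConfig(
            total_length=20_000, ir_length=0, ssc_length=0, seed=2))
        assert detect_quadripartite(rec) is None

    def test_linear_record_unsupported(self):
        rec = GenomeRecord(id="r", sequence="ACGT" * 1000, circular=False)
        with pytest.raises(ValueError):
            detect_quadripartite(rec)


class TestGeneContent:
    def _record(self):
        seq = "A" * 3000
        feats = [
            Feature("rps2", "gene", "+", [(0, 300)]),
            Feature("rps2", "gene", "+", [(600, 900)]),     # IR duplicate
            Feature("rps16", "gene", "+", [(1200, 1400)], pseudo=True),
        ]
        return GenomeRecord(id="g1", sequence=seq, features=feats)

    def test_duplicates_collapse_and_pseudogenes_not_counted(self):
        rec = self._record()
        counts = gene_counts(rec)
        assert counts["total"] == 1
        table = gene_content_table([rec])
        assert table.loc["rps2", "g1"] == "intact"
        assert table.loc["rps16", "g1"] == "pseudo"

    def test_intersection_of_two_records(self):
        rec1 = self._record()
        rec2 = GenomeRecord(id="g2", sequence="A" * 1000, features=[
            Feature("rps4", "gene", "+", [(0, 300)])])
        rec1.features.append(Feature("rps4", "gene", "+", [(2000, 2300)]))
        table = gene_content_table([rec1, rec2])
        shared = table[(table["g1"] == "intact") & (table["g2"] == "intact")]
        assert list(shared.index) == ["rps4"]

    def test_trna_name_normalisation(self):
        rec = GenomeRecord(id="g", sequence="A" * 100, features=[
            Feature("trnl-uaa", "tRNA", "+", [(0, 80)])])
        assert "trnL-UAA" in gene_content_table([rec]).index
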