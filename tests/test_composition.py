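import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar._codes import revcomp
from mitochar.composition import (
    classify_codon_boundaries,
    codon_usage,
    composition_summary,
    region_composition,
    skew_by_codon_position,
    skews_from_percentages,
    trim_stop,
)
from mitochar.io import AnnotatedGenome, GeneFeature

dna = st.text(alphabet="ACGT", min_size=1, max_size=1000)


class TestSkews:
    def test_simple_examples(self):
        s = composition_summary("AAAT")
        assert s.at_skew == pytest.approx(0.5)
        assert s.gc_skew == 0.0 and s.zero_denominator
        assert composition_summary("AATT").at_skew == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_summary("")

    def test_published_percentages_pin_gc_skew_convention(self):
        """Skews recomputed from the printed PCG base percentages of the
        M. indica mitogenome must match the printed skew values — this is
        what fixes GC-skew = (G-C)/(G+C)."""
        at_skew, gc_skew = skews_from_percentages(t=29.8, c=26.2, a=31.4, g=12.6)
        assert at_skew == pytest.approx(0.026, abs=0.002)
        assert gc_skew == pytest.approx(-0.352, abs=0.002)

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_skew_antisymmetry_under_reverse_complement(self, seq):
        fwd = composition_summary(seq)
        rev = composition_summary(revcomp(seq))
        assert rev.at_skew == pytest.approx(-fwd.at_skew, abs=1e-12)
        assert rev.gc_skew == pytest.approx(-fwd.gc_skew, abs=1e-12)

    def test_n_bases_in_length_not_denominator(self):
        s = composition_summary("AANN")
        assert s.length == 4
        assert s.at_content == 1.0

    def test_concatenation_additivity(self):
        rng = random.Random(5)
        parts = ["".join(rng.choice("ACGT") for _ in range(80)) for _ in range(4)]
        whole = composition_summary("".join(parts))
        per = [composition_summary(p) for p in parts]
        assert whole.A == sum(s.A for s in per)
        assert whole.T == sum(s.T for s in per)
        assert whole.G == sum(s.G for s in per)
        assert whole.C == sum(s.C for s in per)


class TestRegionComposition:
    def _genome(self):
        seq = "A" * 30 + "ACGTACGTAC" + "C" * 10
        feats = [
            GeneFeature("rrnS", "rrnS", "rRNA", "H", 1, 30),
            GeneFeature("trnF", "trnF", "tRNA", "L", 31, 40),
        ]
        return AnnotatedGenome("x", sequence=seq, features=feats)

    def test_all_a_rrna(self):
        g = self._genome()
        (s,) = region_composition(g, "rRNA")
        assert s.at_content == 1.0 and s.at_skew == 1.0

    def test_l_strand_concatenated_on_coding_strand(self):
        g = self._genome()
        (s,) = region_composition(g, "tRNA")
        # coding strand of the L feature: revcomp("ACGTACGTAC") = GTACGTACGT
        assert (s.A, s.C, s.G, s.T) == (2, 2, 3, 3)

    def test_unmatched_selector_raises(self):
        with pytest.raises(ValueError, match="matches no feature"):
            region_composition(self._genome(), "PCG")


class TestCodonPositions:
    def test_position_three_bases(self):
        rows = skew_by_codon_position(["ATGGCC"])
        third = rows[2]
        assert third.G == 1 and third.C == 1 and third.length == 2

    def test_positions_sum_to_whole(self):
        rng = random.Random(9)
        cds = "".join(rng.choice("ACGT") for _ in range(300))
        rows = skew_by_codon_position({"g": cds})
        whole = composition_summary(trim_stop(cds))
        assert sum(r.A for r in rows) == whole.A
        assert sum(r.G for r in rows) == whole.G

    def test_frame_violation_names_gene(self):
        with pytest.raises(ValueError, match="nad1"):
            skew_by_codon_position({"nad1": "ATGGC"})  # 5 nt, no T/TA overhang


class TestCodonUsage:
    def test_uniform_family_rscu_one(self):
        t = codon_usage(["GCTGCCGCAGCG"])
        assert [t.rscu[c] for c in ("GCT", "GCC", "GCA", "GCG")] == [1, 1, 1, 1]

    def test_single_codon_family(self):
        t = codon_usage(["GCC" * 4])
        assert t.rscu["GCC"] == 4.0
        assert t.rscu["GCT"] == t.rscu["GCA"] == t.rscu["GCG"] == 0.0

    def test_family_mean_rscu_is_one(self):
        rng = random.Random(1)
        cds = "".join(rng.choice("ACGT") for _ in range(3 * 500))
        t = codon_usage([cds])
        from mitochar._codes import mito_code, sense_codons

        fwd = mito_code().forward_table
        families = {}
        for c in sense_codons():
            families.setdefault(fwd[c], []).append(c)
        for aa, codons in families.items():
            if sum(t.counts[c] for c in codons):
                mean = sum(t.rscu[c] for c in codons) / len(codons)
                assert mean == pytest.approx(1.0)

    def test_aa_frequencies_sum_to_one(self):
        t = codon_usage(["ATGGCCTTTAAA"])
        assert sum(t.aa_frequencies.values()) == pytest.approx(1.0)

    def test_vertebrate_mito_reassignments(self):
        t = codon_usage(["ATATGA"])  # ATA=Met, TGA=Trp in the mito code
        assert t.aa_frequencies["M"] == pytest.approx(0.5)
        assert t.aa_frequencies["W"] == pytest.approx(0.5)
        t2 = codon_usage(["AGAAGG"])  # both are stops: no sense codons
        assert sum(t2.counts.values()) == 0
        assert t2.stop_counts == {"AGA": 1, "AGG": 1}

    def test_ambiguous_codons_skipped(self):
        t = codon_usage(["ATGNNNGCC"])
        assert t.skipped_codons == 1
        assert t.counts["ATG"] == 1 and t.counts["GCC"] == 1


class TestCodonBoundaries:
    def _genome(self, cds, strand="H"):
        pad = "ACGT" * 5
        seq = pad + cds + pad
        if strand == "L":
            seq = pad + revcomp(cds) + pad
        f = GeneFeature("nad1", "nad1", "PCG", strand, 21, 20 + len(cds))
        return AnnotatedGenome("x", sequence=seq, features=[f])

    def test_canonical_start_and_stop(self):
        (r,) = classify_codon_boundaries(self._genome("ATGAAACCCTAA"))
        assert (r.start_class, r.stop_class) == ("ATN_canonical", "TAN_complete")

    def test_abnormal_start(self):
        (r,) = classify_codon_boundaries(self._genome("GCCAAACCCTAA"))
        assert r.start_class == "abnormal" and r.start_codon == "GCC"

    def test_mito_specific_stops(self):
        (r,) = classify_codon_boundaries(self._genome("ATGAAACCCAGA"))
        assert r.stop_class == "AGA"

    def test_incomplete_stop(self):
        (r,) = classify_codon_boundaries(self._genome("ATGAAACCCT"))
        assert r.stop_class == "incomplete" and r.stop_codon == "T"

    def test_l_strand_cds_read_on_coding_strand(self):
        (r,) = classify_codon_boundaries(self._genome("ATGAAACCCTAA", strand="L"))
        assert r.start_codon == "ATG" and r.stop_codon == "TAA"

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            classify_codon_boundaries(self._genome("ATG"))

    def test_synthetic_genome_boundaries_match_ledger(self, synthetic):
        genome, ledger = synthetic
        reports = {r.gene: r for r in classify_codon_boundaries(genome)}
        for gene, (start, stop) in ledger["pcg_boundaries"].items():
            assert reports[gene].start_codon == start
            assert reports[gene].stop_codon == stop
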