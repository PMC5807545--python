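import dataclasses
import random

import pytest

from mitochar.genemap import (
    compare_gene_order,
    detect_duplicates,
    intergenic_profile,
    strand_summary,
    summarize_gene_map,
)
from mitochar.io import AnnotatedGenome, GeneFeature
from mitochar.simulate import GenomeSpec, default_spec, simulate_genome


def _records(genome):
    return {(r.upstream, r.downstream): r for r in intergenic_profile(genome)}


class TestIntergenicProfile:
    def test_signed_counts_match_published_column(self, moschiola):
        recs = _records(moschiola)
        assert recs[("atp8", "atp6")].intergenic_nt == -37
        assert recs[("trnV", "rrnL")].intergenic_nt == -2
        assert recs[("trnN", "trnC")].intergenic_nt == 32
        assert recs[("nad4l", "nad4")].intergenic_nt == -4
        assert recs[("trnT", "trnP")].intergenic_nt == -1
        assert recs[("trnM", "nad2")].kind == "abutting"

    def test_circular_closure_record(self, moschiola):
        recs = intergenic_profile(moschiola)
        closure = recs[-1]
        assert closure.kind == "circular_closure"
        assert (closure.upstream, closure.downstream) == ("trnF.2", "trnF.1")
        assert closure.intergenic_nt == 42  # 16444-16402 through the origin

    def test_abutting_pair(self):
        feats = [
            GeneFeature("a", "a", "tRNA", "H", 1, 100),
            GeneFeature("b", "b", "tRNA", "H", 101, 200),
        ]
        g = AnnotatedGenome("x", sequence="A" * 200, features=feats)
        rec = intergenic_profile(g)[0]
        assert rec.intergenic_nt == 0 and rec.kind == "abutting"

    def test_order_invariance(self, moschiola):
        shuffled = list(moschiola.features)
        random.Random(3).shuffle(shuffled)
        g = AnnotatedGenome(
            moschiola.accession, features=shuffled,
            declared_length=moschiola.declared_length,
        )
        assert intergenic_profile(g) == intergenic_profile(moschiola)


class TestSummary:
    def test_published_overlap_and_spacer_totals(self, moschiola):
        s = summarize_gene_map(moschiola)
        assert s.overlap_count == 5
        assert s.overlap_total_bp == 47
        assert s.longest_overlap == ("atp8", "atp6", 37)
        assert s.spacer_count == 20
        assert s.spacer_total_bp == 131
        assert s.longest_spacer == ("trnN", "trnC", 32)
        assert s.circular_closure_gap == 42
        assert not s.nested_features

    def test_single_feature_genome(self):
        f = GeneFeature("nad1", "nad1", "PCG", "H", 11, 40)
        g = AnnotatedGenome("x", sequence="A" * 100, features=[f])
        s = summarize_gene_map(g)
        assert s.overlap_count == s.spacer_count == 0
        assert s.circular_closure_gap == 100 - 30

    def test_strand_negation_leaves_totals_unchanged(self, moschiola):
        flipped = [
            dataclasses.replace(f, strand="L" if f.strand == "H" else "H")
            for f in moschiola.features
        ]
        g = AnnotatedGenome(
            moschiola.accession, features=flipped,
            declared_length=moschiola.declared_length,
        )
        a, b = summarize_gene_map(moschiola), summarize_gene_map(g)
        assert (a.overlap_total_bp, a.spacer_total_bp) == (
            b.overlap_total_bp, b.spacer_total_bp
        )

    def test_accounting_identity_on_random_synthetic_genomes(self):
        """Sum of lengths - overlaps + spacers + closure == genome length."""
        rng = random.Random(42)
        base = default_spec(0)
        for rep in range(200):
            order = list(base.gene_order)
            rng.shuffle(order)
            k = len(order)
            overlaps, spacers = [], []
            for (u, *_), (d, *_) in zip(order, order[1:]):
                r = rng.random()
                if r < 0.2:
                    overlaps.append((u, d, rng.randint(1, 20)))
                elif r < 0.5:
                    spacers.append((u, d, rng.randint(1, 40)))
            spec = GenomeSpec(
                gene_order=order,
                planted_overlaps=overlaps,
                planted_spacers=spacers,
                closure_gap=rng.randint(0, 80),
                seed=rep,
            )
            genome, ledger = simulate_genome(spec)
            s = summarize_gene_map(genome)
            total = sum(f.length for f in genome.features)
            assert (
                total - s.overlap_total_bp + s.spacer_total_bp + s.circular_closure_gap
                == genome.length
            )
            assert s.overlap_total_bp == ledger["overlap_total_bp"]
            assert s.spacer_total_bp == ledger["spacer_total_bp"]


class TestStrandSummary:
    def test_published_strand_assignments(self, moschiola):
        cells = strand_summary(moschiola)
        assert set(cells[("tRNA", "L")]) == {
            "trnQ", "trnA", "trnN", "trnC", "trnY", "trnS2", "trnE", "trnP"
        }
        assert cells[("PCG", "L")] == ["nad6"]
        # 14 unique H-strand tRNAs plus the duplicated trnF
        assert len(cells[("tRNA", "H")]) == 15

    def test_all_h_genome_has_no_l_counts(self):
        feats = [GeneFeature("a", "a", "tRNA", "H", 1, 10)]
        g = AnnotatedGenome("x", sequence="A" * 20, features=feats)
        assert ("tRNA", "L") not in strand_summary(g)


class TestDuplicatesAndOrder:
    def test_trnf_duplication_reported(self, moschiola):
        rep = detect_duplicates(moschiola)
        assert len(rep["duplicated"]) == 1
        entry = rep["duplicated"][0]
        assert entry["gene"] == "trnF"
        assert ("trnF.2", 16333, 16402, "H") in entry["positions"]
        assert rep["missing_vs_reference"] == []

    def test_synthetic_duplicate_has_full_identity(self, synthetic):
        genome, ledger = synthetic
        rep = detect_duplicates(genome)
        entry = next(d for d in rep["duplicated"] if d["gene"] == "trnF")
        assert entry["identity"] == 1.0
        assert entry["substitutions"] == 0

    def test_reference_match_is_empty_report(self, synthetic):
        genome, _ = synthetic
        no_dup = AnnotatedGenome(
            "x",
            sequence=genome.sequence,
            features=[f for f in genome.features if f.instance_id != "trnF.2"],
        )
        rep = detect_duplicates(no_dup)
        assert rep["duplicated"] == [] and rep["extra_vs_reference"] == []

    def test_order_self_and_rotation_invariance(self, moschiola):
        assert compare_gene_order(moschiola, moschiola)["shared_order"]
        # rotate: start the feature list at nad1 by shifting coordinates
        feats = sorted(moschiola.features, key=lambda f: f.start)
        pivot = next(f for f in feats if f.name == "nad1")
        shift = pivot.start - 1
        n = moschiola.length
        rotated = []
        for f in feats:
            s = (f.start - 1 - shift) % n + 1
            e = s + f.length - 1
            if e <= n:
                rotated.append(dataclasses.replace(f, start=s, end=e))
            # features that would now span the origin are dropped; order of
            # the remainder is what the comparison sees
        g = AnnotatedGenome("rot", features=rotated, declared_length=n)
        res = compare_gene_order(
            AnnotatedGenome(
                "sub", declared_length=n,
                features=[f for f in moschiola.features
                          if f.name in {x.name for x in rotated}],
            ),
            g,
        )
        assert res["shared_order"]

    def test_swap_creates_breakpoints(self):
        def mk(names):
            feats = [
                GeneFeature(nm, nm, "tRNA", "H", 10 * i + 1, 10 * i + 5)
                for i, nm in enumerate(names)
            ]
            return AnnotatedGenome("x", features=feats, declared_length=100)

        a = mk(["g1", "g2", "g3", "g4", "g5"])
        b = mk(["g1", "g3", "g2", "g4", "g5"])
        res = compare_gene_order(a, b)
        assert not res["shared_order"]
        # brute force: adjacencies of a absent from b's circular adjacency set
        order_a = ["g1", "g2", "g3", "g4", "g5"]
        order_b = ["g1", "g3", "g2", "g4", "g5"]
        adj = lambda o: {(o[i], o[(i + 1) % 5]) for i in range(5)}
        expected = len(adj(order_a) - adj(order_b))
        assert res["n_breakpoints"] == expected == 3
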