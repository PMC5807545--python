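from itertools import permutations, product

import numpy as np
import pytest

from mitochar._codes import sense_codons, stop_codons, translate_codon
from mitochar.selection import (
    CodonAlignment,
    count_sites,
    count_substitutions,
    estimate_kappa,
    jukes_cantor,
    site_stats,
    slac_gene,
)
from mitochar.simulate import EvolSpec, balanced_tree, simulate_codon_alignment


def oracle_sites(codon, kappa=1.0):
    """Independent site counter: per position, kappa-weighted synonymous
    fraction over non-stop single-base changes."""
    stops = stop_codons()
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0.0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in stops:
                continue
            w = kappa if {codon[pos], b} in ({"A", "G"}, {"C", "T"}) else 1.0
            tot += w
            syn += w * (translate_codon(mut) == aa)
        s += syn / tot if tot else 0.0
    return 3.0 - s, s


def oracle_substitutions(a, b):
    """Exhaustive path enumeration with stop-path filtering."""
    stops = stop_codons()
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, steps, clean = a, [], True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in stops:
                clean = False
                steps.append("n")
            elif translate_codon(nxt) == translate_codon(cur):
                steps.append("s")
            else:
                steps.append("n")
            cur = nxt
        paths.append((clean, steps))
    clean_paths = [st for cl, st in paths if cl]
    used = clean_paths or [st for _, st in paths]
    n = sum(st.count("n") for st in used) / len(used)
    s = sum(st.count("s") for st in used) / len(used)
    return n, s


class TestSiteCounting:
    def test_phe_example(self):
        # TTT: only the third position has synonymous changes (TTC); of the
        # three third-position changes, TTA/TTG are Leu -> 1/3 synonymous
        n, s = count_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)

    def test_fourfold_third_position(self):
        n, s = count_sites("GCT")  # Ala: every third-position change synonymous
        assert s == pytest.approx(1.0)

    def test_conservation_and_oracle_agreement(self):
        for codon in sense_codons():
            n, s = count_sites(codon)
            assert n + s == pytest.approx(3.0)
            assert (n, s) == pytest.approx(oracle_sites(codon))

    def test_kappa_weighting_matches_oracle(self):
        for codon in ("TTT", "GCT", "ATA", "TGG"):
            assert count_sites(codon, kappa=2.0) == pytest.approx(
                oracle_sites(codon, kappa=2.0)
            )

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestSubstitutionCounting:
    def test_single_step_examples(self):
        assert count_substitutions("TTT", "TTA") == (1.0, 0.0)  # Phe->Leu
        assert count_substitutions("GCT", "GCC") == (0.0, 1.0)  # Ala 4-fold
        assert count_substitutions("ATG", "ATG") == (0.0, 0.0)

    def test_all_pairs_match_exhaustive_oracle(self):
        codons = sense_codons()
        for a, b in product(codons, repeat=2):
            assert count_substitutions(a, b) == pytest.approx(
                oracle_substitutions(a, b)
            ), (a, b)

    def test_symmetry(self):
        codons = sense_codons()
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b = rng.choice(codons, 2)
            assert count_substitutions(a, b) == pytest.approx(
                count_substitutions(b, a)
            )


class TestSiteStats:
    def test_examples(self):
        assert site_stats(["AAAA", "AAAA"])["variable"] == 0
        st = site_stats(["AC", "AC", "CC", "CC"])
        assert st["variable"] == 1 and st["parsimony_informative"] == 1
        st2 = site_stats(["AA", "AA", "AA", "CA"])
        assert st2["variable"] == 1 and st2["parsimony_informative"] == 0

    def test_gaps_and_ambiguity_ignored(self):
        st = site_stats(["AA-", "AAN", "ACN", "ACN"])
        assert st["variable"] == 1  # only column 2 has two unambiguous states
        assert st["parsimony_informative"] == 1  # A,A,C,C

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            site_stats(["AA", "A"])


class TestSlac:
    def test_identical_sequences_flagged_undefined(self):
        aln = CodonAlignment.from_sequences(
            "g", {"a": "ATGGCC", "b": "ATGGCC", "c": "ATGGCC"}
        )
        r = slac_gene(aln, tree="((a:0.1,b:0.1):0.1,c:0.1);", bootstrap=0)
        assert r.undefined and r.ratio is None
        assert r.N_subs == r.S_subs == 0.0

    def test_jc_correction(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-4)
        with pytest.raises(ValueError):
            jukes_cantor(0.8)

    def test_pairwise_and_tree_methods_agree_on_two_taxa(self):
        aln, _ = simulate_codon_alignment(
            EvolSpec(tree="(a:0.2,b:0.2);", omega=0.3, codon_length=300, seed=4)
        )
        rt = slac_gene(aln, tree="(a:0.2,b:0.2);", kappa=1.0, bootstrap=0)
        rp = slac_gene(aln, method="pairwise_mean", kappa=1.0, bootstrap=0)
        # same counts; only the multiple-hit correction granularity differs
        assert rt.N_subs == pytest.approx(rp.N_subs)
        assert rt.S_subs == pytest.approx(rp.S_subs)
        assert rt.ratio == pytest.approx(rp.ratio, rel=0.1)

    def test_ci_contains_point_estimate(self):
        aln, _ = simulate_codon_alignment(
            EvolSpec(tree=balanced_tree(6), omega=0.4, codon_length=200, seed=9)
        )
        r = slac_gene(aln, tree=balanced_tree(6), bootstrap=200, seed=1)
        lo, hi = r.ci95
        assert lo <= r.ratio <= hi

    def test_bootstrap_seed_reproducible(self):
        aln, _ = simulate_codon_alignment(
            EvolSpec(tree=balanced_tree(5), omega=0.4, codon_length=150, seed=2)
        )
        r1 = slac_gene(aln, tree=balanced_tree(5), bootstrap=100, seed=7)
        r2 = slac_gene(aln, tree=balanced_tree(5), bootstrap=100, seed=7)
        assert r1.ci95 == r2.ci95

    def test_monotone_in_simulated_omega(self):
        """Median estimate strictly increases with the generating omega."""
        tree = balanced_tree(9)
        medians = []
        for omega in (0.1, 0.5, 1.0):
            est = []
            for seed in range(5):
                aln, _ = simulate_codon_alignment(
                    EvolSpec(tree=tree, omega=omega, codon_length=400,
                             seed=100 * seed + int(10 * omega))
                )
                est.append(slac_gene(aln, tree=tree, bootstrap=0).ratio)
            medians.append(float(np.median(est)))
        assert medians[0] < medians[1] < medians[2]

    def test_kappa_estimated_from_fourfold_sites(self):
        aln, _ = simulate_codon_alignment(
            EvolSpec(tree=balanced_tree(9), omega=0.5, kappa=4.0,
                     codon_length=800, seed=3)
        )
        k = estimate_kappa(aln)
        assert 2.0 < k < 8.0
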