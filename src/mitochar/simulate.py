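"""Synthetic inputs with known ground truth for every analysis stage.

``simulate_genome`` lays out a circular vertebrate-style mitogenome from a
GenomeSpec — gene order and lengths, planted overlaps and spacers, a target
A+T content and skews, an optional gene duplication after the control
region, an optional tandem motif inside the control region and an optional
planted palindrome — and returns both the AnnotatedGenome and a ledger
recording every planted quantity, so each analysis operation can be checked
against construction truth.

``simulate_codon_alignment`` evolves codon sequences along a tree under a
Muse–Gaut/Goldman–Yang-style process by exact stochastic (Gillespie)
simulation: single-nucleotide changes with transition bias kappa, a factor
omega on amino-acid-changing moves, stop codons forbidden.  Branch lengths
are in expected substitutions per codon site (rates normalized so the mean
total leaving-rate over sense codons is 1).

``cloverleaf`` builds minimal synthetic tRNA cloverleaf structures with
planted stem mismatches, for exercising the pair-typing report offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from ._codes import VERTEBRATE_GENE_ORDER, revcomp, sense_codons, stop_codons, translate_codon
from .io import AnnotatedGenome, GeneFeature
from .selection import CodonAlignment, _is_transition
from .trna import STEM_ORDER

# Typical vertebrate gene lengths (bp), used by the default spec.
_TYPICAL_LENGTHS = {
    "trnF": 70, "rrnS": 958, "trnV": 66, "rrnL": 1576, "trnL2": 74,
    "nad1": 942, "trnI": 69, "trnQ": 72, "trnM": 69, "nad2": 1029,
    "trnW": 67, "trnA": 68, "trnN": 73, "trnC": 69, "trnY": 67,
    "cox1": 1539, "trnS2": 69, "trnD": 67, "cox2": 681, "trnK": 66,
    "atp8": 198, "atp6": 675, "cox3": 783, "trnG": 69, "nad3": 345,
    "trnR": 68, "nad4l": 294, "nad4": 1368, "trnH": 71, "trnS1": 60,
    "trnL1": 70, "nad5": 1803, "nad6": 519, "trnE": 69, "cob": 1134,
    "trnT": 73, "trnP": 67, "CR": 890,
}


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic circular mitogenome.

    ``gene_order`` is a list of (name, feature_class, strand, length);
    ``planted_overlaps``/``planted_spacers`` give (upstream, downstream, bp)
    for chosen adjacencies (all other adjacencies abut).  The default spec
    emulates a tragulid-like genome: ~16.4 kb, the vertebrate 37-gene order,
    A+T content 0.614, a trnF duplication right after the control region and
    a 26 bp tandem motif planted twice in the CR.
    """

    gene_order: list[tuple[str, str, str, int]] = field(default_factory=list)
    planted_overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    planted_spacers: list[tuple[str, str, int]] = field(default_factory=list)
    closure_gap: int = 42
    at_content: float = 0.614
    at_skew: float = 0.05
    gc_skew: float = -0.30
    duplication: tuple[str, str] | None = None     # (gene, insert_after_gene)
    cr_repeat: tuple[str, int] | None = None        # (motif, tandem copies)
    palindrome: tuple[str, int] | None = None       # (sequence, 1-based position)
    accession: str = "SYNTH0001"
    seed: int = 0


def default_spec(seed: int = 0) -> GenomeSpec:
    order = [(n, c, s, _TYPICAL_LENGTHS[n]) for n, c, s in VERTEBRATE_GENE_ORDER]
    return GenomeSpec(
        gene_order=order,
        planted_overlaps=[
            ("trnV", "rrnL", 2), ("trnI", "trnQ", 3), ("atp8", "atp6", 37),
            ("nad4l", "nad4", 4), ("trnT", "trnP", 1),
        ],
        planted_spacers=[
            ("rrnL", "trnL2", 2), ("trnL2", "nad1", 8), ("nad1", "trnI", 8),
            ("trnQ", "trnM", 2), ("nad2", "trnW", 13), ("trnW", "trnA", 1),
            ("trnN", "trnC", 32), ("trnY", "cox1", 7), ("cox1", "trnS2", 7),
            ("trnS2", "trnD", 6), ("cox2", "trnK", 6), ("trnK", "atp8", 1),
            ("atp6", "cox3", 5), ("cox3", "trnG", 1), ("nad3", "trnR", 2),
            ("nad4", "trnH", 10), ("nad5", "nad6", 7), ("nad6", "trnE", 3),
            ("trnE", "cob", 4), ("cob", "trnT", 6),
        ],
        duplication=("trnF", "CR"),
        cr_repeat=("GTACATATTATTATTTATAGTACATA", 2),
        seed=seed,
    )


def _base_probs(at: float, at_skew: float, gc_skew: float) -> dict[str, float]:
    gc = 1.0 - at
    return {
        "A": at * (1 + at_skew) / 2,
        "T": at * (1 - at_skew) / 2,
        "G": gc * (1 + gc_skew) / 2,
        "C": gc * (1 - gc_skew) / 2,
    }


def _layout(spec: GenomeSpec):
    """Place features sequentially, honouring planted adjacencies."""
    over = {(u, d): bp for u, d, bp in spec.planted_overlaps}
    spac = {(u, d): bp for u, d, bp in spec.planted_spacers}
    order = list(spec.gene_order)
    if spec.duplication:
        gene, after = spec.duplication
        src = next(g for g in order if g[0] == gene)
        idx = next(i for i, g in enumerate(order) if g[0] == after)
        order.insert(idx + 1, src)

    rows = []
    pos = 1
    prev = None
    for name, cls, strand, length in order:
        if prev is not None:
            key = (prev, name)
            nt = spac.get(key, 0) - over.get(key, 0)
            pos = pos + nt
        start, end = pos, pos + length - 1
        if start < 1:
            raise ValueError(f"planted overlap pushes {name} before position 1")
        rows.append((name, cls, strand, start, end))
        pos = end + 1
        prev = name
    length = rows[-1][4] + spec.closure_gap
    if spec.closure_gap < 0:
        raise ValueError("closure_gap must be >= 0")
    return rows, length


def _random_codons(rng, n_codons: int, probs: dict[str, float], table_id: int = 2) -> str:
    """n sense codons sampled base-wise from probs, resampling stops."""
    stops = stop_codons(table_id)
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    p = p / p.sum()
    out = []
    draws = rng.choice(bases, size=3 * n_codons + 30, p=p)
    buf = "".join(draws)
    i = 0
    while len(out) < n_codons:
        if i + 3 > len(buf):
            buf += "".join(rng.choice(bases, size=300, p=p))
        codon = buf[i : i + 3]
        i += 3
        if codon not in stops:
            out.append(codon)
    return "".join(out)


def simulate_genome(spec: GenomeSpec | None = None, seed: int | None = None):
    """Build the genome described by ``spec``; returns (genome, ledger).

    Protein-coding features get an ATG start, a TAA stop and a stop-free
    random-codon body on their coding strand; everything else is sampled
    base-wise from the composition target.  Planted motifs are written last
    and never corrupted by the composition adjustment, which resamples only
    free non-coding positions until the realized A+T content is within 0.01
    of target.
    """
    if spec is None:
        spec = default_spec(seed if seed is not None else 0)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, n = _layout(spec)
    probs = _base_probs(spec.at_content, spec.at_skew, spec.gc_skew)
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    p = p / p.sum()

    seq = rng.choice(bases, size=n, p=p)  # background fill
    protected = np.zeros(n, dtype=bool)

    # PCG bodies (coding strand), written in layout order; overlapping spans
    # are overwritten by the later feature, as in real overlapping genes.
    for name, cls, strand, start, end in rows:
        if cls != "PCG":
            continue
        length = end - start + 1
        if length % 3:
            raise ValueError(f"{name}: PCG length {length} not divisible by 3")
        body = "ATG" + _random_codons(rng, length // 3 - 2, probs) + "TAA"
        if strand == "L":
            body = revcomp(body)
        seq[start - 1 : end] = list(body)

    # duplication: the second copy is an exact copy of the first
    dup_info = None
    if spec.duplication:
        gene, _ = spec.duplication
        copies = [(s, e) for (nm, _, _, s, e) in rows if nm == gene]
        if len(copies) >= 2:
            (s1, e1), (s2, e2) = copies[0], copies[1]
            seq[s2 - 1 : e2] = seq[s1 - 1 : e1]
            protected[s1 - 1 : e1] = protected[s2 - 1 : e2] = True
            dup_info = {"gene": gene, "first": (s1, e1), "second": (s2, e2)}

    # tandem motif inside the CR
    repeat_info = None
    if spec.cr_repeat:
        motif, copies = spec.cr_repeat
        cr = next(((s, e) for (nm, _, _, s, e) in rows if nm == "CR"), None)
        if cr is None:
            raise ValueError("cr_repeat planted but spec has no CR feature")
        s, e = cr
        span = len(motif) * copies
        if span > e - s + 1:
            raise ValueError("cr_repeat longer than the CR")
        offset = s - 1 + (e - s + 1 - span) // 2
        planted = motif * copies
        seq[offset : offset + span] = list(planted)
        protected[offset : offset + span] = True
        repeat_info = {
            "motif": motif, "copies": copies, "start": offset + 1,
            "period": len(motif),
        }

    pal_info = None
    if spec.palindrome:
        pal, pos = spec.palindrome
        seq[pos - 1 : pos - 1 + len(pal)] = list(pal)
        protected[pos - 1 : pos - 1 + len(pal)] = True
        pal_info = {"sequence": pal, "start": pos, "end": pos + len(pal) - 1}

    # composition adjustment on free, non-coding positions only
    pcg_mask = np.zeros(n, dtype=bool)
    for name, cls, strand, start, end in rows:
        if cls == "PCG":
            pcg_mask[start - 1 : end] = True
    free = np.flatnonzero(~protected & ~pcg_mask)
    is_at = np.isin(seq, ["A", "T"])
    for _ in range(200):
        realized = is_at.mean()
        delta = spec.at_content - realized
        if abs(delta) <= 0.005:
            break
        n_flip = max(1, int(abs(delta) * n))
        if delta > 0:  # need more A/T: flip G/C -> A/T among free positions
            cand = free[~is_at[free]]
            pick = rng.choice(cand, size=min(n_flip, len(cand)), replace=False)
            pa = probs["A"] / (probs["A"] + probs["T"])
            seq[pick] = rng.choice(["A", "T"], size=len(pick), p=[pa, 1 - pa])
        else:
            cand = free[is_at[free]]
            pick = rng.choice(cand, size=min(n_flip, len(cand)), replace=False)
            pg = probs["G"] / (probs["G"] + probs["C"])
            seq[pick] = rng.choice(["G", "C"], size=len(pick), p=[pg, 1 - pg])
        is_at = np.isin(seq, ["A", "T"])
    realized = is_at.mean()
    if abs(realized - spec.at_content) > 0.01:
        raise ValueError(
            f"could not reach A+T target {spec.at_content} (got {realized:.3f})"
        )

    from collections import Counter

    counts = Counter(name for name, *_ in rows)
    seen: dict[str, int] = {}
    features = []
    for name, cls, strand, start, end in rows:
        if counts[name] > 1:
            seen[name] = seen.get(name, 0) + 1
            iid = f"{name}.{seen[name]}"
        else:
            iid = name
        features.append(GeneFeature(name, iid, cls, strand, start, end))

    sequence = "".join(seq)
    genome = AnnotatedGenome(
        accession=spec.accession, organism="synthetic", sequence=sequence,
        circular=True, features=features,
    )

    boundaries = {}
    for f in features:
        if f.feature_class == "PCG":
            cds = genome.feature_sequence(f)
            boundaries[f.instance_id] = (cds[:3], cds[-3:])

    ledger = {
        "seed": spec.seed if seed is None else seed,
        "length": n,
        "closure_gap": spec.closure_gap,
        "overlaps": list(spec.planted_overlaps),
        "spacers": list(spec.planted_spacers),
        "overlap_total_bp": sum(bp for *_, bp in spec.planted_overlaps),
        "spacer_total_bp": sum(bp for *_, bp in spec.planted_spacers),
        "at_content": float(realized),
        "duplication": dup_info,
        "cr_repeat": repeat_info,
        "palindrome": pal_info,
        "pcg_boundaries": boundaries,
    }
    return genome, ledger


@dataclass
class EvolSpec:
    """Parameters of one codon-alignment simulation."""

    tree: str                 # newick with branch lengths (subs per codon site)
    omega: float = 0.2        # dN/dS of the generating process
    kappa: float = 2.0        # transition/transversion rate ratio
    codon_length: int = 500
    genetic_code: int = 2
    gene: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def _rate_tables(omega: float, kappa: float, table_id: int = 2):
    """Per-codon neighbor indices and rates, mean-normalized to rate 1."""
    codons = sense_codons(table_id)
    index = {c: i for i, c in enumerate(codons)}
    stops = stop_codons(table_id)
    neighbors, rates, totals = [], [], []
    for codon in codons:
        nb, rt = [], []
        aa = translate_codon(codon, table_id)
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in stops:
                    continue
                r = kappa if _is_transition(codon[pos], b) else 1.0
                if translate_codon(mut, table_id) != aa:
                    r *= omega
                nb.append(index[mut])
                rt.append(r)
        neighbors.append(np.array(nb))
        rates.append(np.array(rt, dtype=float))
        totals.append(float(sum(rt)))
    mu = float(np.mean(totals))
    rates = [r / mu for r in rates]
    totals = [t / mu for t in totals]
    return codons, neighbors, rates, totals


def simulate_codon_alignment(spec: EvolSpec):
    """Evolve codons along the tree; returns (CodonAlignment, ledger).

    Exact stochastic simulation per site per branch: exponential waiting
    times at the codon's total leaving rate, neighbor chosen proportionally
    to its rate.  The ledger records the true omega/kappa and the realized
    counts of synonymous and nonsynonymous events.
    """
    rng = np.random.default_rng(spec.seed)
    tree = TreeNode.read([spec.tree], convert_underscores=False)
    codons, neighbors, rates, totals = _rate_tables(
        spec.omega, spec.kappa, spec.genetic_code
    )
    L = spec.codon_length
    root_state = rng.integers(0, len(codons), size=L)

    events = {"synonymous": 0, "nonsynonymous": 0}
    states = {id(tree): root_state}
    for node in tree.preorder(include_self=False):
        parent = states[id(node.parent)]
        t = float(node.length or 0.0)
        cur = parent.copy()
        if t > 0:
            for site in range(L):
                time = 0.0
                c = int(cur[site])
                while totals[c] > 0:
                    time += rng.exponential(1.0 / totals[c])
                    if time > t:
                        break
                    j = int(rng.choice(neighbors[c], p=rates[c] / rates[c].sum()))
                    if translate_codon(codons[j]) != translate_codon(codons[c]):
                        events["nonsynonymous"] += 1
                    else:
                        events["synonymous"] += 1
                    c = j
                cur[site] = c
        states[id(node)] = cur

    taxa, rows = [], []
    for tip in tree.tips():
        taxa.append(tip.name)
        rows.append([codons[i] for i in states[id(tip)]])
    aln = CodonAlignment(spec.gene, taxa, rows, spec.genetic_code)
    ledger = {
        "omega": spec.omega, "kappa": spec.kappa, "seed": spec.seed,
        "events": events, "tree": spec.tree, "codon_length": L,
    }
    return aln, ledger


def balanced_tree(n_taxa: int = 9, branch: float = 0.05) -> str:
    """A simple caterpillar tree over taxa t1..tn with equal branch lengths."""
    tips = [f"t{i + 1}" for i in range(n_taxa)]
    nwk = tips[0]
    for t in tips[1:]:
        nwk = f"({nwk}:{branch},{t}:{branch})"
    return nwk + ";"


# ---------------------------------------------------------------- cloverleafs

_STEM_SIZES = {"AA": 7, "D": 4, "AC": 5, "TPC": 5}
_CANONICAL_CYCLE = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


def cloverleaf(gene: str, mismatches: list[tuple[str, str]] | None = None):
    """A minimal synthetic cloverleaf with planted stem mismatches.

    ``mismatches`` lists (pair, stem) like ("A-C", "AA"); the pair is written
    5'base-3'base at successive positions of that stem (from the stem's 5'
    end), every other pair staying canonical.  Returns (sequence,
    dot_bracket) in RNA alphabet, parseable by ``trna.parse_structure``.
    """
    mismatches = mismatches or []
    stems = {s: [] for s in STEM_ORDER}
    cycle = 0
    for stem in STEM_ORDER:
        for _ in range(_STEM_SIZES[stem]):
            stems[stem].append(_CANONICAL_CYCLE[cycle % 4])
            cycle += 1
    used = {s: 0 for s in STEM_ORDER}
    for pair, stem in mismatches:
        five, three = pair.upper().replace("T", "U").split("-")
        k = used[stem]
        if k >= _STEM_SIZES[stem]:
            raise ValueError(f"{gene}: too many planted mismatches in stem {stem}")
        stems[stem][k] = (five, three)
        used[stem] += 1

    def helix(stem):
        fives = [p[0] for p in stems[stem]]
        threes = [p[1] for p in reversed(stems[stem])]
        return fives, threes

    aa5, aa3 = helix("AA")
    d5, d3 = helix("D")
    ac5, ac3 = helix("AC")
    tp5, tp3 = helix("TPC")
    loop = lambda k: ["A"] * k

    seq = (
        aa5 + loop(2) + d5 + loop(4) + d3 + loop(1)
        + ac5 + loop(7) + ac3 + loop(4)
        + tp5 + loop(7) + tp3 + aa3 + loop(1)
    )
    db = (
        ["("] * 7 + ["."] * 2 + ["("] * 4 + ["."] * 4 + [")"] * 4 + ["."] * 1
        + ["("] * 5 + ["."] * 7 + [")"] * 5 + ["."] * 4
        + ["("] * 5 + ["."] * 7 + [")"] * 5 + [")"] * 7 + ["."] * 1
    )
    return "".join(seq), "".join(db)


__all__ = [
    "GenomeSpec",
    "EvolSpec",
    "default_spec",
    "simulate_genome",
    "simulate_codon_alignment",
    "balanced_tree",
    "cloverleaf",
]
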