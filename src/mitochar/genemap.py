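"""Gene-organization accounting for circular mitogenomes.

The central quantity is the signed intergenic count between consecutive
features in start order: ``start(downstream) − end(upstream) − 1``.  A
positive value is a spacer, a negative value an overlap, zero means the
features abut.  On a circular genome one extra closure record runs from the
last feature's end through the origin to the first feature's start.

For a circular genome whose adjacency chain contains no nested features,
these quantities satisfy the accounting identity

    Σ feature lengths − overlap_total + spacer_total + closure_gap = genome length

which is asserted as a property test on synthetic genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._codes import VERTEBRATE_GENE_ORDER, revcomp
from .io import AnnotatedGenome, GeneFeature, sort_features


@dataclass(frozen=True)
class AdjacencyRecord:
    upstream: str
    downstream: str
    intergenic_nt: int
    kind: str  # spacer | overlap | abutting | circular_closure


@dataclass
class GeneMapSummary:
    overlap_count: int
    overlap_total_bp: int
    longest_overlap: tuple[str, str, int] | None
    spacer_count: int
    spacer_total_bp: int
    longest_spacer: tuple[str, str, int] | None
    coverage_fraction: dict[str, float]
    coverage_fraction_union: dict[str, float]
    strand_counts: dict[tuple[str, str], int]
    circular_closure_gap: int | None
    nested_features: list[tuple[str, str]] = field(default_factory=list)


def _kind(nt: int) -> str:
    return "spacer" if nt > 0 else ("overlap" if nt < 0 else "abutting")


def _adjacency_chain(genome: AnnotatedGenome):
    """Features in the adjacency chain, with nested features set aside.

    A feature wholly inside its predecessor's span would make the signed
    intergenic count meaningless, so it is excluded from the chain and
    reported separately.
    """
    feats = genome.features
    if feats != sort_features(feats):
        warnings.warn("features were not sorted; sorting by start")
        feats = sort_features(feats)
    chain: list[GeneFeature] = []
    nested: list[tuple[str, str]] = []
    for f in feats:
        if chain and f.end <= chain[-1].end:
            nested.append((f.instance_id, chain[-1].instance_id))
        else:
            chain.append(f)
    return chain, nested


def intergenic_profile(genome: AnnotatedGenome) -> list[AdjacencyRecord]:
    """One AdjacencyRecord per consecutive feature pair, plus the circular closure."""
    chain, _ = _adjacency_chain(genome)
    records = []
    for up, down in zip(chain, chain[1:]):
        nt = down.start - up.end - 1
        records.append(AdjacencyRecord(up.instance_id, down.instance_id, nt, _kind(nt)))
    if genome.circular and chain and genome.length:
        gap = (genome.length - chain[-1].end) + (chain[0].start - 1)
        records.append(
            AdjacencyRecord(chain[-1].instance_id, chain[0].instance_id, gap, "circular_closure")
        )
    return records


def summarize_gene_map(genome: AnnotatedGenome) -> GeneMapSummary:
    """Overlap/spacer totals, per-class coverage and strand counts.

    Coverage is reported two ways: the naive per-class length sum over the
    genome length (the convention in comparative mitogenomics tables, where
    overlapping bases are counted once per feature), and a union-of-intervals
    version for completeness.
    """
    profile = intergenic_profile(genome)
    chain, nested = _adjacency_chain(genome)
    linear = [r for r in profile if r.kind != "circular_closure"]
    overlaps = [r for r in linear if r.intergenic_nt < 0]
    spacers = [r for r in linear if r.intergenic_nt > 0]

    def _longest(records, sign):
        if not records:
            return None
        by_id = {f.instance_id: f for f in genome.features}
        best = max(records, key=lambda r: (sign * r.intergenic_nt, -by_id[r.upstream].start))
        return (best.upstream, best.downstream, abs(best.intergenic_nt))

    n = genome.length
    coverage: dict[str, float] = {}
    coverage_union: dict[str, float] = {}
    if n:
        for cls in {f.feature_class for f in genome.features}:
            members = [f for f in genome.features if f.feature_class == cls]
            coverage[cls] = sum(f.length for f in members) / n
            merged: list[list[int]] = []
            for f in sorted(members, key=lambda f: f.start):
                if merged and f.start <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], f.end)
                else:
                    merged.append([f.start, f.end])
            coverage_union[cls] = sum(e - s + 1 for s, e in merged) / n

    closure = next((r for r in profile if r.kind == "circular_closure"), None)
    return GeneMapSummary(
        overlap_count=len(overlaps),
        overlap_total_bp=sum(-r.intergenic_nt for r in overlaps),
        longest_overlap=_longest(overlaps, -1),
        spacer_count=len(spacers),
        spacer_total_bp=sum(r.intergenic_nt for r in spacers),
        longest_spacer=_longest(spacers, +1),
        coverage_fraction=coverage,
        coverage_fraction_union=coverage_union,
        strand_counts={k: len(v) for k, v in strand_summary(genome).items()},
        circular_closure_gap=closure.intergenic_nt if closure else None,
        nested_features=nested,
    )


def strand_summary(genome: AnnotatedGenome) -> dict[tuple[str, str], list[str]]:
    """Feature instance names per (feature_class, strand) cell."""
    out: dict[tuple[str, str], list[str]] = {}
    for f in genome.features:
        out.setdefault((f.feature_class, f.strand), []).append(f.instance_id)
    return out


def _global_identity(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Needleman-Wunsch identity over the aligned length; returns
    (identity_fraction, n_substitutions, n_gap_columns)."""
    import numpy as np

    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    # traceback
    i, j = n, m
    matches = subs = gaps = cols = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            matches += a[i - 1] == b[j - 1]
            subs += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
        cols += 1
    return matches / cols, subs, gaps


def detect_duplicates(genome: AnnotatedGenome, reference_order=None) -> dict:
    """Report duplicated genes and content differences vs a reference order.

    For each gene with more than one instance the positions are listed and,
    when sequence is available, a global-alignment identity between the copies
    (informational; alignment-parameter dependent).
    """
    if reference_order is None:
        reference_order = [name for name, _, _ in VERTEBRATE_GENE_ORDER]
    by_name: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        by_name.setdefault(f.name, []).append(f)

    duplicates = []
    for name, insts in sorted(by_name.items()):
        if len(insts) > 1:
            entry = {
                "gene": name,
                "positions": [(f.instance_id, f.start, f.end, f.strand) for f in insts],
            }
            if genome.sequence:
                ident, subs, gaps = _global_identity(
                    genome.feature_sequence(insts[0]), genome.feature_sequence(insts[1])
                )
                entry["identity"] = round(ident, 4)
                entry["substitutions"] = subs
                entry["gap_columns"] = gaps
            duplicates.append(entry)

    present = set(by_name)
    ref = set(reference_order)
    return {
        "duplicated": duplicates,
        "missing_vs_reference": sorted(ref - present),
        "extra_vs_reference": sorted(present - ref),
    }


def _order_tokens(genome: AnnotatedGenome) -> list[tuple[str, str]]:
    return [(f.name, f.strand) for f in genome.features]


def compare_gene_order(a: AnnotatedGenome, b: AnnotatedGenome) -> dict:
    """Circular gene-order comparison on (name, strand) tokens.

    Rotation-invariant: genome b is rotated to every possible origin (and the
    duplicate-aware token list compared exactly); the best rotation's
    breakpoints — adjacencies of a that are absent from b — are reported.
    """
    ta, tb = _order_tokens(a), _order_tokens(b)
    if len(ta) != len(tb) or sorted(ta) != sorted(tb):
        same = False
    else:
        same = any(tb[i:] + tb[:i] == ta for i in range(len(tb)))

    def circular_adjacencies(tokens):
        return {(tokens[i], tokens[(i + 1) % len(tokens)]) for i in range(len(tokens))}

    adj_a, adj_b = circular_adjacencies(ta), circular_adjacencies(tb)
    breakpoints = sorted(adj_a - adj_b)
    return {"shared_order": same, "n_breakpoints": len(breakpoints), "breakpoints": breakpoints}


def profile_table(profile: list[AdjacencyRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(r.upstream, r.downstream, r.intergenic_nt, r.kind) for r in profile],
        columns=["upstream", "downstream", "intergenic_nt", "kind"],
    )


__all__ = [
    "AdjacencyRecord",
    "GeneMapSummary",
    "intergenic_profile",
    "summarize_gene_map",
    "strand_summary",
    "detect_duplicates",
    "compare_gene_order",
    "profile_table",
]
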