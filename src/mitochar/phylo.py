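"""Supermatrix construction, neighbor-joining sanity trees and clade checks.

The supermatrix concatenates per-gene alignments in a fixed gene order and
carries a partition table of 1-based inclusive spans that tile the matrix
exactly.  Export formats are relaxed PHYLIP and a RAxML-style partition file
("DNA, nad1 = 1-957"), the inputs external tree-inference programs expect.

The bundled tree builder is plain neighbor joining on Jukes–Cantor-corrected
p-distances — a sanity check, not a substitute for model-based inference.
Clade questions are answered as bipartition queries so no rooting convention
is imposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._codes import PCG_NAMES


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def gene_slice(self, gene: str) -> dict[str, str]:
        for g, s, e in self.partitions:
            if g == gene:
                return {t: self.rows[t][s - 1 : e] for t in self.taxa}
        raise KeyError(gene)


def build_supermatrix(
    alignments: dict[str, dict[str, str]], gene_order: list[str] | None = None
) -> Supermatrix:
    """Concatenate per-gene alignments (gene -> taxon -> aligned sequence).

    Genes are concatenated in ``gene_order`` (default: canonical
    mitochondrial PCG order, then any remaining genes alphabetically).
    Taxa missing from a gene are filled with gaps, with a warning.
    """
    if gene_order is None:
        canon = [g for g in PCG_NAMES if g in alignments]
        rest = sorted(set(alignments) - set(canon))
        gene_order = canon + rest
    taxa: list[str] = []
    for gene in gene_order:
        for t in alignments[gene]:
            if t not in taxa:
                taxa.append(t)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")

    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for gene in gene_order:
        aln = alignments[gene]
        lens = {len(s) for s in aln.values()}
        if len(lens) != 1:
            raise ValueError(f"{gene}: unequal aligned lengths")
        glen = lens.pop()
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t].upper())
            else:
                warnings.warn(f"taxon {t!r} missing from {gene}; gap-filled")
                rows[t].append("-" * glen)
        partitions.append((gene, pos, pos + glen - 1))
        pos += glen
    return Supermatrix(taxa, {t: "".join(parts) for t, parts in rows.items()}, partitions)


def jc_distance_matrix(rows: dict[str, str], cap: float = 5.0) -> DistanceMatrix:
    """Pairwise Jukes–Cantor distances (gap/ambiguity sites excluded pairwise).

    Saturated pairs (p >= 3/4) are capped at ``cap`` with a warning.
    """
    taxa = list(rows)
    k = len(taxa)
    mat = np.zeros((k, k))
    seqs = [rows[t].upper() for t in taxa]
    for i in range(k):
        for j in range(i + 1, k):
            diff = same = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    if a == b:
                        same += 1
                    else:
                        diff += 1
            total = same + diff
            p = diff / total if total else 0.0
            if p >= 0.75:
                warnings.warn(f"saturated distance {taxa[i]}-{taxa[j]}; capped")
                d = cap
            else:
                d = -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=taxa)


def nj_tree(dm_or_matrix, taxa: list[str] | None = None) -> str:
    """Neighbor-joining newick string from a DistanceMatrix or square array."""
    if isinstance(dm_or_matrix, DistanceMatrix):
        dm = dm_or_matrix
    else:
        dm = DistanceMatrix(np.asarray(dm_or_matrix, dtype=float), ids=taxa)
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    tree = nj(dm)
    return str(tree).strip()


def nj_tree_from_supermatrix(sm: Supermatrix) -> str:
    return nj_tree(jc_distance_matrix(sm.rows))


def nj_tree_from_alignment(alignment) -> str:
    """NJ tree from a CodonAlignment (codon rows joined to nucleotides)."""
    rows = {t: "".join(r) for t, r in zip(alignment.taxa, alignment.codons)}
    return nj_tree(jc_distance_matrix(rows))


def check_clade(tree, inner, outer_context) -> bool:
    """Does ``inner`` form a clade within the subtree induced by
    inner + outer_context?  Answered as a bipartition query on the sheared,
    unrooted tree, so the rooting of the input newick is irrelevant.
    """
    t = TreeNode.read([tree], convert_underscores=False) if isinstance(tree, str) else tree
    inner, outer = set(inner), set(outer_context)
    tips = {x.name for x in t.tips()}
    unknown = (inner | outer) - tips
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if inner & outer:
        raise ValueError("inner and outer_context overlap")
    keep = inner | outer
    sub = t.shear(sorted(keep))
    all_tips = frozenset(x.name for x in sub.tips())
    if len(inner) <= 1 or inner == all_tips:
        return True
    target = frozenset(inner)
    for node in sub.non_tips(include_self=True):
        below = frozenset(x.name for x in node.tips())
        if below == target or (all_tips - below) == target:
            return True
    return False


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full-length sequence per line."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_partitions(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for gene, s, e in sm.partitions:
            fh.write(f"DNA, {gene} = {s}-{e}\n")


def read_phylip(path, partitions_path=None) -> Supermatrix:
    lines = [ln for ln in open(path).read().splitlines() if ln.strip()]
    n, length = (int(x) for x in lines[0].split())
    rows = {}
    taxa = []
    for ln in lines[1 : n + 1]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        rows[name] = seq.replace(" ", "")
        if len(rows[name]) != length:
            raise ValueError(f"{name}: sequence length != {length}")
    parts: list[tuple[str, int, int]] = []
    if partitions_path:
        for ln in open(partitions_path):
            if not ln.strip():
                continue
            _, rest = ln.split(",", 1)
            gene, span = rest.split("=")
            s, e = span.strip().split("-")
            parts.append((gene.strip(), int(s), int(e)))
    else:
        parts = [("all", 1, length)]
    return Supermatrix(taxa, rows, parts)


__all__ = [
    "Supermatrix",
    "build_supermatrix",
    "jc_distance_matrix",
    "nj_tree",
    "nj_tree_from_supermatrix",
    "nj_tree_from_alignment",
    "check_clade",
    "write_phylip",
    "write_partitions",
    "read_phylip",
]
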