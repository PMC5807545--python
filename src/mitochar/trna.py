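"""Cloverleaf stem pair-type tabulation for annotated tRNA structures.

Structures arrive as (sequence, dot-bracket) pairs — the output of standard
tRNA annotators — never folded here.  The four helices of a cloverleaf are
labelled, in 5'->3' order of their opening strands: AA (amino-acid acceptor),
D, AC (anticodon) and TPC (the T-pseudouridine-C arm, conventionally TΨC).

Base pairs are classified as canonical (A-U/U-A, G-C/C-G), wobble (G-U/U-G)
or mismatch; mismatches are reported as the ordered pair 5'base-3'base.
T and U are equivalent on input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

STEM_ORDER = ("AA", "D", "AC", "TPC")
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class TRNAStructure:
    gene: str
    sequence: str           # RNA alphabet internally (T converted to U)
    pairing: str            # dot-bracket, same length
    pairs: list[tuple[int, int]] = field(default_factory=list)     # 0-based (5', 3')
    stem_of_pair: list[str] = field(default_factory=list)          # parallel to pairs

    def stem_pairs(self, stem: str):
        return [p for p, s in zip(self.pairs, self.stem_of_pair) if s == stem]


def _pair_list(dot_bracket: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i + 1}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"unsupported character {ch!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into helices: runs of stacked pairs (i+1, j-1) after (i, j)."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:  # pairs sorted by 5' position
        if helices and (helices[-1][-1][0] + 1, helices[-1][-1][1] - 1) == p:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def parse_structure(
    sequence: str,
    dot_bracket: str,
    gene: str = "",
    stem_annotation: list[str] | None = None,
    single_stem: bool = False,
) -> TRNAStructure:
    """Parse one structure and label its stems.

    Without an explicit ``stem_annotation`` (one label per pair, 5'->3'),
    a four-helix structure is labelled AA, D, AC, TPC in 5'->3' order of the
    helices' opening strands.  Anything other than 1 (with ``single_stem``)
    or 4 helices is rejected as not a cloverleaf.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) != len(dot_bracket):
        raise ValueError(f"{gene}: sequence and dot-bracket lengths differ")
    pairs = _pair_list(dot_bracket)
    helices = _helices(pairs)
    if stem_annotation is not None:
        if len(stem_annotation) != len(pairs):
            raise ValueError(f"{gene}: need one stem label per pair")
        labels = list(stem_annotation)
    elif len(helices) == 4:
        labels = []
        for helix, stem in zip(helices, STEM_ORDER):
            labels += [stem] * len(helix)
    elif len(helices) == 1 and single_stem:
        labels = ["AA"] * len(pairs)
    else:
        raise ValueError(
            f"{gene}: {len(helices)} helices — not a cloverleaf (expected 4)"
        )
    return TRNAStructure(gene, seq, dot_bracket, pairs, labels)


def classify_pair(five: str, three: str) -> str:
    b = (five.upper().replace("T", "U"), three.upper().replace("T", "U"))
    if b in _CANONICAL:
        return "canonical"
    if b in _WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass
class PairTypeReport:
    per_gene_stem: dict[tuple[str, str], dict[str, int]]
    mismatch_detail: list[tuple[str, str, str]]  # (gene, 5'base-3'base, stem)


def pair_type_report(structures: list[TRNAStructure]) -> PairTypeReport:
    """Canonical/wobble/mismatch counts per (gene, stem) over a structure set."""
    table: dict[tuple[str, str], dict[str, int]] = {}
    detail: list[tuple[str, str, str]] = []
    for st in structures:
        for (i, j), stem in zip(st.pairs, st.stem_of_pair):
            cls = classify_pair(st.sequence[i], st.sequence[j])
            cell = table.setdefault(
                (st.gene, stem), {"canonical": 0, "wobble": 0, "mismatch": 0}
            )
            cell[cls] += 1
            if cls == "mismatch":
                detail.append((st.gene, f"{st.sequence[i]}-{st.sequence[j]}", stem))
    return PairTypeReport(table, detail)


def aggregate_mismatches(report: PairTypeReport):
    """(total mismatches, number of genes with >=1 mismatch, per-stem totals)."""
    per_stem = Counter()
    genes = set()
    for gene, _, stem in report.mismatch_detail:
        per_stem[stem] += 1
        genes.add(gene)
    total = sum(per_stem.values())
    return total, len(genes), {s: per_stem.get(s, 0) for s in STEM_ORDER}


def read_structures(path) -> list[TRNAStructure]:
    """Load structures from a TSV with columns gene, sequence, pairing
    [, stems] (stems as comma-separated per-pair labels)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        stems = None
        if "stems" in df.columns and isinstance(row.get("stems"), str):
            stems = row["stems"].split(",")
        out.append(parse_structure(row["sequence"], row["pairing"], row["gene"], stems))
    return out


__all__ = [
    "TRNAStructure",
    "PairTypeReport",
    "STEM_ORDER",
    "parse_structure",
    "classify_pair",
    "pair_type_report",
    "aggregate_mismatches",
    "read_structures",
]
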