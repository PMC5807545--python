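"""Base composition, strand skews, codon usage and start/stop classification.

Skew conventions
----------------
AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), the standard
strand-asymmetry statistics of mitogenomics.  A positive AT-skew means
adenine is enriched over thymine on the analysed strand; mammalian
mitochondrial protein-coding regions typically show a mildly positive
AT-skew and a strongly negative GC-skew (anti-G bias).  Zero-denominator
skews are reported as 0.0 with a flag rather than NaN.

Codon statistics use the vertebrate mitochondrial genetic code (AGA/AGG are
stops, ATA codes Met, TGA codes Trp).  RSCU for codon c in a synonymous
family of size k is observed(c) · k / Σ family counts, so a uniformly used
family has RSCU 1 for every member.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._codes import mito_code, revcomp, sense_codons, stop_codons
from .io import AnnotatedGenome

PARTIAL_STOPS = ("T", "TA")  # completed to TAA by polyadenylation


@dataclass
class CompositionSummary:
    region_label: str
    length: int
    A: int
    C: int
    G: int
    T: int
    at_content: float
    at_skew: float
    gc_skew: float
    zero_denominator: bool = False


def _safe_skew(x: int, y: int) -> tuple[float, bool]:
    return ((x - y) / (x + y), False) if x + y else (0.0, True)


def composition_summary(sequence: str, label: str = "") -> CompositionSummary:
    """Counts, A+T content and skews of one sequence (its given strand).

    N (or other ambiguity) bases count toward length but are excluded from
    every denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    c = Counter(seq)
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    acgt = a + t + g + cc
    at_skew, z1 = _safe_skew(a, t)
    gc_skew, z2 = _safe_skew(g, cc)
    return CompositionSummary(
        region_label=label,
        length=len(seq),
        A=a, C=cc, G=g, T=t,
        at_content=(a + t) / acgt if acgt else 0.0,
        at_skew=at_skew,
        gc_skew=gc_skew,
        zero_denominator=z1 or z2,
    )


def skews_from_percentages(t: float, c: float, a: float, g: float) -> tuple[float, float]:
    """AT- and GC-skew directly from printed base percentages (T, C, A, G)."""
    return (a - t) / (a + t), (g - c) / (g + c)


def region_composition(genome: AnnotatedGenome, selector, per_feature: bool = False):
    """Composition of a feature-class or gene-set region.

    The selected features are concatenated on their coding strand (L-strand
    features reverse-complemented) and summarized as one row; with
    ``per_feature`` a row per feature instance is returned instead.
    """
    feats = genome.select(selector)
    if per_feature:
        return [
            composition_summary(genome.feature_sequence(f), f.instance_id) for f in feats
        ]
    concat = "".join(genome.feature_sequence(f) for f in feats)
    label = selector if isinstance(selector, str) else "+".join(sorted({f.name for f in feats}))
    return [composition_summary(concat, label)]


def trim_stop(cds: str) -> str:
    """Drop the trailing stop, complete (length %3 == 0 and a stop codon) or
    partial (T / TA overhang).  Used for codon-level statistics only."""
    rem = len(cds) % 3
    if rem:
        return cds[:-rem] if cds[-rem:] in PARTIAL_STOPS else cds
    return cds[:-3] if cds[-3:] in stop_codons() else cds


def skew_by_codon_position(cds_list: dict[str, str] | list[str]) -> list[CompositionSummary]:
    """Composition at codon positions 1/2/3 pooled over a set of CDS.

    Each CDS must be a whole number of codons after stop trimming; a frame
    violation raises with the offending gene named.
    """
    items = cds_list.items() if isinstance(cds_list, dict) else enumerate(cds_list)
    pos = ["", "", ""]
    for name, cds in items:
        body = trim_stop(cds.upper())
        if len(body) % 3:
            raise ValueError(f"CDS {name!r}: length {len(body)} not a multiple of 3")
        for k in range(3):
            pos[k] += body[k::3]
    return [composition_summary(pos[k], f"codon_position_{k + 1}") for k in range(3)]


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float]
    aa_frequencies: dict[str, float]
    genetic_code: str = "vertebrate_mitochondrial"
    skipped_codons: int = 0
    stop_counts: dict[str, int] = field(default_factory=dict)


def codon_usage(cds_list: dict[str, str] | list[str], table_id: int = 2) -> CodonUsageTable:
    """Codon counts, RSCU and amino-acid frequencies over a CDS set.

    Counts cover every in-frame codon including stops; RSCU and amino-acid
    frequencies are computed over sense codons only.  Codons containing an
    ambiguous base are skipped and tallied.
    """
    table = mito_code(table_id)
    senses = sense_codons(table_id)
    stops = stop_codons(table_id)
    counts: Counter = Counter()
    skipped = 0
    items = cds_list.values() if isinstance(cds_list, dict) else cds_list
    for cds in items:
        s = cds.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1

    families: dict[str, list[str]] = {}
    for codon in senses:
        families.setdefault(table.forward_table[codon], []).append(codon)

    rscu = {c: 0.0 for c in senses}
    for aa, codons in families.items():
        total = sum(counts[c] for c in codons)
        if total:
            k = len(codons)
            for c in codons:
                rscu[c] = counts[c] * k / total

    sense_total = sum(counts[c] for c in senses)
    aa_freq = {
        aa: sum(counts[c] for c in codons) / sense_total if sense_total else 0.0
        for aa, codons in families.items()
    }
    return CodonUsageTable(
        counts={c: counts[c] for c in senses},
        rscu=rscu,
        aa_frequencies=aa_freq,
        skipped_codons=skipped,
        stop_counts={c: counts[c] for c in sorted(stops) if counts[c]},
    )


@dataclass(frozen=True)
class CodonBoundaryReport:
    gene: str
    start_codon: str
    start_class: str  # ATN_canonical | abnormal
    stop_codon: str   # 3-mer, or trailing 1-2 bases when incomplete
    stop_class: str   # TAN_complete | AGA | AGG | incomplete | abnormal


def classify_codon_boundaries(genome: AnnotatedGenome) -> list[CodonBoundaryReport]:
    """Start/stop codon classes of every protein-coding gene.

    Start is the first in-frame codon on the coding strand; ATN counts as
    canonical (covers ATG/ATA initiation in the mitochondrial code).  Stops:
    TAA/TAG are complete (TAN), AGA/AGG are the mitochondria-specific stops,
    a 1-2 nt T/TA overhang is an incomplete stop completed by
    polyadenylation of the transcript.
    """
    reports = []
    for f in genome.select("PCG"):
        cds = genome.feature_sequence(f)
        if len(cds) < 6:
            raise ValueError(f"{f.instance_id}: CDS shorter than 6 nt")
        start = cds[:3]
        start_class = "ATN_canonical" if start.startswith("AT") else "abnormal"
        rem = len(cds) % 3
        if rem:
            stop, stop_class = cds[-rem:], "incomplete"
        else:
            stop = cds[-3:]
            if stop in ("TAA", "TAG"):
                stop_class = "TAN_complete"
            elif stop in ("AGA", "AGG"):
                stop_class = stop
            else:
                stop_class = "abnormal"
        reports.append(CodonBoundaryReport(f.instance_id, start, start_class, stop, stop_class))
    return reports


def summary_table(summaries: list[CompositionSummary]):
    import pandas as pd

    return pd.DataFrame(
        [
            (s.region_label, s.length, s.A, s.C, s.G, s.T,
             round(100 * s.at_content, 1), s.at_skew, s.gc_skew)
            for s in summaries
        ],
        columns=["region", "length", "A", "C", "G", "T", "AT_pct", "AT_skew", "GC_skew"],
    )


__all__ = [
    "CompositionSummary",
    "CodonUsageTable",
    "CodonBoundaryReport",
    "composition_summary",
    "skews_from_percentages",
    "region_composition",
    "skew_by_codon_position",
    "codon_usage",
    "classify_codon_boundaries",
    "trim_stop",
    "summary_table",
]
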