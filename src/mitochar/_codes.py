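"""Shared vocabulary: canonical gene tokens, synonym normalization, and the
vertebrate mitochondrial genetic code.

Canonical tokens follow the lowercase MITOS convention (nad1..nad6, nad4l,
cox1..cox3, atp6, atp8, cob, trnX / trnS1, trnS2, trnL1, trnL2, rrnS, rrnL,
CR for the control region / A+T-rich region).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

PCG_NAMES = (
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
)

TRNA_NAMES = (
    "trnF", "trnV", "trnL1", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS1", "trnS2", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnE", "trnT", "trnP",
)

RRNA_NAMES = ("rrnS", "rrnL")

#: Canonical vertebrate mitochondrial gene order (H-strand 5'->3'), as
#: (name, feature_class, strand) triples.  CR sits between trnP and trnF.
VERTEBRATE_GENE_ORDER = (
    ("trnF", "tRNA", "H"),
    ("rrnS", "rRNA", "H"),
    ("trnV", "tRNA", "H"),
    ("rrnL", "rRNA", "H"),
    ("trnL2", "tRNA", "H"),
    ("nad1", "PCG", "H"),
    ("trnI", "tRNA", "H"),
    ("trnQ", "tRNA", "L"),
    ("trnM", "tRNA", "H"),
    ("nad2", "PCG", "H"),
    ("trnW", "tRNA", "H"),
    ("trnA", "tRNA", "L"),
    ("trnN", "tRNA", "L"),
    ("trnC", "tRNA", "L"),
    ("trnY", "tRNA", "L"),
    ("cox1", "PCG", "H"),
    ("trnS2", "tRNA", "L"),
    ("trnD", "tRNA", "H"),
    ("cox2", "PCG", "H"),
    ("trnK", "tRNA", "H"),
    ("atp8", "PCG", "H"),
    ("atp6", "PCG", "H"),
    ("cox3", "PCG", "H"),
    ("trnG", "tRNA", "H"),
    ("nad3", "PCG", "H"),
    ("trnR", "tRNA", "H"),
    ("nad4l", "PCG", "H"),
    ("nad4", "PCG", "H"),
    ("trnH", "tRNA", "H"),
    ("trnS1", "tRNA", "H"),
    ("trnL1", "tRNA", "H"),
    ("nad5", "PCG", "H"),
    ("nad6", "PCG", "L"),
    ("trnE", "tRNA", "L"),
    ("cob", "PCG", "H"),
    ("trnT", "tRNA", "H"),
    ("trnP", "tRNA", "L"),
    ("CR", "control_region", "H"),
)

# Amino-acid single letters for tRNA names, used when normalizing GenBank
# "tRNA-Phe" style products.
_AA3_TO_TRNA = {
    "PHE": "trnF", "VAL": "trnV", "ILE": "trnI", "GLN": "trnQ", "MET": "trnM",
    "TRP": "trnW", "ALA": "trnA", "ASN": "trnN", "CYS": "trnC", "TYR": "trnY",
    "ASP": "trnD", "LYS": "trnK", "GLY": "trnG", "ARG": "trnR", "HIS": "trnH",
    "GLU": "trnE", "THR": "trnT", "PRO": "trnP",
    # Leu/Ser are ambiguous without the anticodon; resolved in read_genbank.
    "LEU": "trnL", "SER": "trnS",
}

# GenBank dialect -> canonical token.  Keys are upper-cased, stripped of
# spaces/underscores/hyphens before lookup.
GENE_SYNONYMS: dict[str, str] = {
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND4L": "nad4l", "ND5": "nad5", "ND6": "nad6",
    "NAD1": "nad1", "NAD2": "nad2", "NAD3": "nad3", "NAD4": "nad4",
    "NAD4L": "nad4l", "NAD5": "nad5", "NAD6": "nad6",
    "NADH1": "nad1", "NADH2": "nad2", "NADH3": "nad3", "NADH4": "nad4",
    "NADH4L": "nad4l", "NADH5": "nad5", "NADH6": "nad6",
    "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
    "COI": "cox1", "COII": "cox2", "COIII": "cox3",
    "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
    "COXI": "cox1", "COXII": "cox2", "COXIII": "cox3",
    "CYTB": "cob", "COB": "cob", "CYB": "cob",
    "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
    "12SRRNA": "rrnS", "16SRRNA": "rrnL", "12S": "rrnS", "16S": "rrnL",
    "RRNS": "rrnS", "RRNL": "rrnL", "SRRNA": "rrnS", "LRRNA": "rrnL",
    "SSURRNA": "rrnS", "LSURRNA": "rrnL",
    "DLOOP": "CR", "CONTROLREGION": "CR", "CR": "CR", "ATRICHREGION": "CR",
}

CLASS_OF_NAME = {
    **{n: "PCG" for n in PCG_NAMES},
    **{n: "tRNA" for n in TRNA_NAMES},
    **{n: "rRNA" for n in RRNA_NAMES},
    "CR": "control_region",
}


def normalize_gene_name(raw: str) -> str | None:
    """Map a GenBank-style gene/product label to its canonical token.

    Returns None when the label is not recognized.
    """
    key = raw.strip().upper().replace(" ", "").replace("_", "").replace("-", "")
    if key in GENE_SYNONYMS:
        return GENE_SYNONYMS[key]
    low = raw.strip()
    if low in CLASS_OF_NAME:
        return low
    # tRNA-Xxx / trnX(anticodon) style
    up = raw.strip().upper()
    if up.startswith("TRNA") or up.startswith("TRN"):
        tail = up.replace("TRNA", "", 1) if up.startswith("TRNA") else up.replace("TRN", "", 1)
        tail = tail.strip("-_ ()")
        if len(tail) >= 3 and tail[:3] in _AA3_TO_TRNA:
            return _AA3_TO_TRNA[tail[:3]]
        if tail[:2] in ("S1", "S2", "L1", "L2"):
            return "trn" + tail[:2]
        if tail[:1].isalpha() and ("trn" + tail[0]) in TRNA_NAMES:
            return "trn" + tail[0]
        if tail[:1] in ("S", "L"):
            return "trn" + tail[0]  # ambiguous Ser/Leu; caller disambiguates
    return None


COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def mito_code(table_id: int = 2):
    """Vertebrate mitochondrial codon table (Biopython table 2 by default)."""
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 2) -> tuple[str, ...]:
    table = mito_code(table_id)
    return tuple(sorted(table.forward_table))


@lru_cache(maxsize=None)
def stop_codons(table_id: int = 2) -> frozenset[str]:
    return frozenset(mito_code(table_id).stop_codons)


def translate_codon(codon: str, table_id: int = 2) -> str:
    """One-letter amino acid, or '*' for stops; raises KeyError on ambiguity."""
    table = mito_code(table_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]
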