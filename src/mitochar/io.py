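"""Reading and writing annotated mitochondrial genomes and report tables.

Two input routes are supported: GenBank flat files (the usual way an
annotated mitogenome is distributed) and a plain feature-table TSV with
columns ``gene, strand, start, end[, size][, anticodon]`` mirroring the way
such annotations are printed in papers.  Coordinates are 1-based inclusive
throughout, the GenBank convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._codes import CLASS_OF_NAME, normalize_gene_name, revcomp

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

_GENBANK_KEY_CLASS = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "control_region",
}


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region, 1-based inclusive coordinates."""

    name: str
    instance_id: str
    feature_class: str
    strand: str  # 'H' (annotated forward strand) or 'L' (complement)
    start: int
    end: int
    anticodon: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(
                f"feature {self.instance_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("H", "L"):
            raise ValueError(f"feature {self.instance_id}: strand must be H or L")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.instance_id}: unknown class {self.feature_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A circular (by default) mitogenome: sequence plus ordered features.

    ``sequence`` may be empty, in which case coordinate-only analyses remain
    available; ``length`` then falls back to an explicitly provided
    ``declared_length``.
    """

    accession: str
    organism: str = ""
    sequence: str = ""
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    declared_length: int | None = None

    def __post_init__(self):
        self.features = sort_features(self.features)
        n = self.length
        if n:
            for f in self.features:
                if f.end > n:
                    raise ValueError(
                        f"feature {f.instance_id} ({f.start}-{f.end}) extends past "
                        f"genome length {n}; origin-spanning features are not supported"
                    )
        ids = [f.instance_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature instance_ids")

    @property
    def length(self) -> int:
        return len(self.sequence) or (self.declared_length or 0)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Coding-strand sequence of a feature (L features reverse-complemented)."""
        if not self.sequence:
            raise ValueError(f"genome {self.accession} has no sequence")
        sub = self.sequence[feat.start - 1 : feat.end]
        return revcomp(sub) if feat.strand == "L" else sub

    def select(self, selector) -> list[GeneFeature]:
        """Features by class name, gene-name set, or predicate."""
        if callable(selector):
            hits = [f for f in self.features if selector(f)]
        elif isinstance(selector, str):
            hits = [f for f in self.features if f.feature_class == selector]
        else:
            wanted = set(selector)
            hits = [f for f in self.features if f.name in wanted]
        if not hits:
            raise ValueError(f"selector {selector!r} matches no feature")
        return hits

    @property
    def unique_gene_names(self) -> int:
        return len({f.name for f in self.features})

    @property
    def n_feature_instances(self) -> int:
        return len(self.features)


def sort_features(features) -> list[GeneFeature]:
    return sorted(features, key=lambda f: (f.start, f.end, f.name))


def _assign_instance_ids(rows):
    """trnF appearing twice becomes trnF.1 / trnF.2; unique names keep theirs."""
    from collections import Counter

    counts = Counter(name for name, *_ in rows)
    seen: dict[str, int] = {}
    out = []
    for name, cls, strand, start, end, anticodon in rows:
        if counts[name] > 1:
            seen[name] = seen.get(name, 0) + 1
            iid = f"{name}.{seen[name]}"
        else:
            iid = name
        out.append(GeneFeature(name, iid, cls, strand, start, end, anticodon))
    return out


def read_genbank(path) -> AnnotatedGenome:
    """Load an annotated mitogenome from a GenBank flat file.

    Gene labels are normalized to canonical tokens via the bundled synonym
    table (ND1 -> nad1, COI -> cox1, CYTB -> cob, D-loop -> CR, ...).  An
    unrecognized label triggers a warning and the feature class is inferred
    from the GenBank feature key.  Ser/Leu tRNAs without an explicit 1/2 tag
    are disambiguated by anticodon where available.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc

    rows = []
    for feat in record.features:
        if feat.type not in _GENBANK_KEY_CLASS:
            continue
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or [feat.type])[0]
        name = normalize_gene_name(label)
        anticodon = ""
        if "anticodon" in quals:
            ac = quals["anticodon"][0]
            anticodon = ac.split("seq:")[-1].strip("() ").upper().replace("U", "T") if ":" in ac else ac.upper()
        if name in ("trnS", "trnL"):  # disambiguate by anticodon
            if name == "trnS":
                name = "trnS1" if anticodon in ("GCT", "") else "trnS2"
            else:
                name = "trnL1" if anticodon in ("TAG", "") else "trnL2"
        if name is None:
            cls = _GENBANK_KEY_CLASS[feat.type]
            warnings.warn(
                f"{path.name}: unknown feature name {label!r}; "
                f"class inferred from key {feat.type}"
            )
            name = label
        else:
            cls = CLASS_OF_NAME.get(name, _GENBANK_KEY_CLASS[feat.type])
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "L" if feat.location.strand == -1 else "H"
        rows.append((name, cls, strand, start, end, anticodon))

    rows.sort(key=lambda r: (r[3], r[4], r[0]))
    return AnnotatedGenome(
        accession=record.id or path.stem,
        organism=record.annotations.get("organism", ""),
        sequence=str(record.seq).upper(),
        circular=record.annotations.get("topology", "circular") == "circular",
        features=_assign_instance_ids(rows),
    )


def read_feature_table(path, sequence: str | None = None) -> AnnotatedGenome:
    """Load a feature-table TSV (columns gene, strand, start, end[, size][, anticodon]).

    Header comment lines of the form ``#key=value`` may declare ``accession``,
    ``organism``, ``length`` and ``circular``.  A ``size`` column, when present,
    is validated against end − start + 1.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no features")

    header = [c.strip() for c in data_lines[0].split("\t")]
    required = {"gene", "strand", "start", "end"}
    if not required.issubset(header):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {header}")

    rows = []
    for lineno, line in enumerate(data_lines[1:], start=2):
        rec = dict(zip(header, (c.strip() for c in line.split("\t"))))
        name = rec["gene"]
        canonical = normalize_gene_name(name) or name
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if rec.get("size"):
            size = int(rec["size"])
            if size != end - start + 1:
                raise ValueError(
                    f"{path}:{lineno} ({name}): size {size} != end-start+1 = {end - start + 1}"
                )
        cls = CLASS_OF_NAME.get(canonical)
        if cls is None:
            cls = rec.get("class", "control_region")
            warnings.warn(f"{path}:{lineno}: unknown gene {name!r}")
        strand = rec["strand"] if rec["strand"] in ("H", "L") else "H"
        rows.append((canonical, cls, strand, start, end, rec.get("anticodon", "")))

    rows.sort(key=lambda r: (r[3], r[4], r[0]))
    return AnnotatedGenome(
        accession=meta.get("accession", path.stem),
        organism=meta.get("organism", ""),
        sequence=(sequence or "").upper(),
        circular=meta.get("circular", "true").lower() != "false",
        features=_assign_instance_ids(rows),
        declared_length=int(meta["length"]) if "length" in meta else None,
    )


def write_feature_table(genome: AnnotatedGenome, path) -> None:
    path = Path(path)
    lines = [f"#accession={genome.accession}"]
    if genome.organism:
        lines.append(f"#organism={genome.organism}")
    if genome.length:
        lines.append(f"#length={genome.length}")
    lines.append(f"#circular={'true' if genome.circular else 'false'}")
    lines.append("gene\tstrand\tstart\tend\tanticodon")
    for f in genome.features:
        lines.append(f"{f.name}\t{f.strand}\t{f.start}\t{f.end}\t{f.anticodon}")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# Float precision per report kind, matching conventional printing.
_PRECISION = {"skew": 3, "dnds": 4, "default": 4}


def write_reports(results, outdir, name: str, precision: int | None = None) -> dict[str, Path]:
    """Write a stage result as deterministic TSV + JSON under ``outdir``.

    ``results`` may be a DataFrame, a list of dataclasses/dicts, or a plain
    dict; column order is preserved, floats rendered at fixed precision so
    identical inputs give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prec = precision if precision is not None else _PRECISION["default"]

    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, dict):
        df = pd.DataFrame([results])
    else:
        recs = []
        for r in results:
            if hasattr(r, "__dataclass_fields__"):
                recs.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                recs.append(dict(r))
        df = pd.DataFrame(recs)

    tsv = outdir / f"{name}.tsv"
    jsn = outdir / f"{name}.json"
    df.to_csv(tsv, sep="\t", index=False, float_format=f"%.{prec}f")
    jsn.write_text(
        json.dumps(json.loads(df.to_json(orient="records", double_precision=prec)), indent=1)
        + "\n"
    )
    return {"tsv": tsv, "json": jsn}


__all__ = [
    "AnnotatedGenome",
    "GeneFeature",
    "read_genbank",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "write_reports",
    "sort_features",
]
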