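"""Bundled reference data.

* the published gene annotation of the *Moschiola indica* mitogenome
  (GenBank KY290452), transcribed as a coordinate-only feature table;
* the published tRNA stem mismatch profile of the same genome;
* the nine-genome artiodactyl comparison panel (species, family, accession);
* a hand-transcribed newick of the published consensus artiodactyl topology
  (topology only, no branch lengths).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import AnnotatedGenome, read_feature_table


def _data_path(name: str):
    return resources.files("mitochar.data") / name


def moschiola_feature_table() -> AnnotatedGenome:
    """The M. indica (KY290452) annotation as a coordinate-only genome."""
    with resources.as_file(_data_path("moschiola_feature_table.tsv")) as p:
        return read_feature_table(p)


def moschiola_trna_mismatches() -> pd.DataFrame:
    """Published stem mismatches: columns gene, pair, stem, count.

    Stems: AA = amino-acid acceptor, D, AC = anticodon, TPC = T-pseudouridine-C.
    """
    with resources.as_file(_data_path("moschiola_trna_mismatches.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def artiodactyl_panel() -> pd.DataFrame:
    """The nine-genome comparison panel (species, family, accession)."""
    with resources.as_file(_data_path("artiodactyl_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def artiodactyl_topology() -> str:
    """Newick string of the published consensus topology of the panel."""
    with resources.as_file(_data_path("artiodactyl_topology.nwk")) as p:
        return p.read_text().strip()


__all__ = [
    "moschiola_feature_table",
    "moschiola_trna_mismatches",
    "artiodactyl_panel",
    "artiodactyl_topology",
]
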