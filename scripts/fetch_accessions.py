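#!/usr/bin/env python
"""Download the nine-genome comparison panel from NCBI (network required).

Fetches each accession of the bundled panel as a GenBank flat file into
tests/data/accessions/, enabling the accession-dependent test set.  The
core library never requires network access; this helper is optional.

    python scripts/fetch_accessions.py [--email you@example.org]
"""

import argparse
from pathlib import Path

from Bio import Entrez

from mitochar.datasets import artiodactyl_panel

OUTDIR = Path(__file__).resolve().parent.parent / "tests" / "data" / "accessions"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default="anonymous@example.org")
    args = ap.parse_args()

    Entrez.email = args.email
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for acc in artiodactyl_panel()["accession"]:
        dest = OUTDIR / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gb", retmode="text") as h:
            dest.write_text(h.read())
        print(f"{acc}: fetched -> {dest}")


if __name__ == "__main__":
    main()
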