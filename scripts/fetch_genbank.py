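#!/usr/bin/env python
"""Fetch the deposited barcode accessions from GenBank (requires network).

Downloads the 21 matK (KM068846-KM068866) and 21 rbcL (KM068867-KM068887)
sequences as plain FASTA plus the matching sample-to-species map, for use
with ``scripts/validate_published.py``.

Usage:
    python scripts/fetch_genbank.py --outdir data_genbank
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

from barcodekit.data.annona_panel import MATK_ACCESSIONS, RBCL_ACCESSIONS

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# sample codes in deposition order (three genotypes per species)
SAMPLES = [
    ("Che1", "A. cherimola"), ("Che2", "A. cherimola"), ("Che3", "A. cherimola"),
    ("Ret1", "A. reticulata"), ("Ret2", "A. reticulata"), ("Ret3", "A. reticulata"),
    ("Squ1", "A. squamosa"), ("Squ2", "A. squamosa"), ("Squ3", "A. squamosa"),
    ("Mur1", "A. muricata"), ("Mur2", "A. muricata"), ("Mur3", "A. muricata"),
    ("Mac1", "A. macroprophyllata"), ("Mac2", "A. macroprophyllata"),
    ("Mac3", "A. macroprophyllata"),
    ("Gla1", "A. glabra"), ("Gla2", "A. glabra"), ("Gla3", "A. glabra"),
    ("Pur1", "A. purpurea"), ("Pur2", "A. purpurea"), ("Pur3", "A. purpurea"),
]


def fetch(accessions, out_fasta: Path) -> None:
    query = urllib.parse.urlencode({
        "db": "nuccore", "id": ",".join(accessions),
        "rettype": "fasta", "retmode": "text",
    })
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as resp:
        out_fasta.write_bytes(resp.read())
    time.sleep(0.5)  # be polite to the endpoint


def write_species_map(accessions, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\torigin\n")
        for acc, (code, species) in zip(accessions, SAMPLES):
            fh.write(f"{acc}\t{species}\t{code}\n")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("data_genbank"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    fetch(MATK_ACCESSIONS, args.outdir / "matK.fasta")
    write_species_map(MATK_ACCESSIONS, args.outdir / "matK.species.tsv")
    fetch(RBCL_ACCESSIONS, args.outdir / "rbcL.fasta")
    write_species_map(RBCL_ACCESSIONS, args.outdir / "rbcL.species.tsv")
    print(f"wrote matK/rbcL FASTA and species maps under {args.outdir}/")


if __name__ == "__main__":
    main()
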