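#!/usr/bin/env python
"""Validate the pipeline against the deposited barcode sequences.

Given the matK/rbcL FASTA files fetched by ``scripts/fetch_genbank.py``,
this recomputes (a) the per-species minimum/maximum intra- and
interspecific K2P distances and the discrimination counts for both loci,
and (b) the in-silico PCR behaviour of the published primer panel on the
matK templates: per-marker band sizes, the extra cross-binding product of
AChReF1 pooled with AChR1 on A. cherimola, and the multiplex size-
separation checks.

Usage:
    python scripts/validate_published.py --datadir data_genbank
"""

from __future__ import annotations

import argparse
from pathlib import Path

from barcodekit import seqio
from barcodekit.alignment import progressive_msa
from barcodekit.barcode_gap import discrimination_count, gap_analysis
from barcodekit.data.annona_panel import (
    CROSS_BAND_ACH_REF1_ACHR1,
    MULTIPLEX_GROUPS,
    SPECIFIC_PRIMERS,
)
from barcodekit.distances import distance_matrix
from barcodekit.insilico_pcr import predict_amplicons, predict_pool


def locus_report(fasta: Path, species_map: Path, name: str) -> None:
    seqs = seqio.read_fasta(fasta, allow_gaps=False)
    species = seqio.species_lookup(seqio.read_species_map(species_map))
    aln = progressive_msa(seqs, species)
    dm = distance_matrix(aln)
    reports = gap_analysis(dm, species)
    print(f"\n== {name}: per-species K2P distance extrema ==")
    print(f"{'species':22s} {'min_intra':>9s} {'max_intra':>9s} "
          f"{'min_inter':>9s} {'max_inter':>9s}  verdict")
    for r in reports:
        fmt = lambda v: "   NA" if v is None else f"{v:9.3f}"
        print(f"{r.species:22s} {fmt(r.min_intra)} {fmt(r.max_intra)} "
              f"{fmt(r.min_inter)} {fmt(r.max_inter)}  {r.discriminated}")
    print(f"{name} discriminates {discrimination_count(reports)}/{len(reports)} species")


def pcr_report(fasta: Path, species_map: Path) -> None:
    seqs = seqio.read_fasta(fasta, allow_gaps=False)
    species = seqio.species_lookup(seqio.read_species_map(species_map))
    primers = {p.name: p.sequence for p in SPECIFIC_PRIMERS}
    print("\n== published markers on matK templates ==")
    pairs = [(SPECIFIC_PRIMERS[i], SPECIFIC_PRIMERS[i + 1])
             for i in range(0, len(SPECIFIC_PRIMERS), 2)]
    for fwd, rev in pairs:
        bands = {}
        for sid, template in seqs.items():
            amps = predict_amplicons(fwd.sequence, rev.sequence, template, sid)
            if amps:
                bands[species[sid]] = [a.product_length for a in amps]
        print(f"{fwd.name}/{rev.name} (expect {fwd.expected_size} bp on "
              f"{fwd.specificity}): {bands}")
    # cross-binding band: AChReF1 pooled with AChR1 on A. cherimola templates
    che = {sid: t for sid, t in seqs.items()
           if species[sid].endswith("cherimola")}
    for sid, template in che.items():
        lengths = sorted(a.product_length for a in predict_pool(
            {"AChF1": primers["AChF1"], "AChReF1": primers["AChReF1"],
             "AChR1": primers["AChR1"]}, template, sid))
        print(f"pooled AChF1+AChReF1+AChR1 on {sid}: bands {lengths} "
              f"(expect {CROSS_BAND_ACH_REF1_ACHR1} alongside 396)")
    print("\n== multiplex size separation ==")
    for temp, sizes in MULTIPLEX_GROUPS.items():
        seps = [abs(a - b) for i, a in enumerate(sizes) for b in sizes[i + 1:]]
        print(f"{temp} C group {sizes}: min pairwise separation {min(seps)} bp "
              f"({'OK' if min(seps) >= 30 else 'FAIL'} at 30 bp)")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("data_genbank"))
    args = ap.parse_args()
    matk = args.datadir / "matK.fasta"
    rbcl = args.datadir / "rbcL.fasta"
    if not matk.exists():
        raise SystemExit(f"{matk} not found - run scripts/fetch_genbank.py first")
    locus_report(matk, args.datadir / "matK.species.tsv", "matK")
    if rbcl.exists():
        locus_report(rbcl, args.datadir / "rbcL.species.tsv", "rbcL")
    pcr_report(matk, args.datadir / "matK.species.tsv")


if __name__ == "__main__":
    main()
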