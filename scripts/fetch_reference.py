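#!/usr/bin/env python
"""Fetch the public reference genomes used by the optional accession tests.

Downloads into scratch/reference/ (kept out of version control):

* CP097204.1  -- complete chromosome, GenBank flat file with annotation
* GCA_003667225.1 -- K. rhizophila type strain TA68 draft assembly (FASTA)

Usage: python scripts/fetch_reference.py [--outdir scratch/reference]

The test suite skips the accession-based tests when these files are absent,
so running this script is only needed for the network-enabled checks.
"""

from __future__ import annotations

import argparse
import os
import sys
import urllib.request

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
CHROMOSOME = f"{EUTILS}?db=nuccore&id=CP097204.1&rettype=gbwithparts&retmode=text"
TA68_FTP = (
    "https://ftp.ncbi.nlm.nih.gov/genomes/all/GCA/003/667/225/"
    "GCA_003667225.1_ASM366722v1/GCA_003667225.1_ASM366722v1_genomic.fna.gz"
)


def fetch(url: str, dest: str) -> None:
    print(f"fetching {url} -> {dest}", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=120) as resp:
        data = resp.read()
    if dest.endswith(".gz"):
        import gzip

        data = gzip.decompress(data)
        dest = dest[:-3]
    with open(dest, "wb") as fh:
        fh.write(data)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="scratch/reference")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)
    fetch(CHROMOSOME, os.path.join(args.outdir, "CP097204.1.gb"))
    fetch(TA68_FTP, os.path.join(args.outdir, "GCA_003667225.1.fna.gz"))
    print("done", file=sys.stderr)


if __name__ == "__main__":
    main()
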