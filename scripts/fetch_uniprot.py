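#!/usr/bin/env python
"""Fetch the seven bovine milk allergen precursors from UniProt (network
required) and write them as a single FASTA for comparison against the
packaged transcription.

Usage:
    python scripts/fetch_uniprot.py --out milk_proteins_uniprot.fasta
"""

import argparse
import urllib.request

ACCESSIONS = ["P00711", "P02754", "P02769", "P02662", "P02663", "P02666", "P02668"]
URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="milk_proteins_uniprot.fasta")
    args = parser.parse_args()
    chunks = []
    for acc in ACCESSIONS:
        with urllib.request.urlopen(URL.format(acc=acc), timeout=30) as resp:
            chunks.append(resp.read().decode())
        print(f"fetched {acc}")
    with open(args.out, "w") as fh:
        fh.write("".join(chunks))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
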