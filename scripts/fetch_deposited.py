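#!/usr/bin/env python
"""Download the deposited reference inputs used by the acceptance tests.

Requires network access (RCSB PDB and NCBI E-utilities); the library itself
never fetches anything.  Usage:

    python scripts/fetch_deposited.py --out tests/data/deposited
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

PDB_ENTRIES = ("6HIU", "6HIH", "2J3E", "6AMG", "4FAS")
SEQUENCES = ("AAD39218", "AAU93287", "WP_011110663.1")

PDB_URL = "https://files.rcsb.org/download/{}.pdb"
EFETCH_URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
              "?db=protein&id={}&rettype=fasta&retmode=text")


def fetch(url: str, dest: Path) -> None:
    print(f"  {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("tests/data/deposited"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    failures = 0
    for entry in PDB_ENTRIES:
        try:
            fetch(PDB_URL.format(entry), args.out / f"{entry}.pdb")
        except Exception as exc:
            print(f"  FAILED {entry}: {exc}", file=sys.stderr)
            failures += 1
    for acc in SEQUENCES:
        try:
            fetch(EFETCH_URL.format(acc), args.out / f"{acc}.fasta")
        except Exception as exc:
            print(f"  FAILED {acc}: {exc}", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
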