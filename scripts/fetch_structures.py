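"""Fetch the public PDB entries used by the accession-based checks.

Downloads the coordinate files into data/pdb/ so that the optional tests in
tests/test_acceptance.py (accession class) can run. Requires network access;
nothing in the test or acceptance path calls this script.

Usage:
    python scripts/fetch_structures.py [--dest data/pdb]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

#: Calmodulin reference plus the motif-bearing structures analysed here.
PDB_CODES = ["1exr", "2z2x", "2zxq", "3c68", "3km5", "1jv2", "2z8r", "3hx6",
             "2bwr"]

URL = "https://files.rcsb.org/download/{code}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path,
                        default=Path(__file__).resolve().parent.parent
                        / "data" / "pdb")
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for code in PDB_CODES:
        target = args.dest / f"{code}.pdb"
        if target.exists():
            print(f"{code}: already present")
            continue
        print(f"{code}: downloading ...")
        with urllib.request.urlopen(URL.format(code=code.upper())) as resp:
            target.write_bytes(resp.read())
    print(f"done; files in {args.dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
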