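#!/usr/bin/env python
"""Fetch the deposited lbe/lbl GenBank accession sets for regression checks.

This is a network-dependent helper kept outside the main test suite: it
downloads the published Drosophila melanogaster *lbe* (FJ754496-FJ754564) and
*lbl* (FJ754565-FJ754633) sequence sets from GenBank and writes one multi-
FASTA per locus.  The offline test suite only checks that this script exists
and is runnable; the accession regression targets in
``tests/data/accession_targets.json`` are compared only when the fetched data
directory is present.

Usage::

    python scripts/fetch_accessions.py --out data/accessions --email you@site
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

LOCI = {
    "lbe": ("FJ754496", "FJ754564"),
    "lbl": ("FJ754565", "FJ754633"),
}


def accession_range(first: str, last: str) -> list[str]:
    """Expand an inclusive GenBank accession range sharing one prefix."""
    prefix = first.rstrip("0123456789")
    if last.rstrip("0123456789") != prefix:
        raise ValueError(f"mixed prefixes: {first} .. {last}")
    lo = int(first[len(prefix):])
    hi = int(last[len(prefix):])
    width = len(first) - len(prefix)
    return [f"{prefix}{k:0{width}d}" for k in range(lo, hi + 1)]


def fetch_locus(accessions: list[str], email: str, batch: int = 50) -> str:
    """Download the accessions as FASTA text via NCBI Entrez."""
    from Bio import Entrez

    Entrez.email = email
    chunks = []
    for start in range(0, len(accessions), batch):
        ids = ",".join(accessions[start:start + batch])
        with Entrez.efetch(
            db="nuccore", id=ids, rettype="fasta", retmode="text"
        ) as handle:
            chunks.append(handle.read())
        time.sleep(0.4)  # NCBI rate limit
    return "".join(chunks)


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument(
        "--out", default="data/accessions",
        help="output directory (default: data/accessions)",
    )
    parser.add_argument(
        "--email", required=True,
        help="contact email passed to NCBI Entrez (required by NCBI)",
    )
    parser.add_argument(
        "--locus", choices=sorted(LOCI), action="append", default=None,
        help="restrict to one locus (may repeat; default: all)",
    )
    args = parser.parse_args(argv)

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = args.locus or sorted(LOCI)
    for name in loci:
        first, last = LOCI[name]
        accs = accession_range(first, last)
        print(f"fetching {name}: {len(accs)} accessions "
              f"({first} .. {last})", file=sys.stderr)
        text = fetch_locus(accs, args.email)
        path = outdir / f"{name}.fasta"
        path.write_text(text)
        n_records = text.count(">")
        print(f"wrote {path} ({n_records} records)", file=sys.stderr)
        if n_records != len(accs):
            print(
                f"warning: expected {len(accs)} records, got {n_records}",
                file=sys.stderr,
            )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
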