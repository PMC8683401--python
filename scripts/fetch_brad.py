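#!/usr/bin/env python
"""Document and (where network allows) fetch the family protein sequences.

The 29 family members are Brassica rapa BRAD accessions; their protein
sequences are not bundled with the package (size/licensing), so the
sequence-level checks — the consensus key matching every member, PTM site
counts, per-protein property values — need a one-time download.  This script
prints the accession list and, with ``--fasta-out``, attempts to retrieve the
sequences from the BRAD database (http://brassicadb.cn / brassicadb.org).

Entirely optional: the offline test suite and the acceptance script do not
depend on it.
"""

from __future__ import annotations

import argparse
import sys

from famscreen.fixtures import load_table1


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta-out", default=None,
                    help="Write downloaded sequences here (needs network).")
    args = ap.parse_args()
    records = [r for r in load_table1() if r.gene]
    for r in records:
        print(f"{r.gene}\t{r.accession}")
    if args.fasta_out is None:
        return
    try:
        from urllib.request import urlopen
    except Exception as exc:  # pragma: no cover
        sys.exit(f"cannot import urllib: {exc}")
    url = "https://brassicadb.cn/api/sequence/protein?ids=" + ",".join(
        r.accession for r in records
    )
    print(f"fetching {url}", file=sys.stderr)
    try:
        data = urlopen(url, timeout=60).read()
    except Exception as exc:
        sys.exit(
            f"download failed ({exc}); retrieve the accessions manually from "
            "the BRAD database and save them as FASTA"
        )
    with open(args.fasta_out, "wb") as fh:
        fh.write(data)
    print(f"wrote {args.fasta_out}", file=sys.stderr)


if __name__ == "__main__":
    main()
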