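#!/usr/bin/env python
"""Optional external validation of PPR match indices against real data.

The published per-site match indices (printed as k/17) require two inputs
that do not ship with this package: the editing factor's motif annotation
(17 P/L/S motifs with their position-5 and last residues) and the soybean
plastome sequence the sites were called on. Given those, this script
recomputes the match index at each listed editing site:

    python scripts/external_validation.py \
        --protein gmpgl2_motifs.tsv \
        --reference soybean_plastome.fasta \
        --sites sites.tsv \
        [--code-table code.tsv] [--offset -4]

``sites.tsv`` needs columns gene, position, strand. Everything is read from
local files; nothing is fetched remotely.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from plastedit import CodeTable, build_window, extract_code, match_index
from plastedit.errors import PlastEditError
from plastedit.io import read_fasta
from plastedit.ppr import DEFAULT_OFFSET, read_ppr_protein


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--protein", required=True, type=Path,
                        help="PPR motif annotation TSV")
    parser.add_argument("--reference", required=True, type=Path,
                        help="plastome FASTA")
    parser.add_argument("--sites", required=True, type=Path,
                        help="TSV with columns gene, position, strand")
    parser.add_argument("--code-table", type=Path, default=None)
    parser.add_argument("--offset", type=int, default=DEFAULT_OFFSET)
    args = parser.parse_args()

    protein = read_ppr_protein(args.protein)
    reference = read_fasta(args.reference)
    table = (
        CodeTable.from_tsv(args.code_table)
        if args.code_table
        else CodeTable.default()
    )
    code = extract_code(protein)
    sites = pd.read_csv(args.sites, sep="\t", comment="#")

    print("gene\tposition\tstrand\tmatch_index")
    for row in sites.itertuples(index=False):
        try:
            window = build_window(
                int(row.position), str(row.strand), reference,
                len(code), args.offset,
            )
            k, n = match_index(code, window, table)
            print(f"{row.gene}\t{row.position}\t{row.strand}\t{k}/{n}")
        except PlastEditError as exc:
            print(f"{row.gene}\t{row.position}\t{row.strand}\tERROR: {exc}",
                  file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
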