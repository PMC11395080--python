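#!/usr/bin/env python
"""Over-representation analysis of the common DEGs against the gene-set
collection; the spiked set should surface at rank 1."""

import argparse
from pathlib import Path

import pandas as pd

from treghub.enrichment import ora_test, read_gmt, significant_records

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--common", type=Path, default=Path("results/common_degs.tsv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

coll = read_gmt(args.data / "genesets.gmt")
query = set(pd.read_csv(args.common, sep="\t")["gene"])
records = ora_test(query, coll)
records.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
sig = significant_records(records)
print(f"{len(sig)} of {len(records)} sets significant at p < 0.05")
top = records.iloc[0]
print(f"top set: {top.set_id} (k={top.k}/{top.K}, p={top.p_value:.3g})")
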