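#!/usr/bin/env python
"""Direction-consistent intersection of the three DE tables.

The planted design shares a 57-gene core (35 up / 22 down); this step
reports how much of it the strict three-way intersection recovers and writes
the common-DEG log2FC matrix (the overlap heatmap's data) and Venn regions.
"""

import argparse
import json
from pathlib import Path

from treghub import io
from treghub.overlap import DatasetDegs, harmonize_gene_ids, intersect_degs, venn_counts

parser = argparse.ArgumentParser()
parser.add_argument("--de-dir", type=Path, default=Path("results"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

sets = [
    DatasetDegs.from_de_table(f"ds{i}", io.read_de_table(args.de_dir / f"de_ds{i}.tsv"))
    for i in (1, 2, 3)
]
sets = harmonize_gene_ids(sets)
common = intersect_degs(sets)
print(f"common DEGs: {len(common.up)} up / {len(common.down)} down "
      f"(planted core was 35 / 22)")

table = common.lfc_matrix.copy()
table.insert(0, "direction", ["up" if g in common.up else "down" for g in table.index])
table.to_csv(args.out / "common_degs.tsv", sep="\t")
venn = {d: {"+".join(k): v for k, v in venn_counts(sets, d).items()} for d in ("up", "down")}
(args.out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
print("wrote common_degs.tsv and venn.json")
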