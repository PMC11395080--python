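#!/usr/bin/env python
"""Generate every synthetic input for the analysis chain.

Emulates the study's three Treg-vs-non-Treg expression series (case/control
shapes 5/5, 12/6, 6/6) with a planted 57-gene shared DEG core split
35 up / 22 down, a gene-set collection with one spiked set, a planted-hub
protein-interaction graph, and a six-cancer pan-cancer panel whose CCR8 /
checkpoint / TMB / MSI rank correlations are set to the observed BRCA
values.  Everything downstream runs from these files.
"""

import argparse
from pathlib import Path

from treghub import enrichment, io, network, simulate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = simulate.SimConfig(n_genes=2000, frac_de=0.05, lfc_magnitude=2.0,
                         dispersion=0.05, seed=args.seed)
trio = simulate.simulate_dataset_trio(cfg, shared_core=57, shared_up=35)
for i, (cm, truth) in enumerate(trio, start=1):
    io.write_count_matrix(cm, args.out / f"ds{i}_counts.tsv", args.out / f"ds{i}_meta.tsv")
    truth.to_csv(args.out / f"ds{i}_truth.tsv", sep="\t", index=False)
    n_case = (cm.groups == "case").sum()
    n_ctrl = (cm.groups == "control").sum()
    print(f"dataset {i}: {len(cm.genes)} genes, {n_case} Treg vs {n_ctrl} non-Treg samples")

shared = set.intersection(*(set(t.loc[t.is_de, "gene"]) for _, t in trio))
print(f"planted shared DEG core: {len(shared)} genes")

universe = list(trio[0][0].genes)
spiked = sorted(shared)[:20]
coll = simulate.simulate_gene_sets(universe, n_sets=50, set_size_range=(10, 60),
                                   spiked_set=spiked, seed=args.seed + 1)
enrichment.write_gmt(coll, args.out / "genesets.gmt")
print(f"gene sets: {len(coll.sets)} (one spiked with {len(spiked)} core genes)")

hubs = ["IL2RA", "CCR8", "TNFRSF4", "TNFRSF18"]
g = simulate.simulate_ppi(n_nodes=60, attachment_edges=3, hub_labels=hubs,
                          seed=args.seed + 2)
network.write_string_tsv(g, args.out / "ppi_edges.tsv")
print(f"PPI graph: {g.number_of_nodes()} nodes / {g.number_of_edges()} edges, "
      f"planted hubs {hubs}")

pcfg = simulate.PanelConfig(
    n_samples=1000,
    target_rank_corr={"PDCD1": 0.584, "CD274": 0.606, "CTLA4": 0.758},
    tmb_corr={"CCR8": 0.35, "CD274": 0.35, "PDCD1": 0.35},
    msi_corr={"CCR8": 0.25, "CD274": 0.25, "PDCD1": 0.25},
    seed=args.seed + 3,
)
panel = simulate.simulate_pan_cancer_panel(pcfg)
io.write_panel(panel, args.out / "panel.tsv")
print(f"pan-cancer panel: {len(panel)} samples across {panel.cancer_type.nunique()} cancers")
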