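"""Cross-dataset DEG intersection: common up/down gene lists and the
common-gene log2FC matrix behind the overlap heatmap.

Gene identifiers are harmonized first (optional ortholog table, then symbol
case-folding) so that human and mouse series can be intersected; a gene is
"common" only if it passes the DEG filter with the same direction in every
dataset, which is the only rule under which the common up and down totals
stay disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .diffexpr import DegSet, DEThresholds, filter_degs

__all__ = [
    "DatasetDegs",
    "CommonDegs",
    "harmonize_gene_ids",
    "intersect_degs",
    "venn_counts",
    "read_ortholog_map",
]


@dataclass
class DatasetDegs:
    """One dataset's filtered DEG sets with per-gene log2FC and p."""

    dataset_id: str
    deg_set: DegSet
    lfc: dict = field(default_factory=dict)
    pvalue: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = (self.deg_set.up | self.deg_set.down) - set(self.lfc)
        if missing:
            raise ValueError(
                f"dataset {self.dataset_id}: DEGs without an lfc entry: {sorted(missing)[:5]}"
            )

    @classmethod
    def from_de_table(
        cls, dataset_id: str, records: pd.DataFrame, thresholds: DEThresholds | None = None
    ) -> "DatasetDegs":
        degs = filter_degs(records, thresholds)
        return cls(
            dataset_id=dataset_id,
            deg_set=degs,
            lfc=dict(zip(records["gene"], records["log2FoldChange"])),
            pvalue=dict(zip(records["gene"], records["pvalue"])),
        )


@dataclass
class CommonDegs:
    up: set
    down: set
    lfc_matrix: pd.DataFrame  # genes x dataset_ids

    @property
    def genes(self) -> set:
        return self.up | self.down


def read_ortholog_map(path) -> dict:
    """Two-column TSV (source symbol TAB target symbol) -> dict."""
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed ortholog map at line {lineno}: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def harmonize_gene_ids(
    sets: list[DatasetDegs], ortholog_map: dict | None = None
) -> list[DatasetDegs]:
    """Map gene symbols to a canonical form across datasets.

    The ortholog map (if any) is applied first, then symbols are upper-cased.
    When two records of one dataset collide on the canonical symbol the one
    with the smaller p-value is kept.
    """
    ortholog_map = ortholog_map or {}

    def canon(g: str) -> str:
        return ortholog_map.get(g, g).upper()

    out = []
    for ds in sets:
        best: dict[str, tuple[float, str]] = {}
        for g in set(ds.lfc) | ds.deg_set.up | ds.deg_set.down:
            c = canon(g)
            p = ds.pvalue.get(g, 1.0)
            if c not in best or p < best[c][0]:
                best[c] = (p, g)
        keep = {orig for _, orig in best.values()}
        remap = {orig: c for c, (_, orig) in best.items()}
        up = {remap[g] for g in ds.deg_set.up if g in keep}
        down = {remap[g] for g in ds.deg_set.down if g in keep}
        lfc = {remap[g]: v for g, v in ds.lfc.items() if g in keep}
        pv = {remap[g]: v for g, v in ds.pvalue.items() if g in keep}
        out.append(
            DatasetDegs(
                dataset_id=ds.dataset_id,
                deg_set=DegSet(up=up, down=down, thresholds=ds.deg_set.thresholds),
                lfc=lfc,
                pvalue=pv,
            )
        )
    return out


def intersect_degs(sets: list[DatasetDegs]) -> CommonDegs:
    """Direction-consistent intersection of per-dataset DEG sets."""
    if len(sets) < 2:
        raise ValueError("need at least two datasets to intersect")
    up = set.intersection(*(set(ds.deg_set.up) for ds in sets))
    down = set.intersection(*(set(ds.deg_set.down) for ds in sets))
    genes = sorted(up | down)
    mat = pd.DataFrame(
        {ds.dataset_id: [ds.lfc.get(g) for g in genes] for ds in sets},
        index=pd.Index(genes, name="gene"),
    )
    return CommonDegs(up=up, down=down, lfc_matrix=mat)


def venn_counts(sets: list[DatasetDegs], direction: str = "up") -> dict:
    """Exclusive region counts of the Venn partition over the DEG sets.

    Keys are tuples of dataset ids naming the region (datasets the genes
    belong to and no others); counts sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least two datasets")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    members = {ds.dataset_id: getattr(ds.deg_set, direction) for ds in sets}
    ids = [ds.dataset_id for ds in sets]
    union = set().union(*members.values())
    regions = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            regions[tuple(sorted(combo))] = 0
    for g in union:
        signature = tuple(sorted(i for i in ids if g in members[i]))
        regions[signature] += 1
    return regions
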