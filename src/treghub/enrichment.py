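"""Over-representation analysis (ORA) of a query gene list against GMT
gene-set collections.

The statistic is the upper hypergeometric tail P(X >= k) for an overlap of k
query genes with a set of size K in a universe of N genes and a query of n,
identical to a one-sided Fisher exact test on the 2x2 overlap table.
Benjamini-Hochberg adjustment is applied across all sets of a collection and
records significant at p < 0.05 (raw p by default) are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora_test",
    "significant_records",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (set_id -> (description, genes)) over a universe."""

    sets: dict
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in self.sets.values()))
        fixed = {}
        for sid, (desc, genes) in self.sets.items():
            genes = frozenset(genes) & self.universe
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty after universe restriction")
            fixed[sid] = (desc, genes)
        self.sets = fixed


def read_gmt(path, universe: set | None = None) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene ...).

    Duplicate genes within a set are collapsed; the universe defaults to the
    union of all sets unless supplied.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = (desc, frozenset(genes))
    return GeneSetCollection(sets=sets, universe=frozenset(universe or ()))


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in coll.sets.items():
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


def ora_test(query: set, coll: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against every set.

    Query genes outside the universe are dropped (count logged).  Returns a
    DataFrame with columns set_id, description, k, K, n, N, p_value,
    p_adjusted, overlap_genes, sorted by (p_value, set_id).
    """
    from statsmodels.stats.multitest import multipletests

    query = set(query)
    dropped = query - coll.universe
    if dropped:
        logger.info("dropping %d query genes outside the universe", len(dropped))
    query &= coll.universe
    if not query:
        logger.warning("query empty after universe restriction; no enrichment computed")
        return pd.DataFrame(
            columns=["set_id", "description", "k", "K", "n", "N",
                     "p_value", "p_adjusted", "overlap_genes"]
        )
    n = len(query)
    N = len(coll.universe)
    rows = []
    for sid, (desc, genes) in coll.sets.items():
        overlap = query & genes
        k, K = len(overlap), len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append(
            {"set_id": sid, "description": desc, "k": k, "K": K, "n": n, "N": N,
             "p_value": min(p, 1.0), "overlap_genes": ",".join(sorted(overlap))}
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    return df[["set_id", "description", "k", "K", "n", "N",
               "p_value", "p_adjusted", "overlap_genes"]]


def significant_records(
    records: pd.DataFrame, alpha: float = 0.05, on_adjusted: bool = False
) -> pd.DataFrame:
    """Records with p < alpha (strict), ordered ascending by p."""
    col = "p_adjusted" if on_adjusted else "p_value"
    out = records.loc[records[col] < alpha]
    return out.sort_values([col, "set_id"], kind="mergesort").reset_index(drop=True)
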