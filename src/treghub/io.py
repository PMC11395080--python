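"""Plain-file readers/writers for the stage handoff formats.

Everything the pipeline exchanges between stages is a small text file:
counts + metadata TSV, DE tables, common-DEG tables, GMT collections,
STRING-format edge lists, pan-cancer panel TSVs, scorecard TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .diffexpr import CountMatrix

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_de_table",
    "read_de_table",
    "write_panel",
    "read_panel",
    "write_scorecards",
]


def write_count_matrix(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame({"sample": cm.samples, "group": cm.groups.to_numpy()})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_count_matrix(counts_path, meta_path,
                      case_label: str = "case", control_label: str = "control") -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    groups = meta.set_index("sample")["group"]
    mapping = {case_label: "case", control_label: "control"}
    groups = groups.map(lambda g: mapping.get(g, g))
    return CountMatrix(counts=counts, groups=groups)


def write_de_table(records: pd.DataFrame, path) -> None:
    cols = ["gene", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]
    records[cols].to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene", drop=False)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scorecards(cards, tsv_path, json_path=None) -> pd.DataFrame:
    """Scorecards as a Table-5-schema TSV (and optionally JSON)."""
    rows = [c.as_row() for c in cards]
    df = pd.DataFrame(rows)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
    return df
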