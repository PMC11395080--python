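"""End-to-end orchestration: simulate-or-load -> DE x3 -> overlap ->
enrichment -> network -> correlation -> scoring.

Stages communicate only through plain files under the output directory, so
any stage can be re-run standalone from the previous stage's outputs.  A
manifest (parameter echo, seeds, per-stage record counts) is written at the
end; re-running an identical config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import correlation as corr_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import network as net_mod
from . import overlap as ovl_mod
from . import scoring as sco_mod
from . import simulate as sim_mod
from .diffexpr import DEThresholds, run_de

__all__ = ["run", "load_config", "DEFAULT_SOC"]

logger = logging.getLogger(__name__)

#: Default standard-of-care ICI status per evaluated cancer type.
DEFAULT_SOC = {"BRCA": True, "HNSC": True, "COAD": True, "STAD": True,
               "THCA": False, "READ": False}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: dict) -> dict:
    """Execute the enabled stages in flowchart order; return the manifest."""
    outdir = Path(config.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"config": config, "stages": {}}

    def enabled(stage: str) -> bool:
        return bool(config.get(stage, {}).get("enabled", False))

    state: dict = {}
    order = ["simulate", "de", "overlap", "enrich", "network", "correlate", "score"]
    runners = {
        "simulate": _stage_simulate,
        "de": _stage_de,
        "overlap": _stage_overlap,
        "enrich": _stage_enrich,
        "network": _stage_network,
        "correlate": _stage_correlate,
        "score": _stage_score,
    }
    for stage in order:
        if not enabled(stage):
            continue
        params = dict(config.get(stage, {}))
        params.pop("enabled", None)
        logger.info("stage %s starting", stage)
        try:
            counts = runners[stage](params, seed, outdir, state)
        except Exception as exc:  # abort with stage name; keep partials
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {"params": params, "records": counts}
        logger.info("stage %s done: %s", stage, counts)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                     default=str) + "\n")
    return manifest


def _stage_simulate(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    data = outdir / "data"
    data.mkdir(exist_ok=True)
    cfg = sim_mod.SimConfig(
        n_genes=int(params.get("n_genes", 2000)),
        dispersion=float(params.get("dispersion", 0.05)),
        frac_de=float(params.get("frac_de", 0.1)),
        lfc_magnitude=float(params.get("lfc_magnitude", 2.0)),
        seed=seed,
    )
    trio = sim_mod.simulate_dataset_trio(
        cfg,
        shared_core=int(params.get("shared_core", 57)),
        shared_up=params.get("shared_up", 35),
    )
    counts = {}
    state["datasets"] = []
    for i, (cm, truth) in enumerate(trio, start=1):
        cpath, mpath = data / f"ds{i}_counts.tsv", data / f"ds{i}_meta.tsv"
        io_mod.write_count_matrix(cm, cpath, mpath)
        truth.to_csv(data / f"ds{i}_truth.tsv", sep="\t", index=False)
        state["datasets"].append((cpath, mpath))
        counts[f"ds{i}_genes"] = len(cm.genes)

    universe = list(trio[0][0].genes)
    spiked = sorted(trio[0][1].loc[trio[0][1]["is_de"], "gene"])[: int(params.get("spiked_size", 20))]
    coll = sim_mod.simulate_gene_sets(
        universe, n_sets=int(params.get("n_sets", 50)),
        set_size_range=(10, 60), spiked_set=spiked, seed=seed + 1,
    )
    enr_mod.write_gmt(coll, data / "genesets.gmt")
    counts["gene_sets"] = len(coll.sets)

    hub_labels = list(params.get("hub_labels",
                                 ["IL2RA", "CCR8", "TNFRSF4", "TNFRSF18"]))
    g = sim_mod.simulate_ppi(
        n_nodes=int(params.get("ppi_nodes", 60)),
        attachment_edges=int(params.get("attachment_edges", 3)),
        hub_labels=hub_labels, seed=seed + 2,
    )
    net_mod.write_string_tsv(g, data / "ppi_edges.tsv")
    counts["ppi_edges"] = g.number_of_edges()

    pcfg = sim_mod.PanelConfig(
        n_samples=int(params.get("panel_samples", 500)),
        target_rank_corr=params.get(
            "target_rank_corr", {"PDCD1": 0.584, "CD274": 0.606, "CTLA4": 0.758}),
        tmb_corr=params.get("tmb_corr", {"CCR8": 0.35, "CD274": 0.35, "PDCD1": 0.35}),
        msi_corr=params.get("msi_corr", {"CCR8": 0.25, "CD274": 0.25, "PDCD1": 0.25}),
        seed=seed + 3,
    )
    panel = sim_mod.simulate_pan_cancer_panel(pcfg)
    io_mod.write_panel(panel, data / "panel.tsv")
    counts["panel_samples"] = len(panel)
    state["panel_path"] = data / "panel.tsv"
    state["gmt_path"] = data / "genesets.gmt"
    state["ppi_path"] = data / "ppi_edges.tsv"
    return counts


def _stage_de(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    thresholds = DEThresholds(
        lfc_min=float(params.get("lfc_min", 0.5)),
        p_max=float(params.get("p_max", 0.05)),
        use_adjusted=bool(params.get("use_adjusted", False)),
    )
    datasets = state.get("datasets") or [
        (Path(c), Path(m)) for c, m in params.get("datasets", [])
    ]
    if not datasets:
        raise ValueError("no datasets: enable simulate or list counts/meta paths")
    counts = {}
    state["de_tables"] = []
    for i, (cpath, mpath) in enumerate(datasets, start=1):
        cm = io_mod.read_count_matrix(cpath, mpath,
                                      case_label=params.get("case", "case"),
                                      control_label=params.get("control", "control"))
        records, degs = run_de(cm, thresholds)
        out = outdir / f"de_ds{i}.tsv"
        io_mod.write_de_table(records, out)
        state["de_tables"].append(out)
        counts[f"ds{i}_up"] = len(degs.up)
        counts[f"ds{i}_down"] = len(degs.down)
    state["de_thresholds"] = thresholds
    return counts


def _stage_overlap(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    paths = state.get("de_tables") or [Path(p) for p in params.get("de_tables", [])]
    if len(paths) < 2:
        raise ValueError("overlap needs at least two DE tables")
    thresholds = state.get("de_thresholds", DEThresholds())
    sets = [
        ovl_mod.DatasetDegs.from_de_table(f"ds{i}", io_mod.read_de_table(p), thresholds)
        for i, p in enumerate(paths, start=1)
    ]
    ortho = params.get("orthologs")
    sets = ovl_mod.harmonize_gene_ids(
        sets, ovl_mod.read_ortholog_map(ortho) if ortho else None)
    common = ovl_mod.intersect_degs(sets)
    table = common.lfc_matrix.copy()
    table.insert(0, "direction",
                 ["up" if g in common.up else "down" for g in table.index])
    table.to_csv(outdir / "common_degs.tsv", sep="\t")
    venn = {d: {"+".join(k): v for k, v in ovl_mod.venn_counts(sets, d).items()}
            for d in ("up", "down")}
    (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
    state["common"] = common
    return {"common_up": len(common.up), "common_down": len(common.down)}


def _stage_enrich(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    gmt = params.get("gmt") or state.get("gmt_path")
    if gmt is None:
        raise ValueError("no GMT collection: enable simulate or give 'gmt'")
    coll = enr_mod.read_gmt(gmt)
    if "query" in params:
        query = set(Path(params["query"]).read_text().split())
    elif "common" in state:
        query = state["common"].genes
    else:
        raise ValueError("no query gene list: run overlap or give 'query'")
    records = enr_mod.ora_test(query, coll)
    records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    sig = enr_mod.significant_records(records, alpha=float(params.get("alpha", 0.05)),
                                      on_adjusted=bool(params.get("on_adjusted", False)))
    sig.to_csv(outdir / "enrichment_significant.tsv", sep="\t", index=False)
    return {"sets": len(records), "significant": len(sig)}


def _stage_network(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    edges = params.get("edges") or state.get("ppi_path")
    if edges is None:
        raise ValueError("no edge list: enable simulate or give 'edges'")
    g = net_mod.read_string_tsv(edges, min_score=float(params.get("min_score", 400)))
    records = net_mod.centralities(g)
    records.to_csv(outdir / "centralities.tsv", sep="\t", index=False)
    hubs = net_mod.select_hubs(records, k=min(int(params.get("top", 10)), len(records)))
    annotation = params.get("annotation")
    if annotation:
        hubs = net_mod.annotate_filter(
            hubs, set(Path(annotation).read_text().split()))
    (outdir / "hubs.txt").write_text("\n".join(hubs) + "\n")
    state["hubs"] = hubs
    return {"nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
            "hubs": len(hubs)}


def _stage_correlate(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    panel_path = params.get("panel") or state.get("panel_path")
    if panel_path is None:
        raise ValueError("no panel: enable simulate or give 'panel'")
    panel = io_mod.read_panel(panel_path)
    target = params.get("target", "CCR8")
    partners = list(params.get("partners", ["PDCD1", "CD274", "CTLA4"]))
    genes = list(params.get("biomarker_genes", ["CCR8", "CD274", "PDCD1"]))
    cp = corr_mod.checkpoint_correlations(panel, target, partners)
    cp.to_csv(outdir / "checkpoint_correlations.tsv", sep="\t", index=False)
    radar = {}
    for biomarker in ("TMB", "MSI"):
        bm = corr_mod.biomarker_correlations(panel, genes, biomarker)
        bm.to_csv(outdir / f"{biomarker.lower()}_correlations.tsv", sep="\t", index=False)
        radar[biomarker] = {
            ct: {r["x"]: {"rho": r["rho"], "stars": r["stars"]}
                 for _, r in sub.iterrows()}
            for ct, sub in bm.groupby("cancer_type")
        }
        state[f"{biomarker.lower()}_corr"] = bm
    (outdir / "radar.json").write_text(json.dumps(radar, indent=2, sort_keys=True) + "\n")
    state["checkpoint_corr"] = cp
    return {"checkpoint_records": len(cp)}


def _stage_score(params: dict, seed: int, outdir: Path, state: dict) -> dict:
    rubric = sco_mod.ScoringRubric(**params.get("rubric", {}))
    if params.get("components"):
        cards = sco_mod.load_components(params["components"], rubric)
    elif "checkpoint_corr" in state:
        cards = _cards_from_correlations(params, state, rubric)
    else:
        raise ValueError("no components: give 'components' or run correlate")
    ranked = sco_mod.rank_indications(cards)
    io_mod.write_scorecards(ranked, outdir / "scorecards.tsv", outdir / "scorecards.json")
    return {"cards": len(ranked), "top": ranked[0].cancer_type,
            "top_score": ranked[0].final}


def _cards_from_correlations(params: dict, state: dict, rubric) -> list:
    cp = state["checkpoint_corr"]
    soc_map = {**DEFAULT_SOC, **params.get("soc", {})}
    treg_map = params.get("treg_rho", {})
    cards = []
    for ct, sub in cp.groupby("cancer_type"):
        pvals = dict(zip(sub["y"], sub["p_value"]))
        tmb = state["tmb_corr"]
        msi = state["msi_corr"]
        tmb_rhos = dict(zip(tmb.loc[tmb["cancer_type"] == ct, "x"],
                            tmb.loc[tmb["cancer_type"] == ct, "rho"]))
        msi_rhos = dict(zip(msi.loc[msi["cancer_type"] == ct, "x"],
                            msi.loc[msi["cancer_type"] == ct, "rho"]))
        cards.append(sco_mod.aggregate(
            ct,
            checkpoint_pvalues=pvals,
            treg_rho=float(treg_map.get(ct, 0.0)),
            tmb_rhos=tmb_rhos,
            msi_rhos=msi_rhos,
            soc=bool(soc_map.get(ct, False)),
            rubric=rubric,
        ))
    return cards
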