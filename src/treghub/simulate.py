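"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline is exercisable without any external download:

* count matrices: negative-binomial counts (Var = mu + alpha * mu^2) with
  log-uniform per-sample size factors and a planted fraction of true DEGs at a
  fixed |log2FC|, in the three case/control shapes of the source microarray
  trio (5/5, 12/6, 6/6);
* a dataset trio whose truth tables share an exactly controlled DEG core;
* gene-set collections with one spiked set for the enrichment stage;
* protein-interaction graphs grown by preferential attachment with planted
  high-degree hubs, exportable as STRING-format TSV;
* pan-cancer panels drawn from a Gaussian copula with requested Spearman
  correlations between a target gene, partner genes, TMB and MSI.

All generators take explicit seeds; identical config + seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import CountMatrix

__all__ = [
    "SimConfig",
    "PanelConfig",
    "simulate_counts",
    "simulate_dataset_trio",
    "simulate_gene_sets",
    "simulate_ppi",
    "simulate_pan_cancer_panel",
    "TRIO_GROUP_SIZES",
]

#: Case/control shapes of the three emulated expression series.
TRIO_GROUP_SIZES = ((5, 5), (12, 6), (6, 6))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the NB count generator.

    mean_log_expression is the natural-log mean of the log-normal baseline
    gene means (log(100) by default, i.e. typical genes around 100 counts);
    dispersion is the NB alpha in Var = mu + alpha * mu^2.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int] = (6, 6)
    mean_log_expression: float = math.log(100.0)
    sd_log_expression: float = 1.0
    dispersion: float = 0.05
    frac_de: float = 0.1
    lfc_magnitude: float = 2.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or self.n_genes <= 0:
            raise ValueError("n_genes must be a positive integer")
        if len(self.group_sizes) != 2 or any(
            (not isinstance(g, (int, np.integer)) or g < 2) for g in self.group_sizes
        ):
            raise ValueError("group_sizes must be a pair of integers >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be positive")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("size_factor_range must be positive with lo <= hi")
        if self.sd_log_expression < 0:
            raise ValueError("sd_log_expression must be nonnegative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu=mean, Var=mean+alpha*mean^2) via the gamma-Poisson mixture."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _gene_labels(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _counts_from_truth(
    rng: np.random.Generator,
    cfg: SimConfig,
    genes: list[str],
    true_log2fc: np.ndarray,
    sample_prefix: str = "",
) -> CountMatrix:
    n_case, n_ctrl = cfg.group_sizes
    samples = [f"{sample_prefix}case_{i+1}" for i in range(n_case)] + [
        f"{sample_prefix}ctrl_{i+1}" for i in range(n_ctrl)
    ]
    x = np.array([1.0] * n_case + [0.0] * n_ctrl)
    mu = np.exp(rng.normal(cfg.mean_log_expression, cfg.sd_log_expression, size=len(genes)))
    lo, hi = cfg.size_factor_range
    s = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(samples)))
    mean = s[None, :] * mu[:, None] * np.power(2.0, x[None, :] * true_log2fc[:, None])
    counts = _nb_draw(rng, mean, cfg.dispersion)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    return CountMatrix(counts=df, groups=groups)


def _truth_frame(genes: list[str], true_log2fc: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene": genes, "is_de": true_log2fc != 0.0, "true_log2fc": true_log2fc}
    ).set_index("gene", drop=False)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one NB count matrix and its truth table.

    Exactly ``round(frac_de * n_genes)`` genes are planted at
    |log2FC| = lfc_magnitude (random signs); everything else has log2FC 0.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_labels(cfg.n_genes)
    true_lfc = np.zeros(cfg.n_genes)
    if cfg.n_de > 0:
        de_idx = rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_de)
        true_lfc[de_idx] = signs * cfg.lfc_magnitude
    cm = _counts_from_truth(rng, cfg, genes, true_lfc)
    return cm, _truth_frame(genes, true_lfc)


def simulate_dataset_trio(
    cfg: SimConfig,
    shared_core: int,
    shared_up: int | None = None,
    group_sizes: tuple[tuple[int, int], ...] = TRIO_GROUP_SIZES,
) -> list[tuple[CountMatrix, pd.DataFrame]]:
    """Three datasets whose truth tables share exactly ``shared_core`` DEGs.

    The shared core has identical signs in every dataset (``shared_up`` of
    them up, the rest down; random split if None); each dataset's remaining
    planted DEGs are private to it (disjoint across datasets), so the
    intersection of the three truth tables is exactly the shared core.
    """
    n_de = cfg.n_de
    if shared_core < 0 or shared_core > n_de:
        raise ValueError(
            f"shared_core ({shared_core}) must lie in [0, planted DEG count {n_de}]"
        )
    n_private = n_de - shared_core
    need = shared_core + 3 * n_private
    if need > cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for a shared core of {shared_core} "
            f"plus 3 x {n_private} private DEGs"
        )
    if shared_up is None:
        shared_up = int(np.random.default_rng(cfg.seed).binomial(shared_core, 0.5))
    if not 0 <= shared_up <= shared_core:
        raise ValueError("shared_up must lie in [0, shared_core]")

    ss = np.random.SeedSequence(cfg.seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    genes = _gene_labels(cfg.n_genes)
    perm = layout_rng.permutation(cfg.n_genes)
    core_idx = perm[:shared_core]
    core_signs = np.array([1.0] * shared_up + [-1.0] * (shared_core - shared_up))
    private_blocks = [
        perm[shared_core + d * n_private : shared_core + (d + 1) * n_private]
        for d in range(3)
    ]

    out = []
    child_seeds = ss.spawn(4)[1:]
    for d, (gs, child) in enumerate(zip(group_sizes, child_seeds)):
        rng = np.random.default_rng(child)
        true_lfc = np.zeros(cfg.n_genes)
        true_lfc[core_idx] = core_signs * cfg.lfc_magnitude
        if n_private:
            priv_signs = rng.choice([-1.0, 1.0], size=n_private)
            true_lfc[private_blocks[d]] = priv_signs * cfg.lfc_magnitude
        dcfg = SimConfig(
            n_genes=cfg.n_genes,
            group_sizes=tuple(gs),
            mean_log_expression=cfg.mean_log_expression,
            sd_log_expression=cfg.sd_log_expression,
            dispersion=cfg.dispersion,
            frac_de=cfg.frac_de,
            lfc_magnitude=cfg.lfc_magnitude,
            size_factor_range=cfg.size_factor_range,
            seed=cfg.seed,
        )
        cm = _counts_from_truth(rng, dcfg, genes, true_lfc, sample_prefix=f"ds{d+1}_")
        out.append((cm, _truth_frame(genes, true_lfc)))
    return out


def simulate_gene_sets(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    spiked_set: list[str],
    seed: int,
):
    """Gene-set collection whose first set equals ``spiked_set`` exactly.

    The remaining ``n_sets - 1`` sets are uniform draws (without replacement)
    from the universe with sizes uniform in ``set_size_range``.
    Returns an :class:`~treghub.enrichment.GeneSetCollection`.
    """
    from .enrichment import GeneSetCollection

    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    outside = [g for g in spiked_set if g not in uset]
    if outside:
        raise ValueError(f"spiked genes outside the universe: {outside[:5]}")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi <= |universe|")
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, frozenset]] = {
        "SPIKED": ("planted enriched set", frozenset(spiked_set))
    }
    for i in range(1, n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i:04d}"] = ("random set", frozenset(members.tolist()))
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def simulate_ppi(
    n_nodes: int,
    attachment_edges: int,
    hub_labels: list[str],
    seed: int,
) -> nx.Graph:
    """Preferential-attachment PPI graph with planted hubs.

    The graph is grown from a seed core whose earliest positions are the
    ``hub_labels``: every hub is connected to every other core node, so
    planted hubs start with the highest degrees and preferential attachment
    amplifies the head start.  Each subsequent node attaches
    ``attachment_edges`` edges to existing nodes with probability
    proportional to degree.  Edges carry a ``combined_score`` in [400, 1000].
    """
    h = len(hub_labels)
    if h < 1:
        raise ValueError("at least one hub label is required")
    if n_nodes <= h:
        raise ValueError("n_nodes must exceed the number of hub labels")
    if attachment_edges >= n_nodes:
        raise ValueError("attachment_edges must be smaller than n_nodes")
    if attachment_edges < 1:
        raise ValueError("attachment_edges must be >= 1")
    rng = np.random.default_rng(seed)
    m = attachment_edges
    core_size = min(max(3 * m + 1, h + 1), n_nodes)
    labels = list(hub_labels) + [f"GENE{i:04d}" for i in range(1, n_nodes - h + 1)]

    g = nx.Graph()
    g.add_nodes_from(range(core_size))
    # every hub connected to every other core node (hubs are multi-centers)
    for i in range(min(h, core_size)):
        for j in range(core_size):
            if i != j:
                g.add_edge(i, j)

    repeated = [n for e in g.edges for n in e]
    for new in range(core_size, n_nodes):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(int(repeated[rng.integers(len(repeated))]))
        for t in targets:
            g.add_edge(new, t)
            repeated.extend([new, t])

    g = nx.relabel_nodes(g, {i: labels[i] for i in range(n_nodes)})
    scores = rng.integers(400, 1001, size=g.number_of_edges())
    for (u, v), sc in zip(g.edges, scores):
        g.edges[u, v]["combined_score"] = int(sc)
    return g


@dataclass(frozen=True)
class PanelConfig:
    """Pan-cancer panel generator settings.

    Requested correlations are Spearman setpoints; unspecified pairs default
    to a single-factor fill (product of each variable's correlation with the
    target gene), which keeps typical structures positive definite.
    """

    cancer_types: tuple[str, ...] = ("BRCA", "HNSC", "COAD", "STAD", "THCA", "READ")
    n_samples: int = 500
    target_gene: str = "CCR8"
    partner_genes: tuple[str, ...] = ("PDCD1", "CD274", "CTLA4")
    target_rank_corr: dict = field(default_factory=dict)
    tmb_corr: dict = field(default_factory=dict)
    msi_corr: dict = field(default_factory=dict)
    tmb_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        for name, mapping in (
            ("target_rank_corr", self.target_rank_corr),
            ("tmb_corr", self.tmb_corr),
            ("msi_corr", self.msi_corr),
        ):
            for k, v in mapping.items():
                if not -1.0 < v < 1.0:
                    raise ValueError(f"{name}[{k}] = {v} must lie in (-1, 1)")

    @property
    def variables(self) -> list[str]:
        return [self.target_gene, *self.partner_genes, "TMB", "MSI"]


def _spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Latent Gaussian correlation producing a given Spearman correlation."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def build_copula_correlation(cfg: PanelConfig) -> pd.DataFrame:
    """Assemble the latent correlation matrix from the requested setpoints."""
    variables = cfg.variables
    t = cfg.target_gene
    requested: dict[tuple[str, str], float] = {}

    def put(a: str, b: str, v: float) -> None:
        requested[(a, b)] = v
        requested[(b, a)] = v

    for gene, rho in cfg.target_rank_corr.items():
        if gene not in variables:
            raise ValueError(f"target_rank_corr names unknown gene {gene!r}")
        put(t, gene, rho)
    for gene, rho in cfg.tmb_corr.items():
        put(gene, "TMB", rho)
    for gene, rho in cfg.msi_corr.items():
        put(gene, "MSI", rho)

    k = len(variables)
    rho_s = np.eye(k)
    with_target = {v: requested.get((t, v), 0.0) for v in variables}
    with_target[t] = 1.0
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if i >= j:
                continue
            if (a, b) in requested:
                val = requested[(a, b)]
            else:
                val = with_target[a] * with_target[b]  # single-factor fill
            rho_s[i, j] = rho_s[j, i] = val
    r = _spearman_to_pearson(rho_s)
    np.fill_diagonal(r, 1.0)
    eig = np.linalg.eigvalsh(r)
    if eig.min() <= 1e-10:
        clipped = _nearest_pd(r)
        raise ValueError(
            "requested correlation structure is not positive definite "
            f"(min eigenvalue {eig.min():.3g}); nearest feasible matrix:\n"
            f"{pd.DataFrame(clipped, index=variables, columns=variables).round(3)}"
        )
    return pd.DataFrame(r, index=variables, columns=variables)


def _nearest_pd(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    w = np.maximum(w, floor)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def simulate_pan_cancer_panel(cfg: PanelConfig) -> pd.DataFrame:
    """Draw a per-cancer panel from the Gaussian copula.

    Marginals: expression on the log scale (Gaussian, gene-specific
    baseline), TMB as Poisson counts, MSI as a logit-normal score in (0, 1).
    Columns: sample, cancer_type, TMB, MSI, then one column per gene.
    """
    r = build_copula_correlation(cfg).to_numpy()
    variables = cfg.variables
    genes = [v for v in variables if v not in ("TMB", "MSI")]
    chol = np.linalg.cholesky(r)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.cancer_types))
    frames = []
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    gene_baseline = {g: 4.0 + base_rng.uniform(-1.0, 3.0) for g in genes}
    for ct, child in zip(cfg.cancer_types, children):
        rng = np.random.default_rng(child)
        z = rng.standard_normal((cfg.n_samples, len(variables))) @ chol.T
        cols: dict[str, np.ndarray] = {}
        for j, var in enumerate(variables):
            zj = z[:, j]
            if var == "TMB":
                u = stats.norm.cdf(zj)
                cols["TMB"] = stats.poisson.ppf(np.clip(u, 1e-12, 1 - 1e-12), cfg.tmb_rate)
            elif var == "MSI":
                cols["MSI"] = 1.0 / (1.0 + np.exp(-zj))
            else:
                cols[var] = gene_baseline[var] + 1.5 * zj  # log-scale expression
        df = pd.DataFrame(cols)
        df.insert(0, "cancer_type", ct)
        df.insert(0, "sample", [f"{ct}_{i+1:04d}" for i in range(cfg.n_samples)])
        frames.append(df)
    panel = pd.concat(frames, ignore_index=True)
    ordered = ["sample", "cancer_type", "TMB", "MSI", *genes]
    return panel[ordered]
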