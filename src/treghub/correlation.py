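"""Per-cancer Spearman correlation of a target gene with checkpoint partners
and with the TMB/MSI immunotherapy biomarkers.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties); the p-value uses the t approximation t = rho * sqrt((n-2)/(1-rho^2))
on n-2 degrees of freedom, two-sided, the convention of the pan-cancer web
platforms whose outputs these statistics mirror.  Radar-plot significance
stars follow p < 0.05 ("*") and p < 0.01 ("**").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman",
    "stars",
    "checkpoint_correlations",
    "biomarker_correlations",
]


def spearman(x, y, covariate=None) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value.

    Zero-variance input raises (an undefined correlation is never reported
    as 0).  ``covariate`` optionally computes a rank-based partial
    correlation (e.g. tumor purity); default is the plain statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} has zero variance; Spearman correlation undefined")
    if covariate is not None:
        # rank-based partial correlation: regress the covariate's ranks out
        # of both rank vectors, then correlate the residuals (t p, n-3 df)
        z = stats.rankdata(np.asarray(covariate, dtype=float))
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        zc = np.column_stack([np.ones(n), z])
        res_x = rx - zc @ np.linalg.lstsq(zc, rx, rcond=None)[0]
        res_y = ry - zc @ np.linalg.lstsq(zc, ry, rcond=None)[0]
        rho = float(np.corrcoef(res_x, res_y)[0, 1])
        if abs(rho) >= 1.0:
            return float(np.sign(rho)), 0.0
        t = rho * np.sqrt((n - 3) / (1.0 - rho**2))
        return rho, float(2.0 * stats.t.sf(abs(t), n - 3))
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:  # perfectly monotone (up to rank round-off)
        return float(np.sign(rho)), 0.0
    return rho, float(p)


def stars(p: float) -> str:
    """Radar-plot significance convention: '**' p<0.01, '*' p<0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _require_columns(panel: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing column(s): {missing}")


def checkpoint_correlations(
    panel: pd.DataFrame, target: str, partners: list[str]
) -> pd.DataFrame:
    """Per-cancer Spearman of target-gene expression vs each partner gene.

    ``panel`` columns: sample, cancer_type, TMB, MSI, one column per gene.
    Returns cancer_type, x, y, rho, p_value, n (one row per cancer/partner).
    """
    _require_columns(panel, ["cancer_type", target, *partners])
    rows = []
    for ct, sub in panel.groupby("cancer_type", sort=True):
        if len(sub) < 3:
            continue
        for partner in partners:
            rho, p = spearman(sub[target], sub[partner])
            rows.append(
                {"cancer_type": ct, "x": target, "y": partner,
                 "rho": rho, "p_value": p, "n": len(sub)}
            )
    return pd.DataFrame(rows)


def biomarker_correlations(
    panel: pd.DataFrame, genes: list[str], biomarker: str
) -> pd.DataFrame:
    """Per-cancer Spearman of gene expression vs TMB or MSI, with stars."""
    if biomarker not in ("TMB", "MSI"):
        raise ValueError("biomarker must be 'TMB' or 'MSI'")
    _require_columns(panel, ["cancer_type", biomarker, *genes])
    rows = []
    for ct, sub in panel.groupby("cancer_type", sort=True):
        if len(sub) < 3:
            continue
        for gene in genes:
            rho, p = spearman(sub[gene], sub[biomarker])
            rows.append(
                {"cancer_type": ct, "x": gene, "y": biomarker,
                 "rho": rho, "p_value": p, "n": len(sub), "stars": stars(p)}
            )
    return pd.DataFrame(rows)
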