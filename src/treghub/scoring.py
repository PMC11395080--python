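"""Integrated indication scoring for CCR8 + immune-checkpoint-inhibitor
combination therapy.

Each candidate cancer type receives component scores on a 0-3 bin rubric:

* checkpoint correlation (one score per checkpoint gene PDCD1/CD274/CTLA4,
  binned from the CCR8-correlation p-value):
  p < 1e-50 -> 3;  1e-50 <= p < 1e-30 -> 2;  1e-30 <= p < 1e-10 -> 1; else 0
* Treg-infiltration correlation and per-gene TMB/MSI correlations (binned
  from the correlation coefficient):
  rho > 0.3 -> 3;  0.2 < rho <= 0.3 -> 2;  0.1 < rho <= 0.2 -> 1; else 0
* TMB and MSI columns are sums of the per-gene bins over {CCR8, CD274,
  PDCD1} (range 0-9)
* +3 points when immune checkpoint inhibitors are the standard of care.

The final score is the plain sum of all components; the maximum attainable
under the default configuration is 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "ScoringRubric",
    "ScoreCard",
    "score_pvalue",
    "score_correlation",
    "score_biomarker",
    "aggregate",
    "rank_indications",
    "load_components",
    "reference_components",
    "CHECKPOINT_GENES",
    "BIOMARKER_GENES",
]

logger = logging.getLogger(__name__)

CHECKPOINT_GENES = ("PDCD1", "CD274", "CTLA4")
BIOMARKER_GENES = ("CCR8", "CD274", "PDCD1")


@dataclass(frozen=True)
class ScoringRubric:
    """Bin thresholds (tightest first) and the standard-of-care bonus.

    ``pvalue_bins`` ascend numerically (most significant bin first);
    ``corr_bins`` descend (strongest correlation bin first).  Each maps to
    the corresponding entry of its scores tuple, with the last score for
    values beyond every threshold.
    """

    pvalue_bins: tuple[float, float, float] = (1e-50, 1e-30, 1e-10)
    pvalue_scores: tuple[int, int, int, int] = (3, 2, 1, 0)
    corr_bins: tuple[float, float, float] = (0.3, 0.2, 0.1)
    corr_scores: tuple[int, int, int, int] = (3, 2, 1, 0)
    soc_bonus: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.pvalue_bins[0] < self.pvalue_bins[1] < self.pvalue_bins[2]):
            raise ValueError("pvalue_bins must be strictly increasing (tightest first)")
        if not (self.corr_bins[0] > self.corr_bins[1] > self.corr_bins[2]):
            raise ValueError("corr_bins must be strictly decreasing")


def score_pvalue(p: float, rubric: ScoringRubric | None = None) -> int:
    """Bin a correlation p-value; smaller p scores higher.

    Boundaries: p < b0 -> top score; b0 <= p < b1 -> next; and so on
    (so p exactly at a threshold falls into the weaker bin).
    """
    rubric = rubric or ScoringRubric()
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, score in zip(rubric.pvalue_bins, rubric.pvalue_scores):
        if p < threshold:
            return score
    return rubric.pvalue_scores[-1]


def score_correlation(rho: float, rubric: ScoringRubric | None = None) -> int:
    """Bin a correlation coefficient; only positive correlations score.

    Boundaries: rho > b0 -> top score; b1 < rho <= b0 -> next; etc.
    (rho exactly at a threshold falls into the weaker bin; rho <= 0.1,
    including all negative values, scores 0).
    """
    rubric = rubric or ScoringRubric()
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    for threshold, score in zip(rubric.corr_bins, rubric.corr_scores):
        if rho > threshold:
            return score
    return rubric.corr_scores[-1]


def score_biomarker(per_gene_rho: dict, rubric: ScoringRubric | None = None) -> int:
    """Sum of per-gene correlation bins (TMB or MSI column; range 0-9)."""
    if not per_gene_rho:
        logger.warning("empty biomarker correlation map; score 0")
        return 0
    return sum(score_correlation(r, rubric) for r in per_gene_rho.values())


@dataclass
class ScoreCard:
    """Per-cancer component scores and the final integrated score."""

    cancer_type: str
    checkpoint_scores: dict = field(default_factory=dict)
    treg_infiltration_score: int = 0
    tmb_score: int = 0
    msi_score: int = 0
    clinical_points: int = 0
    final: int = 0

    def as_row(self) -> dict:
        row = {"cancer_type": self.cancer_type}
        row.update({g: self.checkpoint_scores.get(g, 0) for g in CHECKPOINT_GENES})
        row.update(
            treg_infiltration=self.treg_infiltration_score,
            TMB=self.tmb_score,
            MSI=self.msi_score,
            clinical_status=self.clinical_points,
            final_score=self.final,
        )
        return row


def _resolve(raw, binned, binfn, name: str):
    """Raw values take precedence over pre-binned scores."""
    if raw is not None:
        return binfn(raw)
    if binned is not None:
        return int(binned)
    raise ValueError(f"missing component: {name}")


def aggregate(
    cancer_type: str,
    *,
    checkpoint_pvalues: dict | None = None,
    checkpoint_scores: dict | None = None,
    treg_rho: float | None = None,
    treg_score: int | None = None,
    tmb_rhos: dict | None = None,
    tmb_score: int | None = None,
    msi_rhos: dict | None = None,
    msi_score: int | None = None,
    soc: bool = False,
    rubric: ScoringRubric | None = None,
) -> ScoreCard:
    """Build a scorecard from raw statistics and/or pre-binned scores.

    Raw inputs (p-values / correlation coefficients) take precedence over
    pre-binned scores for the same component; every component must be
    supplied one way or the other.
    """
    rubric = rubric or ScoringRubric()
    if checkpoint_pvalues is not None:
        cp = {g: score_pvalue(p, rubric) for g, p in checkpoint_pvalues.items()}
    elif checkpoint_scores is not None:
        cp = {g: int(s) for g, s in checkpoint_scores.items()}
    else:
        raise ValueError("missing component: checkpoint correlations")
    treg = _resolve(treg_rho, treg_score,
                    lambda r: score_correlation(r, rubric), "Treg infiltration")
    tmb = _resolve(tmb_rhos, tmb_score,
                   lambda m: score_biomarker(m, rubric), "TMB")
    msi = _resolve(msi_rhos, msi_score,
                   lambda m: score_biomarker(m, rubric), "MSI")
    clinical = rubric.soc_bonus if soc else 0
    final = sum(cp.values()) + treg + tmb + msi + clinical
    return ScoreCard(
        cancer_type=cancer_type,
        checkpoint_scores=cp,
        treg_infiltration_score=treg,
        tmb_score=tmb,
        msi_score=msi,
        clinical_points=clinical,
        final=final,
    )


def rank_indications(cards: list[ScoreCard]) -> list[ScoreCard]:
    """Descending by final score; ties broken by cancer-type label."""
    if not cards:
        raise ValueError("need at least one scorecard")
    return sorted(cards, key=lambda c: (-c.final, c.cancer_type))


def load_components(source, rubric: ScoringRubric | None = None) -> list[ScoreCard]:
    """Score every cancer described in a components mapping or YAML path.

    Each entry may carry raw statistics (``checkpoint_pvalues``, ``treg_rho``,
    ``tmb_rhos``, ``msi_rhos``) and/or pre-binned scores (``checkpoint_scores``,
    ``treg_score``, ``tmb_score``, ``msi_score``), plus the ``soc`` flag.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with (open(source) if isinstance(source, (str, bytes)) else source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    cards = []
    for cancer_type, comp in data.items():
        cards.append(aggregate(cancer_type, rubric=rubric, **comp))
    return cards


def reference_components() -> dict:
    """Component inputs for the six evaluated TCGA indications.

    BRCA carries the raw checkpoint-correlation p-values; the other cancers
    carry pre-binned component scores.  Scoring this mapping reproduces the
    published six-indication scorecard (BRCA 30 ... READ 13).
    """
    path = resources.files("treghub").joinpath("data/reference_components.yaml")
    with path.open() as fh:
        return yaml.safe_load(fh)
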