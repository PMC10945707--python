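"""High-confidence network construction.

Interaction-probability scores (SAINT-style, consumed as input) are
benchmarked against curated positive/negative PPI sets with cohort-averaged
ROC curves, the score cutoff is anchored at a target Bayesian FDR, and a
spectral-count reproducibility sweep justifies the minimum-count filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    HighConfidenceNetwork,
    ScoredInteraction,
    SpectralCountTable,
    ValidationSets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "ReproducibilitySweep",
    "build_validation_roc",
    "select_cutoff_by_bfdr",
    "sweep_spectral_cutoff",
    "filter_high_confidence",
]


@dataclass
class RocResult:
    """Cohort-averaged ROC curve of validation scores.

    ``thresholds`` are the candidate score cutoffs (descending sweep of
    "call positive if score >= t"); ``mean_tpr``/``mean_fpr`` are averaged
    pointwise across the negative cohorts at those shared thresholds.
    """

    thresholds: np.ndarray
    mean_tpr: np.ndarray
    mean_fpr: np.ndarray
    auc_mean: float
    n_cohorts: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "mean_tpr": self.mean_tpr, "mean_fpr": self.mean_fpr}
        )


@dataclass
class ReproducibilitySweep:
    """Replicate-correlation statistics over a range of count cutoffs."""

    table: pd.DataFrame  # cutoff, n_retained, mean_correlation (NaN = undefined)
    per_bait: pd.DataFrame  # cutoff, bait, n_retained, correlation

    def grand_mean(self, cutoff: int) -> float:
        row = self.table[self.table["cutoff"] == cutoff]
        return float(row["mean_correlation"].iloc[0])


def _resolve_scores(
    scored: Sequence[ScoredInteraction], pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Scores for validation pairs; pairs absent from the table score 0
    (undetected pairs carry no evidence)."""
    lookup = {(s.bait, s.prey): s.score for s in scored}
    return np.array([lookup.get(p, 0.0) for p in pairs], dtype=float)


def _concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: fraction of positive/negative pairs ranked
    concordantly, ties counting one half."""
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def build_validation_roc(
    scored: Sequence[ScoredInteraction],
    validation: ValidationSets,
    n_cohorts: int = 1000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis of interaction scores against curated PPI sets.

    Because negatives typically vastly outnumber positives, ``n_cohorts``
    random cohorts of negatives, each number-matched to the positive set,
    are drawn without replacement; TPR/FPR are computed per score threshold
    for each cohort and averaged pointwise, and the mean AUC is the average
    rank concordance of positive versus cohort-negative scores.
    """
    positives = sorted(validation.positives)
    negatives = sorted(validation.negatives)
    if not positives:
        raise ValueError("validation positive set is empty")
    if len(negatives) < len(positives):
        raise ValueError(
            f"need at least as many negatives ({len(negatives)}) as positives ({len(positives)})"
        )
    pos_scores = _resolve_scores(scored, positives)
    neg_scores_all = _resolve_scores(scored, negatives)

    observed = np.concatenate([pos_scores, neg_scores_all])
    thresholds = np.unique(np.concatenate([observed, [0.0, 1.0]]))[::-1]  # descending

    rng = np.random.default_rng(seed)
    n_pos = len(positives)
    tprs = np.empty((n_cohorts, thresholds.size))
    fprs = np.empty((n_cohorts, thresholds.size))
    aucs = np.empty(n_cohorts)
    for k in range(n_cohorts):
        idx = rng.choice(len(negatives), size=n_pos, replace=False)
        neg = neg_scores_all[idx]
        tprs[k] = (pos_scores[:, None] >= thresholds[None, :]).mean(axis=0)
        fprs[k] = (neg[:, None] >= thresholds[None, :]).mean(axis=0)
        aucs[k] = _concordance(pos_scores, neg)
    return RocResult(
        thresholds=thresholds,
        mean_tpr=tprs.mean(axis=0),
        mean_fpr=fprs.mean(axis=0),
        auc_mean=float(aucs.mean()),
        n_cohorts=n_cohorts,
        seed=seed,
    )


def select_cutoff_by_bfdr(
    scored: Sequence[ScoredInteraction], target_bfdr: float = 0.01
) -> float:
    """Score cutoff admitting exactly the interactions at or below the
    target Bayesian FDR: the minimum score among interactions with
    ``bfdr <= target_bfdr``."""
    passing = [s.score for s in scored if s.bfdr <= target_bfdr]
    if not passing:
        raise ValueError(
            f"no interaction has BFDR <= {target_bfdr}; loosen the target or check the score table"
        )
    return float(min(passing))


def sweep_spectral_cutoff(
    table: SpectralCountTable,
    cutoffs: Sequence[int] = range(1, 16),
    log_transform: bool = False,
) -> ReproducibilitySweep:
    """Replicate-reproducibility sweep over minimum-spectral-count cutoffs.

    At each cutoff only the bait-prey pairs whose count in *every*
    replicate is >= cutoff are kept; the Pearson correlation of retained
    counts is computed between each replicate pair within each bait,
    averaged within bait, then across baits.  A bait retaining fewer than
    3 pairs at some cutoff has no defined correlation there and is
    excluded from (and logged out of) the grand mean.  Saturation of the
    grand mean along the sweep motivates the final minimum-count choice.
    """
    if table.n_replicates < 2:
        raise ValueError("reproducibility sweep needs at least 2 replicates")
    rows = []
    per_bait_rows = []
    matrices = {b: table.matrix(b).to_numpy(dtype=float) for b in table.baits()}
    for cutoff in cutoffs:
        n_retained_total = 0
        bait_corrs = []
        for bait, mat in matrices.items():
            keep = (mat >= cutoff).all(axis=1)
            retained = mat[keep]
            n_retained_total += retained.shape[0]
            if retained.shape[0] < 3:
                logger.info(
                    "bait %s retains %d pairs at cutoff %d; correlation undefined",
                    bait, retained.shape[0], cutoff,
                )
                corr = np.nan
            else:
                vals = np.log2(retained + 1) if log_transform else retained
                pair_corrs = []
                for i in range(vals.shape[1]):
                    for j in range(i + 1, vals.shape[1]):
                        with np.errstate(invalid="ignore"):
                            r = np.corrcoef(vals[:, i], vals[:, j])[0, 1]
                        pair_corrs.append(r)
                corr = float(np.nanmean(pair_corrs))
            per_bait_rows.append(
                {"cutoff": cutoff, "bait": bait, "n_retained": int(retained.shape[0]),
                 "correlation": corr}
            )
            if not np.isnan(corr):
                bait_corrs.append(corr)
        rows.append(
            {
                "cutoff": cutoff,
                "n_retained": n_retained_total,
                "mean_correlation": float(np.mean(bait_corrs)) if bait_corrs else np.nan,
            }
        )
    return ReproducibilitySweep(pd.DataFrame(rows), pd.DataFrame(per_bait_rows))


def filter_high_confidence(
    scored: Sequence[ScoredInteraction],
    score_cutoff: float,
    min_spec: int = 6,
    all_replicates: bool = True,
    species: str = "",
) -> HighConfidenceNetwork:
    """Emit the high-confidence network.

    Keeps interactions with ``score >= score_cutoff`` whose spectral counts
    satisfy the minimum-count rule: every replicate >= ``min_spec`` when
    ``all_replicates`` (the default), otherwise mean count >= ``min_spec``.
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ValueError(f"score cutoff {score_cutoff} outside [0, 1]")
    kept = []
    for s in scored:
        if s.score < score_cutoff:
            continue
        if s.counts:
            if all_replicates:
                if min(s.counts) < min_spec:
                    continue
            elif float(np.mean(s.counts)) < min_spec:
                continue
        elif min_spec > 0:
            continue
        kept.append(s)
    net = HighConfidenceNetwork(kept, score_cutoff, min_spec, species=species)
    logger.info("high-confidence network: %s", net.summary())
    return net
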