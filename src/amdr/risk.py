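"""Epistasis-enriched risk scores: aggregation, ROC/AUC, threshold selection.

The per-subject score R(k, n) counts, over the significant k-way
interactions, those in which the subject's genotype combination falls in a
high-risk cell. The significance cutoff alpha-hat is chosen within
[0, 0.05] to maximize the AUC of the resulting score, and a final
classification cutoff on the score maximizes overall accuracy.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datatypes import GenotypeDataset, InteractionResult, RiskScoreProfile
from .mdr import cell_indices

__all__ = [
    "risk_scores",
    "roc_auc",
    "select_alpha",
    "best_cutoff",
    "build_profile",
]

log = logging.getLogger(__name__)


def risk_scores(
    data: GenotypeDataset,
    results: list[InteractionResult],
    alpha: float,
) -> np.ndarray:
    """Aggregated risk score per subject at significance threshold ``alpha``.

    An interaction contributes iff its p-value is strictly below ``alpha``;
    a contributing interaction adds 1 for every subject whose genotype
    combination lies in one of its high-risk cells. Genotype combinations
    that were empty in the analysis count as low risk.
    """
    scores = np.zeros(data.n_subjects, dtype=np.int64)
    for res in results:
        if res.pvalue < alpha:
            idx = cell_indices(data.genotypes, res.spec.loci)
            scores += res.table.high_risk[idx]
    return scores


def roc_auc(scores: np.ndarray, phenotype: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC of a score against the binary phenotype.

    AUC is the rank (concordance) statistic with half credit for ties —
    the probability that a random case outscores a random control. ROC
    points are taken at every distinct score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    case = phenotype == 1
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires both cases and controls")
    ranks = rankdata(scores)
    auc = (ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, _ = roc_curve(phenotype, scores)
    return np.column_stack([fpr, tpr]), float(auc)


def select_alpha(
    data: GenotypeDataset,
    results: list[InteractionResult],
    grid: np.ndarray | None = None,
) -> tuple[float | None, float]:
    """Significance threshold in [0, 0.05] maximizing the score's AUC.

    Because inclusion is strict (``pvalue < alpha``), every achievable set
    of significant interactions is realized by some observed p-value used
    as the threshold: the default candidate grid is the distinct observed
    p-values in (0, 0.05] plus 0.05 itself, so the selected threshold is an
    interpretable p-value boundary. Ties in AUC break toward the smallest
    threshold (fewest interactions). Returns ``(alpha_hat, auc)``;
    ``alpha_hat`` is None when no interaction has p-value below 0.05.
    """
    if not results:
        raise ValueError("no interaction results supplied")
    if grid is None:
        observed = sorted({r.pvalue for r in results})
        grid = np.array(
            [p for p in observed if 0.0 < p <= 0.05] + [0.05]
        )
    else:
        grid = np.sort(np.asarray(grid, dtype=float))
    if not any(r.pvalue < a for r in results for a in grid):
        log.warning("no interaction significant at any candidate threshold")
        return None, 0.5
    best_alpha, best_auc = None, -np.inf
    for alpha in grid:  # ascending: first maximum wins -> sparsest model
        scores = risk_scores(data, results, float(alpha))
        _, auc = roc_auc(scores, data.phenotype)
        if auc > best_auc:
            best_alpha, best_auc = float(alpha), auc
    return best_alpha, best_auc


def best_cutoff(scores: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """Score cutoff (predict case when score > cutoff) maximizing accuracy.

    Candidates are the midpoints between adjacent distinct scores plus a
    half-step beyond either extreme; ties break toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    candidates = np.concatenate([[distinct[0] - 0.5], mids, [distinct[-1] + 0.5]])
    best_c, best_acc = candidates[0], -1.0
    for c in candidates:
        acc = float(np.mean((scores > c).astype(int) == phenotype))
        if acc > best_acc:
            best_c, best_acc = float(c), acc
    return best_c, best_acc


def build_profile(
    data: GenotypeDataset,
    results: list[InteractionResult],
    alpha: float | str = "auc-max",
) -> RiskScoreProfile:
    """Full risk-score profile: scores, alpha-hat, ROC, AUC, cutoff, accuracy.

    ``alpha`` may be a fixed threshold or ``"auc-max"`` (default) for the
    AUC-maximizing selection. Scores and diagnostics are evaluated in-sample
    on the analysis dataset.
    """
    if alpha == "auc-max":
        alpha_hat, _ = select_alpha(data, results)
    else:
        alpha_hat = float(alpha)
    if alpha_hat is None:
        scores = np.zeros(data.n_subjects, dtype=np.int64)
        roc, auc = roc_auc(scores, data.phenotype)
        return RiskScoreProfile(
            scores=scores, alpha_hat=None, significant_specs=[], roc=roc,
            auc=auc, cutoff=None, accuracy=None,
        )
    scores = risk_scores(data, results, alpha_hat)
    roc, auc = roc_auc(scores, data.phenotype)
    cutoff, accuracy = best_cutoff(scores, data.phenotype)
    significant = [r.spec for r in results if r.pvalue < alpha_hat]
    log.info(
        "risk profile: %d significant interactions, alpha=%.4g, AUC=%.3f, "
        "cutoff=%.1f, accuracy=%.3f",
        len(significant), alpha_hat, auc, cutoff, accuracy,
    )
    return RiskScoreProfile(
        scores=scores, alpha_hat=alpha_hat, significant_specs=significant,
        roc=roc, auc=auc, cutoff=cutoff, accuracy=accuracy,
    )
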