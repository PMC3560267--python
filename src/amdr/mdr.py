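"""Locus-combination enumeration, genotype-cell partitioning and original MDR.

The multifactor dimensionality reduction step collapses the ``3**k`` genotype
cells of a k-way locus combination into a binary high/low predisposing-risk
attribute: a cell is high risk when its observed case fraction exceeds the
overall case fraction (the naive-Bayes threshold). The original MDR procedure
selects, by cross-validated classification accuracy, a single best combination
per order and assesses it by permutation.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .datatypes import (
    CellCounts,
    GenotypeDataset,
    InteractionSpec,
    MDRResult,
    PredisposingTable,
)

__all__ = [
    "enumerate_interactions",
    "cell_indices",
    "partition_cells",
    "naive_bayes_threshold",
    "build_predisposing_table",
    "run_original_mdr",
    "permutation_test_mdr",
]

log = logging.getLogger(__name__)


def enumerate_interactions(n_snps: int, k: int) -> list[InteractionSpec]:
    """All C(M, k) k-way locus combinations, in lexicographic order."""
    if k < 1:
        raise ValueError("interaction order k must be >= 1")
    if k > n_snps:
        raise ValueError(f"interaction order k={k} exceeds SNP count M={n_snps}")
    return [InteractionSpec(loci) for loci in combinations(range(n_snps), k)]


def cell_indices(genotypes: np.ndarray, loci: tuple[int, ...]) -> np.ndarray:
    """Base-3 genotype-cell index (first locus most significant) per subject."""
    idx = np.zeros(genotypes.shape[0], dtype=np.int64)
    for locus in loci:
        idx = idx * 3 + genotypes[:, locus]
    return idx


def partition_cells(data: GenotypeDataset, spec: InteractionSpec) -> CellCounts:
    """Count cases and controls in each of the 3**k genotype cells."""
    if spec.loci[-1] >= data.n_snps:
        raise ValueError(f"spec {spec.loci} out of range for M={data.n_snps}")
    idx = cell_indices(data.genotypes, spec.loci)
    case = data.phenotype == 1
    nc = spec.n_cells
    x = np.bincount(idx[case], minlength=nc)
    y = np.bincount(idx[~case], minlength=nc)
    return CellCounts(spec=spec, X=x, Y=y)


def naive_bayes_threshold(cells: CellCounts) -> float:
    """Overall case fraction; cells above it are deemed high predisposing risk."""
    total = cells.n_cases + cells.n_controls
    if total == 0:
        raise ValueError("cannot compute a risk threshold from an empty dataset")
    p0 = cells.n_cases / total
    if not 0.0 < p0 < 1.0:
        raise ValueError("threshold requires both cases and controls present")
    return p0


def build_predisposing_table(cells: CellCounts, p0: float) -> PredisposingTable:
    """Collapse cell counts into the 2x2 predisposing-risk table.

    A cell is high risk when its case fraction is strictly greater than
    ``p0``; ties and empty cells (ratio taken as 0) are low risk.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    tot = cells.X + cells.Y
    ratio = np.where(tot > 0, cells.X / np.maximum(tot, 1), 0.0)
    high = ratio > p0
    n11 = int(cells.X[high].sum())
    n12 = int(cells.Y[high].sum())
    n21 = cells.n_cases - n11
    n22 = cells.n_controls - n12
    table = PredisposingTable(n11=n11, n12=n12, n21=n21, n22=n22, p0=p0, high_risk=high)
    if table.degenerate:
        log.debug("degenerate predisposing table for loci %s", cells.spec.loci)
    return table


# ---------------------------------------------------------------------------
# original MDR: stratified CV, exhaustive search, permutation test
# ---------------------------------------------------------------------------


def stratified_folds(
    phenotype: np.ndarray,
    folds: int,
    rng: np.random.Generator,
    subject_ids: list[str] | None = None,
) -> np.ndarray:
    """Assign each subject to a CV fold, stratified by phenotype.

    Per-class fold sizes differ by at most one. When ``subject_ids`` are
    given, subjects are first placed in id-sorted order so the assignment
    (for a fixed seed) does not depend on row order.
    """
    n = phenotype.shape[0]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError("more folds than subjects")
    order = (
        np.array(sorted(range(n), key=lambda i: subject_ids[i]))
        if subject_ids is not None
        else np.arange(n)
    )
    fold = np.empty(n, dtype=np.int64)
    for cls in (0, 1):
        idx = order[phenotype[order] == cls]
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % folds
    return fold


def _cv_accuracies(
    cellidx: np.ndarray,
    case: np.ndarray,
    fold: np.ndarray,
    folds: int,
    n_cells: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold training and testing accuracy for one locus combination.

    Within each training set (all folds but one) cells are classified
    high/low risk against that training set's own case fraction; accuracy is
    the proportion of subjects whose class matches their cell's risk label.
    Cells unseen in training are labelled low risk.
    """
    key = fold * n_cells + cellidx
    size = folds * n_cells
    x_fc = np.bincount(key[case], minlength=size).reshape(folds, n_cells)
    y_fc = np.bincount(key[~case], minlength=size).reshape(folds, n_cells)
    x_tr = x_fc.sum(axis=0) - x_fc  # (folds, cells): training counts per fold
    y_tr = y_fc.sum(axis=0) - y_fc
    tr_cases = x_tr.sum(axis=1)
    tr_total = tr_cases + y_tr.sum(axis=1)
    p0 = tr_cases / tr_total
    tot = x_tr + y_tr
    ratio = np.where(tot > 0, x_tr / np.maximum(tot, 1), 0.0)
    high = ratio > p0[:, None]
    train_acc = np.where(high, x_tr, y_tr).sum(axis=1) / tr_total
    val_total = x_fc.sum(axis=1) + y_fc.sum(axis=1)
    test_acc = np.where(high, x_fc, y_fc).sum(axis=1) / np.maximum(val_total, 1)
    return train_acc, test_acc


def _search_order_k(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    specs: list[InteractionSpec],
    fold: np.ndarray,
    folds: int,
) -> tuple[int, float, float, int]:
    """Exhaustive CV search over ``specs``; returns the winning model.

    Returns ``(best_index, train_acc, mean_test_acc, cvc)`` where the best
    model maximizes mean testing accuracy (ties broken toward higher CVC,
    then the lexicographically first combination) and CVC counts the folds
    in which that model had the best training accuracy.
    """
    case = phenotype == 1
    n_specs = len(specs)
    train = np.empty((n_specs, folds))
    test = np.empty((n_specs, folds))
    for s, spec in enumerate(specs):
        cidx = cell_indices(genotypes, spec.loci)
        train[s], test[s] = _cv_accuracies(cidx, case, fold, folds, spec.n_cells)
    mean_test = test.mean(axis=1)
    winner_per_fold = np.argmax(train, axis=0)  # first index wins ties
    cvc_all = np.bincount(winner_per_fold, minlength=n_specs)
    # best spec: highest mean testing accuracy, then higher CVC, then first
    order = np.lexsort((np.arange(n_specs), -cvc_all, -mean_test))
    best = int(order[0])
    return best, float(train[best].mean()), float(mean_test[best]), int(cvc_all[best])


def run_original_mdr(
    data: GenotypeDataset,
    k_values: list[int] | tuple[int, ...] = (2,),
    folds: int = 10,
    rng_seed: int | np.random.SeedSequence = 0,
) -> dict[int, MDRResult]:
    """Original MDR: exhaustive search with stratified k-fold CV, per order."""
    rng = np.random.default_rng(rng_seed)
    fold = stratified_folds(data.phenotype, folds, rng, data.subject_ids)
    out: dict[int, MDRResult] = {}
    for k in k_values:
        specs = enumerate_interactions(data.n_snps, k)
        best, tr, te, cvc = _search_order_k(
            data.genotypes, data.phenotype, specs, fold, folds
        )
        out[k] = MDRResult(
            k=k,
            best=specs[best],
            training_accuracy=tr,
            testing_accuracy=te,
            cvc=cvc,
            folds=folds,
        )
        log.info(
            "MDR k=%d: best=%s test_acc=%.3f CVC=%d/%d",
            k, specs[best].loci, te, cvc, folds,
        )
    return out


def permutation_test_mdr(
    data: GenotypeDataset,
    k: int = 2,
    folds: int = 10,
    B: int = 1000,
    rng_seed: int | np.random.SeedSequence = 0,
    observed: MDRResult | None = None,
    null: str = "model",
) -> float:
    """Permutation p-value for the optimal k-way MDR model.

    Each replicate permutes the phenotype and re-derives stratified folds.
    With ``null="model"`` (default) the reference distribution is the
    cross-validated testing accuracy of the selected model itself under
    permutation — a test of that model's association. ``null="search"``
    instead re-runs the full exhaustive search per replicate and compares
    against the permuted best-of-all testing accuracy, which additionally
    corrects for model selection and is markedly more conservative. The
    p-value is the proportion of replicates reaching the observed accuracy.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if null not in ("model", "search"):
        raise ValueError("null must be 'model' or 'search'")
    ss = np.random.SeedSequence(rng_seed) if isinstance(rng_seed, int) else rng_seed
    obs_seed, perm_seed = ss.spawn(2)
    if observed is None:
        observed = run_original_mdr(data, (k,), folds, obs_seed)[k]
    rng = np.random.default_rng(perm_seed)
    specs = enumerate_interactions(data.n_snps, k)
    case_idx = cell_indices(data.genotypes, observed.best.loci)
    hits = 0
    for _ in range(B):
        pheno = data.phenotype[rng.permutation(data.n_subjects)]
        fold = stratified_folds(pheno, folds, rng)
        if null == "search":
            _, _, te, _ = _search_order_k(data.genotypes, pheno, specs, fold, folds)
        else:
            _, test_acc = _cv_accuracies(
                case_idx, pheno == 1, fold, folds, observed.best.n_cells
            )
            te = float(test_acc.mean())
        if te >= observed.testing_accuracy:
            hits += 1
    return hits / B
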