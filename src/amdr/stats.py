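"""Calibrated predisposing statistics pOR, pRR and pChi.

For each locus combination the 2x2 predisposing table yields a raw odds
ratio (OR), relative risk (RR) and chi-square statistic (Chi). Because the
high/low-risk split is itself chosen from the data (it conditions on the
naive-Bayes classifier), these raw statistics are inflated above their
nominal null behaviour. They are therefore calibrated against two
empirically estimated distributions:

* ``F0`` — the statistic's distribution with the phenotype permuted
  (association destroyed), and
* ``F``  — its distribution under jackknife subsampling of the observed
  data (association preserved).

The corrected statistic is ``x / F0^{-1}(F(x))``: the raw value divided by
the null quantile matching its rank under the alternative distribution.
Under no association ``F ~ F0`` and the corrected value centres at 1.
Permutation p-values, 95% resampling confidence intervals and
Benjamini-Hochberg FDR adjustment complete the per-combination inference.
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    STATISTICS,
    GenotypeDataset,
    InteractionResult,
    InteractionSpec,
    NullCalibration,
    PredisposingTable,
)
from .mdr import (
    build_predisposing_table,
    cell_indices,
    enumerate_interactions,
    naive_bayes_threshold,
    partition_cells,
)

__all__ = [
    "raw_statistics",
    "permutation_null",
    "jackknife_alt",
    "ecdf",
    "quantile",
    "corrected_statistic",
    "permutation_pvalue",
    "confidence_interval",
    "fdr_adjust",
    "analyze_all",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# raw statistics, vectorized over resamples
# ---------------------------------------------------------------------------


def _margins_from_cells(
    X: np.ndarray, Y: np.ndarray, p0: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2x2 table margins (n11, n12, n21, n22) from per-cell counts.

    ``X``/``Y`` may carry leading resample axes; the cell axis is last.
    Empty cells have case ratio 0 and fall in the low-risk stratum, as do
    cells whose ratio ties the threshold.
    """
    tot = X + Y
    ratio = np.where(tot > 0, X / np.maximum(tot, 1), 0.0)
    p0 = np.asarray(p0)[..., None] if np.ndim(p0) else p0
    high = ratio > p0
    n11 = np.where(high, X, 0).sum(axis=-1)
    n12 = np.where(high, Y, 0).sum(axis=-1)
    n21 = X.sum(axis=-1) - n11
    n22 = Y.sum(axis=-1) - n12
    return n11, n12, n21, n22


def _raw_from_margins(
    n11: np.ndarray, n12: np.ndarray, n21: np.ndarray, n22: np.ndarray
) -> dict[str, np.ndarray]:
    """OR, RR and Chi from 2x2 margins, kept finite for resampling.

    When any cell is empty, OR and RR use the Haldane-Anscombe +0.5
    continuity correction (added to all four cells). Chi is the uncorrected
    Pearson statistic; tables with an empty margin (where expected counts
    vanish together with their observed counts) contribute 0.
    """
    n11 = np.asarray(n11, dtype=float)
    n12 = np.asarray(n12, dtype=float)
    n21 = np.asarray(n21, dtype=float)
    n22 = np.asarray(n22, dtype=float)
    shift = np.where((n11 == 0) | (n12 == 0) | (n21 == 0) | (n22 == 0), 0.5, 0.0)
    a, b, c, d = n11 + shift, n12 + shift, n21 + shift, n22 + shift
    odds = (a * d) / (b * c)
    rr = (a / (a + b)) / (c / (c + d))
    n = n11 + n12 + n21 + n22
    r1, r2 = n11 + n12, n21 + n22
    c1, c2 = n11 + n21, n12 + n22
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, n * (n11 * n22 - n12 * n21) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    return {"OR": odds, "RR": rr, "Chi": chi}


def raw_statistics(table: PredisposingTable) -> tuple[float, float, float]:
    """Raw (OR, RR, Chi) of one predisposing table.

    A fully degenerate table (an empty high- or low-risk margin) still
    returns finite values via the continuity correction / zero convention;
    callers should check :attr:`PredisposingTable.degenerate` and treat the
    combination as uninformative.
    """
    stats = _raw_from_margins(
        np.asarray(table.n11), np.asarray(table.n12),
        np.asarray(table.n21), np.asarray(table.n22),
    )
    return float(stats["OR"]), float(stats["RR"]), float(stats["Chi"])


def _stats_from_membership(
    onehot: np.ndarray, case_matrix: np.ndarray, totals: np.ndarray, p0
) -> dict[str, np.ndarray]:
    """Raw statistics for many resamples at once.

    ``onehot`` is the (N, cells) cell-membership matrix, ``case_matrix`` a
    (B, N) 0/1 case indicator per resample, ``totals`` the per-cell subject
    counts of each resample ((cells,) or (B, cells)).
    """
    X = case_matrix @ onehot
    Y = totals - X
    return _raw_from_margins(*_margins_from_cells(X, Y, p0))


def permutation_null(
    data: GenotypeDataset,
    spec: InteractionSpec,
    B: int = 1000,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Raw statistics of ``spec`` under ``B`` phenotype permutations.

    Each subject's SNP vector is kept intact; only the phenotype labels are
    reshuffled, so the case count — and with it the threshold p0 — is
    unchanged. Returns arrays keyed by statistic name.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng_seed)
    n = data.n_subjects
    perms = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        perms[b] = rng.permutation(n)
    case_matrix = (data.phenotype[perms] == 1).astype(np.float64)
    idx = cell_indices(data.genotypes, spec.loci)
    onehot = (idx[:, None] == np.arange(spec.n_cells)).astype(np.float64)
    totals = onehot.sum(axis=0)
    return _stats_from_membership(onehot, case_matrix, totals, data.case_fraction)


def jackknife_alt(
    data: GenotypeDataset,
    spec: InteractionSpec,
    B_j: int = 200,
    fraction: float = 0.9,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Raw statistics of ``spec`` on ``B_j`` jackknife subsamples.

    Each draw keeps a random ``fraction`` of subjects with their SNP and
    phenotype vectors intact, preserving the association; the risk threshold
    and cell classification are recomputed per subsample. Draws missing a
    phenotype class are rejected and redrawn.
    """
    if B_j < 1:
        raise ValueError("need at least one jackknife draw")
    if not 0.0 < fraction < 1.0:
        raise ValueError("subsample fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    n = data.n_subjects
    m = max(2, round(fraction * n))
    keep = np.zeros((B_j, n), dtype=bool)
    pheno = data.phenotype == 1
    for b in range(B_j):
        redraws = 0
        while True:
            sel = rng.choice(n, size=m, replace=False)
            if pheno[sel].any() and (~pheno[sel]).any():
                break
            redraws += 1
            if redraws == 100:
                log.warning(
                    "100 degenerate jackknife draws for loci %s; still retrying",
                    spec.loci,
                )
            if redraws > 10_000:
                raise RuntimeError("could not draw a two-class jackknife subsample")
        keep[b, sel] = True
    idx = cell_indices(data.genotypes, spec.loci)
    onehot = (idx[:, None] == np.arange(spec.n_cells)).astype(np.float64)
    case_matrix = (keep & pheno).astype(np.float64)
    totals = keep.astype(np.float64) @ onehot
    p0 = case_matrix.sum(axis=1) / keep.sum(axis=1)
    return _stats_from_membership(onehot, case_matrix, totals, p0)


# ---------------------------------------------------------------------------
# empirical CDF machinery and the corrected statistic
# ---------------------------------------------------------------------------


def ecdf(samples: np.ndarray, x) -> np.ndarray | float:
    """Empirical CDF: fraction of ``samples`` less than or equal to ``x``."""
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size == 0:
        raise ValueError("ecdf of an empty sample")
    out = np.searchsorted(s, x, side="right") / s.size
    return float(out) if np.ndim(x) == 0 else out


def quantile(samples: np.ndarray, p) -> np.ndarray | float:
    """Order-statistic inverse CDF: ``inf{x : ecdf(x) >= p}``.

    For ``p`` in ``(0, 1]`` this is the ``ceil(p*B)``-th order statistic;
    ``p = 0`` returns the sample minimum.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size == 0:
        raise ValueError("quantile of an empty sample")
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("quantile probability must be in [0, 1]")
    idx = np.clip(np.ceil(p * s.size).astype(np.int64) - 1, 0, s.size - 1)
    out = s[idx]
    return float(out) if p.ndim == 0 else out


def _null_floor(null_sorted: np.ndarray, name: str) -> float:
    pos = null_sorted[null_sorted > 0]
    if pos.size == 0:
        raise ValueError(
            f"all null samples of {name} are non-positive; calibration impossible"
        )
    return float(pos[0])


def corrected_statistic(x_obs: float, calib: NullCalibration) -> float:
    """Calibrated statistic ``x / F0^{-1}(F(x))``.

    ``F`` is the jackknife (alternative) ECDF, ``F0^{-1}`` the permutation
    (null) quantile function. A non-positive null quantile (possible for
    Chi, whose null samples can be 0) is clamped to the smallest positive
    null sample so the ratio stays defined.
    """
    return float(_corrected_many(np.asarray([x_obs], dtype=float), calib)[0])


def _corrected_many(x: np.ndarray, calib: NullCalibration) -> np.ndarray:
    """Vectorized ``x / F0^{-1}(F(x))`` through one fixed calibration."""
    alt = np.sort(calib.alt_samples)
    null = np.sort(calib.null_samples)
    ranks = np.searchsorted(alt, x, side="right") / alt.size
    idx = np.clip(np.ceil(ranks * null.size).astype(np.int64) - 1, 0, null.size - 1)
    denom = null[idx]
    if (denom <= 0).any():
        floor = _null_floor(null, calib.statistic_name)
        log.debug(
            "clamping %d non-positive null quantiles of %s to %g",
            int((denom <= 0).sum()), calib.statistic_name, floor,
        )
        denom = np.where(denom <= 0, floor, denom)
    return x / denom


def permutation_pvalue(
    z_obs: float, z_perm: np.ndarray, conservative: bool = False
) -> float:
    """Upper-tail permutation p-value ``(1/B) #{i : z_obs < z_i}``.

    With ``conservative=True`` the add-one variant ``(#+1)/(B+1)`` is used,
    which never returns an exact zero.
    """
    z_perm = np.asarray(z_perm, dtype=float)
    if z_perm.size < 1:
        raise ValueError("need at least one permutation statistic")
    hits = int((z_perm > z_obs).sum())
    if conservative:
        return (hits + 1) / (z_perm.size + 1)
    return hits / z_perm.size


def confidence_interval(z_resamples: np.ndarray) -> tuple[float, float]:
    """95% resampling interval: the (2.5th, 97.5th) order-statistic quantiles."""
    z = np.asarray(z_resamples, dtype=float)
    if z.size < 40:
        log.warning("only %d resamples; 95%% interval will be coarse", z.size)
    return float(quantile(z, 0.025)), float(quantile(z, 0.975))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full per-dataset analysis
# ---------------------------------------------------------------------------


def analyze_interaction(
    data: GenotypeDataset,
    spec: InteractionSpec,
    B: int = 1000,
    B_j: int = 200,
    fraction: float = 0.9,
    rng_seed: int | np.random.SeedSequence = 0,
    primary: str = "OR",
    ci_source: str = "jackknife",
    conservative_p: bool = False,
) -> InteractionResult:
    """All three calibrated statistics for one locus combination.

    One shared permutation set and one shared jackknife set feed OR, RR and
    Chi alike. The permutation p-value compares the observed statistic with
    the permuted ones on the raw scale, which is equivalent to comparing
    them through any common monotone calibration and avoids the instability
    of re-scaling null-range values by near-zero null quantiles.
    Confidence intervals come from the jackknife resamples scaled by the
    observed statistic's calibration denominator. Because a
    keep-``fraction`` subsample understates full-sample variability, the
    resample deviations are inflated on the log scale by the delete-d
    jackknife factor ``sqrt(m / (n - m))`` before taking percentiles;
    without this the interval collapses around the point estimate and
    rarely covers 1 under no association. ``ci_source="permutation"``
    switches to percentiles of the corrected permutation statistics.
    """
    ss = np.random.SeedSequence(rng_seed) if isinstance(rng_seed, int) else rng_seed
    perm_seed, jack_seed = ss.spawn(2)
    cells = partition_cells(data, spec)
    p0 = naive_bayes_threshold(cells)
    table = build_predisposing_table(cells, p0)
    raw_or, raw_rr, raw_chi = raw_statistics(table)
    raw = {"OR": raw_or, "RR": raw_rr, "Chi": raw_chi}
    null = permutation_null(data, spec, B, perm_seed)
    alt = jackknife_alt(data, spec, B_j, fraction, jack_seed)
    corrected: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    pvalues: dict[str, float] = {}
    if table.degenerate:
        log.warning(
            "degenerate predisposing table for loci %s; statistics undefined",
            spec.loci,
        )
        nan_ci = (float("nan"), float("nan"))
        return InteractionResult(
            spec=spec, p0=p0, table=table, raw=raw,
            corrected={s: float("nan") for s in STATISTICS},
            ci={s: nan_ci for s in STATISTICS},
            pvalues={s: 1.0 for s in STATISTICS},
            fdrs={s: 1.0 for s in STATISTICS},
            primary=primary, degenerate=True,
        )
    for name in STATISTICS:
        calib = NullCalibration(
            statistic_name=name, null_samples=null[name], alt_samples=alt[name]
        )
        corrected[name] = corrected_statistic(raw[name], calib)
        pvalues[name] = permutation_pvalue(raw[name], null[name], conservative_p)
        if ci_source == "permutation":
            z_ci = _corrected_many(null[name], calib)
        else:
            denom = raw[name] / corrected[name] if corrected[name] > 0 else 1.0
            m = max(2, round(fraction * data.n_subjects))
            inflation = np.sqrt(m / (data.n_subjects - m))
            floor = max(np.min(alt[name][alt[name] > 0], initial=1.0) * 1e-6, 1e-12)
            log_alt = np.log(np.maximum(alt[name], floor))
            center = log_alt.mean()
            z_ci = np.exp(center + inflation * (log_alt - center)) / denom
        ci[name] = confidence_interval(z_ci)
    return InteractionResult(
        spec=spec, p0=p0, table=table, raw=raw, corrected=corrected, ci=ci,
        pvalues=pvalues, fdrs=dict(pvalues), primary=primary,
    )


def analyze_all(
    data: GenotypeDataset,
    k: int = 2,
    B: int = 1000,
    B_j: int = 200,
    fraction: float = 0.9,
    rng_seed: int | np.random.SeedSequence = 0,
    primary: str = "OR",
    ci_source: str = "jackknife",
    conservative_p: bool = False,
) -> list[InteractionResult]:
    """Analyze every k-way combination; FDR across all C(M, k) tests.

    Returns results sorted by the primary statistic's p-value (ascending).
    """
    if primary not in STATISTICS:
        raise ValueError(f"primary statistic must be one of {STATISTICS}")
    specs = enumerate_interactions(data.n_snps, k)
    ss = np.random.SeedSequence(rng_seed) if isinstance(rng_seed, int) else rng_seed
    children = ss.spawn(len(specs))
    results = []
    for i, (spec, child) in enumerate(zip(specs, children)):
        results.append(
            analyze_interaction(
                data, spec, B, B_j, fraction, child, primary, ci_source,
                conservative_p,
            )
        )
        if (i + 1) % 100 == 0:
            log.info("analyzed %d/%d interactions", i + 1, len(specs))
    for name in STATISTICS:
        adjusted = fdr_adjust([r.pvalues[name] for r in results])
        for r, q in zip(results, adjusted):
            r.fdrs[name] = float(q)
    results.sort(key=lambda r: (r.pvalue, r.spec.loci))
    return results
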