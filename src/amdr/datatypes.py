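"""Core containers for case-control genotype data and interaction results.

Genotypes are coded 0 (homozygous reference), 1 (heterozygous),
2 (homozygous variant); the phenotype is 1 for affected (case) and 0 for
unaffected (control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeDataset",
    "InteractionSpec",
    "CellCounts",
    "PredisposingTable",
    "MDRResult",
    "NullCalibration",
    "InteractionResult",
    "RiskScoreProfile",
    "STATISTICS",
]

#: canonical order of the three predisposing-table statistics
STATISTICS = ("OR", "RR", "Chi")


@dataclass
class GenotypeDataset:
    """An N-subject x M-SNP biallelic genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes
        ``(N, M)`` integer array with codes in ``{0, 1, 2}``.
    phenotype
        Length-``N`` vector in ``{0, 1}``; 1 marks a case. Both classes
        must be present.
    snp_labels
        ``M`` SNP names. Auto-generated (``SNP1..SNPM``) if omitted.
    subject_ids
        ``N`` subject identifiers. Auto-generated (``S1..SN``) if omitted.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (subjects x SNPs) array")
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} subjects"
            )
        bad = (self.genotypes < 0) | (self.genotypes > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.genotypes[r, c]} at subject {r}, "
                f"SNP column {c} is not in {{0, 1, 2}}"
            )
        values = set(np.unique(self.phenotype).tolist())
        if not values <= {0, 1}:
            raise ValueError(f"phenotype values {values} are not binary 0/1")
        if values != {0, 1}:
            raise ValueError("phenotype must contain at least one case and one control")
        if not self.snp_labels:
            self.snp_labels = [f"SNP{j + 1}" for j in range(m)]
        if len(self.snp_labels) != m:
            raise ValueError("snp_labels length does not match SNP count")
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match subject count")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    @property
    def case_fraction(self) -> float:
        """Overall case proportion; this is the naive-Bayes threshold p0."""
        return self.n_cases / self.n_subjects


@dataclass(frozen=True, order=True)
class InteractionSpec:
    """A k-way locus combination, identified by strictly increasing indices."""

    loci: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(int(x) for x in self.loci))
        if len(self.loci) < 1:
            raise ValueError("an interaction needs at least one locus")
        if any(b <= a for a, b in zip(self.loci, self.loci[1:])):
            raise ValueError(f"loci {self.loci} must be strictly increasing")
        if min(self.loci) < 0:
            raise ValueError("locus indices must be non-negative")

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def n_cells(self) -> int:
        return 3 ** self.k

    def labels(self, snp_labels: Sequence[str]) -> tuple[str, ...]:
        return tuple(snp_labels[i] for i in self.loci)


@dataclass
class CellCounts:
    """Case/control counts for the ``3**k`` genotype cells of one combination.

    Cell ``j`` is the base-3 encoding of the genotype tuple, first locus most
    significant: ``j = g1 * 3**(k-1) + ... + gk``.
    """

    spec: InteractionSpec
    X: np.ndarray  # case count per cell
    Y: np.ndarray  # control count per cell

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.Y = np.asarray(self.Y, dtype=np.int64)
        nc = self.spec.n_cells
        if self.X.shape != (nc,) or self.Y.shape != (nc,):
            raise ValueError("cell count vectors must have length 3**k")
        if (self.X < 0).any() or (self.Y < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return int(self.X.sum())

    @property
    def n_controls(self) -> int:
        return int(self.Y.sum())

    @staticmethod
    def cell_index(genotype_tuple: Sequence[int]) -> int:
        j = 0
        for g in genotype_tuple:
            j = 3 * j + int(g)
        return j


@dataclass
class PredisposingTable:
    """The 2x2 table cross-classifying predisposing risk with disease status.

    ``n11``/``n12`` count cases/controls in high-risk genotype cells,
    ``n21``/``n22`` in low-risk cells. ``expected`` holds the usual
    independence-model expected counts e_st = n_{s+} n_{+t} / N.
    """

    n11: int
    n12: int
    n21: int
    n22: int
    p0: float
    high_risk: np.ndarray  # bool per cell

    @property
    def n(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def expected(self) -> np.ndarray:
        n = self.n
        rows = np.array([self.n11 + self.n12, self.n21 + self.n22], dtype=float)
        cols = np.array([self.n11 + self.n21, self.n12 + self.n22], dtype=float)
        return np.outer(rows, cols) / n

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]], dtype=float)

    @property
    def degenerate(self) -> bool:
        """True when an entire high/low-risk margin is empty."""
        return (self.n11 + self.n12 == 0) or (self.n21 + self.n22 == 0)

    @property
    def high_risk_cells(self) -> frozenset[int]:
        return frozenset(int(j) for j in np.flatnonzero(self.high_risk))


@dataclass
class MDRResult:
    """Outcome of an original-MDR exhaustive search at one interaction order."""

    k: int
    best: InteractionSpec
    training_accuracy: float
    testing_accuracy: float
    cvc: int
    folds: int
    pvalue: float | None = None


@dataclass
class NullCalibration:
    """Resampled raw-statistic values used to calibrate one statistic.

    ``null_samples`` estimate the statistic's distribution under phenotype
    permutation (no association, F0); ``alt_samples`` estimate it under
    jackknife subsampling of the observed data (association preserved, F).
    """

    statistic_name: str
    null_samples: np.ndarray
    alt_samples: np.ndarray

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=float)
        self.alt_samples = np.asarray(self.alt_samples, dtype=float)
        if self.null_samples.size < 1 or self.alt_samples.size < 1:
            raise ValueError("calibration requires at least one resample of each kind")
        if not (
            np.isfinite(self.null_samples).all() and np.isfinite(self.alt_samples).all()
        ):
            raise ValueError("calibration samples must be finite")

    @property
    def B(self) -> int:
        return self.null_samples.size

    @property
    def B_j(self) -> int:
        return self.alt_samples.size


@dataclass
class InteractionResult:
    """All statistics for one locus combination.

    ``raw``, ``corrected``, ``ci``, ``pvalues`` and ``fdrs`` are keyed by
    statistic name (``"OR"``, ``"RR"``, ``"Chi"``); the scalar ``pvalue`` /
    ``fdr`` accessors report the ``primary`` statistic, which downstream
    risk aggregation uses.
    """

    spec: InteractionSpec
    p0: float
    table: PredisposingTable
    raw: dict[str, float]
    corrected: dict[str, float]
    ci: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    fdrs: dict[str, float]
    primary: str = "OR"
    degenerate: bool = False

    @property
    def pvalue(self) -> float:
        return self.pvalues[self.primary]

    @property
    def fdr(self) -> float:
        return self.fdrs[self.primary]

    @property
    def por(self) -> float:
        return self.corrected["OR"]

    @property
    def prr(self) -> float:
        return self.corrected["RR"]

    @property
    def pchi(self) -> float:
        return self.corrected["Chi"]

    @property
    def high_risk_cells(self) -> frozenset[int]:
        return self.table.high_risk_cells


@dataclass
class RiskScoreProfile:
    """Per-subject aggregated epistasis-enriched risk scores and diagnostics."""

    scores: np.ndarray
    alpha_hat: float | None
    significant_specs: list[InteractionSpec]
    roc: np.ndarray  # (n_points, 2) columns FPR, TPR
    auc: float
    cutoff: float | None
    accuracy: float | None
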