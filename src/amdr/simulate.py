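"""Penetrance-model case-control simulation and the power/type-I harness.

Balanced case-control datasets are generated by rejection sampling: each
candidate subject receives five independent Hardy-Weinberg genotypes, and is
affected with probability given by a two-locus penetrance table (or a
mixture/union of two such tables). Three susceptibility scenarios are
supported:

* ``A`` — a single interacting pair, loci 1x2: ``P(D|g) = p12``;
* ``B`` — genetic heterogeneity: a fraction gamma1 of the affected subjects
  owes disease to the loci-1x2 process and the rest to loci 4x5; controls
  follow the mixture susceptibility ``gamma1 * p12 + gamma2 * p45``;
* ``C`` — additive (union of two independent disease processes):
  ``P(D|g) = p12 + p45 - p12 * p45``.

The four built-in penetrance models are purely epistatic or nearly so; the
power harness estimates, over replicated datasets, how often each detection
method declares the causal pair(s) significant, and how often it falsely
flags non-causal pairs (type-I error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, InteractionSpec
from .mdr import enumerate_interactions, permutation_test_mdr, run_original_mdr
from .stats import analyze_all

__all__ = [
    "PenetranceModel",
    "MODELS",
    "SimulationScenario",
    "hwe_genotype_probs",
    "penetrance",
    "susceptibility",
    "simulate_dataset",
    "power_study",
    "PowerStudyResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PenetranceModel:
    """A 3x3 two-locus penetrance table P(D=1 | g1, g2) plus its MAF.

    Rows index the first locus (0=AA common homozygote, 1=Aa, 2=aa) and
    columns the second (BB, Bb, bb).
    """

    name: str
    table: tuple[tuple[float, float, float], ...]
    maf: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("penetrance values must lie in [0, 1]")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("minor allele frequency must be in (0, 0.5]")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=float)


#: The four canonical epistatic penetrance models. Models 1 and 2 (MAF 0.5)
#: are strictly epistatic with no marginal effects; Models 3 and 4 (MAF 0.25)
#: are noisier variants with small marginal components.
MODELS: dict[str, PenetranceModel] = {
    "Model1": PenetranceModel(
        "Model1", ((0.0, 0.1, 0.0), (0.1, 0.0, 0.1), (0.0, 0.1, 0.0)), 0.5
    ),
    "Model2": PenetranceModel(
        "Model2", ((0.0, 0.0, 0.1), (0.0, 0.05, 0.0), (0.1, 0.0, 0.0)), 0.5
    ),
    "Model3": PenetranceModel(
        "Model3",
        ((0.08, 0.07, 0.05), (0.1, 0.0, 0.1), (0.03, 0.1, 0.04)),
        0.25,
    ),
    "Model4": PenetranceModel(
        "Model4",
        ((0.09, 0.05, 0.02), (0.08, 0.09, 0.01), (0.03, 0.01, 0.03)),
        0.25,
    ),
}


@dataclass
class SimulationScenario:
    """A susceptibility scenario over five biallelic loci.

    ``model_pair_1`` drives loci (1, 2); ``model_pair_2`` drives loci (4, 5)
    in scenarios B and C. Mixture weights gamma1/gamma2 apply to scenario B
    only and must sum to 1.
    """

    type: str  # "A", "B" or "C"
    model_pair_1: PenetranceModel
    model_pair_2: PenetranceModel | None = None
    gamma1: float = 0.5
    gamma2: float = 0.5
    n_snps: int = 5

    def __post_init__(self) -> None:
        if self.type not in ("A", "B", "C"):
            raise ValueError("scenario type must be 'A', 'B' or 'C'")
        if self.type in ("B", "C"):
            if self.model_pair_2 is None:
                raise ValueError(f"scenario {self.type} needs a second penetrance model")
            if self.model_pair_2.maf != self.model_pair_1.maf:
                raise ValueError("both penetrance models must share one MAF")
            if self.n_snps < 5:
                raise ValueError("scenarios B and C need at least 5 SNPs")
        if self.type == "B":
            if self.gamma1 < 0 or self.gamma2 < 0 or abs(self.gamma1 + self.gamma2 - 1) > 1e-12:
                raise ValueError("gamma1, gamma2 must be non-negative and sum to 1")
        if self.n_snps < 2:
            raise ValueError("need at least 2 SNPs")

    @property
    def maf(self) -> float:
        return self.model_pair_1.maf

    @property
    def causal_pairs(self) -> list[tuple[int, int]]:
        """0-based causal locus pairs: (0, 1), plus (3, 4) for B and C."""
        return [(0, 1)] if self.type == "A" else [(0, 1), (3, 4)]

    @property
    def causal_loci(self) -> frozenset[int]:
        """Loci entering the susceptibility formula (0-based)."""
        return frozenset(i for pair in self.causal_pairs for i in pair)


def hwe_genotype_probs(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 < q <= 0.5:
        raise ValueError("minor allele frequency must be in (0, 0.5]")
    return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


def penetrance(model: PenetranceModel, g1: int, g2: int) -> float:
    """P(D=1 | g1, g2) by table lookup (codes 0/1/2, 0 = common homozygote)."""
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError("genotype codes must be 0, 1 or 2")
    return float(model.array[g1, g2])


def susceptibility(scenario: SimulationScenario, genotypes: np.ndarray) -> np.ndarray:
    """Disease probability per subject under the scenario's formula.

    ``genotypes`` is an (N, M) matrix, M >= 2 (>= 5 for scenarios B/C); only
    loci (1, 2) and — for B/C — (4, 5) enter the formula.
    """
    g = np.atleast_2d(np.asarray(genotypes))
    p12 = scenario.model_pair_1.array[g[:, 0], g[:, 1]]
    if scenario.type == "A":
        return p12
    p45 = scenario.model_pair_2.array[g[:, 3], g[:, 4]]
    if scenario.type == "B":
        return scenario.gamma1 * p12 + scenario.gamma2 * p45
    return p12 + p45 - p12 * p45


_MAX_DRAWS = 10**7


def simulate_dataset(
    scenario: SimulationScenario,
    n_total: int,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
    return_latent: bool = False,
) -> GenotypeDataset | tuple[GenotypeDataset, np.ndarray]:
    """A balanced case-control dataset of ``n_total`` subjects.

    Candidates receive independent HWE genotypes at every locus and are
    affected with probability ``susceptibility``; sampling continues until
    ``n_total/2`` cases and ``n_total/2`` controls are accumulated, so the
    study design (not the penetrance) fixes the case fraction at one half.

    In the heterogeneity scenario the mixture weights describe the
    composition of the affected sample: a fraction gamma1 of the cases is
    generated by the loci-1x2 disease process and a fraction gamma2 by the
    loci-4x5 process (each case's latent source is drawn first, then a
    genotype accepted with that process's penetrance). Controls are
    rejection-sampled against the mixture susceptibility.

    With ``return_latent=True`` (scenario B only) the latent source label is
    returned for each retained subject: 0 when the disease process ran
    through loci 1x2, 1 for loci 4x5, -1 for controls.
    """
    if n_total % 2:
        raise ValueError("n_total must be even for a balanced design")
    if return_latent and scenario.type != "B":
        raise ValueError("latent source labels exist only in scenario B")
    rng = np.random.default_rng(rng_seed)
    need = n_total // 2
    probs = np.array(hwe_genotype_probs(scenario.maf))
    budget = [_MAX_DRAWS]

    def draw_genotypes(batch: int) -> np.ndarray:
        budget[0] -= batch
        if budget[0] < 0:
            raise RuntimeError(
                "rejection sampling budget exceeded; penetrances may be too small"
            )
        return rng.choice(3, size=(batch, scenario.n_snps), p=probs)

    batch = max(1024, 4 * n_total)
    case_chunks, src_chunks = [], []
    if scenario.type == "B":
        # fixed case-sample composition: gamma1 of the cases from the
        # loci-1x2 process, the rest from loci 4x5
        quota = {0: round(scenario.gamma1 * need)}
        quota[1] = need - quota[0]
        for src_label, n_src in quota.items():
            model = (scenario.model_pair_1, scenario.model_pair_2)[src_label]
            loci = ((0, 1), (3, 4))[src_label]
            got: list[np.ndarray] = []
            while sum(map(len, got)) < n_src:
                g = draw_genotypes(batch)
                p = model.array[g[:, loci[0]], g[:, loci[1]]]
                got.append(g[rng.random(len(g)) < p])
            case_chunks.append(np.concatenate(got)[:n_src])
            src_chunks.append(np.full(n_src, src_label, dtype=np.int8))
    else:
        while sum(map(len, case_chunks)) < need:
            g = draw_genotypes(batch)
            affected = rng.random(len(g)) < susceptibility(scenario, g)
            case_chunks.append(g[affected])
            src_chunks.append(np.full(int(affected.sum()), -1, dtype=np.int8))
    ctrl_chunks = []
    while sum(map(len, ctrl_chunks)) < need:
        g = draw_genotypes(batch)
        unaffected = rng.random(len(g)) >= susceptibility(scenario, g)
        ctrl_chunks.append(g[unaffected])
    case_g = np.concatenate(case_chunks)[:need]
    case_src = np.concatenate(src_chunks)[:need]
    ctrl_g = np.concatenate(ctrl_chunks)[:need]
    genotypes = np.concatenate([case_g, ctrl_g])
    phenotype = np.concatenate([np.ones(need, np.int8), np.zeros(need, np.int8)])
    data = GenotypeDataset(genotypes=genotypes, phenotype=phenotype)
    if return_latent:
        latent = np.concatenate([case_src, np.full(need, -1, np.int8)])
        return data, latent
    return data


@dataclass
class PowerStudyResult:
    """Rejection outcomes of a replicated power study.

    ``rejections`` maps method name ("pOR", "pRR", "pChi", "MDR") to a
    (reps, n_pairs) boolean matrix over the lexicographic SNP pairs;
    ``table`` summarizes power for the causal pairs and the mean type-I
    error over non-causal pairs.
    """

    scenario: SimulationScenario
    n_total: int
    pairs: list[InteractionSpec]
    rejections: dict[str, np.ndarray]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rejection_rate(self, method: str, pair: tuple[int, int]) -> float:
        j = self.pairs.index(InteractionSpec(pair))
        return float(self.rejections[method][:, j].mean())

    def type_one_error(self, method: str) -> float:
        """Mean rejection rate over pairs of loci unrelated to the outcome.

        Pairs sharing one causal locus are excluded: under penetrance models
        with marginal effects such pairs carry a real association, so a
        rejection there is not a false positive of the association test.
        Returns NaN when every pair touches a causal locus (scenarios B/C
        with five loci).
        """
        causal = self.scenario.causal_loci
        null_cols = [
            j for j, p in enumerate(self.pairs) if not (set(p.loci) & causal)
        ]
        if not null_cols:
            return float("nan")
        return float(self.rejections[method][:, null_cols].mean())


def power_study(
    scenario: SimulationScenario,
    n_total: int,
    reps: int = 100,
    methods: tuple[str, ...] = ("pOR", "pRR", "pChi", "MDR"),
    alpha: float = 0.05,
    B: int = 1000,
    B_j: int = 200,
    fraction: float = 0.9,
    rng_seed: int | np.random.SeedSequence = 0,
    rule: str = "fdr",
    folds: int = 10,
    mdr_permutations: int = 200,
) -> PowerStudyResult:
    """Estimate per-pair rejection rates over ``reps`` simulated datasets.

    A calibrated statistic rejects a pair when its adjusted p-value
    (``rule="fdr"``; ``rule="pvalue"`` uses the unadjusted one) falls below
    ``alpha``. Original MDR rejects only when the pair is the best CV model
    *and* its permutation p-value is below ``alpha`` — so a pair the search
    never selects has zero rejection rate by construction.
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    if rule not in ("fdr", "pvalue"):
        raise ValueError("rule must be 'fdr' or 'pvalue'")
    amdr_stats = [m for m in methods if m != "MDR"]
    stat_key = {"pOR": "OR", "pRR": "RR", "pChi": "Chi"}
    for m in amdr_stats:
        if m not in stat_key:
            raise ValueError(f"unknown method {m!r}")
    pairs = enumerate_interactions(scenario.n_snps, 2)
    n_pairs = len(pairs)
    rejections = {m: np.zeros((reps, n_pairs), dtype=bool) for m in methods}
    ss = np.random.SeedSequence(rng_seed) if isinstance(rng_seed, int) else rng_seed
    rep_children = ss.spawn(reps)
    for r, child in enumerate(rep_children):
        data_seed, amdr_seed, mdr_seed = child.spawn(3)
        data = simulate_dataset(scenario, n_total, data_seed)
        if amdr_stats:
            results = analyze_all(data, 2, B, B_j, fraction, amdr_seed)
            by_spec = {res.spec: res for res in results}
            for m in amdr_stats:
                key = stat_key[m]
                for j, pair in enumerate(pairs):
                    res = by_spec[pair]
                    p = res.fdrs[key] if rule == "fdr" else res.pvalues[key]
                    rejections[m][r, j] = p < alpha
        if "MDR" in methods:
            s1, s2 = mdr_seed.spawn(2)
            mdr_res = run_original_mdr(data, (2,), folds, s1)[2]
            pval = permutation_test_mdr(
                data, 2, folds, mdr_permutations, s2, observed=mdr_res
            )
            if pval < alpha:
                j = pairs.index(mdr_res.best)
                rejections["MDR"][r, j] = True
        if (r + 1) % 10 == 0:
            log.info("power study: %d/%d replicates done", r + 1, reps)
    out = PowerStudyResult(
        scenario=scenario, n_total=n_total, pairs=pairs, rejections=rejections
    )
    rows = []
    for m in methods:
        row = {
            "method": m,
            "scenario": scenario.type,
            "model": scenario.model_pair_1.name,
            "n": n_total,
            "power_pair12": out.rejection_rate(m, (0, 1)),
            "power_pair45": (
                out.rejection_rate(m, (3, 4)) if scenario.type != "A" else float("nan")
            ),
            "type1": out.type_one_error(m),
        }
        rows.append(row)
    out.table = pd.DataFrame(rows)
    return out
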