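"""Penetrance models, scenario formulas, the genotype generator and harness."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from amdr.simulate import (
    MODELS,
    PenetranceModel,
    SimulationScenario,
    hwe_genotype_probs,
    penetrance,
    power_study,
    simulate_dataset,
    susceptibility,
)


class TestHweProbs:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.5, (0.25, 0.5, 0.25)), (0.25, (0.5625, 0.375, 0.0625))],
    )
    def test_closed_form(self, q, expected):
        assert hwe_genotype_probs(q) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [0.05, 0.17, 0.33, 0.5])
    def test_sums_to_one(self, q):
        assert sum(hwe_genotype_probs(q)) == pytest.approx(1.0)

    @pytest.mark.parametrize("q", [0.0, 0.6, -0.1])
    def test_rejects_out_of_range(self, q):
        with pytest.raises(ValueError):
            hwe_genotype_probs(q)


class TestPenetranceModels:
    @pytest.mark.parametrize(
        "model,g1,g2,expected",
        [
            ("Model1", 0, 1, 0.1),
            ("Model2", 1, 1, 0.05),
            ("Model4", 0, 0, 0.09),
            ("Model3", 1, 1, 0.0),
            ("Model3", 2, 1, 0.1),
        ],
    )
    def test_table_lookup(self, model, g1, g2, expected):
        assert penetrance(MODELS[model], g1, g2) == expected

    def test_mafs(self):
        assert MODELS["Model1"].maf == MODELS["Model2"].maf == 0.5
        assert MODELS["Model3"].maf == MODELS["Model4"].maf == 0.25

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            PenetranceModel("bad", ((1.5, 0, 0), (0, 0, 0), (0, 0, 0)), 0.5)


class TestSusceptibility:
    def test_heterogeneity_mixture_value(self):
        m1 = PenetranceModel("c1", ((0.1,) * 3,) * 3, 0.5)
        m2 = PenetranceModel("c2", ((0.05,) * 3,) * 3, 0.5)
        scn = SimulationScenario(type="B", model_pair_1=m1, model_pair_2=m2)
        g = np.zeros((1, 5), dtype=int)
        assert susceptibility(scn, g)[0] == pytest.approx(0.075)

    def test_additive_union_value(self):
        m = PenetranceModel("c", ((0.1,) * 3,) * 3, 0.5)
        scn = SimulationScenario(type="C", model_pair_1=m, model_pair_2=m)
        g = np.zeros((1, 5), dtype=int)
        assert susceptibility(scn, g)[0] == pytest.approx(0.19)

    def test_scenario_a_ignores_other_loci(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        g1 = np.array([[1, 2, 0, 0, 0]])
        g2 = np.array([[1, 2, 2, 2, 1]])
        assert susceptibility(scn, g1) == susceptibility(scn, g2)

    @pytest.mark.parametrize("stype", ["B", "C"])
    def test_all_genotype_combinations_against_brute_force(self, stype):
        scn = SimulationScenario(
            type=stype, model_pair_1=MODELS["Model1"],
            model_pair_2=MODELS["Model2"], gamma1=0.7, gamma2=0.3,
        )
        p1 = MODELS["Model1"].array
        p2 = MODELS["Model2"].array
        for g1, g2, g4, g5 in itertools.product(range(3), repeat=4):
            g = np.array([[g1, g2, 0, g4, g5]])
            got = susceptibility(scn, g)[0]
            if stype == "B":
                want = 0.7 * p1[g1, g2] + 0.3 * p2[g4, g5]
            else:
                want = p1[g1, g2] + p2[g4, g5] - p1[g1, g2] * p2[g4, g5]
            assert got == pytest.approx(want)

    def test_gamma_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationScenario(
                type="B", model_pair_1=MODELS["Model1"],
                model_pair_2=MODELS["Model2"], gamma1=0.7, gamma2=0.7,
            )


class TestSimulateDataset:
    def test_balanced_design_contract(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        data = simulate_dataset(scn, 300, 0)
        assert data.n_cases == 150 and data.n_controls == 150
        assert data.n_snps == 5

    def test_odd_total_rejected(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        with pytest.raises(ValueError):
            simulate_dataset(scn, 301, 0)

    def test_null_locus_recovers_hwe(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model3"])
        data = simulate_dataset(scn, 10_000, 1)
        counts = np.bincount(data.genotypes[:, 2], minlength=3)
        expected = np.array(hwe_genotype_probs(0.25)) * data.n_subjects
        assert chisquare(counts, expected).pvalue > 0.001

    def test_inter_locus_independence_of_null_loci(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        data = simulate_dataset(scn, 10_000, 2)
        from scipy.stats import chi2_contingency

        table = np.zeros((3, 3))
        for a, b in zip(data.genotypes[:, 2], data.genotypes[:, 3]):
            table[a, b] += 1
        assert chi2_contingency(table).pvalue > 0.001

    def test_cases_only_in_penetrant_cells(self):
        # Model 1 has zero penetrance on diagonal-like cells
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        data = simulate_dataset(scn, 400, 3)
        cases = data.genotypes[data.phenotype == 1]
        pen = MODELS["Model1"].array[cases[:, 0], cases[:, 1]]
        assert (pen > 0).all()

    def test_latent_source_fraction_matches_gamma(self):
        scn = SimulationScenario(
            type="B", model_pair_1=MODELS["Model1"],
            model_pair_2=MODELS["Model2"], gamma1=0.7, gamma2=0.3,
        )
        data, latent = simulate_dataset(scn, 2000, 4, return_latent=True)
        case_src = latent[data.phenotype == 1]
        assert np.mean(case_src == 0) == pytest.approx(0.7, abs=0.01)
        assert (latent[data.phenotype == 0] == -1).all()

    def test_seeded_bit_reproducibility(self):
        scn = SimulationScenario(
            type="C", model_pair_1=MODELS["Model1"], model_pair_2=MODELS["Model2"]
        )
        a = simulate_dataset(scn, 200, 5)
        b = simulate_dataset(scn, 200, 5)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)


class TestPowerStudy:
    def test_single_replicate_binary_outcome(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        res = power_study(
            scn, 200, reps=1, methods=("pChi",), B=100, B_j=30, rng_seed=0
        )
        assert res.rejection_rate("pChi", (0, 1)) in (0.0, 1.0)

    def test_table_columns(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        res = power_study(
            scn, 200, reps=2, methods=("pOR", "MDR"), B=100, B_j=30,
            rng_seed=1, mdr_permutations=30,
        )
        assert list(res.table.columns) == [
            "method", "scenario", "model", "n", "power_pair12",
            "power_pair45", "type1",
        ]
        assert set(res.table["method"]) == {"pOR", "MDR"}

    def test_strong_signal_detected_and_nulls_spared(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        res = power_study(
            scn, 300, reps=8, methods=("pChi",), B=400, B_j=50, rng_seed=2
        )
        assert res.rejection_rate("pChi", (0, 1)) == 1.0
        assert res.type_one_error("pChi") <= 0.15

    def test_heterogeneity_has_no_pure_null_pair(self):
        scn = SimulationScenario(
            type="B", model_pair_1=MODELS["Model1"], model_pair_2=MODELS["Model2"]
        )
        res = power_study(
            scn, 200, reps=1, methods=("pOR",), B=50, B_j=20, rng_seed=3
        )
        assert np.isnan(res.type_one_error("pOR"))

    def test_unknown_method_rejected(self):
        scn = SimulationScenario(type="A", model_pair_1=MODELS["Model1"])
        with pytest.raises(ValueError):
            power_study(scn, 200, reps=1, methods=("pXYZ",))
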