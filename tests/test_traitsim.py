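"""QTN selection, genetic values, and heritability calibration."""

import numpy as np
import pytest

import gscross as g
from gscross.popsim import GenotypeMatrix
from gscross.traitsim import QTNSet


def make_geno(values):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix(
        values=values,
        coding="discrete_012",
        individual_ids=[f"i{r}" for r in range(values.shape[0])],
        marker_ids=[f"m{c}" for c in range(values.shape[1])],
    )


class TestSelectQtns:
    def test_shared_scenario_identical_sets_and_effects(self):
        arch = g.select_qtns("S.QTN", 356, "A20D0E0", seed=0)
        a, b = arch.panel_a, arch.panel_b
        assert len(np.intersect1d(a.additive_idx, b.additive_idx)) == 20
        np.testing.assert_array_equal(a.additive_eff, b.additive_eff)

    def test_partial_scenario_half_shared(self):
        arch = g.select_qtns("P.QTN", 356, "A20D0E0", seed=1)
        shared = np.intersect1d(arch.panel_a.additive_idx, arch.panel_b.additive_idx)
        assert len(shared) == 10

    def test_disjoint_scenarios(self):
        for scen in ("D.QTN", "D.QTN.Msi", "D.QTN.Msa"):
            arch = g.select_qtns(scen, 356, "A20D4E0", seed=2)
            all_a = np.concatenate([arch.panel_a.additive_idx, arch.panel_a.dominance_idx])
            all_b = np.concatenate([arch.panel_b.additive_idx, arch.panel_b.dominance_idx])
            assert len(np.intersect1d(all_a, all_b)) == 0

    def test_large_small_effect_ranges(self):
        arch = g.select_qtns("D.QTN.Msi", 356, "A20D0E0", seed=3, signed_effects=False)
        assert np.all((arch.panel_a.additive_eff >= 0.5) & (arch.panel_a.additive_eff <= 0.99))
        assert np.all((arch.panel_b.additive_eff >= 0.0) & (arch.panel_b.additive_eff <= 0.25))
        mirror = g.select_qtns("D.QTN.Msa", 356, "A20D0E0", seed=3, signed_effects=False)
        assert np.all(np.abs(mirror.panel_b.additive_eff) >= 0.5)

    def test_signed_effects_keep_magnitude_range(self):
        arch = g.select_qtns("D.QTN.Msi", 356, "A20D0E0", seed=4, signed_effects=True)
        mags = np.abs(arch.panel_a.additive_eff)
        assert np.all((mags >= 0.5) & (mags <= 0.99))
        assert (arch.panel_a.additive_eff < 0).any()

    def test_architecture_counts(self):
        arch = g.select_qtns("S.QTN", 356, "A20D4E0", seed=5)
        assert len(arch.panel_a.additive_eff) == 20
        assert len(arch.panel_a.dominance_eff) == 4
        assert len(arch.panel_a.epistasis_eff) == 0
        epi = g.select_qtns("S.QTN", 356, "A20D0E4", seed=5)
        assert epi.panel_a.epistasis_pairs.shape == (2, 2)
        assert len(epi.panel_a.dominance_eff) == 0

    def test_loci_disjoint_within_panel(self):
        arch = g.select_qtns("D.QTN", 356, "A20D0E4", seed=6)
        loci = np.concatenate([arch.panel_a.additive_idx,
                               arch.panel_a.epistasis_pairs.ravel()])
        assert len(np.unique(loci)) == len(loci)

    def test_scenario_aliases_and_errors(self):
        assert g.select_qtns("1", 356, seed=0).scenario == "S.QTN"
        with pytest.raises(ValueError):
            g.select_qtns("X.QTN", 356, seed=0)
        with pytest.raises(ValueError):
            g.select_qtns("D.QTN", 30, seed=0)  # not enough markers


class TestGeneticValue:
    def test_no_segregation_constant(self):
        geno = make_geno(np.full((4, 5), 2.0))
        qtns = QTNSet(np.array([0, 1]), np.array([0.3, 0.7]),
                      np.empty(0, int), np.empty(0),
                      np.empty((0, 2), int), np.empty(0))
        gv = g.genetic_value(geno, qtns)
        assert np.ptp(gv) == 0

    def test_single_additive_identity(self):
        geno = make_geno([[0, 1], [1, 0], [2, 2]])
        qtns = QTNSet(np.array([0]), np.array([1.0]),
                      np.empty(0, int), np.empty(0),
                      np.empty((0, 2), int), np.empty(0))
        np.testing.assert_array_equal(g.genetic_value(geno, qtns), [-1.0, 0.0, 1.0])

    def test_hand_computed_with_dominance_and_epistasis(self):
        # 3 individuals x 4 markers; oracle computed by hand with
        # a = (0.5, -0.2) at markers 0,1; d = 0.3 at marker 2;
        # w = 0.4 on pair (0, 3)
        geno = make_geno([[0, 1, 1, 2], [2, 2, 0, 0], [1, 0, 2, 1]])
        qtns = QTNSet(
            additive_idx=np.array([0, 1]), additive_eff=np.array([0.5, -0.2]),
            dominance_idx=np.array([2]), dominance_eff=np.array([0.3]),
            epistasis_pairs=np.array([[0, 3]]), epistasis_eff=np.array([0.4]),
        )
        # ind0: a: 0.5*(-1) + (-0.2)*0 = -0.5; d: het at m2 -> +0.3; e: (-1)(1)*0.4 = -0.4
        # ind1: a: 0.5*1 + (-0.2)*1 = 0.3;  d: 0;                e: (1)(-1)*0.4 = -0.4
        # ind2: a: 0.5*0 + (-0.2)*(-1) = 0.2; d: 0;              e: 0
        np.testing.assert_allclose(
            g.genetic_value(geno, qtns), [-0.6, -0.1, 0.2], atol=1e-12
        )

    def test_index_out_of_range(self):
        geno = make_geno([[0, 1], [1, 0]])
        qtns = QTNSet(np.array([5]), np.array([1.0]),
                      np.empty(0, int), np.empty(0),
                      np.empty((0, 2), int), np.empty(0))
        with pytest.raises(IndexError):
            g.genetic_value(geno, qtns)

    def test_permutation_equivariance(self, species_pair_small):
        panel, _ = species_pair_small
        arch = g.select_qtns("S.QTN", panel.genotypes.n_markers, seed=7)
        gv = g.genetic_value(panel.genotypes, arch.panel_a)
        perm = np.random.default_rng(0).permutation(panel.n_individuals)
        permuted = make_geno(panel.genotypes.values[perm])
        np.testing.assert_allclose(g.genetic_value(permuted, arch.panel_a), gv[perm])


class TestNoiseCalibration:
    def test_h2_one_is_noiseless(self, rng):
        gv = rng.normal(size=50)
        trait = g.add_noise_to_target_h2(gv, 1.0, seed=0)
        np.testing.assert_array_equal(trait.phenotypes, gv)
        assert trait.realized_h2 == 1.0

    def test_degenerate_trait_rejected(self):
        with pytest.raises(g.DegenerateTraitError):
            g.add_noise_to_target_h2(np.zeros(10), 0.5, seed=0)

    def test_invalid_target(self, rng):
        with pytest.raises(ValueError):
            g.add_noise_to_target_h2(rng.normal(size=10), 0.0, seed=0)

    def test_realized_h2_concentrates_with_n(self, rng):
        spread = []
        for n in (100, 300, 1000):
            gv = rng.normal(size=n)
            h2 = [g.add_noise_to_target_h2(gv, 0.6, seed=s).realized_h2 for s in range(40)]
            spread.append(np.std(h2))
        assert spread[2] < spread[0]
        assert abs(np.mean(h2) - 0.6) < 0.03


class TestTraitSuite:
    def test_additive_only_architecture(self, species_pair_small, family_small):
        pa, pb = species_pair_small
        suite = g.simulate_trait_suite(pa, pb, family_small, "S.QTN", "A20D0E0", seed=8)
        arch = suite["architecture"]
        assert len(arch.panel_a.dominance_eff) == 0
        assert len(arch.panel_a.epistasis_eff) == 0
        assert len(suite["families"]) == len(family_small)

    def test_shared_scenario_same_genetic_values(self, species_pair_small, family_small):
        """Under the fully shared scenario, both panels' QTN sets give identical
        genetic values on a common genotype matrix, and so does the F2 union."""
        pa, pb = species_pair_small
        suite = g.simulate_trait_suite(pa, pb, family_small, "S.QTN", seed=9)
        arch = suite["architecture"]
        gv_a = g.genetic_value(pa.genotypes, arch.panel_a)
        gv_b = g.genetic_value(pa.genotypes, arch.panel_b)
        gv_u = g.genetic_value(pa.genotypes, arch.union())
        np.testing.assert_allclose(gv_a, gv_b)
        np.testing.assert_allclose(gv_a, gv_u)

    def test_deterministic(self, species_pair_small, family_small):
        pa, pb = species_pair_small
        s1 = g.simulate_trait_suite(pa, pb, family_small, "P.QTN", seed=10)
        s2 = g.simulate_trait_suite(pa, pb, family_small, "P.QTN", seed=10)
        np.testing.assert_array_equal(s1["panel_a"].phenotypes, s2["panel_a"].phenotypes)
        np.testing.assert_array_equal(
            s1["families"][1].phenotypes, s2["families"][1].phenotypes
        )

    def test_degenerate_family_names_culprit(self, species_pair_small, map_small):
        from gscross.meiosis import PhasedIndividual

        pa, pb = species_pair_small
        # family from two identical fully homozygous founders: nothing segregates
        hom = PhasedIndividual(np.zeros((2, map_small.n_markers), dtype=np.uint8))
        fam = g.make_f2_family(hom, hom, map_small, n_f1=4, n_f2=10, seed=0,
                               family_id="degenerate_fam")
        with pytest.raises(g.DegenerateTraitError, match="degenerate_fam"):
            g.simulate_trait_suite(pa, pb, [fam], "S.QTN", seed=11)
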