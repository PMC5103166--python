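import numpy as np
import pandas as pd
import pytest

from nirseed import qtl
from nirseed import synthetic as syn
from nirseed.io import GeneticMap, PhenotypeTable, RILPopulation
from oracles import single_marker_lod


def _phen(pop, values, trait="trait"):
    return PhenotypeTable(pd.DataFrame(
        {"line_id": pop.line_ids, "trait": trait, "value": values}
    ))


@pytest.fixture(scope="module")
def pop164():
    return syn.simulate_ril_population(syn.default_map(), 164, seed=20)


class TestGenotypeProbabilities:
    def test_observed_marker_probability_is_genotype(self, two_chrom_map):
        g = pd.DataFrame(
            {"m1a": [1.0, 0.0], "m1b": [1.0, 1.0], "m1c": [0.0, 0.0],
             "m2a": [1.0, 0.0], "m2b": [0.0, 1.0]},
            index=["L1", "L2"],
        )
        pop = RILPopulation(two_chrom_map, g)
        chroms, positions, P = qtl.genotype_probabilities(pop, step=5.0)
        at = dict(zip(zip(chroms, positions), P.T))
        np.testing.assert_array_equal(at[("1", 0.0)], [1.0, 0.0])
        np.testing.assert_array_equal(at[("1", 10.0)], [1.0, 1.0])

    def test_midpoint_between_concordant_markers_stays_near(self):
        gmap = GeneticMap(["1"], {"1": ["a", "b"]}, {"1": np.array([0.0, 2.0])})
        pop = RILPopulation(gmap, pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["L1"]))
        from nirseed.qtl import _prob_b_at

        p = _prob_b_at(pop.genotypes.to_numpy(), np.array([0.0, 2.0]), 1.0)
        assert p[0] <= 0.01

    def test_midpoint_between_discordant_markers_is_half(self):
        gmap = GeneticMap(["1"], {"1": ["a", "b"]}, {"1": np.array([0.0, 20.0])})
        pop = RILPopulation(gmap, pd.DataFrame({"a": [0.0], "b": [1.0]}, index=["L1"]))
        from nirseed.qtl import _prob_b_at

        p = _prob_b_at(pop.genotypes.to_numpy(), np.array([0.0, 20.0]), 10.0)
        assert p[0] == pytest.approx(0.5)

    def test_missing_genotype_conditions_on_flanks(self):
        gmap = GeneticMap(["1"], {"1": ["a", "b", "c"]},
                          {"1": np.array([0.0, 5.0, 10.0])})
        pop = RILPopulation(
            gmap,
            pd.DataFrame({"a": [1.0], "b": [np.nan], "c": [1.0]}, index=["L1"]),
        )
        _, positions, P = qtl.genotype_probabilities(pop, step=5.0)
        p_at_5 = P[0][np.where(positions == 5.0)[0][0]]
        assert p_at_5 > 0.95  # flanked by two B alleles 5 cM away each


class TestIntervalMapping:
    def test_lod_at_marker_matches_closed_form(self, pop164):
        rng = np.random.default_rng(21)
        x = 2.0 * pop164.genotypes["m3_45"].to_numpy() - 1.0
        y = 1.0 * x + rng.standard_normal(164)
        curve = qtl.interval_mapping(pop164, _phen(pop164, y))
        at = curve.to_frame().set_index(["chr", "pos_cM"])
        lod_pkg = at.loc[("3", 45.0), "lod"]
        assert lod_pkg == pytest.approx(single_marker_lod(y, x), rel=1e-10)

    def test_null_phenotype_max_lod_below_threshold(self, pop164):
        rng = np.random.default_rng(22)
        y = rng.standard_normal(164)
        cfg = qtl.ScanConfig(n_permutations=200, seed=23)
        curve = qtl.interval_mapping(pop164, _phen(pop164, y), cfg)
        thr = qtl.permutation_threshold(pop164, _phen(pop164, y), cfg)
        assert curve.max_lod() < max(thr, 4.0)

    def test_constant_phenotype_rejected(self, pop164):
        with pytest.raises(ValueError):
            qtl.interval_mapping(pop164, _phen(pop164, np.ones(164)))

    def test_planted_qtl_peak_found(self, pop164):
        phen, _ = syn.simulate_ril_phenotypes(
            pop164, [("4", 36.7, 1.61)], residual_sd=3.7, seed=24
        )
        curve = qtl.interval_mapping(pop164, phen)
        i = int(np.argmax(curve.lod))
        assert curve.chrom[i] == "4"
        assert abs(curve.pos_cM[i] - 36.7) <= 10.0


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, pop164):
        rng = np.random.default_rng(25)
        phen = _phen(pop164, rng.standard_normal(164))
        cfg = qtl.ScanConfig(n_permutations=200, seed=26)
        assert qtl.permutation_threshold(pop164, phen, cfg) == qtl.permutation_threshold(
            pop164, phen, cfg
        )

    def test_larger_genome_higher_threshold(self):
        rng = np.random.default_rng(27)
        one = syn.simulate_ril_population(
            syn.default_map(n_chromosomes=1), 120, seed=28
        )
        five = syn.simulate_ril_population(
            syn.default_map(n_chromosomes=5), 120, seed=28
        )
        y = rng.standard_normal(120)
        cfg = qtl.ScanConfig(n_permutations=300, seed=29)
        t1 = qtl.permutation_threshold(one, _phen(one, y), cfg)
        t5 = qtl.permutation_threshold(five, _phen(five, y), cfg)
        assert t5 > t1

    def test_band_and_linear_invariance(self, pop164):
        rng = np.random.default_rng(30)
        y = rng.standard_normal(164)
        cfg = qtl.ScanConfig(n_permutations=300, seed=31)
        thr = qtl.permutation_threshold(pop164, _phen(pop164, y), cfg)
        assert 2.0 <= thr <= 4.0
        thr2 = qtl.permutation_threshold(pop164, _phen(pop164, 3.0 * y + 10.0), cfg)
        assert thr2 == pytest.approx(thr, rel=1e-10)


class TestMQM:
    def test_no_cofactors_reduces_to_interval_mapping(self, pop164):
        rng = np.random.default_rng(32)
        phen = _phen(pop164, rng.standard_normal(164))
        im = qtl.interval_mapping(pop164, phen)
        mqm = qtl.mqm_scan(pop164, phen, [])
        np.testing.assert_allclose(mqm.lod, im.lod, atol=1e-8)

    def test_cofactor_excluded_near_its_own_position(self, pop164):
        """LOD at the cofactor's own location must not condition on itself:
        it stays equal to the plain IM LOD there."""
        phen, _ = syn.simulate_ril_phenotypes(
            pop164, [("2", 30.0, 1.5)], residual_sd=2.5, seed=33
        )
        im = qtl.interval_mapping(pop164, phen)
        mqm = qtl.mqm_scan(pop164, phen, ["m2_30"])
        sel = (mqm.chrom == "2") & (np.abs(mqm.pos_cM - 30.0) < 1e-9)
        im_sel = (im.chrom == "2") & (np.abs(im.pos_cM - 30.0) < 1e-9)
        assert mqm.lod[sel][0] == pytest.approx(im.lod[im_sel][0], rel=1e-8)

    def test_background_control_raises_lod_at_second_qtl(self):
        wins = 0
        reps = 10
        for s in range(reps):
            pop = syn.simulate_ril_population(syn.default_map(), 164, seed=40 + s)
            phen, _ = syn.simulate_ril_phenotypes(
                pop, [("1", 30.0, 1.5), ("3", 50.0, 1.2)], residual_sd=2.0,
                seed=60 + s,
            )
            im = qtl.interval_mapping(pop, phen)
            mqm = qtl.mqm_scan(pop, phen, ["m1_30"])
            sel = (im.chrom == "3") & (np.abs(im.pos_cM - 50.0) < 1e-9)
            wins += mqm.lod[sel][0] >= im.lod[sel][0]
        assert wins >= 0.8 * reps

    def test_collinear_cofactor_dropped_with_warning(self, pop164):
        rng = np.random.default_rng(34)
        phen = _phen(pop164, rng.standard_normal(164))
        gmap = pop164.map
        dup_map = GeneticMap(
            ["1"], {"1": ["a", "b"]}, {"1": np.array([0.0, 0.0])}
        )
        g = pop164.genotypes[["m1_0"]].copy()
        dup = RILPopulation(dup_map, pd.DataFrame(
            {"a": g["m1_0"].to_numpy(), "b": g["m1_0"].to_numpy()},
            index=pop164.line_ids,
        ))
        with pytest.warns(UserWarning, match="collinear"):
            qtl.mqm_scan(dup, phen, ["a", "b"])


class TestDetectQTL:
    def _curve(self, lods, step=1.0, chrom="1"):
        pos = np.arange(len(lods), dtype=float) * step
        return qtl.LodCurve(np.array([chrom] * len(lods), dtype=object), pos,
                            np.asarray(lods, float))

    def test_below_threshold_empty(self):
        curve = self._curve(np.full(50, 1.0))
        assert qtl.detect_qtl(curve, 3.0) == []

    def test_single_clean_peak(self):
        lods = np.exp(-0.5 * ((np.arange(80) - 40.0) / 6.0) ** 2) * 6.0
        res = qtl.detect_qtl(self._curve(lods), 3.0)
        assert len(res) == 1
        assert res[0].pos_cM == 40.0
        assert res[0].ci_lo <= 40.0 <= res[0].ci_hi

    def test_two_distant_peaks_on_one_chromosome(self):
        """Two peaks ~58 cM apart separated by a deep valley are distinct."""
        x = np.arange(0.0, 71.0)
        lods = (4.6 * np.exp(-0.5 * ((x - 6.0) / 5.0) ** 2)
                + 7.7 * np.exp(-0.5 * ((x - 64.0) / 5.0) ** 2))
        res = qtl.detect_qtl(self._curve(lods), 3.0)
        assert len(res) == 2
        assert sorted(round(r.pos_cM) for r in res) == [6, 64]

    def test_support_intervals_never_overlap(self):
        x = np.arange(0.0, 71.0)
        lods = (5.0 * np.exp(-0.5 * ((x - 20.0) / 8.0) ** 2)
                + 5.5 * np.exp(-0.5 * ((x - 50.0) / 8.0) ** 2))
        res = qtl.detect_qtl(self._curve(lods), 3.0)
        if len(res) == 2:
            a, b = sorted(res, key=lambda r: r.pos_cM)
            assert a.ci_hi < b.ci_lo


class TestFitQTLModel:
    def test_noise_free_exact_recovery(self):
        pop = syn.simulate_ril_population(syn.default_map(), 80, seed=70)
        phen, _ = syn.simulate_ril_phenotypes(
            pop, [("2", 15.0, 1.7)], residual_sd=0.0, seed=71
        )
        effects, r2, total = qtl.fit_qtl_model(pop, phen, [("2", 15.0)])
        assert effects[0] == pytest.approx(1.7, abs=1e-10)
        assert total == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_qtl_r2_additivity(self):
        """On a balanced two-marker factorial the drop-one R^2 values sum to
        the total model R^2."""
        gmap = GeneticMap(
            ["1", "2"], {"1": ["a"], "2": ["b"]},
            {"1": np.array([0.0]), "2": np.array([0.0])},
        )
        reps = 10
        g1 = np.tile([0.0, 0.0, 1.0, 1.0], reps)
        g2 = np.tile([0.0, 1.0, 0.0, 1.0], reps)
        lines = [f"L{i}" for i in range(4 * reps)]
        pop = RILPopulation(gmap, pd.DataFrame({"a": g1, "b": g2}, index=lines))
        rng = np.random.default_rng(73)
        y = (2 * g1 - 1) + 0.7 * (2 * g2 - 1) + 0.3 * rng.standard_normal(4 * reps)
        phen = _phen(pop, y)
        _, r2, total = qtl.fit_qtl_model(pop, phen, [("1", 0.0), ("2", 0.0)])
        assert abs(r2.sum() - total) < 1e-8

    def test_collinear_positions_rejected(self):
        gmap = GeneticMap(["1"], {"1": ["a", "b"]}, {"1": np.array([0.0, 0.0])})
        pop = syn.simulate_ril_population(gmap, 50, seed=74)
        phen, _ = syn.simulate_ril_phenotypes(pop, [("1", 0.0, 1.0)], 1.0, seed=75)
        with pytest.raises(ValueError, match="collinear"):
            qtl.fit_qtl_model(pop, phen, [("1", 0.0), ("1", 0.0)])


class TestMapQTLWorkflow:
    def test_two_pass_workflow_recovers_planted_qtl(self, pop164):
        phen, _ = syn.simulate_ril_phenotypes(
            pop164, [("4", 36.7, 1.61), ("3", 63.0, 1.28)], residual_sd=3.0,
            seed=76,
        )
        cfg = qtl.ScanConfig(n_permutations=200, seed=77)
        out = qtl.map_qtl(pop164, phen, cfg)
        assert out["threshold"] > 2.0
        found = {(r.chrom, round(r.pos_cM, -1)) for r in out["qtl"]}
        assert ("4", 40.0) in found
        for r in out["qtl"]:
            assert r.additive_effect is not None and r.r2_pct is not None
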