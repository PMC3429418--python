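"""Generators: marker panels, Mendelian transmission, dropout, damage scoring."""

import numpy as np
import pandas as pd
import pytest

from herbdiv.simulate import (
    DAMAGE_CLASS_LABELS,
    DAMAGE_CLASS_MIDPOINTS,
    DEATH_RATE_DEFAULT,
    FAIL_RATE_DEFAULT,
    GENOTYPE_COLUMNS,
    HerbivoryEffectSpec,
    LocusModel,
    apply_dropout,
    classify_damage,
    make_locus_panel,
    simulate_dyads,
    simulate_genotypes,
    simulate_herbivory,
)


class TestLocusModel:
    def test_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LocusModel("L", (1, 2), np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="positive"):
            LocusModel("L", (1, 2), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="duplicate"):
            LocusModel("L", (1, 1), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="equal length"):
            LocusModel("L", (1, 2, 3), np.array([0.5, 0.5]))

    def test_frequency_lookup(self):
        locus = LocusModel("L", (3, 7), np.array([0.25, 0.75]))
        assert locus.frequency_of(7) == 0.75
        with pytest.raises(KeyError):
            locus.frequency_of(4)

    def test_panel_shapes(self):
        panel = make_locus_panel(n_loci=5, n_alleles=7, seed=1)
        assert len(panel) == 5
        assert all(l.n_alleles == 7 for l in panel)
        assert all(abs(l.frequencies.sum() - 1.0) < 1e-12 for l in panel)

    def test_panel_allele_range(self):
        panel = make_locus_panel(n_loci=30, n_alleles=(6, 19), seed=3)
        counts = [l.n_alleles for l in panel]
        assert min(counts) >= 6 and max(counts) <= 19
        assert len(set(counts)) > 1

    def test_equifrequent(self, panel11):
        for locus in panel11:
            assert np.allclose(locus.frequencies, 1.0 / 11)


class TestGenotypes:
    def test_frame_contract(self, cohort, mating4):
        _, genotypes = cohort
        assert list(genotypes.columns) == GENOTYPE_COLUMNS
        assert set(genotypes["role"]) == {"mother", "offspring"}
        mothers = genotypes[genotypes["role"] == "mother"]
        assert set(mothers["individual_id"]) == set(mating4.family_names)
        # every individual typed at every locus
        per_ind = genotypes.groupby("individual_id").size()
        assert (per_ind == 11).all()

    def test_mendelian_maternal_allele(self, cohort):
        """Error-free offspring share an allele with their mother at every locus."""
        design, genotypes = cohort
        mothers = {
            (r["individual_id"], r["locus"]): {r["allele_1"], r["allele_2"]}
            for _, r in genotypes[genotypes["role"] == "mother"].iterrows()
        }
        off = genotypes[genotypes["role"] == "offspring"]
        for _, r in off.iterrows():
            mom = mothers[(r["family"], r["locus"])]
            assert {r["allele_1"], r["allele_2"]} & mom

    def test_alleles_from_locus_support(self, cohort, panel11):
        _, genotypes = cohort
        support = {l.locus_id: set(l.alleles) for l in panel11}
        for locus, grp in genotypes.groupby("locus"):
            calls = set(grp["allele_1"]) | set(grp["allele_2"])
            assert {int(a) for a in calls} <= support[locus]

    def test_failure_rate_blanks_whole_individuals(self, cohort, panel11, mating4):
        design, _ = cohort
        genotypes = simulate_genotypes(design, panel11, mating4, seed=9, failure_rate=0.3)
        off = genotypes[genotypes["role"] == "offspring"]
        per_ind_nan = off.groupby("individual_id")["allele_1"].apply(lambda s: s.isna().mean())
        assert set(np.round(per_ind_nan.unique(), 9)) <= {0.0, 1.0}
        assert 0.0 < per_ind_nan.mean() < 1.0

    def test_error_rate_localized(self, cohort, panel11, mating4):
        design, clean = cohort
        noisy = simulate_genotypes(
            design, panel11, mating4, seed=5, error_rate={"L03": 0.5}
        )
        diff = (noisy[["allele_1", "allele_2"]] != clean[["allele_1", "allele_2"]]).any(axis=1)
        assert set(noisy.loc[diff, "locus"]) == {"L03"}
        assert (noisy.loc[diff, "role"] == "offspring").all()

    def test_determinism(self, cohort, panel11, mating4):
        design, genotypes = cohort
        again = simulate_genotypes(design, panel11, mating4, seed=5)
        pd.testing.assert_frame_equal(genotypes, again)


class TestDyads:
    def test_shapes_and_kinds(self, panel11):
        for kind in ("full-sib", "half-sib", "unrelated"):
            g1, g2 = simulate_dyads(kind, 20, panel11, seed=4)
            assert g1.shape == g2.shape == (20, 11, 2)
        with pytest.raises(ValueError):
            simulate_dyads("cousins", 5, panel11, seed=4)

    def test_sibs_share_maternal_allele(self, panel11):
        g1, g2 = simulate_dyads("half-sib", 50, panel11, seed=8)
        shared = [
            bool(set(g1[d, j]) & set(g2[d, j]))
            for d in range(50)
            for j in range(11)
        ]
        # maternal transmission makes sharing far more common than the
        # unrelated baseline (1 - (10/11)^4 ~ 0.32); no exact guarantee per
        # locus because the shared mother may transmit different alleles
        assert np.mean(shared) > 0.6

    def test_full_sibs_more_similar_than_unrelated(self, panel11):
        def share(kind):
            g1, g2 = simulate_dyads(kind, 200, panel11, seed=13)
            return np.mean(
                [len(set(g1[d, j]) & set(g2[d, j])) for d in range(200) for j in range(11)]
            )

        assert share("full-sib") > share("half-sib") > share("unrelated")


class TestDropout:
    def test_rates_and_nesting(self):
        from herbdiv.design import MatingDesign, build_design

        design = build_design(20, MatingDesign(n_mothers=4), seed=1)
        out = apply_dropout(design, seed=3)
        assert not out.loc[~out["alive"], "genotyped"].any()
        assert out["alive"].mean() == pytest.approx(1 - DEATH_RATE_DEFAULT, abs=0.02)
        survivors = out[out["alive"]]
        assert survivors["genotyped"].mean() == pytest.approx(1 - FAIL_RATE_DEFAULT, abs=0.02)

    def test_rate_validation(self, cohort):
        design, _ = cohort
        with pytest.raises(ValueError):
            apply_dropout(design, death_rate=1.5)

    def test_zero_rates_noop(self, cohort):
        design, _ = cohort
        out = apply_dropout(design, death_rate=0.0, fail_rate=0.0)
        assert out["alive"].all() and out["genotyped"].all()


class TestDamageClasses:
    @pytest.mark.parametrize(
        "pct,label,score",
        [
            (0.0, "0", 0.0),
            (0.5, "1-5", 3.0),
            (5.0, "1-5", 3.0),
            (5.1, "6-15", 10.5),
            (15.0, "6-15", 10.5),
            (20.0, "16-25", 20.5),
            (25.0, "16-25", 20.5),
            (38.0, "26-50", 38.0),
            (50.0, "26-50", 38.0),
            (75.0, "51-75", 63.0),
            (76.0, ">76", 88.0),
            (100.0, ">76", 88.0),
        ],
    )
    def test_scalar_edges(self, pct, label, score):
        assert classify_damage(pct) == (label, score)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        pcts = rng.uniform(0, 100, size=200)
        labels, scores = classify_damage(pcts)
        for pct, lab, sc in zip(pcts, labels, scores):
            assert classify_damage(pct) == (lab, sc)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1, np.nan):
            with pytest.raises(ValueError):
                classify_damage(bad)

    def test_midpoints_table(self):
        assert len(DAMAGE_CLASS_LABELS) == len(DAMAGE_CLASS_MIDPOINTS) == 7
        assert list(DAMAGE_CLASS_MIDPOINTS) == [0.0, 3.0, 10.5, 20.5, 38.0, 63.0, 88.0]


class TestHerbivory:
    def test_output_contract(self, cohort):
        design, _ = cohort
        fx = HerbivoryEffectSpec(
            family_means_monoculture={"MT1": 5.5, "MT2": 6.5, "MT3": 7.5, "MT4": 8.3}
        )
        pheno = simulate_herbivory(design, fx, seed=2)
        assert list(pheno.columns) == ["sapling_id", "height", "ecto_damage", "mine_count"]
        assert len(pheno) == len(design)
        assert (pheno["height"] > 0).all()
        assert pheno["ecto_damage"].between(0, 100).all()
        assert (pheno["mine_count"] >= 0).all()
        assert pheno["mine_count"].dtype.kind in "iu"

    def test_damage_is_mean_of_midpoints(self, cohort):
        design, _ = cohort
        pheno = simulate_herbivory(design, seed=2, n_leaves=1)
        # with one leaf the sapling score must itself be a class midpoint
        assert set(np.round(pheno["ecto_damage"], 6)) <= set(DAMAGE_CLASS_MIDPOINTS)

    def test_family_ranking_recovered(self):
        """With dominant family signal, monoculture damage orders with the means."""
        from herbdiv.design import MatingDesign, build_design

        design = build_design(30, MatingDesign(n_mothers=2), seed=6)
        fx = HerbivoryEffectSpec(
            family_means_monoculture={"MT1": 3.0, "MT2": 20.0},
            height_log_means={"MT1": 4.8, "MT2": 4.8},
            gd_slope=0.0,
            height_slope_ecto=0.0,
            block_sd=0.0,
            plot_sd=0.0,
        )
        pheno = simulate_herbivory(design, fx, seed=6)
        mono = design[design["gd"] == 1].merge(pheno, on="sapling_id")
        means = mono.groupby("family")["ecto_damage"].mean()
        assert means["MT2"] > means["MT1"] + 5

    def test_miner_height_association(self):
        from herbdiv.design import MatingDesign, build_design

        design = build_design(40, MatingDesign(n_mothers=2), seed=7)
        pheno = simulate_herbivory(design, seed=7)
        r = np.corrcoef(np.log(pheno["height"]), pheno["mine_count"])[0, 1]
        assert r > 0.1

    def test_unknown_family_rejected(self, cohort):
        design, _ = cohort
        fx = HerbivoryEffectSpec(family_means_monoculture={"MT1": 5.0})
        with pytest.raises(ValueError, match="families"):
            simulate_herbivory(design, fx, seed=1)

    def test_effect_spec_validation(self):
        with pytest.raises(ValueError):
            HerbivoryEffectSpec(leaf_sd=-1.0)
        with pytest.raises(ValueError):
            HerbivoryEffectSpec(family_means_monoculture={"MT1": 0.0})
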