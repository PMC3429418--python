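"""Additive diversity-effect partition: algebra, identities, inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbdiv.partition import (
    DEFAULT_DIRECTIONS,
    MixtureObservation,
    PartitionResult,
    partition_all,
    partition_anova,
    partition_mixture,
    partition_table,
    partition_tests,
    relative_forage,
)


def _obs(C, M, families=None):
    C = np.asarray(C, dtype=float)
    families = families or tuple(f"F{i}" for i in range(len(C)))
    return MixtureObservation("B1", "P1", tuple(families), C, np.asarray(M, dtype=float))


class TestAlgebra:
    def test_worked_example(self):
        """n=2, M=(6,8), C=(4,5): NGDE=2, CE=49/24, SE=-1/24."""
        res = partition_mixture(_obs([4.0, 5.0], [6.0, 8.0]))
        assert res.ngde == pytest.approx(2.0)
        assert res.ce == pytest.approx(2.0416666666667)
        assert res.se == pytest.approx(-0.0416666666667)
        assert res.rf_obs == pytest.approx([4 / 6, 5 / 8])
        assert res.delta_rc == pytest.approx([4 / 6 - 0.5, 5 / 8 - 0.5])

    def test_proportional_null_gives_zero(self):
        """C_i = M_i / n (no diversity effect) zeroes every component."""
        M = np.array([3.0, 7.0, 11.0])
        res = partition_mixture(_obs(M / 3, M))
        assert res.ngde == pytest.approx(0.0, abs=1e-12)
        assert res.ce == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_pure_complementarity(self):
        """Uniform relative overconsumption with equal M has no selection part."""
        M = np.array([5.0, 5.0])
        res = partition_mixture(_obs(1.2 * M / 2, M))
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.ce == pytest.approx(res.ngde)
        assert res.ngde > 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 50.0),
                st.floats(0.1, 50.0),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_additivity_identity(self, cm):
        C = [c for c, _ in cm]
        M = [m for _, m in cm]
        res = partition_mixture(_obs(C, M))
        assert res.ngde == pytest.approx(res.ce + res.se, abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.floats(0.0, 20.0), st.floats(0.5, 20.0)), min_size=2, max_size=4),
        st.floats(0.1, 10.0),
    )
    def test_scale_equivariance(self, cm, scale):
        """Scaling both C and M by a scalar scales all three components."""
        C = np.array([c for c, _ in cm])
        M = np.array([m for _, m in cm])
        base = partition_mixture(_obs(C, M))
        scaled = partition_mixture(_obs(scale * C, scale * M))
        assert scaled.ngde == pytest.approx(scale * base.ngde, rel=1e-9, abs=1e-9)
        assert scaled.ce == pytest.approx(scale * base.ce, rel=1e-9, abs=1e-9)
        assert scaled.se == pytest.approx(scale * base.se, rel=1e-9, abs=1e-9)

    def test_relative_forage(self):
        assert relative_forage(3.0, 6.0) == 0.5
        with pytest.raises(ZeroDivisionError):
            relative_forage(3.0, 0.0)

    def test_zero_monoculture_rejected(self):
        with pytest.raises(ZeroDivisionError):
            partition_mixture(_obs([1.0, 1.0], [2.0, 0.0]))

    def test_observation_validation(self):
        with pytest.raises(ValueError, match="2 families"):
            _obs([1.0], [2.0], families=("F0",))
        with pytest.raises(ValueError, match="align"):
            MixtureObservation("B", "P", ("a", "b"), np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="non-negative"):
            _obs([-1.0, 1.0], [2.0, 2.0])


class TestCohortPartition:
    def test_null_cohort_centres_on_zero(self, perfect_maternity):
        """With gd_slope=0 the mean NGDE over many mixtures is near zero."""
        from herbdiv.design import MatingDesign, build_design
        from herbdiv.simulate import HerbivoryEffectSpec, simulate_herbivory

        design = build_design(12, MatingDesign(n_mothers=2), seed=31)
        fx = HerbivoryEffectSpec(
            family_means_monoculture={"MT1": 5.5, "MT2": 8.3},
            height_log_means={"MT1": 4.8, "MT2": 4.86},
            gd_slope=0.0,
        )
        pheno = simulate_herbivory(design, fx, seed=31)
        results = partition_all(pheno, perfect_maternity(design), design)
        assert len(results) == 12  # one mixture plot per block
        ngde = np.array([r.ngde for r in results])
        assert abs(ngde.mean()) < 3 * ngde.std(ddof=1) / np.sqrt(len(ngde))

    def test_positive_gd_effect_detected(self, perfect_maternity):
        from herbdiv.design import MatingDesign, build_design
        from herbdiv.simulate import HerbivoryEffectSpec, simulate_herbivory

        design = build_design(25, MatingDesign(n_mothers=2), seed=33)
        fx = HerbivoryEffectSpec(
            family_means_monoculture={"MT1": 5.5, "MT2": 8.3},
            height_log_means={"MT1": 4.8, "MT2": 4.86},
            gd_slope=0.8,
            block_sd=0.05,
            plot_sd=0.05,
        )
        pheno = simulate_herbivory(design, fx, seed=33)
        results = partition_all(pheno, perfect_maternity(design), design)
        tests = partition_tests(results, scope="grand")
        ngde = next(t for t in tests if t.effect == "NGDE")
        assert ngde.mean > 0
        assert ngde.p_value < 0.05

    def test_excluded_saplings_ignored(self, perfect_maternity):
        from herbdiv.design import MatingDesign, build_design
        from herbdiv.simulate import simulate_herbivory, HerbivoryEffectSpec

        design = build_design(3, MatingDesign(n_mothers=2), seed=35)
        fx = HerbivoryEffectSpec(
            family_means_monoculture={"MT1": 5.5, "MT2": 8.3},
            height_log_means={"MT1": 4.8, "MT2": 4.86},
        )
        pheno = simulate_herbivory(design, fx, seed=35)
        maternity = perfect_maternity(design)
        # exclude one whole family's saplings in one mixture -> plot skipped
        mix_plot = design.loc[design["gd"] == 2, "plot"].iloc[0]
        drop = design[(design["plot"] == mix_plot) & (design["family"] == "MT1")][
            "sapling_id"
        ]
        maternity.loc[maternity["offspring_id"].isin(drop), "status"] = "excluded"
        results = partition_all(pheno, maternity, design)
        assert mix_plot not in {r.plot_id for r in results}
        assert len(results) == 2

    def test_partition_table_contract(self):
        res = partition_mixture(_obs([4.0, 5.0], [6.0, 8.0]))
        tab = partition_table([res])
        assert list(tab.columns) == [
            "block", "plot", "n", "families", "NGDE", "CE", "SE", "RF_obs", "dRC",
        ]
        assert tab.loc[0, "NGDE"] == pytest.approx(2.0)


def _fake_results(values, n=2):
    out = []
    for i, v in enumerate(values):
        out.append(
            PartitionResult(
                "B1", f"P{i}", n, tuple("ab"), v, v * 0.8, v * 0.2,
                np.zeros(2), np.zeros(2),
            )
        )
    return out


class TestInference:
    def test_one_sided_matches_scipy(self):
        from scipy import stats as sps

        vals = [0.5, 1.2, -0.3, 0.9, 0.7]
        tests = partition_tests(_fake_results(vals), scope="grand")
        ngde = next(t for t in tests if t.effect == "NGDE")
        t_ref = sps.ttest_1samp(vals, 0.0, alternative="greater")
        assert ngde.t_statistic == pytest.approx(t_ref.statistic)
        assert ngde.p_value == pytest.approx(t_ref.pvalue)
        assert ngde.df == len(vals) - 1
        se = next(t for t in tests if t.effect == "SE")
        se_ref = sps.ttest_1samp([v * 0.2 for v in vals], 0.0, alternative="less")
        assert se.p_value == pytest.approx(se_ref.pvalue)

    def test_direction_override(self):
        vals = [0.5, 1.2, 0.3, 0.9]
        up = partition_tests(_fake_results(vals), directions={"NGDE": 1, "CE": 1, "SE": 1})
        down = partition_tests(_fake_results(vals), directions={"NGDE": -1, "CE": -1, "SE": -1})
        for a, b in zip(up, down):
            assert a.p_value == pytest.approx(1.0 - b.p_value)

    def test_default_directions(self):
        assert DEFAULT_DIRECTIONS == {"NGDE": 1, "CE": 1, "SE": -1}

    def test_exact_null_degenerate_case(self):
        tests = partition_tests(_fake_results([0.0, 0.0, 0.0]), scope="grand")
        for t in tests:
            assert t.t_statistic == 0.0
            assert t.p_value == 0.5

    def test_constant_nonzero_raises(self):
        with pytest.raises(ZeroDivisionError):
            partition_tests(_fake_results([1.0, 1.0, 1.0]))

    def test_by_gd_scope_and_bad_scope(self):
        results = _fake_results([0.5, 1.0], n=2) + _fake_results([0.2, 0.4, 0.1], n=3)
        by_gd = partition_tests(results, scope="by_gd")
        assert {t.scope for t in by_gd} == {"GD=2", "GD=3"}
        with pytest.raises(ValueError):
            partition_tests(results, scope="per_block")
        with pytest.raises(ValueError, match=">= 2 mixtures"):
            partition_tests(_fake_results([1.0]), scope="grand")

    def test_anova_matches_pooled_t_square(self):
        """Two groups: one-way F equals the square of the pooled two-sample t."""
        from scipy import stats as sps

        a = [0.5, 1.0, 0.8, 1.3]
        b = [0.2, 0.4, 0.1]
        results = _fake_results(a, n=2) + _fake_results(b, n=3)
        tab = partition_anova(results)
        t_ref = sps.ttest_ind(a, b, equal_var=True)
        row = tab[tab["effect"] == "NGDE"].iloc[0]
        assert row["F"] == pytest.approx(t_ref.statistic**2)
        assert row["p_value"] == pytest.approx(t_ref.pvalue)

    def test_anova_needs_two_levels(self):
        with pytest.raises(ValueError):
            partition_anova(_fake_results([0.1, 0.2, 0.3], n=2))
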