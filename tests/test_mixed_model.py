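import numpy as np
import pandas as pd
import pytest

from ssgwas.mixed_model import (
    ModelSpec,
    VarianceComponents,
    build_design,
    em_reml,
    genetic_parameters,
    restricted_loglik,
    solve_mme,
)
from ssgwas.relationship import a_inverse, numerator_relationship
from ssgwas.synthetic import (
    SimulationConfig,
    complete_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    single_trait_model,
)


def trio_data(trio, farm=("f1", "f1", "f2")):
    table = pd.DataFrame(
        {"T1": [1.0, 2.0, 3.0], "farm": farm}, index=list(trio.ids)
    )
    spec = ModelSpec(traits=("T1",), fixed_effects=("farm",))
    design = build_design(table, spec, trio.ids)
    return table, spec, design


class TestBuildDesign:
    def test_two_farms_give_intercept_plus_one_column(self, trio):
        _, _, design = trio_data(trio)
        assert design.X.shape == (3, 2)
        assert design.x_columns == ("intercept", "farm[f2]")

    def test_single_level_factor_contributes_nothing(self, trio):
        _, _, design = trio_data(trio, farm=("f1", "f1", "f1"))
        assert design.X.shape == (3, 1)

    def test_full_rank_with_all_cells_filled(self):
        rng = np.random.default_rng(0)
        n = 40
        table = pd.DataFrame(
            {
                "T1": rng.normal(size=n),
                "farm": [f"f{i % 3}" for i in range(n)],
                "last_parity": [str(1 + i % 4) for i in range(n)],
            },
            index=[f"a{i}" for i in range(n)],
        )
        spec = ModelSpec(traits=("T1",), fixed_effects=("farm", "last_parity"))
        design = build_design(table, spec, tuple(table.index))
        expected_rank = 1 + (3 - 1) + (4 - 1)
        assert np.linalg.matrix_rank(design.X) == expected_rank

    def test_unseen_animal_rejected(self, trio):
        table = pd.DataFrame({"T1": [1.0], "farm": ["f1"]}, index=["ghost"])
        with pytest.raises(KeyError, match="ghost"):
            build_design(table, ModelSpec(traits=("T1",), fixed_effects=("farm",)), trio.ids)


class TestSolveMme:
    def test_gls_closed_form_on_trio(self, trio):
        table, spec, design = trio_data(trio)
        vc = VarianceComponents.single("T1", 0.4, 0.6)
        sol = solve_mme(design, a_inverse(trio), vc, table[["T1"]])
        A = numerator_relationship(trio).values
        V = design.Z @ A @ design.Z.T * 0.4 + np.eye(3) * 0.6
        Vi = np.linalg.inv(V)
        X, y = design.X, table["T1"].to_numpy()
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 0.4 * A @ design.Z.T @ Vi @ (y - X @ beta)
        assert np.abs(sol.beta["T1"].to_numpy() - beta).max() < 1e-8
        assert np.abs(sol.u["T1"].to_numpy() - u).max() < 1e-8

    def test_vanishing_additive_variance_shrinks_gebv_to_zero(self, trio):
        table, spec, design = trio_data(trio)
        vc = VarianceComponents.single("T1", 1e-10, 1.0)
        sol = solve_mme(design, a_inverse(trio), vc, table[["T1"]])
        assert np.abs(sol.u["T1"].to_numpy()).max() < 1e-6

    def test_unrelated_unphenotyped_animal_gets_zero(self, trio):
        from ssgwas.io_formats import Pedigree

        ped = Pedigree.from_records(
            [("s", "0", "0"), ("d", "0", "0"), ("k", "s", "d"), ("lone", "0", "0")]
        )
        table = pd.DataFrame(
            {"T1": [1.0, 2.0, 3.0], "farm": ["f1", "f1", "f2"]},
            index=["s", "d", "k"],
        )
        spec = ModelSpec(traits=("T1",), fixed_effects=("farm",))
        design = build_design(table, spec, ped.ids)
        sol = solve_mme(design, a_inverse(ped), VarianceComponents.single("T1", 0.4, 0.6), table[["T1"]])
        assert sol.u.loc["lone", "T1"] == pytest.approx(0.0, abs=1e-12)

    def test_mme_residual_check(self, trio):
        # plugging the solutions back into the Henderson system
        from ssgwas.mixed_model import _mme_parts, _stack_rhs

        table, spec, design = trio_data(trio)
        vc = VarianceComponents.single("T1", 0.4, 0.6)
        sol = solve_mme(design, a_inverse(trio), vc, table[["T1"]])
        C, sei, _ = _mme_parts(design, a_inverse(trio).values, vc)
        rhs = _stack_rhs(design, sei, table[["T1"]].to_numpy())
        theta = np.concatenate([sol.beta["T1"].to_numpy(), sol.u["T1"].to_numpy()])
        assert np.linalg.norm(C @ theta - rhs) < 1e-8 * np.linalg.norm(C)

    def test_multi_trait_diagonal_covariances_match_single_trait(self, trio):
        table, _, design = trio_data(trio)
        table["T2"] = [3.0, 1.0, 2.0]
        spec = ModelSpec(traits=("T1", "T2"), fixed_effects=("farm",))
        vc2 = VarianceComponents(
            traits=("T1", "T2"),
            sigma_a=np.diag([0.4, 0.2]),
            sigma_e=np.diag([0.6, 0.8]),
        )
        sol2 = solve_mme(design, a_inverse(trio), vc2, table[["T1", "T2"]])
        for trait, sa, se in (("T1", 0.4, 0.6), ("T2", 0.2, 0.8)):
            sol1 = solve_mme(
                design, a_inverse(trio), VarianceComponents.single(trait, sa, se), table[[trait]]
            )
            assert np.abs(sol2.u[trait].to_numpy() - sol1.u[trait].to_numpy()).max() < 1e-10


class TestEmReml:
    def _simulated(self, seed, h2=0.25, nf=200, ng=1, opm=4, drop_record=False):
        cfg = SimulationConfig(
            seed=seed,
            n_founders=nf,
            n_generations=ng,
            offspring_per_mating=opm,
            n_chromosomes=1,
            markers_per_chromosome=2,
            traits=single_trait_model(h2),
        )
        ped = simulate_pedigree(cfg)
        table, _ = simulate_phenotypes(ped, complete_genotypes(ped, cfg), cfg)
        if drop_record:
            table = table.iloc[1:]
        spec = ModelSpec(traits=("T1",), fixed_effects=("farm", "last_parity"))
        design = build_design(table, spec, ped.ids)
        return ped, table, design

    def test_null_additive_variance_stays_near_boundary(self):
        ped, table, design = self._simulated(0, h2=0.0, nf=150)
        sp = float(np.var(table["T1"]))
        res = em_reml(
            design,
            a_inverse(ped),
            table[["T1"]],
            VarianceComponents.single("T1", 0.5 * sp, 0.5 * sp),
            max_rounds=5000,
            tol=1e-9,
        )
        assert res.varcomp.sigma_a[0, 0] <= 0.02 * res.varcomp.sigma_p[0, 0]

    def test_loglik_nondecreasing_dense_path(self):
        ped, table, design = self._simulated(2, nf=40, ng=1, opm=2, drop_record=True)
        A = numerator_relationship(ped).values
        res = em_reml(
            design,
            a_inverse(ped),
            table[["T1"]],
            VarianceComponents.single("T1", 0.6, 0.6),
            max_rounds=25,
            tol=0.0,
        )
        lls = [
            restricted_loglik(
                design,
                A,
                VarianceComponents(traits=("T1",), sigma_a=sa, sigma_e=se),
                table[["T1"]],
            )
            for sa, se in res.history
        ]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_canonical_and_dense_paths_agree(self):
        ped, table, design = self._simulated(5, nf=60, ng=1, opm=2)
        from ssgwas.mixed_model import _em_reml_dense, _is_identity_incidence

        assert _is_identity_incidence(design)
        start = VarianceComponents.single("T1", 0.5, 0.5)
        fast = em_reml(design, a_inverse(ped), table[["T1"]], start, max_rounds=60, tol=0.0)
        slow = _em_reml_dense(
            design, a_inverse(ped).values, table[["T1"]].to_numpy(), start, 60, 0.0
        )
        assert fast.varcomp.sigma_a[0, 0] == pytest.approx(
            slow.varcomp.sigma_a[0, 0], rel=1e-6
        )
        assert fast.varcomp.sigma_e[0, 0] == pytest.approx(
            slow.varcomp.sigma_e[0, 0], rel=1e-6
        )

    def test_reference_level_choice_does_not_move_estimates(self):
        ped, table, design = self._simulated(6, nf=60, ng=1, opm=2)
        spec = ModelSpec(traits=("T1",), fixed_effects=("farm", "last_parity"))
        # reversing record order changes each factor's first-observed level
        table_rev = table.iloc[::-1]
        design_rev = build_design(table_rev, spec, ped.ids)
        start = VarianceComponents.single("T1", 0.5, 0.5)
        r1 = em_reml(design, a_inverse(ped), table[["T1"]], start, tol=1e-10)
        r2 = em_reml(design_rev, a_inverse(ped), table_rev[["T1"]], start, tol=1e-10)
        assert r1.varcomp.sigma_a[0, 0] == pytest.approx(
            r2.varcomp.sigma_a[0, 0], rel=1e-5
        )

    def test_nonconvergence_is_flagged_not_silent(self):
        ped, table, design = self._simulated(7, nf=40, ng=1, opm=2)
        res = em_reml(
            design,
            a_inverse(ped),
            table[["T1"]],
            VarianceComponents.single("T1", 0.5, 0.5),
            max_rounds=2,
            tol=1e-12,
        )
        assert res.converged is False
        assert res.n_rounds == 2


class TestGeneticParameters:
    @pytest.mark.parametrize(
        "sa2, se2, h2",
        [(0.18, 1.78, 0.09), (115.60, 343.50, 0.25)],
    )
    def test_heritability_arithmetic(self, sa2, se2, h2):
        params = genetic_parameters(VarianceComponents.single("X", sa2, se2))
        assert round(float(params.h2.iloc[0]), 2) == h2

    def test_diagonal_covariances_give_zero_correlations(self):
        vc = VarianceComponents(
            traits=("a", "b"), sigma_a=np.diag([1.0, 2.0]), sigma_e=np.diag([1.0, 1.0])
        )
        params = genetic_parameters(vc)
        assert params.r_g.iloc[0, 1] == 0.0
        assert params.r_p.iloc[0, 1] == 0.0

    def test_zero_variance_flagged_undefined(self):
        vc = VarianceComponents(
            traits=("a", "b"), sigma_a=np.diag([0.0, 2.0]), sigma_e=np.diag([1.0, 1.0])
        )
        params = genetic_parameters(vc)
        assert np.isnan(params.r_g.iloc[0, 1])

    def test_h2_plus_residual_fraction_is_one(self):
        vc = VarianceComponents.single("X", 0.3, 0.7)
        params = genetic_parameters(vc)
        resid_frac = vc.sigma_e[0, 0] / vc.sigma_p[0, 0]
        assert float(params.h2.iloc[0]) + resid_frac == 1.0
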