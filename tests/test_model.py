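import numpy as np
import pandas as pd
import pytest

from ssgblup.model import (
    AnimalModel,
    ModelSpec,
    build_design,
    run_model,
    single_step_kernel,
    solve_mme,
)
from ssgblup.pedigree import Pedigree, RelationshipKind
from ssgblup.simulate import SimConfig, simulate_dataset

from conftest import random_pedigree


def phen_for(ped, seed=0, trait="y", n_cg=2, n_par=1, animals=None):
    rng = np.random.default_rng(seed)
    animals = animals if animals is not None else list(ped.ids)
    return pd.DataFrame(
        {
            "animal": animals,
            trait: rng.standard_normal(len(animals)),
            "contemporary_group": rng.integers(n_cg, size=len(animals)),
            "parity_class": rng.integers(1, n_par + 1, size=len(animals)),
        }
    )


class TestBuildDesign:
    def test_drop_first_coding_shapes(self, trio_frame):
        ped = Pedigree(trio_frame)
        df = pd.DataFrame(
            {
                "animal": ["s", "d", "o", "o"],
                "y": [1.0, 2.0, 3.0, 4.0],
                "contemporary_group": ["a", "a", "b", "b"],
                "parity_class": [1, 1, 1, 1],
            }
        )
        d = build_design(df, ped, ModelSpec("y", var_ratio=1.0))
        assert d.X.shape == (4, 2)  # intercept + 1 CG dummy; 1-level parity drops out
        assert np.linalg.matrix_rank(d.X) == 2

    def test_single_record_z_row(self, trio_frame):
        ped = Pedigree(trio_frame)
        df = pd.DataFrame({"animal": ["o"], "y": [1.0]})
        d = build_design(df, ped, ModelSpec("y", fixed_effects=(), var_ratio=1.0))
        row = d.Z.toarray()[0]
        assert row.sum() == 1 and row[ped.id_index["o"]] == 1

    def test_study_scale_column_count(self):
        # 1691 records, 142 contemporary groups, 4 parity classes
        ped = random_pedigree(1, n_founders=100, n_extra=1700)
        rng = np.random.default_rng(0)
        animals = [ped.ids[i] for i in rng.choice(ped.n, 1691, replace=False)]
        df = pd.DataFrame(
            {
                "animal": animals,
                "y": rng.standard_normal(1691),
                "contemporary_group": np.r_[np.arange(142), rng.integers(142, size=1691 - 142)],
                "parity_class": np.r_[np.arange(1, 5), rng.integers(1, 5, size=1691 - 4)],
            }
        )
        d = build_design(df, ped, ModelSpec("y", var_ratio=1.0))
        assert d.X.shape[1] == 1 + 141 + 3

    def test_unknown_animal_is_named(self, trio_frame):
        ped = Pedigree(trio_frame)
        df = pd.DataFrame({"animal": ["nobody"], "y": [1.0]})
        with pytest.raises(ValueError, match="nobody"):
            build_design(df, ped, ModelSpec("y", fixed_effects=(), var_ratio=1.0))


class TestSolveMME:
    def test_infinite_shrinkage_limit_is_ols(self):
        ped = random_pedigree(2, 6, 24)
        df = phen_for(ped, seed=1, n_cg=3)
        spec = ModelSpec("y", ("contemporary_group",), var_ratio=1e12)
        res = solve_mme(build_design(df, ped, spec), ped.a_inverse(), spec)
        assert np.abs(res.ebv.to_numpy()).max() < 1e-6
        d = build_design(df, ped, spec)
        bhat = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert np.allclose(res.fixed_solutions["estimate"], bhat, atol=1e-4)

    def test_single_animal_closed_form(self):
        # one founder, one record y=10, intercept + animal, lambda=1:
        # C = [[1,1],[1,2]], rhs=[10,10] -> b=10, a=0
        ped = Pedigree(pd.DataFrame({"animal": ["a"], "sire": ["0"], "dam": ["0"]}))
        df = pd.DataFrame({"animal": ["a"], "y": [10.0]})
        spec = ModelSpec("y", fixed_effects=(), var_ratio=1.0)
        res = solve_mme(build_design(df, ped, spec), ped.a_inverse(), spec)
        C = np.array([[1.0, 1.0], [1.0, 2.0]])
        sol = np.linalg.solve(C, [10.0, 10.0])
        assert res.fixed_solutions["estimate"][0] == pytest.approx(sol[0], abs=1e-10)
        assert res.ebv["a"] == pytest.approx(sol[1], abs=1e-10)

    def test_matches_dense_gls_oracle(self):
        ped = random_pedigree(3, 6, 24)
        df = phen_for(ped, seed=2, n_cg=2)
        sa2, se2 = 0.4, 0.6
        spec = ModelSpec("y", ("contemporary_group",), sigma_a2=sa2, sigma_e2=se2)
        d = build_design(df, ped, spec)
        res = solve_mme(d, ped.a_inverse(), spec)
        A = ped.relationship_matrix().to_dense()
        Z = d.Z.toarray()
        V = Z @ A @ Z.T * sa2 + np.eye(d.n_records) * se2
        Vi = np.linalg.inv(V)
        X = d.X
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d.y)
        a = sa2 * A @ Z.T @ Vi @ (d.y - X @ b)
        assert np.allclose(res.fixed_solutions["estimate"], b, atol=1e-8)
        assert np.allclose(res.ebv.to_numpy(), a, atol=1e-8)

    def test_fixed_residual_orthogonality(self):
        ped = random_pedigree(4, 6, 30)
        df = phen_for(ped, seed=3, n_cg=4)
        spec = ModelSpec("y", ("contemporary_group",), var_ratio=2.0)
        model = AnimalModel(df, ped, spec, kernel_inv=ped.a_inverse())
        res = model.fit()
        # MME row for b: X'(y - Xb - Za) = 0
        assert np.abs(res.design.X.T @ res.residuals()).max() < 1e-8

    def test_solution_invariant_to_animal_ordering(self):
        ped = random_pedigree(5, 6, 20)
        df = phen_for(ped, seed=4, n_cg=2)
        spec = ModelSpec("y", ("contemporary_group",), var_ratio=1.5)
        r1 = run_model(ped, df, spec, "PBLUP")
        # rebuild pedigree from a shuffled frame: ids map identically
        frame = ped.to_frame().sample(frac=1.0, random_state=1).reset_index(drop=True)
        ped2 = Pedigree(frame)
        r2 = run_model(ped2, df.sample(frac=1.0, random_state=2), spec, "PBLUP")
        common = list(ped.ids)
        assert np.allclose(r1.ebv[common], r2.ebv[common], atol=1e-8)


@pytest.fixture(scope="module")
def data():
    return simulate_dataset(
        SimConfig(seed=9, n_founders=40, n_generations=3, n_snp=120, n_qtl=20,
                  prop_genotyped_by_cohort=(0, 0, 0.5, 1.0))
    )


class TestRunModel:

    def test_pblup_equals_ssgblup_with_no_genotypes(self, data):
        spec = ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)
        r1 = run_model(data.pedigree, data.phenotypes, spec, "PBLUP")
        empty = data.genotypes.subset_animals([])
        kinv = single_step_kernel(data.pedigree, empty)
        m = AnimalModel(data.phenotypes, data.pedigree, spec, kernel_inv=kinv)
        r2 = m.fit()
        assert np.allclose(r1.ebv.to_numpy(), r2.ebv.to_numpy(), atol=1e-8)

    def test_ssgblup_with_g_equal_a22_is_pblup(self, data):
        spec = ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)
        a22, _ = data.pedigree.a22(list(data.genotypes.animal_ids))
        from ssgblup.pedigree import RelationshipFactor

        g = RelationshipFactor(RelationshipKind.G_TUNED, a22.to_dense(), list(a22.ids))
        kinv = single_step_kernel(data.pedigree, data.genotypes, g_override=g,
                                  alpha=0.5, beta=0.5)
        r_ss = AnimalModel(data.phenotypes, data.pedigree, spec, kernel_inv=kinv).fit()
        r_pb = run_model(data.pedigree, data.phenotypes, spec, "PBLUP")
        assert np.abs(r_ss.ebv.to_numpy() - r_pb.ebv.to_numpy()).max() < 1e-8

    def test_wssgblup_requires_weights(self, data):
        spec = ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)
        with pytest.raises(ValueError, match="weight"):
            run_model(data.pedigree, data.phenotypes, spec, "WSSGBLUP",
                      genotypes=data.genotypes)

    def test_unknown_method(self, data):
        spec = ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)
        with pytest.raises(ValueError, match="unknown method"):
            run_model(data.pedigree, data.phenotypes, spec, "GBLUP")

    def test_summary_mentions_kernel_and_trait(self, data):
        spec = ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)
        res = run_model(data.pedigree, data.phenotypes, spec, "SSGBLUP",
                        genotypes=data.genotypes)
        s = res.summary()
        assert "H_INV" in s and spec.trait in s
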