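import numpy as np
import pytest

from ssgblup.model import ModelSpec, run_model
from ssgblup.simulate import SimConfig, simulate_dataset
from ssgblup.weights import (
    SnpEffects,
    SnpWeights,
    backsolve_snp_effects,
    nonlinear_a_weights,
    normalize_weights,
    window_variance_explained,
    wssgblup_iterate,
)

from test_genotypes import make_gm


class TestBacksolve:
    def test_square_invertible_recovers_exactly(self):
        # external reference frequencies keep the centered M full rank
        # (centering on the sample's own frequencies forces 1'M = 0)
        rng = np.random.default_rng(1)
        g = make_gm(rng.integers(0, 3, size=(3, 3)))
        g.freqs = np.full(3, 0.45)
        M = g.centered()
        assert abs(np.linalg.det(M)) > 1e-8
        a = rng.standard_normal(3)
        u = backsolve_snp_effects(a, g).u
        assert np.allclose(u, np.linalg.solve(M, a), atol=1e-10)

    def test_zero_ebv_zero_effects(self):
        rng = np.random.default_rng(1)
        g = make_gm(rng.integers(0, 3, size=(4, 6)))
        assert np.allclose(backsolve_snp_effects(np.zeros(4), g).u, 0.0)

    def test_dense_formula_oracle(self):
        rng = np.random.default_rng(2)
        g = make_gm(rng.integers(0, 3, size=(5, 3)))
        g.freqs = g.dosages.mean(axis=0) / 2
        d = rng.uniform(0.5, 2.0, 3)
        a = rng.standard_normal(5)
        M = g.centered()
        expect = np.diag(d) @ M.T @ np.linalg.pinv(M @ np.diag(d) @ M.T) @ a
        got = backsolve_snp_effects(a, g, weights=d).u
        assert np.allclose(got, expect, atol=1e-8)

    def test_reconstruction_correlation_on_full_rank_toy(self):
        rng = np.random.default_rng(3)
        g = make_gm(rng.integers(0, 3, size=(8, 40)))
        g.freqs = np.full(40, 0.4)
        a = rng.standard_normal(8)
        u = backsolve_snp_effects(a, g).u
        rebuilt = g.centered() @ u
        assert np.corrcoef(rebuilt, a)[0, 1] > 0.99

    def test_dimension_mismatch(self):
        g = make_gm([[0, 1], [1, 2]])
        with pytest.raises(ValueError, match="length"):
            backsolve_snp_effects(np.zeros(3), g)


class TestNonlinearA:
    def test_effect_at_two_sd_gets_unit_weight(self):
        u = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
        sd = np.std(u)
        eff = SnpEffects(u=np.array([2 * sd, 1.0, -1.0, 0.5, -0.5]))
        # first SNP sits exactly at 2 sd of THIS vector only if constructed so;
        # use a direct vector instead
        u = np.array([2.0, 0.0, 0.0, 0.0, -2.0, 2.0, -2.0, 0.0])
        eff = SnpEffects(u=u)
        w = nonlinear_a_weights(eff, CT=1.25, limit=10.0)
        two_sd = 2 * np.std(u)
        i = np.flatnonzero(np.isclose(np.abs(u), two_sd))
        assert np.allclose(w.d[i], 1.0)

    def test_zero_effect_closed_form(self):
        u = np.array([0.0, 1.0, -1.0])
        w = nonlinear_a_weights(SnpEffects(u=u), CT=1.25)
        assert w.d[0] == pytest.approx(1.25**-2, abs=1e-12)  # 0.64 > 1/1.953

    @pytest.mark.parametrize(
        "ct,cap", [(1.105, 1.105**3), (1.125, 1.424), (1.250, 1.953)]
    )
    def test_default_caps(self, ct, cap):
        u = np.zeros(50)
        u[0] = 100.0  # ~10 sd outlier
        w = nonlinear_a_weights(SnpEffects(u=u), CT=ct)
        assert w.d.max() == pytest.approx(cap, abs=5e-4)
        assert w.d.min() >= 1.0 / w.limit - 1e-12

    def test_constant_effects_warns_unit_weights(self):
        with pytest.warns(UserWarning, match="identical"):
            w = nonlinear_a_weights(SnpEffects(u=np.ones(5)), CT=1.25)
        assert np.all(w.d == 1.0)

    def test_ct_below_one_rejected(self):
        with pytest.raises(ValueError):
            nonlinear_a_weights(SnpEffects(u=np.arange(3.0)), CT=0.9)


class TestNormalize:
    def test_constant_two_becomes_one(self):
        w = normalize_weights(SnpWeights(np.full(10, 2.0)))
        assert np.allclose(w.d, 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        w = normalize_weights(SnpWeights(rng.uniform(0.1, 3.0, 100)))
        w2 = normalize_weights(w)
        assert np.allclose(w.d, w2.d)
        assert w.trace == pytest.approx(100.0, abs=1e-10)


@pytest.fixture(scope="module")
def data():
    return simulate_dataset(
        SimConfig(seed=17, n_founders=50, n_generations=3, n_snp=200, n_qtl=5,
                  prop_genotyped_by_cohort=(0, 0, 0.5, 1.0))
    )


@pytest.fixture(scope="module")
def spec(data):
    return ModelSpec(data.config.trait_names[0], sigma_a2=0.35, sigma_e2=0.65)


class TestIterate:

    def test_iteration_one_is_ssgblup(self, data, spec):
        iters = wssgblup_iterate(data.pedigree, data.phenotypes, data.genotypes,
                                 spec, CT=1.25, n_iter=2)
        ss = run_model(data.pedigree, data.phenotypes, spec, "SSGBLUP",
                       genotypes=data.genotypes)
        assert np.abs(iters[0].results.ebv.to_numpy() - ss.ebv.to_numpy()).max() < 1e-10

    def test_cap_and_trace_every_iteration(self, data, spec):
        iters = wssgblup_iterate(data.pedigree, data.phenotypes, data.genotypes,
                                 spec, CT=1.25, n_iter=3)
        n_snp = data.genotypes.n_snp
        for it in iters:
            assert it.weights.trace == pytest.approx(n_snp, abs=1e-8)
            assert it.next_weights.trace == pytest.approx(n_snp, abs=1e-8)
            assert it.next_weights.d.max() <= it.next_weights.limit + 1e-9
            assert it.next_weights.d.min() >= 1 / it.next_weights.limit - 1e-9

    def test_ct_near_one_approaches_ssgblup(self, data, spec):
        base = run_model(data.pedigree, data.phenotypes, spec, "SSGBLUP",
                         genotypes=data.genotypes).ebv.to_numpy()
        devs = []
        for ct in (1.25, 1.05, 1.005):
            it = wssgblup_iterate(data.pedigree, data.phenotypes, data.genotypes,
                                  spec, CT=ct, n_iter=2)[-1]
            devs.append(np.abs(it.results.ebv.to_numpy() - base).max())
        assert devs[2] < devs[1] < devs[0]

    def test_divergence_or_missing_genotypes_rejected(self, data, spec):
        with pytest.raises(ValueError, match="genotypes"):
            wssgblup_iterate(data.pedigree, data.phenotypes, None, spec, CT=1.25)


class TestWindowVariance:
    def test_single_window_is_total(self):
        rng = np.random.default_rng(5)
        g = make_gm(rng.integers(0, 3, size=(10, 7)))
        g.freqs = g.dosages.mean(axis=0) / 2
        eff = SnpEffects(u=rng.standard_normal(7))
        tab = window_variance_explained(eff, g, window_size=7)
        assert len(tab) == 1
        assert tab["pct_var"].iloc[0] == pytest.approx(100.0)

    def test_lone_nonzero_snp_carries_everything(self):
        rng = np.random.default_rng(6)
        g = make_gm(rng.integers(0, 3, size=(10, 9)))
        g.freqs = g.dosages.mean(axis=0) / 2
        u = np.zeros(9)
        u[4] = 1.0
        tab = window_variance_explained(SnpEffects(u=u), g, window_size=3)
        assert tab["pct_var"].iloc[1] == pytest.approx(100.0)
        assert tab["pct_var"].iloc[0] == 0.0

    def test_three_window_brute_force(self):
        rng = np.random.default_rng(7)
        g = make_gm(rng.integers(0, 3, size=(12, 9)))
        g.freqs = g.dosages.mean(axis=0) / 2
        u = rng.standard_normal(9)
        tab = window_variance_explained(SnpEffects(u=u), g, window_size=3)
        M = g.centered()
        tot = np.var(M @ u)
        for w in range(3):
            sl = slice(3 * w, 3 * w + 3)
            assert tab["pct_var"].iloc[w] == pytest.approx(
                100 * np.var(M[:, sl] @ u[sl]) / tot, abs=1e-10
            )

    def test_empty_effects_rejected(self):
        g = make_gm([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            window_variance_explained(SnpEffects(u=np.zeros(2)), g)
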