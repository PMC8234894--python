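import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pedigree import RelationshipFactor, RelationshipKind
from ssgblup.relationships import blend_G, h_inverse, tune_G, vanraden_G

from conftest import random_pedigree
from test_genotypes import make_gm


def factor(kind, m, ids):
    return RelationshipFactor(kind, np.asarray(m, dtype=float), list(ids))


class TestVanRaden:
    def test_unit_weights_equal_no_weights(self):
        rng = np.random.default_rng(1)
        g = make_gm(rng.integers(0, 3, size=(8, 20)))
        a = vanraden_G(g).to_dense()
        b = vanraden_G(g, np.ones(20)).to_dense()
        assert np.array_equal(a, b)

    def test_all_heterozygous_gives_zero_matrix(self):
        g = make_gm([[1.0], [1.0], [1.0]])
        assert np.allclose(vanraden_G(g).to_dense(), 0.0)

    def test_hand_computed_toy(self):
        g = make_gm([[0, 2], [1, 1], [2, 0]])
        # p = (0.5, 0.5); M = dos - 1; denom = 2*(0.25+0.25) = 1
        M = np.array([[-1, 1], [0, 0], [1, -1]], dtype=float)
        expect = M @ M.T
        assert np.abs(vanraden_G(g).to_dense() - expect).max() < 1e-12

    def test_weighted_toy_matches_formula(self):
        rng = np.random.default_rng(2)
        g = make_gm(rng.integers(0, 3, size=(5, 7)))
        d = rng.uniform(0.5, 2.0, 7)
        p = g.dosages.mean(axis=0) / 2
        M = g.dosages - 2 * p
        expect = (M * d) @ M.T / (2 * np.sum(p * (1 - p)))
        assert np.abs(vanraden_G(g, d).to_dense() - expect).max() < 1e-12

    def test_monomorphic_panel_is_error(self):
        g = make_gm([[2.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_G(g)

    def test_centering_property(self):
        rng = np.random.default_rng(3)
        g = make_gm(rng.integers(0, 3, size=(12, 30)))
        g.freqs = g.dosages.mean(axis=0) / 2
        assert np.abs(g.centered().mean(axis=0)).max() < 1e-12


class TestTuneAndBlend:
    def _pair(self, seed, n=10):
        rng = np.random.default_rng(seed)
        B = rng.standard_normal((n, n + 3))
        G = B @ B.T / (n + 3)
        C = rng.standard_normal((n, n + 3))
        A = C @ C.T / (n + 3) + np.eye(n) * 0.2
        ids = [f"a{i}" for i in range(n)]
        return (
            factor(RelationshipKind.G_RAW, G, ids),
            factor(RelationshipKind.A22, A, ids),
        )

    def test_already_matching_is_identity(self):
        G, _ = self._pair(0)
        res = tune_G(G, factor(RelationshipKind.A22, G.matrix, G.ids))
        assert np.abs(res.to_dense() - G.to_dense()).max() < 1e-10

    def test_means_match_after_tuning(self):
        G, A = self._pair(1)
        t = tune_G(G, A).to_dense()
        Ad = A.to_dense()
        n = t.shape[0]
        off = ~np.eye(n, dtype=bool)
        assert np.mean(np.diag(t)) == pytest.approx(np.mean(np.diag(Ad)), abs=1e-10)
        assert np.mean(t[off]) == pytest.approx(np.mean(Ad[off]), abs=1e-10)

    def test_scalars_match_independent_2x2_solve(self):
        G, A = self._pair(2)
        Gd, Ad = G.to_dense(), A.to_dense()
        n = Gd.shape[0]
        off = ~np.eye(n, dtype=bool)
        M = np.array([[1.0, np.mean(np.diag(Gd))], [1.0, np.mean(Gd[off])]])
        a, b = np.linalg.solve(M, [np.mean(np.diag(Ad)), np.mean(Ad[off])])
        assert np.abs(tune_G(G, A).to_dense() - (a + b * Gd)).max() < 1e-10

    def test_constant_G_is_degenerate(self):
        ids = ["x", "y"]
        G = factor(RelationshipKind.G_RAW, np.ones((2, 2)), ids)
        A = factor(RelationshipKind.A22, np.eye(2), ids)
        with pytest.raises(ValueError, match="degenerate"):
            tune_G(G, A)

    def test_blend_alpha_one_is_identity(self):
        G, A = self._pair(3)
        with pytest.warns(UserWarning):
            out = blend_G(G, A, alpha=1.0, beta=0.5)
        # alpha=1, beta=0 exact case
        out = blend_G(G, A, alpha=1.0, beta=0.0)
        assert np.array_equal(out.to_dense(), G.to_dense())

    def test_blend_of_equal_matrices_is_fixed_point(self):
        _, A = self._pair(4)
        Gt = factor(RelationshipKind.G_TUNED, A.matrix, A.ids)
        out = blend_G(Gt, A, 0.95, 0.05)
        assert np.abs(out.to_dense() - A.to_dense()).max() < 1e-12

    def test_default_blend_fixes_rank_deficiency(self):
        # rank-1 G is singular; 0.95/0.05 blend with PD A22 must be PD
        ids = [f"a{i}" for i in range(6)]
        v = np.arange(1.0, 7.0)[:, None]
        G = factor(RelationshipKind.G_TUNED, v @ v.T / 6, ids)
        A = factor(RelationshipKind.A22, np.eye(6) + 0.1, ids)
        out = blend_G(G, A).to_dense()
        assert np.linalg.eigvalsh(out).min() > 0


class TestHInverse:
    def test_empty_genotyped_set_is_a_inverse(self):
        ped = random_pedigree(31, 6, 20)
        ainv = ped.a_inverse()
        h = h_inverse(ainv, factor(RelationshipKind.A22, np.empty((0, 0)), []),
                      factor(RelationshipKind.G_BLEND, np.empty((0, 0)), []))
        assert (h.matrix != ainv.matrix).nnz == 0
        assert h.kind == RelationshipKind.H_INV

    def test_g_equal_a22_cancels(self):
        ped = random_pedigree(32, 6, 24)
        ids = [ped.ids[i] for i in range(20, 28)]
        a22, _ = ped.a22(ids)
        ainv = ped.a_inverse()
        h = h_inverse(ainv, a22, factor(RelationshipKind.G_BLEND, a22.matrix, ids))
        assert abs(h.matrix - ainv.matrix).max() < 1e-10

    def test_matches_dense_partitioned_H(self):
        # H from the standard partitioned identity, inverted densely,
        # must agree with the sparse-assembled H inverse.
        ped = random_pedigree(33, 8, 22)
        ids = [ped.ids[i] for i in range(22, 30)]
        gi = np.array([ped.id_index[a] for a in ids])
        A = ped.relationship_matrix().to_dense()
        a22, _ = ped.a22(ids)
        rng = np.random.default_rng(5)
        B = rng.standard_normal((8, 15))
        G = B @ B.T / 15
        G = 0.8 * G + 0.2 * a22.to_dense()  # keep it near A22 so H is PD
        Gf = factor(RelationshipKind.G_BLEND, G, ids)
        Hinv = h_inverse(ped.a_inverse(), a22, Gf).matrix.toarray()
        # dense H: A + corrections on the genotyped block via partitioning
        A11 = np.delete(np.delete(A, gi, 0), gi, 1)
        others = np.setdiff1d(np.arange(ped.n), gi)
        A12 = A[np.ix_(others, gi)]
        A22d = a22.to_dense()
        H = np.zeros_like(A)
        A22inv = np.linalg.inv(A22d)
        H[np.ix_(others, others)] = A11 + A12 @ A22inv @ (G - A22d) @ A22inv @ A12.T
        H[np.ix_(others, gi)] = A12 @ A22inv @ G
        H[np.ix_(gi, others)] = H[np.ix_(others, gi)].T
        H[np.ix_(gi, gi)] = G
        assert np.abs(np.linalg.inv(H) - Hinv).max() < 1e-6

    def test_singular_blend_reports_blending(self):
        ped = random_pedigree(34, 6, 14)
        ids = [ped.ids[i] for i in range(16, 20)]
        a22, _ = ped.a22(ids)
        bad = factor(RelationshipKind.G_BLEND, np.zeros((4, 4)), ids)
        with pytest.raises(ValueError, match="blend"):
            h_inverse(ped.a_inverse(), a22, bad)
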