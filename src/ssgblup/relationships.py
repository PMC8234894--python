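"""Genomic relationship matrices and the single-step H⁻¹.

The genomic matrix follows VanRaden's first method,

    G = M D Mᵀ / (2 Σ pᵢ(1−pᵢ)),

with M the dosage matrix centered by twice the allele frequency and D an
optional diagonal matrix of per-SNP weights (D = I for the unweighted G).
G is then made compatible with the pedigree base by *tuning* (matching its
mean diagonal and off-diagonal to A22's) and kept invertible by *blending*
with A22 (G_b = αG + βA22, default α = 0.95, β = 0.05).  The single-step
inverse adds the genomic correction on the genotyped block:

    H⁻¹ = A⁻¹ + [0 0; 0 (αG + βA22)⁻¹ − A22⁻¹].
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenotypeMatrix, allele_frequencies
from .pedigree import RelationshipFactor, RelationshipKind

__all__ = ["vanraden_G", "tune_G", "blend_G", "h_inverse"]


def _weights_vector(g: GenotypeMatrix, weights) -> np.ndarray:
    if weights is None:
        return np.ones(g.n_snp)
    d = np.asarray(weights, dtype=float)
    if d.shape != (g.n_snp,):
        raise ValueError(f"weights must have length n_snp={g.n_snp}")
    if (d <= 0).any():
        raise ValueError("SNP weights must be strictly positive")
    return d


def vanraden_G(g: GenotypeMatrix, weights=None) -> RelationshipFactor:
    """VanRaden method-1 genomic relationship matrix, optionally weighted."""
    p = g.freqs if g.freqs is not None else allele_frequencies(g)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: Σ p(1−p) = 0")
    d = _weights_vector(g, weights)
    M = g.dosages - 2.0 * p
    G = (M * d) @ M.T / denom
    G = 0.5 * (G + G.T)
    return RelationshipFactor(RelationshipKind.G_RAW, G, list(g.animal_ids))


def _mean_diag_offdiag(m: np.ndarray) -> tuple[float, float]:
    n = m.shape[0]
    dg = float(np.trace(m) / n)
    if n == 1:
        return dg, 0.0
    off = float((m.sum() - np.trace(m)) / (n * (n - 1)))
    return dg, off


def tune_G(G: RelationshipFactor, A22: RelationshipFactor) -> RelationshipFactor:
    """Rescale G (a + bG) so its mean diagonal and off-diagonal match A22's.

    The scalars solve the 2×2 linear system
        a + b·mean(diag G)    = mean(diag A22)
        a + b·mean(offdiag G) = mean(offdiag A22).
    """
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must share the same animal ordering")
    Gd = G.to_dense()
    Ad = A22.to_dense()
    gdg, goff = _mean_diag_offdiag(Gd)
    adg, aoff = _mean_diag_offdiag(Ad)
    if abs(gdg - goff) < 1e-12:
        raise ValueError("G has equal mean diagonal and off-diagonal; tuning is degenerate")
    b = (adg - aoff) / (gdg - goff)
    a = adg - b * gdg
    return RelationshipFactor(RelationshipKind.G_TUNED, a + b * Gd, list(G.ids))


def blend_G(
    G_t: RelationshipFactor,
    A22: RelationshipFactor,
    alpha: float = 0.95,
    beta: float = 0.05,
) -> RelationshipFactor:
    """G_b = α·G + β·A22; β > 0 guarantees invertibility in practice."""
    if list(G_t.ids) != list(A22.ids):
        raise ValueError("G and A22 must share the same animal ordering")
    if abs(alpha + beta - 1.0) > 1e-8:
        warnings.warn(f"blending weights alpha+beta = {alpha + beta} != 1", stacklevel=2)
    Gb = alpha * G_t.to_dense() + beta * A22.to_dense()
    return RelationshipFactor(RelationshipKind.G_BLEND, Gb, list(G_t.ids))


def h_inverse(
    a_inv: RelationshipFactor,
    a22: RelationshipFactor,
    g_blend: RelationshipFactor,
) -> RelationshipFactor:
    """Single-step H⁻¹: sparse A⁻¹ plus the genomic correction block.

    The correction G_b⁻¹ − A22⁻¹ is added on the genotyped-by-genotyped
    submatrix; ``g_blend`` must already contain the blended (invertible)
    genomic matrix.
    """
    ids_all = list(a_inv.ids)
    gen_ids = list(g_blend.ids)
    if list(a22.ids) != gen_ids:
        raise ValueError("A22 and G must index the same genotyped animals")
    if len(gen_ids) == 0:
        return RelationshipFactor(RelationshipKind.H_INV, a_inv.matrix.copy(), ids_all)
    index = {a: i for i, a in enumerate(ids_all)}
    try:
        gidx = np.array([index[a] for a in gen_ids], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"genotyped animal not in pedigree factor: {e.args[0]}") from None

    Gb = g_blend.to_dense()
    try:
        cG = cho_factor(Gb)
    except np.linalg.LinAlgError:
        raise ValueError(
            "blended G is singular; increase the A22 blending fraction"
        ) from None
    Gb_inv = cho_solve(cG, np.eye(Gb.shape[0]))
    A22d = a22.to_dense()
    A22_inv = cho_solve(cho_factor(A22d), np.eye(A22d.shape[0]))
    corr = Gb_inv - A22_inv
    corr = 0.5 * (corr + corr.T)

    rr, cc = np.meshgrid(gidx, gidx, indexing="ij")
    block = sparse.coo_matrix(
        (corr.ravel(), (rr.ravel(), cc.ravel())), shape=a_inv.matrix.shape
    )
    H = (a_inv.matrix + block).tocsr()
    return RelationshipFactor(RelationshipKind.H_INV, H, ids_all)
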