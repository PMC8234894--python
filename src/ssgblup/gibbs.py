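"""Gibbs sampling of animal-model variance components.

Location parameters (fixed effects and breeding values) are updated by
single-site sweeps of their full conditionals over the mixed-model
coefficient matrix; variances come from their scaled inverse chi-square
(univariate) or inverse-Wishart (multi-trait) full conditionals, using the
pedigree quadratic form aᵀA⁻¹a.  Multi-trait chains sample the full 3×3-
style genetic (G0) and residual (R0) covariance matrices under the usual
G0 ⊗ A and R0 ⊗ I structures and require complete records across traits.

The coefficient matrix is stored once as a sparse pattern with separate
data vectors for the XᵀX/XᵀZ/ZᵀZ part and the A⁻¹ (or H⁻¹) part, so each
draw only rescales values; the sweep itself is numba-compiled and consumes
pre-drawn standard normals, which keeps all randomness in one seeded
NumPy generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.stats import invwishart

from .model import DesignBundle
from .pedigree import Pedigree, RelationshipFactor

__all__ = [
    "GibbsConfig",
    "PosteriorSamples",
    "MultiTraitDesign",
    "build_multitrait_design",
    "gibbs_univariate",
    "gibbs_multitrait",
    "posterior_summary",
    "hpd_interval",
]


@dataclass
class GibbsConfig:
    """Chain settings and priors.

    Defaults are desk-scale (20,000/2,000/10); ``GibbsConfig.reference()``
    returns the long 200,000/5,000/100 preset whose bookkeeping retains
    1,950 draws.  ``nu_prior = -2`` with zero scale makes the univariate
    variance prior flat; the multi-trait sampler uses the analogous flat
    covariance prior (inverse-Wishart df -(T+1), zero scale).
    """

    chain_length: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    nu_prior: float = -2.0
    scale_prior: float = 0.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_count(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin

    @classmethod
    def reference(cls, seed: int = 0) -> "GibbsConfig":
        return cls(chain_length=200_000, burn_in=5_000, thin=100, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained draws of the genetic and residual covariance matrices.

    Univariate chains are the T = 1 special case; ``G0`` and ``R0`` have
    shape (retained, T, T).
    """

    trait_names: list
    G0: np.ndarray
    R0: np.ndarray
    config: GibbsConfig | None = None

    @property
    def n_traits(self) -> int:
        return self.G0.shape[1]

    @property
    def retained_count(self) -> int:
        return self.G0.shape[0]

    @property
    def sigma_a2(self) -> np.ndarray:
        return self.G0[:, 0, 0]

    @property
    def sigma_e2(self) -> np.ndarray:
        return self.R0[:, 0, 0]

    def heritability(self, trait: int = 0) -> np.ndarray:
        return self.G0[:, trait, trait] / (
            self.G0[:, trait, trait] + self.R0[:, trait, trait]
        )

    def genetic_correlation(self, i: int, j: int) -> np.ndarray:
        return self.G0[:, i, j] / np.sqrt(self.G0[:, i, i] * self.G0[:, j, j])

    def residual_correlation(self, i: int, j: int) -> np.ndarray:
        return self.R0[:, i, j] / np.sqrt(self.R0[:, i, i] * self.R0[:, j, j])

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for t, name in enumerate(self.trait_names):
            cols[f"sigma_a2:{name}"] = self.G0[:, t, t]
            cols[f"sigma_e2:{name}"] = self.R0[:, t, t]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# sparse machinery
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sweep(indptr, indices, vals, rhs, theta, z):
    """One full single-site Gibbs pass over Cθ = rhs with precision C."""
    for j in range(theta.size):
        s = 0.0
        cjj = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            c = indices[k]
            if c == j:
                cjj = vals[k]
            else:
                s += vals[k] * theta[c]
        mu = (rhs[j] - s) / cjj
        theta[j] = mu + z[j] / np.sqrt(cjj)


class _System:
    """Pattern-aligned pieces of the MME coefficient matrix."""

    def __init__(self, design: DesignBundle, kinv: RelationshipFactor) -> None:
        if list(kinv.ids) != list(design.animal_ids):
            raise ValueError("kernel inverse and design index different animals")
        X = sparse.csr_matrix(design.X)
        Z = design.Z
        self.W = sparse.hstack([X, Z], format="csr")
        self.p = design.n_fixed
        self.n_animal = Z.shape[1]
        self.N = self.p + self.n_animal
        K = kinv.matrix if sparse.issparse(kinv.matrix) else sparse.csr_matrix(kinv.matrix)
        self.Kinv = K.tocsr()
        Kpad = sparse.bmat(
            [
                [sparse.csr_matrix((self.p, self.p)), None],
                [None, self.Kinv],
            ],
            format="csr",
        )
        WtW = (self.W.T @ self.W).tocsr()
        U = (_pattern(WtW) + _pattern(Kpad)).tocsr()
        U.sort_indices()
        rows = np.repeat(np.arange(self.N), np.diff(U.indptr))
        cols = U.indices
        self.indptr = U.indptr
        self.indices = U.indices
        self.wtw = np.asarray(WtW[rows, cols]).ravel()
        self.k = np.asarray(Kpad[rows, cols]).ravel()
        self.Wty = None  # set by caller
        self.y = None


def _pattern(m: sparse.csr_matrix) -> sparse.csr_matrix:
    out = m.copy()
    out.data = np.ones_like(out.data)
    return out


# ---------------------------------------------------------------------------
# univariate sampler
# ---------------------------------------------------------------------------


def gibbs_univariate(
    design: DesignBundle, kinv: RelationshipFactor, cfg: GibbsConfig
) -> PosteriorSamples:
    """Single-trait animal-model Gibbs chain.

    Fixed effects get flat priors; σa² and σe² get scaled inverse
    chi-square full conditionals using aᵀK⁻¹a and eᵀe.
    """
    sysm = _System(design, kinv)
    y = design.y
    n = y.size
    Wty = sysm.W.T @ y
    rng = np.random.default_rng(cfg.seed)

    vy = float(np.var(y, ddof=1))
    sig_a, sig_e = vy / 2.0, vy / 2.0
    theta = np.zeros(sysm.N)
    nu, S0 = cfg.nu_prior, cfg.scale_prior
    df_a = sysm.n_animal + nu
    df_e = n + nu
    if df_a <= 0 or df_e <= 0:
        raise ValueError("too few animals/records for the chosen prior df")

    m = cfg.retained_count
    G0 = np.empty((m, 1, 1))
    R0 = np.empty((m, 1, 1))
    kept = 0
    for it in range(1, cfg.chain_length + 1):
        vals = sysm.wtw / sig_e + sysm.k / sig_a
        rhs = Wty / sig_e
        z = rng.standard_normal(sysm.N)
        _sweep(sysm.indptr, sysm.indices, vals, rhs, theta, z)
        a = theta[sysm.p :]
        q_a = float(a @ (sysm.Kinv @ a))
        sig_a = (q_a + nu * S0) / rng.chisquare(df_a)
        e = y - sysm.W @ theta
        sig_e = float(e @ e + nu * S0) / rng.chisquare(df_e)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            G0[kept, 0, 0] = sig_a
            R0[kept, 0, 0] = sig_e
            kept += 1
    return PosteriorSamples(["trait"], G0[:kept], R0[:kept], config=cfg)


# ---------------------------------------------------------------------------
# multi-trait sampler
# ---------------------------------------------------------------------------


@dataclass
class MultiTraitDesign:
    """Shared-design multi-trait bundle: one X/Z, a column of y per trait."""

    Y: np.ndarray
    X: np.ndarray
    Z: sparse.csr_matrix
    trait_names: list
    fixed_labels: list
    animal_ids: list

    def __post_init__(self) -> None:
        if self.Y.ndim != 2 or self.Y.shape[1] < 2:
            raise ValueError("multi-trait design needs at least 2 traits")
        if np.isnan(self.Y).any():
            raise ValueError("multi-trait sampler requires complete records for all traits")


def build_multitrait_design(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    traits: list[str],
    fixed_effects: tuple = ("contemporary_group", "parity_class"),
) -> MultiTraitDesign:
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    from .model import ModelSpec, build_design

    base = build_design(phenotypes, ped, ModelSpec(traits[0], fixed_effects, var_ratio=1.0))
    df = phenotypes.loc[phenotypes[traits[0]].notna()].reset_index(drop=True)
    Y = df[traits].to_numpy(dtype=float)
    return MultiTraitDesign(Y, base.X, base.Z, list(traits), base.fixed_labels, base.animal_ids)


@njit(cache=True)
def _sweep_block(indptr, indices, wtw, kvals, Rinv, Ginv, rhs, Theta, Z):
    """Blocked multi-trait pass: for each effect level, sample the vector
    of its T trait solutions jointly from the T-variate full conditional.

    The coefficient block between levels i and j is
    Rinv·wtw_ij + Ginv·k_ij; Theta is (N, T), Z pre-drawn N(0,1)."""
    N, T = Theta.shape
    s = np.empty(T)
    for i in range(N):
        s[:] = 0.0
        wii = 0.0
        kii = 0.0
        for kk in range(indptr[i], indptr[i + 1]):
            j = indices[kk]
            w = wtw[kk]
            k = kvals[kk]
            if j == i:
                wii = w
                kii = k
            else:
                for tj in range(T):
                    th = Theta[j, tj]
                    if th != 0.0:
                        for ti in range(T):
                            s[ti] += (Rinv[ti, tj] * w + Ginv[ti, tj] * k) * th
        Cb = Rinv * wii + Ginv * kii
        L = np.linalg.cholesky(Cb)
        # mean: solve Cb mu = rhs_i - s via the Cholesky factor
        b = np.empty(T)
        for ti in range(T):
            acc = rhs[i, ti] - s[ti]
            for tj in range(ti):
                acc -= L[ti, tj] * b[tj]
            b[ti] = acc / L[ti, ti]
        mu = np.empty(T)
        for ti in range(T - 1, -1, -1):
            acc = b[ti]
            for tj in range(ti + 1, T):
                acc -= L[tj, ti] * mu[tj]
            mu[ti] = acc / L[ti, ti]
        # noise with covariance Cb^{-1}: solve L' x = z
        x = np.empty(T)
        for ti in range(T - 1, -1, -1):
            acc = Z[i, ti]
            for tj in range(ti + 1, T):
                acc -= L[tj, ti] * x[tj]
            x[ti] = acc / L[ti, ti]
        for ti in range(T):
            Theta[i, ti] = mu[ti] + x[ti]


def gibbs_multitrait(
    design: MultiTraitDesign, kinv: RelationshipFactor, cfg: GibbsConfig
) -> PosteriorSamples:
    """Multi-trait chain sampling G0 and R0 from inverse-Wishart
    full conditionals under G0 ⊗ A and R0 ⊗ I covariance structures."""
    T = design.Y.shape[1]
    uni = DesignBundle(
        design.Y[:, 0], design.X, design.Z, design.fixed_labels,
        [], design.animal_ids,
    )
    sysm = _System(uni, kinv)
    p = sysm.p
    n = design.Y.shape[0]
    rng = np.random.default_rng(cfg.seed)

    Wty = np.asarray(sysm.W.T @ design.Y)  # (N, T)
    # flat prior on the covariance matrices (|G|^0), the multi-trait
    # analogue of the univariate nu = -2 scaled-inverse-chi-square default
    df0 = -(T + 1)
    S0 = np.zeros((T, T))
    vy = np.var(design.Y, axis=0, ddof=1)
    G0c = np.diag(vy / 2.0)
    R0c = np.diag(vy / 2.0)
    Theta = np.zeros((sysm.N, T))

    m = cfg.retained_count
    G0 = np.empty((m, T, T))
    R0 = np.empty((m, T, T))
    kept = 0
    for it in range(1, cfg.chain_length + 1):
        Ginv = np.linalg.inv(G0c)
        Rinv = np.linalg.inv(R0c)
        rhs = Wty @ Rinv
        Z = rng.standard_normal((sysm.N, T))
        _sweep_block(
            sysm.indptr, sysm.indices, sysm.wtw, sysm.k, Rinv, Ginv, rhs, Theta, Z
        )
        Ua = Theta[p:, :]
        S_G = Ua.T @ (sysm.Kinv @ Ua)
        G0c = invwishart.rvs(df=sysm.n_animal + df0, scale=S_G + S0, random_state=rng)
        E = design.Y - np.asarray(sysm.W @ Theta)
        S_R = E.T @ E
        R0c = invwishart.rvs(df=n + df0, scale=S_R + S0, random_state=rng)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            G0[kept] = G0c
            R0[kept] = R0c
            kept += 1
    return PosteriorSamples(list(design.trait_names), G0[:kept], R0[:kept], config=cfg)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws (scan on sorted)."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    if m < 2:
        return float(x[0]), float(x[0])
    k = int(np.ceil(prob * m))
    k = min(max(k, 1), m)
    widths = x[k - 1 :] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def posterior_summary(s: PosteriorSamples, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean and HPD per variance, heritability and correlation."""
    if s.retained_count < 30:
        raise ValueError("need at least 30 retained draws for a summary")
    rows = []

    def add(name, draws):
        lo, hi = hpd_interval(draws, prob)
        rows.append(
            {"parameter": name, "mean": float(np.mean(draws)), "hpd_low": lo, "hpd_high": hi}
        )

    T = s.n_traits
    for t, name in enumerate(s.trait_names):
        add(f"sigma_a2:{name}", s.G0[:, t, t])
        add(f"sigma_e2:{name}", s.R0[:, t, t])
        add(f"h2:{name}", s.heritability(t))
    for i in range(T):
        for j in range(i + 1, T):
            add(f"r_g:{s.trait_names[i]}~{s.trait_names[j]}", s.genetic_correlation(i, j))
            add(f"r_e:{s.trait_names[i]}~{s.trait_names[j]}", s.residual_correlation(i, j))
    return pd.DataFrame(rows)
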