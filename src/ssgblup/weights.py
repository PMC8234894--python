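"""SNP weighting for weighted single-step GBLUP (nonlinearA).

SNP allele-substitution effects are backsolved from the genomic breeding
values of the genotyped animals,

    û = δ · D Mᵀ (M D Mᵀ)⁻¹ â,

and turned into per-SNP variance weights with the nonlinearA rule

    dᵢ = CT^(|ûᵢ|/sd(û) − 2),

where CT > 1 controls how far the assumed SNP-effect distribution departs
from normality.  Weights are capped (default cap CT³, the usual
"maximum change in SNP variance CT^(5−2)"), floored at the reciprocal of
the cap, and normalised so tr(D) stays equal to the SNP count, keeping
the genetic variance constant across iterations.  The iterative scheme
alternates solve → backsolve → reweight → rebuild G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenotypeMatrix
from .model import AnimalModelResults, ModelSpec, run_model
from .pedigree import Pedigree

__all__ = [
    "SnpEffects",
    "SnpWeights",
    "WssgblupIteration",
    "backsolve_snp_effects",
    "nonlinear_a_weights",
    "normalize_weights",
    "wssgblup_iterate",
    "window_variance_explained",
]


@dataclass
class SnpEffects:
    """Backsolved allele-substitution effects (trait units per allele copy).

    The absolute scale is arbitrary up to the base-change constant δ;
    everything downstream uses |û|/sd(û) only.
    """

    u: np.ndarray
    delta: float = 1.0

    @property
    def sd(self) -> float:
        return float(np.std(self.u))

    @property
    def n_snp(self) -> int:
        return self.u.size


@dataclass
class SnpWeights:
    """Per-SNP diagonal weights D with their shrinkage bookkeeping."""

    d: np.ndarray
    CT: float = 1.0
    limit: float = np.inf
    iteration: int = 1

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if (self.d <= 0).any():
            raise ValueError("SNP weights must be positive")

    @property
    def trace(self) -> float:
        return float(self.d.sum())

    @property
    def n_snp(self) -> int:
        return self.d.size

    @classmethod
    def unit(cls, n_snp: int) -> "SnpWeights":
        return cls(np.ones(n_snp), CT=1.0, limit=np.inf, iteration=1)


def backsolve_snp_effects(
    a_g: np.ndarray,
    g: GenotypeMatrix,
    weights: SnpWeights | np.ndarray | None = None,
    delta: float = 1.0,
) -> SnpEffects:
    """Backsolve SNP effects from genotyped-animal (G)EBVs.

    ``a_g`` must be ordered like ``g.animal_ids``.  When M D Mᵀ is
    numerically singular a ridge of 1e−8·mean(diag) is added.
    """
    a_g = np.asarray(a_g, dtype=float)
    if a_g.shape != (g.n_animals,):
        raise ValueError(
            f"EBV vector length {a_g.size} != number of genotyped animals {g.n_animals}"
        )
    d = weights.d if isinstance(weights, SnpWeights) else weights
    d = np.ones(g.n_snp) if d is None else np.asarray(d, dtype=float)
    if d.shape != (g.n_snp,):
        raise ValueError("weights length mismatch")
    M = g.centered()
    T = (M * d) @ M.T
    try:
        f = cho_factor(T)
    except np.linalg.LinAlgError:
        T = T + 1e-8 * float(np.mean(np.diag(T))) * np.eye(T.shape[0])
        f = cho_factor(T)
    u = delta * d * (M.T @ cho_solve(f, a_g))
    return SnpEffects(u=u, delta=delta)


def nonlinear_a_weights(
    eff: SnpEffects, CT: float, limit: float | None = None, iteration: int = 1
) -> SnpWeights:
    """nonlinearA rule dᵢ = CT^(|ûᵢ|/sd(û) − 2), capped in [1/limit, limit].

    ``limit`` defaults to CT³ (the CT^(5−2) convention: for CT 1.125 and
    1.250 this is 1.424 and 1.953).
    """
    if CT <= 1.0:
        raise ValueError("CT must exceed 1")
    if limit is None:
        limit = CT**3
    if limit <= 1.0:
        raise ValueError("weight cap must exceed 1")
    sd = eff.sd
    if sd == 0.0:
        warnings.warn("all SNP effects identical; weights set to 1", stacklevel=2)
        return SnpWeights(np.ones(eff.n_snp), CT=CT, limit=limit, iteration=iteration)
    z = np.abs(eff.u) / sd
    d = np.power(CT, z - 2.0)
    d = np.clip(d, 1.0 / limit, limit)
    return SnpWeights(d, CT=CT, limit=limit, iteration=iteration)


def normalize_weights(w: SnpWeights, trace_ref: float | None = None) -> SnpWeights:
    """Rescale so tr(D) equals the iteration-1 trace (= n_snp for D=I)."""
    ref = float(w.n_snp) if trace_ref is None else float(trace_ref)
    d = w.d * (ref / w.trace)
    return SnpWeights(d, CT=w.CT, limit=w.limit, iteration=w.iteration)


def capped_normalize(w: SnpWeights, tol: float = 1e-10, max_pass: int = 100) -> SnpWeights:
    """Alternate clipping to [1/limit, limit] and trace renormalisation
    until both the cap and tr(D) = n_snp hold simultaneously."""
    d = w.d.copy()
    ref = float(w.n_snp)
    for _ in range(max_pass):
        d = np.clip(d, 1.0 / w.limit, w.limit)
        d *= ref / d.sum()
        if d.max() <= w.limit + tol and d.min() >= 1.0 / w.limit - tol:
            break
    return SnpWeights(d, CT=w.CT, limit=w.limit, iteration=w.iteration)


@dataclass
class WssgblupIteration:
    """One pass of the iterative weighting loop.

    ``weights`` is the diagonal D actually used for this iteration's G
    (D = I at iteration 1); ``effects`` are backsolved from its solutions
    and ``next_weights`` is the normalised nonlinearA update they imply.
    """

    iteration: int
    results: AnimalModelResults
    weights: SnpWeights
    effects: SnpEffects
    next_weights: SnpWeights


def wssgblup_iterate(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    spec: ModelSpec,
    CT: float,
    limit: float | None = None,
    n_iter: int = 2,
    alpha: float = 0.95,
    beta: float = 0.05,
    tune: bool = True,
    stop_corr: float | None = None,
) -> list[WssgblupIteration]:
    """Iteratively weighted single-step GBLUP.

    Steps per iteration t: solve the single-step MME with G(D(t))
    (D(1) = I, i.e. plain ssGBLUP), backsolve SNP effects, apply the
    nonlinearA rule, normalise to constant trace, rebuild G for t+1.
    ``stop_corr`` optionally stops early once successive weight vectors
    correlate above the threshold.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if genotypes is None or genotypes.n_animals == 0:
        raise ValueError("weighted ssGBLUP requires genotypes")
    w = SnpWeights.unit(genotypes.n_snp)
    out: list[WssgblupIteration] = []
    for t in range(1, n_iter + 1):
        method = "SSGBLUP" if t == 1 else "WSSGBLUP"
        res = run_model(
            pedigree,
            phenotypes,
            spec,
            method=method,
            genotypes=genotypes,
            snp_weights=None if t == 1 else w.d,
            alpha=alpha,
            beta=beta,
            tune=tune,
        )
        ebv_g = res.ebv_of(genotypes.animal_ids)
        if not np.all(np.isfinite(ebv_g)):
            raise RuntimeError(f"weighted ssGBLUP diverged at iteration {t}")
        eff = backsolve_snp_effects(ebv_g, genotypes, weights=w)
        w_next = capped_normalize(
            nonlinear_a_weights(eff, CT, limit=limit, iteration=t + 1)
        )
        res.model_tag = f"WssGBLUP(CT={CT},iter={t})" if t > 1 else "ssGBLUP"
        out.append(WssgblupIteration(t, res, w, eff, w_next))
        if stop_corr is not None and t > 1:
            c = np.corrcoef(w.d, w_next.d)[0, 1]
            if c > stop_corr:
                break
        w = w_next
        w.iteration = t + 1
    return out


def window_variance_explained(
    eff: SnpEffects, g: GenotypeMatrix, window_size: int = 20
) -> pd.DataFrame:
    """Percent of genomic variance per block of ``window_size`` SNPs.

    SNPs are partitioned, in map order and restarting at each chromosome,
    into consecutive non-overlapping blocks; the share of window w is
    Var(M_w û_w) / Var(M û) × 100 over the genotyped animals.  Returns a
    Manhattan-plot table (chrom, start/end/mid position, pct_var).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if eff.n_snp != g.n_snp:
        raise ValueError("effects and genotypes disagree on SNP count")
    if eff.n_snp == 0:
        raise ValueError("empty SNP effect vector")
    M = g.centered()
    total = float(np.var(M @ eff.u))
    if total == 0.0:
        raise ValueError("genomic variance is zero; nothing to decompose")
    rows = []
    sm = g.snp_map.reset_index(drop=True)
    for chrom, grp in sm.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        for s in range(0, idx.size, window_size):
            block = idx[s : s + window_size]
            v = float(np.var(M[:, block] @ eff.u[block]))
            pos = sm["pos"].to_numpy()[block]
            rows.append(
                {
                    "chrom": chrom,
                    "start_pos": int(pos.min()),
                    "end_pos": int(pos.max()),
                    "mid_pos": int(pos[len(pos) // 2]),
                    "n_snp": int(block.size),
                    "pct_var": 100.0 * v / total,
                }
            )
    return pd.DataFrame(rows)
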