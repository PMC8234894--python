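"""Animal-model mixed-model engine.

The model is the classical single-trait animal model

    y = Xb + Za + e,     a ~ N(0, K σa²),   e ~ N(0, I σe²),

where K is either the pedigree numerator relationship matrix A (PBLUP) or
the single-step matrix H combining pedigree and genomic information
(ssGBLUP / WssGBLUP).  Estimates come from Henderson's mixed-model
equations

    [XᵀX   XᵀZ      ] [b̂]   [Xᵀy]
    [ZᵀX   ZᵀZ + λK⁻¹] [â] = [Zᵀy],    λ = σe²/σa²,

solved by sparse LU factorisation (conjugate-gradient fallback).  The API
follows the Model/Results convention: build an :class:`AnimalModel`, call
``fit()``, inspect the returned :class:`AnimalModelResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, RelationshipFactor, RelationshipKind
from .relationships import blend_G, h_inverse, tune_G, vanraden_G

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "AnimalModel",
    "AnimalModelResults",
    "build_design",
    "solve_mme",
    "run_model",
    "single_step_kernel",
]


@dataclass
class ModelSpec:
    """What to fit: trait, fixed effects and variance components.

    Either ``var_ratio`` (λ = σe²/σa²) or both variances must be given;
    absolute variances matter only for Gibbs sampling and reporting.
    """

    trait: str
    fixed_effects: tuple = ("contemporary_group", "parity_class")
    sigma_a2: float | None = None
    sigma_e2: float | None = None
    var_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.var_ratio is None:
            if self.sigma_a2 is None or self.sigma_e2 is None:
                raise ValueError("give var_ratio or both sigma_a2 and sigma_e2")
            if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
                raise ValueError("variance components must be positive")
            self.var_ratio = self.sigma_e2 / self.sigma_a2
        if self.var_ratio <= 0:
            raise ValueError("variance ratio λ must be positive")

    @property
    def heritability(self) -> float | None:
        if self.sigma_a2 is None or self.sigma_e2 is None:
            return None
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class DesignBundle:
    """y, X, Z for one trait, plus the labels needed to interpret them."""

    y: np.ndarray
    X: np.ndarray
    Z: sparse.csr_matrix
    fixed_labels: list
    record_animals: list
    animal_ids: list

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def build_design(phenotypes: pd.DataFrame, ped: Pedigree, spec: ModelSpec) -> DesignBundle:
    """Build the design matrices for the animal model.

    X uses an explicit intercept plus drop-first dummy coding of every
    categorical fixed effect (levels with no record are dropped).  Z maps
    each record to its animal's pedigree index; animals without records
    simply get no row in Z but stay in the random-effect vector.
    """
    df = phenotypes
    if "animal" not in df.columns:
        raise ValueError("phenotype table needs an 'animal' column")
    if spec.trait not in df.columns:
        raise ValueError(f"trait '{spec.trait}' not in phenotype table")
    for eff in spec.fixed_effects:
        if eff not in df.columns:
            raise ValueError(f"fixed effect '{eff}' not in phenotype table")
    df = df.loc[df[spec.trait].notna()].reset_index(drop=True)

    animals = [str(a) for a in df["animal"]]
    missing = [a for a in animals if a not in ped.id_index]
    if missing:
        raise ValueError(f"phenotyped animal(s) not in pedigree: {sorted(set(missing))[:5]}")

    n = len(df)
    cols = [np.ones(n)]
    labels: list[str] = ["intercept"]
    for eff in spec.fixed_effects:
        cat = pd.Categorical(df[eff].astype(str))
        levels = list(cat.categories)
        for lev in levels[1:]:  # first level absorbed by the intercept
            cols.append((cat == lev).astype(float))
            labels.append(f"{eff}:{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient after drop-first coding; "
            "check for confounded factor levels"
        )

    rows = np.arange(n)
    acols = np.array([ped.id_index[a] for a in animals], dtype=np.int64)
    Z = sparse.csr_matrix((np.ones(n), (rows, acols)), shape=(n, ped.n))
    y = df[spec.trait].to_numpy(dtype=float)
    return DesignBundle(y, X, Z, labels, animals, list(ped.ids))


def solve_mme(
    design: DesignBundle,
    kinv: RelationshipFactor,
    spec: ModelSpec,
    rtol: float = 1e-8,
) -> "AnimalModelResults":
    """Solve Henderson's mixed-model equations for one trait."""
    if kinv.kind not in (RelationshipKind.A_INV, RelationshipKind.H_INV):
        raise ValueError("kinv must be an A_INV or H_INV factor")
    if list(kinv.ids) != list(design.animal_ids):
        raise ValueError("kernel inverse and design index different animals")
    lam = spec.var_ratio
    X = sparse.csr_matrix(design.X)
    Z = design.Z
    K = kinv.matrix.tocsr() if sparse.issparse(kinv.matrix) else sparse.csr_matrix(kinv.matrix)
    C = sparse.bmat(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * K]], format="csc"
    )
    rhs = np.concatenate([X.T @ design.y, Z.T @ design.y])
    converged = True
    try:
        theta = splu(C).solve(rhs)
    except RuntimeError:
        theta, info = cg(C, rhs, rtol=1e-10, maxiter=10_000)
        converged = info == 0
    resid = C @ theta - rhs
    if np.linalg.norm(resid) > rtol * max(np.linalg.norm(rhs), 1.0):
        theta2, info = cg(C, rhs, x0=theta, rtol=1e-12, maxiter=10_000)
        if np.linalg.norm(C @ theta2 - rhs) < np.linalg.norm(resid):
            theta = theta2
        converged = np.linalg.norm(C @ theta - rhs) <= rtol * max(np.linalg.norm(rhs), 1.0)
    p = design.n_fixed
    fixed = pd.DataFrame({"effect": design.fixed_labels, "estimate": theta[:p]})
    ebv = pd.Series(theta[p:], index=pd.Index(design.animal_ids, name="animal"), name="ebv")
    return AnimalModelResults(
        fixed_solutions=fixed,
        ebv=ebv,
        spec=spec,
        design=design,
        kernel_kind=kinv.kind,
        converged=bool(converged),
    )


def single_step_kernel(
    ped: Pedigree,
    genotypes: GenotypeMatrix | None,
    snp_weights: np.ndarray | None = None,
    alpha: float = 0.95,
    beta: float = 0.05,
    tune: bool = True,
    g_override: RelationshipFactor | None = None,
) -> RelationshipFactor:
    """Assemble A⁻¹ (no genotypes) or the single-step H⁻¹.

    ``tune`` rescales G to A22's mean diagonal/off-diagonal before
    blending.  ``g_override`` substitutes a caller-supplied genomic matrix
    (used mainly for algebraic consistency checks).
    """
    a_inv = ped.a_inverse()
    if genotypes is None or genotypes.n_animals == 0:
        return RelationshipFactor(RelationshipKind.H_INV, a_inv.matrix.copy(), list(ped.ids))
    a22, _ = ped.a22(list(genotypes.animal_ids))
    if g_override is not None:
        g = g_override
    else:
        g = vanraden_G(genotypes, snp_weights)
        if tune:
            g = tune_G(g, a22)
    gb = blend_G(g, a22, alpha=alpha, beta=beta)
    return h_inverse(a_inv, a22, gb)


class AnimalModel:
    """Single-trait animal model bound to data and a relationship kernel.

    Parameters
    ----------
    phenotypes : record table (columns: animal, trait, fixed effects).
    pedigree : sorted :class:`Pedigree` covering every phenotyped animal.
    spec : :class:`ModelSpec`.
    kernel_inv : pre-built A⁻¹/H⁻¹; if None, built from ``genotypes``
        (PBLUP when genotypes is None).
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        pedigree: Pedigree,
        spec: ModelSpec,
        kernel_inv: RelationshipFactor | None = None,
        genotypes: GenotypeMatrix | None = None,
        snp_weights: np.ndarray | None = None,
        alpha: float = 0.95,
        beta: float = 0.05,
        tune: bool = True,
    ) -> None:
        self.phenotypes = phenotypes
        self.pedigree = pedigree
        self.spec = spec
        self.genotypes = genotypes
        if kernel_inv is None:
            kernel_inv = single_step_kernel(
                pedigree, genotypes, snp_weights, alpha=alpha, beta=beta, tune=tune
            )
        self.kernel_inv = kernel_inv
        self.design = build_design(phenotypes, pedigree, spec)

    @classmethod
    def from_dataframes(cls, phenotypes, pedigree_frame, spec, **kw) -> "AnimalModel":
        return cls(phenotypes, Pedigree(pedigree_frame), spec, **kw)

    def fit(self) -> "AnimalModelResults":
        return solve_mme(self.design, self.kernel_inv, self.spec)

    def fit_gibbs(self, cfg):
        """Gibbs-sample the variance components of this model."""
        from .gibbs import gibbs_univariate

        return gibbs_univariate(self.design, self.kernel_inv, cfg)


@dataclass
class AnimalModelResults:
    """Solutions of one model run on one dataset."""

    fixed_solutions: pd.DataFrame
    ebv: pd.Series
    spec: ModelSpec
    design: DesignBundle
    kernel_kind: RelationshipKind
    converged: bool = True
    model_tag: str = ""
    dataset_tag: str = "WHOLE"

    def fitted_values(self) -> np.ndarray:
        b = self.fixed_solutions["estimate"].to_numpy()
        return self.design.X @ b + self.design.Z @ self.ebv.to_numpy()

    def residuals(self) -> np.ndarray:
        return self.design.y - self.fitted_values()

    def ebv_of(self, ids) -> np.ndarray:
        return self.ebv.loc[[str(a) for a in ids]].to_numpy()

    def summary(self) -> str:
        lines = [
            "Animal model results",
            "=" * 48,
            f"trait:            {self.spec.trait}",
            f"kernel:           {self.kernel_kind.value}"
            + (f" ({self.model_tag})" if self.model_tag else ""),
            f"records:          {self.design.n_records}",
            f"animals (random): {len(self.ebv)}",
            f"fixed columns:    {self.design.n_fixed}",
            f"lambda (se2/sa2): {self.spec.var_ratio:.6g}",
            f"converged:        {self.converged}",
            "-" * 48,
            "fixed effects (first 10):",
        ]
        for _, r in self.fixed_solutions.head(10).iterrows():
            lines.append(f"  {r['effect']:<28s} {r['estimate']: .6g}")
        e = self.ebv.to_numpy()
        lines += [
            "-" * 48,
            f"EBV mean {e.mean(): .4g}  sd {e.std(ddof=1):.4g}  "
            f"min {e.min(): .4g}  max {e.max(): .4g}",
        ]
        return "\n".join(lines)


def run_model(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    method: str = "PBLUP",
    genotypes: GenotypeMatrix | None = None,
    snp_weights: np.ndarray | None = None,
    alpha: float = 0.95,
    beta: float = 0.05,
    tune: bool = True,
) -> AnimalModelResults:
    """One-call orchestration of kernel construction and MME solve.

    method: "PBLUP" (pedigree only), "SSGBLUP" (unweighted G) or
    "WSSGBLUP" (requires ``snp_weights``).
    """
    method = method.upper()
    if method not in ("PBLUP", "SSGBLUP", "WSSGBLUP"):
        raise ValueError(f"unknown method '{method}'")
    if method == "PBLUP":
        kinv = pedigree.a_inverse()
    else:
        if genotypes is None:
            raise ValueError(f"{method} requires genotypes")
        if method == "WSSGBLUP" and snp_weights is None:
            raise ValueError("WSSGBLUP requires a SNP weight vector")
        kinv = single_step_kernel(
            pedigree,
            genotypes,
            snp_weights if method == "WSSGBLUP" else None,
            alpha=alpha,
            beta=beta,
            tune=tune,
        )
    model = AnimalModel(phenotypes, pedigree, spec, kernel_inv=kinv, genotypes=genotypes)
    res = model.fit()
    res.model_tag = method
    return res
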