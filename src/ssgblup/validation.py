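"""LR-method cross-validation of breeding-value predictions.

The LR ("linear regression") method compares EBVs of a focal group —
typically young genotyped selection candidates — estimated from a
*partial* dataset (phenotypes truncated at a cut-off birth year) with
EBVs from the *whole* dataset:

    bias        = mean(û_p) − mean(û_w)          (0 when unbiased)
    dispersion  = cov(û_w, û_p) / var(û_p)       (1 when well-calibrated)
    acc         = corr(û_w, û_p)
    rel         = cov(û_w, û_p) / ((1 − F̄) σu²)  (≈ acc² in expectation)

and the genomic accuracy gain inc = ρ_{A,G}⁻¹ − 1 with its genetic-
variance adjustment inc_adj = (σA²/σG²)·inc, where ρ_{A,G} is the focal
correlation of partial-data pedigree vs genomic EBVs.

Sample (n−1) covariances/variances are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnimalModelResults
from .pedigree import Pedigree

__all__ = [
    "LRStats",
    "make_partial",
    "lr_statistics",
    "genomic_gain",
    "genetic_trend",
]


@dataclass
class LRStats:
    """The LR estimators for one focal group."""

    bias: float
    bias_std: float
    dispersion: float
    acc: float
    rel: float
    n_focal: int
    inc: float | None = None
    inc_adj: float | None = None

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "bias_std": self.bias_std,
            "dispersion": self.dispersion,
            "acc": self.acc,
            "rel": self.rel,
            "n_focal": self.n_focal,
            "inc": self.inc,
            "inc_adj": self.inc_adj,
        }


def make_partial(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    genotyped_ids: list,
    cutoff_year: int,
) -> tuple[pd.DataFrame, list]:
    """Truncate phenotypes at a birth-year cut-off and pick focal animals.

    Partial data keep the records of animals born in or before
    ``cutoff_year``; the focal group is the genotyped animals born after
    it (their phenotypes, if any, exist only in the whole data).
    """
    years = {a: int(y) for a, y in zip(ped.ids, ped.birth_year)}
    animals = [str(a) for a in phenotypes["animal"]]
    missing = [a for a in animals if a not in years]
    if missing:
        raise ValueError(f"phenotyped animal(s) not in pedigree: {sorted(set(missing))[:5]}")
    keep = np.array([years[a] <= cutoff_year for a in animals])
    partial = phenotypes.loc[keep].reset_index(drop=True)
    if len(partial) == 0:
        raise ValueError("cut-off year leaves no record in the partial dataset")
    focal = [str(a) for a in genotyped_ids if years.get(str(a), -(10**9)) > cutoff_year]
    if len(focal) == 0:
        raise ValueError("no genotyped animal born after the cut-off year (empty focal group)")
    return partial, focal


def _cov(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.cov(x, y, ddof=1)[0, 1])


def lr_statistics(
    u_p: np.ndarray,
    u_w: np.ndarray,
    sigma_a: float,
    f_mean: float = 0.0,
    sigma_u2: float | None = None,
) -> LRStats:
    """LR estimators from aligned focal EBV vectors.

    ``sigma_a`` (genetic SD) standardises the bias; ``sigma_u2`` is the
    whole-data genetic variance entering rel (defaults to sigma_a²);
    ``f_mean`` is the mean inbreeding of the focal group.
    """
    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    if u_p.shape != u_w.shape or u_p.ndim != 1:
        raise ValueError("u_p and u_w must be aligned 1-D vectors")
    n = u_p.size
    if n < 2:
        raise ValueError("need at least 2 focal animals")
    var_p = float(np.var(u_p, ddof=1))
    var_w = float(np.var(u_w, ddof=1))
    if var_p == 0.0:
        raise ValueError("partial-data EBVs have zero variance; dispersion undefined")
    c = _cov(u_w, u_p)
    bias = float(np.mean(u_p) - np.mean(u_w))
    sigma_u2 = sigma_a**2 if sigma_u2 is None else float(sigma_u2)
    return LRStats(
        bias=bias,
        bias_std=bias / sigma_a,
        dispersion=c / var_p,
        acc=c / np.sqrt(var_p * var_w) if var_w > 0 else np.nan,
        rel=c / ((1.0 - f_mean) * sigma_u2),
        n_focal=n,
    )


def genomic_gain(
    u_A: np.ndarray, u_G: np.ndarray, varA: float, varG: float
) -> tuple[float, float]:
    """Accuracy gain from genomic data: inc = ρ_{A,G}⁻¹ − 1 and its
    genetic-variance-ratio adjustment inc_adj = (σA²/σG²)·inc."""
    u_A = np.asarray(u_A, dtype=float)
    u_G = np.asarray(u_G, dtype=float)
    if u_A.shape != u_G.shape:
        raise ValueError("u_A and u_G must be aligned")
    rho = _cov(u_A, u_G) / np.sqrt(np.var(u_A, ddof=1) * np.var(u_G, ddof=1))
    if rho <= 0:
        raise ValueError(f"pedigree/genomic EBV correlation {rho:.3f} <= 0; gain undefined")
    inc = 1.0 / rho - 1.0
    return inc, (varA / varG) * inc


def lr_calibration_replicate(
    seed: int,
    n_founders: int = 200,
    n_generations: int = 4,
    h2: float = 0.35,
    n_snp: int = 300,
    n_qtl: int = 100,
) -> LRStats:
    """One LR calibration replicate under the null of no selection.

    Simulates a random-mating population (five cohorts of ``n_founders``
    animals by default, ~1,000 total), phenotypes every non-founder, and
    fits the correctly specified pedigree animal model with the true
    variance ratio on the whole data and on data truncated before the
    last cohort; the LR statistics are computed on the last cohort.
    With a correct model their expectations are bias 0 and dispersion 1.
    """
    from .model import ModelSpec, run_model
    from .simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=seed,
        n_founders=n_founders,
        n_generations=n_generations,
        n_snp=n_snp,
        n_qtl=n_qtl,
        h2=(h2,),
        founder_maf_range=(0.1, 0.5),
        prop_genotyped_by_cohort=tuple([0.0] * n_generations + [1.0]),
    )
    data = simulate_dataset(cfg)
    ped = data.pedigree
    cutoff = int(ped.birth_year.max()) - 1
    partial, focal = make_partial(
        data.phenotypes, ped, list(data.genotypes.animal_ids), cutoff
    )
    spec = ModelSpec(cfg.trait_names[0], var_ratio=(1.0 - h2) / h2)
    whole_res = run_model(ped, data.phenotypes, spec, method="PBLUP")
    part_res = run_model(ped, partial, spec, method="PBLUP")
    return lr_statistics(
        part_res.ebv_of(focal),
        whole_res.ebv_of(focal),
        sigma_a=float(np.sqrt(h2)),
        sigma_u2=h2,
    )


def genetic_trend(
    results: AnimalModelResults, ped: Pedigree, sigma_a: float
) -> tuple[pd.DataFrame, float]:
    """Mean EBV per birth year in genetic-SD units, plus its OLS slope."""
    ebv = results.ebv.to_numpy() / sigma_a
    df = (
        pd.DataFrame({"birth_year": ped.birth_year, "std_ebv": ebv})
        .groupby("birth_year")
        .agg(n=("std_ebv", "size"), mean_std_ebv=("std_ebv", "mean"))
        .reset_index()
    )
    if len(df) > 1:
        slope = float(np.polyfit(df["birth_year"], df["mean_std_ebv"], 1)[0])
    else:
        slope = 0.0
    return df, slope
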