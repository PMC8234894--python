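"""Synthetic pedigree/genotype/phenotype generator with known truth.

Emulates the data structure of a small dual-purpose cattle population
under performance testing: a multi-generation pedigree with known parents,
SNP genotypes inherited by gene dropping from founder haplotypes (Haldane
crossovers, one Morgan per chromosome), and one or more correlated traits
built from a modest number of QTL plus contemporary-group and parity
fixed effects.  Genotyping can be concentrated in recent cohorts and
phenotyping restricted (e.g. to males), mirroring performance-tested
bulls.  Every quantity the estimators try to recover — breeding values,
QTL effects, heritabilities — is returned in a :class:`TruthBundle`.

Randomness is split into three seeded substreams (pedigree structure,
gene dropping, trait machinery) so the composable operations and the
one-call :func:`simulate_dataset` produce identical output for the same
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TruthBundle",
    "SimData",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "rendena_like_dataset",
]


@dataclass
class SimConfig:
    """Full recipe for one synthetic dataset.

    Sizes: ``n_founders`` animals in generation 0, then ``n_generations``
    discrete generations of ``offspring_per_generation`` animals each
    (default: constant population size).  ``offspring_per_mating`` > 1
    produces full-sib families.  ``h2`` has one entry per trait; the
    phenotypic variance of every trait is 1, so effect SDs are in
    phenotypic-SD units.  ``selection="TRUNCATION"`` selects the top
    ``selected_fraction`` of each sex on the first trait's phenotype as
    parents of the next generation.
    """

    seed: int = 0
    n_founders: int = 100
    n_generations: int = 4
    offspring_per_generation: int | None = None
    offspring_per_mating: int = 1
    prop_genotyped_by_cohort: tuple | None = None  # len n_generations+1; default: last gen only
    n_snp: int = 1000
    n_chromosomes: int = 5
    founder_maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 50
    h2: tuple = (0.35,)
    trait_names: tuple | None = None
    genetic_correlations: np.ndarray | None = None
    residual_correlations: np.ndarray | None = None
    n_contemporary_groups: int = 10
    n_parity_classes: int = 4
    cg_sd: float = 0.5
    parity_sd: float = 0.2
    phenotyped_generations: tuple | None = None  # default: all non-founder generations
    phenotyped_fraction: float = 1.0
    phenotyped_sex: str | None = None  # None = both, "M" or "F"
    selection: str = "NONE"
    selected_fraction: float = 0.5
    base_year: int = 2000

    def __post_init__(self) -> None:
        self.h2 = tuple(float(h) for h in np.atleast_1d(self.h2))
        for h in self.h2:
            if not (0.0 <= h < 1.0):
                raise ValueError(f"h2 must lie in [0, 1), got {h}")
        if self.n_qtl > self.n_snp:
            raise ValueError("n_qtl cannot exceed n_snp")
        if self.selection not in ("NONE", "TRUNCATION"):
            raise ValueError("selection must be NONE or TRUNCATION")
        if self.trait_names is None:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(self.n_traits))
        if self.genetic_correlations is not None:
            R = np.asarray(self.genetic_correlations, dtype=float)
            if np.any(np.linalg.eigvalsh(R) <= 0):
                raise ValueError("genetic correlation matrix must be positive definite")
            self.genetic_correlations = R

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    @property
    def cohort_size(self) -> int:
        return self.offspring_per_generation or self.n_founders

    def _rngs(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return tuple(np.random.default_rng(k) for k in kids)


@dataclass
class TruthBundle:
    """What the simulator knows and the models try to recover."""

    tbv: pd.DataFrame  # n_pedigree x n_traits, indexed by animal id
    qtl: pd.DataFrame  # snp_id, chrom, pos and per-trait effects
    realized_h2: np.ndarray
    founder_freqs: np.ndarray
    realized_freqs: np.ndarray
    sigma_a: np.ndarray  # true genetic SD per trait

    def tbv_of(self, ids, trait: int = 0) -> np.ndarray:
        return self.tbv.iloc[:, trait].loc[[str(a) for a in ids]].to_numpy()


@dataclass
class SimData:
    """A complete synthetic study: data the models see plus the truth."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped cohorts only
    phenotypes: pd.DataFrame
    truth: TruthBundle

    def to_files(self, outdir) -> dict:
        """Write the bundle in the dialects the readers consume."""
        from .genotypes import write_genotype_csv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": out / "pedigree.csv",
            "phenotypes": out / "phenotypes.csv",
            "genotypes": out / "genotypes.csv",
            "snp_map": out / "snp_map.tsv",
            "tbv": out / "true_breeding_values.tsv",
        }
        self.pedigree.to_frame().to_csv(paths["pedigree"], index=False)
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        write_genotype_csv(self.genotypes, paths["genotypes"])
        self.genotypes.snp_map.to_csv(paths["snp_map"], sep="\t", index=False)
        self.truth.tbv.to_csv(paths["tbv"], sep="\t")
        return paths


# ---------------------------------------------------------------------------
# pedigree structure
# ---------------------------------------------------------------------------


def _structure_random(cfg: SimConfig, rng) -> pd.DataFrame:
    """Random-mating discrete-generation pedigree (no selection)."""
    rows = []
    gen_members: list[list[int]] = []
    idx = 0
    for g in range(cfg.n_generations + 1):
        size = cfg.n_founders if g == 0 else cfg.cohort_size
        members = []
        if g > 0:
            prev = gen_members[g - 1]
            sexes = np.array([rows[i]["sex"] for i in prev])
            males = [prev[i] for i in np.flatnonzero(sexes == "M")]
            females = [prev[i] for i in np.flatnonzero(sexes == "F")]
            if not males or not females:
                raise RuntimeError(f"generation {g - 1} lacks parents of one sex")
            n_matings = int(np.ceil(size / cfg.offspring_per_mating))
            sires = rng.choice(males, size=n_matings, replace=True)
            dams = rng.choice(females, size=n_matings, replace=True)
        for k in range(size):
            if g == 0:
                s = d = "0"
            else:
                m = k // cfg.offspring_per_mating
                s, d = rows[sires[m]]["animal"], rows[dams[m]]["animal"]
            rows.append(
                {
                    "animal": f"A{idx:06d}",
                    "sire": s,
                    "dam": d,
                    "birth_year": cfg.base_year + g,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "generation": g,
                }
            )
            members.append(idx)
            idx += 1
        gen_members.append(members)
    return pd.DataFrame(rows)


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation pedigree; with TRUNCATION selection the full
    engine runs (selection acts on simulated phenotypes) and the
    resulting pedigree is returned."""
    if cfg.selection == "TRUNCATION":
        return simulate_dataset(cfg).pedigree
    rng_ped, _, _ = cfg._rngs()
    frame = _structure_random(cfg, rng_ped)
    return Pedigree(frame.drop(columns="generation"))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _chromosome_layout(cfg: SimConfig):
    base = cfg.n_snp // cfg.n_chromosomes
    rem = cfg.n_snp % cfg.n_chromosomes
    sizes = [base + (1 if c < rem else 0) for c in range(cfg.n_chromosomes)]
    sizes = [s for s in sizes if s > 0]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{c + 1}_{i + 1}" for c, s in enumerate(sizes) for i in range(s)],
            "chrom": np.repeat(np.arange(1, len(sizes) + 1), sizes),
            "pos": np.concatenate(
                [np.linspace(1, 100_000_000, s).astype(np.int64) for s in sizes]
            ),
        }
    )
    # Haldane recombination fraction between adjacent SNPs, 1 Morgan/chromosome
    rec = []
    for s in sizes:
        d = 1.0 / (s - 1) if s > 1 else 0.0
        rec.append(np.full(max(s - 1, 0), 0.5 * (1.0 - np.exp(-2.0 * d))))
    return sizes, snp_map, rec


def _gamete(hap: np.ndarray, sizes, rec, rng) -> np.ndarray:
    """Recombine one parent's two haplotypes into a gamete."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    off = 0
    for c, s in enumerate(sizes):
        path = np.empty(s, dtype=np.int64)
        path[0] = rng.integers(2)
        if s > 1:
            flips = rng.random(s - 1) < rec[c]
            path[1:] = (path[0] + np.cumsum(flips)) % 2
        seg = hap[:, off : off + s]
        out[off : off + s] = seg[path, np.arange(s)]
        off += s
    return out


def _founder_haplotypes(cfg: SimConfig, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.founder_maf_range
    p = rng.uniform(lo, hi, size=cfg.n_snp)
    hap = (rng.random((n, 2, cfg.n_snp)) < p).astype(np.int8)
    return hap, p


def _drop_full(ped: Pedigree, cfg: SimConfig, rng) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Gene-drop the whole pedigree; returns (haplotypes, snp_map, founder p)."""
    sizes, snp_map, rec = _chromosome_layout(cfg)
    n = ped.n
    founders = ped.is_founder()
    hap = np.zeros((n, 2, cfg.n_snp), dtype=np.int8)
    fh, p = _founder_haplotypes(cfg, int(founders.sum()), rng)
    hap[np.flatnonzero(founders)] = fh
    for i in range(n):
        if founders[i]:
            continue
        s, d = ped.sire[i], ped.dam[i]
        # a missing parent contributes a fresh founder-population gamete
        hap[i, 0] = (
            _gamete(hap[s], sizes, rec, rng)
            if s >= 0
            else (rng.random(cfg.n_snp) < p).astype(np.int8)
        )
        hap[i, 1] = (
            _gamete(hap[d], sizes, rec, rng)
            if d >= 0
            else (rng.random(cfg.n_snp) < p).astype(np.int8)
        )
    return hap, snp_map, p


def _genotyped_ids(ped: Pedigree, cfg: SimConfig, rng) -> list[str]:
    props = cfg.prop_genotyped_by_cohort
    gens = ped.birth_year - cfg.base_year
    if props is None:
        props = [0.0] * cfg.n_generations + [1.0]
    ids = []
    for g in range(cfg.n_generations + 1):
        members = np.flatnonzero(gens == g)
        f = props[g] if g < len(props) else props[-1]
        k = int(round(f * members.size))
        if k > 0:
            chosen = rng.choice(members, size=k, replace=False)
            ids.extend(ped.ids[i] for i in sorted(chosen))
    return ids


def drop_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes down a sorted pedigree; emit genotyped cohorts."""
    _, rng_geno, _ = cfg._rngs()
    hap, snp_map, _ = _drop_full(ped, cfg, rng_geno)
    ids = _genotyped_ids(ped, cfg, rng_geno)
    rows = [ped.id_index[a] for a in ids]
    dos = hap[rows].sum(axis=1).astype(float)
    return GenotypeMatrix(dos, ids, snp_map)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _corr_or_identity(R, T: int) -> np.ndarray:
    if R is None:
        return np.eye(T)
    R = np.asarray(R, dtype=float)
    if R.shape != (T, T):
        raise ValueError("correlation matrix shape mismatch")
    return R


def _qtl_effects_and_tbv(dosages: np.ndarray, p: np.ndarray, cfg: SimConfig, rng):
    T = cfg.n_traits
    qtl_idx = np.sort(rng.choice(cfg.n_snp, size=cfg.n_qtl, replace=False))
    L = np.linalg.cholesky(_corr_or_identity(cfg.genetic_correlations, T))
    raw = rng.standard_normal((cfg.n_qtl, T)) @ L.T
    Mq = dosages[:, qtl_idx] - 2.0 * p[qtl_idx]
    tbv = Mq @ raw
    eff = raw.copy()
    for t in range(T):
        target = cfg.h2[t]  # phenotypic variance fixed at 1
        v = float(np.var(tbv[:, t]))
        if target > 0 and v <= 0:
            raise ValueError("zero genetic variance among QTL; cannot reach target h2")
        scale = np.sqrt(target / v) if target > 0 else 0.0
        tbv[:, t] *= scale
        eff[:, t] *= scale
    return qtl_idx, eff, tbv


def _record_animals(ped: Pedigree, cfg: SimConfig, rng) -> np.ndarray:
    gens = ped.birth_year - cfg.base_year
    which = cfg.phenotyped_generations or tuple(range(1, cfg.n_generations + 1))
    mask = np.isin(gens, which)
    if cfg.phenotyped_sex in ("M", "F"):
        mask &= ped.sex == cfg.phenotyped_sex
    idx = np.flatnonzero(mask)
    if cfg.phenotyped_fraction < 1.0:
        k = int(round(cfg.phenotyped_fraction * idx.size))
        idx = np.sort(rng.choice(idx, size=k, replace=False))
    if idx.size == 0:
        raise ValueError("no animal qualifies for a phenotype record")
    return idx


def simulate_phenotypes(
    ped: Pedigree, g: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate correlated traits on top of a full genotype matrix.

    ``g`` must cover every pedigree animal (the truth needs everyone's
    genotype even when only a subset is 'observed' downstream).
    """
    if g.n_animals != ped.n:
        raise ValueError("simulate_phenotypes needs genotypes for every pedigree animal")
    _, _, rng = cfg._rngs()
    return _build_phenotypes(ped, g, cfg, rng)


def _build_phenotypes(
    ped: Pedigree,
    g: GenotypeMatrix,
    cfg: SimConfig,
    rng,
    qtl_idx: np.ndarray | None = None,
    eff: np.ndarray | None = None,
    center_p: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Trait machinery; a predetermined QTL architecture (from the
    selection engine) can be injected via ``qtl_idx``/``eff``."""
    T = cfg.n_traits
    p = g.dosages.mean(axis=0) / 2.0 if center_p is None else center_p
    if qtl_idx is None:
        qtl_idx, eff, tbv = _qtl_effects_and_tbv(g.dosages, p, cfg, rng)
    else:
        tbv = (g.dosages[:, qtl_idx] - 2.0 * p[qtl_idx]) @ eff

    rec_idx = _record_animals(ped, cfg, rng)
    n = rec_idx.size
    # contemporary groups: birth-year cohorts split into random subgroups
    gens = (ped.birth_year - cfg.base_year)[rec_idx]
    n_sub = max(1, int(round(cfg.n_contemporary_groups / max(len(set(gens)), 1))))
    sub = rng.integers(n_sub, size=n)
    cg_labels = np.array([f"y{gq}s{sq}" for gq, sq in zip(gens, sub)])
    cg_levels = sorted(set(cg_labels))
    cg_eff = rng.normal(0.0, cfg.cg_sd, size=(len(cg_levels), T))
    cg_of = {lev: i for i, lev in enumerate(cg_levels)}
    parity = rng.integers(1, cfg.n_parity_classes + 1, size=n)
    par_eff = rng.normal(0.0, cfg.parity_sd, size=(cfg.n_parity_classes, T))

    Le = np.linalg.cholesky(_corr_or_identity(cfg.residual_correlations, T))
    resid = rng.standard_normal((n, T)) @ Le.T
    resid *= np.sqrt(1.0 - np.array(cfg.h2))

    Y = (
        tbv[rec_idx]
        + resid
        + cg_eff[[cg_of[c] for c in cg_labels]]
        + par_eff[parity - 1]
    )
    phen = pd.DataFrame({"animal": [ped.ids[i] for i in rec_idx]})
    for t, name in enumerate(cfg.trait_names):
        phen[name] = Y[:, t]
    phen["contemporary_group"] = cg_labels
    phen["parity_class"] = parity
    phen["birth_year"] = ped.birth_year[rec_idx]

    gvar = tbv[rec_idx].var(axis=0)
    realized_h2 = gvar / Y.var(axis=0)
    qtl = g.snp_map.iloc[qtl_idx].reset_index(drop=True).copy()
    for t, name in enumerate(cfg.trait_names):
        qtl[f"effect_{name}"] = eff[:, t]
    truth = TruthBundle(
        tbv=pd.DataFrame(tbv, index=pd.Index(ped.ids, name="animal"), columns=list(cfg.trait_names)),
        qtl=qtl,
        realized_h2=realized_h2,
        founder_freqs=p,
        realized_freqs=g.dosages.mean(axis=0) / 2.0,
        sigma_a=np.sqrt(np.array(cfg.h2)),
    )
    return phen, truth


# ---------------------------------------------------------------------------
# full engine
# ---------------------------------------------------------------------------


def _structure_selected(cfg: SimConfig, rng_ped, rng_geno, rng_phen):
    """Generation loop with truncation selection on the first trait.

    Genotypes are dropped generation by generation so selection decisions
    and emitted genotypes stay consistent.
    """
    sizes, snp_map, rec = _chromosome_layout(cfg)
    T = cfg.n_traits
    fh, p = _founder_haplotypes(cfg, cfg.n_founders, rng_geno)
    L = np.linalg.cholesky(_corr_or_identity(cfg.genetic_correlations, T))
    qtl_idx = np.sort(rng_phen.choice(cfg.n_snp, size=cfg.n_qtl, replace=False))
    raw = rng_phen.standard_normal((cfg.n_qtl, T)) @ L.T
    # scale QTL effects on founder genetic variance
    Mq = fh.sum(axis=1)[:, qtl_idx] - 2.0 * p[qtl_idx]
    g0 = Mq @ raw
    eff = raw.copy()
    for t in range(T):
        v = float(np.var(g0[:, t]))
        if cfg.h2[t] > 0 and v <= 0:
            raise ValueError("zero founder genetic variance; cannot apply selection")
        eff[:, t] *= np.sqrt(cfg.h2[t] / v) if cfg.h2[t] > 0 else 0.0

    rows, haps = [], []
    prev = []
    idx = 0
    for g in range(cfg.n_generations + 1):
        size = cfg.n_founders if g == 0 else cfg.cohort_size
        cur = []
        if g > 0:
            tb = np.array(
                [
                    (haps[i].sum(axis=0)[qtl_idx] - 2.0 * p[qtl_idx]) @ eff
                    for i in prev
                ]
            )
            noise = rng_phen.standard_normal(len(prev)) * np.sqrt(max(1.0 - cfg.h2[0], 1e-12))
            score = tb[:, 0] + noise
            sex = np.array([rows[i]["sex"] for i in prev])
            elig: dict[str, list[int]] = {}
            for sx in ("M", "F"):
                cand = np.flatnonzero(sex == sx)
                if cand.size == 0:
                    raise RuntimeError(f"generation {g - 1} lacks {sx} parents")
                k = max(1, int(round(cfg.selected_fraction * cand.size)))
                top = cand[np.argsort(score[cand])[::-1][:k]]
                elig[sx] = [prev[i] for i in top]
            n_matings = int(np.ceil(size / cfg.offspring_per_mating))
            sires = rng_ped.choice(elig["M"], size=n_matings, replace=True)
            dams = rng_ped.choice(elig["F"], size=n_matings, replace=True)
        for k in range(size):
            if g == 0:
                srow = drow = "0"
                h = fh[k]
            else:
                m = k // cfg.offspring_per_mating
                srow, drow = rows[sires[m]]["animal"], rows[dams[m]]["animal"]
                h = np.stack(
                    [
                        _gamete(haps[sires[m]], sizes, rec, rng_geno),
                        _gamete(haps[dams[m]], sizes, rec, rng_geno),
                    ]
                )
            rows.append(
                {
                    "animal": f"A{idx:06d}",
                    "sire": srow,
                    "dam": drow,
                    "birth_year": cfg.base_year + g,
                    "sex": "M" if rng_ped.random() < 0.5 else "F",
                }
            )
            haps.append(h)
            cur.append(idx)
            idx += 1
        prev = cur
    ped = Pedigree(pd.DataFrame(rows))
    order = [ped.id_index[r["animal"]] for r in rows]
    hap = np.zeros((ped.n, 2, cfg.n_snp), dtype=np.int8)
    for src, dst in enumerate(order):
        hap[dst] = haps[src]
    return ped, hap, snp_map, p, qtl_idx, eff


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Generate the full bundle (pedigree, genotypes, phenotypes, truth)."""
    rng_ped, rng_geno, rng_phen = cfg._rngs()
    if cfg.selection == "NONE":
        ped = Pedigree(_structure_random(cfg, rng_ped).drop(columns="generation"))
        hap, snp_map, _ = _drop_full(ped, cfg, rng_geno)
        full = GenotypeMatrix(hap.sum(axis=1).astype(float), list(ped.ids), snp_map)
        phen, truth = _build_phenotypes(ped, full, cfg, rng_phen)
    else:
        ped, hap, snp_map, p, qtl_idx, eff = _structure_selected(
            cfg, rng_ped, rng_geno, rng_phen
        )
        full = GenotypeMatrix(hap.sum(axis=1).astype(float), list(ped.ids), snp_map)
        phen, truth = _build_phenotypes(
            ped, full, cfg, rng_phen, qtl_idx=qtl_idx, eff=eff, center_p=p
        )
    ids = _genotyped_ids(ped, cfg, rng_geno)
    rows = [ped.id_index[a] for a in ids]
    observed = GenotypeMatrix(full.dosages[rows].copy(), ids, snp_map.copy())
    return SimData(cfg, ped, observed, phen, truth)


# ---------------------------------------------------------------------------
# scaled study-like bundle
# ---------------------------------------------------------------------------

# Table-2-style targets for the three performance-test traits
_RENDENA_H2 = (0.335, 0.304, 0.392)
_RENDENA_RG = np.array(
    [
        [1.000, 0.364, 0.398],
        [0.364, 1.000, 0.981],
        [0.398, 0.981, 1.000],
    ]
)
_RENDENA_RE = np.array(
    [
        [1.000, 0.572, 0.613],
        [0.572, 1.000, 0.792],
        [0.613, 0.792, 1.000],
    ]
)


def rendena_like_dataset(seed: int = 0, scale: float = 0.25) -> SimData:
    """A scaled emulation of the study population structure.

    At scale 0.25: ~2,100-animal pedigree over 7 cohorts, phenotypes on
    the males of the last three cohorts (~450 performance-tested bulls),
    genotyping concentrated in recent cohorts (~450 animals), three
    correlated traits with heritability targets (0.335, 0.304, 0.392).
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    n_gen = 6
    cohort = max(30, int(round(8372 * scale / (n_gen + 1))))
    cfg = SimConfig(
        seed=seed,
        n_founders=cohort,
        n_generations=n_gen,
        n_snp=max(400, int(round(8000 * scale))),
        n_chromosomes=29,
        n_qtl=30,
        h2=_RENDENA_H2,
        trait_names=("ADG", "EUROP", "DP"),
        genetic_correlations=_RENDENA_RG,
        residual_correlations=_RENDENA_RE,
        n_contemporary_groups=max(8, int(round(142 * scale))),
        n_parity_classes=4,
        phenotyped_generations=(4, 5, 6),
        phenotyped_sex="M",
        prop_genotyped_by_cohort=(0.0, 0.0, 0.0, 0.0, 0.3, 0.5, 0.7),
        base_year=2010,
    )
    return simulate_dataset(cfg)
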