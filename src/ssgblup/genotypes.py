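"""SNP genotype container, file readers and quality control.

Dosages are coded 0/1/2 copies of the counted allele (real-valued after
mean imputation of residual missing calls).  Quality control mirrors the
usual preGSf90-style pipeline: per-SNP call rate, minor allele frequency,
Hardy–Weinberg heterozygote deviation, then per-animal call rate; what
remains is mean-imputed to 2p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "allele_frequencies",
    "qc_filter",
    "read_plink_raw",
    "read_genotype_csv",
]

# columns of a PLINK --recode A export that precede the SNP dosages
_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus SNP map and allele frequencies.

    dosages : (n_animals, n_snp) float array, NaN = missing call
    animal_ids : row labels
    snp_map : DataFrame with columns snp_id, chrom, pos (sorted by
        chromosome then position)
    """

    dosages: np.ndarray
    animal_ids: list
    snp_map: pd.DataFrame
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x SNPs)")
        if len(self.animal_ids) != self.dosages.shape[0]:
            raise ValueError("animal_ids length mismatch")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ValueError("snp_map length mismatch")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2]")
        sm = self.snp_map.reset_index(drop=True)
        order = np.lexsort((sm["pos"].to_numpy(), sm["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(sm))):
            self.snp_map = sm.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
            if self.freqs is not None:
                self.freqs = np.asarray(self.freqs)[order]
        else:
            self.snp_map = sm

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def subset_animals(self, ids: list) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [index[a] for a in ids]
        return GenotypeMatrix(
            self.dosages[rows], list(ids), self.snp_map.copy(),
            None if self.freqs is None else self.freqs.copy(),
        )

    def centered(self) -> np.ndarray:
        """M = dosages − 2p, the centered marker matrix of VanRaden."""
        p = self.freqs if self.freqs is not None else allele_frequencies(self)
        return self.dosages - 2.0 * p


@dataclass
class QCThresholds:
    """Removal thresholds; defaults follow common 50K-chip practice."""

    maf_min: float = 0.05
    callrate_min_snp: float = 0.90
    callrate_min_animal: float = 0.90
    hwe_max_dev: float = 0.15

    def __post_init__(self) -> None:
        for name in ("maf_min", "callrate_min_snp", "callrate_min_animal", "hwe_max_dev"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    n_snp_in: int = 0
    n_animals_in: int = 0
    removed_callrate_snp: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_callrate_animal: int = 0
    n_snp_out: int = 0
    n_animals_out: int = 0
    removed_snp_ids: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["callrate_snp", "maf", "hwe", "callrate_animal"],
                "removed": [
                    self.removed_callrate_snp,
                    self.removed_maf,
                    self.removed_hwe,
                    self.removed_callrate_animal,
                ],
            }
        )


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Observed ("current") allele frequency of the counted allele per SNP."""
    if g.n_snp == 0 or g.n_animals == 0:
        raise ValueError("empty genotype matrix")
    import warnings as _w

    with np.errstate(invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g.dosages, axis=0) / 2.0
    if np.isnan(p).any():
        bad = g.snp_map["snp_id"].iloc[int(np.flatnonzero(np.isnan(p))[0])]
        raise ValueError(f"SNP '{bad}' has no called genotypes")
    return p


def qc_filter(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP call rate → MAF → HWE → animal call rate, then impute.

    The HWE rule removes SNPs whose observed heterozygote frequency
    deviates from the Hardy–Weinberg expectation 2p(1−p) by more than
    ``hwe_max_dev``.
    """
    t = t or QCThresholds()
    rep = QCReport(n_snp_in=g.n_snp, n_animals_in=g.n_animals)
    X = g.dosages.copy()
    snp_keep = np.ones(g.n_snp, dtype=bool)
    called = ~np.isnan(X)

    # 1. SNP call rate
    cr = called.mean(axis=0)
    drop = cr < t.callrate_min_snp
    rep.removed_callrate_snp = int(drop.sum())
    rep.removed_snp_ids["callrate_snp"] = list(g.snp_map["snp_id"][drop])
    snp_keep &= ~drop

    # 2. MAF
    with np.errstate(invalid="ignore"):
        p = np.where(called.any(axis=0), np.nanmean(np.where(called, X, np.nan), axis=0) / 2.0, 0.0)
    maf = np.minimum(p, 1.0 - p)
    drop = (maf < t.maf_min) & snp_keep
    rep.removed_maf = int(drop.sum())
    rep.removed_snp_ids["maf"] = list(g.snp_map["snp_id"][drop])
    snp_keep &= ~drop

    # 3. HWE heterozygote deviation
    with np.errstate(invalid="ignore"):
        het = np.where(called.any(axis=0), np.nanmean(np.where(called, X == 1.0, np.nan), axis=0), 0.0)
    dev = np.abs(het - 2.0 * p * (1.0 - p))
    drop = (dev > t.hwe_max_dev) & snp_keep
    rep.removed_hwe = int(drop.sum())
    rep.removed_snp_ids["hwe"] = list(g.snp_map["snp_id"][drop])
    snp_keep &= ~drop

    if not snp_keep.any():
        raise ValueError("quality control removed every SNP")
    X = X[:, snp_keep]
    called = called[:, snp_keep]

    # 4. animal call rate
    acr = called.mean(axis=1)
    animal_keep = acr >= t.callrate_min_animal
    rep.removed_callrate_animal = int((~animal_keep).sum())
    if not animal_keep.any():
        raise ValueError("quality control removed every animal")
    X = X[animal_keep]

    out = GenotypeMatrix(
        X,
        [a for a, k in zip(g.animal_ids, animal_keep) if k],
        g.snp_map[snp_keep].reset_index(drop=True),
    )
    # impute residual missing calls to the column mean 2p
    p = allele_frequencies(out)
    miss = np.isnan(out.dosages)
    if miss.any():
        out.dosages[miss] = np.broadcast_to(2.0 * p, out.dosages.shape)[miss]
    out.freqs = p
    rep.n_snp_out = out.n_snp
    rep.n_animals_out = out.n_animals
    return out, rep


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _default_map(snp_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snp_id": snp_ids, "chrom": 1, "pos": np.arange(1, len(snp_ids) + 1)}
    )


def read_snp_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    need = {"snp_id", "chrom", "pos"}
    if not need <= set(m.columns):
        raise ValueError(f"SNP map must have columns {sorted(need)}")
    return m[["snp_id", "chrom", "pos"]]


def read_plink_raw(path, snp_map=None) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` additive-dosage export (.raw).

    SNP columns are named ``<snp_id>_<counted allele>``; ``NA`` marks a
    missing call.  ``snp_map`` (TSV path or DataFrame) supplies genomic
    coordinates; without it SNPs are placed on one nominal chromosome in
    file order.
    """
    df = pd.read_csv(path, sep=r"\s+")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    ids = [str(i) for i in df["IID"]] if "IID" in df.columns else [str(i) for i in df.index]
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    dos = df[snp_cols].to_numpy(dtype=float)
    if snp_map is None:
        m = _default_map(snp_ids)
    else:
        m = snp_map if isinstance(snp_map, pd.DataFrame) else read_snp_map(snp_map)
        m = m.set_index("snp_id").loc[snp_ids].reset_index()
    return GenotypeMatrix(dos, ids, m)


def read_genotype_csv(path, snp_map=None) -> GenotypeMatrix:
    """Read a plain CSV dosage matrix: first column ``animal``, one column
    per SNP, values 0/1/2 or empty for missing."""
    df = pd.read_csv(path)
    ids = [str(a) for a in df.iloc[:, 0]]
    snp_ids = list(df.columns[1:])
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    if snp_map is None:
        m = _default_map(snp_ids)
    else:
        m = snp_map if isinstance(snp_map, pd.DataFrame) else read_snp_map(snp_map)
        m = m.set_index("snp_id").loc[snp_ids].reset_index()
    return GenotypeMatrix(dos, ids, m)


def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, columns=list(g.snp_map["snp_id"]))
    df.insert(0, "animal", g.animal_ids)
    df.to_csv(path, index=False)
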