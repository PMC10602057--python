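"""Synthetic GWAS summary-statistic panels with known factor structure.

Simulation operates at the z-statistic level (no genotypes): per SNP j the
P-vector of z-statistics is multivariate normal with covariance

    C_j = D_N^{1/2} (Sigma_g * l_j / M) D_N^{1/2} + C_e,

the generative inverse of the LDSC moment model; D_N = diag(N_p), l_j the
SNP's LD score, and C_e the error covariance with unit diagonal and
off-diagonals ``overlap_rho`` (phenotypic correlation times sample-overlap
fraction, absorbed by the bivariate LDSC intercept).  Sigma_g is built from
standardized loadings Lambda, factor correlations Phi and per-phenotype
heritabilities, so every pipeline stage has exact ground truth.  Fixed
SNP-to-factor effects can be injected for latent-GWAS power checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gibnet.sumstats import LdScoreTable, SumStatsPanel, write_ldscores, write_sumstats

N_AUTOSOMES = 22


def default_loadings(p: int = 12, k: int = 2) -> np.ndarray:
    """Block loading pattern: p/k phenotypes per factor, loadings 0.5-0.8."""
    if p % k:
        raise ValueError("p must be divisible by k for the block pattern")
    per = p // k
    lam = np.zeros((p, k))
    vals = np.linspace(0.5, 0.8, per)
    for f in range(k):
        lam[f * per : (f + 1) * per, f] = vals
    return lam


@dataclass
class TruthConfig:
    """Generative ground truth for one synthetic panel.

    ``lambda_true`` and ``phi_true`` live on the genetic-correlation scale
    (unit-diagonal Sigma before the h2 rescale); ``h2`` is the total
    per-phenotype SNP heritability, and the residual genetic variance is
    whatever the factors leave unexplained.  ``injected_effects`` is a list
    of (snp_id, factor index, per-allele effect a).
    """

    p: int = 12
    m: int = 20_000
    n: float = 30_000.0
    lambda_true: np.ndarray = field(default_factory=default_loadings)
    phi_true: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.45], [0.45, 1.0]]))
    h2: float | np.ndarray = 0.3
    overlap_rho: float = 0.0
    ld_block_size: int = 50
    ld_mean: float = 10.0
    injected_effects: tuple[tuple[str, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.lambda_true = np.asarray(self.lambda_true, float)
        self.phi_true = np.asarray(self.phi_true, float)
        if self.lambda_true.shape[0] != self.p:
            raise ValueError("lambda_true rows must equal p")
        k = self.lambda_true.shape[1]
        if self.phi_true.shape != (k, k):
            raise ValueError("phi_true must be k x k")
        if not np.allclose(np.diag(self.phi_true), 1.0):
            raise ValueError("phi_true must have unit diagonal")
        if np.linalg.eigvalsh(self.phi_true).min() < -1e-10:
            raise ValueError("phi_true is not positive semidefinite")
        h2 = np.broadcast_to(np.asarray(self.h2, float), (self.p,))
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("h2 must lie in [0, 1]")
        comm = np.diag(self.lambda_true @ self.phi_true @ self.lambda_true.T)
        if np.any(comm > 1.0 + 1e-10):
            raise ValueError("factor communalities exceed 1; shrink the loadings")
        if not (-1.0 / (self.p - 1) <= self.overlap_rho <= 1.0):
            raise ValueError("overlap_rho makes the error covariance non-PSD")
        if self.ld_mean < 1.0:
            raise ValueError("ld_mean must be >= 1")

    @property
    def k(self) -> int:
        return self.lambda_true.shape[1]

    @property
    def h2_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.h2, float), (self.p,)).copy()

    @property
    def n_per_phenotype(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.n, float), (self.p,)).copy()

    @property
    def resid_h2(self) -> np.ndarray:
        """Residual genetic variance: h2 times the uniqueness."""
        comm = np.diag(self.lambda_true @ self.phi_true @ self.lambda_true.T)
        return self.h2_vector * (1.0 - comm)

    @property
    def genetic_correlation(self) -> np.ndarray:
        comm = self.lambda_true @ self.phi_true @ self.lambda_true.T
        r = comm.copy()
        np.fill_diagonal(r, 1.0)
        return r

    @property
    def sigma_g(self) -> np.ndarray:
        """Implied genetic covariance: diag sqrt(h2) * R_g * diag sqrt(h2)."""
        hr = np.sqrt(self.h2_vector)
        return self.genetic_correlation * np.outer(hr, hr)

    @property
    def phenotype_names(self) -> list[str]:
        return [f"region{i + 1:02d}" for i in range(self.p)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "p": self.p,
                "m": self.m,
                "n": self.n,
                "lambda_true": self.lambda_true.tolist(),
                "phi_true": self.phi_true.tolist(),
                "h2": np.asarray(self.h2).tolist(),
                "overlap_rho": self.overlap_rho,
                "ld_block_size": self.ld_block_size,
                "ld_mean": self.ld_mean,
                "injected_effects": [list(e) for e in self.injected_effects],
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthConfig":
        d = json.loads(text)
        return cls(
            p=d["p"],
            m=d["m"],
            n=d["n"],
            lambda_true=np.asarray(d["lambda_true"]),
            phi_true=np.asarray(d["phi_true"]),
            h2=np.asarray(d["h2"]) if isinstance(d["h2"], list) else d["h2"],
            overlap_rho=d["overlap_rho"],
            ld_block_size=d["ld_block_size"],
            ld_mean=d["ld_mean"],
            injected_effects=tuple((e[0], int(e[1]), float(e[2])) for e in d["injected_effects"]),
            seed=d["seed"],
        )


@dataclass
class SyntheticDataset:
    panel: SumStatsPanel
    ldscores: LdScoreTable
    truth: TruthConfig

    def __post_init__(self) -> None:
        if not np.array_equal(self.panel.snp_id, self.ldscores.snp_id):
            raise ValueError("panel and LD-score SNP ids disagree")


def ldscore_block_model(m: int, block_size: int = 50, ld_mean: float = 10.0,
                        seed: int | None = None) -> LdScoreTable:
    """Blocked LD scores: contiguous blocks share one l drawn from 1 + Gamma.

    The shifted gamma (shape 4) has mean ``ld_mean`` and is floored at 1 by
    construction; blocks are dealt to chromosomes 1-22 in contiguous shares.
    """
    if m < 1 or block_size < 1:
        raise ValueError("m and block_size must be positive")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(m / block_size))
    if ld_mean > 1.0:
        shape = 4.0
        block_l = 1.0 + rng.gamma(shape, (ld_mean - 1.0) / shape, size=n_blocks)
    else:
        block_l = np.ones(n_blocks)
    block_of_snp = np.repeat(np.arange(n_blocks), block_size)[:m]
    chrom_of_block = np.concatenate(
        [np.full(len(part), c + 1, dtype=int)
         for c, part in enumerate(np.array_split(np.arange(n_blocks), N_AUTOSOMES))]
    )
    chrom = chrom_of_block[block_of_snp]
    bp = np.empty(m, dtype=int)
    for c in range(1, N_AUTOSOMES + 1):
        mask = chrom == c
        bp[mask] = (np.arange(mask.sum()) + 1) * 10_000
    return LdScoreTable(
        snp_id=np.array([f"rs{i + 1}" for i in range(m)], dtype=object),
        chrom=chrom,
        bp=bp,
        l2=block_l[block_of_snp],
    )


def simulate_z_panel(truth: TruthConfig, ldscores: LdScoreTable) -> SumStatsPanel:
    """Draw the z-statistic panel from the LDSC moment model; seed-deterministic."""
    m = len(ldscores)
    nvec = truth.n_per_phenotype
    sigma = truth.sigma_g
    ce = np.full((truth.p, truth.p), truth.overlap_rho)
    np.fill_diagonal(ce, 1.0)
    dn = np.sqrt(np.outer(nvec, nvec))

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2026]))
    maf = rng.uniform(0.05, 0.5, size=m)
    z = np.empty((m, truth.p))
    # one Cholesky per distinct LD-score value (one per block)
    ells = ldscores.l2
    change = np.flatnonzero(np.r_[True, np.diff(ells) != 0])
    bounds = np.r_[change, m]
    for s, e in zip(bounds[:-1], bounds[1:]):
        c = dn * sigma * (ells[s] / truth.m) + ce
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("per-SNP covariance is not positive definite; "
                             "check Sigma_g and overlap_rho") from exc
        z[s:e] = rng.standard_normal((e - s, truth.p)) @ chol.T

    return SumStatsPanel(
        phenotype_names=truth.phenotype_names,
        snp_id=ldscores.snp_id.copy(),
        chrom=ldscores.chrom.copy(),
        bp=ldscores.bp.copy(),
        a1=np.full(m, "A", dtype=object),
        a2=np.full(m, "G", dtype=object),
        maf=maf,
        z=z,
        n=np.tile(nvec, (m, 1)),
    )


def inject_fixed_snp_effects(panel: SumStatsPanel, truth: TruthConfig) -> SumStatsPanel:
    """Add fixed SNP->factor effects to the z-statistics.

    For each (snp_id, factor f, a): z_p += sqrt(N_p) * lambda_pf * a *
    sqrt(2 maf (1 - maf)); a = 0 is a no-op.  Unknown SNP ids or factor
    indices are errors.
    """
    if not truth.injected_effects:
        return panel
    z = panel.z.copy()
    pos = {sid: i for i, sid in enumerate(panel.snp_id)}
    for snp_id, f, a in truth.injected_effects:
        if snp_id not in pos:
            raise KeyError(f"injection target {snp_id!r} absent from the panel")
        if not (0 <= f < truth.k):
            raise IndexError(f"factor index {f} out of range for k={truth.k}")
        i = pos[snp_id]
        maf = panel.maf[i]
        shift = np.sqrt(panel.n[i]) * truth.lambda_true[:, f] * a * np.sqrt(2 * maf * (1 - maf))
        z[i] = z[i] + shift
    out = SumStatsPanel(
        phenotype_names=list(panel.phenotype_names),
        snp_id=panel.snp_id, chrom=panel.chrom, bp=panel.bp,
        a1=panel.a1, a2=panel.a2, maf=panel.maf, z=z, n=panel.n,
    )
    return out


def generate_dataset(truth: TruthConfig) -> SyntheticDataset:
    """LD scores + z panel + injected effects, all derived from truth.seed."""
    ldscores = ldscore_block_model(truth.m, truth.ld_block_size, truth.ld_mean,
                                   seed=truth.seed)
    panel = simulate_z_panel(truth, ldscores)
    panel = inject_fixed_snp_effects(panel, truth)
    return SyntheticDataset(panel=panel, ldscores=ldscores, truth=truth)


def write_synthetic_dataset(dataset: SyntheticDataset, directory: str | Path,
                            overwrite: bool = False) -> None:
    """One .sumstats file per phenotype, one LD-score table, one truth JSON."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    for name in dataset.panel.phenotype_names:
        write_sumstats(dataset.panel, name, directory / f"{name}.sumstats")
    write_ldscores(dataset.ldscores, directory / "ldscores.tsv")
    (directory / "truth.json").write_text(dataset.truth.to_json())
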