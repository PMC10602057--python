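"""LD score regression: heritability, genetic covariance, and the jackknife.

The univariate model regresses per-SNP z^2 on LD score l_j,

    E[z_j^2] = intercept + (N h2 / M) * l_j,

with a free intercept absorbing confounding; the bivariate model regresses
the z-product of two studies,

    E[z_aj z_bj] = intercept + (sqrt(N_a N_b) rho_g / M) * l_j,

whose intercept absorbs sample overlap.  Slopes are rescaled to h2 / rho_g
via M over the mean sample size.  Estimation is a deterministic two-pass
weighted regression (unweighted pass to get provisional variance parameters,
then heteroscedasticity weights); standard errors come from a delete-block
jackknife over contiguous genome-ordered SNP blocks.  The full P x P
genetic covariance matrix shares a single block partition across all
P(P+1)/2 regressions so the jackknife sampling covariance V is coherent
across elements — required for a valid DWLS factor-model fit downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from gibnet.sumstats import LdScoreTable, SnpRecord, SumStatsPanel, harmonize_panel

DEFAULT_N_BLOCKS = 200


class UndefinedRgError(ValueError):
    """Genetic correlation undefined because a heritability is non-positive."""


@dataclass
class LdscFit:
    """One LDSC regression: h2 (kind='h2') or genetic covariance (kind='gencov')."""

    estimate: float
    intercept: float
    se_estimate: float
    se_intercept: float
    n_blocks: int
    m: int
    kind: str = "h2"

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("jackknife needs at least 2 blocks")
        if self.m < self.n_blocks:
            raise ValueError("fewer SNPs than jackknife blocks")


def vech_indices(p: int) -> list[tuple[int, int]]:
    """Row-major half-vectorization order (i, j) with i <= j, diagonal included."""
    return [(i, j) for i in range(p) for j in range(i, p)]


@dataclass
class GeneticCovariance:
    """LDSC genetic covariance matrix S with jackknife sampling covariance V.

    ``v`` covers the P(P+1)/2 unique elements of ``s`` in the order of
    :func:`vech_indices`.
    """

    labels: list[str]
    s: np.ndarray
    v: np.ndarray
    chrom_subset: str = "all"
    n_blocks: int = DEFAULT_N_BLOCKS
    m: int = 0

    def __post_init__(self) -> None:
        p = len(self.labels)
        e = p * (p + 1) // 2
        if self.s.shape != (p, p):
            raise ValueError("S dimension does not match labels")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("S must be symmetric")
        if self.v.shape != (e, e):
            raise ValueError(f"V must be {e}x{e} for P={p}")

    @property
    def p(self) -> int:
        return len(self.labels)

    def vech(self) -> np.ndarray:
        return np.array([self.s[i, j] for i, j in vech_indices(self.p)])

    def element_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.v), 0.0, None))

    def reorder(self, labels: Sequence[str]) -> "GeneticCovariance":
        """Permute phenotypes; S and V are permuted consistently."""
        perm = [self.labels.index(l) for l in labels]
        s = self.s[np.ix_(perm, perm)]
        old = {ij: e for e, ij in enumerate(vech_indices(self.p))}
        emap = []
        for i, j in vech_indices(self.p):
            a, b = perm[i], perm[j]
            emap.append(old[(min(a, b), max(a, b))])
        v = self.v[np.ix_(emap, emap)]
        return GeneticCovariance(list(labels), s, v, self.chrom_subset, self.n_blocks, self.m)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        import pandas as pd

        pd.DataFrame(self.s, index=self.labels, columns=self.labels).to_csv(
            f"{prefix}_S.tsv", sep="\t"
        )
        names = [f"{self.labels[i]}:{self.labels[j]}" for i, j in vech_indices(self.p)]
        pd.DataFrame(self.v, index=names, columns=names).to_csv(f"{prefix}_V.tsv", sep="\t")
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "chrom_subset": self.chrom_subset,
                    "n_blocks": self.n_blocks,
                    "m": self.m,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "GeneticCovariance":
        import pandas as pd

        with open(f"{prefix}_meta.json") as fh:
            meta = json.load(fh)
        s = pd.read_csv(f"{prefix}_S.tsv", sep="\t", index_col=0).to_numpy()
        v = pd.read_csv(f"{prefix}_V.tsv", sep="\t", index_col=0).to_numpy()
        return cls(meta["labels"], s, v, meta["chrom_subset"], meta["n_blocks"], meta["m"])


@dataclass
class RgEstimate:
    """Cross-trait genetic correlation with jackknife SE and two-sided p."""

    rg: float
    se: float
    p: float
    q: float | None = None
    out_of_bounds: bool = field(default=False)

    def __post_init__(self) -> None:
        self.out_of_bounds = abs(self.rg) > 1.0


# ---------------------------------------------------------------- internals


def _resolve_blocks(m: int, n_blocks: int) -> np.ndarray:
    """Contiguous block boundaries; fall back to floor(m/10) blocks at desk scale."""
    if m < 2 * n_blocks:
        n_blocks = max(m // 10, 2)
    if n_blocks > m:
        raise ValueError(f"{n_blocks} jackknife blocks exceed {m} SNPs")
    if n_blocks < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray,
             bounds: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Weighted regression of y on x with intercept, plus delete-block estimates.

    Weights are held fixed across jackknife blocks.  Returns
    (slope, intercept, loo_slopes, loo_intercepts).
    """
    terms = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    block_sums = np.add.reduceat(terms, bounds[:-1], axis=0)
    total = block_sums.sum(axis=0)

    def solve(s: np.ndarray) -> tuple[float, float]:
        sw, sx, sxx, sy, sxy = s
        denom = sw * sxx - sx * sx
        if denom <= 0:
            return 0.0, sy / sw if sw > 0 else 0.0
        slope = (sw * sxy - sx * sy) / denom
        return slope, (sy - slope * sx) / sw

    slope, intercept = solve(total)
    loo = total[None, :] - block_sums
    loo_slopes = np.empty(len(block_sums))
    loo_inters = np.empty(len(block_sums))
    for b in range(len(block_sums)):
        loo_slopes[b], loo_inters[b] = solve(loo[b])
    return slope, intercept, loo_slopes, loo_inters


def jackknife_cov(loo_estimates: np.ndarray) -> np.ndarray:
    """Delete-block jackknife covariance of (possibly vector) estimators.

    ``loo_estimates`` is (B, E): one leave-one-block-out estimate per block
    per element.  Returns v with
    v[e, f] = ((B-1)/B) * sum_b (t_eb - tbar_e)(t_fb - tbar_f).
    """
    loo = np.atleast_2d(np.asarray(loo_estimates, dtype=float))
    if loo.ndim != 2:
        raise ValueError("expected a (B, E) array")
    b = loo.shape[0]
    if b < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    dev = loo - loo.mean(axis=0, keepdims=True)
    return (b - 1) / b * dev.T @ dev


def _h2_weights(ell: np.ndarray, n: np.ndarray, h2: float, m: int) -> np.ndarray:
    ell = np.maximum(ell, 1.0)
    return 1.0 / (2.0 * ell * (1.0 + n * h2 * ell / m) ** 2)


def _gencov_weights(ell: np.ndarray, na: np.ndarray, nb: np.ndarray,
                    h2a: float, h2b: float, rho: float, icept: float, m: int) -> np.ndarray:
    ell = np.maximum(ell, 1.0)
    va = 1.0 + na * h2a * ell / m
    vb = 1.0 + nb * h2b * ell / m
    cab = np.sqrt(na * nb) * rho * ell / m + icept
    return 1.0 / (ell * (va * vb + cab * cab))


def h2_from_arrays(
    z: np.ndarray,
    n: np.ndarray,
    ell: np.ndarray,
    m: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weights: str = "ldsc",
    two_pass: bool = True,
) -> LdscFit:
    """Univariate LDSC on aligned arrays (genome order assumed)."""
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    ell = np.asarray(ell, float)
    m = m or len(z)
    bounds = _resolve_blocks(len(z), n_blocks)
    y = z * z
    scale = m / n.mean()
    if weights == "unit" or not two_pass:
        w = np.ones_like(ell)
    else:
        # pass 1: unweighted provisional fit
        s1, _, _, _ = _wls_fit(ell, y, np.ones_like(ell), bounds)
        h2_prov = float(np.clip(s1 * scale, 0.0, 1.0))
        w = _h2_weights(ell, n, h2_prov, m)
    slope, icept, loo_s, loo_i = _wls_fit(ell, y, w, bounds)
    b = len(loo_s)
    se_slope = np.sqrt(jackknife_cov(loo_s[:, None])[0, 0])
    se_icept = np.sqrt(jackknife_cov(loo_i[:, None])[0, 0])
    return LdscFit(
        estimate=float(slope * scale),
        intercept=float(icept),
        se_estimate=float(se_slope * scale),
        se_intercept=float(se_icept),
        n_blocks=b,
        m=m,
        kind="h2",
    )


def _subset_mask(panel: SumStatsPanel, chrom_subset: str) -> np.ndarray:
    if chrom_subset == "all":
        return np.ones(panel.n_snps, dtype=bool)
    if chrom_subset == "odd":
        return panel.chrom % 2 == 1
    if chrom_subset == "even":
        return panel.chrom % 2 == 0
    raise ValueError(f"chrom_subset must be odd/even/all, got {chrom_subset!r}")


def _align(panel: SumStatsPanel, ldscores: LdScoreTable,
           chrom_subset: str = "all") -> tuple[SumStatsPanel, np.ndarray]:
    """Join panel to LD scores on snp_id, restrict chromosomes, sort by genome order."""
    panel = panel.subset(_subset_mask(panel, chrom_subset))
    lmap = {sid: float(l2) for sid, l2 in zip(ldscores.snp_id, ldscores.l2)}
    have = np.array([sid in lmap for sid in panel.snp_id])
    if not have.any():
        raise ValueError("panel and LD-score SNP sets do not overlap")
    panel = panel.subset(have)
    order = np.lexsort((panel.bp, panel.chrom))
    panel = panel.subset(order)
    ell = np.array([lmap[sid] for sid in panel.snp_id])
    return panel, ell


def estimate_h2(
    panel: SumStatsPanel,
    phenotype: str,
    ldscores: LdScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chrom_subset: str = "all",
    weights: str = "ldsc",
    two_pass: bool = True,
) -> LdscFit:
    """SNP heritability of one phenotype by two-pass weighted LDSC."""
    sub, ell = _align(panel, ldscores, chrom_subset)
    if len(ell) < 2 * 2:
        raise ValueError("too few SNPs joinable to LD scores")
    z, n = sub.column(phenotype)
    return h2_from_arrays(z, n, ell, n_blocks=n_blocks, weights=weights, two_pass=two_pass)


def estimate_gencov(
    panel: SumStatsPanel,
    phenotype_a: str,
    phenotype_b: str,
    ldscores: LdScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chrom_subset: str = "all",
    weights: str = "ldsc",
    two_pass: bool = True,
) -> LdscFit:
    """Genetic covariance of two phenotypes by regressing the z-product on LD score."""
    sub, ell = _align(panel, ldscores, chrom_subset)
    za, na = sub.column(phenotype_a)
    zb, nb = sub.column(phenotype_b)
    m = len(ell)
    bounds = _resolve_blocks(m, n_blocks)
    y = za * zb
    scale = m / np.sqrt(na.mean() * nb.mean())
    if weights == "unit" or not two_pass:
        w = np.ones_like(ell)
    elif phenotype_a == phenotype_b:
        # self-covariance is the h2 regression; use the identical weights
        s1 = _wls_fit(ell, y, np.ones_like(ell), bounds)[0]
        h2_prov = float(np.clip(s1 * scale, 0.0, 1.0))
        w = _h2_weights(ell, na, h2_prov, m)
    else:
        s1, i1, _, _ = _wls_fit(ell, y, np.ones_like(ell), bounds)
        rho1 = s1 * scale
        h2a = float(np.clip(_wls_fit(ell, za * za, np.ones_like(ell), bounds)[0] * m / na.mean(), 0, 1))
        h2b = float(np.clip(_wls_fit(ell, zb * zb, np.ones_like(ell), bounds)[0] * m / nb.mean(), 0, 1))
        rho1 = float(np.clip(rho1, -np.sqrt(h2a * h2b) - 0.1, np.sqrt(h2a * h2b) + 0.1))
        w = _gencov_weights(ell, na, nb, h2a, h2b, rho1, i1, m)
    slope, icept, loo_s, loo_i = _wls_fit(ell, y, w, bounds)
    return LdscFit(
        estimate=float(slope * scale),
        intercept=float(icept),
        se_estimate=float(np.sqrt(jackknife_cov(loo_s[:, None])[0, 0]) * scale),
        se_intercept=float(np.sqrt(jackknife_cov(loo_i[:, None])[0, 0])),
        n_blocks=len(loo_s),
        m=m,
        kind="gencov",
    )


def build_gencov_matrix(
    panel: SumStatsPanel,
    ldscores: LdScoreTable,
    chrom_subset: str = "all",
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> GeneticCovariance:
    """All P(P+1)/2 LDSC regressions on one shared jackknife block partition.

    Diagonal elements are heritabilities, off-diagonals genetic covariances;
    V is the delete-block jackknife covariance across all elements computed
    from the same blocks, so cross-element sampling covariances are coherent.
    Phenotypes with non-positive estimated h2 are flagged with a warning (the
    matrix is still returned; standardization fails loudly downstream).
    """
    sub, ell = _align(panel, ldscores, chrom_subset)
    m = len(ell)
    bounds = _resolve_blocks(m, n_blocks)
    p = sub.n_phenotypes
    nmat = sub.n
    zmat = sub.z

    # provisional unweighted h2 per phenotype, for the second-pass weights
    h2_prov = np.empty(p)
    for a in range(p):
        s1 = _wls_fit(ell, zmat[:, a] ** 2, np.ones(m), bounds)[0]
        h2_prov[a] = np.clip(s1 * m / nmat[:, a].mean(), 0.0, 1.0)

    elements = vech_indices(p)
    theta = np.empty(len(elements))
    loo = np.empty((len(bounds) - 1, len(elements)))
    for e, (a, b) in enumerate(elements):
        y = zmat[:, a] * zmat[:, b]
        na, nb = nmat[:, a], nmat[:, b]
        scale = m / np.sqrt(na.mean() * nb.mean())
        if a == b:
            w = _h2_weights(ell, na, h2_prov[a], m)
        else:
            s1, i1 = _wls_fit(ell, y, np.ones(m), bounds)[:2]
            rho1 = float(np.clip(s1 * scale, -1.0, 1.0))
            w = _gencov_weights(ell, na, nb, h2_prov[a], h2_prov[b], rho1, i1, m)
        slope, _, loo_s, _ = _wls_fit(ell, y, w, bounds)
        theta[e] = slope * scale
        loo[:, e] = loo_s * scale

    v = jackknife_cov(loo)
    s = np.zeros((p, p))
    for e, (a, b) in enumerate(elements):
        s[a, b] = s[b, a] = theta[e]

    bad = [sub.phenotype_names[a] for a in range(p) if s[a, a] <= 0]
    if bad:
        warnings.warn(f"non-positive estimated h2 for: {', '.join(bad)}", stacklevel=2)
    return GeneticCovariance(
        labels=list(sub.phenotype_names),
        s=s,
        v=v,
        chrom_subset=chrom_subset,
        n_blocks=len(bounds) - 1,
        m=m,
    )


def estimate_rg(
    gwas_a: Sequence[SnpRecord],
    gwas_b: Sequence[SnpRecord],
    ldscores: LdScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> RgEstimate:
    """Cross-trait genetic correlation rg = rho_g / sqrt(h2_a h2_b).

    The two studies are harmonized against each other first; the SE comes
    from jackknifing the ratio over one shared block partition, and p is a
    two-sided normal p-value.  FDR q-values are batch-filled by the caller
    via :func:`gibnet.overlap.fdr_adjust`.
    """
    panel = harmonize_panel([list(gwas_a), list(gwas_b)], ["a", "b"])
    sub, ell = _align(panel, ldscores)
    m = len(ell)
    bounds = _resolve_blocks(m, n_blocks)
    za, na = sub.column("a")
    zb, nb = sub.column("b")

    comps = []  # (estimate, loo) for h2_a, h2_b, rho
    for y, nn1, nn2, kind in (
        (za * za, na, na, "h2"),
        (zb * zb, nb, nb, "h2"),
        (za * zb, na, nb, "gencov"),
    ):
        scale = m / np.sqrt(nn1.mean() * nn2.mean())
        s1, i1 = _wls_fit(ell, y, np.ones(m), bounds)[:2]
        prov = np.clip(s1 * scale, 0.0 if kind == "h2" else -1.0, 1.0)
        if kind == "h2":
            w = _h2_weights(ell, nn1, float(prov), m)
        else:
            h2a = max(comps[0][0], 1e-6)
            h2b = max(comps[1][0], 1e-6)
            w = _gencov_weights(ell, nn1, nn2, h2a, h2b, float(prov), i1, m)
        slope, _, loo_s, _ = _wls_fit(ell, y, w, bounds)
        comps.append((float(slope * scale), loo_s * scale))

    h2a, h2b, rho = comps[0][0], comps[1][0], comps[2][0]
    if h2a <= 0 or h2b <= 0:
        raise UndefinedRgError(
            f"rg undefined: non-positive heritability (h2_a={h2a:.4g}, h2_b={h2b:.4g})"
        )
    rg = rho / np.sqrt(h2a * h2b)
    with np.errstate(invalid="ignore"):
        loo_rg = comps[2][1] / np.sqrt(np.maximum(comps[0][1], 1e-12) * np.maximum(comps[1][1], 1e-12))
    se = float(np.sqrt(jackknife_cov(loo_rg[:, None])[0, 0]))
    if se > 0:
        pval = 2.0 * stats.norm.sf(abs(rg) / se)
    else:
        pval = 0.0 if rg != 0 else 1.0
    return RgEstimate(rg=float(rg), se=se, p=float(pval))
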