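"""Multivariate GWAS of latent factors.

For each SNP the standardized phenotype covariance structure is augmented
with the SNP's covariances to all phenotypes, (z_p / sqrt(N_p)) * sd(G),
with genotype variance var(G) = 2 maf (1 - maf); SNP-to-factor regressions
for all factors are then estimated jointly.  The default "fixed" mode holds
the measurement model (Lambda, Phi, theta) at its no-SNP solution and
solves the SNP paths by weighted least squares in closed form; "refit" mode
re-minimizes the full DWLS discrepancy per SNP.

Reported ``beta`` is the per-allele effect on the standardized factor: the
coefficient b in cov(pheno_p, allele count) = lambda_p * b * var(G).  For a
degenerate single-indicator factor this reduces to the SNP's per-allele
standardized regional effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gibnet.factors import FactorModel, _CfaParam, vech_indices
from gibnet.ldsc import GeneticCovariance, LdScoreTable, h2_from_arrays
from gibnet.sumstats import SumStatsPanel

log = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8
# median of the chi-square(1) distribution, denominator of lambda_GC
_CHI2_MEDIAN = 0.45494

RESULT_COLUMNS = ["snp_id", "factor", "beta", "se", "z", "p", "gws", "locus_id"]


@dataclass
class InflationReport:
    """Bulk inflation diagnostics for one factor's GWAS."""

    lambda_gc: float
    ldsc_intercept: float | None = None


def expand_covariance_for_snp(
    model_cov: GeneticCovariance,
    z: np.ndarray,
    n: np.ndarray,
    maf: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Append one SNP to a standardized covariance matrix.

    Returns (S_aug, V_aug): the (P+1)x(P+1) matrix with the SNP in the last
    row/column, and the expanded sampling covariance over its half-vectorized
    elements.  SNP-phenotype covariances are (z_p/sqrt(N_p)) * sd(G) with
    sampling variance var(G)/N_p; the SNP variance 2 maf (1-maf) is treated
    as a known constant, and SNP elements as independent of the LDSC block.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    p = model_cov.p
    if len(z) != p or len(n) != p:
        raise ValueError("z/n length does not match the number of phenotypes")
    var_g = 2.0 * maf * (1.0 - maf)
    cov_snp = (z / np.sqrt(n)) * np.sqrt(var_g)

    s_aug = np.zeros((p + 1, p + 1))
    s_aug[:p, :p] = model_cov.s
    s_aug[:p, p] = s_aug[p, :p] = cov_snp
    s_aug[p, p] = var_g

    old = {ij: e for e, ij in enumerate(vech_indices(p))}
    new_elements = vech_indices(p + 1)
    v_aug = np.zeros((len(new_elements), len(new_elements)))
    for e, (i, j) in enumerate(new_elements):
        if i < p and j < p:
            for f, (a, b) in enumerate(new_elements):
                if a < p and b < p:
                    v_aug[e, f] = model_cov.v[old[(i, j)], old[(a, b)]]
        elif i < p and j == p:
            v_aug[e, e] = var_g / n[i]
        # the (p, p) genotype-variance element stays at zero (fixed)
    return s_aug, v_aug


def _snp_paths_fixed(
    lam: np.ndarray, n_row: np.ndarray, z_row: np.ndarray, maf: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form WLS for the SNP->factor paths with a fixed measurement model."""
    var_g = 2.0 * maf * (1.0 - maf)
    c = (z_row / np.sqrt(n_row)) * np.sqrt(var_g)        # cov(pheno, G)
    w = n_row / var_g                                    # 1 / var(c)
    a = lam * var_g                                      # implied c = A b
    g = a.T @ (w[:, None] * a)
    ginv = np.linalg.pinv(g)
    b = ginv @ (a.T @ (w * c))
    se = np.sqrt(np.clip(np.diag(ginv), 0.0, None))
    return b, se


def snp_factor_gwas(
    model: FactorModel,
    panel: SumStatsPanel,
    maf: np.ndarray | None = None,
    mode: str = "fixed",
    gencov: GeneticCovariance | None = None,
) -> pd.DataFrame:
    """Per-SNP, per-factor association results for a fitted factor model.

    ``maf`` overrides the panel's MAF column; SNPs without a usable MAF are
    skipped with a logged count.  "refit" mode re-minimizes the joint DWLS
    discrepancy per SNP and needs ``gencov`` (the standardized matrix the
    model was fitted to) for the measurement-block weights.  Returns a
    DataFrame with columns snp_id, factor, beta, se, z, p, gws, locus_id
    (plus chrom/bp for clumping); ``locus_id`` is filled by
    :func:`clump_loci`.
    """
    if not model.converged:
        raise ValueError("refusing to run a GWAS from a non-converged model")
    if mode not in ("fixed", "refit"):
        raise ValueError(f"mode must be 'fixed' or 'refit', got {mode!r}")
    if mode == "refit" and gencov is None:
        raise ValueError("refit mode needs the standardized gencov the model was fitted to")
    maf = panel.maf if maf is None else np.asarray(maf, float)
    if sorted(model.labels) != sorted(panel.phenotype_names):
        raise ValueError("panel phenotypes do not match model labels")
    lam = model.lambda_est

    usable = np.isfinite(maf) & (maf > 0) & (maf <= 0.5)
    skipped = int((~usable).sum())
    if skipped:
        log.info("skipped %d SNPs without usable MAF", skipped)
    if not usable.any():
        raise ValueError("no SNP carries a MAF; the per-SNP variance step requires it")

    # vectorized fixed-mode path: align panel columns to model label order
    idx = np.flatnonzero(usable)
    col_of_label = [panel.phenotype_names.index(name) for name in model.labels]
    zmat = panel.z[idx][:, col_of_label]
    nmat = panel.n[idx][:, col_of_label]
    mafv = maf[idx]
    var_g = 2.0 * mafv * (1.0 - mafv)
    c = (zmat / np.sqrt(nmat)) * np.sqrt(var_g)[:, None]
    w = nmat / var_g[:, None]
    # G_m = lam' diag(w_m) lam * var_g^2 ; rhs_m = lam' (w_m * c_m) * var_g
    gmats = np.einsum("pk,mp,pl->mkl", lam, w, lam) * (var_g**2)[:, None, None]
    rhs = np.einsum("pk,mp->mk", lam, w * c) * var_g[:, None]
    ginv = np.linalg.pinv(gmats)
    betas = np.einsum("mkl,ml->mk", ginv, rhs)
    ses = np.sqrt(np.clip(np.einsum("mkk->mk", ginv), 0.0, None))

    if mode == "refit":
        for r, m_i in enumerate(idx):
            try:
                b, se = _refit_snp(model, gencov, zmat[r], nmat[r], mafv[r], betas[r])
                betas[r], ses[r] = b, se
            except Exception as exc:  # pragma: no cover - per-SNP failure is non-fatal
                log.warning("refit failed for %s: %s", panel.snp_id[m_i], exc)

    zstat = np.divide(betas, ses, out=np.zeros_like(betas), where=ses > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    out = []
    for fi, fname in enumerate(model.factor_names):
        out.append(
            pd.DataFrame(
                {
                    "snp_id": panel.snp_id[idx],
                    "chrom": panel.chrom[idx],
                    "bp": panel.bp[idx],
                    "factor": fname,
                    "beta": betas[:, fi],
                    "se": ses[:, fi],
                    "z": zstat[:, fi],
                    "p": pvals[:, fi],
                    "gws": pvals[:, fi] < GWS_THRESHOLD,
                    "locus_id": pd.array([None] * len(idx), dtype="Int64"),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _refit_snp(model: FactorModel, gencov: GeneticCovariance, z_row: np.ndarray,
               n_row: np.ndarray, maf: float,
               b0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-estimate all free parameters jointly with the SNP paths for one SNP.

    The measurement block keeps its DWLS weights (inverse diagonal of the
    LDSC sampling covariance); the SNP block is weighted by the inverse
    sampling variance of the SNP-phenotype covariances, N_p / var(G).
    """
    from scipy import optimize

    from gibnet.factors import _included_elements

    var_g = 2.0 * maf * (1.0 - maf)
    c_obs = (z_row / np.sqrt(n_row)) * np.sqrt(var_g)
    w_snp = n_row / var_g
    par = _CfaParam(model.spec, model.labels, np.diag(gencov.s))
    k = par.k
    elements = vech_indices(par.p)
    s_vec = gencov.vech()
    incl = _included_elements(gencov)
    v_diag = np.clip(np.diag(gencov.v), 0.0, None)
    w_meas = np.zeros(len(elements))
    w_meas[incl] = 1.0 / v_diag[incl]

    x_meas0 = np.concatenate(
        [
            [model.lambda_est[i, f] for i, f in par.load_ix],
            [model.phi[a, b] for a in range(k) for b in range(a + 1, k)],
        ]
    )
    x0 = np.concatenate([x_meas0, b0])

    def objective(x: np.ndarray) -> float:
        xm, b = x[:-k], x[-k:]
        lam, _, _ = par.unpack(xm)
        sig = par.sigma(xm)
        sig_vec = np.array([sig[i, j] for i, j in elements])
        f_meas = np.sum(w_meas * (s_vec - sig_vec) ** 2)
        c_imp = lam @ b * var_g
        f_snp = np.sum(w_snp * (c_obs - c_imp) ** 2)
        return float(f_meas + f_snp)

    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-14})
    b_hat = res.x[-k:]
    lam, _, _ = par.unpack(res.x[:-k])
    a = lam * var_g
    ginv = np.linalg.pinv(a.T @ (w_snp[:, None] * a))
    se = np.sqrt(np.clip(np.diag(ginv), 0.0, None))
    return b_hat, se


def genomic_lambda(
    results: pd.DataFrame,
    ldscores: LdScoreTable | None = None,
    n_eff: float | None = None,
) -> InflationReport:
    """Genomic inflation factor for one factor's results; optional LDSC intercept.

    lambda = median(z^2) / 0.45494.  When LD scores are supplied, the
    factor GWAS (z, effective N) is run through univariate LDSC and its
    intercept reported alongside.
    """
    if results["factor"].nunique() != 1:
        raise ValueError("pass the results of a single factor")
    z = results["z"].to_numpy(float)
    lam = float(np.median(z * z) / _CHI2_MEDIAN)
    intercept = None
    if ldscores is not None:
        if n_eff is None:
            raise ValueError("n_eff is required to compute the LDSC intercept")
        lmap = {sid: l2 for sid, l2 in zip(ldscores.snp_id, ldscores.l2)}
        have = results["snp_id"].map(lmap).notna().to_numpy()
        sub = results[have].sort_values(["chrom", "bp"])
        ell = sub["snp_id"].map(lmap).to_numpy(float)
        zz = sub["z"].to_numpy(float)
        fit = h2_from_arrays(zz, np.full(len(zz), float(n_eff)), ell)
        intercept = fit.intercept
    return InflationReport(lambda_gc=lam, ldsc_intercept=intercept)


def clump_loci(results: pd.DataFrame, window_kb: float = 250.0) -> pd.DataFrame:
    """Greedy distance-based clumping of genome-wide significant rows.

    Within each factor, the most significant unassigned GWS SNP becomes a
    locus lead and claims every GWS SNP within +/- window on the same
    chromosome; repeat until all GWS SNPs are assigned.  Non-GWS rows keep
    a null locus_id.  Returns a copy with locus_id filled (numbered 1..L
    per factor in lead-significance order).
    """
    out = results.copy()
    out["locus_id"] = pd.array([None] * len(out), dtype="Int64")
    window = window_kb * 1000.0
    for factor, grp in results.groupby("factor", sort=True):
        gws = grp[grp["gws"]].sort_values(["p", "chrom", "bp"], kind="mergesort")
        assigned: dict[int, int] = {}
        locus = 0
        for row in gws.itertuples():
            if row.Index in assigned:
                continue
            locus += 1
            near = gws[
                (gws["chrom"] == row.chrom) & (np.abs(gws["bp"] - row.bp) <= window)
            ]
            for j in near.index:
                if j not in assigned:
                    assigned[j] = locus
        for j, lid in assigned.items():
            out.loc[j, "locus_id"] = lid
    return out


def locus_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-locus summary: lead SNP, chromosome, bp range, minimum p, factor."""
    gws = results[results["gws"] & results["locus_id"].notna()]
    rows = []
    for (factor, lid), grp in gws.groupby(["factor", "locus_id"]):
        lead = grp.loc[grp["p"].idxmin()]
        rows.append(
            {
                "factor": factor,
                "locus_id": int(lid),
                "lead_snp": lead["snp_id"],
                "chrom": int(lead["chrom"]),
                "bp_min": int(grp["bp"].min()),
                "bp_max": int(grp["bp"].max()),
                "min_p": float(grp["p"].min()),
                "n_snps": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["factor", "locus_id", "lead_snp", "chrom",
                                       "bp_min", "bp_max", "min_p", "n_snps"])


def write_factor_gwas(results: pd.DataFrame, panel: SumStatsPanel,
                      directory: str | Path) -> None:
    """One sumstats-dialect file per factor (N_eff = mean regional N) plus loci.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_eff = float(panel.n.mean())
    meta = pd.DataFrame(
        {
            "snp_id": panel.snp_id,
            "A1": panel.a1,
            "A2": panel.a2,
            "CHR": panel.chrom,
            "BP": panel.bp,
        }
    )
    for factor, grp in results.groupby("factor"):
        df = grp.merge(meta, on="snp_id")
        out = pd.DataFrame(
            {
                "SNP": df["snp_id"],
                "CHR": df["CHR"],
                "BP": df["BP"],
                "A1": df["A1"],
                "A2": df["A2"],
                "N_eff": n_eff,
                "Z": df["z"],
                "P": df["p"],
            }
        )
        out.to_csv(directory / f"{factor}.sumstats", sep="\t", index=False)
    locus_table(results).to_csv(directory / "loci.tsv", sep="\t", index=False)
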