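"""Factor discovery on LDSC genetic covariance matrices.

Protocol: the odd-chromosome genetic correlation matrix gets an exploratory
factor analysis (minimum-residual extraction, oblique promax rotation) for
1..k_max factors; positive rotated loadings above a threshold (0.3 or 0.5)
define each confirmatory model; the confirmatory models are fitted to the
even-chromosome matrix by diagonally weighted least squares,

    F(theta) = (s - sigma(theta))' diag(V)^-1 (s - sigma(theta)),

over the half-vectorized unique elements, with inference from a sandwich
using the full sampling covariance V.  Candidates are pruned of
non-significant loadings and the converged model minimizing
AIC = chi2 + 2 * n_free wins.

Because the correlation-scale matrix has an exactly-unit diagonal (zero
sampling variance under the delta-method transform), residual variances are
profiled out as theta_i = s_ii - (Lambda Phi Lambda')_ii, clipped at zero
(Heywood flag); the DWLS sum then runs over the elements with positive
sampling variance.  Degrees of freedom are unchanged by the profiling:
P(P+1)/2 minus all free parameters (residuals included) equals the
off-diagonal count minus the measurement parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from gibnet.ldsc import GeneticCovariance, vech_indices

log = logging.getLogger(__name__)

_VAR_FLOOR_FACTOR = 1e-10   # relative cutoff for "zero" sampling variance
_PRUNE_ALPHA = 0.05


# ------------------------------------------------------------ standardization


def standardize_to_correlation(gencov: GeneticCovariance) -> GeneticCovariance:
    """Rescale S to a genetic correlation matrix; propagate V by the delta method.

    r_ij = s_ij / sqrt(s_ii s_jj), so the Jacobian has entries
    dr_ij/ds_ij = 1/sqrt(s_ii s_jj), dr_ij/ds_ii = -r_ij/(2 s_ii), and
    likewise for s_jj; diagonal elements map to the constant 1 and end up
    with zero sampling variance.
    """
    d = np.diag(gencov.s)
    bad = [gencov.labels[i] for i in range(len(d)) if d[i] <= 0]
    if bad:
        raise ValueError(f"non-positive genetic variance for: {', '.join(bad)}")
    p = gencov.p
    elements = vech_indices(p)
    eidx = {ij: e for e, ij in enumerate(elements)}
    r = gencov.s / np.sqrt(np.outer(d, d))
    jac = np.zeros((len(elements), len(elements)))
    for e, (i, j) in enumerate(elements):
        if i == j:
            continue  # r_ii = 1 identically
        jac[e, eidx[(i, j)]] = 1.0 / np.sqrt(d[i] * d[j])
        jac[e, eidx[(i, i)]] = -r[i, j] / (2.0 * d[i])
        jac[e, eidx[(j, j)]] = -r[i, j] / (2.0 * d[j])
    v = jac @ gencov.v @ jac.T
    return GeneticCovariance(
        labels=list(gencov.labels), s=r, v=v,
        chrom_subset=gencov.chrom_subset, n_blocks=gencov.n_blocks, m=gencov.m,
    )


def smooth_to_pd(matrix: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Nearest-PD smoothing by eigenvalue clipping, preserving the diagonal.

    A no-op (bitwise) for matrices already positive definite.
    """
    matrix = np.asarray(matrix, float)
    sym = 0.5 * (matrix + matrix.T)
    eig = np.linalg.eigvalsh(sym)
    if eig.min() >= 1e-8 and np.allclose(matrix, matrix.T):
        return matrix
    w, u = np.linalg.eigh(sym)
    w = np.maximum(w, min_eig)
    out = (u * w) @ u.T
    scale = np.sqrt(np.diag(sym) / np.diag(out))
    out = out * np.outer(scale, scale)
    np.fill_diagonal(out, np.diag(sym))
    return 0.5 * (out + out.T)


# ----------------------------------------------------------------------- EFA


@dataclass
class EfaSolution:
    """One exploratory solution: pattern loadings after oblique rotation."""

    k: int
    labels: list[str]
    loadings: np.ndarray        # (P, k) rotated pattern matrix
    phi: np.ndarray             # (k, k) factor correlations
    eigenvalues: np.ndarray     # scree eigenvalues of the input correlation
    rotation: str
    converged: bool = True


def _smc_start(r: np.ndarray) -> np.ndarray:
    rinv = np.linalg.pinv(r)
    smc = 1.0 - 1.0 / np.clip(np.diag(rinv), 1.0, None)
    return np.clip(1.0 - smc, 0.05, 1.0)


def _loadings_given_psi(r: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    w, u = np.linalg.eigh(r - np.diag(psi))
    idx = np.argsort(w)[::-1][:k]
    return u[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def _minres(r: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Minimum-residual extraction: minimize off-diagonal squared residuals over psi."""
    p = r.shape[0]
    off = ~np.eye(p, dtype=bool)

    def objective(psi: np.ndarray) -> float:
        lam = _loadings_given_psi(r, psi, k)
        resid = r - lam @ lam.T
        return float(np.sum(resid[off] ** 2))

    res = optimize.minimize(
        objective, _smc_start(r), method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * p, options={"maxiter": 1000, "ftol": 1e-12},
    )
    return _loadings_given_psi(r, res.x, k), bool(res.success)


def _varimax(lam: np.ndarray, normalize: bool = True,
             tol: float = 1e-10, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser varimax by pairwise Jacobi rotations (closed-form planar angle)."""
    p, k = lam.shape
    if k < 2:
        return lam, np.eye(k)
    comm = np.sqrt(np.sum(lam**2, axis=1)) if normalize else np.ones(p)
    comm = np.where(comm > 0, comm, 1.0)
    x = lam / comm[:, None]
    # small deterministic pre-rotation: perfectly balanced loading patterns
    # are stationary points of the criterion with an exactly-zero gradient
    rot = np.eye(k)
    for a in range(k - 1):
        g = np.eye(k)
        c, s = np.cos(0.1), np.sin(0.1)
        g[a, a] = g[a + 1, a + 1] = c
        g[a, a + 1], g[a + 1, a] = -s, s
        rot = rot @ g
    xr = x @ rot
    for _ in range(max_iter):
        biggest = 0.0
        for j in range(k - 1):
            for l in range(j + 1, k):
                a, b = xr[:, j], xr[:, l]
                u = a * a - b * b
                v = 2.0 * a * b
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / p
                den = (u * u - v * v).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                angle = 0.25 * np.arctan2(num, den)
                if abs(angle) < 1e-13:
                    continue
                biggest = max(biggest, abs(angle))
                c, s = np.cos(angle), np.sin(angle)
                xr[:, j], xr[:, l] = c * a + s * b, -s * a + c * b
                rj, rl = rot[:, j].copy(), rot[:, l].copy()
                rot[:, j], rot[:, l] = c * rj + s * rl, -s * rj + c * rl
        if biggest < tol:
            break
    return xr * comm[:, None], rot


def _promax(lam: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation; returns (pattern, factor correlation)."""
    vx, _ = _varimax(lam)
    k = lam.shape[1]
    if k < 2:
        return vx, np.eye(k)
    target = vx * np.abs(vx) ** (power - 1)
    u, *_ = np.linalg.lstsq(vx, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = vx @ u
    phi = np.linalg.inv(u.T @ u)
    phi = 0.5 * (phi + phi.T)
    np.fill_diagonal(phi, 1.0)
    return pattern, phi


def _fix_signs(pattern: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign indeterminacy: largest-magnitude loading of each factor made positive
    signs = np.array([np.sign(col[np.argmax(np.abs(col))]) or 1.0 for col in pattern.T])
    return pattern * signs, phi * np.outer(signs, signs)


def run_efa(corr: GeneticCovariance, k_range: Iterable[int] = range(1, 11)) -> list[EfaSolution]:
    """Exploratory factor analysis of a standardized genetic covariance.

    One solution per requested factor count; oblique promax rotation for
    k >= 2 (the factors are expected to correlate).  Non-converging counts
    are flagged and skipped.
    """
    p = corr.p
    if not np.allclose(np.diag(corr.s), 1.0, atol=1e-8):
        raise ValueError("run_efa expects a standardized (unit-diagonal) matrix")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("factor counts must be >= 1")
    if ks[-1] >= p:
        raise ValueError(f"k={ks[-1]} must be smaller than P={p}")
    r = smooth_to_pd(corr.s)
    eigenvalues = np.sort(np.linalg.eigvalsh(r))[::-1]
    solutions = []
    for k in ks:
        try:
            lam, ok = _minres(r, k)
        except np.linalg.LinAlgError:
            log.warning("EFA with k=%d failed; skipped", k)
            continue
        if k >= 2:
            pattern, phi = _promax(lam)
            rotation = "promax"
        else:
            pattern, phi, rotation = lam, np.eye(1), "none"
        pattern, phi = _fix_signs(pattern, phi)
        solutions.append(
            EfaSolution(k=k, labels=list(corr.labels), loadings=pattern, phi=phi,
                        eigenvalues=eigenvalues, rotation=rotation, converged=ok)
        )
    return solutions


# ------------------------------------------------------------------ CFA spec


@dataclass(frozen=True)
class CfaSpec:
    """Sparsity pattern for a confirmatory model: regions each factor loads on."""

    factor_map: dict[str, tuple[str, ...]]
    threshold_used: float

    def __post_init__(self) -> None:
        if not self.factor_map:
            raise ValueError("a CFA specification needs at least one factor")
        for name, regions in self.factor_map.items():
            if len(regions) < 2:
                raise ValueError(f"factor {name} loads on fewer than 2 regions")

    @property
    def n_factors(self) -> int:
        return len(self.factor_map)

    def canonical(self) -> frozenset[frozenset[str]]:
        """Structure identity ignoring factor names/order, for deduplication."""
        return frozenset(frozenset(r) for r in self.factor_map.values())


def build_cfa_spec(efa: EfaSolution, tau: float) -> CfaSpec:
    """Carry positive rotated loadings above tau forward as free CFA loadings.

    Cross-loadings are retained on every factor where they exceed tau;
    factors left with fewer than two regions are removed (single regions do
    not constitute a network).
    """
    if tau <= 0:
        raise ValueError("threshold must be positive")
    factor_map: dict[str, tuple[str, ...]] = {}
    removed = []
    idx = 0
    for f in range(efa.k):
        regions = tuple(
            efa.labels[i] for i in range(len(efa.labels)) if efa.loadings[i, f] > tau
        )
        if len(regions) < 2:
            removed.append(f + 1)
            continue
        idx += 1
        factor_map[f"F{idx}"] = regions
    if removed:
        log.info("removed %d single-region factor(s) from k=%d EFA at tau=%.2f",
                 len(removed), efa.k, tau)
    if not factor_map:
        raise ValueError(f"no factor retains >= 2 regions at threshold {tau}")
    return CfaSpec(factor_map=factor_map, threshold_used=tau)


# ----------------------------------------------------------------- CFA model


@dataclass
class FitStats:
    chi2: float
    df: int
    aic: float
    cfi: float
    srmr: float
    n_free_params: int

    def __post_init__(self) -> None:
        if self.df < 0:
            raise ValueError("negative degrees of freedom")


@dataclass
class FactorModel:
    """Fitted confirmatory factor model on the genetic correlation scale."""

    spec: CfaSpec
    labels: list[str]
    factor_names: list[str]
    lambda_est: np.ndarray      # (P, k), zeros where fixed
    lambda_se: np.ndarray       # (P, k), NaN where fixed
    phi: np.ndarray             # (k, k), unit diagonal
    phi_se: np.ndarray
    theta: np.ndarray           # (P,) residual variances, >= 0
    theta_se: np.ndarray
    converged: bool
    heywood: bool = False
    fmin: float = np.nan
    fit: FitStats | None = None

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def implied(self) -> np.ndarray:
        sigma = self.lambda_est @ self.phi @ self.lambda_est.T + np.diag(self.theta)
        return 0.5 * (sigma + sigma.T)

    def free_loadings(self) -> list[tuple[int, int]]:
        """(region index, factor index) pairs of free loadings, deterministic order."""
        out = []
        for fi, fname in enumerate(self.factor_names):
            for region in self.spec.factor_map[fname]:
                out.append((self.labels.index(region), fi))
        return out

    def n_free_params(self) -> int:
        k = self.k
        return len(self.free_loadings()) + k * (k - 1) // 2 + len(self.labels)


class _CfaParam:
    """Maps a flat parameter vector to (Lambda, Phi, theta) with theta profiled."""

    def __init__(self, spec: CfaSpec, labels: Sequence[str], s_diag: np.ndarray):
        self.spec = spec
        self.labels = list(labels)
        self.s_diag = np.asarray(s_diag, float)
        self.factor_names = list(spec.factor_map)
        self.k = len(self.factor_names)
        self.p = len(self.labels)
        self.load_ix: list[tuple[int, int]] = []
        for fi, fname in enumerate(self.factor_names):
            for region in spec.factor_map[fname]:
                if region not in self.labels:
                    raise ValueError(f"region {region!r} absent from covariance labels")
                self.load_ix.append((self.labels.index(region), fi))
        self.n_load = len(self.load_ix)
        self.n_phi = self.k * (self.k - 1) // 2
        self.n_par = self.n_load + self.n_phi

    def start(self) -> np.ndarray:
        return np.concatenate([np.full(self.n_load, 0.6), np.full(self.n_phi, 0.3)])

    def bounds(self) -> list[tuple[float, float]]:
        return [(-2.0, 2.0)] * self.n_load + [(-0.99, 0.99)] * self.n_phi

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam = np.zeros((self.p, self.k))
        for val, (i, f) in zip(x[: self.n_load], self.load_ix):
            lam[i, f] = val
        phi = np.eye(self.k)
        pos = self.n_load
        for a in range(self.k):
            for b in range(a + 1, self.k):
                phi[a, b] = phi[b, a] = x[pos]
                pos += 1
        common = lam @ phi @ lam.T
        theta = np.clip(self.s_diag - np.diag(common), 0.0, None)
        return lam, phi, theta

    def sigma(self, x: np.ndarray) -> np.ndarray:
        lam, phi, theta = self.unpack(x)
        return lam @ phi @ lam.T + np.diag(theta)


def _variance_floor(v_diag: np.ndarray) -> float:
    top = float(np.max(v_diag)) if len(v_diag) else 0.0
    return max(top * _VAR_FLOOR_FACTOR, 1e-30)


def _included_elements(gencov: GeneticCovariance) -> np.ndarray:
    v_diag = np.clip(np.diag(gencov.v), 0.0, None)
    return v_diag > _variance_floor(v_diag)


def _num_jac(fun: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
             h: float = 1e-6) -> np.ndarray:
    f0 = fun(x)
    jac = np.empty((len(f0), len(x)))
    for j in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        jac[:, j] = (fun(xp) - fun(xm)) / (2 * h)
    return jac


def fit_cfa(spec: CfaSpec, gencov: GeneticCovariance) -> FactorModel:
    """DWLS fit of a confirmatory factor model to a standardized matrix.

    Factor variances are fixed to 1 for identification, factor covariances
    free; standard errors come from a sandwich using the full V.  A Heywood
    case (residual variance pinned at zero) is flagged, not fatal.
    """
    par = _CfaParam(spec, gencov.labels, np.diag(gencov.s))
    elements = vech_indices(gencov.p)
    incl = _included_elements(gencov)
    s_vec = gencov.vech()
    w = np.zeros(len(elements))
    v_diag = np.clip(np.diag(gencov.v), 0.0, None)
    w[incl] = 1.0 / v_diag[incl]

    def sigma_vech(x: np.ndarray) -> np.ndarray:
        sig = par.sigma(x)
        return np.array([sig[i, j] for i, j in elements])

    def objective(x: np.ndarray) -> float:
        resid = s_vec - sigma_vech(x)
        f = float(np.sum(w * resid * resid))
        if par.k > 1:
            _, phi, _ = par.unpack(x)
            emin = np.linalg.eigvalsh(phi).min()
            if emin < 1e-3:
                f += 1e4 * (1e-3 - emin) ** 2
        return f

    best = None
    for x0 in (par.start(), np.concatenate([np.full(par.n_load, 0.4), np.zeros(par.n_phi)])):
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=par.bounds(),
                                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    assert best is not None
    x = best.x
    lam, phi, theta = par.unpack(x)
    heywood = bool(np.any(theta <= 1e-12))

    # sandwich covariance over the included (positive-variance) elements
    jac = _num_jac(sigma_vech, x)[incl]
    v_full = gencov.v[np.ix_(incl, incl)]
    wi = w[incl]
    bread = np.linalg.pinv(jac.T @ (wi[:, None] * jac))
    meat = (jac * wi[:, None]).T @ v_full @ (jac * wi[:, None])
    cov = bread @ meat @ bread

    lam_se = np.full_like(lam, np.nan)
    for q, (i, f) in enumerate(par.load_ix):
        lam_se[i, f] = np.sqrt(max(cov[q, q], 0.0))
    phi_se = np.zeros_like(phi)
    pos = par.n_load
    for a in range(par.k):
        for b in range(a + 1, par.k):
            phi_se[a, b] = phi_se[b, a] = np.sqrt(max(cov[pos, pos], 0.0))
            pos += 1

    # theta is a smooth function of the measurement parameters
    def theta_fun(xx: np.ndarray) -> np.ndarray:
        return par.unpack(xx)[2]

    tjac = _num_jac(theta_fun, x)
    theta_se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", tjac, cov, tjac), 0.0, None))

    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged:
        log.warning("CFA did not converge: %s", best.message)
    return FactorModel(
        spec=spec, labels=list(gencov.labels), factor_names=par.factor_names,
        lambda_est=lam, lambda_se=lam_se, phi=phi, phi_se=phi_se,
        theta=theta, theta_se=theta_se, converged=converged, heywood=heywood,
        fmin=float(best.fun),
    )


def srmr(observed: np.ndarray, implied: np.ndarray) -> float:
    """Root mean square standardized residual over the unique elements."""
    observed = np.asarray(observed, float)
    implied = np.asarray(implied, float)
    d = np.sqrt(np.diag(observed))
    resid = (observed - implied) / np.outer(d, d)
    vals = [resid[i, j] for i, j in vech_indices(observed.shape[0])]
    return float(np.sqrt(np.mean(np.square(vals))))


def compute_fit_stats(model: FactorModel, gencov: GeneticCovariance) -> FitStats:
    """Residual-based chi2 with full V, AIC = chi2 + 2k, CFI, SRMR.

    chi2 is the quadratic form r' M r with
    M = Vi - Vi D (D' Vi D)^+ D' Vi, D the Jacobian of the implied moments
    in the free parameters, evaluated over the positive-variance elements;
    the CFI baseline is the independence (diagonal-only) model.
    """
    p = gencov.p
    elements = vech_indices(p)
    e_total = len(elements)
    incl = _included_elements(gencov)
    s_vec = gencov.vech()
    sigma = model.implied()
    sig_vec = np.array([sigma[i, j] for i, j in elements])
    resid = s_vec - sig_vec

    par = _CfaParam(model.spec, model.labels, np.diag(gencov.s))
    x = np.concatenate(
        [
            [model.lambda_est[i, f] for i, f in par.load_ix],
            [model.phi[a, b] for a in range(par.k) for b in range(a + 1, par.k)],
        ]
    )

    def sigma_vech(xx: np.ndarray) -> np.ndarray:
        sig = par.sigma(xx)
        return np.array([sig[i, j] for i, j in elements])

    vi = np.linalg.pinv(0.5 * (gencov.v[np.ix_(incl, incl)] + gencov.v[np.ix_(incl, incl)].T))
    jac = _num_jac(sigma_vech, x)[incl]
    inner = np.linalg.pinv(jac.T @ vi @ jac)
    mmat = vi - vi @ jac @ inner @ jac.T @ vi
    r_in = resid[incl]
    chi2 = float(max(r_in @ mmat @ r_in, 0.0))

    n_free = model.n_free_params()
    df = e_total - n_free

    # independence baseline: free residual variances only, all covariances zero
    base_resid = np.array(
        [s_vec[e] if i != j else 0.0 for e, (i, j) in enumerate(elements)]
    )[incl]
    chi2_b = float(max(base_resid @ vi @ base_resid, 0.0))
    df_b = e_total - p

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den

    return FitStats(chi2=chi2, df=df, aic=chi2 + 2.0 * n_free, cfi=float(np.clip(cfi, 0.0, 1.0)),
                    srmr=srmr(gencov.s, sigma), n_free_params=n_free)


def prune_nonsignificant(model: FactorModel, gencov: GeneticCovariance,
                         alpha: float = _PRUNE_ALPHA) -> FactorModel:
    """Iteratively drop the least-significant free loading (two-sided Wald p > alpha).

    One loading per refit, largest p first (ties broken by factor then
    region label); a factor is never reduced below two regions.  The number
    of factors never increases.
    """
    current = model
    while True:
        candidates = []
        for i, f in current.free_loadings():
            se = current.lambda_se[i, f]
            if not np.isfinite(se) or se <= 0:
                continue
            pval = 2.0 * stats.norm.sf(abs(current.lambda_est[i, f]) / se)
            fname = current.factor_names[f]
            if pval > alpha and len(current.spec.factor_map[fname]) > 2:
                candidates.append((pval, fname, current.labels[i]))
        if not candidates:
            return current
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, fname, region = candidates[0]
        new_map = {
            f: tuple(r for r in regions if not (f == fname and r == region))
            for f, regions in current.spec.factor_map.items()
        }
        spec = CfaSpec(factor_map=new_map, threshold_used=current.spec.threshold_used)
        refit = fit_cfa(spec, gencov)
        refit.fit = compute_fit_stats(refit, gencov)
        current = refit


def select_best_model(candidates: Sequence[FactorModel]) -> FactorModel:
    """Converged candidate minimizing AIC; ties -> fewer factors, then fewer parameters."""
    usable = [m for m in candidates if m.converged and m.fit is not None]
    if not usable:
        raise ValueError("no converged candidate model")
    return min(usable, key=lambda m: (m.fit.aic, m.k, m.fit.n_free_params))


def run_factor_discovery(
    gencov_odd: GeneticCovariance,
    gencov_even: GeneticCovariance,
    k_range: Iterable[int] = range(1, 11),
    thresholds: Sequence[float] = (0.3, 0.5),
    prune: bool = True,
) -> tuple[FactorModel, list[FactorModel]]:
    """Full discovery protocol: EFA on odd chromosomes, CFA on even, AIC selection.

    Identical sparsity patterns arising from different (k, tau) pairs are
    deduplicated before fitting.  Returns (selected model, all fitted
    candidates).
    """
    corr_odd = standardize_to_correlation(gencov_odd)
    corr_even = standardize_to_correlation(gencov_even)
    solutions = run_efa(corr_odd, k_range)
    specs: dict[frozenset[frozenset[str]], CfaSpec] = {}
    for sol in solutions:
        for tau in thresholds:
            try:
                spec = build_cfa_spec(sol, tau)
            except ValueError:
                continue
            specs.setdefault(spec.canonical(), spec)
    if not specs:
        raise ValueError("no viable CFA specification from any EFA solution")
    candidates = []
    for spec in specs.values():
        model = fit_cfa(spec, corr_even)
        model.fit = compute_fit_stats(model, corr_even)
        if prune and model.converged:
            model = prune_nonsignificant(model, corr_even)
        candidates.append(model)
    return select_best_model(candidates), candidates


def candidate_table(candidates: Sequence[FactorModel]):
    """Fit-statistics table (k, tau, chi2, df, AIC, CFI, SRMR, converged) as a DataFrame."""
    import pandas as pd

    rows = []
    for m in candidates:
        rows.append(
            {
                "n_factors": m.k,
                "threshold": m.spec.threshold_used,
                "chi2": m.fit.chi2 if m.fit else np.nan,
                "df": m.fit.df if m.fit else -1,
                "aic": m.fit.aic if m.fit else np.nan,
                "cfi": m.fit.cfi if m.fit else np.nan,
                "srmr": m.fit.srmr if m.fit else np.nan,
                "converged": m.converged,
            }
        )
    return pd.DataFrame(rows)
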