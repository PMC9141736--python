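"""Conventional GWAS engines: per-SNP mixed linear model and FarmCPU.

The MLM uses the spectral trick: decompose the kinship once, estimate the
variance ratio delta = sigma2_e/sigma2_g by 1-D REML on the rotated data
(the EMMA likelihood), and keep delta fixed across markers (the P3D/EMMAX
approximation), so the per-SNP step is weighted least squares.

FarmCPU alternates a fixed-effect scan conditioned on pseudo-QTN covariates
with a random-effect model whose kinship is built from candidate pseudo-QTN
genotypes; the (bin size, pseudo-QTN count) combination maximizing the REM
likelihood defines the next covariate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotype_qc import KinshipMatrix
from .io_formats import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "MlmNullFit",
    "MlmScanResult",
    "FarmCpuState",
    "fit_mlm_null",
    "mlm_scan",
    "farmcpu_scan",
    "bh_fdr_threshold",
]

_DELTA_BOUNDS = (-10.0, 10.0)  # ln(delta) search interval


@dataclass
class MlmNullFit:
    """Null-model REML fit caching the kinship spectrum for the scan."""

    covariates: np.ndarray        # n x c, includes intercept
    kinship: KinshipMatrix
    delta: float                  # sigma2_e / sigma2_g
    sigma2_g: float
    eigenvalues: np.ndarray       # kinship spectrum (full, length n)
    eigenvectors: np.ndarray
    loglik: float


@dataclass
class MlmScanResult:
    df: pd.DataFrame  # snp_id, chrom, pos, beta, se, p_value


@dataclass
class FarmCpuState:
    pseudo_qtns: list[int]
    bin_size: float
    iteration: int
    p_values: np.ndarray
    betas: np.ndarray
    history: list[dict] = field(default_factory=list)


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        return ones
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.hstack([ones, C])


def _check_full_rank(X: np.ndarray) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(piv[r:])
        raise ValueError(f"covariate matrix is singular; collinear columns {bad}")


def _emma_reml_delta(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """REML of delta on the null model via the eigenvalues of S K S
    restricted to the complement of the fixed-effect space."""
    n, p = X.shape
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    xi, W = np.linalg.eigh(S @ K @ S)
    # keep the n-p largest (the p null directions have eigenvalue ~0 with
    # eigenvectors inside col(X))
    xi, W = xi[p:], W[:, p:]
    xi = np.maximum(xi, 0.0)
    eta2 = (W.T @ y) ** 2
    nf = n - p

    def neg_reml(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi + d
        return 0.5 * (nf * np.log(eta2 @ (1.0 / denom)) + np.sum(np.log(denom)))

    res = minimize_scalar(neg_reml, bounds=_DELTA_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    sigma2_g = float((eta2 @ (1.0 / (xi + delta))) / nf)
    loglik = -float(res.fun) - 0.5 * nf * (1.0 + np.log(2.0 * np.pi / nf))
    return delta, sigma2_g, loglik


def fit_mlm_null(y: np.ndarray, covariates: np.ndarray | None,
                 kinship: KinshipMatrix) -> MlmNullFit:
    """REML fit of the SNP-free mixed model; caches the kinship spectrum.

    ``y`` is the per-genotype trait vector (typically BLUPs), aligned with
    ``kinship.sample_ids``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if kinship.values.shape[0] != n:
        raise ValueError("phenotype length does not match kinship dimension")
    X = _with_intercept(covariates, n)
    if n < X.shape[1] + 2:
        raise ValueError("too few samples for the covariate set")
    _check_full_rank(X)
    K = kinship.values
    # stabilizing shift for strictly PSD spectrum
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8:
        raise ValueError(f"kinship has large negative eigenvalue {lam.min():.3g}")
    lam = np.maximum(lam, 0.0)
    delta, sigma2_g, loglik = _emma_reml_delta(y, X, K)
    return MlmNullFit(covariates=X, kinship=kinship, delta=delta,
                      sigma2_g=sigma2_g, eigenvalues=lam, eigenvectors=U,
                      loglik=loglik)


def mlm_scan(null: MlmNullFit, panel: GenotypePanel,
             y: np.ndarray) -> MlmScanResult:
    """Per-SNP generalized least squares at the null fit's delta.

    Each SNP is tested by Wald/t statistic from GLS with covariance
    sigma2_g (K + delta I); with identity kinship this reduces exactly to
    OLS regression.  Monomorphic SNPs report beta = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if panel.n_samples != n:
        raise ValueError("sample mismatch between panel and phenotype")
    if np.isnan(panel.dosage).any():
        raise ValueError("mlm_scan requires an imputed panel")
    U, lam = null.eigenvectors, null.eigenvalues
    w = 1.0 / (lam + null.delta)
    sw = np.sqrt(w)
    ys = sw * (U.T @ y)
    Xs = sw[:, None] * (U.T @ null.covariates)
    Gs = sw[:, None] * (U.T @ panel.dosage)

    # Frisch-Waugh: residualize on the covariates
    XtX_inv = np.linalg.inv(Xs.T @ Xs)
    H = Xs @ XtX_inv
    ry = ys - H @ (Xs.T @ ys)
    RG = Gs - H @ (Xs.T @ Gs)
    rss0 = float(ry @ ry)

    sjj = np.einsum("ij,ij->j", RG, RG)
    sjy = RG.T @ ry
    c = null.covariates.shape[1]
    df = n - c - 1

    beta = np.zeros(panel.n_snps)
    se = np.zeros(panel.n_snps)
    pval = np.ones(panel.n_snps)
    ok = sjj > 1e-10 * max(rss0, 1e-300)
    beta[ok] = sjy[ok] / sjj[ok]
    rss = np.maximum(rss0 - beta[ok] ** 2 * sjj[ok], 1e-300)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / sjj[ok])
    tstat = beta[ok] / se[ok]
    if n > 100:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pval[ok] = np.clip(p, np.finfo(float).tiny, 1.0)

    return MlmScanResult(df=pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos,
        "beta": beta, "se": se, "p_value": pval,
    }))


# ---------------------------------------------------------------------------
# FarmCPU

def _ols_scan(y: np.ndarray, C: np.ndarray, G: np.ndarray,
              exclude: dict[int, int] | None = None):
    """Per-SNP OLS with fixed covariates C; ``exclude`` maps SNP index ->
    covariate column to drop for that SNP (pseudo-QTN self-exclusion)."""
    n, c = C.shape
    CtC_inv = np.linalg.pinv(C.T @ C)
    H = C @ CtC_inv
    ry = y - H @ (C.T @ y)
    RG = G - H @ (C.T @ G)
    rss0 = float(ry @ ry)
    sjj = np.einsum("ij,ij->j", RG, RG)
    sjy = RG.T @ ry
    df = n - c - 1
    m = G.shape[1]
    beta = np.zeros(m)
    pval = np.ones(m)
    ok = sjj > 1e-10 * max(rss0, 1e-300)
    beta[ok] = sjy[ok] / sjj[ok]
    rss = np.maximum(rss0 - beta[ok] ** 2 * sjj[ok], 1e-300)
    tstat = beta[ok] / np.sqrt((rss / df) / sjj[ok])
    if n > 100:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pval[ok] = np.clip(p, np.finfo(float).tiny, 1.0)

    if exclude:
        for j, col in exclude.items():
            keep = [k for k in range(c) if k != col]
            Cj = C[:, keep]
            x = G[:, j]
            Xf = np.hstack([Cj, x[:, None]])
            coef, res_, rank, _ = np.linalg.lstsq(Xf, y, rcond=None)
            resid = y - Xf @ coef
            rssj = float(resid @ resid)
            dfj = n - Xf.shape[1]
            XtXi = np.linalg.pinv(Xf.T @ Xf)
            sej = np.sqrt(max(rssj / dfj, 1e-300) * XtXi[-1, -1])
            if sej <= 0 or not np.isfinite(sej):
                beta[j], pval[j] = 0.0, 1.0
                continue
            t = coef[-1] / sej
            if n > 100:
                pj = 2.0 * stats.norm.sf(abs(t))
            else:
                pj = 2.0 * stats.t.sf(abs(t), df=dfj)
            beta[j] = coef[-1]
            pval[j] = float(np.clip(pj, np.finfo(float).tiny, 1.0))
    return beta, pval


def _select_bins(pvals: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                 bin_size: float, t: int) -> list[int]:
    """Most significant SNP per bin: greedy pick by ascending p, skipping
    SNPs within bin_size of an already-picked SNP on the same chromosome."""
    order = np.argsort(pvals, kind="stable")
    picked: list[int] = []
    for j in order:
        if len(picked) >= t:
            break
        ok = True
        for k in picked:
            if chrom[j] == chrom[k] and abs(pos[j] - pos[k]) < bin_size:
                ok = False
                break
        if ok:
            picked.append(int(j))
    return picked


def _rem_loglik(y: np.ndarray, qtn_geno: np.ndarray) -> float:
    """REML log-likelihood of y = mu + u + e with kinship built from the
    candidate pseudo-QTN genotypes (VanRaden form)."""
    p = qtn_geno.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        return -np.inf
    W = qtn_geno[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    K = W @ W.T / denom
    X = np.ones((len(y), 1))
    _, _, loglik = _emma_reml_delta(y, X, K)
    return loglik


def farmcpu_scan(
    y: np.ndarray,
    covariates: np.ndarray | None,
    panel: GenotypePanel,
    max_iter: int = 10,
    bin_ladder: tuple[float, ...] = (5e4, 5e5, 5e6),
    entry_alpha: float = 0.01,
) -> FarmCpuState:
    """Iterative fixed/random-model scan with pseudo-QTN covariates.

    Iteration: (i) fixed-effect model tests every SNP with the current
    pseudo-QTNs as covariates (a SNP inside a pseudo-QTN's bin is tested
    with that pseudo-QTN dropped); (ii) candidate pseudo-QTN sets are the
    per-bin best SNPs over a (bin size, count) ladder; (iii) the random
    model scores each candidate set by REML likelihood with a kinship
    built from the candidate genotypes, and the best set feeds the next
    iteration.  Stops when the set repeats or ``max_iter`` is reached.
    If no SNP passes the Bonferroni-scaled entry threshold in iteration 1
    the plain covariates-only scan is returned with an empty set.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if panel.n_samples != n:
        raise ValueError("sample mismatch between panel and phenotype")
    if np.isnan(panel.dosage).any():
        raise ValueError("farmcpu_scan requires an imputed panel")
    G = panel.dosage
    m = panel.n_snps
    base_C = _with_intercept(covariates, n)
    _check_full_rank(base_C)

    t_grid = [t for t in range(2, max(n // 10, 3), 2)] or [2]
    beta, pvals = _ols_scan(y, base_C, G)
    entry_threshold = entry_alpha / m
    if pvals.min() >= entry_threshold:
        return FarmCpuState(pseudo_qtns=[], bin_size=bin_ladder[0],
                            iteration=1, p_values=pvals, betas=beta)

    seen: set[tuple[int, ...]] = set()
    qtns: list[int] = []
    bin_size = bin_ladder[0]
    history: list[dict] = []
    iteration = 1
    while iteration < max_iter:
        iteration += 1
        best_ll, best_set, best_bin = -np.inf, None, bin_size
        for b in bin_ladder:
            for t in t_grid:
                cand = _select_bins(pvals, panel.chrom, panel.pos, b, t)
                if len(cand) < 2:
                    continue
                ll = _rem_loglik(y, G[:, cand])
                if ll > best_ll:
                    best_ll, best_set, best_bin = ll, cand, b
        if best_set is None:
            break
        history.append({"iteration": iteration, "bin_size": best_bin,
                        "t": len(best_set), "loglik": best_ll})
        key = tuple(sorted(best_set))
        qtns, bin_size = best_set, best_bin
        C = np.hstack([base_C, G[:, qtns]])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            # drop collinear pseudo-QTNs (e.g. perfect LD duplicates)
            keep, cols = [], [base_C]
            for k, j in enumerate(qtns):
                trial = np.hstack(cols + [G[:, [j]]])
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    keep.append(j)
                    cols.append(G[:, [j]])
            qtns = keep
            C = np.hstack(cols)
        exclude: dict[int, int] = {}
        for k, jq in enumerate(qtns):
            col = base_C.shape[1] + k
            near = np.where((panel.chrom == panel.chrom[jq])
                            & (np.abs(panel.pos - panel.pos[jq]) < bin_size))[0]
            for j in near:
                exclude[int(j)] = col
        beta, pvals = _ols_scan(y, C, G, exclude=exclude)
        if key in seen:
            break
        seen.add(key)

    return FarmCpuState(pseudo_qtns=qtns, bin_size=bin_size,
                        iteration=iteration, p_values=pvals, betas=beta,
                        history=history)


def bh_fdr_threshold(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up threshold at level ``q``.

    Returns ``(threshold, significant)`` where ``threshold`` is the largest
    p_(k) <= k q / m (NaN when nothing passes) and ``significant`` is a
    boolean mask over the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    crit = (np.arange(1, m + 1) * q) / m
    passing = np.where(ps <= crit)[0]
    if len(passing) == 0:
        return float("nan"), np.zeros(m, dtype=bool)
    k = passing[-1]
    threshold = float(ps[k])
    return threshold, p <= threshold
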