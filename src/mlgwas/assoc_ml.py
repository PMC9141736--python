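"""ML-mediated association engines: cross-validated SNP importance.

Random forest importance is the mean decrease in node impurity (variance
reduction) of a regression forest; SVR importance is the held-out
permutation importance of an epsilon-insensitive support-vector regression
with a polynomial kernel (x.y/p + constant)^degree.  Both are averaged
over a repeated K-fold cross-validation, affinely scaled to 0-100, and
declared significant against a global empirical threshold: the
(1 - alpha) quantile of the maximum scaled importance over phenotype
permutations, which controls family-wise error at alpha.

The SVR permutation importance is computed by updating the polynomial
Gram matrix against the fitted support vectors for each permuted SNP
column, rather than re-invoking the estimator per SNP; this exact
shortcut is what makes thousand-replicate permutation thresholds
affordable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .io_formats import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "RfModelSpec",
    "SvrKernelSpec",
    "ImportanceProfile",
    "EmpiricalNull",
    "scale_importance",
    "rf_importance_scan",
    "svr_importance_scan",
    "empirical_threshold",
]


@dataclass(frozen=True)
class CvScheme:
    """Repeated K-fold cross-validation (default 5-fold x 10 repeats)."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def splits(self, n: int):
        for rep in range(self.n_repeats):
            ss = np.random.SeedSequence([self.seed, rep])
            kf = KFold(n_splits=self.n_folds, shuffle=True,
                       random_state=int(ss.generate_state(1)[0] % (2**31)))
            for train, test in kf.split(np.arange(n)):
                yield rep, train, test


@dataclass(frozen=True)
class RfModelSpec:
    """Regression-forest hyperparameters (1000 trees, mtry = p/3 by default)."""

    n_trees: int = 1000
    mtry: int | None = None       # None -> p/3
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class SvrKernelSpec:
    """Polynomial-kernel SVR hyperparameters: (x.y/p + constant)^degree."""

    degree: int = 2
    constant: float = 1.0
    cost: float = 1.0
    epsilon: float = 0.1
    seed: int = 0
    n_perm: int = 1               # permutation draws per SNP per fold

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("kernel degree must be >= 1")
        if self.constant < 0 or self.cost <= 0 or self.epsilon < 0:
            raise ValueError("invalid SVR hyperparameters")


@dataclass
class ImportanceProfile:
    """Per-SNP raw and 0-100 scaled importances with per-fit spread."""

    df: pd.DataFrame  # snp_id, chrom, pos, raw_importance, scaled_importance, fold_spread
    method: str
    n_fits: int


@dataclass
class EmpiricalNull:
    """Permutation distribution of the maximum scaled importance."""

    max_importances: np.ndarray
    n_reps: int
    alpha: float
    threshold: float
    engine: str

    def __post_init__(self) -> None:
        self.max_importances = np.asarray(self.max_importances, dtype=float)
        if len(self.max_importances) != self.n_reps:
            raise ValueError("stored maxima length does not match n_reps")


def scale_importance(raw: np.ndarray) -> np.ndarray:
    """Affine map of raw importances onto [0, 100] (min -> 0, max -> 100).

    An all-equal vector maps to all zeros with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty importance vector")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        warnings.warn("all importances equal; scaled profile is all zeros")
        return np.zeros_like(raw)
    return np.clip(100.0 * (raw - lo) / (hi - lo), 0.0, 100.0)


def _check_inputs(y: np.ndarray, panel: GenotypePanel) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if panel.n_samples != len(y):
        raise ValueError("sample mismatch between panel and phenotype")
    if np.isnan(panel.dosage).any():
        raise ValueError("importance scans require an imputed panel")
    if np.var(y) <= 0:
        raise ValueError("constant phenotype: no variance to explain")
    return y


def _rf_raw_importance(y: np.ndarray, G: np.ndarray, spec: RfModelSpec,
                       cv: CvScheme | None):
    """Impurity importances averaged over CV training-fold fits (or one
    full-data fit when cv is None)."""
    p = G.shape[1]
    max_features = spec.mtry if spec.mtry is not None else max(1, p // 3)
    fits = []
    if cv is None:
        splits = [(0, np.arange(len(y)), np.arange(0))]
    else:
        splits = cv.splits(len(y))
    for k, (rep, train, _) in enumerate(splits):
        seed = int(np.random.SeedSequence([spec.seed, 7, k]).generate_state(1)[0]
                   % (2**31))
        rf = RandomForestRegressor(
            n_estimators=spec.n_trees, max_features=max_features,
            min_samples_leaf=spec.min_leaf, random_state=seed, n_jobs=1,
        )
        rf.fit(G[train], y[train])
        fits.append(rf.feature_importances_)
    fits = np.asarray(fits)
    return fits.mean(axis=0), fits.std(axis=0), len(fits)


def _svr_fold_importance(model: SVR, X_te: np.ndarray, y_te: np.ndarray,
                         spec: SvrKernelSpec, gamma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Held-out permutation importance for one fitted fold.

    importance_j = R2(test) - R2(test with SNP column j permuted),
    clamped at 0, computed by shifting the test-vs-support-vector Gram
    matrix for each permuted column.
    """
    n_te, p = X_te.shape
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    if ss_tot <= 0:
        return np.zeros(p)
    SV = model.support_vectors_
    if SV.shape[0] == 0:
        warnings.warn("degenerate SVR fit (no support vectors); importances 0")
        return np.zeros(p)
    dual = model.dual_coef_.ravel()
    b = float(model.intercept_[0])
    D = X_te @ SV.T
    K = (gamma * D + spec.constant) ** spec.degree
    pred = K @ dual + b
    ss_base = float(np.sum((y_te - pred) ** 2))
    r2_base = 1.0 - ss_base / ss_tot

    # Permuting column j shifts the test-vs-SV dot products by the rank-1
    # matrix delta_j (x) SV[:, j]; expanding (A + gamma * shift)^degree
    # binomially turns the per-SNP prediction update into d matmuls shared
    # across SNPs:
    #   pred_j[i] = pred[i] + sum_k C(d,k) gamma^k delta_j[i]^k M_k[i, j],
    #   M_k = A^(d-k) @ (dual * SV^k),   A = gamma * D + constant.
    d = spec.degree
    A = gamma * D + spec.constant
    M = [
        (A ** (d - k)) @ (dual[:, None] * SV ** k)  # (n_te, p)
        for k in range(1, d + 1)
    ]
    coefs = [float(comb(d, k)) * gamma ** k for k in range(1, d + 1)]

    imp = np.zeros(p)
    for _ in range(spec.n_perm):
        perm = rng.permutation(n_te)
        delta = X_te[perm] - X_te                               # (n_te, p)
        pred_j = np.broadcast_to(pred[:, None], (n_te, p)).copy()
        dk = np.ones_like(delta)
        for k in range(1, d + 1):
            dk = dk * delta
            pred_j += coefs[k - 1] * dk * M[k - 1]
        ss_j = np.sum((y_te[:, None] - pred_j) ** 2, axis=0)
        imp += r2_base - (1.0 - ss_j / ss_tot)
    return np.maximum(imp / spec.n_perm, 0.0)


def _svr_raw_importance(y: np.ndarray, G: np.ndarray, spec: SvrKernelSpec,
                        cv: CvScheme | None):
    """Permutation importances averaged over CV folds (in-sample when
    cv is None); dosages are standardized per SNP on the training fold."""
    n, p = G.shape
    gamma = 1.0 / p
    if cv is None:
        splits = [(0, np.arange(n), np.arange(n))]
    else:
        splits = cv.splits(n)
    fits = []
    for k, (rep, train, test) in enumerate(splits):
        mu = G[train].mean(axis=0)
        sd = G[train].std(axis=0)
        sd[sd == 0] = 1.0
        X_tr = (G[train] - mu) / sd
        X_te = (G[test] - mu) / sd
        # standardize the response per fold so epsilon is on a unit scale
        y_mu, y_sd = y[train].mean(), y[train].std()
        if y_sd <= 0:
            y_sd = 1.0
        model = SVR(kernel="poly", degree=spec.degree, gamma=gamma,
                    coef0=spec.constant, C=spec.cost, epsilon=spec.epsilon)
        model.fit(X_tr, (y[train] - y_mu) / y_sd)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13, k]))
        fits.append(_svr_fold_importance(model, X_te, (y[test] - y_mu) / y_sd,
                                         spec, gamma, rng))
    fits = np.asarray(fits)
    return fits.mean(axis=0), fits.std(axis=0), len(fits)


def _profile(panel: GenotypePanel, raw: np.ndarray, spread: np.ndarray,
             method: str, n_fits: int) -> ImportanceProfile:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        scaled = scale_importance(raw)
    return ImportanceProfile(df=pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos,
        "raw_importance": raw, "scaled_importance": scaled,
        "fold_spread": spread,
    }), method=method, n_fits=n_fits)


def rf_importance_scan(y: np.ndarray, panel: GenotypePanel,
                       spec: RfModelSpec = RfModelSpec(),
                       cv: CvScheme | None = CvScheme()) -> ImportanceProfile:
    """Random-forest impurity importance per SNP, averaged over CV fits
    and scaled to 0-100."""
    y = _check_inputs(y, panel)
    raw, spread, n_fits = _rf_raw_importance(y, panel.dosage, spec, cv)
    return _profile(panel, raw, spread, "RF", n_fits)


def svr_importance_scan(y: np.ndarray, panel: GenotypePanel,
                        spec: SvrKernelSpec = SvrKernelSpec(),
                        cv: CvScheme | None = CvScheme()) -> ImportanceProfile:
    """Polynomial-kernel SVR permutation importance per SNP, averaged over
    CV folds and scaled to 0-100."""
    y = _check_inputs(y, panel)
    raw, spread, n_fits = _svr_raw_importance(y, panel.dosage, spec, cv)
    return _profile(panel, raw, spread, "SVR", n_fits)


def empirical_threshold(
    y: np.ndarray,
    panel: GenotypePanel,
    engine: str,
    spec: RfModelSpec | SvrKernelSpec | None = None,
    cv: CvScheme | None = None,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    reference: ImportanceProfile | None = None,
) -> EmpiricalNull:
    """Global empirical significance threshold for an importance engine.

    Each replicate permutes the phenotype across samples (genotypes
    untouched), reruns the engine's importance computation with the same
    configuration as the real scan, and stores the maximum importance;
    the threshold is the empirical (1 - alpha) quantile (type-7
    interpolation) of the stored maxima.

    Because the 0-100 scaling is recomputed per profile, within-replicate
    scaling would pin every stored maximum at 100; the permutation maxima
    are therefore expressed on the *observed* scan's scale (the affine map
    fixed by ``reference``, computed here if not supplied), which leaves
    the threshold comparable to the real scaled importances and preserves
    the family-wise error guarantee (the map is monotone and common to
    both sides).  A threshold above 100 simply means no SNP is declared.
    """
    if n_reps < 20:
        raise ValueError("n_reps < 20: quantile estimate would be unstable")
    engine = engine.upper()
    if engine not in ("RF", "SVR"):
        raise ValueError(f"unknown engine {engine!r}; expected RF or SVR")
    y = _check_inputs(y, panel)
    if spec is None:
        spec = RfModelSpec() if engine == "RF" else SvrKernelSpec()
    G = panel.dosage
    if reference is None:
        if engine == "RF":
            reference = rf_importance_scan(y, panel, spec, cv)
        else:
            reference = svr_importance_scan(y, panel, spec, cv)
    ref_raw = reference.df["raw_importance"].to_numpy()
    lo, hi = float(ref_raw.min()), float(ref_raw.max())
    span = hi - lo if hi > lo else 1.0

    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    maxima = np.empty(n_reps)
    for r in range(n_reps):
        y_perm = rng.permutation(y)
        rep_spec = _reseed(spec, int(rng.integers(2**31)))
        if engine == "RF":
            raw, _, _ = _rf_raw_importance(y_perm, G, rep_spec, cv)
        else:
            raw, _, _ = _svr_raw_importance(y_perm, G, rep_spec, cv)
        maxima[r] = 100.0 * (raw.max() - lo) / span
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return EmpiricalNull(max_importances=maxima, n_reps=n_reps, alpha=alpha,
                         threshold=threshold, engine=engine)


def _reseed(spec, seed: int):
    from dataclasses import replace

    return replace(spec, seed=seed)
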