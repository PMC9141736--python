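"""Marker QC, Markov imputation, kinship, PCA covariates and LD decay.

The QC chain mirrors a standard GBS panel workflow: drop SNPs with minor
allele frequency below 0.05 or heterozygosity above 50% (filters applied
on raw calls), then fill remaining missing calls with a first-order
Markov chain along each chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SnpQcReport",
    "KinshipMatrix",
    "LdDecayCurve",
    "compute_snp_qc",
    "apply_snp_qc",
    "impute_markov",
    "compute_kinship",
    "pca_covariates",
    "pairwise_r2",
    "estimate_ld_decay",
]


@dataclass
class SnpQcReport:
    """Per-SNP QC metrics and keep/drop verdicts."""

    df: pd.DataFrame  # snp_id, maf, het_rate, missing_rate, kept, reason

    def kept_index(self) -> np.ndarray:
        return np.where(self.df["kept"].to_numpy())[0]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class KinshipMatrix:
    """Realized genomic relationship matrix (VanRaden centered cross-product)."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),) * 2:
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (self.values + self.values.T) / 2.0

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")


@dataclass
class LdDecayCurve:
    """Binned mean r² against physical distance and the derived decay distance."""

    bins: pd.DataFrame        # columns: midpoint, mean_r2, n_pairs
    decay_distance: float     # bp where the curve first crosses r2_level
    r2_level: float
    crossed: bool             # False if the curve never fell below r2_level


def compute_snp_qc(panel: GenotypePanel, maf_min: float = 0.05,
                   het_max: float = 0.5) -> SnpQcReport:
    """MAF / heterozygosity filter verdicts on raw (pre-imputation) calls.

    A SNP is kept iff MAF >= ``maf_min`` and het rate <= ``het_max``;
    MAF counts alleles among non-missing calls only.
    """
    if not (0.0 <= maf_min <= 0.5) or not (0.0 <= het_max <= 1.0):
        raise ValueError("maf_min must be in [0, 0.5], het_max in [0, 1]")
    D = panel.dosage
    obs = ~np.isnan(D)
    n_obs = obs.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nansum(D, axis=0) / (2.0 * np.maximum(n_obs, 1))
        het = np.nansum(D == 1, axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = 1.0 - n_obs / D.shape[0]
    all_missing = n_obs == 0
    maf[all_missing] = 0.0
    if all_missing.any():
        logger.warning("compute_snp_qc: %d SNPs have no observed calls", all_missing.sum())
    low_maf = maf < maf_min
    high_het = het > het_max
    kept = ~(low_maf | high_het)
    reason = np.where(low_maf, "low_maf", np.where(high_het, "high_het", "pass"))
    df = pd.DataFrame({
        "snp_id": panel.snp_ids,
        "maf": maf,
        "het_rate": het,
        "missing_rate": missing_rate,
        "kept": kept,
        "reason": reason,
    })
    return SnpQcReport(df=df)


def apply_snp_qc(panel: GenotypePanel, report: SnpQcReport) -> GenotypePanel:
    """Subset the panel to SNPs the QC report keeps."""
    return panel.take_snps(report.kept_index())


def _transition_probs(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """3x3 transition frequency table P(right | left) with Laplace smoothing,
    estimated from samples observed at both SNPs."""
    T = np.ones((3, 3))  # Laplace prior
    both = ~np.isnan(left) & ~np.isnan(right)
    l, r = left[both].astype(int), right[both].astype(int)
    np.add.at(T, (l, r), 1.0)
    return T / T.sum(axis=1, keepdims=True)


def impute_markov(panel: GenotypePanel) -> GenotypePanel:
    """Fill missing calls with a first-order Markov chain along each chromosome.

    Transition frequencies between adjacent SNPs are estimated from samples
    with both calls observed.  A left-to-right and a right-to-left pass are
    averaged (removing orientation asymmetry) and each missing call takes
    the most probable state.  Columns with no informative neighbours fall
    back to the per-SNP modal dosage.  Observed calls are never altered.
    """
    panel = panel.sorted_by_position()
    D = panel.dosage.copy()
    if not np.isnan(D).any():
        return panel

    for c in pd.unique(panel.chrom):
        cols = np.where(panel.chrom == c)[0]
        sub = D[:, cols]
        m = sub.shape[1]
        probs = np.zeros((sub.shape[0], m, 3))

        def modal_prob(col: np.ndarray) -> np.ndarray:
            # marginal state frequencies: the chain prior at terminal columns
            # (argmax of the two-pass average falls back to the modal dosage
            # when no neighbour is informative)
            obs = col[~np.isnan(col)].astype(int)
            if len(obs) == 0:
                return np.array([1.0, 0.0, 0.0])  # wholly missing column
            counts = np.bincount(obs, minlength=3).astype(float)
            return counts / counts.sum()

        # forward pass
        fwd = np.zeros_like(probs)
        state = np.zeros((sub.shape[0], 3))
        for j in range(m):
            col = sub[:, j]
            if j == 0:
                base = modal_prob(col)
                cur = np.tile(base, (sub.shape[0], 1))
            else:
                T = _transition_probs(sub[:, j - 1], col)
                cur = state @ T
            obs = ~np.isnan(col)
            cur[obs] = 0.0
            cur[obs, col[obs].astype(int)] = 1.0
            fwd[:, j, :] = cur
            state = cur
        # backward pass
        bwd = np.zeros_like(probs)
        state = np.zeros((sub.shape[0], 3))
        for j in range(m - 1, -1, -1):
            col = sub[:, j]
            if j == m - 1:
                base = modal_prob(col)
                cur = np.tile(base, (sub.shape[0], 1))
            else:
                T = _transition_probs(sub[:, j + 1], col)
                cur = state @ T
            obs = ~np.isnan(col)
            cur[obs] = 0.0
            cur[obs, col[obs].astype(int)] = 1.0
            bwd[:, j, :] = cur
            state = cur

        avg = (fwd + bwd) / 2.0
        fill = np.argmax(avg, axis=2).astype(float)
        missing = np.isnan(sub)
        sub[missing] = fill[missing]
        D[:, cols] = sub

    return GenotypePanel(
        sample_ids=panel.sample_ids, snp_ids=panel.snp_ids, chrom=panel.chrom,
        pos=panel.pos, ref_allele=panel.ref_allele, alt_allele=panel.alt_allele,
        dosage=D,
    )


def compute_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    K = W W' / sum_j 2 p_j (1 - p_j), with W the column-centered dosage
    (x_ij - 2 p_j).  Monomorphic SNPs contribute nothing and are excluded
    from the scaling sum.
    """
    D = panel.dosage
    if np.isnan(D).any():
        raise ValueError("kinship requires an imputed panel (no missing calls)")
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("compute_kinship: %d monomorphic SNPs excluded from scaling", n_mono)
    W = D[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    K = W @ W.T / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(sample_ids=panel.sample_ids, values=K)


def pca_covariates(panel: GenotypePanel, q: int) -> np.ndarray:
    """Top-q principal-component scores of the centered dosage matrix.

    Sign convention: within each component the loading of largest
    magnitude is positive.  ``q <= 0`` returns an (n, 0) matrix
    (intercept-only downstream models).
    """
    n = panel.n_samples
    if q <= 0:
        return np.zeros((n, 0))
    if q >= min(n, panel.n_snps):
        raise ValueError(f"q = {q} must be < min(n, p) = {min(n, panel.n_snps)}")
    D = panel.dosage
    if np.isnan(D).any():
        raise ValueError("PCA requires an imputed panel")
    X = D - D.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = (U * s) * flip
    return scores[:, :q]


def pairwise_r2(panel: GenotypePanel, max_dist: float) -> pd.DataFrame:
    """Squared Pearson correlation of dosage for intra-chromosome SNP pairs
    within ``max_dist`` bp.  Monomorphic SNPs are skipped."""
    D = panel.dosage
    if np.isnan(D).any():
        raise ValueError("pairwise_r2 requires an imputed panel")
    rows = []
    for c in pd.unique(panel.chrom):
        cols = np.where(panel.chrom == c)[0]
        if len(cols) < 2:
            continue
        pos = panel.pos[cols]
        sub = D[:, cols]
        sd = sub.std(axis=0)
        keep = sd > 0
        sub, pos = sub[:, keep], pos[keep]
        if sub.shape[1] < 2:
            continue
        Z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        R = Z.T @ Z / Z.shape[0]
        m = len(pos)
        iu, ju = np.triu_indices(m, k=1)
        dist = pos[ju] - pos[iu]
        sel = dist <= max_dist
        r2 = R[iu[sel], ju[sel]] ** 2
        rows.append(pd.DataFrame({
            "chrom": c, "pos1": pos[iu[sel]], "pos2": pos[ju[sel]],
            "dist": dist[sel], "r2": np.clip(r2, 0.0, 1.0),
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos1", "pos2", "dist", "r2"])
    return pd.concat(rows, ignore_index=True)


def estimate_ld_decay(pairs: pd.DataFrame, bin_width: float,
                      r2_level: float | None = None) -> LdDecayCurve:
    """Mean r² per distance bin and the distance where it first crosses
    ``r2_level`` (default: half the first-bin mean), interpolating linearly
    between bin midpoints."""
    if len(pairs) == 0:
        raise ValueError("no LD pairs supplied")
    d = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    nbin = int(np.ceil(d.max() / bin_width))
    idx = np.minimum((d // bin_width).astype(int), nbin - 1)
    sums = np.bincount(idx, weights=r2, minlength=nbin)
    counts = np.bincount(idx, minlength=nbin)
    keep = counts > 0
    mids = (np.arange(nbin) + 0.5) * bin_width
    bins = pd.DataFrame({
        "midpoint": mids[keep],
        "mean_r2": sums[keep] / counts[keep],
        "n_pairs": counts[keep],
    })
    if r2_level is None:
        r2_level = float(bins["mean_r2"].iloc[0] / 2.0)

    mid = bins["midpoint"].to_numpy()
    mean_r2 = bins["mean_r2"].to_numpy()
    crossed = False
    decay = float(mid[-1])
    below = np.where(mean_r2 < r2_level)[0]
    if len(below) > 0:
        k = below[0]
        crossed = True
        if k == 0:
            decay = float(mid[0])
        else:
            x0, x1 = mid[k - 1], mid[k]
            y0, y1 = mean_r2[k - 1], mean_r2[k]
            decay = float(x0 + (y0 - r2_level) / (y0 - y1) * (x1 - x0))
    else:
        logger.warning("LD curve never crosses r2 = %.3g; decay set to max distance", r2_level)
    return LdDecayCurve(bins=bins, decay_distance=decay, r2_level=float(r2_level),
                        crossed=crossed)
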