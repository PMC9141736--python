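"""From significant markers to QTL windows, candidate genes and effects.

Significant SNPs collapse to peaks (best statistic within the flank
distance), peaks expand to windows (peak +/- flank, clipped to the
chromosome), windows collect overlapping gene models sorted by edge
distance from the peak, and peak SNPs get allelic-effect summaries
(difference of homozygote-class BLUP means; heterozygotes excluded in an
inbred panel).  The default flank is 150 kbp, an LD-decay-informed window
for a soybean-type panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AssociationTable, GeneAnnotation, GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "QtlWindow",
    "AlleleEffect",
    "call_significant",
    "extract_qtl_windows",
    "annotate_candidate_genes",
    "estimate_allele_effects",
    "method_overlap_report",
    "export_manhattan_qq",
    "DEFAULT_FLANK",
]

DEFAULT_FLANK = 150_000


@dataclass
class QtlWindow:
    chrom: str
    start: int
    end: int
    peak_snp: str
    peak_pos: int
    peak_statistic: float
    method: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    gene_distances: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end}]")
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("peak position outside window")


@dataclass
class AlleleEffect:
    snp_id: str
    trait: str
    mean_ref: float
    mean_alt: float
    n_ref: int
    n_alt: int

    @property
    def effect(self) -> float:
        return self.mean_alt - self.mean_ref


def _better(method: str, a: float, b: float) -> bool:
    """True if statistic a beats b for the method (smaller p / larger importance)."""
    if method in AssociationTable.LINEAR_METHODS:
        return a < b
    return a > b


def call_significant(table: AssociationTable, flank: float = DEFAULT_FLANK) -> pd.DataFrame:
    """Collapse significant SNPs into peaks.

    Within a chromosome, significant SNPs closer than ``flank`` to each
    other (transitively) form one peak, represented by the SNP with the
    best statistic; ties break toward the lower position.
    """
    peaks = []
    for method, grp in table.df.groupby("method"):
        sig = grp[grp["significant"]].sort_values(["chrom", "pos"])
        for chrom, cg in sig.groupby("chrom"):
            cg = cg.sort_values("pos")
            cluster: list[pd.Series] = []
            prev_pos = None
            for _, row in cg.iterrows():
                if prev_pos is not None and row["pos"] - prev_pos >= flank:
                    peaks.append(_best_of(cluster, method))
                    cluster = []
                cluster.append(row)
                prev_pos = row["pos"]
            if cluster:
                peaks.append(_best_of(cluster, method))
    if not peaks:
        return pd.DataFrame(columns=["snp_id", "chrom", "pos", "method", "statistic"])
    return pd.DataFrame(peaks).reset_index(drop=True)


def _best_of(cluster: list[pd.Series], method: str) -> dict:
    best = cluster[0]
    for row in cluster[1:]:
        if _better(method, row["statistic"], best["statistic"]) or (
            row["statistic"] == best["statistic"] and row["pos"] < best["pos"]
        ):
            best = row
    return {"snp_id": best["snp_id"], "chrom": best["chrom"],
            "pos": int(best["pos"]), "method": method,
            "statistic": float(best["statistic"])}


def extract_qtl_windows(peaks: pd.DataFrame, flank: int = DEFAULT_FLANK,
                        chrom_lengths: dict[str, int] | None = None) -> list[QtlWindow]:
    """Peak SNP +/- flank windows, clipped to [1, chromosome length];
    overlapping windows from the same method merge, keeping the best peak."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: list[QtlWindow] = []
    for _, row in peaks.iterrows():
        L = None
        if chrom_lengths is not None:
            L = chrom_lengths.get(row["chrom"])
            if L is None:
                logger.warning("unknown length for chromosome %s; window unclipped",
                               row["chrom"])
        start = max(1, int(row["pos"]) - flank)
        end = int(row["pos"]) + flank if L is None else min(L, int(row["pos"]) + flank)
        windows.append(QtlWindow(
            chrom=str(row["chrom"]), start=start, end=end,
            peak_snp=str(row["snp_id"]), peak_pos=int(row["pos"]),
            peak_statistic=float(row["statistic"]), method=str(row["method"]),
        ))
    # merge overlapping windows per (method, chrom)
    merged: list[QtlWindow] = []
    key = lambda w: (w.method, w.chrom, w.start)
    for w in sorted(windows, key=key):
        if merged and merged[-1].method == w.method and merged[-1].chrom == w.chrom \
                and w.start <= merged[-1].end:
            prev = merged[-1]
            keep_new = _better(w.method, w.peak_statistic, prev.peak_statistic)
            peak = w if keep_new else prev
            merged[-1] = QtlWindow(
                chrom=prev.chrom, start=prev.start, end=max(prev.end, w.end),
                peak_snp=peak.peak_snp, peak_pos=peak.peak_pos,
                peak_statistic=peak.peak_statistic, method=prev.method,
            )
        else:
            merged.append(w)
    return merged


def annotate_candidate_genes(windows: list[QtlWindow],
                             genes: list[GeneAnnotation]) -> list[QtlWindow]:
    """Attach genes overlapping each window by >= 1 bp, sorted by edge
    distance from the peak (0 when the gene contains the peak)."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for w in windows:
        hits = []
        for g in by_chrom.get(w.chrom, []):
            if g.end >= w.start and g.start <= w.end:
                if g.start <= w.peak_pos <= g.end:
                    d = 0
                else:
                    d = min(abs(g.start - w.peak_pos), abs(g.end - w.peak_pos))
                hits.append((d, g))
        hits.sort(key=lambda t: (t[0], t[1].gene_id))
        out.append(QtlWindow(
            chrom=w.chrom, start=w.start, end=w.end, peak_snp=w.peak_snp,
            peak_pos=w.peak_pos, peak_statistic=w.peak_statistic,
            method=w.method, genes=[g for _, g in hits],
            gene_distances=[d for d, _ in hits],
        ))
    return out


def estimate_allele_effects(panel: GenotypePanel, blups: pd.Series,
                            peaks: pd.DataFrame, trait: str = "") -> list[AlleleEffect]:
    """Mean BLUP per homozygote class at each peak SNP; effect = alt - ref.

    Heterozygotes are excluded (inbred panel); a SNP with an empty
    homozygote class is reported with NaN means for that class.
    """
    snp_index = {s: j for j, s in enumerate(panel.snp_ids)}
    y = blups.reindex(panel.sample_ids).to_numpy(dtype=float)
    out = []
    for snp in pd.unique(peaks["snp_id"]):
        j = snp_index.get(snp)
        if j is None:
            logger.warning("peak SNP %s not in panel; skipped", snp)
            continue
        d = panel.dosage[:, j]
        ref_mask = (d == 0) & ~np.isnan(y)
        alt_mask = (d == 2) & ~np.isnan(y)
        n_ref, n_alt = int(ref_mask.sum()), int(alt_mask.sum())
        mean_ref = float(y[ref_mask].mean()) if n_ref else float("nan")
        mean_alt = float(y[alt_mask].mean()) if n_alt else float("nan")
        if n_ref == 0 or n_alt == 0:
            logger.warning("SNP %s: a homozygote class is empty; effect undefined", snp)
        out.append(AlleleEffect(snp_id=str(snp), trait=trait, mean_ref=mean_ref,
                                mean_alt=mean_alt, n_ref=n_ref, n_alt=n_alt))
    return out


def method_overlap_report(tables: dict[str, AssociationTable],
                          flank: float = DEFAULT_FLANK) -> pd.DataFrame:
    """Venn-style overlap of significant loci across methods.

    Peaks from all methods are pooled and clustered transitively (same
    chromosome, closer than ``flank``); each cluster counts once, under
    the subset of methods that hit it.  Counts therefore partition the
    union of loci.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 methods")
    peaks = []
    for method, table in tables.items():
        p = call_significant(table, flank=flank)
        p["method"] = method
        peaks.append(p)
    pooled = pd.concat(peaks, ignore_index=True)
    subsets: dict[tuple[str, ...], int] = {}
    if len(pooled):
        pooled = pooled.sort_values(["chrom", "pos"]).reset_index(drop=True)
        cluster_methods: set[str] = set()
        prev_chrom, prev_pos = None, None
        clusters: list[set[str]] = []
        for _, row in pooled.iterrows():
            new = (row["chrom"] != prev_chrom
                   or (prev_pos is not None and row["pos"] - prev_pos >= flank))
            if new and cluster_methods:
                clusters.append(cluster_methods)
                cluster_methods = set()
            cluster_methods.add(row["method"])
            prev_chrom, prev_pos = row["chrom"], row["pos"]
        if cluster_methods:
            clusters.append(cluster_methods)
        for c in clusters:
            key = tuple(sorted(c))
            subsets[key] = subsets.get(key, 0) + 1
    rows = [{"methods": "+".join(k), "n_methods": len(k), "n_loci": v}
            for k, v in sorted(subsets.items())]
    return pd.DataFrame(rows, columns=["methods", "n_methods", "n_loci"])


def export_manhattan_qq(table: AssociationTable, out_prefix: str,
                        chrom_lengths: dict[str, int] | None = None,
                        make_plots: bool = False) -> dict[str, str]:
    """Write Manhattan (and, for p-value methods, QQ) data files.

    Manhattan: cumulative genome coordinate, -log10 p or scaled importance,
    and the per-method threshold.  QQ: expected vs observed -log10 p for
    linear methods; importance engines have no uniform null quantiles so
    their QQ file is skipped with a note.
    """
    df = table.sorted()
    chroms = list(pd.unique(df["chrom"]))
    if chrom_lengths is None:
        chrom_lengths = {c: int(df.loc[df["chrom"] == c, "pos"].max()) for c in chroms}
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += chrom_lengths.get(c, int(df.loc[df["chrom"] == c, "pos"].max()))
    written: dict[str, str] = {}
    man_rows = []
    for method, grp in df.groupby("method"):
        linear = method in AssociationTable.LINEAR_METHODS
        val = (-np.log10(grp["statistic"]) if linear
               else grp["statistic"].to_numpy())
        thr = grp["threshold"].to_numpy(dtype=float)
        thr_val = -np.log10(thr) if linear else thr
        man_rows.append(pd.DataFrame({
            "method": method, "chrom": grp["chrom"],
            "genome_pos": grp["pos"].to_numpy() + grp["chrom"].map(offsets).to_numpy(),
            "value": val, "threshold": thr_val,
            "significant": grp["significant"],
        }))
    man = pd.concat(man_rows, ignore_index=True)
    man_path = f"{out_prefix}_manhattan.tsv"
    man.to_csv(man_path, sep="\t", index=False, float_format="%.6g")
    written["manhattan"] = man_path

    qq_rows = []
    for method, grp in df.groupby("method"):
        if method not in AssociationTable.LINEAR_METHODS:
            logger.info("QQ skipped for %s (importances have no uniform null)", method)
            continue
        p = np.sort(grp["statistic"].to_numpy(dtype=float))
        m = len(p)
        expected = (np.arange(1, m + 1) - 0.5) / m
        qq_rows.append(pd.DataFrame({
            "method": method,
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p),
        }))
    if qq_rows:
        qq = pd.concat(qq_rows, ignore_index=True)
        qq_path = f"{out_prefix}_qq.tsv"
        qq.to_csv(qq_path, sep="\t", index=False, float_format="%.6g")
        written["qq"] = qq_path

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for method, grp in man.groupby("method"):
            fig, ax = plt.subplots(figsize=(9, 3))
            for i, (c, cg) in enumerate(grp.groupby("chrom", sort=False)):
                ax.scatter(cg["genome_pos"], cg["value"], s=4,
                           color=["#41618a", "#8aa1bf"][i % 2])
            ax.axhline(grp["threshold"].iloc[0], color="red", lw=0.8, ls="--")
            ax.set_xlabel("genome position (bp)")
            ax.set_ylabel("-log10 p" if method in AssociationTable.LINEAR_METHODS
                          else "importance (0-100)")
            ax.set_title(method)
            fig.tight_layout()
            path = f"{out_prefix}_manhattan_{method}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"plot_{method}"] = path
    return written
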