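"""Readers/writers and the in-memory data model shared by all modules.

The central container is :class:`GenotypePanel`, an individuals x SNPs
alt-allele dosage matrix (0/1/2, NaN for missing) with per-SNP map
metadata.  Positions are 1-based inclusive everywhere inside the package;
only BED output converts to 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "PhenotypeTable",
    "GeneAnnotation",
    "AssociationTable",
    "read_vcf",
    "write_vcf",
    "read_hapmap",
    "read_phenotypes",
    "read_gff3",
    "write_association_tsv",
    "read_association_tsv",
    "write_windows_bed",
    "read_windows_bed",
]

# IUPAC ambiguity codes for heterozygous HapMap calls
_IUPAC = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


@dataclass
class GenotypePanel:
    """Biallelic SNP dosages for a panel of individuals.

    ``dosage[i, j]`` counts copies of the ALT allele (VCF convention) of
    SNP ``j`` carried by individual ``i``; ``np.nan`` marks a missing call.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, p = self.dosage.shape
        if n != len(self.sample_ids) or p != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref_allele, "ref_allele"),
                          (self.alt_allele, "alt_allele")):
            if len(arr) != p:
                raise ValueError(f"{name} has length {len(arr)}, expected {p}")
        if np.any(self.ref_allele == self.alt_allele):
            bad = self.snp_ids[self.ref_allele == self.alt_allele]
            raise ValueError(f"ref and alt alleles identical for SNPs {list(bad[:5])}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def sorted_by_position(self) -> "GenotypePanel":
        """Return a copy with SNPs ordered by (chromosome, position)."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_snps(order)

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            sample_ids=self.sample_ids[idx],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            dosage=self.dosage[idx, :],
        )

    def check_positions_sorted(self) -> bool:
        """True if positions are strictly increasing within each chromosome."""
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                return False
        return True


@dataclass
class PhenotypeTable:
    """Long-format plot-level phenotype records.

    One row per (sample, location, year, block, trait); ``value`` is NaN
    for missing observations.  ``environment`` is the location x year
    combination, the unit the multi-environment mixed model treats as a
    fixed effect.
    """

    records: pd.DataFrame

    REQUIRED = ("sample_id", "location", "year", "block", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype records missing columns {missing}")
        self.records = self.records.copy()
        for c in ("sample_id", "location", "year", "block", "trait"):
            self.records[c] = self.records[c].astype(str)
        self.records["value"] = pd.to_numeric(self.records["value"], errors="coerce")
        key = ["sample_id", "location", "year", "block", "trait"]
        dup = self.records.duplicated(subset=key)
        if dup.any():
            first = self.records.loc[dup, key].iloc[0].to_dict()
            raise ValueError(f"duplicate phenotype key: {first}")

    @property
    def environments(self) -> pd.Series:
        return self.records["location"] + ":" + self.records["year"]

    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        df = self.records[self.records["trait"] == trait].copy()
        df["environment"] = df["location"] + ":" + df["year"]
        return df


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model: 1-based inclusive coordinates on a chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class AssociationTable:
    """Per-SNP association results for one or more engines.

    ``statistic`` is a p-value in (0, 1] for linear methods (MLM,
    FarmCPU) and a 0-100 scaled importance for ML methods (RF, SVR);
    ``threshold`` lives on the same scale and ``significant`` encodes
    p <= threshold (linear) or importance >= threshold (ML).
    """

    df: pd.DataFrame

    COLUMNS = ("snp_id", "chrom", "pos", "method", "statistic", "threshold", "significant")
    LINEAR_METHODS = frozenset({"MLM", "FarmCPU"})
    ML_METHODS = frozenset({"RF", "SVR"})

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"association table missing columns {missing}")
        self.df = self.df.copy()
        self.df["pos"] = self.df["pos"].astype(np.int64)
        self.df["significant"] = self.df["significant"].astype(bool)
        for method, grp in self.df.groupby("method"):
            stat = grp["statistic"].to_numpy(dtype=float)
            if method in self.LINEAR_METHODS:
                if np.any((stat <= 0) | (stat > 1)):
                    raise ValueError(f"method {method}: p-values must lie in (0, 1]")
            elif method in self.ML_METHODS:
                if np.any((stat < 0) | (stat > 100)):
                    raise ValueError(f"method {method}: importances must lie in [0, 100]")

    def sorted(self) -> pd.DataFrame:
        return self.df.sort_values(
            ["chrom", "pos", "method"], kind="mergesort"
        ).reset_index(drop=True)

    def significant_snps(self, method: str | None = None) -> pd.DataFrame:
        df = self.df if method is None else self.df[self.df["method"] == method]
        return df[df["significant"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a :class:`GenotypePanel`.

    Dosage counts ALT-allele copies; ``./.`` becomes NaN.  Indels and
    multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    panel = GenotypePanel(
        sample_ids=np.array(samples, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=np.vstack(rows).T,
    )
    return panel.sorted_by_position()


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as minimal uncompressed VCF 4.2 (diploid GT only)."""
    panel = panel.sorted_by_position()
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(panel.chrom):
            ln = int(panel.pos[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in panel.sample_ids) + "\n")
        for j in range(panel.n_snps):
            calls = [
                gt_map.get(panel.dosage[i, j], "./.")
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref_allele[j]}\t{panel.alt_allele[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# HapMap

def write_hapmap(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel in the tab-delimited HapMap format (ref allele listed first)."""
    panel = panel.sorted_by_position()
    head = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
            "protLSID", "assayLSID", "panelLSID", "QCcode"]
    with open(path, "w") as fh:
        fh.write("\t".join(head + [str(s) for s in panel.sample_ids]) + "\n")
        for j in range(panel.n_snps):
            r, a = panel.ref_allele[j], panel.alt_allele[j]
            calls = []
            for i in range(panel.n_samples):
                d = panel.dosage[i, j]
                if np.isnan(d):
                    calls.append("NN")
                elif d == 0:
                    calls.append(r + r)
                elif d == 2:
                    calls.append(a + a)
                else:
                    calls.append(r + a)
            fh.write(
                "\t".join(
                    [str(panel.snp_ids[j]), f"{r}/{a}", str(panel.chrom[j]),
                     str(panel.pos[j]), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
                    + calls
                )
                + "\n"
            )


def read_hapmap(path: str | Path) -> GenotypePanel:
    """Read a tab-delimited HapMap genotype file.

    The first allele in the ``alleles`` column is taken as the reference;
    dosage counts the second (alternate) allele, matching :func:`read_vcf`.
    Two-letter allele pairs ("AG"), single IUPAC codes ("R") and "NN"/"N"
    are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise ValueError("HapMap file must have 11 metadata columns plus samples")
    samples = list(df.columns[11:])
    n, p = len(samples), len(df)
    dosage = np.full((n, p), np.nan)
    refs, alts = [], []
    for j, row in enumerate(df.itertuples(index=False)):
        alleles = str(row[1]).replace("|", "/").split("/")
        if len(alleles) != 2:
            raise ValueError(f"SNP {row[0]}: cannot parse alleles field {row[1]!r}")
        ref, alt = alleles
        refs.append(ref)
        alts.append(alt)
        for i, tok in enumerate(row[11:]):
            tok = str(tok).upper()
            if tok in ("NN", "N", "--", "NA", "nan"):
                continue
            if len(tok) == 1:
                pair = _IUPAC.get(tok)
                if pair is None:
                    if tok == ref:
                        tok = ref + ref
                    elif tok == alt:
                        tok = alt + alt
                    else:
                        raise ValueError(
                            f"SNP {row[0]}, sample {samples[i]}: unknown genotype code {tok!r}"
                        )
                else:
                    if set(pair) != {ref, alt}:
                        raise ValueError(
                            f"SNP {row[0]}, sample {samples[i]}: IUPAC code {tok!r} "
                            f"inconsistent with alleles {ref}/{alt}"
                        )
                    tok = ref + alt
            if len(tok) != 2 or not set(tok) <= {ref, alt}:
                raise ValueError(
                    f"SNP {row[0]}, sample {samples[i]}: unknown genotype code {tok!r}"
                )
            dosage[i, j] = sum(1 for ch in tok if ch == alt)
    panel = GenotypePanel(
        sample_ids=np.array(samples, dtype=object),
        snp_ids=df.iloc[:, 0].to_numpy(dtype=object),
        chrom=df.iloc[:, 2].to_numpy(dtype=object),
        pos=df.iloc[:, 3].astype(np.int64).to_numpy(),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=dosage,
    )
    return panel.sorted_by_position()


# ---------------------------------------------------------------------------
# Phenotypes

def read_phenotypes(
    path: str | Path,
    sample_col: str = "sample_id",
    location_col: str = "location",
    year_col: str = "year",
    block_col: str = "block",
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a wide delimited phenotype table into long format.

    Every column other than the four design columns is treated as a trait.
    Non-numeric cells become missing values (count logged).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    design = [sample_col, location_col, year_col, block_col]
    missing = [c for c in design if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing design columns {missing}")
    trait_cols = [c for c in df.columns if c not in design]
    if not trait_cols:
        raise ValueError("phenotype file has no trait columns")
    long = df.melt(id_vars=design, value_vars=trait_cols,
                   var_name="trait", value_name="value")
    long = long.rename(columns={sample_col: "sample_id", location_col: "location",
                                year_col: "year", block_col: "block"})
    numeric = pd.to_numeric(long["value"], errors="coerce")
    n_bad = int((numeric.isna() & long["value"].notna()
                 & (long["value"].astype(str).str.strip().str.upper() != "NA")).sum())
    if n_bad:
        logger.info("read_phenotypes: %d non-numeric cells treated as missing", n_bad)
    long["value"] = numeric
    return PhenotypeTable(records=long)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneAnnotation]:
    """Read gene models from a GFF3 file (records of type ``gene`` by default)."""
    genes: list[GeneAnnotation] = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype not in feature_types:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                n_rejected += 1
                continue
            attr_d = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_d[k.strip()] = v.strip()
            gene_id = attr_d.get("ID") or attr_d.get("Name") or f"{chrom}:{start}-{end}"
            genes.append(GeneAnnotation(
                gene_id=gene_id, chrom=chrom, start=start_i, end=end_i,
                strand=strand if strand in "+-" else "+",
                description=attr_d.get("Note", attr_d.get("description", "")),
            ))
    if n_rejected:
        logger.warning("read_gff3: rejected %d records with start > end", n_rejected)
    return genes


# ---------------------------------------------------------------------------
# Association tables and BED windows

def write_association_tsv(table: AssociationTable, path: str | Path) -> None:
    """Write an association table as TSV, rows ordered by (chrom, pos, method)."""
    if len(table.df) == 0:
        raise ValueError("refusing to write an empty association table")
    out = table.sorted()[list(AssociationTable.COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_association_tsv(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t")
    return AssociationTable(df=df)


def write_windows_bed(windows: Iterable, path: str | Path,
                      chrom_lengths: dict[str, int] | None = None) -> None:
    """Write QTL windows as BED6 (0-based half-open; name = peak SNP id)."""
    lines = []
    for w in windows:
        start, end = w.start, w.end
        if chrom_lengths is not None and w.chrom in chrom_lengths:
            L = chrom_lengths[w.chrom]
            if end > L:
                logger.warning("window %s clipped to chromosome length %d", w.peak_snp, L)
                end = L
        lines.append((str(w.chrom), start - 1, end, str(w.peak_snp),
                      float(w.peak_statistic), "."))
    lines.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        for t in lines:
            fh.write("\t".join(str(x) for x in t) + "\n")


def read_windows_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 back into 1-based inclusive window coordinates."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start_bed", "end_bed", "name", "score", "strand"])
    df["start"] = df["start_bed"] + 1
    df["end"] = df["end_bed"]
    return df[["chrom", "start", "end", "name", "score"]]
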