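"""Synthetic soybean-like GWAS panels with known ground truth.

Genotypes: per-chromosome haplotypes from a first-order Markov chain whose
neighbour correlation decays with physical distance (r² halves every
``ld_half_length`` bp), optional Balding–Nichols subpopulation structure,
and an inbreeding coefficient controlling residual heterozygosity (soybean
lines are near-fully inbred).

Phenotypes: plot-level records under the multi-environment mixed-model
structure Y = environment/block fixed effects + genotype effect +
genotype-by-environment interaction + residual, with planted additive QTL
and a polygenic remainder scaled to a target heritability.  Heritability is
parameterised on the plot basis sigma2_g / (sigma2_g + sigma2_e), matching
the literal variance-ratio definition used by the phenotype module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel, PhenotypeTable

__all__ = [
    "QtlSpec",
    "SimulationConfig",
    "SimulatedPanel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_panel",
    "simulate_null_panel",
]


@dataclass(frozen=True)
class QtlSpec:
    """A planted causal SNP: index into the panel (or "random") and its
    share of total phenotypic (plot-level) variance."""

    snp: int | str = "random"
    variance_share: float = 0.1


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the field study the toolkit targets: 227 inbred
    genotypes on 20 chromosomes, grown in 4 environments (2 locations x
    2 years) under an RCBD with 2 blocks, trait heritabilities in the
    0.24-0.78 range (default 0.5).
    """

    n_individuals: int = 227
    n_snps: int = 2000
    n_chromosomes: int = 20
    chrom_length: int = 50_000_000
    ld_half_length: float = 150_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    qtl: Sequence[QtlSpec] = field(default_factory=tuple)
    h2: float = 0.5
    n_envs: int = 4
    n_blocks: int = 2
    env_effect_sd: float = 1.0
    block_sd: float = 0.25
    gxe_sd: float = 0.0
    inbreeding: float = 0.95
    missing_rate: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"infeasible maf_range {self.maf_range}")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        total_share = sum(q.variance_share for q in self.qtl)
        if total_share > self.h2 + 1e-12:
            raise ValueError(
                f"QTL variance shares sum to {total_share:.3f} > h2 = {self.h2}"
            )


@dataclass
class SimulatedPanel:
    """A synthetic panel with its generating truth."""

    panel: GenotypePanel
    phenotypes: PhenotypeTable
    causal_snp_ids: list[str]
    causal_effects: list[float]
    true_components: dict[str, float]
    genetic_values: np.ndarray  # per individual, trait units


def _haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                pos: np.ndarray, ld_half_length: float) -> np.ndarray:
    """Markov-chain haplotypes: allele correlation between neighbours
    r(d) = exp(-d*ln2 / (2L)) so that r² halves every L bp."""
    p = len(freqs)
    H = np.empty((n_hap, p), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, p):
        d = pos[j] - pos[j - 1]
        r = np.exp(-d * np.log(2.0) / (2.0 * ld_half_length))
        pj, pprev = freqs[j], freqs[j - 1]
        denom = np.sqrt(max(pprev * (1 - pprev), 1e-12))
        slope = r * np.sqrt(pj * (1 - pj)) / denom
        cond = np.clip(pj + slope * (H[:, j - 1] - pprev), 0.0, 1.0)
        H[:, j] = rng.random(n_hap) < cond
    return H


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Generate an inbred biallelic panel with LD blocks, a MAF spectrum in
    ``maf_range`` and optional Balding–Nichols subpopulation structure."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n, p = config.n_individuals, config.n_snps
    per_chrom = np.full(config.n_chromosomes, p // config.n_chromosomes)
    per_chrom[: p % config.n_chromosomes] += 1

    lo, hi = config.maf_range
    # assign individuals to subpopulations (balanced)
    subpop = np.repeat(np.arange(config.n_subpops),
                       int(np.ceil(n / config.n_subpops)))[:n]

    chroms, poss = [], []
    dosage = np.empty((n, p), dtype=float)
    col = 0
    for c in range(config.n_chromosomes):
        m = per_chrom[c]
        pos = np.unique(rng.integers(1, config.chrom_length + 1, size=2 * m + 16))
        while len(pos) < m:  # collisions are vanishingly rare at genome scale
            pos = np.unique(np.concatenate(
                [pos, rng.integers(1, config.chrom_length + 1, size=m)]))
        pos = np.sort(rng.choice(pos, size=m, replace=False))
        chroms.extend([f"Chr{c + 1:02d}"] * m)
        poss.extend(pos.tolist())

        # Block-constant ancestral frequencies (renewal process with mean
        # block length ~10 LD half-lengths).  SNPs in strong LD must have
        # similar allele frequencies -- the Frechet bound caps r between
        # frequency-mismatched loci -- so frequency blocks are what makes
        # the configured r2 decay realizable, mirroring real LD blocks.
        block_half = 10.0 * config.ld_half_length
        gaps = np.diff(pos, prepend=pos[0])
        renew = rng.random(m) < 1.0 - np.exp(-gaps / block_half)
        renew[0] = True
        block_id = np.cumsum(renew) - 1
        n_blocks = block_id[-1] + 1
        block_freq = rng.uniform(lo, hi, size=n_blocks)
        freqs = block_freq[block_id]

        for s in range(config.n_subpops):
            idx = np.where(subpop == s)[0]
            if config.fst > 0 and config.n_subpops > 1:
                # Balding-Nichols drift per frequency block (keeps adjacent
                # frequencies coherent within each subpopulation)
                a = block_freq * (1 - config.fst) / config.fst
                b = (1 - block_freq) * (1 - config.fst) / config.fst
                drifted = np.clip(rng.beta(np.maximum(a, 1e-3),
                                           np.maximum(b, 1e-3)), 0.005, 0.995)
                sub_freqs = drifted[block_id]
            else:
                sub_freqs = freqs
            H = _haplotypes(rng, 2 * len(idx), sub_freqs, pos,
                            config.ld_half_length)
            h1, h2 = H[::2], H[1::2]
            auto = rng.random(len(idx)) < config.inbreeding
            h2 = np.where(auto[:, None], h1, h2)
            dosage[idx, col: col + m] = (h1 + h2).astype(float)
        col += m

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    snp_ids = np.array([f"{c}_{q}" for c, q in zip(chroms, poss)], dtype=object)
    ref = np.full(p, "A", dtype=object)
    alt = np.full(p, "G", dtype=object)
    panel = GenotypePanel(
        sample_ids=np.array([f"G{i + 1:04d}" for i in range(n)], dtype=object),
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
    )
    return panel


def simulate_phenotypes(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[PhenotypeTable, dict]:
    """Simulate plot-level phenotype records over the trial design.

    Total plot-level variance decomposes as sigma2_g = h2 (QTL + polygenic),
    sigma2_int = gxe_sd², sigma2_e = 1 - h2, plus fixed environment and
    block effects; heritability in the literal variance-ratio sense equals
    h2 / (h2 + (1 - h2)) = h2.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = panel.n_samples
    sigma2_g = config.h2
    sigma2_e = 1.0 - config.h2

    # planted QTL
    causal_idx: list[int] = []
    effects: list[float] = []
    g = np.zeros(n)
    qtl_var = 0.0
    for q in config.qtl:
        if q.snp == "random":
            while True:
                j = int(rng.integers(panel.n_snps))
                x = panel.dosage[:, j]
                if j not in causal_idx and np.nanvar(x) > 1e-8:
                    break
        else:
            j = int(q.snp)
        x = np.nan_to_num(panel.dosage[:, j], nan=float(np.nanmean(panel.dosage[:, j])))
        vx = x.var()
        if vx < 1e-12:
            raise ValueError(f"QTL SNP {panel.snp_ids[j]} is monomorphic")
        beta = np.sqrt(q.variance_share / vx)
        causal_idx.append(j)
        effects.append(float(beta))
        g = g + beta * (x - x.mean())
        qtl_var += q.variance_share
    poly_var = sigma2_g - qtl_var
    if poly_var > 1e-12:
        g = g + rng.normal(0.0, np.sqrt(poly_var), size=n)

    envs = [f"E{e + 1}" for e in range(config.n_envs)]
    env_eff = rng.normal(0.0, config.env_effect_sd, size=config.n_envs)
    rows = []
    for e, env in enumerate(envs):
        loc = f"L{e % 2 + 1}"
        year = f"Y{2018 + e // 2}"
        gxe = (rng.normal(0.0, config.gxe_sd, size=n)
               if config.gxe_sd > 0 else np.zeros(n))
        for b in range(config.n_blocks):
            blk_eff = rng.normal(0.0, config.block_sd)
            eps = rng.normal(0.0, np.sqrt(sigma2_e), size=n)
            vals = env_eff[e] + blk_eff + g + gxe + eps
            for i in range(n):
                rows.append((panel.sample_ids[i], loc, year, f"B{b + 1}",
                             config.trait_name, vals[i]))
    table = PhenotypeTable(records=pd.DataFrame(
        rows, columns=["sample_id", "location", "year", "block", "trait", "value"]))
    truth = {
        "causal_snp_ids": [str(panel.snp_ids[j]) for j in causal_idx],
        "causal_idx": causal_idx,
        "causal_effects": effects,
        "true_components": {
            "sigma2_g": sigma2_g,
            "sigma2_int": config.gxe_sd ** 2,
            "sigma2_e": sigma2_e,
            "h2": config.h2,
        },
        "genetic_values": g,
    }
    return table, truth


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Genotypes + phenotypes + truth in one call."""
    panel = simulate_genotypes(config)
    phenos, truth = simulate_phenotypes(panel, config)
    return SimulatedPanel(
        panel=panel,
        phenotypes=phenos,
        causal_snp_ids=truth["causal_snp_ids"],
        causal_effects=truth["causal_effects"],
        true_components=truth["true_components"],
        genetic_values=truth["genetic_values"],
    )


def simulate_null_panel(config: SimulationConfig) -> SimulatedPanel:
    """A panel whose phenotype is null at the marker level: no planted QTL.

    The polygenic remainder is drawn independently of the simulated
    markers, so any ``h2`` with an empty QTL list is a global null for
    per-SNP association while keeping the BLUP phenotype non-degenerate
    (with ``h2 = 0`` REML shrinks every BLUP to zero and there is nothing
    to scan).  The reference object for threshold and type-I calibration.
    """
    if config.qtl:
        raise ValueError("null panel must have an empty QTL list")
    sim = simulate_panel(config)
    sim.true_components["null"] = True
    return sim
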