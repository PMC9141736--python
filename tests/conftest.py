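import numpy as np
import pytest

from mlgwas.io_formats import GenotypePanel


@pytest.fixture
def tiny_panel() -> GenotypePanel:
    """3 samples x 5 SNPs on 2 chromosomes, one missing call."""
    dosage = np.array([
        [0, 1, 2, 0, 1],
        [1, 2, 0, np.nan, 0],
        [2, 0, 1, 2, 2],
    ], dtype=float)
    return GenotypePanel(
        sample_ids=["S1", "S2", "S3"],
        snp_ids=[f"snp{i}" for i in range(1, 6)],
        chrom=["Chr01", "Chr01", "Chr01", "Chr02", "Chr02"],
        pos=[100, 2000, 35000, 500, 8000],
        ref_allele=["A", "C", "G", "T", "A"],
        alt_allele=["G", "T", "A", "C", "C"],
        dosage=dosage,
    )


def make_random_panel(n: int, p: int, seed: int = 0,
                      missing_rate: float = 0.0) -> GenotypePanel:
    """Unstructured random panel (independent SNPs) for oracle tests."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.5, size=p)
    dosage = rng.binomial(2, freqs, size=(n, p)).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=p, replace=False))
    return GenotypePanel(
        sample_ids=[f"I{i:03d}" for i in range(n)],
        snp_ids=[f"m{j}" for j in range(p)],
        chrom=["Chr01"] * p,
        pos=pos,
        ref_allele=["A"] * p,
        alt_allele=["G"] * p,
        dosage=dosage,
    )
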