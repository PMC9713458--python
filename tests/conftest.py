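import numpy as np
import pandas as pd
import pytest

from xqtl.io_formats import FounderPanel, GeneticMap, PooledSample
from xqtl.synthetic_data import ChromSpec, SimConfig


@pytest.fixture
def uniform_map():
    """One 10 Mb chromosome at 2 cM/Mb: bp 1 -> 0 cM, bp 1e7 -> ~20 cM."""
    return GeneticMap({"chr1": (np.array([1.0, 10_000_000.0]), np.array([0.0, 19.999998]))})


@pytest.fixture
def tiny_config():
    return SimConfig(
        chromosomes=[ChromSpec("chr1", 5_000_000, 2.0)],
        snp_density=60,
        cohort_size=80,
        pool_size_selected=30,
        pool_size_control=30,
        coverage=40,
        n_replicates=2,
        step_cm=0.5,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_panel(n_snps=20, founders=("f1", "f2"), chrom="chr1", length_bp=10_000_000, alleles=None, rng=None):
    """Small deterministic founder panel on a uniform 2 cM/Mb chromosome."""
    pos = np.linspace(1, length_bp, n_snps).round().astype(int)
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"})
    df["cM"] = (pos - 1) / 1e6 * 2.0
    if alleles is None:
        rng = rng or np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(n_snps, len(founders)))
        # force polymorphism
        mono = (alleles.sum(1) == 0) | (alleles.sum(1) == len(founders))
        alleles[mono, 0] = 1 - alleles[mono, 0]
    for j, f in enumerate(founders):
        df[f] = np.asarray(alleles)[:, j].astype(float)
    return FounderPanel(df, list(founders))


def make_sample(panel, ref_freq, depth=50, sample_id="s1", replicate=1, sex="F", treatment="control", rng=None):
    """Pool whose observed counts realize (or exactly equal) a REF frequency."""
    n = panel.n_snps
    q = np.broadcast_to(np.asarray(ref_freq, float), (n,))
    d = np.full(n, depth)
    if rng is None:
        ref = np.round(q * d).astype(int)
    else:
        ref = rng.binomial(d, q)
    counts = pd.DataFrame(
        {
            "chrom": panel.table["chrom"].to_numpy(),
            "pos": panel.table["pos"].to_numpy(),
            "ref_count": ref,
            "alt_count": d - ref,
        }
    )
    return PooledSample(sample_id, replicate, sex, treatment, counts)
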