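import numpy as np
import pandas as pd
import pytest

import methylsex as mx
from methylsex.simulate import CohortSpec, EffectSpec


@pytest.fixture(scope="session")
def small_layout():
    """3 chromosomes x 30 kb, 3-gene SDR panel on chr3."""
    return mx.build_genome(
        n_chrom=3,
        chrom_length=30_000,
        cytosine_density=24.0,
        genes_per_chrom=2,
        sdr_panel_size=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_effects(small_layout):
    return mx.default_effects(small_layout, n_weak_background=2, seed=12)


@pytest.fixture(scope="session")
def small_cohort(small_layout, small_effects):
    """12 samples (3 F + 3 M genotypes x 2 sites) with the planted gene."""
    cohort = CohortSpec(n_female=3, n_male=3, seed=13)
    return mx.simulate_cohort(small_layout, cohort, small_effects)


@pytest.fixture(scope="session")
def small_annotation(small_layout):
    return mx.GeneAnnotation(small_layout.genes)


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    return [mx.filter_coverage(s) for s in small_cohort]


@pytest.fixture()
def toy_sample():
    """Hand-built 4-call sample spanning all contexts and both strands."""
    calls = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [10, 11, 50, 7],
            "strand": ["+", "-", "+", "-"],
            "context": ["CG", "CG", "CHG", "CHH"],
            "meth": [7, 2, 0, 5],
            "unmeth": [3, 8, 12, 0],
        }
    )
    return mx.MethylomeSample("toy", calls, sex="F", genotype="g1", site="PA")


def planted_matrix(n_per_class=10, p_noise=30, delta=2.0, seed=0, n_signal=1):
    """Feature matrix with `n_signal` class-separated features among noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array(["F"] * n_per_class + ["M"] * n_per_class)
    X = rng.normal(0, 1, size=(n, p_noise + n_signal))
    for j in range(n_signal):
        X[:, j] += np.where(y == "M", delta / 2, -delta / 2)
    X = 1 / (1 + np.exp(-X))  # keep values in [0, 1]
    cols = [f"chr1:{(j + 1) * 500}-{(j + 2) * 500}" for j in range(n_signal)] + [
        f"chr2:{(j + 1) * 500}-{(j + 2) * 500}" for j in range(p_noise)
    ]
    samples = [f"s{i:02d}" for i in range(n)]
    values = pd.DataFrame(X, index=samples, columns=cols)
    tiles = pd.DataFrame(
        {
            "chrom": [c.split(":")[0] for c in cols],
            "start": [int(c.split(":")[1].split("-")[0]) for c in cols],
            "end": [int(c.split("-")[1]) for c in cols],
        },
        index=pd.Index(cols, name="tile"),
    )
    return mx.FeatureMatrix(values, pd.Series(y, index=samples), tiles)


@pytest.fixture()
def signal_matrix():
    return planted_matrix()
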