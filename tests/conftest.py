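import numpy as np
import pandas as pd
import pytest

from contrastdep.de import SampleDesign, run_contrast
from contrastdep.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard seeded recovery dataset: 10k genes, 20% dependent, 5% independent."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast dataset for smoke-level checks."""
    return generate_dataset(SimulationConfig(n_genes=400, seed=3))


def run_both_contrasts(ds, norm_method="cpm_log2", **kwargs):
    groups = dict(zip(ds.metadata["sample_id"], ds.metadata["group"]))
    res = {}
    for name, contrast in (("A", ("koA", "controlA")), ("B", ("koB", "controlB"))):
        design = SampleDesign(groups=groups, contrast=contrast)
        res[name] = run_contrast(ds.counts, design, norm_method=norm_method, **kwargs)
    return res


def toy_counts():
    """A tiny deterministic count matrix with two groups of three samples."""
    rng = np.random.default_rng(99)
    counts = pd.DataFrame(
        rng.poisson(50, size=(20, 6)),
        index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        columns=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    groups = {f"s{i}": ("ko" if i < 3 else "ctrl") for i in range(6)}
    return counts, SampleDesign(groups=groups, contrast=("ko", "ctrl"))
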