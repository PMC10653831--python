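import numpy as np
import pandas as pd
import pytest

from damdiff.methylation import MethylationTable


def make_table(coverage: np.ndarray, methylated: np.ndarray, samples=None) -> MethylationTable:
    """Build a small table from dense arrays (rows = adenines)."""
    n, m = np.asarray(coverage).shape
    samples = samples or [f"s{j+1}" for j in range(m)]
    idx = pd.MultiIndex.from_tuples(
        [("chr", 10 * i, "+" if i % 2 == 0 else "-") for i in range(n)],
        names=["chrom", "pos", "strand"],
    )
    cov = pd.DataFrame(np.asarray(coverage, float), index=idx, columns=samples)
    met = pd.DataFrame(np.asarray(methylated, float), index=idx, columns=samples)
    return MethylationTable(cov, met)


@pytest.fixture
def small_genome():
    """300 bp circular sequence with a handful of GATC sites."""
    from damdiff.simulate import simulate_genome

    return simulate_genome(300, gc=0.5, seed=11)
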