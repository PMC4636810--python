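import numpy as np
import pytest

from crossase.ase import SnpCountData
from crossase.design import CrossDesign


@pytest.fixture
def design() -> CrossDesign:
    return CrossDesign(seed=11)


@pytest.fixture
def sample_map(design):
    return design.sample_table()


def make_snp_data(per_site, samples, quals=None, missing=None):
    """Build a SnpCountData from explicit per-site DP4 tuples.

    ``per_site`` is a list of dicts mapping sample name -> (rf, rr, af, ar);
    omitted samples get zero counts and a missing flag.
    """
    n, s = len(per_site), len(samples)
    dp4 = np.zeros((n, s, 4), dtype=int)
    miss = np.ones((n, s), dtype=bool)
    qual = np.full((n, s), 99.0)
    for i, site in enumerate(per_site):
        for j, name in enumerate(samples):
            if name in site:
                dp4[i, j] = site[name]
                miss[i, j] = False
    if quals is not None:
        qual = np.asarray(quals, dtype=float)
    if missing is not None:
        miss = np.asarray(missing, dtype=bool)
    return SnpCountData(
        chrom=np.array([f"chr{i + 1}" for i in range(n)], dtype=object),
        pos=np.arange(1, n + 1) * 100,
        ref=np.array(["A"] * n, dtype="<U1"),
        alt=np.array(["G"] * n, dtype="<U1"),
        samples=list(samples),
        dp4=dp4,
        qual=qual,
        missing=miss,
        gene_id=np.array([f"gene{i}" for i in range(n)], dtype=object),
    )
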