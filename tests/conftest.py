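import numpy as np
import pandas as pd
import pytest

from pedtrace.io import GenotypeMatrix


def make_gm(calls, samples=None, chrom="chr1", spacing=100):
    """GenotypeMatrix from a (samples x sites) array of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": np.arange(1, n_sites + 1) * spacing,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    })
    return GenotypeMatrix(samples, sites, calls)


@pytest.fixture(scope="session")
def small_sim():
    """One default-structure pedigree at reduced genome scale, shared read-only."""
    from pedtrace.simulate import default_backcross_spec, run_pedigree

    spec = default_backcross_spec(seed=42, n_chrom=2, chrom_length_bp=1_000_000)
    return run_pedigree(spec)
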