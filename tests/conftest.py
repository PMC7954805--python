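import numpy as np
import pandas as pd
import pytest

import bridgehead as bh


def make_matrix(calls, samples=None, chrom="1", kind="variant"):
    """GenotypeMatrix from a raw dosage array (samples x sites)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 * (np.arange(n_sites) + 1),
            "ref": "A",
            "alt": "T",
            "kind": kind,
            "n_alt": 1,
        }
    )
    return bh.GenotypeMatrix(list(samples), sites, calls)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small six-deme sampling design for fast simulations."""
    return bh.SampleConfig(
        haploids={"ALE": 10, "AKBC": 14, "COAST": 8, "NORTH": 12, "SOUTH": 10, "UK": 24},
        n_snps=120,
    )


@pytest.fixture(scope="session")
def informative_params():
    """A fixed, informative 2-wave truth: AKBC founding + NORTH pulse."""
    return bh.ScenarioParams(
        ne={
            "ALE": 2000.0,
            "AKBC": 2000.0,
            "COAST": 2000.0,
            "NORTH": 2000.0,
            "SOUTH": 2000.0,
            "UK": 1000.0,
            "ANC": 5000.0,
        },
        t0a=100.0,
        wave_times=(50.0,),
        wave_props=(0.3,),
        splits={"t1": 2000.0, "t2": 4000.0, "t3": 8000.0, "t4": 6000.0, "t5": 3000.0},
    )


@pytest.fixture(scope="session")
def two_wave_truth():
    return bh.Scenario("TRUTH", "AKBC", ("NORTH",))
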