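import numpy as np
import pandas as pd
import pytest

from ancestra import GenotypeMatrix, SimScenario, run_scenario


def make_matrix(dosage, chrom=None, pos=None, groups=None, ids=None):
    """Small GenotypeMatrix from a plain array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    idx = ids if ids is not None else [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(index=pd.Index(idx, name="sample_id"))
    if groups is not None:
        samples["group"] = groups
    return GenotypeMatrix(dosage=dosage, variants=variants, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """One desk-scale neutral simulation shared across tests."""
    scen = SimScenario.test_scale(h2=0.5, omega=None, selection_mode="none", seed=42)
    return run_scenario(scen)


@pytest.fixture(scope="session")
def shifted_sim():
    """Desk-scale simulation with an optimum shift in the EEF branch."""
    scen = SimScenario.test_scale(
        h2=0.5, omega=1.0, shift_ancestry="EEF", shift=1.0, seed=7
    )
    return run_scenario(scen)
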