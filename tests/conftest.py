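import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from signburden.genotypes import DosageMatrix, SamplePanel
from signburden.simulate import SimConfig, emit_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(dosage, samples=None, variants=None, chrom=None, pos=None, source=None):
    """Convenience constructor for small hand-built dosage matrices."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return DosageMatrix(
        samples=samples or [f"S{i}" for i in range(n)],
        variants=variants or [f"rs{j}" for j in range(m)],
        dosage=dosage,
        source=source or ["GT"] * m,
        chrom=chrom or ["1"] * m,
        pos=pos or list(range(100, 100 + 100 * m, 100)),
    )


def make_panel(assignments):
    """assignments: list of (sample, pop, super_pop)."""
    import pandas as pd

    return SamplePanel(pd.DataFrame(assignments, columns=["sample", "pop", "super_pop"]))


@pytest.fixture(scope="session")
def sim_selected(tmp_path_factory):
    """Simulated dataset with a clear selection signal (delta=1.0)."""
    out = emit_dataset(
        SimConfig(n_variants=40, n_per_pop=120, fst=0.15, delta=1.0, seed=11),
        tmp_path_factory.mktemp("sim_sel"),
    )
    return out


@pytest.fixture(scope="session")
def sim_neutral(tmp_path_factory):
    """Neutral simulated dataset (delta=0)."""
    out = emit_dataset(
        SimConfig(n_variants=40, n_per_pop=120, fst=0.15, delta=0.0, seed=5),
        tmp_path_factory.mktemp("sim_neu"),
    )
    return out
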