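import numpy as np
import pytest

from protnorm import AbundanceMatrix, GroupSpec, SimulationConfig, StudyDesign


@pytest.fixture
def tiny_matrix():
    """3 proteins × 2 samples, raw scale, values 1..6."""
    return AbundanceMatrix(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        scale="raw",
        protein_ids=("p1", "p2", "p3"),
        sample_ids=("s1", "s2"),
    )


@pytest.fixture
def two_group_design():
    return StudyDesign(
        groups={"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
    )


def make_log2_matrix(values, prefix="p"):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        values=values,
        scale="log2",
        protein_ids=tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        sample_ids=tuple(f"s{j}" for j in range(values.shape[1])),
    )


@pytest.fixture
def small_spikein_config():
    """Cheap 3-group spike-in dataset for pipeline tests."""
    return SimulationConfig(
        n_background=200,
        n_spike=8,
        groups=(
            GroupSpec(label="low", concentration=2.0),
            GroupSpec(label="mid", concentration=4.0),
            GroupSpec(label="high", concentration=10.0),
        ),
        noise_sd_log2=0.15,
        zero_rate=0.003,
        seed=17,
    )
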