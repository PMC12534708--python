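import numpy as np
import pandas as pd
import pytest

from methylcode.io import BetaMatrix, ProbeManifest, SampleSheet
from methylcode.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_bm() -> BetaMatrix:
    data = pd.DataFrame(
        {
            "s1": [0.1, 0.5, 0.9],
            "s2": [0.2, np.nan, 0.8],
        },
        index=["cgA", "cgB", "cgC"],
    )
    return BetaMatrix(data)


@pytest.fixture
def replicate_manifest() -> ProbeManifest:
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": ["g1_A", "g1_B", "g2_A", "g2_B", "g3"],
                "chrom": "chr1",
                "start": [0, 0, 100, 100, 200],
                "end": [2, 2, 102, 102, 202],
                "replicate_prefix": ["g1", "g1", "g2", "g2", "g3"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort: 800 probes, 30 samples, 3 tissues."""
    cfg = SimulationConfig(
        n_probes=800, n_celltypes=3, n_samples=30, n_markers_per_type=10, seed=42
    )
    return simulate_cohort(cfg)
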