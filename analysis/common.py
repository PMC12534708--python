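"""Shared study conditions for the analysis scripts.

Every script regenerates the same synthetic cohort deterministically from
COHORT_SEED, so each driver can run standalone while all of them agree on
the data and its ground truth.
"""

from pathlib import Path

from methylcode.simulate import SimulationConfig, simulate_cohort

COHORT_SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_CONFIG = SimulationConfig(
    n_probes=4000,
    n_celltypes=5,
    n_samples=40,
    n_markers_per_type=20,
    marker_delta=0.4,
    noise_sd=0.5,
    seed=COHORT_SEED,
)


def get_cohort():
    """(5modC BetaMatrix, 5hmC BetaMatrix, SampleSheet, GroundTruth)."""
    return simulate_cohort(COHORT_CONFIG)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
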