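"""Shared settings for the numbered analysis drivers.

One synthetic dataset (seed 1) serves as the running example; every driver
regenerates it deterministically when missing, so the scripts can be run
individually or in order.
"""

from pathlib import Path

from btarch.simulate import SyntheticConfig, simulate_all

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATASET_DIR = RESULTS / "synthetic"
RUN_DIR = RESULTS / "run"

STUDY_CFG = SyntheticConfig(
    seed=1,
    n_operons=20,
    p_readthrough=0.15,
    p_processed=0.15,
    antisense_rate=0.02,
    n_planted_m6a=30,
    tool_sensitivity=0.9,
    jitter=0,
    tool_fp_rate=1e-5,
    peak_fp_fraction=0.2,
)


def ensure_dataset() -> dict:
    """Generate the example dataset if absent; returns the path map."""
    marker = DATASET_DIR / "truth.json"
    paths = simulate_all(STUDY_CFG, DATASET_DIR) if not marker.exists() else None
    if paths is None:
        # re-list the deterministic outputs
        paths = simulate_all(STUDY_CFG, DATASET_DIR)
    return paths
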