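"""Shared configuration for the numbered analysis scripts.

The cohort is a desk-scale synthetic stand-in with the study's structure:
two groups (controls scanned once, two stroke therapy arms scanned at T1,
T2, T3), lateralized ROI atlas, ~35% high-motion frames in patients,
hypo/hyper aberrant connection sets and a motor-arm pre-to-post shift on
the contralesional indices.  Volumes land under scratch/ (bulky, binary);
the tables the scripts derive land under results/.
"""

from pathlib import Path

from strokeconn import synthdata as sd
from strokeconn.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
COHORT_DIR = SCRATCH / "cohort"
DERIVED_DIR = SCRATCH / "derived"

SEED = 2024

HYPO = [(0, 1, -0.8), (2, 3, -0.8), (5, 7, -0.8), (4, 6, -0.8)]
HYPER = [(9, 11, 0.8), (8, 10, 0.8), (13, 15, 0.8)]


def cohort_config() -> sd.CohortConfig:
    return sd.CohortConfig(
        n_controls=8,
        n_stroke_sensorimotor=6,
        n_stroke_motor=6,
        n_rois=20,
        n_frames=250,
        grid_shape=(16, 16, 16),
        n_sessions=3,
        hypo_connections=list(HYPO),
        hyper_connections=list(HYPER),
        noise_sd=0.5,
        treatment_effects={
            "sensorimotor": {"T2": {}, "T3": {}},
            "motor": {"T2": {"contra_hypo": 0.3, "contra_hyper": 0.3}, "T3": {}},
        },
        seed=SEED,
    )


def run_config() -> RunConfig:
    return RunConfig(
        input_dir=str(COHORT_DIR),
        output_dir=str(DERIVED_DIR),
        seed=SEED,
    )
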