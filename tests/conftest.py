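"""Shared fixtures: a small synthetic demo cohort run end-to-end once."""

from __future__ import annotations

import numpy as np
import pytest

from strokeconn import synthdata as sd
from strokeconn.pipeline import RunConfig, run_pipeline

# planted aberrant connections for the demo cohort (canonical positions:
# even = left = contralesional, odd = right = ipsilesional)
DEMO_HYPO = [(0, 1, -0.8), (2, 3, -0.8), (5, 7, -0.8), (4, 6, -0.8)]
DEMO_HYPER = [(9, 11, 0.8), (8, 10, 0.8), (13, 15, 0.8)]
DEMO_TREATMENT = {
    "sensorimotor": {"T2": {}, "T3": {}},
    "motor": {"T2": {"contra_hypo": 0.3, "contra_hyper": 0.3}, "T3": {}},
}


def demo_config(seed: int = 42) -> sd.CohortConfig:
    return sd.CohortConfig(
        n_controls=6,
        n_stroke_sensorimotor=5,
        n_stroke_motor=5,
        n_rois=20,
        n_frames=200,
        grid_shape=(16, 16, 16),
        n_sessions=3,
        hypo_connections=list(DEMO_HYPO),
        hyper_connections=list(DEMO_HYPER),
        noise_sd=0.5,
        treatment_effects=DEMO_TREATMENT,
        seed=seed,
    )


@pytest.fixture(scope="session")
def demo_cohort(tmp_path_factory):
    root = tmp_path_factory.mktemp("demo_cohort")
    cfg = demo_config()
    truth = sd.generate_cohort(cfg, root / "in")
    return {"root": root, "config": cfg, "truth": truth, "input_dir": root / "in"}


@pytest.fixture(scope="session")
def demo_run(demo_cohort):
    rc = RunConfig(
        input_dir=str(demo_cohort["input_dir"]),
        output_dir=str(demo_cohort["root"] / "out"),
        seed=42,
    )
    results = run_pipeline(rc)
    out = dict(demo_cohort)
    out["cohort_config"] = demo_cohort["config"]
    out.update({"config": rc, "results": results})
    return out
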