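#!/usr/bin/env python
"""Generate the synthetic cohort all later scripts analyse.

Writes per-subject BOLD volumes, realignment tables, lesion masks, the toy
atlas and the phenotype table to scratch/analysis/cohort, plus the
ground-truth manifest that records what was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, RESULTS, cohort_config

from strokeconn import synthdata as sd


def main() -> None:
    cfg = cohort_config()
    truth = sd.generate_cohort(cfg, COHORT_DIR)
    n_stroke = sum(1 for s in truth.subjects if s.group == "stroke")
    n_ctrl = len(truth.subjects) - n_stroke
    print(f"cohort written to {COHORT_DIR}")
    print(f"  {n_ctrl} controls (1 session), {n_stroke} stroke patients (3 sessions)")
    print(f"  planted hypo connections: {truth.hypo_connections}")
    print(f"  planted hyper connections: {truth.hyper_connections}")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ground_truth.json").write_text(
        (COHORT_DIR / "ground_truth.json").read_text()
    )


if __name__ == "__main__":
    main()
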