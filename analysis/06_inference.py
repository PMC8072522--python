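#!/usr/bin/env python
"""Treatment effects and brain-behaviour associations.

Mixed model per index and session contrast with treatment arm as the
between-group factor (age and session-averaged mean FD as nuisance
regressors, Bonferroni threshold 0.05/18 ~ 0.003), plus Spearman partial
correlations of T1->T2 index changes with behavioural change scores.
"""

import json
import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, run_config

from strokeconn.pipeline import stage_infer


def main() -> None:
    cfg = run_config()
    results = stage_infer(cfg)
    te = results["treatment_effects"]
    print("treatment effects (sensorimotor - motor change, Fisher z):")
    cols = ["index_name", "contrast", "estimate", "se", "p", "significant", "method"]
    print(te[cols].round(3).to_string(index=False))
    thr = results["bonferroni"]
    print(f"Bonferroni-corrected threshold: {thr.raw:.5f} (rounded {thr.rounded})")
    bb = results["brain_behaviour"]
    if len(bb):
        print("brain-behaviour partial Spearman correlations (T1->T2):")
        print(bb.round(3).to_string(index=False))
    RESULTS.mkdir(exist_ok=True)
    for name in ("treatment_effects.tsv", "brain_behaviour.tsv"):
        shutil.copy(Path(cfg.output_dir) / name, RESULTS / name)
    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "bonferroni_threshold": thr.raw,
        "bonferroni_threshold_rounded": thr.rounded,
    }
    (RESULTS / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
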