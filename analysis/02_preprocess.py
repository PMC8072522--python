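#!/usr/bin/env python
"""Motion scrubbing, aCompCor + band-pass denoising, lesion-masked ROI extraction.

For every subject-session: frame-wise displacement and global %BOLD change
are computed from the realignment table and BOLD volume, frames exceeding
0.5 mm FD or 50 d%BOLD are censored, confounds (6 motion parameters, spike
indicators, 5 WM + 5 CSF aCompCor components) are regressed out, the
residuals are band-passed to 0.009-0.08 Hz, and mean time series are
extracted per lesion-masked ROI.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DERIVED_DIR, RESULTS, run_config

from strokeconn.pipeline import stage_preprocess


def main() -> None:
    cfg = run_config()
    stage_preprocess(cfg)
    motion_dir = Path(cfg.output_dir) / "motion"
    rows = []
    for path in sorted(motion_dir.glob("*.tsv")):
        df = pd.read_csv(path, sep="\t")
        sid, ses = path.stem.rsplit("_", 1)
        rows.append(
            dict(
                subject_id=sid,
                session=ses,
                mean_fd=df["fd"].mean(),
                censored_fraction=df["censored"].mean(),
            )
        )
    summary = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "motion_summary.tsv", sep="\t", index=False)
    by_group = summary.assign(group=summary.subject_id.str.startswith("strk"))
    stats = by_group.groupby("group")[["mean_fd", "censored_fraction"]].mean()
    print("preprocessing complete; motion summary:")
    print(stats.rename(index={False: "control", True: "stroke"}).round(3).to_string())
    print(f"denoised ROI series under {DERIVED_DIR / 'roiseries'}")


if __name__ == "__main__":
    main()
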