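#!/usr/bin/env python
"""Fisher-z ROI-to-ROI connectivity matrices over uncensored frames."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DERIVED_DIR, run_config

from strokeconn.pipeline import stage_connectivity


def main() -> None:
    cfg = run_config()
    stage_connectivity(cfg)
    mats = sorted((Path(cfg.output_dir) / "matrices").glob("*.tsv"))
    zs = []
    for path in mats:
        z = pd.read_csv(path, sep="\t", index_col="roi").to_numpy()
        zs.append(np.nanmean(z))
    print(f"{len(mats)} connectivity matrices written under {DERIVED_DIR / 'matrices'}")
    print(f"grand mean off-diagonal Fisher z: {np.mean(zs):.3f}")


if __name__ == "__main__":
    main()
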