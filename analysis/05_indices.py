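#!/usr/bin/env python
"""Six hemispheric connectivity indices per stroke subject per session."""

import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, run_config

from strokeconn.pipeline import stage_indices


def main() -> None:
    cfg = run_config()
    table = stage_indices(cfg)
    wide = table.pivot_table(index="index_name", columns="session", values="value")
    print("session means per index (Fisher z):")
    print(wide.round(3).to_string())
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(Path(cfg.output_dir) / "indices.tsv", RESULTS / "indices.tsv")
    print(f"index table written to {RESULTS / 'indices.tsv'}")


if __name__ == "__main__":
    main()
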