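#!/usr/bin/env python
"""Select aberrant connections: baseline stroke vs control contrast.

Connection-wise regression of Fisher-z values on group with mean FD as
nuisance regressor, seed-level FDR at two-sided p = 0.01, then hypo/hyper
classification by compartment (interhemispheric, ipsilesional and
contralesional intrahemispheric, after homologue-flip orientation).
"""

import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, run_config

from strokeconn.pipeline import stage_select


def main() -> None:
    cfg = run_config()
    conn = stage_select(cfg)
    counts = conn.counts()
    print(f"{len(conn)} connections-of-interest selected")
    for (cls, comp), n in sorted(counts.items()):
        if n:
            print(f"  {cls:5s} {comp:12s}: {n}")
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(Path(cfg.output_dir) / "connections.tsv", RESULTS / "connections.tsv")
    print(f"table written to {RESULTS / 'connections.tsv'}")


if __name__ == "__main__":
    main()
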