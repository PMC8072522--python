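#!/usr/bin/env python
"""Calibration of the statistical machinery under the study conditions.

Null calibration of seed-level FDR selection, recovery of planted
aberrant connections, treatment-effect parameter recovery / type-I error,
and the deterministic signal-processing contracts.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from strokeconn import experiments as ex


def main() -> None:
    out = {
        "null_selection": ex.null_selection_calibration(seed=SEED),
        "planted_recovery": ex.planted_recovery(seed=SEED),
        "treatment_recovery": ex.treatment_effect_recovery(seed=SEED),
        "treatment_type_i": ex.treatment_effect_type_i(seed=SEED),
        "signal_contracts": ex.signal_processing_contracts(),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "calibration.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    print(json.dumps(out, indent=1, sort_keys=True))
    print(f"written to {RESULTS / 'calibration.json'}")


if __name__ == "__main__":
    main()
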