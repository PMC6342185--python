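"""Generate the study-scale synthetic dataset (diet, biomass, ground truth)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from paths import SEED, SIM_DIR

from ppmr.cli import run

if __name__ == "__main__":
    sys.exit(run([
        "simulate", "--seed", str(SEED), "--out", str(SIM_DIR),
    ]))
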