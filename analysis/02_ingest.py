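"""Preprocess the raw diet records into analysis-ready stomachs."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from paths import INGEST_DIR, SIM_DIR

from ppmr.cli import run

if __name__ == "__main__":
    sys.exit(run([
        "ingest", "--input", str(SIM_DIR / "diet_raw.csv"),
        "--out", str(INGEST_DIR),
    ]))
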