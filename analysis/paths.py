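"""Shared locations for the analysis scripts.

Large intermediates (raw simulated data, cleaned records, posterior draws)
live under ``scratch/``; small summary tables meant to be read go to
``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SIM_DIR = SCRATCH / "sim"
INGEST_DIR = SCRATCH / "ingest"
GROUPS_CSV = SCRATCH / "groups.csv"
FIT_DIR = {"R_bio": SCRATCH / "fit_rbio", "R_num": SCRATCH / "fit_rnum"}

SEED = 20180915
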