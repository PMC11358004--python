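#!/usr/bin/env python
"""Build the analysis workspace: simulated condition pair + cohort table.

Writes a seeded "standard" and "RA-like" xenograft dataset sharing one
human cell-type reference (the RA condition carries five planted 4-fold
marker shifts), the reference profiles, the per-subject cohort table and a
ready-to-run pipeline config under results/workspace/.
"""

import sys
from pathlib import Path

from xenospot.pipeline import make_demo

ROOT = Path(__file__).resolve().parents[1]
WORKSPACE = ROOT / "scratch" / "workspace"


def build(seed: int = 0) -> Path:
    info = make_demo(WORKSPACE, seed=seed)
    print(f"workspace ready under {WORKSPACE}")
    for name, paths in info["inputs"].items():
        print(f"  {name}: {paths['matrix']}")
    return WORKSPACE


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    build(seed)
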