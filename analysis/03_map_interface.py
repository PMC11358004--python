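#!/usr/bin/env python
"""Graft-host interface mapping.

Marks pig spots lying within the 20 nearest neighbours of a human spot and
closer than 1,500 px as interfaced (human-like), and reports the spot
partition per condition.
"""

from pathlib import Path

import pandas as pd

from xenospot import (
    InterfaceConfig,
    annotate_interfaced,
    find_interfaced_spots,
    interface_summary,
    write_labels,
)
from xenospot.io import SpotLabelTable, read_positions

ROOT = Path(__file__).resolve().parents[1]
WORKSPACE = ROOT / "scratch" / "workspace"
OUT = ROOT / "results"


def main():
    rows = []
    for name in ("standard", "RA"):
        labels_path = OUT / f"labels_{name}.csv"
        if not labels_path.exists():
            raise SystemExit("run analysis/02_classify_species.py first")
        labels = SpotLabelTable(pd.read_csv(labels_path).set_index("barcode"))
        positions = read_positions(WORKSPACE / name / "tissue_positions.csv")
        interfaced = find_interfaced_spots(positions, labels, InterfaceConfig())
        annotated = annotate_interfaced(labels, interfaced)
        write_labels(annotated, OUT / f"labels_{name}.csv")
        rep = interface_summary(annotated, interfaced)
        rep["condition"] = name
        rows.append(rep)
        print(f"{name}: {rep['n_human']} human / {rep['n_interfaced']} interfaced / "
              f"{rep['n_pure_pig']} pure pig spots")
    pd.DataFrame(rows).to_csv(OUT / "interface_summary.csv", index=False)


if __name__ == "__main__":
    main()
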