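"""Graft-host interface detection.

A pig spot is *interfaced* (human-like) when it lies among the k nearest
neighbours of at least one human spot and within a pixel-distance cap of
that spot.  Such spots form the neighbourhood where graft-host cellular
interactions (e.g. paracrine signalling) can occur.

Neighbour search is exact; ties in distance are broken by barcode order so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpotLabelTable


@dataclass
class InterfaceConfig:
    """k nearest neighbours within d_max full-resolution pixels (strict <).

    ``neighbor_pool`` decides whether human spots can occupy neighbour
    slots ("all_spots", default) or only pig spots compete ("pig_only").
    """

    k: int = 20
    d_max: float = 1500.0
    neighbor_pool: str = "all_spots"

    def validate(self) -> "InterfaceConfig":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if self.neighbor_pool not in {"all_spots", "pig_only"}:
            raise ValueError("neighbor_pool must be 'all_spots' or 'pig_only'")
        return self


def find_interfaced_spots(
    positions: pd.DataFrame,
    labels: SpotLabelTable,
    config: InterfaceConfig | None = None,
) -> set[str]:
    """Barcodes of pig spots interfaced with the human graft.

    For every human spot, its k nearest neighbours (Euclidean pixel
    distance, self excluded, ties by barcode order) are searched within the
    configured pool; pig spots among them closer than d_max are interfaced.
    """
    config = (config or InterfaceConfig()).validate()
    barcodes = labels.barcodes
    missing = [b for b in barcodes if b not in positions.index]
    if missing:
        raise ValueError(f"labelled spots without coordinates: {missing[:5]}")
    lab = labels.table["label"].to_numpy()
    xy = positions.loc[barcodes, ["x_px", "y_px"]].to_numpy(float)
    human_idx = np.flatnonzero(lab == "human")
    pig_mask = lab == "pig"
    if len(human_idx) == 0:
        raise ValueError("nothing to interface: no human spots")

    if config.neighbor_pool == "pig_only":
        pool_idx = np.flatnonzero(pig_mask)
    else:
        pool_idx = np.arange(len(barcodes))

    interfaced: set[str] = set()
    for hi in human_idx:
        cand = pool_idx[pool_idx != hi]
        if len(cand) == 0:
            continue
        d = np.linalg.norm(xy[cand] - xy[hi], axis=1)
        # ties broken by barcode position: lexsort minor key first
        order = np.lexsort((cand, d))
        nearest = cand[order[: config.k]]
        near_d = d[order[: config.k]]
        for j, dj in zip(nearest, near_d):
            if pig_mask[j] and dj < config.d_max:
                interfaced.add(barcodes[j])
    return interfaced


def interface_summary(labels: SpotLabelTable, interfaced: set[str]) -> dict:
    """Spot counts by class; interfaced spots are a subset of pig spots."""
    lab = labels.table["label"]
    pig = set(lab.index[lab == "pig"])
    stray = interfaced - pig
    if stray:
        raise ValueError(f"interfaced spots that are not pig spots: {sorted(stray)[:5]}")
    n_human = int((lab == "human").sum())
    n_excluded = int((lab == "excluded").sum())
    n_interfaced = len(interfaced)
    n_pure_pig = len(pig) - n_interfaced
    return {
        "n_human": n_human,
        "n_pure_pig": n_pure_pig,
        "n_interfaced": n_interfaced,
        "n_excluded": n_excluded,
        "n_spots": n_human + n_pure_pig + n_interfaced + n_excluded,
    }


def annotate_interfaced(labels: SpotLabelTable, interfaced: set[str]) -> SpotLabelTable:
    """Return a copy of the label table with an ``interfaced`` flag column."""
    table = labels.table.copy()
    table["interfaced"] = [b in interfaced for b in table.index]
    return SpotLabelTable(table)
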