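"""Species-of-origin spot classification for dual-species spatial data.

Each spot gets a *human score* (total reads on human-tagged genes) and a
*pig score* (total reads on pig-tagged genes).  A spot is called human when
its human score strictly exceeds ``tau_h`` (default 30) and its pig score is
strictly below a sample-specific ``tau_p``, optionally requiring a minimum
number of detected human genes.  ``suggest_pig_threshold`` makes the
density-based threshold choice reproducible: it places ``tau_p`` at the
deepest valley between the two dominant modes of the pig-score distribution
on the log scale.  ``species_pca_check`` reports how cleanly the labels
separate spots in expression space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import SpotDataset, SpotLabelTable

logger = logging.getLogger(__name__)


@dataclass
class SpeciesThresholds:
    """Score cutoffs; both inequalities are strict (h > tau_h, p < tau_p)."""

    tau_h: float = 30.0
    tau_p: float = 700.0

    def validate(self) -> "SpeciesThresholds":
        if self.tau_h < 0 or self.tau_p <= 0:
            raise ValueError("tau_h must be >= 0 and tau_p > 0")
        return self


@dataclass
class QCConfig:
    """Gene/spot quality-control settings.

    ``apply_to="human_candidates"`` restricts the detected-human-genes floor
    to spots competing for the human label (spots failing it fall back to
    pig); ``"all_spots"`` instead marks any spot below the floor as
    excluded, regardless of its scores.
    """

    min_human_genes_per_human_spot: int = 80
    min_spots_per_gene: int = 10
    apply_to: str = "human_candidates"

    def validate(self) -> "QCConfig":
        if self.min_human_genes_per_human_spot < 0 or self.min_spots_per_gene < 0:
            raise ValueError("QC thresholds must be non-negative")
        if self.apply_to not in {"human_candidates", "all_spots"}:
            raise ValueError("apply_to must be 'human_candidates' or 'all_spots'")
        return self


def compute_species_scores(dataset: SpotDataset) -> pd.DataFrame:
    """Per-spot human/pig read totals and detected-gene counts.

    The two scores partition each spot's total retained counts.
    """
    human = dataset.species_mask("human")
    pig = dataset.species_mask("pig")
    counts = dataset.counts.tocsc()
    h = np.asarray(counts[human].sum(axis=0)).ravel()
    p = np.asarray(counts[pig].sum(axis=0)).ravel()
    detected = counts.copy()
    detected.data = (detected.data > 0).astype(np.int64)
    n_h = np.asarray(detected[human].sum(axis=0)).ravel()
    n_p = np.asarray(detected[pig].sum(axis=0)).ravel()
    return pd.DataFrame(
        {
            "h": h.astype(np.int64),
            "p": p.astype(np.int64),
            "n_human_genes_detected": n_h.astype(np.int64),
            "n_pig_genes_detected": n_p.astype(np.int64),
        },
        index=pd.Index(dataset.barcodes, name="barcode"),
    )


def apply_gene_qc(dataset: SpotDataset, qc: QCConfig) -> SpotDataset:
    """Drop genes detected in fewer than ``min_spots_per_gene`` spots.

    Removal is species-agnostic; the per-species removal counts are logged.
    """
    qc.validate()
    detected_in = np.asarray((dataset.counts > 0).sum(axis=1)).ravel()
    keep = detected_in >= qc.min_spots_per_gene
    if not keep.any():
        raise ValueError("gene QC removed every gene")
    removed = dataset.features.loc[~keep, "species"].value_counts()
    logger.info(
        "gene QC: removed %d human and %d pig genes (threshold %d spots)",
        int(removed.get("human", 0)),
        int(removed.get("pig", 0)),
        qc.min_spots_per_gene,
    )
    return dataset.subset_genes(keep)


def classify_spots(
    scores: pd.DataFrame,
    thresholds: SpeciesThresholds | None = None,
    qc: QCConfig | None = None,
) -> SpotLabelTable:
    """Label spots human/pig from their species scores.

    human  iff  h > tau_h  and  p < tau_p  (strict), and — under
    ``apply_to="human_candidates"`` — at least
    ``min_human_genes_per_human_spot`` human genes detected.
    """
    thresholds = (thresholds or SpeciesThresholds()).validate()
    qc = (qc or QCConfig()).validate()
    h = scores["h"].to_numpy()
    p = scores["p"].to_numpy()
    n_hg = scores["n_human_genes_detected"].to_numpy()
    passes_scores = (h > thresholds.tau_h) & (p < thresholds.tau_p)
    passes_floor = n_hg >= qc.min_human_genes_per_human_spot
    if qc.apply_to == "human_candidates":
        label = np.where(passes_scores & passes_floor, "human", "pig")
    else:  # all_spots: the floor is a global QC gate
        label = np.where(passes_scores, "human", "pig")
        label = np.where(passes_floor, label, "excluded")
    table = scores.copy()
    table["label"] = label
    return SpotLabelTable(table)


def suggest_pig_threshold(
    scores: pd.DataFrame,
    bw_method: str = "silverman",
    grid_size: int = 512,
) -> float | None:
    """Data-driven ``tau_p`` from the pig-score density on the log scale.

    Fits a Gaussian KDE to log10(1 + p) over all spots and returns the
    antilog of the deepest local minimum between the two largest density
    modes.  Returns None when the density is unimodal (the caller must then
    supply a threshold).
    """
    p = scores["p"].to_numpy(float)
    if len(p) < 50:
        raise ValueError("insufficient spots for density estimation (need >= 50)")
    logp = np.log10(1.0 + p)
    kde = gaussian_kde(logp, bw_method=bw_method)
    grid = np.linspace(logp.min(), logp.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    if len(maxima) < 2:
        return None
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top_two)
    between = minima[(minima > lo) & (minima < hi)]
    if len(between) == 0:
        return None
    valley = between[np.argmin(dens[between])]
    return float(10.0 ** grid[valley] - 1.0)


def species_pca_check(
    dataset: SpotDataset,
    labels: SpotLabelTable,
    n_components: int = 2,
    scale_per_spot: float = 1e4,
) -> dict:
    """PCA separation report for the human/pig labelling.

    Counts are library-size normalised (counts per ``scale_per_spot``),
    log1p-transformed and projected on the leading principal components;
    the silhouette coefficient of the labelling on those coordinates
    quantifies separation.
    """
    lab = labels.table.loc[dataset.barcodes, "label"].to_numpy()
    used = np.isin(lab, ["human", "pig"])
    for species in ("human", "pig"):
        if (lab == species).sum() < 2:
            raise ValueError(f"need at least 2 spots labelled {species}")
    mat = dataset.counts.tocsc()[:, used].T.toarray().astype(float)  # spots x genes
    totals = mat.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    expr = np.log1p(mat / totals * scale_per_spot)
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(expr)
    sil = float(silhouette_score(coords, lab[used]))
    return {
        "coords": pd.DataFrame(
            coords,
            index=np.array(dataset.barcodes)[used],
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        "silhouette": sil,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }
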