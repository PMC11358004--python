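"""Reference-based cell-type decomposition of spots.

Each graft (human) spot contains roughly 1-9 cells, so its counts are a
mixture over cell types.  Given reference profiles ``pi`` (one probability
vector over genes per type), the spot's counts are modelled as multinomial
with gene probabilities ``sum_k w_k pi_kg`` and the weight vector ``w`` on
the simplex is estimated by maximum likelihood via EM (multiplicative
updates).  This is the Poisson/multinomial core of reference-based
deconvolution, without platform-effect or doublet terms: with a matched
reference those terms are unidentifiable and unnecessary.

The predominant type of a spot is the argmax weight.  An independent,
reference-free k-means clustering of the same spots provides a consistency
check, scored by the adjusted Rand index after optimally coarse-graining
the predominant types to the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import SpotDataset, SpotLabelTable
from .simulate import ReferenceProfiles

_PROB_FLOOR = 1e-12


@dataclass
class DeconvolutionResult:
    """Weights for one spot with fit diagnostics."""

    weights: np.ndarray
    cell_types: list[str]
    log_likelihood: float
    predominant_type: str
    converged: bool
    iterations: int
    objective_path: np.ndarray | None = None


def fit_spot_weights(
    y: np.ndarray,
    profiles: ReferenceProfiles,
    tol: float = 1e-6,
    max_iter: int = 500,
    track_objective: bool = False,
) -> DeconvolutionResult:
    """Maximum-likelihood mixture weights for a single spot.

    Maximises sum_g y_g log(sum_k w_k pi_kg) over the simplex by EM:
        w_k <- w_k * sum_g (y_g / N) * pi_kg / (sum_j w_j pi_jg)
    starting from uniform weights.  The objective is concave in w along the
    EM path and never decreases; iteration stops when max|dw| < tol.
    """
    profiles.validate()
    y = np.asarray(y, dtype=float)
    k, g = profiles.pi.shape
    if y.shape != (g,):
        raise ValueError(f"y has length {y.shape}, profiles have {g} genes")
    n = y.sum()
    if n <= 0:
        raise ValueError("empty spot: no counts to decompose")
    if k == 1:
        pi0 = np.clip(profiles.pi[0], _PROB_FLOOR, None)
        ll = float(y @ np.log(pi0))
        return DeconvolutionResult(
            np.array([1.0]), list(profiles.cell_types), ll, profiles.cell_types[0], True, 0
        )

    # drop genes unexplained by every profile, floor the rest
    pi = np.clip(profiles.pi, 0.0, None)
    usable = pi.sum(axis=0) > 0
    pi = np.clip(pi[:, usable], _PROB_FLOOR, None)
    yy = y[usable]

    w = np.full(k, 1.0 / k)
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = w @ pi  # length G
        if track_objective:
            path.append(float(yy @ np.log(mix)))
        w_new = w * (pi @ (yy / mix)) / yy.sum()
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    ll = float(yy @ np.log(w @ pi))
    if track_objective:
        path.append(ll)
    pred = profiles.cell_types[int(np.argmax(w))]
    return DeconvolutionResult(
        w, list(profiles.cell_types), ll, pred, converged, it,
        np.array(path) if track_objective else None,
    )


def deconvolve(
    dataset: SpotDataset,
    labels: SpotLabelTable,
    profiles: ReferenceProfiles,
    include_interfaced: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Fit weights for every human spot (optionally interfaced spots too).

    Returns a frame indexed by barcode with one weight column per cell
    type plus ``predominant_type``, ``log_likelihood``, ``converged`` and
    ``iterations``.  Pig-only spots are skipped.
    """
    profiles.validate()
    lab = labels.table
    select = lab["label"] == "human"
    if include_interfaced and "interfaced" in lab.columns:
        select |= lab["interfaced"].fillna(False).astype(bool)
    spots = [b for b in dataset.barcodes if b in lab.index[select]]
    if not spots:
        raise ValueError("no human spots to deconvolve")

    name_to_row = {n: i for i, n in enumerate(dataset.features["feature_name"])}
    missing = [g for g in profiles.genes if g not in name_to_row]
    if missing:
        raise ValueError(f"profile genes absent from dataset: {missing[:5]}")
    gene_rows = np.array([name_to_row[g] for g in profiles.genes])
    col_of = {b: j for j, b in enumerate(dataset.barcodes)}
    sub = dataset.counts.tocsc()[:, [col_of[b] for b in spots]][gene_rows].toarray()

    records = []
    for j, barcode in enumerate(spots):
        res = fit_spot_weights(sub[:, j], profiles, tol=tol, max_iter=max_iter)
        rec = dict(zip(profiles.cell_types, res.weights))
        rec.update(
            barcode=barcode,
            predominant_type=res.predominant_type,
            log_likelihood=res.log_likelihood,
            converged=res.converged,
            iterations=res.iterations,
        )
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("barcode")
    return out


def cluster_spots(
    dataset: SpotDataset,
    spots: list[str],
    n_clusters: int,
    seed: int = 0,
    scale_per_spot: float = 1e4,
) -> pd.Series:
    """Reference-free k-means grouping of spots into 2-3 broad categories.

    Operates on log1p library-size-normalised counts over all genes; the
    seed fixes the k-means initialisation.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if len(spots) < n_clusters:
        raise ValueError(f"{len(spots)} spots cannot form {n_clusters} clusters")
    col_of = {b: j for j, b in enumerate(dataset.barcodes)}
    mat = dataset.counts.tocsc()[:, [col_of[b] for b in spots]].T.toarray().astype(float)
    totals = mat.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    expr = np.log1p(mat / totals * scale_per_spot)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return pd.Series(km.fit_predict(expr), index=pd.Index(spots, name="barcode"), name="cluster")


def consistency_check(
    predominant_types: pd.Series,
    cluster_labels: pd.Series,
    max_exhaustive_types: int = 8,
) -> dict:
    """Agreement between deconvolution calls and reference-free clusters.

    Coarse-grains the K predominant types into as many groups as there are
    clusters — exhaustively over all type->group assignments for K <= 8,
    greedily beyond — and reports the best adjusted Rand index together
    with the grouping that achieved it.
    """
    common = predominant_types.index.intersection(cluster_labels.index)
    if len(common) == 0:
        raise ValueError("no common spots")
    types = predominant_types.loc[common].to_numpy()
    clusters = cluster_labels.loc[common].to_numpy()
    type_names = sorted(set(types))
    n_groups = len(set(clusters))
    k = len(type_names)

    def ari_of(assignment: dict[str, int]) -> float:
        grouped = np.array([assignment[t] for t in types])
        return adjusted_rand_score(clusters, grouped)

    if k <= n_groups:
        best_map = {t: i for i, t in enumerate(type_names)}
        best = ari_of(best_map)
    elif k <= max_exhaustive_types:
        best, best_map = -np.inf, None
        for combo in product(range(n_groups), repeat=k):
            assignment = dict(zip(type_names, combo))
            score = ari_of(assignment)
            if score > best:
                best, best_map = score, assignment
    else:  # greedy: seed with the most frequent types, place the rest
        order = pd.Series(types).value_counts().index.tolist()
        best_map = {t: i for i, t in enumerate(order[:n_groups])}
        for t in order[n_groups:]:
            scores = []
            for grp in range(n_groups):
                trial = dict(best_map)
                trial[t] = grp
                full = {u: trial.get(u, 0) for u in type_names}
                scores.append(ari_of(full))
            best_map[t] = int(np.argmax(scores))
        best_map = {u: best_map.get(u, 0) for u in type_names}
        best = ari_of(best_map)
    return {"ari": float(best), "grouping": best_map, "n_spots": int(len(common))}
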