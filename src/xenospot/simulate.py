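"""Synthetic dual-species spatial datasets and cohorts with known ground truth.

The generator emulates the structure of a xenograft ("barnyard") spatial
gene-expression experiment: a hexagonal spot array over host (pig)
myocardium containing an embedded human graft region.  Each spot has a true
human read fraction ``f_h`` given by a logistic function of its distance to
the graft boundary, a true cell-type weight vector on the simplex, and
negative-binomial counts over a hybrid human+pig gene panel.  Cross-species
bleed-through (homolog mis-mapping) is modelled by binomial thinning:
a fraction of each gene's reads is re-assigned to its homolog-paired gene
of the other species, conserving per-spot totals.

The cohort generator emulates a cell-therapy cohort in which arrhythmia
burden (hours/day) is linearly linked to the percentage of an arrhythmogenic
cardiomyocyte subpopulation (CD200+) in the cell dose, with the remaining
flow-cytometry subpopulations drawn from a scaled Dirichlet.

``load_table1_fixture`` returns the packaged per-subject cohort table used
by the correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .io import SpotDataset, read_cohort_table

DEFAULT_CELL_TYPES = {
    "ventricular_CM": 0.55,
    "atrial_pacemaker_CM": 0.15,
    "fibroblast": 0.20,
    "endothelial": 0.10,
}


@dataclass
class XenoSimConfig:
    """Parameters of the xenograft spatial simulation.

    The defaults describe the study conditions exercised by the test
    suite: a 30 x 30 hexagonal array, 300 human + 300 pig genes, ~5,000
    UMIs per spot and a graft occupying a disk of radius 1,000 px.
    ``boundary_softness`` is the logistic transition width of the human
    fraction in pixels; the default (5 px, a small fraction of the spot
    pitch) encodes a graft boundary that is sharp at spot resolution, so
    nearly all spots are species-pure as in a barnyard design.  The default
    graft center sits slightly off the grid's symmetry axes — a graft never
    aligns with the capture array — which avoids degenerate ties in
    boundary distances.
    """

    grid_rows: int = 30
    grid_cols: int = 30
    spot_pitch_px: float = 250.0
    graft_center: tuple[float, float] | None = None  # array (row, col); None = grid center
    graft_radius_px: float = 1000.0
    n_human_genes: int = 300
    n_pig_genes: int = 300
    cell_types: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    celltype_concentration: float = 50.0
    depth_mean: float = 5000.0
    nb_dispersion: float = 0.05
    bleed_rate: float = 0.005
    boundary_softness: float = 5.0
    condition: str = "standard"
    de_planted: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> "XenoSimConfig":
        if min(self.grid_rows, self.grid_cols, self.n_human_genes, self.n_pig_genes) <= 0:
            raise ValueError("grid and gene-panel sizes must be positive")
        if self.spot_pitch_px <= 0 or self.graft_radius_px <= 0 or self.boundary_softness <= 0:
            raise ValueError("pitch, graft radius and boundary softness must be positive")
        if not (0 <= self.bleed_rate < 0.5):
            raise ValueError("bleed_rate must be in [0, 0.5)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        props = np.array(list(self.cell_types.values()), float)
        if len(props) < 1 or (props <= 0).any() or abs(props.sum() - 1) > 1e-8:
            raise ValueError("cell-type proportions must be positive and sum to 1")
        return self


@dataclass
class GroundTruth:
    """Per-spot and per-gene truth recorded by the simulator."""

    f_h: np.ndarray                 # true human read fraction per spot
    labels: np.ndarray              # "human" iff f_h > 0.5 else "pig"
    weights: pd.DataFrame           # spots x cell types, rows on the simplex
    gene_effects: pd.DataFrame      # gene, condition, log2fc of planted effects
    homolog_pairs: pd.DataFrame     # human_gene <-> pig_gene used for bleed-through


@dataclass
class ReferenceProfiles:
    """Cell-type x gene mean-expression profiles; rows sum to one."""

    cell_types: list[str]
    genes: list[str]
    pi: np.ndarray  # K x G

    def validate(self) -> "ReferenceProfiles":
        if self.pi.shape != (len(self.cell_types), len(self.genes)):
            raise ValueError("profile matrix shape does not match names")
        if len(self.cell_types) < 1:
            raise ValueError("need at least one cell type")
        if (self.pi < 0).any() or not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("profile rows must be probability vectors")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pi, index=self.cell_types, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceProfiles":
        return cls(list(df.index), list(df.columns), df.to_numpy(float)).validate()


@dataclass
class ProfileSimConfig:
    cell_types: list[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    n_genes: int = 300
    marker_genes_per_type: int = 20
    marker_boost: float = 8.0
    log_sigma: float = 1.0
    gene_prefix: str = "HGENE"
    seed: int = 0


def hexagonal_grid(rows: int, cols: int, pitch: float) -> pd.DataFrame:
    """Visium-like hexagonal offset grid (odd rows shifted by pitch/2).

    Returns a positions frame indexed by generated barcodes with array and
    full-resolution pixel coordinates; row spacing is pitch * sqrt(3)/2 so
    nearest-neighbour distances equal the pitch.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    x = cc * pitch + (rr % 2) * pitch / 2.0
    y = rr * pitch * np.sqrt(3) / 2.0
    barcodes = [f"SPOT-{r:03d}-{c:03d}" for r, c in zip(rr, cc)]
    return pd.DataFrame(
        {"in_tissue": 1, "array_row": rr, "array_col": cc, "x_px": x, "y_px": y},
        index=pd.Index(barcodes, name="barcode"),
    )


def simulate_reference_profiles(config: ProfileSimConfig) -> ReferenceProfiles:
    """Draw per-type expression profiles with disjoint marker blocks.

    Every gene gets a shared log-normal baseline; each cell type's marker
    block is boosted ``marker_boost``-fold, so marker genes stand well above
    their level in any other type.
    """
    k = len(config.cell_types)
    if k < 2:
        raise ValueError("need at least 2 cell types")
    if config.marker_genes_per_type * k > config.n_genes:
        raise ValueError("marker blocks exceed the gene panel")
    rng = np.random.default_rng(config.seed)
    genes = [f"{config.gene_prefix}{i:04d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=config.log_sigma, size=config.n_genes)
    pi = np.tile(baseline, (k, 1))
    for t in range(k):
        lo = t * config.marker_genes_per_type
        pi[t, lo : lo + config.marker_genes_per_type] *= config.marker_boost
    pi /= pi.sum(axis=1, keepdims=True)
    return ReferenceProfiles(list(config.cell_types), genes, pi).validate()


def _pig_background(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    rho = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    return rho / rho.sum()


def simulate_xenograft_dataset(
    config: XenoSimConfig,
    profiles: ReferenceProfiles | None = None,
) -> tuple[SpotDataset, GroundTruth]:
    """Simulate one dual-species spatial dataset with recorded ground truth.

    Parameters
    ----------
    config : XenoSimConfig
    profiles : ReferenceProfiles, optional
        Human cell-type profiles to mix from.  If omitted they are drawn
        from the config seed; pass the same object to several calls to
        simulate conditions sharing a reference.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    positions = hexagonal_grid(config.grid_rows, config.grid_cols, config.spot_pitch_px)
    xy = positions[["x_px", "y_px"]].to_numpy()
    n_spots = len(positions)

    if config.graft_center is None:
        center_rc = ((config.grid_rows - 1) / 2.0 + 0.271, (config.grid_cols - 1) / 2.0 + 0.413)
    else:
        center_rc = config.graft_center
    # array coords -> plane point (the center need not be a spot)
    center_xy = np.array(
        [
            center_rc[1] * config.spot_pitch_px,
            center_rc[0] * config.spot_pitch_px * np.sqrt(3) / 2.0,
        ]
    )
    dist = np.linalg.norm(xy - center_xy, axis=1)
    if dist.min() > config.graft_radius_px:
        raise ValueError("graft disk does not intersect the spot grid")

    # logistic human fraction of distance to the graft boundary
    f_h = expit(-(dist - config.graft_radius_px) / config.boundary_softness)
    labels = np.where(f_h > 0.5, "human", "pig")

    if profiles is None:
        profiles = simulate_reference_profiles(
            ProfileSimConfig(
                cell_types=list(config.cell_types),
                n_genes=config.n_human_genes,
                seed=config.seed,
            )
        )
    if len(profiles.genes) != config.n_human_genes:
        raise ValueError("profiles gene panel does not match n_human_genes")

    props = np.array([config.cell_types[t] for t in profiles.cell_types], float)
    weights = rng.dirichlet(config.celltype_concentration * props, size=n_spots)

    rho = _pig_background(config.n_pig_genes, rng)
    pig_genes = [f"PGENE{i:04d}" for i in range(config.n_pig_genes)]

    # per-spot expected counts
    mu_h = (config.depth_mean * f_h)[:, None] * (weights @ profiles.pi)  # spots x Gh
    mu_p = (config.depth_mean * (1.0 - f_h))[:, None] * rho[None, :]     # spots x Gp

    effects = []
    human_gene_index = {g: i for i, g in enumerate(profiles.genes)}
    pig_gene_index = {g: i for i, g in enumerate(pig_genes)}
    for gene, cond, lfc in config.de_planted:
        effects.append({"gene": gene, "condition": cond, "log2fc": lfc})
        if cond != config.condition:
            continue
        if gene in human_gene_index:
            mu_h[:, human_gene_index[gene]] *= 2.0 ** lfc
        elif gene in pig_gene_index:
            mu_p[:, pig_gene_index[gene]] *= 2.0 ** lfc
        else:
            raise ValueError(f"planted DE gene {gene!r} not in the panel")

    def _nb(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion == 0:
            return rng.poisson(mu)
        # Gamma(shape=1/phi, scale=mu*phi) has mean mu and CV^2 = phi,
        # so Poisson-Gamma mixing gives NB with Var = mu + phi*mu^2.
        shape = 1.0 / config.nb_dispersion
        lam = np.zeros_like(mu)
        pos = mu > 0
        lam[pos] = rng.gamma(shape, mu[pos] * config.nb_dispersion)
        return rng.poisson(lam)

    counts_h = _nb(mu_h)  # spots x Gh
    counts_p = _nb(mu_p)  # spots x Gp

    # cross-species bleed-through: each gene is paired with a fixed homolog
    # of the other species (index pairing); a Binomial(count, eps) portion of
    # its reads is re-labelled to the partner, conserving spot totals.
    h2p = np.arange(config.n_human_genes) % config.n_pig_genes
    p2h = np.arange(config.n_pig_genes) % config.n_human_genes
    if config.bleed_rate > 0:
        moved_h = rng.binomial(counts_h, config.bleed_rate)
        moved_p = rng.binomial(counts_p, config.bleed_rate)
        map_h2p = sp.csr_matrix(
            (np.ones(config.n_human_genes), (np.arange(config.n_human_genes), h2p)),
            shape=(config.n_human_genes, config.n_pig_genes),
        )
        map_p2h = sp.csr_matrix(
            (np.ones(config.n_pig_genes), (np.arange(config.n_pig_genes), p2h)),
            shape=(config.n_pig_genes, config.n_human_genes),
        )
        counts_h = counts_h - moved_h + (moved_p @ map_p2h).astype(np.int64)
        counts_p = counts_p - moved_p + (moved_h @ map_h2p).astype(np.int64)

    features = pd.DataFrame(
        {
            "feature_id": [f"GRCh38_{g}" for g in profiles.genes]
            + [f"Sscrofa11-1_{g}" for g in pig_genes],
            "feature_name": list(profiles.genes) + list(pig_genes),
            "species": ["human"] * config.n_human_genes + ["pig"] * config.n_pig_genes,
        }
    )
    counts = sp.csr_matrix(np.vstack([counts_h.T, counts_p.T]).astype(np.int64))

    dataset = SpotDataset(
        counts=counts,
        features=features,
        barcodes=list(positions.index),
        positions=positions,
    ).validate()

    truth = GroundTruth(
        f_h=f_h,
        labels=labels,
        weights=pd.DataFrame(weights, index=positions.index, columns=profiles.cell_types),
        gene_effects=pd.DataFrame(effects, columns=["gene", "condition", "log2fc"]),
        homolog_pairs=pd.DataFrame(
            {"human_gene": profiles.genes, "pig_gene": [pig_genes[j] for j in h2p]}
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# cohort simulation

#: mean flow-composition (fractions of the cell dose) per simulated group;
#: chosen to resemble a standard ventricular-directed dose vs an
#: atrial/pacemaker-enriched (RA-treated) dose.
GROUP_COMPOSITION = {
    "PSC-CM": {
        "cm_cd200neg": 0.41,
        "cm_cd200pos": 0.15,
        "committed_vcm": 0.02,
        "mesoderm_cd13": 0.13,
        "fibroblast_cd90": 0.02,
        "endothelial": 0.01,
        "nonmyocyte_unspecified": 0.26,
    },
    "RA-PSC-CM": {
        "cm_cd200neg": 0.01,
        "cm_cd200pos": 0.47,
        "committed_vcm": 0.01,
        "mesoderm_cd13": 0.14,
        "fibroblast_cd90": 0.09,
        "endothelial": 0.005,
        "nonmyocyte_unspecified": 0.275,
    },
}


@dataclass
class CohortSimConfig:
    """Cohort with a tunable linear composition -> burden association.

    burden = max(0, a + b * cm_cd200pos_pct + Normal(0, sigma_c)).
    """

    n_subjects: dict[str, int] = field(default_factory=lambda: {"PSC-CM": 5, "RA-PSC-CM": 3})
    intercept_a: float = 1.0
    slope_b: float = 0.3
    noise_sd: float = 2.0
    dirichlet_concentration: float = 40.0
    seed: int = 0

    def validate(self) -> "CohortSimConfig":
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        unknown = set(self.n_subjects) - set(GROUP_COMPOSITION)
        if unknown:
            raise ValueError(f"no composition model for groups {sorted(unknown)}")
        return self


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table; truth records the linear-model parameters."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, n in config.n_subjects.items():
        comp_mean = GROUP_COMPOSITION[group]
        cols = list(comp_mean)
        alpha = config.dirichlet_concentration * np.array([comp_mean[c] for c in cols])
        for i in range(n):
            comp = rng.dirichlet(alpha) * 100.0
            row = {"subject_id": f"{group}{i + 1}", "group": group}
            row.update(dict(zip(cols, comp)))
            row["cm_sirpa_cd90neg"] = row["cm_cd200neg"] + row["cm_cd200pos"]
            burden_lin = (
                config.intercept_a
                + config.slope_b * row["cm_cd200pos"]
                + rng.normal(0.0, config.noise_sd)
            )
            row["burden_h_per_day"] = max(0.0, burden_lin)
            row["burden_untruncated"] = burden_lin
            rows.append(row)
    cohort = pd.DataFrame(rows)
    truth = {
        "intercept_a": config.intercept_a,
        "slope_b": config.slope_b,
        "noise_sd": config.noise_sd,
    }
    return cohort, truth


def load_table1_fixture() -> pd.DataFrame:
    """The packaged per-subject cohort table (16 cell-treated subjects).

    Values are transcribed verbatim, with "N/A" cells explicit as missing
    (the PSC-CM5 and PSC-CM+AA5 flow rows, several graft-size entries).
    Note the source table's PSC-CM "graft % of LV" summary row prints
    6.4 (0.8) while its per-subject entries (1.9, 3.8, 0.4, 0.3) average
    1.6; this fixture stores the per-subject values and computed summaries
    will reflect them.
    """
    with resources.files("xenospot.data").joinpath("table1_cohort.csv").open() as fh:
        return read_cohort_table(fh)
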