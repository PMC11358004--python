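"""Reading and writing of on-disk artifacts.

The pipeline's spatial input is the standard 10x/Visium triplet — a
MatrixMarket gene x spot count matrix, a features table and a barcodes
table — plus a ``tissue_positions`` CSV carrying per-spot array and
full-resolution pixel coordinates.  Because the counts come from a hybrid
human+pig reference, each feature carries a species tag derived from its
feature-ID prefix (e.g. ``GRCh38_`` for human, ``Sscrofa11-1_`` for pig).
Cohort data (per-subject arrhythmia burden and flow-cytometry subpopulation
percentages) are a plain CSV.

All result writers produce deterministic CSVs: stable column order, rows
sorted by barcode or gene, floats at 6 significant digits.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: feature-ID prefix -> species; hybrid-reference builders differ in the
#: separator they emit, so both dot and dash dialects are accepted.
DEFAULT_SPECIES_PREFIXES: dict[str, str] = {
    "GRCh38_": "human",
    "GRCh38-": "human",
    "Sscrofa11-1_": "pig",
    "Sscrofa11.1_": "pig",
    "Sscrofa11_": "pig",
}

COHORT_GROUPS = ("PSC-CM", "PSC-CM+AA", "PSC-CM+CA", "RA-PSC-CM", "vehicle", "vehicle+AA")

COHORT_PERCENT_COLUMNS = (
    "graft_pct_scar",
    "graft_pct_lv",
    "pre_freeze_ctnt_pct",
    "cm_sirpa_cd90neg",
    "cm_cd200neg",
    "cm_cd200pos",
    "committed_vcm",
    "mesoderm_cd13",
    "fibroblast_cd90",
    "endothelial",
    "nonmyocyte_unspecified",
)


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class ValidationError(ValueError):
    """Input parses but violates a domain invariant."""


@dataclass
class SpotDataset:
    """Sparse gene x spot counts with species tags and spot coordinates.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Non-negative integer matrix, genes x spots.
    features : pandas.DataFrame
        One row per gene: ``feature_id``, ``feature_name``,
        ``species`` in {"human", "pig"}.
    barcodes : list of str
        Spot identifiers, one per matrix column.
    positions : pandas.DataFrame
        Indexed by barcode: ``in_tissue``, ``array_row``, ``array_col``,
        ``x_px``, ``y_px`` (full-resolution pixels).
    """

    counts: sp.csr_matrix
    features: pd.DataFrame
    barcodes: list[str]
    positions: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def species_mask(self, species: str) -> np.ndarray:
        """Boolean mask over genes for one species tag."""
        return (self.features["species"] == species).to_numpy()

    def validate(self) -> "SpotDataset":
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise FormatError(
                f"count matrix is {self.counts.shape} but there are "
                f"{len(self.features)} features and {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        bad_species = set(self.features["species"]) - {"human", "pig"}
        if bad_species:
            raise ValidationError(f"unknown species tags: {sorted(bad_species)}")
        missing = [b for b in self.barcodes if b not in self.positions.index]
        if missing:
            raise ValidationError(f"barcodes without positions: {missing[:5]}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        xy = self.positions.loc[self.barcodes, ["x_px", "y_px"]].to_numpy(float)
        if not np.isfinite(xy).all() or (xy < 0).any():
            raise ValidationError("coordinates must be finite and non-negative")
        return self

    def subset_genes(self, mask: np.ndarray) -> "SpotDataset":
        return SpotDataset(
            counts=self.counts[mask].tocsr(),
            features=self.features.loc[mask].reset_index(drop=True),
            barcodes=list(self.barcodes),
            positions=self.positions,
        )

    def subset_spots(self, mask: np.ndarray) -> "SpotDataset":
        keep = [b for b, m in zip(self.barcodes, mask) if m]
        return SpotDataset(
            counts=self.counts[:, mask].tocsr(),
            features=self.features,
            barcodes=keep,
            positions=self.positions.loc[keep],
        )

    def xy(self) -> np.ndarray:
        """(n_spots, 2) pixel coordinates in barcode order."""
        return self.positions.loc[self.barcodes, ["x_px", "y_px"]].to_numpy(float)


@dataclass
class SpotLabelTable:
    """Per-spot species classification with the scores that produced it."""

    table: pd.DataFrame  # index barcode; columns h, p, label, optionally interfaced

    def __post_init__(self):
        allowed = {"human", "pig", "interfaced", "excluded"}
        bad = set(self.table["label"]) - allowed
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    def mask(self, label: str) -> np.ndarray:
        return (self.table["label"] == label).to_numpy()


def _open_maybe_gz(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_tsv(path: Path, n_min_cols: int) -> pd.DataFrame:
    with _open_maybe_gz(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.shape[1] < n_min_cols:
        raise FormatError(f"{path}: expected >= {n_min_cols} columns, found {df.shape[1]}")
    return df


def species_from_feature_ids(
    feature_ids: pd.Series, prefixes: dict[str, str] | None = None
) -> pd.Series:
    """Map feature IDs to species via their reference-genome prefix."""
    prefixes = prefixes or DEFAULT_SPECIES_PREFIXES
    # longest prefixes first so e.g. "Sscrofa11-1_" wins over "Sscrofa11_"
    ordered = sorted(prefixes.items(), key=lambda kv: -len(kv[0]))
    species = pd.Series(pd.NA, index=feature_ids.index, dtype=object)
    for prefix, sp_name in ordered:
        hit = feature_ids.str.startswith(prefix) & species.isna()
        species[hit] = sp_name
    if species.isna().any():
        offenders = feature_ids[species.isna()].head(5).tolist()
        raise ValidationError(f"features with unknown species prefix: {offenders}")
    return species


def read_positions(path: Path) -> pd.DataFrame:
    """Read a Visium tissue-positions CSV (headerless v1 or headered variant).

    Returns a frame indexed by barcode with in_tissue, array_row, array_col
    and full-resolution pixel coordinates mapped to (x_px, y_px) =
    (pxl_col_in_fullres, pxl_row_in_fullres).
    """
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(f"{path}: tissue positions must have 6 columns, found {df.shape[1]}")
    df.columns = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]
    out = pd.DataFrame(
        {
            "in_tissue": df["in_tissue"].to_numpy(int),
            "array_row": df["array_row"].to_numpy(int),
            "array_col": df["array_col"].to_numpy(int),
            "x_px": df["pxl_col"].to_numpy(float),
            "y_px": df["pxl_row"].to_numpy(float),
        },
        index=pd.Index(df["barcode"].astype(str).to_numpy(), name="barcode"),
    )
    return out


def read_spot_dataset(
    matrix_path,
    features_path,
    barcodes_path,
    positions_path,
    species_prefixes: dict[str, str] | None = None,
) -> SpotDataset:
    """Read the MatrixMarket triplet plus positions into a SpotDataset.

    Spots missing from the positions file or flagged out-of-tissue are
    dropped (with a logged count); fractional counts are rejected.
    """
    mat = scipy.io.mmread(matrix_path)
    dense_data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
    if dense_data.size and not np.allclose(dense_data, np.round(dense_data)):
        raise ValidationError(f"{matrix_path}: fractional counts are not allowed")
    counts = sp.csr_matrix(mat, dtype=np.int64)

    feat = _read_tsv(features_path, 2)
    features = pd.DataFrame(
        {
            "feature_id": feat.iloc[:, 0].astype(str),
            "feature_name": feat.iloc[:, 1].astype(str),
        }
    )
    features["species"] = species_from_feature_ids(features["feature_id"], species_prefixes)

    bc = _read_tsv(barcodes_path, 1)
    barcodes = bc.iloc[:, 0].astype(str).tolist()

    if counts.shape[0] != len(features):
        raise FormatError(
            f"{matrix_path}: {counts.shape[0]} rows but {features_path} has "
            f"{len(features)} features"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path}: {counts.shape[1]} columns but {barcodes_path} has "
            f"{len(barcodes)} barcodes"
        )

    positions = read_positions(positions_path)
    in_pos = np.array([b in positions.index for b in barcodes])
    keep = in_pos.copy()
    keep[in_pos] &= positions.loc[np.array(barcodes)[in_pos], "in_tissue"].to_numpy() == 1
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d spots without positions or out of tissue", n_drop)
    ds = SpotDataset(
        counts=counts[:, keep].tocsr(),
        features=features,
        barcodes=[b for b, k in zip(barcodes, keep) if k],
        positions=positions,
    )
    return ds.validate()


def write_spot_dataset(dataset: SpotDataset, out_dir) -> dict[str, Path]:
    """Write the triplet + positions for a dataset; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "positions": out_dir / "tissue_positions.csv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(dataset.counts), field="integer")
    dataset.features[["feature_id", "feature_name"]].assign(kind="Gene Expression").to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    pd.Series(dataset.barcodes).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    pos = dataset.positions.loc[dataset.barcodes]
    pd.DataFrame(
        {
            "barcode": pos.index,
            "in_tissue": pos["in_tissue"].astype(int),
            "array_row": pos["array_row"].astype(int),
            "array_col": pos["array_col"].astype(int),
            "pxl_row_in_fullres": pos["y_px"],
            "pxl_col_in_fullres": pos["x_px"],
        }
    ).to_csv(paths["positions"], header=True, index=False)
    return paths


def read_cohort_table(csv_path) -> pd.DataFrame:
    """Read a cohort CSV (per-subject cohort schema) with explicit missingness.

    "N/A" and empty cells become NaN; percentages outside [0, 100] or
    negative burden raise with the offending subject named.
    """
    df = pd.read_csv(csv_path, na_values=["N/A", "NA", ""], dtype={"subject_id": str})
    if df.empty:
        raise FormatError(f"{csv_path}: no rows")
    required = {"subject_id", "group", "burden_h_per_day"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{csv_path}: missing columns {sorted(missing_cols)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id: {dupes}")
    bad_groups = set(df["group"]) - set(COHORT_GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown groups: {sorted(bad_groups)}")
    if (df["burden_h_per_day"].dropna() < 0).any():
        bad = df.loc[df["burden_h_per_day"] < 0, "subject_id"].tolist()
        raise ValidationError(f"negative burden for subjects {bad}")
    for col in COHORT_PERCENT_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            out_of_range = vals[(vals < 0) | (vals > 100)]
            if len(out_of_range):
                rows = df.loc[out_of_range.index, "subject_id"].tolist()
                raise ValidationError(f"{col} outside [0, 100] for subjects {rows}")
    return df


def _write_result_csv(df: pd.DataFrame, path, sort_col: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.sort_values(sort_col, kind="mergesort") if len(df) else df
    out.to_csv(path, index=False, float_format="%.6g")
    return path


def write_labels(labels: SpotLabelTable, path) -> Path:
    df = labels.table.reset_index().rename(columns={"index": "barcode"})
    if "barcode" not in df.columns:  # index may already be named
        df = df.rename(columns={df.columns[0]: "barcode"})
    return _write_result_csv(df, path, "barcode")


def write_weights(weights: pd.DataFrame, path) -> Path:
    """Weights frame indexed by barcode, one column per cell type."""
    df = weights.reset_index()
    df = df.rename(columns={df.columns[0]: "barcode"})
    return _write_result_csv(df, path, "barcode")


def write_de_table(de_table: pd.DataFrame, path) -> Path:
    df = de_table.reset_index()
    df = df.rename(columns={df.columns[0]: "gene"})
    return _write_result_csv(df, path, "gene")
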