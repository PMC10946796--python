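"""Region-of-interest feature extraction, normalization and matrix filtering.

ROIs are labeled pixel sets: single-pixel sROIs for within-tissue
variation, 10-pixel lROIs (5 for small tissues) as the statistical
observations, and off-tissue "matrix" ROIs containing chemical-matrix
background only. The ROI x ion feature matrix is the input to every
downstream statistic.

The canonical processing order — extract -> TIC normalize -> matrix-ion
filter -> log2 — is enforced by the pipeline and recorded in provenance.
All standard deviations in this module are population SDs (ddof 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import BinnedImage

ROI_KINDS = ("sROI", "lROI", "matrix")
META_COLUMNS = ["roi_id", "tissue", "zone", "bone", "replicate", "kind",
                "sample", "genotype"]


@dataclass
class RoiSet:
    """Pixel memberships and labels for a set of ROIs.

    ``table`` has one row per (roi, pixel): columns ``roi_id, row, col,
    tissue, zone, bone, replicate, kind`` (zone/bone may be empty).
    """

    table: pd.DataFrame
    allowed_lroi_sizes: tuple[int, ...] = (5, 10)

    def __post_init__(self):
        required = ["roi_id", "row", "col", "tissue", "kind"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"RoiSet table missing columns {missing}")
        for col in ("zone", "bone", "replicate"):
            if col not in self.table.columns:
                self.table[col] = ""
        bad = set(self.table["kind"]) - set(ROI_KINDS)
        if bad:
            raise ValueError(f"unknown ROI kinds {sorted(bad)}")
        sizes = self.table.groupby("roi_id").size()
        kinds = self.table.groupby("roi_id")["kind"].first()
        for roi_id, size in sizes.items():
            kind = kinds[roi_id]
            if kind == "sROI" and size != 1:
                raise ValueError(f"sROI {roi_id!r} must have exactly 1 pixel, has {size}")
            if kind == "lROI" and size not in self.allowed_lroi_sizes:
                raise ValueError(
                    f"lROI {roi_id!r} has {size} pixels; allowed {self.allowed_lroi_sizes}"
                )
        mt = self.table[self.table["kind"] == "matrix"]
        if len(mt) and not mt["tissue"].isin(["off_tissue", "matrix"]).all():
            raise ValueError("matrix ROIs must contain only off-tissue pixels")

    @property
    def roi_ids(self) -> list[str]:
        return self.table["roi_id"].drop_duplicates().tolist()

    def meta(self) -> pd.DataFrame:
        """One row of labels per ROI, in first-appearance order."""
        return (
            self.table.groupby("roi_id", sort=False)
            .agg(tissue=("tissue", "first"), zone=("zone", "first"),
                 bone=("bone", "first"), replicate=("replicate", "first"),
                 kind=("kind", "first"))
            .reset_index()
        )

    def to_csv(self, path: str | Path) -> None:
        cols = ["roi_id", "row", "col", "tissue", "zone", "bone", "replicate", "kind"]
        self.table[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RoiSet":
        df = pd.read_csv(path, keep_default_na=False)
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        return cls(df, **kwargs)


@dataclass
class FeatureMatrix:
    """ROIs x binned-ion intensities with ROI metadata and a scale flag.

    ``values`` columns are target bin_ids; ``meta`` is row-aligned ROI
    metadata. ``scale`` is ``'linear'`` or ``'log2'``; ``excluded_ions``
    records ions dropped by filters together with the reason.
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    scale: str = "linear"
    excluded_ions: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")
        if len(self.meta) != len(self.values):
            raise ValueError("meta and values row counts differ")
        if self.scale == "linear" and len(self.values):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative linear intensities")

    @property
    def bin_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.meta.copy(), self.values.copy(), self.scale,
                             list(self.excluded_ions), list(self.provenance))

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta.reset_index(drop=True),
                         self.values.reset_index(drop=True)], axis=1)
        out.insert(0, "scale", self.scale)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, keep_default_na=False)
        scale = df.pop("scale").iloc[0] if "scale" in df.columns else "linear"
        meta_cols = [c for c in META_COLUMNS if c in df.columns]
        values = df.drop(columns=meta_cols).apply(pd.to_numeric)
        return cls(df[meta_cols], values, scale)


def extract_features(img: BinnedImage, rois: RoiSet) -> FeatureMatrix:
    """One row per ROI: the mean over the ROI's pixels of each target."""
    coord_index = {tuple(rc): i for i, rc in enumerate(img.coords)}
    rows = []
    for roi_id, grp in rois.table.groupby("roi_id", sort=False):
        idx = []
        for r, c in zip(grp["row"], grp["col"]):
            if (r, c) not in coord_index:
                raise ValueError(f"ROI {roi_id!r} references missing pixel ({r}, {c})")
            idx.append(coord_index[(r, c)])
        rows.append(img.matrix.iloc[idx].mean(axis=0))
    values = pd.DataFrame(rows).reset_index(drop=True)
    meta = rois.meta()
    meta["sample"] = img.metadata.get("sample", "")
    meta["genotype"] = img.metadata.get("genotype", "")
    prov = list(img.provenance) + [{"operation": "extract_features",
                                    "n_rois": len(meta)}]
    return FeatureMatrix(meta, values, "linear", provenance=prov)


def concat_features(fms: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack feature matrices from multiple samples (shared target list)."""
    cols = fms[0].bin_ids
    for fm in fms[1:]:
        if fm.bin_ids != cols:
            raise ValueError("feature matrices must share a target list")
        if fm.scale != fms[0].scale:
            raise ValueError("feature matrices must share a scale")
    meta = pd.concat([fm.meta for fm in fms], ignore_index=True)
    values = pd.concat([fm.values for fm in fms], ignore_index=True)
    prov = [rec for fm in fms for rec in fm.provenance]
    return FeatureMatrix(meta, values, fms[0].scale, provenance=prov)


def tic_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each ROI row by its total ion count so rows sum to 1.

    All-zero rows are left as zeros with a warning.
    """
    if fm.scale != "linear":
        raise ValueError("TIC normalization requires linear-scale data")
    out = fm.copy()
    totals = out.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero ROI rows left unnormalized")
        totals = totals.replace(0, 1.0)
    out.values = out.values.div(totals, axis=0)
    out.provenance.append({"operation": "tic_normalize",
                           "n_zero_rows": int(zero.sum())})
    return out


def standard_normalize(fm: FeatureMatrix, standard_bin: str) -> FeatureMatrix:
    """Divide each ROI row by its internal-standard ion intensity.

    The spiked deuterated standard is deposited uniformly with the
    chemical matrix, so its per-ROI intensity tracks acquisition scale
    without the compositional coupling TIC normalization introduces when
    effects are one-sided. Rows where the standard is 0 are left
    unchanged with a warning.
    """
    if fm.scale != "linear":
        raise ValueError("standard normalization requires linear-scale data")
    if standard_bin not in fm.values.columns:
        raise KeyError(f"standard bin {standard_bin!r} not among ion columns")
    out = fm.copy()
    ref = out.values[standard_bin]
    zero = ref == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} ROIs with zero standard intensity left unnormalized"
        )
    out.values = out.values.div(ref.where(~zero, 1.0), axis=0)
    out.provenance.append({"operation": "standard_normalize",
                           "standard_bin": standard_bin,
                           "n_zero_rows": int(zero.sum())})
    return out


def matrix_ion_filter(fm: FeatureMatrix, n_sd: float = 2.0) -> FeatureMatrix:
    """Exclude chemical-matrix background ions.

    For each ion, mean and population SD are computed across the matrix
    (off-tissue) ROIs and across ALL tissue ROIs pooled; the ion is
    excluded iff ``mean_matrix - n_sd*SD_matrix > mean_tissue +
    n_sd*SD_tissue``. Both intervals are logged for every dropped ion.
    Requires at least 2 ROIs on each side so the SD is defined.
    """
    is_matrix = fm.meta["kind"] == "matrix"
    n_m, n_t = int(is_matrix.sum()), int((~is_matrix).sum())
    if n_m < 2 or n_t < 2:
        raise ValueError(
            f"matrix filter needs >=2 matrix and >=2 tissue ROIs, got {n_m}/{n_t}"
        )
    vm = fm.values[is_matrix.to_numpy()]
    vt = fm.values[~is_matrix.to_numpy()]
    m_lo = vm.mean(axis=0) - n_sd * vm.std(axis=0, ddof=0)
    t_hi = vt.mean(axis=0) + n_sd * vt.std(axis=0, ddof=0)
    drop = m_lo > t_hi
    out = fm.copy()
    for bin_id in out.values.columns[drop]:
        out.excluded_ions.append({
            "bin_id": bin_id,
            "reason": "matrix_ion",
            "matrix_lower": float(m_lo[bin_id]),
            "tissue_upper": float(t_hi[bin_id]),
        })
    out.values = out.values.loc[:, ~drop]
    out.provenance.append({"operation": "matrix_ion_filter",
                           "n_excluded": int(drop.sum()), "n_sd": n_sd})
    return out


def log_scale(fm: FeatureMatrix, pseudocount: float = 1.0,
              prescale: float = 1.0) -> FeatureMatrix:
    """Replace values by ``log2(prescale*value + pseudocount)``.

    ``prescale`` rescales TIC-normalized fractions (which are << 1) back
    to a count-like range before the pseudocount is added; the pipeline
    default is 1e4.
    """
    if fm.scale != "linear":
        raise ValueError("log_scale requires linear-scale data")
    if len(fm.values) and (fm.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-scaled")
    out = fm.copy()
    out.values = np.log2(prescale * out.values + pseudocount)
    out.scale = "log2"
    out.provenance.append({"operation": "log_scale",
                           "pseudocount": pseudocount, "prescale": prescale})
    return out


def zscore_columns(fm: FeatureMatrix) -> FeatureMatrix:
    """Center each ion column and divide by its population SD.

    Zero-variance columns become all zeros with a warning; a single-row
    matrix is an error.
    """
    if len(fm.values) < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    out = fm.copy()
    mean = out.values.mean(axis=0)
    sd = out.values.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance columns set to 0")
    centered = out.values - mean
    out.values = centered.div(sd.where(~zero, 1.0), axis=1)
    out.values.loc[:, zero] = 0.0
    out.provenance.append({"operation": "zscore_columns",
                           "n_zero_variance": int(zero.sum())})
    return out
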