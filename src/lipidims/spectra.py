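"""Pixel-resolved peak data: containers, reduction, binning, lock mass, IO.

The raw imaging object is a :class:`PixelSpectrumSet`: one centroided MS1
peak list per ablation pixel on a rectangular grid, held in long form
(pixel index, m/z, optional drift time, intensity). Drift time is carried
as opaque metadata and never interpreted beyond bin labels.

Processing mirrors a standard imaging-MS workflow: per-pixel noise
reduction (intensity threshold then top-N), construction of a shared
target list by binning all observed peaks (half-open bins, origin 0,
left-closed; the declared dialect of this package), re-binning every
pixel against the shared targets, and per-sample multiplicative lock-mass
correction against a spiked internal standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["pixel", "mz", "drift", "intensity"]


@dataclass
class PixelSpectrumSet:
    """Grid-indexed peak lists for one acquired sample.

    Parameters
    ----------
    coords : (n_pixels, 2) int array of (row, col), unique, row-major order.
    peaks : long-form DataFrame with columns ``pixel`` (index into coords),
        ``mz``, ``drift`` (NaN when ion mobility disabled) and ``intensity``,
        sorted by (pixel, mz).
    metadata : free-form sample metadata (sample id, genotype, tag).
    """

    coords: np.ndarray
    peaks: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2) row/col pairs")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peaks missing columns {missing}")
        if len(self.peaks):
            if (self.peaks["intensity"].to_numpy() < 0).any():
                raise ValueError("negative intensities")
            if (self.peaks["mz"].to_numpy() <= 0).any():
                raise ValueError("non-positive m/z")
        self.peaks = (
            self.peaks[PEAK_COLUMNS]
            .sort_values(["pixel", "mz"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def pixel_peaks(self, pixel: int) -> pd.DataFrame:
        return self.peaks[self.peaks["pixel"] == pixel]


@dataclass
class TargetList:
    """Shared ion targets: one (m/z center, drift center) per non-empty bin."""

    targets: pd.DataFrame  # columns: bin_id, mz_center, drift_center

    def __post_init__(self):
        t = self.targets
        if t["bin_id"].duplicated().any():
            raise ValueError("bin_ids must be unique")
        for _, grp in t.groupby("drift_center", dropna=False):
            mz = grp["mz_center"].to_numpy()
            if not (np.diff(mz) > 0).all():
                raise ValueError("mz_centers must be strictly increasing per drift bin")
        self.targets = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def bin_ids(self) -> list[str]:
        return self.targets["bin_id"].tolist()


@dataclass
class BinnedImage:
    """Pixels x targets intensity matrix with processing provenance."""

    coords: np.ndarray
    matrix: pd.DataFrame  # index: pixel ordinal, columns: bin_ids
    target_list: TargetList
    provenance: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.matrix.columns) != self.target_list.bin_ids:
            raise ValueError("matrix columns must equal target bin_ids")
        if len(self.matrix) and (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative binned intensities")


def reduce_peaks(
    ps: PixelSpectrumSet, top_n: int = 3000, min_intensity: float = 100.0
) -> PixelSpectrumSet:
    """Per-pixel noise reduction: keep peaks with intensity strictly above
    ``min_intensity``, then at most the ``top_n`` most intense.

    Ties at the top-N boundary are resolved in favour of lower m/z. The
    operation is idempotent. Empty pixel peak lists are legal.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    peaks = ps.peaks[ps.peaks["intensity"] > min_intensity]
    # rank within pixel by (-intensity, mz); head(top_n) keeps the rule
    peaks = (
        peaks.sort_values(["pixel", "intensity", "mz"],
                          ascending=[True, False, True], kind="mergesort")
        .groupby("pixel", sort=True)
        .head(top_n)
    )
    return PixelSpectrumSet(ps.coords, peaks, dict(ps.metadata))


def build_target_list(
    ps: PixelSpectrumSet, mz_bin: float = 0.04, drift_bin: float | None = 100.0
) -> TargetList:
    """Partition all observed peaks into half-open m/z bins
    ``[k*mz_bin, (k+1)*mz_bin)`` (crossed with drift bins when drift is
    present) and emit one target per non-empty bin at the intensity-weighted
    mean m/z of its member peaks.
    """
    if mz_bin <= 0:
        raise ValueError("mz_bin must be positive")
    if not len(ps.peaks):
        warnings.warn("no peaks anywhere; empty target list")
        return TargetList(pd.DataFrame(columns=["bin_id", "mz_center", "drift_center"]))

    df = ps.peaks.copy()
    df["_mzk"] = np.floor(df["mz"].to_numpy() / mz_bin).astype(np.int64)
    has_drift = df["drift"].notna().any()
    if has_drift and drift_bin:
        drift = df["drift"].to_numpy()
        df["_dk"] = np.where(
            np.isnan(drift), -1, np.floor(np.nan_to_num(drift) / drift_bin)
        ).astype(np.int64)
    else:
        df["_dk"] = -1

    df["_wmz"] = df["mz"] * df["intensity"]
    grouped = df.groupby(["_dk", "_mzk"], sort=True)
    agg = grouped.agg(
        _wmz=("_wmz", "sum"), _i=("intensity", "sum"), drift_center=("drift", "mean")
    )
    agg["mz_center"] = agg["_wmz"] / agg["_i"]
    out = agg[["mz_center", "drift_center"]].reset_index()
    out = out.sort_values(["_dk", "mz_center"], kind="mergesort").reset_index(drop=True)
    out["bin_id"] = [
        f"T{i:05d}_mz{mzc:.4f}" for i, mzc in enumerate(out["mz_center"])
    ]
    return TargetList(out[["bin_id", "mz_center", "drift_center"]])


def rebin_to_targets(
    ps: PixelSpectrumSet,
    tl: TargetList,
    tolerance_da: float | None = None,
    tolerance_ppm: float | None = None,
    drift_bin: float | None = 100.0,
) -> BinnedImage:
    """Assign every peak to its nearest target and sum co-assigned
    intensities into a pixels x targets matrix.

    A peak is assigned to the nearest target m/z center within the
    tolerance (``tolerance_da`` Da, or ``tolerance_ppm`` relative; default
    0.04 Da when neither is given). Equidistant peaks go to the lower-m/z
    target. Unassigned peaks are dropped and counted in provenance. When
    targets carry drift centers, matching is performed within the peak's
    drift bin.
    """
    if not len(tl):
        raise ValueError("target list is empty")
    if tolerance_da is None and tolerance_ppm is None:
        tolerance_da = 0.04

    targets = tl.targets.copy()
    has_drift = targets["drift_center"].notna().any()
    targets["_dk"] = (
        np.floor(targets["drift_center"].to_numpy() / drift_bin).astype(np.int64)
        if has_drift and drift_bin
        else -1
    )

    n_px, n_t = ps.n_pixels, len(tl)
    mat = np.zeros((n_px, n_t), dtype=float)
    n_dropped = 0

    peaks = ps.peaks
    if len(peaks):
        pk_dk = (
            np.floor(np.nan_to_num(peaks["drift"].to_numpy()) / drift_bin).astype(np.int64)
            if has_drift and drift_bin
            else np.full(len(peaks), -1, dtype=np.int64)
        )
        for dk in np.unique(pk_dk):
            tsub = targets[targets["_dk"] == dk]
            sel = pk_dk == dk
            sub = peaks[sel]
            if tsub.empty:
                n_dropped += len(sub)
                continue
            centers = tsub["mz_center"].to_numpy()
            col_idx = tsub.index.to_numpy()  # ordinal position in target list
            mz = sub["mz"].to_numpy()
            # nearest center; ties (exact midpoint) -> lower-m/z target
            right = np.searchsorted(centers, mz)
            left = np.clip(right - 1, 0, len(centers) - 1)
            right = np.clip(right, 0, len(centers) - 1)
            d_left = np.abs(mz - centers[left])
            d_right = np.abs(mz - centers[right])
            nearest = np.where(d_left <= d_right, left, right)
            dist = np.minimum(d_left, d_right)
            tol = (
                tolerance_da
                if tolerance_da is not None
                else centers[nearest] * tolerance_ppm * 1e-6
            )
            ok = dist <= tol
            n_dropped += int((~ok).sum())
            np.add.at(
                mat,
                (sub["pixel"].to_numpy()[ok], col_idx[nearest[ok]]),
                sub["intensity"].to_numpy()[ok],
            )

    matrix = pd.DataFrame(mat, columns=tl.bin_ids)
    prov = [{
        "operation": "rebin_to_targets",
        "n_targets": n_t,
        "n_peaks_in": int(len(peaks)),
        "n_peaks_dropped": int(n_dropped),
        "tolerance_da": tolerance_da,
        "tolerance_ppm": tolerance_ppm,
    }]
    return BinnedImage(ps.coords, matrix, tl, prov, dict(ps.metadata))


def lock_mass_correct(
    ps: PixelSpectrumSet,
    reference_mz: float = 753.6134,
    search_window_ppm: float = 50.0,
) -> PixelSpectrumSet:
    """Multiplicative per-sample mass-drift correction against a spiked
    internal standard.

    The sample-mean spectrum inside ``reference_mz +/- search_window_ppm``
    is scanned for its most intense feature (fine 0.01-Da bins, summed
    over pixels); the correction factor ``reference_mz / observed_mz`` is
    applied to every m/z in the sample. If no peak falls in the window the
    data are returned unchanged with a warning. The applied ppm shift is
    recorded in ``metadata['lockmass']``.
    """
    if reference_mz <= 0:
        raise ValueError("reference_mz must be positive")
    half = reference_mz * search_window_ppm * 1e-6
    mz = ps.peaks["mz"].to_numpy()
    sel = (mz >= reference_mz - half) & (mz <= reference_mz + half)
    if not sel.any():
        warnings.warn(
            f"lock mass: no peak within +/-{search_window_ppm} ppm of "
            f"{reference_mz}; sample left uncorrected"
        )
        meta = dict(ps.metadata)
        meta["lockmass"] = {"applied": False, "reference_mz": reference_mz}
        return PixelSpectrumSet(ps.coords, ps.peaks.copy(), meta)

    window = ps.peaks[sel]
    # sample-mean spectrum at 0.01-Da granularity
    fine = np.floor(window["mz"].to_numpy() / 0.01).astype(np.int64)
    sums = window.groupby(fine)["intensity"].sum()
    best = sums.idxmax()
    members = window[fine == best]
    observed = float(np.average(members["mz"], weights=members["intensity"]))
    factor = reference_mz / observed

    peaks = ps.peaks.copy()
    peaks["mz"] = peaks["mz"] * factor
    meta = dict(ps.metadata)
    meta["lockmass"] = {
        "applied": True,
        "reference_mz": reference_mz,
        "observed_mz": observed,
        "factor": factor,
        "ppm_shift": (observed - reference_mz) / reference_mz * 1e6,
    }
    return PixelSpectrumSet(ps.coords, peaks, meta)


# ---------------------------------------------------------------------------
# IO: long-form peak TSV, binned tabular dialect, continuous-mode imzML
# ---------------------------------------------------------------------------

def write_peaks_tsv(ps: PixelSpectrumSet, path: str | Path) -> None:
    """Write raw peaks as ``row  col  mz  drift  intensity`` TSV."""
    df = ps.peaks.copy()
    df.insert(0, "col", ps.coords[df["pixel"].to_numpy(), 1])
    df.insert(0, "row", ps.coords[df["pixel"].to_numpy(), 0])
    df = df.drop(columns="pixel")
    with open(path, "w") as fh:
        for key, value in sorted(ps.metadata.items()):
            if isinstance(value, (str, int, float)):
                fh.write(f"#meta\t{key}\t{value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_peaks_tsv(path: str | Path) -> PixelSpectrumSet:
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#meta\t"):
            _, key, value = line.rstrip("\n").split("\t", 2)
            try:
                metadata[key] = int(value)
            except ValueError:
                try:
                    metadata[key] = float(value)
                except ValueError:
                    metadata[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    coords = (
        df[["row", "col"]].drop_duplicates().sort_values(["row", "col"])
        .to_numpy(dtype=int)
    )
    index = {tuple(rc): i for i, rc in enumerate(coords)}
    df["pixel"] = [index[(r, c)] for r, c in zip(df["row"], df["col"])]
    return PixelSpectrumSet(coords, df[PEAK_COLUMNS], metadata)


def write_tabular(img: BinnedImage, path: str | Path) -> None:
    """Write a BinnedImage in the internal tabular dialect: a target-list
    block (``#target  bin_id  mz_center  drift_center``) followed by a
    per-pixel table with header ``row  col  <bin_id> ...``."""
    with open(path, "w") as fh:
        for rec in img.target_list.targets.itertuples(index=False):
            drift = "" if pd.isna(rec.drift_center) else f"{rec.drift_center:.17g}"
            fh.write(f"#target\t{rec.bin_id}\t{rec.mz_center:.17g}\t{drift}\n")
        body = img.matrix.copy()
        body.insert(0, "col", img.coords[:, 1])
        body.insert(0, "row", img.coords[:, 0])
        body.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_tabular(path: str | Path) -> BinnedImage:
    target_rows = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#target\t"):
            _, bin_id, mzc, drift = line.rstrip("\n").split("\t")
            target_rows.append(
                (bin_id, float(mzc), float(drift) if drift else np.nan)
            )
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        body = pd.read_csv(fh, sep="\t")
    tl = TargetList(
        pd.DataFrame(target_rows, columns=["bin_id", "mz_center", "drift_center"])
    )
    coords = body[["row", "col"]].to_numpy(dtype=int)
    matrix = body.drop(columns=["row", "col"])
    return BinnedImage(coords, matrix, tl, [{"operation": "read_tabular"}])


def write_imzml(img: BinnedImage, path: str | Path) -> None:
    """Export as continuous-mode imzML (shared m/z axis = target centers).

    imzML pixel coordinates are 1-based (x = col + 1, y = row + 1).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    mz_axis = img.target_list.targets["mz_center"].to_numpy(dtype=np.float64)
    with ImzMLWriter(str(path), mode="continuous",
                     mz_dtype=np.float64,
                     intensity_dtype=np.float64) as writer:
        for i, (row, col) in enumerate(img.coords):
            writer.addSpectrum(
                mz_axis,
                img.matrix.iloc[i].to_numpy(dtype=np.float64),
                (int(col) + 1, int(row) + 1, 1),
            )


def read_imzml(path: str | Path) -> BinnedImage:
    """Read a continuous-mode imzML written by :func:`write_imzml`."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.array([(y - 1, x - 1) for x, y, _ in parser.coordinates], dtype=int)
    mz_axis, _ = parser.getspectrum(0)
    rows = [parser.getspectrum(i)[1] for i in range(len(parser.coordinates))]
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    matrix = pd.DataFrame(np.asarray(rows)[order])
    tl = TargetList(pd.DataFrame({
        "bin_id": [f"T{i:05d}_mz{m:.4f}" for i, m in enumerate(mz_axis)],
        "mz_center": mz_axis,
        "drift_center": np.nan,
    }))
    matrix.columns = tl.bin_ids
    return BinnedImage(coords, matrix, tl, [{"operation": "read_imzml"}])
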