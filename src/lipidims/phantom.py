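"""Seeded synthetic MALDI-IMS phantoms with known ground truth.

The phantom emulates a sagittal knee-joint section laid out as labeled
bands on a rectangular pixel grid: an off-tissue margin carrying chemical
matrix only, plus articular cartilage, the three growth-plate zones
(resting, proliferating, hypertrophic), cortical bone and bone marrow.
Each ground-truth lipid has a per-region mean log2 intensity; pixel
intensities are log-normal around the region mean (multiplicative noise)
with an optional additive baseline. Lipids ionize as a mixture of
protonated, sodiated, potassiated and dehydrated adducts with optional
single-13C satellites, at theoretical m/z perturbed by a per-pixel ppm
jitter. A deuterated internal standard can be spiked into every pixel,
and KO-vs-WT genotype effects multiply the growth-plate zone means.

Everything is driven by one integer seed; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .annotation import LipidLibrary, LipidRecord
from .nomenclature import LipidParseError, parse_shorthand
from .roi import RoiSet
from .spectra import PixelSpectrumSet

REGIONS = (
    "off_tissue", "marrow", "cortical_bone", "articular_cartilage",
    "gp_resting", "gp_proliferating", "gp_hypertrophic",
)
GP_ZONES = {"gp_resting": "resting", "gp_proliferating": "proliferating",
            "gp_hypertrophic": "hypertrophic"}
TISSUE_OF_REGION = {
    "off_tissue": "off_tissue",
    "marrow": "marrow",
    "cortical_bone": "cortical_bone",
    "articular_cartilage": "articular_cartilage",
    "gp_resting": "growth_plate",
    "gp_proliferating": "growth_plate",
    "gp_hypertrophic": "growth_plate",
}
BASE_ADDUCTS = ("M+H", "M+Na", "M+K", "M+H-H2O")

#: internal standard: deuterated PC (15:0/18:1(d7)), [M+H]+ at 753.6134
STANDARD_NAME = "PC (15:0/18:1(d7))"
STANDARD_FORMULA = "C41H73D7NO8P"
STANDARD_MH_MZ = chem.formula_mass(STANDARD_FORMULA) + chem.PROTON


@dataclass
class GroundTruthLipid:
    """One planted species with its spatial profile and truth flags."""

    name: str
    lipid_class: str
    region_profile: dict[str, float | None]  # mean log2 intensity; None = absent
    neutral_mass: float | None = None
    is_matrix: bool = False
    diff_atlas: bool = False
    diff_zones: tuple[str, ...] = ()   # zones where the KO effect applies

    def __post_init__(self):
        if self.neutral_mass is None:
            parsed = parse_shorthand(self.name)
            self.neutral_mass = chem.lipid_neutral_mass(
                parsed.headgroup, parsed.total_carbons, parsed.total_double_bonds,
                ether=parsed.ether or parsed.plasmenyl,
                deuterium=parsed.deuterium,
            )
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name!r}: neutral_mass must be positive")
        missing = set(REGIONS) - set(self.region_profile)
        if missing:
            raise ValueError(f"{self.name!r}: region_profile missing {sorted(missing)}")
        if self.is_matrix:
            off = self.region_profile["off_tissue"]
            others = [v for r, v in self.region_profile.items()
                      if r != "off_tissue" and v is not None]
            if off is None or (others and off <= max(others)):
                raise ValueError(
                    f"matrix species {self.name!r} must peak in off_tissue"
                )

    @property
    def home_region(self) -> str:
        defined = {r: v for r, v in self.region_profile.items() if v is not None}
        return max(defined, key=defined.get)


@dataclass
class StandardSpec:
    name: str = STANDARD_NAME
    mz: float = STANDARD_MH_MZ
    intensity: float = 5000.0


@dataclass
class PhantomSpec:
    """Complete description of one synthetic acquisition."""

    grid_shape: tuple[int, int]
    region_map: np.ndarray                  # (rows, cols) of region labels
    lipid_panel: list[GroundTruthLipid]
    genotype: str = "WT"
    effect_table: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma_log2: float = 1.0                 # pixel-level multiplicative noise
    baseline: float = 0.0                   # additive intensity floor
    adduct_profile: dict[str, float] = field(
        default_factory=lambda: {"M+H": 0.6, "M+Na": 0.15, "M+K": 0.1,
                                 "M+H-H2O": 0.05, "13C": 0.1})
    isotope_fraction: float = 0.3           # 13C satellite / monoisotopic
    standard_spec: StandardSpec | None = field(default_factory=StandardSpec)
    mz_jitter_ppm: float = 0.0
    mz_shift_ppm: float = 0.0   # systematic calibration offset, whole sample
    seed: int = 0
    sample_id: str = ""

    def __post_init__(self):
        self.region_map = np.asarray(self.region_map, dtype=object)
        if self.region_map.shape != tuple(self.grid_shape):
            raise ValueError("region_map shape must equal grid_shape")
        bad = set(self.region_map.ravel()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        if not (self.region_map == "off_tissue").any():
            raise ValueError(
                "grid has no off_tissue pixels; matrix filter untestable"
            )
        if not self.lipid_panel:
            raise ValueError("empty lipid_panel")
        if self.genotype not in ("WT", "KO"):
            raise ValueError("genotype must be 'WT' or 'KO'")
        for key, fold in self.effect_table.items():
            if fold <= 0:
                raise ValueError(f"effect_table[{key}] must be > 0")
        total = sum(self.adduct_profile.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"adduct weights must sum to 1, got {total}")
        unknown = set(self.adduct_profile) - set(BASE_ADDUCTS) - {"13C"}
        if unknown:
            raise ValueError(f"unknown adduct labels {sorted(unknown)}")


def striped_region_map(
    grid_shape: tuple[int, int] = (64, 64), margin_cols: int = 8
) -> np.ndarray:
    """Default geometry: an off-tissue margin on the left, tissue bands
    stacked top to bottom with the growth plate as three adjacent
    horizontal zones (the anatomical stacking, not the anatomy)."""
    rows, cols = grid_shape
    rmap = np.full((rows, cols), "off_tissue", dtype=object)
    bands = [
        ("articular_cartilage", 0.16), ("gp_resting", 0.12),
        ("gp_proliferating", 0.12), ("gp_hypertrophic", 0.12),
        ("cortical_bone", 0.20), ("marrow", 0.28),
    ]
    r0 = 0
    for label, frac in bands:
        r1 = min(rows, r0 + max(1, round(frac * rows)))
        rmap[r0:r1, margin_cols:] = label
        r0 = r1
    return rmap


def default_lipid_panel(
    n_matrix: int = 10,
    n_per_tissue: int = 12,
    n_background: int = 40,
    n_ko_up_per_zone: int = 20,
    n_ko_down_per_zone: int = 0,
    enrichment_log2: float = 3.0,
    base_log2: float = 10.0,
    seed: int = 0,
) -> tuple[list[GroundTruthLipid], dict[tuple[str, str], float]]:
    """Build a panel reproducing the study's qualitative spatial structure.

    LPC/PC species are enriched in the growth plate, ether-PCs and
    long-chain polyunsaturated phospholipids in marrow, SMs in articular
    cartilage and PEs in cortical bone; ``n_background`` lipids are flat
    across tissue; ``n_matrix`` matrix-only ions dominate off-tissue
    pixels. KO-vs-WT effects (folds drawn uniformly in 1.5-3x) are
    attached to the first ``n_ko_up_per_zone`` growth-plate lipids in
    every zone (and symmetrically for down-regulated ones).

    Returns the panel and the matching effect table.
    """
    rng = np.random.default_rng(seed)

    def profile(home: str | None, enriched: float = enrichment_log2):
        prof: dict[str, float | None] = {r: base_log2 for r in REGIONS}
        prof["off_tissue"] = None
        if home == "growth_plate":
            for r in GP_ZONES:
                prof[r] = base_log2 + enriched
        elif home is not None:
            prof[home] = base_log2 + enriched
        return prof

    panel: list[GroundTruthLipid] = []
    # growth plate: LPC and PC species (the lyso signature)
    gp_names = ["LPC (14:0/0:0)", "LPC (16:1/0:0)", "LPC (16:0/0:0)",
                "LPC (18:1/0:0)", "LPE (20:4/0:0)", "PC (32:2)", "PC (32:1)",
                "PC (30:0)", "PC (34:2)", "PC (36:3)", "LPC (18:3/0:0)",
                "PC (38:2)"]
    # marrow: ether-PCs (platelet-activating-factor family) and long PUFAs
    marrow_names = ["LPC (O-16:0/0:0)", "LPC (O-18:0/0:0)", "PC (O-16:0/16:0)",
                    "PC (O-36:4)", "PC (40:6)", "PC (38:6)", "PE (38:4)",
                    "PE (40:6)", "LPC (18:2/0:0)", "PC (36:4)", "PC (38:4)",
                    "PE (36:2)"]
    # articular cartilage: sphingomyelins
    ac_names = ["SM (d34:1)", "SM (d32:2)", "SM (d42:1)", "SM (d36:1)",
                "SM (d38:1)", "SM (d40:1)", "SM (d34:2)", "SM (d36:2)",
                "SM (d42:2)", "SM (d40:2)", "SM (d38:2)", "SM (d33:1)"]
    # cortical bone
    cb_names = ["PE (34:1)", "PE (34:2)", "PE (36:1)", "PE (36:4)",
                "PC (32:0)", "PC (34:1)", "PA (34:1)", "PA (36:2)",
                "PE (38:6)", "PC (34:0)", "PA (36:1)", "PE (40:4)"]
    for names, home, klass in [
        (gp_names, "growth_plate", "GP"),
        (marrow_names, "marrow", "marrow"),
        (ac_names, "articular_cartilage", "SM"),
        (cb_names, "cortical_bone", "bone"),
    ]:
        for name in names[:n_per_tissue]:
            panel.append(GroundTruthLipid(
                name=name, lipid_class=klass, region_profile=profile(home),
                diff_atlas=True,
            ))

    # flat background lipids: PC/PE/SM totals over a grid of compositions,
    # skipping names already used by the tissue signatures
    taken = {lip.name for lip in panel}
    combos = [(hg, c, d)
              for d in range(7) for c in range(30, 48)
              for hg in ("PC", "PE", "SM")]
    added = 0
    for hg, c, d in combos:
        if added >= n_background:
            break
        name = f"{hg} (d{c}:{d})" if hg == "SM" else f"{hg} ({c}:{d})"
        if name in taken:
            continue
        taken.add(name)
        jig = float(rng.uniform(-0.5, 0.5))
        prof = profile(None)
        prof = {r: (None if v is None else v + jig) for r, v in prof.items()}
        panel.append(GroundTruthLipid(
            name=name, lipid_class="background", region_profile=prof,
        ))
        added += 1
    if added < n_background:
        raise ValueError(f"background composition grid exhausted at {added}")

    # chemical-matrix ions: low-mass clusters present everywhere,
    # dominant off tissue
    for i in range(n_matrix):
        mass = float(rng.uniform(120.0, 420.0))
        prof = {r: base_log2 - 1.0 for r in REGIONS}
        prof["off_tissue"] = base_log2 + 4.0
        panel.append(GroundTruthLipid(
            name=f"MATRIX_{i:02d}", lipid_class="matrix", region_profile=prof,
            neutral_mass=mass, is_matrix=True,
        ))

    # genotype effects on growth-plate lipids, per zone
    effects: dict[tuple[str, str], float] = {}
    gp_homed = [l for l in panel
                if TISSUE_OF_REGION.get(l.home_region) == "growth_plate"]
    background = [l for l in panel if l.lipid_class == "background"]
    gp_lipids = gp_homed + background  # all are present in growth-plate pixels
    ups = gp_lipids[:n_ko_up_per_zone]
    downs = gp_lipids[n_ko_up_per_zone:n_ko_up_per_zone + n_ko_down_per_zone]
    for lip in ups:
        zones = tuple(GP_ZONES.values())
        lip.diff_zones = zones
        for zone in zones:
            effects[(lip.name, zone)] = float(rng.uniform(1.5, 3.0))
    for lip in downs:
        zones = tuple(GP_ZONES.values())
        lip.diff_zones = zones
        for zone in zones:
            effects[(lip.name, zone)] = float(1.0 / rng.uniform(1.5, 3.0))
    return panel, effects


def make_phantom_spec(
    genotype: str = "WT",
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
    sigma_log2: float = 1.0,
    mz_jitter_ppm: float = 0.0,
    mz_shift_ppm: float = 0.0,
    adduct_profile: dict[str, float] | None = None,
    panel_kwargs: dict | None = None,
    apply_effects: bool = True,
    sample_id: str = "",
) -> PhantomSpec:
    """Convenience builder: default geometry + default panel.

    The panel (and hence truth flags and effect folds) depends only on
    ``panel_kwargs``' seed, so WT and KO phantoms built with the same
    panel seed share their ground truth.
    """
    panel_kwargs = dict(panel_kwargs or {})
    panel_kwargs.setdefault("seed", 0)
    panel, effects = default_lipid_panel(**panel_kwargs)
    return PhantomSpec(
        grid_shape=grid_shape,
        region_map=striped_region_map(grid_shape),
        lipid_panel=panel,
        genotype=genotype,
        effect_table=effects if apply_effects else {},
        sigma_log2=sigma_log2,
        mz_jitter_ppm=mz_jitter_ppm,
        mz_shift_ppm=mz_shift_ppm,
        seed=seed,
        sample_id=sample_id or f"{genotype}_{seed}",
        **({"adduct_profile": adduct_profile} if adduct_profile else {}),
    )


def ground_truth_table(spec: PhantomSpec) -> pd.DataFrame:
    """One row per emitted ion species: source lipid, adduct, true m/z,
    and differential-status flags."""
    base = [a for a in BASE_ADDUCTS if spec.adduct_profile.get(a, 0) > 0]
    w13 = spec.adduct_profile.get("13C", 0)
    rows = []
    for lip in spec.lipid_panel:
        adducts = list(base)
        if w13 > 0:
            adducts += [f"{a}+13C" for a in base]
        for adduct in adducts:
            rows.append({
                "lipid": lip.name,
                "lipid_class": lip.lipid_class,
                "adduct": adduct,
                "theoretical_mz": chem.adduct_mz(lip.neutral_mass, adduct),
                "is_matrix": lip.is_matrix,
                "home_region": lip.home_region,
                "diff_atlas": lip.diff_atlas,
                "diff_zones": ";".join(lip.diff_zones),
            })
    if spec.standard_spec is not None:
        rows.append({
            "lipid": spec.standard_spec.name, "lipid_class": "standard",
            "adduct": "M+H", "theoretical_mz": spec.standard_spec.mz,
            "is_matrix": False, "home_region": "all",
            "diff_atlas": False, "diff_zones": "",
        })
    return pd.DataFrame(rows)


def generate_phantom(spec: PhantomSpec) -> tuple[PixelSpectrumSet, pd.DataFrame]:
    """Simulate one acquisition: per-pixel peak lists plus the truth table.

    Every lipid present in a pixel's region appears as one peak per
    weighted adduct (plus 13C satellites at ``isotope_fraction`` of the
    monoisotopic intensity), at theoretical m/z perturbed by
    ``Normal(0, mz_jitter_ppm)``. Matrix ions appear in all pixels; the
    internal standard in every pixel at its spiked intensity +/- noise.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=int)
    region_idx = np.array(
        [REGIONS.index(spec.region_map[r, c]) for r, c in coords]
    )
    n_px = len(coords)

    base = [a for a in BASE_ADDUCTS if spec.adduct_profile.get(a, 0) > 0]
    wsum = sum(spec.adduct_profile[a] for a in base)
    shares = {a: spec.adduct_profile[a] / wsum for a in base}
    w13 = spec.adduct_profile.get("13C", 0)

    px_parts: list[np.ndarray] = []
    mz_parts: list[np.ndarray] = []
    it_parts: list[np.ndarray] = []

    def emit(pixels: np.ndarray, mz_theory: float, intensity: np.ndarray) -> None:
        mz = np.full(len(pixels), mz_theory * (1.0 + spec.mz_shift_ppm * 1e-6))
        if spec.mz_jitter_ppm > 0:
            mz = mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm, len(pixels)) * 1e-6)
        if spec.baseline > 0:
            intensity = intensity + spec.baseline
        px_parts.append(pixels)
        mz_parts.append(mz)
        it_parts.append(intensity)

    for lip in spec.lipid_panel:
        mu = np.array([
            np.nan if lip.region_profile[r] is None else lip.region_profile[r]
            for r in REGIONS
        ])[region_idx]
        if spec.genotype == "KO":
            for (name, zone), fold in spec.effect_table.items():
                if name != lip.name:
                    continue
                region = {v: k for k, v in GP_ZONES.items()}[zone]
                mu = np.where(
                    region_idx == REGIONS.index(region), mu + np.log2(fold), mu
                )
        present = ~np.isnan(mu)
        if not present.any():
            continue
        pixels = np.nonzero(present)[0]
        noise = rng.normal(0.0, spec.sigma_log2, len(pixels)) if spec.sigma_log2 > 0 \
            else np.zeros(len(pixels))
        total = 2.0 ** (mu[present] + noise)
        for adduct in base:
            mono = total * shares[adduct]
            emit(pixels, chem.adduct_mz(lip.neutral_mass, adduct), mono)
            if w13 > 0:
                emit(pixels, chem.adduct_mz(lip.neutral_mass, f"{adduct}+13C"),
                     mono * spec.isotope_fraction)

    if spec.standard_spec is not None:
        pixels = np.arange(n_px)
        noise = rng.normal(0.0, spec.sigma_log2, n_px) if spec.sigma_log2 > 0 \
            else np.zeros(n_px)
        emit(pixels, spec.standard_spec.mz,
             spec.standard_spec.intensity * 2.0 ** noise)

    peaks = pd.DataFrame({
        "pixel": np.concatenate(px_parts),
        "mz": np.concatenate(mz_parts),
        "drift": np.nan,
        "intensity": np.concatenate(it_parts),
    })
    meta = {"sample": spec.sample_id, "genotype": spec.genotype,
            "seed": spec.seed}
    return PixelSpectrumSet(coords, peaks, meta), ground_truth_table(spec)


def generate_library(
    spec: PhantomSpec,
    decoys: int = 0,
    seed: int | None = None,
    manual_fraction: float = 0.3,
    min_decoy_ppm: float = 300.0,
) -> LipidLibrary:
    """Reference library for the phantom: one record per non-matrix
    ground-truth lipid (correct neutral mass + simulated database-match
    evidence for tier scoring) plus ``decoys`` records whose every adduct
    m/z lies at least ``min_decoy_ppm`` from any truth adduct m/z."""
    if decoys < 0:
        raise ValueError("decoys must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records = []
    truth = [l for l in spec.lipid_panel if not l.is_matrix]
    for lip in truth:
        manual = lip.diff_atlas and rng.random() < manual_fraction
        both = rng.random() < 0.6
        records.append(LipidRecord(
            name=lip.name, neutral_mass=lip.neutral_mass,
            manual_id=manual,
            lipidmatch_hit=True,
            lipidmatch_score_high=not both,
            lipidblast_hit=both,
        ))
    if spec.standard_spec is not None:
        records.append(LipidRecord(
            name=spec.standard_spec.name,
            formula=STANDARD_FORMULA,
            manual_id=True, lipidmatch_hit=True,
            lipidmatch_score_high=True, lipidblast_hit=True,
        ))

    truth_mz = np.sort(np.array([
        chem.adduct_mz(l.neutral_mass, a)
        for l in truth for a in chem.ADDUCT_DELTAS
    ] + ([spec.standard_spec.mz] if spec.standard_spec is not None else [])))
    n_placed = 0
    attempts = 0
    while n_placed < decoys:
        attempts += 1
        if attempts > 1000 * max(decoys, 1):
            raise RuntimeError("could not place decoys outside the ppm margin")
        mass = float(rng.uniform(350.0, 950.0))
        dmz = np.array([chem.adduct_mz(mass, a) for a in chem.ADDUCT_DELTAS])
        j = np.searchsorted(truth_mz, dmz)
        near = []
        for k, m in zip(j, dmz):
            for kk in (k - 1, k):
                if 0 <= kk < len(truth_mz):
                    near.append(abs(m - truth_mz[kk]) / m * 1e6)
        if near and min(near) < min_decoy_ppm:
            continue
        records.append(LipidRecord(
            name=f"DECOY_{n_placed:03d}", neutral_mass=mass,
            lipidmatch_hit=bool(rng.random() < 0.5),
        ))
        n_placed += 1
    return LipidLibrary(records)


def default_rois(
    spec: PhantomSpec,
    n_lrois_per_region: int = 3,
    lroi_size: int = 10,
    n_matrix_rois: int = 3,
    n_srois_per_region: int = 0,
    replicate: str = "rep1",
) -> RoiSet:
    """Deterministic ROI layout on the phantom grid.

    For every tissue region, ``n_lrois_per_region`` non-overlapping
    lROIs of ``lroi_size`` consecutive raster pixels (plus optional
    sROIs); ``n_matrix_rois`` matrix ROIs in the off-tissue margin.
    """
    rows_, cols_ = spec.grid_shape
    coords = [(r, c) for r in range(rows_) for c in range(cols_)]
    by_region: dict[str, list[tuple[int, int]]] = {r: [] for r in REGIONS}
    for r, c in coords:
        by_region[str(spec.region_map[r, c])].append((r, c))

    rows = []

    def add_roi(roi_id, pixels, tissue, zone, kind):
        for r, c in pixels:
            rows.append({"roi_id": roi_id, "row": r, "col": c,
                         "tissue": tissue, "zone": zone, "bone": "tibia",
                         "replicate": replicate, "kind": kind})

    for region in REGIONS:
        pixels = by_region[region]
        tissue = TISSUE_OF_REGION[region]
        zone = GP_ZONES.get(region, "")
        if region == "off_tissue":
            need = n_matrix_rois * lroi_size
            if len(pixels) < need:
                raise ValueError("not enough off-tissue pixels for matrix ROIs")
            for i in range(n_matrix_rois):
                add_roi(f"matrix_{i}", pixels[i * lroi_size:(i + 1) * lroi_size],
                        "off_tissue", "", "matrix")
            continue
        if not pixels:
            continue
        need = n_lrois_per_region * lroi_size
        if len(pixels) < need + n_srois_per_region:
            raise ValueError(f"region {region!r} too small for requested ROIs")
        for i in range(n_lrois_per_region):
            add_roi(f"{region}_l{i}", pixels[i * lroi_size:(i + 1) * lroi_size],
                    tissue, zone, "lROI")
        for i in range(n_srois_per_region):
            add_roi(f"{region}_s{i}", [pixels[need + i]], tissue, zone, "sROI")
    return RoiSet(pd.DataFrame(rows), allowed_lroi_sizes=(lroi_size, 5, 10))


def truth_to_bins(
    truth: pd.DataFrame, targets, tolerance_da: float = 0.04
) -> pd.DataFrame:
    """Map ground-truth ions to the target bins they landed in.

    Each truth ion is matched to the nearest target m/z center within
    ``tolerance_da``; ions that fell outside every bin get ``bin_id`` ''.
    Several truth ions may share one bin (near-isobaric adduct/isotope
    combinations)."""
    centers = targets.targets["mz_center"].to_numpy()
    ids = np.asarray(targets.targets["bin_id"])
    out = truth.copy()
    mz = out["theoretical_mz"].to_numpy()
    right = np.searchsorted(centers, mz)
    left = np.clip(right - 1, 0, len(centers) - 1)
    right = np.clip(right, 0, len(centers) - 1)
    nearest = np.where(
        np.abs(mz - centers[left]) <= np.abs(mz - centers[right]), left, right
    )
    ok = np.abs(mz - centers[nearest]) <= tolerance_da
    out["bin_id"] = np.where(ok, ids[nearest], "")
    return out


def simulate_feature_matrix(
    n_ions: int = 200,
    n_rois_per_group: int = 10,
    n_pixels_per_roi: int = 10,
    zones: tuple[str, ...] = ("resting", "proliferating", "hypertrophic"),
    n_effect_ions: int = 0,
    effect_range: tuple[float, float] = (1.5, 3.0),
    sigma_log2: float = 1.0,
    base_log2_range: tuple[float, float] = (8.0, 12.0),
    seed: int = 0,
):
    """ROI-level fast path for Monte Carlo calibration studies.

    Draws the same intensity model as the pixel phantom — log-normal pixel
    intensities around a per-ion mean, averaged over ``n_pixels_per_roi``
    pixels per ROI, then log2 — directly at the ROI level, skipping peak
    lists and binning. The first ``n_effect_ions`` ions carry KO-vs-WT
    folds drawn from ``effect_range`` in every zone.

    Returns ``(FeatureMatrix (log2 scale), truth)`` where truth maps each
    zone to the set of planted ion ids.
    """
    from .roi import FeatureMatrix

    rng = np.random.default_rng(seed)
    bin_ids = [f"ion{i:04d}" for i in range(n_ions)]
    mu = rng.uniform(*base_log2_range, n_ions)
    folds = np.ones(n_ions)
    if n_effect_ions:
        folds[:n_effect_ions] = rng.uniform(*effect_range, n_effect_ions)
    truth = {z: set(bin_ids[:n_effect_ions]) for z in zones}

    meta_rows, value_rows = [], []
    for zone in zones:
        for genotype in ("WT", "KO"):
            shift = np.where(
                (genotype == "KO") & (folds != 1.0), np.log2(folds), 0.0
            )
            for i in range(n_rois_per_group):
                z = rng.normal(0.0, sigma_log2, (n_ions, n_pixels_per_roi))
                linear = 2.0 ** (mu[:, None] + shift[:, None] + z)
                value_rows.append(np.log2(linear.mean(axis=1)))
                meta_rows.append({
                    "roi_id": f"{zone}_{genotype}_{i}", "tissue": "growth_plate",
                    "zone": zone, "bone": "tibia", "replicate": f"rep{i % 3}",
                    "kind": "lROI", "sample": genotype, "genotype": genotype,
                })
    fm = FeatureMatrix(
        pd.DataFrame(meta_rows),
        pd.DataFrame(np.vstack(value_rows), columns=bin_ids),
        scale="log2",
    )
    return fm, truth


def write_phantom_csvs(
    spec: PhantomSpec, outdir: str | Path, decoys: int = 25
) -> dict[str, Path]:
    """Materialize a phantom: peaks TSV, truth CSV, library CSV, ROI CSV."""
    from .spectra import write_peaks_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ps, truth = generate_phantom(spec)
    lib = generate_library(spec, decoys=decoys)
    rois = default_rois(spec)
    paths = {
        "peaks": outdir / f"{spec.sample_id or 'phantom'}_peaks.tsv",
        "truth": outdir / f"{spec.sample_id or 'phantom'}_truth.csv",
        "library": outdir / "library.csv",
        "rois": outdir / f"{spec.sample_id or 'phantom'}_rois.csv",
    }
    write_peaks_tsv(ps, paths["peaks"])
    truth.to_csv(paths["truth"], index=False)
    lib.to_csv(paths["library"])
    rois.to_csv(paths["rois"])
    return paths
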