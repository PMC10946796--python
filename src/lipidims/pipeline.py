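"""End-to-end orchestration of the two study designs.

``run_atlas`` reproduces the healthy-joint workflow: ingest -> peak
reduction -> shared target list -> re-binning -> ROI features -> TIC ->
matrix-ion filter -> log2 -> PCA -> pairwise-tissue OPLS-DA (each tissue
vs rest plus growth plate vs articular cartilage) -> panel merge ->
hierarchical clustering -> adduct annotation.

``run_genotype_contrast`` reproduces the KO-vs-WT growth-plate workflow:
ingest -> lock-mass correction -> shared targets across samples ->
features -> normalizations -> whole-growth-plate OPLS-DA -> per-zone
Welch tests with BH q-values and fold changes -> volcano tables ->
cross-zone overlap -> annotation of significant ions.

Every stage appends a record (operation, parameters, output digests) to a
JSON-lines provenance log; reruns with the same seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstats, multivariate, phantom, roi, spectra
from .annotation import LipidLibrary, hits_to_frame, match_ions, score_tiers

TISSUES = ("growth_plate", "articular_cartilage", "cortical_bone", "marrow")


@dataclass
class RunConfig:
    """Parameters for one pipeline run; YAML-loadable, CLI-overridable."""

    design: str = "atlas"                   # atlas | genotype_contrast
    outdir: str = "out"
    seed: int = 0
    # input files; when absent the phantom generator supplies the inputs
    spectra: dict[str, str] = field(default_factory=dict)  # sample -> peaks TSV
    rois: dict[str, str] = field(default_factory=dict)     # sample -> ROI CSV
    library: str | None = None
    # simulation parameters (used when no spectra files are given)
    grid_shape: tuple[int, int] = (64, 64)
    sigma_log2: float = 1.0
    mz_jitter_ppm: float = 5.0
    mz_shift_ppm: float = 0.0
    panel_kwargs: dict = field(default_factory=dict)
    apply_effects: bool = True
    decoys: int = 25
    # processing parameters
    top_n: int = 3000
    min_intensity: float = 0.0
    mz_bin: float = 0.04
    drift_bin: float = 100.0
    lockmass_ref: float = phantom.STANDARD_MH_MZ
    lockmass_window_ppm: float = 50.0
    lockmass_enabled: bool = True
    matrix_filter_enabled: bool = True
    # row normalization: "tic", "standard" or "none"; None picks the design
    # default (atlas -> tic, genotype_contrast -> internal standard)
    normalization: str | None = None
    n_lrois: int | None = None  # lROIs per region (atlas 3, contrast 10)
    pseudocount: float = 1.0
    prescale: float = 1e4
    n_orth: int = 1
    panel_stat: str = "cov"
    panel_threshold: float = 0.04
    q_cut: float = 0.05
    fc_cut: float | None = None
    ppm_tolerance: float = 100.0
    write_imzml: bool = False
    compute_q2: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class ProvenanceLog:
    """Append-only JSON-lines log of pipeline stages and output digests."""

    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("")

    def record(self, operation: str, parameters: dict | None = None,
               outputs: list[Path] | None = None,
               warnings_: list[str] | None = None) -> None:
        rec = {
            "stage": len(self.records),
            "operation": operation,
            "parameters": parameters or {},
            "outputs": {p.name: _sha256(p) for p in outputs or []},
        }
        if warnings_:
            rec["warnings"] = warnings_
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")

    def digests(self) -> dict[str, str]:
        out = {}
        for rec in self.records:
            out.update(rec["outputs"])
        return out


def _load_or_simulate(
    config: RunConfig, genotype: str, sample_id: str, seed_offset: int = 0
) -> tuple[spectra.PixelSpectrumSet, roi.RoiSet, pd.DataFrame | None,
           phantom.PhantomSpec | None]:
    """Return (spectra, rois, truth table or None, phantom spec or None)."""
    if sample_id in config.spectra:
        ps = spectra.read_peaks_tsv(config.spectra[sample_id])
        rs = roi.RoiSet.from_csv(config.rois[sample_id])
        return ps, rs, None, None
    spec = phantom.make_phantom_spec(
        genotype=genotype,
        seed=config.seed + seed_offset,
        grid_shape=config.grid_shape,
        sigma_log2=config.sigma_log2,
        mz_jitter_ppm=config.mz_jitter_ppm,
        mz_shift_ppm=config.mz_shift_ppm,
        panel_kwargs=dict(config.panel_kwargs),
        apply_effects=config.apply_effects,
        sample_id=sample_id,
    )
    ps, truth = phantom.generate_phantom(spec)
    n_lrois = config.n_lrois or (10 if config.design == "genotype_contrast" else 3)
    rs = phantom.default_rois(spec, n_lrois_per_region=n_lrois)
    return ps, rs, truth, spec


def _get_library(config: RunConfig, spec: phantom.PhantomSpec | None) -> LipidLibrary:
    if config.library:
        return LipidLibrary.from_csv(config.library)
    if spec is None:
        raise ValueError("no library file given and no phantom to derive one from")
    return phantom.generate_library(spec, decoys=config.decoys, seed=config.seed)


def _shared_targets(samples: list[spectra.PixelSpectrumSet],
                    config: RunConfig) -> spectra.TargetList:
    """Target list built from the pooled peaks of all samples."""
    offset = 0
    frames, coords = [], []
    for i, ps in enumerate(samples):
        pk = ps.peaks.copy()
        pk["pixel"] += offset
        frames.append(pk)
        # disambiguate coordinates across samples with a large row offset
        coords.append(ps.coords + np.array([[10 ** 6 * i, 0]]))
        offset += ps.n_pixels
    pooled = spectra.PixelSpectrumSet(
        np.vstack(coords), pd.concat(frames, ignore_index=True)
    )
    return spectra.build_target_list(pooled, config.mz_bin, config.drift_bin)


def _feature_block(ps, rs, tl, config, sample_id) -> roi.FeatureMatrix:
    img = spectra.rebin_to_targets(ps, tl, tolerance_da=config.mz_bin,
                                   drift_bin=config.drift_bin)
    fm = roi.extract_features(img, rs)
    fm.meta["roi_id"] = sample_id + ":" + fm.meta["roi_id"].astype(str)
    return fm


def _find_standard_bin(fm: roi.FeatureMatrix, tl: spectra.TargetList,
                       reference_mz: float, window_ppm: float = 50.0) -> str | None:
    """Target bin holding the internal-standard ion, by m/z proximity."""
    t = tl.targets
    ppm = (t["mz_center"] - reference_mz).abs() / reference_mz * 1e6
    cand = t[(ppm <= window_ppm) & t["bin_id"].isin(fm.bin_ids)]
    if cand.empty:
        return None
    return cand.loc[
        (cand["mz_center"] - reference_mz).abs().idxmin(), "bin_id"]


def _normalize(fm: roi.FeatureMatrix, config: RunConfig, log: ProvenanceLog,
               tl: spectra.TargetList | None = None) -> roi.FeatureMatrix:
    mode = config.normalization or (
        "standard" if config.design == "genotype_contrast" else "tic")
    if mode == "standard":
        std_bin = _find_standard_bin(fm, tl, config.lockmass_ref) if tl else None
        if std_bin is None:
            warnings.warn("internal-standard ion not found; falling back to TIC")
            mode = "tic"
        else:
            fm = roi.standard_normalize(fm, std_bin)
            log.record("standard_normalize", {"standard_bin": std_bin})
    if mode == "tic":
        fm = roi.tic_normalize(fm)
        log.record("tic_normalize")
    if config.matrix_filter_enabled:
        fm = roi.matrix_ion_filter(fm)
        log.record("matrix_ion_filter",
                   {"n_excluded": fm.provenance[-1]["n_excluded"]})
    fm = roi.log_scale(fm, config.pseudocount, config.prescale)
    log.record("log_scale", {"pseudocount": config.pseudocount,
                             "prescale": config.prescale})
    return fm


def run_atlas(config: RunConfig) -> dict:
    """Healthy-atlas design: tissue-level differential panels + clustering."""
    if config.design != "atlas":
        raise ValueError("config.design must be 'atlas'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(outdir / "provenance.jsonl")
    log.record("config", config.to_dict())

    ps, rs, truth, spec = _load_or_simulate(config, "WT", "atlas")
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        log.record("simulate", {"seed": config.seed},
                   [outdir / "ground_truth.csv"])
    library = _get_library(config, spec)

    ps = spectra.reduce_peaks(ps, config.top_n, config.min_intensity)
    log.record("reduce_peaks", {"top_n": config.top_n,
                                "min_intensity": config.min_intensity})
    tl = spectra.build_target_list(ps, config.mz_bin, config.drift_bin)
    tl.targets.to_csv(outdir / "targets.csv", index=False)
    log.record("build_target_list", {"mz_bin": config.mz_bin,
                                     "n_targets": len(tl)},
               [outdir / "targets.csv"])
    fm = _feature_block(ps, rs, tl, config, "atlas")
    log.record("extract_features", {"n_rois": len(fm.meta)})
    if config.write_imzml:
        img = spectra.rebin_to_targets(ps, tl, tolerance_da=config.mz_bin)
        spectra.write_imzml(img, outdir / "binned.imzML")
        log.record("write_imzml", outputs=[outdir / "binned.imzML"])

    fm = _normalize(fm, config, log, tl)
    fm.to_csv(outdir / "features.csv")
    log.record("features", outputs=[outdir / "features.csv"])

    tissue_fm = roi.FeatureMatrix(
        fm.meta[fm.meta["kind"] != "matrix"].reset_index(drop=True),
        fm.values[(fm.meta["kind"] != "matrix").to_numpy()].reset_index(drop=True),
        fm.scale,
    )
    n_pc = min(5, len(tissue_fm.values) - 1, len(tissue_fm.bin_ids))
    pca = multivariate.fit_pca(tissue_fm, n_components=n_pc)
    pd.concat([tissue_fm.meta.reset_index(drop=True), pca.scores], axis=1).to_csv(
        outdir / "pca_scores.csv", index=False)
    log.record("fit_pca",
               {"explained_pct": [round(float(v), 3)
                                  for v in pca.explained_variance_pct]},
               [outdir / "pca_scores.csv"])

    panels = []
    contrasts = [(t, "rest") for t in TISSUES if
                 (tissue_fm.meta["tissue"] == t).any()]
    contrasts.append(("growth_plate", "articular_cartilage"))
    for pos, neg in contrasts:
        if neg == "rest":
            groups = np.where(tissue_fm.meta["tissue"] == pos, pos, "rest")
            sub = tissue_fm
        else:
            keep = tissue_fm.meta["tissue"].isin([pos, neg]).to_numpy()
            sub = roi.FeatureMatrix(
                tissue_fm.meta[keep].reset_index(drop=True),
                tissue_fm.values[keep].reset_index(drop=True), tissue_fm.scale)
            groups = sub.meta["tissue"].to_numpy()
        model = multivariate.fit_oplsda(
            sub, groups, group_pos=pos, n_orth=config.n_orth,
            contrast=f"{pos}_vs_{neg}", compute_q2=config.compute_q2)
        model.splot.reset_index().to_csv(
            outdir / f"splot_{pos}_vs_{neg}.csv", index=False)
        panel = multivariate.select_panel(
            model, config.panel_stat, config.panel_threshold)
        panel.to_csv(outdir / f"panel_{pos}_vs_{neg}.csv")
        log.record("oplsda", {"contrast": model.contrast,
                              "r2y": round(model.r2y, 4),
                              "panel_size": len(panel)},
                   [outdir / f"splot_{pos}_vs_{neg}.csv",
                    outdir / f"panel_{pos}_vs_{neg}.csv"])
        panels.append(panel)

    merged = multivariate.merge_panels(panels)
    merged.to_csv(outdir / "panel_merged.csv")
    log.record("merge_panels",
               {"size": len(merged),
                "overlaps": {f"{a}|{b}": n
                             for (a, b), n in merged.overlap.items()}},
               [outdir / "panel_merged.csv"])

    cluster = None
    if len(merged) >= 2:
        cluster = multivariate.hierarchical_cluster(tissue_fm, merged)
        cluster.ordered.to_csv(outdir / "heatmap.csv")
        log.record("hierarchical_cluster",
                   {"metric": cluster.metric, "method": cluster.method},
                   [outdir / "heatmap.csv"])

    kept = set(fm.bin_ids)
    tl_kept = spectra.TargetList(
        tl.targets[tl.targets["bin_id"].isin(kept)].reset_index(drop=True))
    hits = score_tiers(match_ions(tl_kept, library, config.ppm_tolerance), library)
    hits_to_frame(hits).to_csv(outdir / "annotation.csv", index=False)
    log.record("annotate", {"n_hits": len(hits),
                            "ppm": config.ppm_tolerance},
               [outdir / "annotation.csv"])

    return {"feature_matrix": fm, "tissue_fm": tissue_fm, "pca": pca,
            "panels": panels, "merged_panel": merged, "cluster": cluster,
            "hits": hits, "targets": tl, "truth": truth,
            "provenance": log, "outdir": outdir}


def run_genotype_contrast(config: RunConfig) -> dict:
    """KO-vs-WT design: growth-plate OPLS-DA + zone-wise FDR testing."""
    if config.design != "genotype_contrast":
        raise ValueError("config.design must be 'genotype_contrast'")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(outdir / "provenance.jsonl")
    log.record("config", config.to_dict())

    samples = {}
    truths = {}
    spec_for_lib = None
    for i, genotype in enumerate(("WT", "KO")):
        ps, rs, truth, spec = _load_or_simulate(config, genotype, genotype,
                                                seed_offset=i)
        samples[genotype] = (ps, rs)
        if truth is not None:
            truths[genotype] = truth
            spec_for_lib = spec_for_lib or spec
    if truths:
        truths["WT"].to_csv(outdir / "ground_truth.csv", index=False)
        log.record("simulate", {"seed": config.seed},
                   [outdir / "ground_truth.csv"])
    library = _get_library(config, spec_for_lib)

    processed = {}
    for genotype, (ps, rs) in samples.items():
        ps = spectra.reduce_peaks(ps, config.top_n, config.min_intensity)
        if config.lockmass_enabled:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ps = spectra.lock_mass_correct(
                    ps, config.lockmass_ref, config.lockmass_window_ppm)
            log.record("lock_mass_correct",
                       {"sample": genotype,
                        **{k: v for k, v in ps.metadata.get("lockmass", {}).items()
                           if k in ("applied", "ppm_shift")}},
                       warnings_=[str(w.message) for w in caught])
        processed[genotype] = (ps, rs)

    tl = _shared_targets([ps for ps, _ in processed.values()], config)
    tl.targets.to_csv(outdir / "targets.csv", index=False)
    log.record("build_target_list", {"n_targets": len(tl)},
               [outdir / "targets.csv"])

    blocks = [_feature_block(ps, rs, tl, config, genotype)
              for genotype, (ps, rs) in processed.items()]
    fm = roi.concat_features(blocks)
    missing = fm.meta[(fm.meta["kind"] == "lROI")
                      & (fm.meta["tissue"] == "growth_plate")
                      & (fm.meta["zone"] == "")]
    if len(missing):
        raise ValueError(
            f"growth-plate ROIs without zone labels: {missing['roi_id'].tolist()}"
        )
    fm = _normalize(fm, config, log, tl)
    fm.to_csv(outdir / "features.csv")
    log.record("features", outputs=[outdir / "features.csv"])

    gp = fm.meta["tissue"] == "growth_plate"
    gp_fm = roi.FeatureMatrix(
        fm.meta[gp].reset_index(drop=True),
        fm.values[gp.to_numpy()].reset_index(drop=True), fm.scale)

    model = multivariate.fit_oplsda(
        gp_fm, gp_fm.meta["genotype"], group_pos="KO",
        n_orth=config.n_orth, contrast="KO_vs_WT",
        compute_q2=config.compute_q2)
    model.splot.reset_index().to_csv(outdir / "splot_KO_vs_WT.csv", index=False)
    panel = multivariate.select_panel(model, config.panel_stat,
                                      config.panel_threshold)
    panel.to_csv(outdir / "panel_KO_vs_WT.csv")
    log.record("oplsda", {"contrast": "KO_vs_WT", "r2y": round(model.r2y, 4),
                          "panel_size": len(panel)},
               [outdir / "splot_KO_vs_WT.csv", outdir / "panel_KO_vs_WT.csv"])

    results = {}
    up_sets, down_sets = {}, {}
    for zone in diffstats.ZONES:
        res = diffstats.zone_ttest(gp_fm, zone)
        res.to_csv(outdir / f"ttest_{zone}.csv")
        diffstats.volcano_table(res).to_csv(outdir / f"volcano_{zone}.csv",
                                            index=False)
        up, down = diffstats.significant_sets(res, config.q_cut, config.fc_cut)
        results[zone] = res
        up_sets[zone], down_sets[zone] = up, down
        log.record("zone_ttest", {"zone": zone, "n_up": len(up),
                                  "n_down": len(down), "q_cut": config.q_cut},
                   [outdir / f"ttest_{zone}.csv", outdir / f"volcano_{zone}.csv"])

    summary = diffstats.cross_zone_overlap(up_sets, down_sets)
    summary.to_csv(outdir / "zone_membership.csv")
    log.record("cross_zone_overlap",
               {"common_up": len(summary.common_up),
                "common_down": len(summary.common_down)},
               [outdir / "zone_membership.csv"])

    sig_ions = set().union(*up_sets.values(), *down_sets.values())
    tl_sig = spectra.TargetList(
        tl.targets[tl.targets["bin_id"].isin(sig_ions)].reset_index(drop=True))
    hits = score_tiers(match_ions(tl_sig, library, config.ppm_tolerance), library)
    hits_to_frame(hits).to_csv(outdir / "annotation.csv", index=False)
    log.record("annotate", {"n_hits": len(hits)}, [outdir / "annotation.csv"])

    return {"feature_matrix": fm, "gp_fm": gp_fm, "model": model,
            "panel": panel, "zone_results": results, "up_sets": up_sets,
            "down_sets": down_sets, "summary": summary, "hits": hits,
            "targets": tl, "truths": truths, "provenance": log,
            "outdir": outdir}
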