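import numpy as np
import pandas as pd
import pytest

from lipidims import chem, phantom
from lipidims.phantom import (
    GroundTruthLipid, PhantomSpec, REGIONS, default_lipid_panel,
    default_rois, generate_library, generate_phantom, make_phantom_spec,
    simulate_feature_matrix, striped_region_map, truth_to_bins,
)


def _one_lipid_spec(**kwargs):
    """Minimal spec: off-tissue margin + one marrow band, one lipid."""
    rmap = np.full((4, 4), "off_tissue", dtype=object)
    rmap[:, 2:] = "marrow"
    profile = {r: None for r in REGIONS}
    profile["marrow"] = 10.0
    lipid = GroundTruthLipid("LPC (16:0/0:0)", "LPC", profile)
    defaults = dict(
        grid_shape=(4, 4), region_map=rmap, lipid_panel=[lipid],
        sigma_log2=0.0, adduct_profile={"M+H": 1.0}, standard_spec=None,
        mz_jitter_ppm=0.0, seed=3,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestDegenerateCases:
    def test_noise_free_single_adduct_single_peak(self):
        """With one lipid, one region, zero noise and a pure protonated
        profile, every tissue pixel holds exactly one peak at
        neutral mass + proton."""
        spec = _one_lipid_spec()
        ps, truth = generate_phantom(spec)
        expected_mz = chem.lipid_neutral_mass("LPC", 16, 0) + chem.PROTON
        marrow_pixels = [i for i, (r, c) in enumerate(ps.coords) if c >= 2]
        for pix in marrow_pixels:
            peaks = ps.pixel_peaks(pix)
            assert len(peaks) == 1
            assert peaks["mz"].iloc[0] == pytest.approx(expected_mz, abs=1e-9)
            assert peaks["intensity"].iloc[0] == pytest.approx(2.0 ** 10)
        off_pixels = set(range(ps.n_pixels)) - set(marrow_pixels)
        for pix in off_pixels:
            assert len(ps.pixel_peaks(pix)) == 0

    def test_seeded_determinism(self):
        spec_a = make_phantom_spec(seed=7, grid_shape=(16, 16),
                                   panel_kwargs={"n_background": 5})
        spec_b = make_phantom_spec(seed=7, grid_shape=(16, 16),
                                   panel_kwargs={"n_background": 5})
        ps_a, truth_a = generate_phantom(spec_a)
        ps_b, truth_b = generate_phantom(spec_b)
        pd.testing.assert_frame_equal(ps_a.peaks, ps_b.peaks)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_different_seeds_differ(self):
        a, _ = generate_phantom(make_phantom_spec(seed=1, grid_shape=(16, 16)))
        b, _ = generate_phantom(make_phantom_spec(seed=2, grid_shape=(16, 16)))
        assert not a.peaks["intensity"].equals(b.peaks["intensity"])


class TestTruthTable:
    def test_differential_lipid_count_per_zone(self):
        panel, effects = default_lipid_panel(n_ko_up_per_zone=20, seed=0)
        n_diff = sum(1 for lip in panel if lip.diff_zones)
        assert n_diff == 20
        for zone in ("resting", "proliferating", "hypertrophic"):
            assert sum(1 for (name, z) in effects if z == zone) == 20
        assert all(f > 0 for f in effects.values())
        assert all(1.5 <= f <= 3.0 for f in effects.values())

    def test_truth_lists_every_adduct_ion(self):
        spec = make_phantom_spec(seed=0, grid_shape=(16, 16))
        _, truth = generate_phantom(spec)
        base = [a for a in phantom.BASE_ADDUCTS
                if spec.adduct_profile.get(a, 0) > 0]
        per_lipid = truth[~truth["lipid"].str.startswith("MATRIX")
                          & (truth["lipid_class"] != "standard")]
        counts = per_lipid.groupby("lipid").size()
        assert (counts == 2 * len(base)).all()  # base + 13C satellites

    def test_internal_standard_in_every_pixel(self):
        spec = make_phantom_spec(seed=0, grid_shape=(8, 8), sigma_log2=0.0)
        ps, truth = generate_phantom(spec)
        std = ps.peaks[np.isclose(ps.peaks["mz"], phantom.STANDARD_MH_MZ,
                                  atol=1e-6)]
        assert set(std["pixel"]) == set(range(ps.n_pixels))
        np.testing.assert_allclose(std["intensity"],
                                   spec.standard_spec.intensity)


class TestInvariantsAndErrors:
    def test_no_off_tissue_rejected(self):
        rmap = np.full((4, 4), "marrow", dtype=object)
        with pytest.raises(ValueError, match="off_tissue"):
            _one_lipid_spec(region_map=rmap)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            _one_lipid_spec(lipid_panel=[])

    def test_adduct_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _one_lipid_spec(adduct_profile={"M+H": 0.5, "M+Na": 0.2})

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError, match="effect_table"):
            _one_lipid_spec(effect_table={("LPC (16:0/0:0)", "resting"): 0.0})

    def test_matrix_species_must_peak_off_tissue(self):
        profile = {r: 10.0 for r in REGIONS}
        with pytest.raises(ValueError, match="off_tissue"):
            GroundTruthLipid("MATRIX_X", "matrix", profile,
                             neutral_mass=200.0, is_matrix=True)

    def test_region_profile_must_cover_regions(self):
        with pytest.raises(ValueError, match="region_profile"):
            GroundTruthLipid("PC (34:1)", "PC", {"marrow": 1.0})


class TestFidelity:
    def test_genotype_effect_recovered_at_zero_noise(self):
        """The KO/WT mean-intensity ratio of a planted differential ion
        equals its effect-table fold when noise is off."""
        kwargs = dict(grid_shape=(32, 32), sigma_log2=0.0,
                      panel_kwargs={"n_ko_up_per_zone": 5, "seed": 1},
                      adduct_profile={"M+H": 1.0})
        wt, _ = generate_phantom(make_phantom_spec("WT", seed=5, **kwargs))
        ko, truth = generate_phantom(make_phantom_spec("KO", seed=5, **kwargs))
        spec = make_phantom_spec("KO", seed=5, **kwargs)
        region = striped_region_map((32, 32))
        flat = region.ravel()
        diff = truth[(truth["diff_zones"] != "")
                     & (truth["adduct"] == "M+H")].iloc[0]
        for zone_region, zone in phantom.GP_ZONES.items():
            pixels = np.nonzero(flat == zone_region)[0]
            fold = spec.effect_table[(diff["lipid"], zone)]
            ratios = []
            for ps in (wt, ko):
                sub = ps.peaks[np.isclose(ps.peaks["mz"],
                                          diff["theoretical_mz"], atol=1e-6)
                               & ps.peaks["pixel"].isin(pixels)]
                ratios.append(sub["intensity"].mean())
            assert ratios[1] / ratios[0] == pytest.approx(fold, rel=1e-9)

    def test_home_region_has_highest_mean_at_zero_noise(self):
        spec = make_phantom_spec("WT", seed=2, grid_shape=(32, 32),
                                 sigma_log2=0.0,
                                 adduct_profile={"M+H": 1.0})
        ps, truth = generate_phantom(spec)
        flat = spec.region_map.ravel()
        gp_lipid = truth[(truth["home_region"] == "gp_resting")
                         & (truth["adduct"] == "M+H")].iloc[0]
        peaks = ps.peaks[np.isclose(ps.peaks["mz"], gp_lipid["theoretical_mz"],
                                    atol=1e-6)]
        means = {}
        for region in set(flat) - {"off_tissue"}:
            pixels = np.nonzero(flat == region)[0]
            sub = peaks[peaks["pixel"].isin(pixels)]
            means[region] = sub["intensity"].mean() if len(sub) else 0.0
        best = max(means, key=means.get)
        assert phantom.TISSUE_OF_REGION[best] == "growth_plate"


class TestLibrary:
    def test_no_decoys_matches_panel(self):
        spec = make_phantom_spec(seed=0, grid_shape=(16, 16))
        lib = generate_library(spec, decoys=0)
        n_lipids = sum(1 for l in spec.lipid_panel if not l.is_matrix)
        assert len(lib) == n_lipids + 1  # + internal standard

    def test_decoys_respect_ppm_margin(self):
        spec = make_phantom_spec(seed=0, grid_shape=(16, 16))
        lib = generate_library(spec, decoys=50)
        truth_mz = [chem.adduct_mz(l.neutral_mass, a)
                    for l in spec.lipid_panel if not l.is_matrix
                    for a in chem.ADDUCT_DELTAS]
        decoy_mz = [chem.adduct_mz(r.neutral_mass, a)
                    for r in lib if r.name.startswith("DECOY")
                    for a in chem.ADDUCT_DELTAS]
        assert len([r for r in lib if r.name.startswith("DECOY")]) == 50
        for dm in decoy_mz:  # brute-force all-pairs check
            for tm in truth_mz:
                assert abs(dm - tm) / dm * 1e6 >= 150

    def test_odd_chain_flag_carried(self):
        rec = [r for r in generate_library(
            make_phantom_spec(seed=0, grid_shape=(16, 16)), decoys=0)
            if r.name == phantom.STANDARD_NAME][0]
        assert rec.parsed.odd_chain  # 15 + 18 = 33 carbons

    def test_library_csv_round_trip(self, tmp_path):
        from lipidims.annotation import LipidLibrary

        spec = make_phantom_spec(seed=0, grid_shape=(16, 16))
        lib = generate_library(spec, decoys=5)
        path = tmp_path / "lib.csv"
        lib.to_csv(path)
        back = LipidLibrary.from_csv(path)
        assert len(back) == len(lib)
        for a, b in zip(lib, back):
            assert a.name == b.name
            assert a.neutral_mass == pytest.approx(b.neutral_mass, abs=1e-5)
            assert a.manual_id == b.manual_id


class TestRois:
    def test_default_layout_valid(self, small_spec):
        rs = default_rois(small_spec)
        kinds = rs.table.groupby("roi_id")["kind"].first()
        assert (kinds == "matrix").sum() == 3
        sizes = rs.table.groupby("roi_id").size()
        assert (sizes[kinds[sizes.index] != "sROI"] == 10).all()

    def test_zone_labels_on_growth_plate(self, small_spec):
        rs = default_rois(small_spec)
        gp = rs.table[rs.table["tissue"] == "growth_plate"]
        assert set(gp["zone"]) == {"resting", "proliferating", "hypertrophic"}


class TestTruthToBins:
    def test_maps_ions_to_nearest_targets(self, small_spec):
        from lipidims import spectra

        ps, truth = generate_phantom(small_spec)
        tl = spectra.build_target_list(ps, 0.04)
        mapped = truth_to_bins(truth, tl)
        hit = mapped[mapped["bin_id"] != ""]
        assert len(hit) == len(mapped)  # zero jitter: everything lands
        centers = tl.targets.set_index("bin_id")["mz_center"]
        err = (mapped["theoretical_mz"].to_numpy()
               - centers[mapped["bin_id"]].to_numpy())
        assert np.abs(err).max() <= 0.04


class TestFeatureFastPath:
    def test_shapes_and_truth(self):
        fm, truth = simulate_feature_matrix(
            n_ions=50, n_rois_per_group=4, n_effect_ions=5, seed=0)
        assert fm.scale == "log2"
        assert fm.values.shape == (4 * 2 * 3, 50)
        assert all(len(truth[z]) == 5 for z in truth)

    def test_effect_direction(self):
        fm, truth = simulate_feature_matrix(
            n_ions=20, n_rois_per_group=6, n_effect_ions=3,
            sigma_log2=0.01, seed=1)
        ko = fm.values[(fm.meta["genotype"] == "KO").to_numpy()]
        wt = fm.values[(fm.meta["genotype"] == "WT").to_numpy()]
        diff = ko.mean() - wt.mean()
        planted = sorted(truth["resting"])
        assert (diff[planted] > 0.4).all()
        assert np.abs(diff.drop(planted)).max() < 0.1
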