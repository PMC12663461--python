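import numpy as np
import pytest

from asymdiv.composition import (
    assign_zone,
    cargo_metrics,
    classify_composition,
    division_orientation,
    nuclei_s_edges,
    registration_from_nuclei,
    segment_endosomes,
    segment_nuclei,
)
from asymdiv.errors import AsymdivError, DegenerateGeometryError
from asymdiv.io_core import max_intensity_projection
from asymdiv.pipeline import analyze_fixed_cell
from asymdiv.synthetic import FixedCellSpec, simulate_fixed_cell


def noiseless(zone_counts, **kw):
    spec = FixedCellSpec(zone_counts=zone_counts, poisson_noise=False,
                         read_noise_sigma=0.0, **kw)
    return spec, *simulate_fixed_cell(spec, seed=7)


class TestSegmentNuclei:
    def test_centroids_match_truth(self):
        spec, movie, truth = noiseless({})
        dapi = max_intensity_projection(movie, "DAPI")[0]
        masks = segment_nuclei(dapi, spec.ap_direction)
        px = np.array(movie.voxel_size[1:])
        for mask, center in zip(masks, truth.nucleus_centers_um):
            centroid = np.argwhere(mask).mean(axis=0) * px
            assert np.linalg.norm(centroid - center) < 0.5

    def test_single_nucleus_is_an_error(self, rng):
        yy, xx = np.indices((64, 64))
        one = 100 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 40.0)
        with pytest.raises(AsymdivError):
            segment_nuclei(one, (0, 1))

    def test_empty_dapi_is_an_error(self):
        with pytest.raises(AsymdivError):
            segment_nuclei(np.zeros((32, 32)), (0, 1))


class TestSegmentEndosomes:
    def test_blank_image_has_no_labels(self):
        labels = segment_endosomes(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_blob_count_and_areas_recovered(self):
        spec, movie, truth = noiseless({"central": {(): 6}, "posterior_surround": {(): 4}})
        ref = max_intensity_projection(movie, "Dld")[0]
        labels = segment_endosomes(ref)
        assert labels.max() == 10
        px_area = movie.voxel_size[1] * movie.voxel_size[2]
        areas = sorted(np.bincount(labels.ravel())[1:] * px_area)
        true_area = truth.blobs[0].area_um2
        for a in areas:
            assert abs(a - true_area) / true_area < 0.2

    def test_touching_blobs_merge_into_one_label(self):
        yy, xx = np.indices((64, 64))
        img = (np.hypot(yy - 32, xx - 30) < 4) * 200.0 + (np.hypot(yy - 32, xx - 36) < 4) * 200.0
        labels = segment_endosomes(img)
        assert labels.max() == 1

    def test_constant_image_rejected(self):
        with pytest.raises(AsymdivError):
            segment_endosomes(np.full((32, 32), 180.0))


class TestZones:
    def test_zone_assignment_from_geometry(self):
        spec, movie, truth = noiseless({})
        dapi = max_intensity_projection(movie, "DAPI")[0]
        masks = segment_nuclei(dapi, spec.ap_direction)
        px = movie.voxel_size[1:]
        reg = registration_from_nuclei(masks, px)
        edges = nuclei_s_edges(masks, reg, px)
        center = truth.center_um
        u = truth.axis_unit
        assert assign_zone(center, reg, edges) == "central"
        assert assign_zone(center - 6.0 * u, reg, edges) == "anterior_surround"
        assert assign_zone(center + 6.0 * u, reg, edges) == "posterior_surround"

    def test_overlapping_nuclei_are_an_error(self):
        masks = (np.zeros((40, 40), bool), np.zeros((40, 40), bool))
        masks[0][10:30, 5:25] = True
        masks[1][10:30, 15:35] = True
        reg = registration_from_nuclei(masks, (0.2, 0.2))
        with pytest.raises(DegenerateGeometryError):
            nuclei_s_edges(masks, reg, (0.2, 0.2))

    def test_simulated_scene_zones_fully_recovered(self, mixed_fixed_scene):
        spec, movie, truth = mixed_fixed_scene
        res = analyze_fixed_cell(movie, spec.ap_direction)
        # match records to truth blobs by centroid
        for blob in truth.blobs:
            rec = min(res.records,
                      key=lambda r: np.linalg.norm(r.centroid_um - blob.position_um))
            assert rec.zone == blob.zone


class TestComposition:
    def test_blob_in_all_channels_is_both(self):
        labels = np.zeros((20, 20), int)
        labels[5:9, 5:9] = 1
        strong = np.where(labels == 1, 100.0, 0.0)
        recs = classify_composition(labels, {"Par3": strong, "Dlic1": strong},
                                    {"Par3": 10.0, "Dlic1": 10.0})
        assert recs[0].combo == ("Par3", "Dlic1")

    def test_single_marker_blob(self):
        labels = np.zeros((20, 20), int)
        labels[5:9, 5:9] = 1
        strong = np.where(labels == 1, 100.0, 0.0)
        recs = classify_composition(labels, {"Par3": strong, "Dlic1": np.zeros((20, 20))},
                                    {"Par3": 10.0, "Dlic1": 10.0})
        assert recs[0].combo == ("Par3",)
        assert recs[0].presence == {"Par3": True, "Dlic1": False}

    def test_mixed_scene_recovers_spec_table(self):
        spec, movie, truth = noiseless(
            {"central": {("Par3",): 3, ("Dlic1",): 2, ("Par3", "Dlic1"): 5}})
        res = analyze_fixed_cell(movie, spec.ap_direction)
        combos = [r.combo for r in res.records]
        assert len(combos) == 10
        assert combos.count(("Par3",)) == 3
        assert combos.count(("Dlic1",)) == 2
        assert combos.count(("Par3", "Dlic1")) == 5

    def test_categories_partition_endosomes(self, mixed_fixed_scene):
        spec, movie, _ = mixed_fixed_scene
        res = analyze_fixed_cell(movie, spec.ap_direction)
        assert res.table["count"].sum() == len(res.records)
        per_zone = res.table.groupby("zone")["count"].sum()
        zones = [r.zone for r in res.records]
        for zone, total in per_zone.items():
            assert total == zones.count(zone)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_composition(np.zeros((4, 4), int), {"m": np.zeros((5, 5))}, {"m": 1.0})


class TestCargoMetrics:
    def setup_method(self):
        self.fp = np.zeros((20, 20), bool)
        self.fp[4:10, 4:10] = True
        self.dapi = np.full((20, 20), 50.0)
        self.dapi_mask = np.ones((20, 20), bool)

    def test_full_coverage_gives_fraction_one(self):
        cargo = np.where(self.fp, 80.0, 0.0)
        norm, fr = cargo_metrics(self.fp, cargo, 10.0, self.dapi, self.dapi_mask,
                                 {"Par3": self.fp})
        assert fr["Par3"] == 1.0

    def test_no_cargo_gives_zeros(self):
        norm, fr = cargo_metrics(self.fp, np.zeros((20, 20)), 10.0, self.dapi,
                                 self.dapi_mask, {"Par3": self.fp})
        assert norm == 0.0
        assert fr["Par3"] == 0.0

    def test_half_coverage(self):
        cargo = np.zeros((20, 20))
        cargo[4:7, 4:10] = 80.0  # upper half of the 6x6 footprint
        _, fr = cargo_metrics(self.fp, cargo, 10.0, self.dapi, self.dapi_mask,
                              {"Par3": self.fp})
        assert fr["Par3"] == pytest.approx(0.5)

    def test_dapi_normalization(self):
        cargo = np.where(self.fp, 100.0, 0.0)
        norm, _ = cargo_metrics(self.fp, cargo, 10.0, self.dapi, self.dapi_mask,
                                {"Par3": self.fp})
        assert norm == pytest.approx(2.0)  # 100 / 50

    def test_zero_dapi_is_an_error(self):
        with pytest.raises(AsymdivError):
            cargo_metrics(self.fp, np.ones((20, 20)), 0.5, np.zeros((20, 20)),
                          self.dapi_mask, {"Par3": self.fp})


class TestDivisionOrientation:
    @pytest.mark.parametrize("n1,n2,angle,cls", [
        ((0, 0, 1), (0, 0, 1), 90.0, "60-90"),   # parallel normals
        ((0, 0, 1), (0, 1, 0), 0.0, "0-30"),     # orthogonal normals
        ((0, 0, 1), (0, 1, 1), 45.0, "30-60"),   # 45 degrees
    ])
    def test_geometry_and_classes(self, n1, n2, angle, cls):
        a, c = division_orientation(n1, n2)
        assert a == pytest.approx(angle, abs=1e-9)
        assert c == cls

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            division_orientation((0, 0, 0), (0, 0, 1))
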