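"""Segmentation, zone geometry, event detection and per-cell quantification."""

import numpy as np
import pandas as pd
import pytest

from synapse_capture import simulate
from synapse_capture.simulate import SimulationConfig
from synapse_capture.synapse import (
    SynapseFrame,
    colocalize_clusters,
    detect_unquenching_events,
    discrimination_ratio,
    extraction_efficiency,
    extraction_kinetics,
    partition_zones,
    quantify_synapse,
    segment_cell,
)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def disk_synapse(radius_px=60, pad=10, pixel_size=1.0):
    size = 2 * (radius_px + pad)
    c = size // 2
    mask = disk_mask((size, size), (c, c), radius_px)
    return SynapseFrame(
        frame=0, mask=mask, centroid_um=(c * pixel_size, c * pixel_size), pixel_size=pixel_size
    )


class TestSegmentCell:
    def test_uniform_disk_area_and_centroid(self):
        img = np.zeros((128, 128))
        truth_mask = disk_mask(img.shape, (64, 64), 25)
        img[truth_mask] = 100.0
        seg = segment_cell(img, pixel_size=0.2)
        assert seg is not None
        true_area = truth_mask.sum() * 0.2**2
        assert seg.area_um2 == pytest.approx(true_area, rel=0.02)
        assert abs(seg.centroid_um[0] / 0.2 - 64) < 1
        assert abs(seg.centroid_um[1] / 0.2 - 64) < 1

    def test_blank_frame_gives_no_cell(self):
        assert segment_cell(np.zeros((64, 64)), pixel_size=0.2) is None

    def test_noisy_cell_area_within_five_percent(self):
        rng = np.random.default_rng(0)
        img = np.full((128, 128), 100.0)
        truth_mask = disk_mask(img.shape, (64, 64), 30)
        img[truth_mask] += 5 * np.sqrt(100)  # SNR 5 over Poisson background
        img = rng.poisson(img).astype(float)
        seg = segment_cell(img, pixel_size=0.2)
        assert seg is not None
        assert seg.area_um2 == pytest.approx(truth_mask.sum() * 0.04, rel=0.05)

    def test_small_component_below_min_area_rejected(self):
        img = np.zeros((64, 64))
        img[30:32, 30:32] = 100.0
        assert segment_cell(img, pixel_size=0.2, min_area_um2=10.0) is None

    def test_contact_time_is_first_frame_with_a_cell(self):
        from synapse_capture.io import MovieStack
        from synapse_capture.synapse import find_contact_time

        frames = np.zeros((5, 64, 64))
        frames[3:][:, disk_mask((64, 64), (32, 32), 20)] = 100.0
        movie = MovieStack(pixels=frames, pixel_size=0.3, frame_interval=8.0)
        assert find_contact_time(movie) == pytest.approx(24.0)
        blank = MovieStack(pixels=np.zeros((3, 64, 64)), pixel_size=0.3, frame_interval=8.0)
        assert find_contact_time(blank) is None


class TestPartitionZones:
    def test_half_radius_is_peripheral(self):
        syn = disk_synapse(radius_px=60)
        cx, cy = syn.centroid_um
        norm, zone = partition_zones(syn, (cx + 30.0, cy))
        assert zone == "peripheral"
        assert norm == pytest.approx(0.5, abs=0.02)

    def test_centroid_is_central(self):
        syn = disk_synapse()
        assert partition_zones(syn, syn.centroid_um) == (0.0, "central")

    def test_boundary_thirds_are_half_open(self):
        # a normalized distance of exactly 1/3 (2/3) falls in the outer zone
        assert simulate.zone_of(1 / 3) == "peripheral"
        assert simulate.zone_of(2 / 3) == "distal"
        assert simulate.zone_of(np.nextafter(1 / 3, 0)) == "central"
        syn = disk_synapse(radius_px=60)
        cx, cy = syn.centroid_um
        assert partition_zones(syn, (cx + 25.0, cy))[1] == "peripheral"
        assert partition_zones(syn, (cx + 45.0, cy))[1] == "distal"

    def test_point_outside_mask_rejected(self):
        syn = disk_synapse(radius_px=20, pad=30)
        cx, cy = syn.centroid_um
        with pytest.raises(ValueError):
            partition_zones(syn, (cx + 45.0, cy))

    def test_uniform_disk_zone_fractions_one_three_five(self):
        """Equal-width annuli cover 1/9, 3/9 and 5/9 of the disk area."""
        syn = disk_synapse(radius_px=60)
        cx, cy = syn.centroid_um
        rng = np.random.default_rng(1)
        n = 4000
        r = np.sqrt(rng.uniform(0, 1, n)) * 59.0
        theta = rng.uniform(0, 2 * np.pi, n)
        zones = [
            partition_zones(syn, (cx + ri * np.cos(ti), cy + ri * np.sin(ti)))[1]
            for ri, ti in zip(r, theta)
        ]
        counts = pd.Series(zones).value_counts(normalize=True)
        # sampled radius 59/60 of the boundary: expected fractions scale by (60/59)^2
        scale = (60.0 / 59.0) ** 2
        for zone, frac in (("central", 1 / 9), ("peripheral", 3 / 9), ("distal", 1.0)):
            expected = frac * scale if zone != "distal" else 1 - 4 / 9 * scale
            ci = 3 * np.sqrt(expected * (1 - expected) / n)
            assert abs(counts[zone] - expected) < ci + 0.01


class TestUnquenchingEvents:
    @staticmethod
    def movie_with_spot(start_frame, n_frames=10, end_frame=None):
        config = SimulationConfig(
            seed=0, duration=n_frames, fov_px=48, noise_model="none", background=100.0,
            pixel_size=1.0, psf_sigma=1.3,
        )
        emitters = pd.DataFrame(
            {
                "x_um": [24.0],
                "y_um": [24.0],
                "intensity": [5000.0],
                "start_frame": [start_frame],
                "end_frame": [end_frame if end_frame is not None else n_frames],
            }
        )
        movie, _ = simulate.render_movie(emitters, config)
        return movie

    def test_preexisting_spot_is_not_an_event(self):
        movie = self.movie_with_spot(start_frame=0)
        assert detect_unquenching_events(movie, psf_sigma_px=1.3) == []

    def test_single_frame_blink_rejected(self):
        movie = self.movie_with_spot(start_frame=4, end_frame=5)
        assert detect_unquenching_events(movie, psf_sigma_px=1.3, min_persist_frames=3) == []

    def test_appearing_persistent_spot_is_an_event(self):
        movie = self.movie_with_spot(start_frame=4)
        events = detect_unquenching_events(movie, psf_sigma_px=1.3)
        assert len(events) == 1
        assert events[0].frame == 4
        assert events[0].onset_time == pytest.approx(4 * movie.frame_interval)

    def test_synthetic_experiment_detection_quality(self):
        """Precision/recall >= 0.9 and onsets within one frame on rendered movies."""
        config = SimulationConfig(seed=17, duration=30, fov_px=96)
        movies, truth = simulate.simulate_extraction_experiment(
            n_cells=3, config=config, waiting_time_mean=25.0
        )
        sig = config.psf_sigma / config.pixel_size
        detected = []
        for cid, pair in enumerate(movies):
            detected += detect_unquenching_events(
                pair["internalized"], cell_id=cid, psf_sigma_px=sig
            )
        truth_df = truth.events[truth.events["frame"] <= config.duration - 3]
        matched = onset_ok = 0
        for e in detected:
            cand = truth_df[truth_df["cell_id"] == e.cell_id]
            if not len(cand):
                continue
            d = np.hypot(cand["x_um"] - e.x_um, cand["y_um"] - e.y_um)
            if d.min() < 0.5:
                matched += 1
                onset_ok += int(abs(cand.iloc[int(np.argmin(d.values))]["frame"] - e.frame) <= 1)
        assert len(detected) > 0 and len(truth_df) > 0
        assert matched / len(detected) >= 0.9
        assert matched / len(truth_df) >= 0.9
        assert onset_ok / matched >= 0.9


class TestQuantifySynapse:
    def test_uniform_intensity_mean_and_total(self):
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True  # 100 px
        syn = SynapseFrame(frame=0, mask=mask, centroid_um=(15.0, 15.0), pixel_size=1.0)
        img = np.zeros((40, 40))
        img[mask] = 10.0
        m = quantify_synapse({"antigen": img}, syn)
        assert m.mean_intensity["antigen"] == pytest.approx(10.0)
        assert m.total_intensity["antigen"] == pytest.approx(1000.0)

    def test_empty_channel_zero_everything(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:25] = True
        syn = SynapseFrame(frame=0, mask=mask, centroid_um=(15.0, 15.0), pixel_size=1.0)
        m = quantify_synapse({"c": np.zeros((40, 40))}, syn, cluster_channel="c")
        assert m.mean_intensity["c"] == 0.0
        assert m.total_intensity["c"] == 0.0
        assert len(m.cluster_table) == 0

    def test_rendered_cluster_intensity_recovered(self):
        config = SimulationConfig(
            seed=0, duration=1, fov_px=64, noise_model="none", background=50.0,
            pixel_size=1.0, psf_sigma=1.5,
        )
        emitters = pd.DataFrame({"x_um": [32.0], "y_um": [32.0], "intensity": [20000.0]})
        movie, _ = simulate.render_movie(emitters, config)
        mask = disk_mask((64, 64), (32, 32), 25)
        syn = SynapseFrame(frame=0, mask=mask, centroid_um=(32.0, 32.0), pixel_size=1.0)
        m = quantify_synapse({"int": movie.pixels[0]}, syn, cluster_channel="int")
        assert len(m.cluster_table) == 1
        assert m.cluster_table["total_intensity"].iloc[0] == pytest.approx(20000.0, rel=0.05)

    def test_shape_mismatch_rejected(self):
        mask = np.ones((10, 10), bool)
        syn = SynapseFrame(frame=0, mask=mask, centroid_um=(5.0, 5.0), pixel_size=1.0)
        with pytest.raises(ValueError):
            quantify_synapse({"c": np.zeros((5, 5))}, syn)


class TestEfficiencyAndKinetics:
    def test_efficiency_simple_ratios(self):
        assert extraction_efficiency(0.0, 100.0) == 0.0
        assert extraction_efficiency(100.0, 100.0) == 1.0
        assert np.isnan(extraction_efficiency(10.0, 0.0))

    def test_time_to_first_is_minimum_onset(self):
        events = pd.DataFrame({"cell_id": [0, 0, 0], "onset_time_s": [120.0, 74.0, 300.0]})
        per_cell, frac = extraction_kinetics(events, [0])
        assert per_cell["time_to_first_s"].iloc[0] == 74.0
        assert frac == 1.0

    def test_eventless_cell_counts_in_denominator(self):
        events = pd.DataFrame({"cell_id": [0], "onset_time_s": [100.0]})
        per_cell, frac = extraction_kinetics(events, [0, 1])
        assert np.isnan(per_cell["time_to_first_s"].iloc[1])
        assert frac == 0.5

    def test_exponential_cohort_fraction_matches_cdf(self):
        rng = np.random.default_rng(4)
        mean = 74.0
        firsts = rng.exponential(mean, size=100)
        events = pd.DataFrame(
            {"cell_id": np.arange(100), "onset_time_s": firsts}
        )
        _, frac = extraction_kinetics(events, list(range(100)))
        expected = 1 - np.exp(-300.0 / mean)
        se = np.sqrt(expected * (1 - expected) / 100)
        assert abs(frac - expected) < 3 * se


class TestColocalization:
    def test_zero_marker_zero_percent(self):
        labels = np.zeros((20, 20), int)
        labels[2:4, 2:4] = 1
        labels[10:12, 10:12] = 2
        res = colocalize_clusters(labels, np.zeros((20, 20)), threshold=5.0)
        assert res.percent_positive == 0.0

    def test_bright_marker_full_percent(self):
        labels = np.zeros((20, 20), int)
        labels[2:4, 2:4] = 1
        res = colocalize_clusters(labels, np.full((20, 20), 100.0), threshold=5.0)
        assert res.percent_positive == 100.0

    def test_partial_positivity_recovered(self):
        rng = np.random.default_rng(6)
        labels = np.zeros((60, 60), int)
        marker = rng.normal(10.0, 1.0, size=(60, 60))
        positives = 0
        for cid in range(25):
            r, c = 2 + 11 * (cid % 5), 2 + 11 * (cid // 5)
            labels[r : r + 3, c : c + 3] = cid + 1
            if cid < 5:  # 20 % marker-positive
                marker[r : r + 3, c : c + 3] += 50.0
                positives += 1
        res = colocalize_clusters(labels, marker)
        assert res.percent_positive == pytest.approx(100.0 * positives / 25, abs=4.0)

    def test_no_clusters_flagged(self):
        res = colocalize_clusters(np.zeros((10, 10), int), np.zeros((10, 10)))
        assert np.isnan(res.percent_positive)
        assert "no_clusters" in res.flags


class TestDiscriminationRatio:
    @staticmethod
    def cohort(means_by_exp, n_cells=30, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for exp, mu in means_by_exp.items():
            for _ in range(n_cells):
                rows.append({"experiment_id": exp, "value": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_identical_cohorts_ratio_one(self):
        c = self.cohort({"e1": 5.0, "e2": 7.0})
        mean, _, _ = discrimination_ratio(c, c)
        assert mean == pytest.approx(1.0)

    def test_exact_double_ratio_two(self):
        lo = self.cohort({"e1": 5.0, "e2": 7.0})
        hi = lo.assign(value=lo["value"] * 2)
        mean, _, table = discrimination_ratio(hi, lo)
        assert mean == pytest.approx(2.0)
        assert np.allclose(table["ratio"], 2.0)

    def test_noisy_three_to_one_recovered(self):
        hi = self.cohort({"e1": 9.0, "e2": 9.0, "e3": 9.0}, sd=1.0, seed=1)
        lo = self.cohort({"e1": 3.0, "e2": 3.0, "e3": 3.0}, sd=1.0, seed=2)
        mean, sem, _ = discrimination_ratio(hi, lo)
        assert mean == pytest.approx(3.0, rel=0.1)
        assert sem > 0

    def test_empty_cohort_rejected(self):
        c = self.cohort({"e1": 1.0})
        with pytest.raises(ValueError):
            discrimination_ratio(c, c.iloc[0:0])
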