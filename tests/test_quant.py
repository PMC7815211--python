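"""Fluorescence operators, colocalization, morphometry, tracks, adhesion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuemech import quant as qnt
from tissuemech import synthetic as syn


def _square_cell(cluster_centers=(), cluster_value=200.0, cytoplasm_value=20.0, **kw):
    return syn.render_cell_image(
        syn.CellImageSpec(
            shape_px=(128, 128),
            cell_polygon=[(20, 20), (20, 108), (108, 108), (108, 20)],
            cluster_centers=cluster_centers,
            cluster_value=cluster_value,
            cytoplasm_value=cytoplasm_value,
            **kw,
        )
    )


class TestClusterFraction:
    def test_uniform_ventral_signal_gives_zero(self):
        img = _square_cell()
        with pytest.warns(UserWarning, match="empty cluster mask"):
            assert qnt.cluster_fraction(img, cluster_mask=img.masks["clusters"]) == 0.0

    def test_all_signal_in_clusters_gives_one(self):
        img = _square_cell(cluster_centers=[(50, 50), (80, 70)], cytoplasm_value=0.0)
        frac = qnt.cluster_fraction(img, cluster_mask=img.masks["clusters"])
        assert frac == pytest.approx(1.0)

    def test_programmed_share_recovered_with_ground_truth_mask(self):
        img = _square_cell(cluster_centers=[(40, 40), (60, 80), (90, 50)])
        sig = img.channels["signal"]
        clusters, ventral = img.masks["clusters"], img.masks["ventral"]
        programmed = sig[clusters].sum() / sig[ventral].sum()
        measured = qnt.cluster_fraction(img, cluster_mask=clusters)
        assert measured == pytest.approx(programmed, rel=1e-12)

    def test_mad_threshold_recovers_share_within_5_percent(self):
        shares = []
        for seed in range(20):
            img = _square_cell(
                cluster_centers=[(40, 40), (60, 80), (90, 50), (30, 90)],
                noise_model="gaussian",
                noise_sd=2.0,
                seed=seed,
            )
            noiseless = _square_cell(cluster_centers=[(40, 40), (60, 80), (90, 50), (30, 90)])
            sig = noiseless.channels["signal"]
            programmed = sig[noiseless.masks["clusters"]].sum() / sig[noiseless.masks["ventral"]].sum()
            measured = qnt.cluster_fraction(img)
            shares.append(abs(measured - programmed) / programmed)
        assert np.mean(shares) < 0.05

    def test_invariant_to_intensity_scaling(self):
        img = _square_cell(cluster_centers=[(40, 40), (70, 70)])
        f1 = qnt.cluster_fraction(img)
        scaled = syn.QuantImage(
            channels={"signal": img.channels["signal"] * 3.7},
            pixel_size_um=img.pixel_size_um,
            masks=img.masks,
        )
        assert qnt.cluster_fraction(scaled) == pytest.approx(f1, rel=1e-9)

    def test_empty_ventral_mask_errors(self):
        img = _square_cell()
        with pytest.raises(ValueError, match="ventral"):
            qnt.cluster_fraction(img, ventral_mask=np.zeros((128, 128), bool))


class TestLineScanRatios:
    @pytest.fixture
    def membrane_cell(self):
        return syn.render_cell_image(
            syn.CellImageSpec(
                shape_px=(96, 96),
                pixel_size_um=1.0,
                cell_polygon=[(10, 10), (10, 85), (85, 85), (85, 10)],
                cytoplasm_value=20.0,
                membrane_value=100.0,
                free_edge_segments=[[(10, 10), (10, 85)]],
                contact_segments=[[(85, 10), (85, 85)]],
            )
        )

    def test_uniform_image_ratio_one(self):
        img = syn.QuantImage(channels={"signal": np.full((64, 64), 37.0)}, pixel_size_um=1.0)
        r = qnt.cortical_ratio(
            img,
            qnt.LineScan(((10, 5), (10, 60)), "free_edge"),
            qnt.LineScan(((40, 5), (40, 60)), "cytoplasm"),
        )
        assert r == pytest.approx(1.0)

    def test_membrane_over_cytoplasm_five(self, membrane_cell):
        r = qnt.cortical_ratio(
            membrane_cell,
            qnt.LineScan(((10, 20), (10, 75)), "free_edge"),
            qnt.LineScan(((47, 20), (47, 75)), "cytoplasm"),
        )
        assert r == pytest.approx(5.0, rel=1e-9)

    def test_background_constant_invariance(self, membrane_cell):
        edge = qnt.LineScan(((10, 20), (10, 75)), "free_edge")
        cyto = qnt.LineScan(((47, 20), (47, 75)), "cytoplasm")
        r0 = qnt.cortical_ratio(membrane_cell, edge, cyto)
        shifted = syn.QuantImage(
            channels={"signal": membrane_cell.channels["signal"] + 50.0},
            pixel_size_um=1.0,
        )
        assert qnt.cortical_ratio(shifted, edge, cyto, background=50.0) == pytest.approx(r0)

    def test_zero_cytoplasm_flagged(self, membrane_cell):
        edge = qnt.LineScan(((10, 20), (10, 75)), "free_edge")
        cyto = qnt.LineScan(((47, 20), (47, 75)), "cytoplasm")
        with pytest.warns(UserWarning, match="cytoplasm"):
            assert np.isnan(qnt.cortical_ratio(membrane_cell, edge, cyto, background=20.0))

    def test_contact_enrichment_unpolarized_marker(self):
        # contact carries two apposed membranes = 2x the free-edge intensity
        img = syn.QuantImage(channels={"signal": np.zeros((64, 64))}, pixel_size_um=1.0)
        img.channels["signal"][10:13, :] = 100.0  # free edge
        img.channels["signal"][40:43, :] = 200.0  # contact
        res = qnt.contact_enrichment(
            img,
            qnt.LineScan(((41, 5), (41, 58)), "contact"),
            qnt.LineScan(((11, 5), (11, 58)), "free_edge"),
        )
        assert res.ratio == pytest.approx(1.0, rel=1e-9)
        assert res.raw_ratio == pytest.approx(2.0, rel=1e-9)

    def test_contact_enrichment_uniform_intensity_half(self):
        img = syn.QuantImage(channels={"signal": np.full((64, 64), 80.0)}, pixel_size_um=1.0)
        res = qnt.contact_enrichment(
            img,
            qnt.LineScan(((40, 5), (40, 58)), "contact"),
            qnt.LineScan(((10, 5), (10, 58)), "free_edge"),
        )
        assert res.ratio == pytest.approx(0.5)

    def test_fourfold_contact_gives_two(self):
        img = syn.QuantImage(channels={"signal": np.zeros((64, 64))}, pixel_size_um=1.0)
        img.channels["signal"][10:13, :] = 50.0
        img.channels["signal"][40:43, :] = 200.0
        res = qnt.contact_enrichment(
            img,
            qnt.LineScan(((41, 5), (41, 58)), "contact"),
            qnt.LineScan(((11, 5), (11, 58)), "free_edge"),
        )
        assert res.ratio == pytest.approx(2.0, rel=1e-9)

    def test_scan_outside_image_errors(self):
        img = syn.QuantImage(channels={"signal": np.zeros((32, 32))}, pixel_size_um=1.0)
        with pytest.raises(ValueError, match="outside"):
            qnt.scan_mean(img, qnt.LineScan(((10, 10), (10, 100)), "free_edge"))


class TestMembraneMask:
    def test_peripheral_mean_within_2_percent(self, membrane_fixture):
        res = qnt.membrane_mask_quant(membrane_fixture, {"marker": membrane_fixture})
        assert res.peripheral_means["marker"] == pytest.approx(90.0, rel=0.02)

    def test_mask_thickness_3px_on_straight_membrane(self):
        img = np.full((64, 64), 5.0)
        img[30:37, 5:59] = 100.0  # thick band; skeleton is its 1-px centerline
        res = qnt.membrane_mask_quant(img, {})
        cols = res.mask[:, 20:45]
        widths = cols.sum(axis=0)
        assert np.all(widths[widths > 0] == 3)

    def test_linearity_in_intensity(self, membrane_fixture):
        r1 = qnt.membrane_mask_quant(membrane_fixture, {"m": membrane_fixture})
        r2 = qnt.membrane_mask_quant(membrane_fixture, {"m": membrane_fixture * 2.0})
        assert r2.peripheral_means["m"] == pytest.approx(2 * r1.peripheral_means["m"], rel=1e-9)

    def test_empty_mask_reports_stage_diagnostics(self):
        flat = np.zeros((32, 32))
        with pytest.raises(ValueError, match="stages"):
            qnt.membrane_mask_quant(flat, {})


def _pearson_oracle(a, b):
    a, b = a.ravel(), b.ravel()
    n = len(a)
    sa, sb = a.sum(), b.sum()
    num = (a * b).sum() - sa * sb / n
    den = np.sqrt((a * a).sum() - sa**2 / n) * np.sqrt((b * b).sum() - sb**2 / n)
    return num / den


def _manders_oracle(a, b, ta, tb):
    m1 = a[b > tb].sum() / a.sum()
    m2 = b[a > ta].sum() / b.sum()
    return m1, m2


class TestColocalization:
    def test_identical_channels(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        res = qnt.colocalization(a, a, thresholds=(0.0, 0.0))
        assert res.pearson == pytest.approx(1.0, abs=1e-12)
        assert res.m1 == res.m2 == 1.0

    def test_inverted_channel_anticorrelates(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        res = qnt.colocalization(a, 100.0 - a)
        assert res.pearson == pytest.approx(-1.0, abs=1e-12)

    def test_disjoint_supports_zero_manders(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[:4] = 50.0
        b[4:] = 50.0
        res = qnt.colocalization(a, b, thresholds=(10.0, 10.0))
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(1000):
            a = rng.uniform(0, 255, (8, 8))
            b = rng.uniform(0, 255, (8, 8))
            ta, tb = rng.uniform(20, 200, 2)
            res = qnt.colocalization(a, b, thresholds=(ta, tb))
            assert res.pearson == pytest.approx(_pearson_oracle(a, b), abs=1e-12)
            m1, m2 = _manders_oracle(a, b, ta, tb)
            assert res.m1 == pytest.approx(m1, abs=1e-12)
            assert res.m2 == pytest.approx(m2, abs=1e-12)
            assert 0.0 <= res.m1 <= 1.0 and 0.0 <= res.m2 <= 1.0

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="variance"):
            res = qnt.colocalization(np.full((8, 8), 5.0), np.arange(64.0).reshape(8, 8))
        assert np.isnan(res.pearson)

    def test_roi_restricts_computation(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        b = a.copy()
        b[:8] = rng.uniform(0, 100, (8, 16))  # decorrelate outside ROI
        roi = np.zeros((16, 16), bool)
        roi[8:] = True
        assert qnt.colocalization(a, b, roi_mask=roi).pearson == pytest.approx(1.0)


class TestMorphometry:
    @staticmethod
    def _disc(r, shape=(128, 128)):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return (yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2 <= r**2

    def test_disc_circularity_near_one(self):
        disc = self._disc(50)
        res = qnt.morphometry(disc, disc, pixel_size_um=0.5)
        assert res.circularity >= 0.95
        assert res.area_um2 == pytest.approx(np.pi * 50**2 * 0.25, rel=0.01)
        assert res.ventral_to_max_ratio == 1.0

    def test_ellipse_less_circular_than_disc(self):
        yy, xx = np.mgrid[:128, :128]
        ellipse = ((yy - 64) / 25) ** 2 + ((xx - 64) / 50) ** 2 <= 1
        disc = self._disc(35)
        res_e = qnt.morphometry(ellipse, ellipse, 1.0)
        res_d = qnt.morphometry(disc, disc, 1.0)
        assert res_e.circularity < res_d.circularity

    def test_ventral_smaller_than_maxproj(self):
        res = qnt.morphometry(self._disc(30), self._disc(60), 1.0)
        assert res.ventral_to_max_ratio == pytest.approx(0.25, rel=0.02)


class TestOrientation:
    def test_perpendicular_axis_90(self):
        angle = qnt.orientation_angle([(0, 0), (0, 10)], [(-50, 20), (50, 20)])
        assert angle == pytest.approx(90.0)

    def test_parallel_axis_0(self):
        angle = qnt.orientation_angle([(0, 0), (10, 0)], [(-50, 20), (50, 20)])
        assert angle == pytest.approx(0.0)

    def test_sine_wave_interface_local_tangent(self):
        x = np.linspace(0, 20, 400)
        wave = list(zip(x, np.sin(x)))
        # near x=pi the tangent slope is cos(pi) = -1, i.e. -45 degrees;
        # an axis at -15 degrees sits 30 degrees from the local tangent
        mid = np.pi
        axis_dir = np.radians(-15.0)
        axis = [
            (mid - np.cos(axis_dir), np.sin(mid) - np.sin(axis_dir)),
            (mid + np.cos(axis_dir), np.sin(mid) + np.sin(axis_dir)),
        ]
        assert qnt.orientation_angle(axis, wave) == pytest.approx(30.0, abs=1.0)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="distinct"):
            qnt.orientation_angle([(1, 1), (1, 1)], [(0, 0), (1, 0)])
        with pytest.raises(ValueError, match="degenerate"):
            qnt.orientation_angle([(0, 0), (1, 0)], [(2, 2), (2, 2)])


def _straight_track(n=60, step=5.0, dt=2.5, morphology=None):
    frames = np.arange(n)
    return qnt.CellTrack(
        cell_id="c0",
        frames=frames,
        t_min=frames * dt,
        x_um=frames * step,
        y_um=np.zeros(n),
        morphology=morphology,
    )


class TestTrackSpeed:
    def test_straight_line_closed_form(self):
        res = qnt.track_speed(_straight_track())
        assert res.mean_speed == pytest.approx(2.0, rel=1e-12)

    def test_stationary_cell_zero(self):
        tr = qnt.CellTrack(
            cell_id="c1",
            frames=np.arange(50),
            t_min=np.arange(50) * 2.5,
            x_um=np.full(50, 7.0),
            y_um=np.full(50, -3.0),
        )
        assert qnt.track_speed(tr).mean_speed == 0.0

    def test_translation_invariance_and_scaling_equivariance(self):
        tr = _straight_track()
        shifted = qnt.CellTrack("c2", tr.frames, tr.t_min, tr.x_um + 100, tr.y_um - 50)
        assert qnt.track_speed(shifted).mean_speed == qnt.track_speed(tr).mean_speed
        scaled = qnt.CellTrack("c3", tr.frames, tr.t_min, tr.x_um * 3, tr.y_um * 3)
        assert qnt.track_speed(scaled).mean_speed == pytest.approx(
            3 * qnt.track_speed(tr).mean_speed
        )

    def test_per_morphology_speeds_recovered(self):
        n = 60
        frames = np.arange(n)
        labels = ["b"] * 25 + ["s"] * 35
        # programmed speeds: b 0.3 um/min, s 2.0 um/min at 2.5 min/frame
        steps = np.where(np.array(labels) == "b", 0.75, 5.0)
        x = np.concatenate([[0.0], np.cumsum(steps[:-1])])
        tr = qnt.CellTrack("c4", frames, frames * 2.5, x, np.zeros(n), morphology=labels)
        res = qnt.track_speed(tr)
        assert res.per_morphology["b"] == pytest.approx(0.3, rel=1e-9)
        assert res.per_morphology["s"] == pytest.approx(2.0, rel=1e-9)

    def test_short_track_warns_and_uses_overlap(self):
        tr = _straight_track(n=30)
        with pytest.warns(UserWarning, match="overlap"):
            res = qnt.track_speed(tr)
        assert res.mean_speed == pytest.approx(2.0)


class TestAdhesionAndMorphology:
    def test_adhesion_percent(self):
        assert qnt.adhesion_fraction(100, 80) == 80.0
        assert qnt.adhesion_fraction(50, 0) == 0.0

    def test_miscount_errors(self):
        with pytest.raises(ValueError, match="miscount"):
            qnt.adhesion_fraction(10, 11)

    def test_experiment_statistics_match_spreadsheet(self):
        counts = [(200, 150), (180, 90), (220, 220), (100, 25), (150, 120)]
        pct, mean, sd = qnt.adhesion_statistics(counts)
        expected = np.array([75.0, 50.0, 100.0, 25.0, 80.0])
        assert np.allclose(pct, expected)
        assert mean == pytest.approx(expected.mean())
        assert sd == pytest.approx(expected.std(ddof=1))

    def test_morphology_distribution_sums_to_100(self):
        dist = qnt.morphology_distribution(["s"] * 7)
        assert dist["s"] == 100.0 and sum(dist.values()) == 100.0
        dist = qnt.morphology_distribution(["b", "b", "s", "s"])
        assert dist == {"b": 50.0, "r": 0.0, "p": 0.0, "s": 50.0, "pb": 0.0}

    @given(st.permutations(["b", "r", "p", "s", "pb", "b", "s", "s"]))
    @settings(max_examples=50, derandomize=True)
    def test_distribution_order_invariant(self, labels):
        base = qnt.morphology_distribution(["b", "r", "p", "s", "pb", "b", "s", "s"])
        assert qnt.morphology_distribution(labels) == base

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            qnt.morphology_distribution(["b", "x"])
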