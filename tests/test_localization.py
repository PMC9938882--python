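"""Peak localization, signed distances, QC and cell aggregation."""

import math

import numpy as np
import pytest

import golgimap as gm
from golgimap.localization import (
    DegenerateChannelError,
    OrientationUndefinedError,
    aggregate_cells,
    reference_distance,
)


def _prep(profile):
    gm.normalize_profile(profile)
    gm.smooth_profile(profile, 5)
    return profile


class TestFindPeak:
    def test_gaussian_center_recovered_subpixel(self, profile_factory):
        """Gaussian centered at 37.3 px sampled every 0.5 px: parabolic
        refinement recovers the center within 0.05 px."""
        t = np.arange(150) * 0.5
        y = np.exp(-((t - 37.3) ** 2) / (2 * 3.0**2))
        prof = _prep(profile_factory({k: y for k in "abc"}))
        pk = gm.find_peak(prof, "tgn")
        assert pk.position_px == pytest.approx(37.3, abs=0.05)
        assert pk.position_nm == pytest.approx(pk.position_px * 40.0)

    def test_symmetric_triangle_apex_exact(self, profile_factory):
        y = np.concatenate([np.arange(8.0), [8.0], np.arange(8.0)[::-1]])
        prof = profile_factory({k: y for k in "abc"})
        gm.normalize_profile(prof)
        gm.smooth_profile(prof, 1)  # keep the apex a single exact sample
        pk = gm.find_peak(prof, "poi")
        assert pk.position_px == pytest.approx(8 * 0.5)

    def test_plateau_ties_return_centroid(self, profile_factory):
        y = np.array([0.0, 0.2, 1.0, 1.0, 1.0, 0.2, 0.0])
        prof = profile_factory({k: y for k in "abc"})
        gm.normalize_profile(prof)
        gm.smooth_profile(prof, 1)
        pk = gm.find_peak(prof, "cis")
        assert pk.position_px == pytest.approx(3 * 0.5)  # centroid of samples 2..4

    def test_degenerate_channel_raises(self, profile_factory):
        prof = _prep(profile_factory({"a": np.ones(20), "b": np.r_[np.zeros(10), 1.0,
                                      np.zeros(9)], "c": np.r_[np.zeros(10), 1.0, np.zeros(9)]}))
        with pytest.raises(DegenerateChannelError):
            gm.find_peak(prof, "cis")

    def test_prominence_of_clean_peak_is_near_full_range(self, profile_factory):
        t = np.arange(100) * 0.5
        y = np.exp(-((t - 25.0) ** 2) / (2 * 4.0**2))
        prof = _prep(profile_factory({k: y for k in "abc"}))
        pk = gm.find_peak(prof, "tgn")
        # the 5-sample moving average attenuates a sigma = 4 px peak by
        # sigma / sqrt(sigma^2 + (w^2-1)/12 * step^2) ~ 1.5%
        assert pk.prominence == pytest.approx(1.0, abs=0.05)


class TestSignedDistances:
    def test_arithmetic_from_convention(self):
        d = gm.signed_distances(10.0, 20.0, 25.0)
        assert d == {"d_cis_tgn": 10.0, "d_tgn_poi": 5.0, "d_cis_poi": 15.0}

    def test_line_reversal_invariance_exact(self):
        a = gm.signed_distances(10.0, 20.0, 25.0)
        b = gm.signed_distances(-10.0, -20.0, -25.0)
        assert a == b

    def test_poi_coincident_with_tgn(self):
        d = gm.signed_distances(0.0, 30.0, 30.0)
        assert d["d_tgn_poi"] == 0.0

    def test_additivity_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rng.normal(size=3) * 100
            if s[0] == s[1]:
                continue
            d = gm.signed_distances(*s)
            assert d["d_cis_poi"] == pytest.approx(
                d["d_cis_tgn"] + d["d_tgn_poi"], abs=1e-9
            )
            assert d["d_cis_tgn"] > 0

    def test_swapping_roles_negates(self):
        d = gm.signed_distances(10.0, 20.0, 25.0)
        # swapping tgn and poi endpoints negates the tgn->poi leg
        d2 = gm.signed_distances(10.0, 20.0, 15.0)
        assert d2["d_tgn_poi"] == -d["d_tgn_poi"]

    def test_coincident_cis_tgn_is_undefined(self):
        with pytest.raises(OrientationUndefinedError):
            gm.signed_distances(5.0, 5.0, 9.0)


class TestMeasureStack:
    def test_clean_render_passes_qc(self, default_geometry, noiseless_model):
        img, _ = gm.render_stack(default_geometry, noiseless_model)
        roi = _axis_roi(img, default_geometry)
        m = gm.measure_stack(img, roi)
        assert m.qc_pass and m.qc_reasons == []
        assert m.d_tgn_poi == pytest.approx(150.0, abs=20.0)
        assert m.d_cis_poi == pytest.approx(m.d_cis_tgn + m.d_tgn_poi, abs=1e-9)

    def test_line_reversal_gives_identical_distances(self, default_geometry, noiseless_model):
        img, _ = gm.render_stack(default_geometry, noiseless_model)
        roi = _axis_roi(img, default_geometry)
        m1 = gm.measure_stack(img, roi)
        m2 = gm.measure_stack(img, roi.reversed())
        # bit-exact: reversal changes nothing at all
        assert m1.d_tgn_poi == m2.d_tgn_poi
        assert m1.d_cis_tgn == m2.d_cis_tgn
        assert m1.d_cis_poi == m2.d_cis_poi
        assert m1.qc_pass == m2.qc_pass

    def test_inplane_rotation_changes_distance_below_quarter_pixel(self, noiseless_model):
        vals = []
        for angle in (0.0, 0.35, 1.1, 2.0, math.pi / 2):
            geom = gm.StackGeometry(None, angle, 0.0, (0.0, 400.0, 550.0))
            img, _ = gm.render_stack(geom, noiseless_model)
            m = gm.measure_stack(img, _axis_roi(img, geom))
            vals.append(m.d_tgn_poi)
        spread_px = (max(vals) - min(vals)) / noiseless_model.pixel_size_nm
        assert spread_px < 0.25

    def test_overlapping_distractor_fails_qc(self, noiseless_model):
        """A second stack on the ROI line produces >= 2 peaks in some
        channel (verified on the noiseless profile) and raises the
        secondary-peak QC flag."""
        geom = gm.StackGeometry(None, math.pi / 2, 0.0, (0.0, 400.0, 550.0))
        img, _ = gm.render_stack(geom, noiseless_model)
        c = img.shape[0] // 2
        geom2 = gm.StackGeometry((float(c), float(c) - 14.0), math.pi / 2, 0.0,
                                 (0.0, 400.0, 550.0))
        crowded = gm.add_distractor_stack(img, geom2, noiseless_model)
        roi = gm.LineROI("c", "s", (c, c - 22.0), (c, c + 22.0))
        prof = gm.extract_profile(crowded, roi)
        gm.normalize_profile(prof)
        gm.smooth_profile(prof, 5)
        # oracle: count prominent local maxima on the noiseless profile
        from scipy.signal import find_peaks

        n_peaks = max(
            len(find_peaks(prof.smoothed[ch], prominence=0.2)[0])
            for ch in prof.channels
        )
        assert n_peaks >= 2
        m = gm.measure_stack(crowded, roi)
        assert not m.qc_pass
        assert any("secondary peak" in r for r in m.qc_reasons)

    def test_far_distractor_leaves_qc_unchanged(self, noiseless_model):
        """A distractor stack 10 um away does not perturb a centered ROI."""
        c = 150.0
        geom = gm.StackGeometry((c, c), math.pi / 2, 0.0, (0.0, 400.0, 550.0))
        img = gm.render_scene([geom], noiseless_model, shape=(440, 440))
        # 10 um at 40 nm/px = 250 px along x
        far = gm.StackGeometry((c + 250.0, c), math.pi / 2, 0.0, (0.0, 400.0, 550.0))
        roi = gm.LineROI("c", "s", (c, c - 22.0), (c, c + 22.0))
        base = gm.measure_stack(img, roi)
        crowded = gm.add_distractor_stack(img, far, noiseless_model)
        m = gm.measure_stack(crowded, roi)
        assert m.qc_pass == base.qc_pass
        assert m.d_tgn_poi == pytest.approx(base.d_tgn_poi, abs=1e-6)

    def test_edge_on_stack_fails_min_axis(self, noiseless_model):
        geom = gm.StackGeometry(None, math.pi / 2, math.radians(89.0),
                                (0.0, 400.0, 550.0))
        img, _ = gm.render_stack(geom, noiseless_model)
        c = img.shape[0] // 2
        roi = gm.LineROI("c", "s", (c, c - 15.0), (c, c + 15.0))
        m = gm.measure_stack(img, roi)
        assert not m.qc_pass
        assert any("edge-on" in r or "axis" in r for r in m.qc_reasons)


def _axis_roi(img, geom, margin_px=15.0, pixel_size_nm=40.0):
    """Line along the projected axis covering every layer plus a margin."""
    c = img.shape[0] // 2
    ux, uy = geom.axis_unit
    offs = [o * geom.projection_factor / pixel_size_nm for o in geom.layer_offsets_nm]
    lo, hi = min(offs) - margin_px, max(offs) + margin_px
    return gm.LineROI("cell0", "stack0",
                      (c + lo * ux, c + lo * uy),
                      (c + hi * ux, c + hi * uy))


def _meas(cell, stack, d_tgn_poi, d_cis_tgn, qc=True, reasons=()):
    return gm.StackMeasurement(
        cell_id=cell, stack_id=stack, protein="X", peaks={},
        d_tgn_poi=d_tgn_poi, d_cis_tgn=d_cis_tgn,
        d_cis_poi=d_cis_tgn + d_tgn_poi, qc_pass=qc,
        qc_reasons=list(reasons), cis_marker="GM130",
    )


class TestAggregate:
    def test_single_stack_cell(self):
        cells = aggregate_cells([_meas("c1", "s1", 100.0, 400.0)])
        assert len(cells) == 1
        assert cells[0].d_tgn_poi == 100.0 and cells[0].n_stacks_used == 1

    def test_mean_over_stacks(self):
        cells = aggregate_cells(
            [_meas("c1", "s1", 100.0, 380.0), _meas("c1", "s2", 200.0, 420.0)]
        )
        assert cells[0].d_tgn_poi == pytest.approx(150.0)
        assert cells[0].d_cis_tgn == pytest.approx(400.0)

    def test_all_failing_cell_dropped_and_logged(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="golgimap.localization"):
            cells = aggregate_cells(
                [
                    _meas("c1", "s1", 100.0, 400.0),
                    _meas("c2", "s1", 50.0, 400.0, qc=False, reasons=["low prominence"]),
                ]
            )
        assert [c.cell_id for c in cells] == ["c1"]
        assert any("c2" in rec.message for rec in caplog.records)

    def test_failing_stacks_excluded_from_mean(self):
        cells = aggregate_cells(
            [_meas("c1", "s1", 100.0, 400.0),
             _meas("c1", "s2", 999.0, 400.0, qc=False)]
        )
        assert cells[0].d_tgn_poi == 100.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_cells([])


class TestReferenceDistance:
    def _cell(self, cid, marker, d_cis_tgn):
        return gm.CellMeasurement(cid, "X", marker, 0.0, d_cis_tgn,
                                  d_cis_tgn, 3)

    def test_constant_dataset(self):
        cells = [self._cell(f"c{i}", "GM130", 400.0) for i in range(4)]
        assert reference_distance(cells) == {"GM130": pytest.approx(400.0)}

    def test_mean_of_two(self):
        cells = [self._cell("c1", "GM130", 300.0), self._cell("c2", "GM130", 500.0)]
        assert reference_distance(cells)["GM130"] == pytest.approx(400.0)

    def test_markers_computed_separately(self):
        cells = [
            self._cell("c1", "GM130", 300.0),
            self._cell("c2", "GM130", 500.0),
            self._cell("c3", "giantin", 250.0),
        ]
        refs = reference_distance(cells)
        assert refs["GM130"] == pytest.approx(400.0)
        assert refs["giantin"] == pytest.approx(250.0)


class TestRecovery:
    def test_noiseless_offset_sweep(self, noiseless_model):
        """Recovered TGN->POI distance within max(0.5 px, 2%) of truth for
        offsets 25-400 nm at tilt 0."""
        for offset in (25.0, 50.0, 100.0, 200.0, 400.0):
            geom = gm.StackGeometry(None, 1.0, 0.0, (0.0, 400.0, 400.0 + offset))
            img, _ = gm.render_stack(geom, noiseless_model)
            m = gm.measure_stack(img, _axis_roi(img, geom))
            tol = max(0.5 * noiseless_model.pixel_size_nm, 0.02 * offset)
            assert m.d_tgn_poi == pytest.approx(offset, abs=tol)
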