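"""Georeferencing and precedence compositing."""

import numpy as np
import pytest

from nightshift.calibration import Frame
from nightshift.mosaic import (
    ControlPointSet,
    composite,
    georeference,
    precedence_score,
)
from nightshift.raster import GridGeometry

from _helpers import geom


GRID = GridGeometry.study_grid(shape=(60, 60))


def radiance_frame(values=None, window=(10, 10), frame=(30, 30), jitter=0.0, seed=0, **geom_kw):
    """Calibrated frame whose true placement is an integer translation."""
    rng = np.random.default_rng(seed)
    h, w = frame
    if values is None:
        values = rng.uniform(1.0, 5.0, (3, h, w))
    rows = np.linspace(2, h - 3, 7)
    cols = np.linspace(2, w - 3, 7)
    rr, cc = [a.ravel() for a in np.meshgrid(rows, cols)]
    x, y = GRID.transform.xy(window[0] + rr, window[1] + cc, center=True)
    if jitter > 0:
        x = x + rng.normal(0, jitter * GRID.resolution, x.shape)
        y = y + rng.normal(0, jitter * GRID.resolution, y.shape)
    cps = np.column_stack([rr, cc, x, y])
    g = geom(center=(window[0] + h // 2, window[1] + w // 2), frame=frame, **geom_kw)
    return Frame(
        values=np.asarray(values, float),
        valid=np.ones((h, w), bool),
        reasons=np.zeros((h, w), np.uint8),
        geometry=g,
        window=window,
        grid=GRID,
        control_points=cps,
        units="radiance",
    )


class TestControlPoints:
    def test_minimum_count_enforced(self):
        with pytest.raises(ValueError, match="at least 4"):
            ControlPointSet(np.zeros((3, 2)) + np.arange(3)[:, None], np.zeros((3, 2)))

    def test_duplicate_frame_points_rejected(self):
        fp = np.array([[0, 0], [1, 1], [2, 2], [0, 0]], float)
        with pytest.raises(ValueError, match="duplicate"):
            ControlPointSet(fp, fp)

    def test_collinear_points_rejected_for_affine(self):
        f = radiance_frame()
        n = f.control_points.shape[0]
        f.control_points[:, 2] = np.arange(n)  # map x varies
        f.control_points[:, 3] = 0.0  # map y constant -> rank 2
        with pytest.raises(ValueError, match="collinear"):
            georeference(f, method="affine")


class TestGeoreference:
    def test_exact_control_points_place_frame_exactly(self):
        f = radiance_frame()
        gf = georeference(f, method="affine")
        assert gf.cp_rmse_px < 1e-9
        window = gf.radiance[:, 10:40, 10:40]
        np.testing.assert_allclose(window, f.values, atol=1e-9)
        assert gf.valid.sum() == 30 * 30

    def test_jittered_control_points_report_expected_rmse(self):
        # georeferencing error of ~4 px should show up as ~4 px residual RMSE
        rmses = [
            georeference(radiance_frame(jitter=4.0, seed=s), method="affine").cp_rmse_px
            for s in range(5)
        ]
        assert 3.0 < np.mean(rmses) < 5.0

    def test_thin_plate_spline_fits_smooth_nonlinear_warp(self):
        f = radiance_frame()
        # displace control-point map coords by a smooth quadratic warp
        cp = f.control_points
        r, c = cp[:, 0], cp[:, 1]
        dx = 0.002 * (r - 15) ** 2 - 0.001 * (c - 15) ** 2
        dy = 0.0015 * (r - 15) * (c - 15)
        cp[:, 2] += dx * GRID.resolution
        cp[:, 3] += dy * GRID.resolution
        gf = georeference(f, method="tps")
        assert gf.cp_rmse_px < 1.0  # residual below one pixel

    def test_tps_needs_six_points(self):
        f = radiance_frame()
        f.control_points = f.control_points[:5]
        with pytest.raises(ValueError, match="at least 6"):
            georeference(f, method="tps")

    def test_uncalibrated_frame_rejected(self):
        f = radiance_frame()
        f.units = "counts"
        with pytest.raises(ValueError, match="radiance"):
            georeference(f)


class TestPrecedence:
    def test_lower_observation_angle_wins(self):
        a = precedence_score(geom(angle_deg=10.0), 5.0)
        b = precedence_score(geom(angle_deg=40.0), 5.0)
        assert a < b

    def test_longer_focal_length_wins(self):
        a = precedence_score(geom(focal_mm=400.0), 5.0)
        b = precedence_score(geom(focal_mm=50.0), 5.0)
        assert a < b

    def test_smaller_center_offset_wins(self):
        assert precedence_score(geom(), 2.0) < precedence_score(geom(), 9.0)

    def test_recency_only_matters_under_post_policy(self):
        old = geom(timestamp=2014.0, frame_id="a")
        new = geom(timestamp=2019.0, frame_id="a")
        assert precedence_score(new, 5.0, "post") < precedence_score(old, 5.0, "post")
        assert precedence_score(new, 5.0, "pre") == precedence_score(old, 5.0, "pre")

    def test_identical_metadata_breaks_tie_on_frame_id(self):
        a = precedence_score(geom(frame_id="a_000"), 5.0)
        b = precedence_score(geom(frame_id="b_000"), 5.0)
        assert a < b


class TestComposite:
    def test_single_frame_mosaic_equals_frame(self):
        gf = georeference(radiance_frame())
        m = composite([gf])
        np.testing.assert_array_equal(m.valid, gf.valid)
        np.testing.assert_allclose(m.data[:, m.valid], gf.radiance[:, gf.valid])

    def test_overlap_provenance_is_single_winner(self):
        # two frames overlap in the middle; the near-nadir one must own
        # every overlap pixel
        f1 = georeference(radiance_frame(window=(10, 5), angle_deg=5.0, frame_id="a"))
        f2 = georeference(radiance_frame(window=(10, 20), angle_deg=40.0, frame_id="b", seed=1))
        m = composite([f1, f2])
        overlap = f1.valid & f2.valid
        assert overlap.any()
        assert set(np.unique(m.provenance[overlap])) == {m.frame_ids.index("a")}
        only2 = f2.valid & ~f1.valid
        assert (m.provenance[only2] == m.frame_ids.index("b")).all()

    def test_no_pixel_mixes_frames(self):
        # watermark each frame with a unique constant; every mosaic pixel
        # must carry exactly one watermark
        f1 = georeference(radiance_frame(values=np.full((3, 30, 30), 1.0), window=(10, 5), frame_id="w1"))
        f2 = georeference(radiance_frame(values=np.full((3, 30, 30), 2.0), window=(10, 20), frame_id="w2"))
        m = composite([f1, f2])
        vals = m.data[0][m.valid]
        assert set(np.unique(vals)) <= {1.0, 2.0}

    def test_order_independence(self):
        frames = [
            georeference(radiance_frame(window=(5, 5), angle_deg=12.0, frame_id="a", seed=1)),
            georeference(radiance_frame(window=(5, 20), angle_deg=7.0, frame_id="b", seed=2)),
            georeference(radiance_frame(window=(20, 12), angle_deg=30.0, frame_id="c", seed=3)),
        ]
        m1 = composite(frames)
        m2 = composite(frames[::-1])
        np.testing.assert_array_equal(m1.provenance, m2.provenance)
        np.testing.assert_array_equal(
            np.nan_to_num(m1.data), np.nan_to_num(m2.data)
        )

    def test_composite_is_idempotent(self):
        m = composite([georeference(radiance_frame())])
        again = composite([m.as_frame()])
        np.testing.assert_array_equal(again.valid, m.valid)
        np.testing.assert_allclose(
            again.data[:, again.valid], m.data[:, m.valid]
        )

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composite([])

    def test_winner_takes_all_beats_mean_blend_on_biased_pair(self):
        # frame b carries a 20% calibration bias; the precedence winner
        # (near-nadir frame a) should beat the mean blend against truth
        truth = np.random.default_rng(0).uniform(1, 5, (3, 30, 30))
        fa = georeference(radiance_frame(values=truth, window=(10, 10), angle_deg=5.0, frame_id="a"))
        fb = georeference(
            radiance_frame(values=truth * 1.2, window=(10, 10), angle_deg=45.0, frame_id="b")
        )
        m = composite([fa, fb])
        sel = m.valid
        blend = np.where(sel, 0.5 * (np.nan_to_num(fa.radiance) + np.nan_to_num(fb.radiance)), np.nan)
        full_truth = fa.radiance  # truth placed on the grid
        err_winner = np.nanmean(np.abs(m.data[:, sel] - full_truth[:, sel]))
        err_blend = np.nanmean(np.abs(blend[:, sel] - full_truth[:, sel]))
        assert err_winner < err_blend
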