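"""Segmentation, medial axis, profiles, and constriction detection."""
import numpy as np
import pytest

from divplane import geometry
from divplane.synthgen import (
    CellTruth,
    PlacementModel,
    ScopeConfig,
    arrange_in_rows,
    render_cell,
    render_field,
    sample_population,
)
from tests.conftest import analyze_single_cell


def _field_of_three(scope, seed=0):
    truths = arrange_in_rows(
        [
            CellTruth(length=3.2, nucleoid_centers=[0.0]),
            CellTruth(length=4.0, nucleoid_centers=[0.1]),
            CellTruth(length=5.0, nucleoid_centers=[-0.2]),
        ],
        spacing=3.0,
        per_row=2,
    )
    return render_field(truths, scope, rng=np.random.default_rng(seed))


def test_segmentation_recovers_three_cells_and_areas(scope):
    img = _field_of_three(scope)
    records = geometry.segment_cells(img, flag_division_pairs=False)
    assert len(records) == 3
    # match each segmented mask to the overlapping truth mask
    for rec in records:
        overlaps = [
            (rec.mask & img.mask_of(i)).sum() for i in range(len(img.truths))
        ]
        i = int(np.argmax(overlaps))
        truth_area = img.mask_of(i).sum()
        assert rec.mask.sum() == pytest.approx(truth_area, rel=0.05)


def test_blank_noise_image_segments_to_nothing(scope):
    rng = np.random.default_rng(0)
    noise = {
        "cyto": rng.normal(scope.background, scope.read_noise_sd, (64, 64))
    }
    assert geometry.segment_cells(noise, pixel_size=scope.pixel_size) == []


def test_adhered_pair_flagged_as_division_candidate(scope):
    truth = CellTruth(length=5.0, division_fraction=0.5, waist_depth=0.45)
    img = render_cell(truth, scope, rng=np.random.default_rng(2))
    records = geometry.segment_cells(img)
    assert len(records) == 1
    assert records[0].division_candidate


def test_straight_rod_length_recovered(scope):
    truth = CellTruth(length=4.0, nucleoid_centers=[0.0])
    img = render_cell(truth, scope, rng=np.random.default_rng(0))
    rec, _ = analyze_single_cell(img)
    assert rec.length == pytest.approx(4.0, abs=0.05)


def test_straight_rod_axis_is_straight(scope):
    truth = CellTruth(length=4.0)
    img = render_cell(truth, scope, noise=False)
    rec, _ = analyze_single_cell(img)
    rows = rec.axis_px[:, 0]
    line = np.polyval(np.polyfit(rec.axis_px[:, 1], rows, 1), rec.axis_px[:, 1])
    assert np.sqrt(np.mean((rows - line) ** 2)) < 0.5  # px RMS


def test_disk_shaped_region_raises_shape_error():
    yy, xx = np.mgrid[:41, :41]
    mask = (yy - 20) ** 2 + (xx - 20) ** 2 < 14**2
    rec = geometry.CellRecord(mask=mask, pixel_size=0.16)
    with pytest.raises(geometry.ShapeError):
        geometry.extract_axis(rec)


def test_bent_cell_length_matches_generative_arc(scope):
    truth = CellTruth(length=5.0, curvature=0.15, nucleoid_centers=[0.0])
    img = render_cell(truth, scope, rng=np.random.default_rng(4))
    rec, _ = analyze_single_cell(img)
    assert rec.length == pytest.approx(5.0, rel=0.02)


def test_axis_rotation_equivariance(scope):
    truth = CellTruth(length=4.0, nucleoid_centers=[0.0])
    img = render_cell(truth, scope, rng=np.random.default_rng(5))
    rec, _ = analyze_single_cell(img)
    rotated = {k: np.rot90(v) for k, v in img.channels.items()}
    rec_rot = geometry.segment_cells(
        rotated, pixel_size=scope.pixel_size, flag_division_pairs=False
    )[0]
    geometry.extract_axis(rec_rot, image=rotated)
    assert rec_rot.length == pytest.approx(rec.length, rel=0.005)


def test_uniform_rod_profile_flat_in_midsection(scope):
    truth = CellTruth(length=5.0)
    img = render_cell(truth, scope, noise=False)
    rec, prof = analyze_single_cell(img)
    y = prof.channel("cyto")
    mid = (prof.s > 1.2) & (prof.s < rec.length - 1.2)
    assert y[mid].std() / y[mid].mean() < 0.02
    caps = prof.s < 0.3
    assert y[caps].mean() < 0.8 * y[mid].mean()


def test_ring_profile_argmax_at_true_offset(scope):
    truth = CellTruth(length=4.0, ring_offsets=[0.4])
    img = render_cell(truth, scope, rng=np.random.default_rng(6))
    rec, prof = analyze_single_cell(img)
    peak_s = prof.s[np.argmax(prof.channel("ring"))]
    assert peak_s - rec.length / 2 == pytest.approx(0.4, abs=scope.pixel_size)


def test_zero_image_gives_zero_profile(scope):
    truth = CellTruth(length=4.0)
    img = render_cell(truth, scope, noise=False)
    rec, _ = analyze_single_cell(img)
    zero = {"cyto": np.zeros_like(img.channels["cyto"])}
    prof = geometry.line_profiles(zero, rec, channels=["cyto"])
    np.testing.assert_allclose(prof.channel("cyto"), 0.0, atol=1e-9)


def test_profile_integral_conserves_band_intensity(scope):
    """The profile integral matches the pixel sum over the same band.

    Band membership is recomputed independently: pixels inside the mask
    whose distance to the axis polyline is at most the profile half-width.
    """
    from scipy.spatial import cKDTree

    truth = CellTruth(length=4.0, nucleoid_centers=[0.2])
    img = render_cell(truth, scope, rng=np.random.default_rng(7))
    rec, prof = analyze_single_cell(img)
    px = scope.pixel_size
    ds = np.gradient(prof.s)
    integral = (prof.channel("dapi") * prof.band_width * ds).sum() / px**2
    bg = prof.background["dapi"]
    tree = cKDTree(rec.axis_px)
    pix = np.argwhere(rec.mask)
    dist, _ = tree.query(pix.astype(float), workers=1)
    in_band = dist * px <= 0.35
    band_sum = (
        img.channels["dapi"][pix[in_band, 0], pix[in_band, 1]] - bg
    ).sum()
    assert integral == pytest.approx(band_sum, rel=0.05)


def test_half_width_beyond_radius_warns(scope):
    truth = CellTruth(length=4.0)
    img = render_cell(truth, scope, rng=np.random.default_rng(8))
    rec, _ = analyze_single_cell(img)
    with pytest.warns(UserWarning):
        geometry.line_profiles(img, rec, half_width=2.0, channels=["cyto"])


def test_constriction_position_from_both_poles(scope):
    truth = CellTruth(length=5.0, division_fraction=0.29, waist_depth=0.45)
    img = render_cell(truth, scope, rng=np.random.default_rng(9))
    rec, _ = analyze_single_cell(img)
    c = geometry.detect_constriction(rec, image=img)
    assert c is not None
    s_true = truth.constriction_position()
    frac = min(c.from_poles) / rec.length
    assert frac == pytest.approx(min(s_true, 5.0 - s_true) / 5.0, abs=0.02)
    assert c.from_poles[0] + c.from_poles[1] == pytest.approx(rec.length)


def test_smooth_rod_has_no_constriction(scope):
    truth = CellTruth(length=5.0)
    img = render_cell(truth, scope, rng=np.random.default_rng(10))
    rec, _ = analyze_single_cell(img)
    assert geometry.detect_constriction(rec, image=img) is None


@pytest.mark.parametrize(
    "depth,expected", [(0.05, False), (0.10, False), (0.30, True), (0.45, True)]
)
def test_waist_depth_threshold_boundary(scope, depth, expected):
    """Detection flips as the generative waist depth crosses the threshold."""
    truth = CellTruth(
        length=5.0, division_fraction=0.5, waist_depth=depth
    )
    img = render_cell(truth, scope, noise=False)
    rec, _ = analyze_single_cell(img)
    c = geometry.detect_constriction(rec, image=img, min_depth=0.15)
    assert (c is not None) == expected
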