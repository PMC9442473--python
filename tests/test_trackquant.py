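"""Image chain: projection, bleach correction, background, detection, linking."""

import numpy as np
import pytest

from centrikit import trackquant as tq
from centrikit.series import CentrioleSeries
from centrikit.synth import SpotMovieConfig, simulate_spot_movie


def gaussian_spot(shape, x0, y0, sigma_px, amplitude, background=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return background + amplitude * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_px ** 2)
    )


# ------------------------------------------------------------- max_project


def test_single_slice_projection_is_identity():
    img = np.random.default_rng(0).random((1, 32, 32))
    assert np.array_equal(tq.max_project(img), img[0])


def test_projection_of_scaled_slices_picks_larger():
    a = np.random.default_rng(1).random((16, 16))
    assert np.array_equal(tq.max_project(np.stack([a, 2 * a])), 2 * a)


def test_projection_peak_from_brightest_slice():
    stack = np.zeros((17, 32, 32))
    for z in range(17):
        stack[z] = gaussian_spot((32, 32), 16, 16, 2.0, np.exp(-0.5 * ((z - 9) / 3) ** 2))
    assert tq.max_project(stack)[16, 16] == pytest.approx(stack[9, 16, 16])


def test_projection_idempotent_and_commutes_with_monotone_rescale():
    stack = np.random.default_rng(2).random((5, 8, 8))
    mip = tq.max_project(stack)
    assert np.array_equal(tq.max_project(mip[None]), mip)
    assert np.allclose(tq.max_project(3 * stack + 1), 3 * mip + 1)


# ---------------------------------------------------------- bleach_correct


def test_exact_exponential_movie_corrected_to_constant():
    t = np.arange(30)
    means = 50.0 * np.exp(-0.1 * t)
    movie = means[:, None, None] * np.ones((30, 16, 16))
    corrected, info = tq.bleach_correct(movie)
    cm = corrected.mean(axis=(1, 2))
    assert info["b"] == pytest.approx(0.1, rel=1e-4)
    assert np.all(np.abs(cm - cm[0]) / cm[0] < 1e-3)


def test_constant_movie_unchanged_with_warning():
    movie = np.full((10, 8, 8), 5.0)
    corrected, info = tq.bleach_correct(movie)
    assert np.array_equal(corrected, movie)
    assert info["b"] == 0.0 and info["warning"]


def test_bleach_rate_recovered_from_simulated_movie():
    # high-SNR movie: the max-projection of shot noise otherwise adds a
    # sqrt(signal) component that decays at k/2 and biases the fit low
    k = 0.05
    cfg = SpotMovieConfig(n_pairs=8, bleach_rate=k, n_frames=40, poisson_noise=True,
                          initial_separation=2.0, pair_separation_rate=0.0,
                          spot_intensity=2000.0, background_level=5.0,
                          image_shape=(96, 96), seed=4)
    movie = simulate_spot_movie(cfg)
    mip = np.stack([tq.max_project(s) for s in movie.frames])
    _, info = tq.bleach_correct(mip)
    assert info["b"] == pytest.approx(k, rel=0.05)


# ------------------------------------------------------------ rolling_ball


def test_constant_image_maps_to_zeros():
    assert np.allclose(tq.rolling_ball(np.full((32, 32), 9.0), 10), 0.0)


def test_spot_preserved_background_removed():
    img = gaussian_spot((64, 64), 32, 32, 2.0, 100.0, background=50.0)
    out = tq.rolling_ball(img, 10)
    assert out[32, 32] == pytest.approx(100.0, rel=0.10)
    corner = out[:10, :10]
    assert np.max(corner) < 0.01 * 50.0


def test_ramp_background_suppressed():
    yy, xx = np.mgrid[:64, :64]
    ramp = 40.0 * xx / 63.0
    img = ramp + gaussian_spot((64, 64), 32, 32, 2.0, 100.0)
    out = tq.rolling_ball(img, 10)
    blank = out[5:15, 45:55]  # away from the spot
    assert np.median(blank) < 0.05 * 40.0


def test_rolling_ball_anti_extensive_and_idempotent():
    yy, xx = np.mgrid[:48, :48]
    img = 30.0 + 20.0 * xx / 47.0 + gaussian_spot((48, 48), 24, 24, 2.0, 80.0)
    once = tq.rolling_ball(img, 10)
    assert np.all(once <= img + 1e-9)
    assert np.all(once >= 0)
    twice = tq.rolling_ball(once, 10)
    rms = np.sqrt(np.mean((twice - once) ** 2))
    assert rms < 0.01 * np.sqrt(np.mean(once ** 2)) + 1e-6


# ------------------------------------------------------------ detect_spots


def test_blank_image_no_detections():
    assert tq.detect_spots(np.zeros((32, 32)), 1.1, 0.2) == []


def test_single_spot_localized_within_half_pixel():
    px = 0.2
    img = gaussian_spot((64, 64), 30.3, 41.7, 1.25, 100.0)
    dets = tq.detect_spots(img, 1.1, px, quality_threshold=1.0)
    assert len(dets) == 1
    x, y, q = dets[0]
    assert x / px - 0.5 == pytest.approx(30.3, abs=0.5)
    assert y / px - 0.5 == pytest.approx(41.7, abs=0.5)


def test_two_spots_three_diameters_apart_both_found():
    px = 0.2
    sep_px = 3 * 1.1 / px  # 16.5 px
    img = (gaussian_spot((64, 64), 20, 32, 1.25, 100.0)
           + gaussian_spot((64, 64), 20 + sep_px, 32, 1.25, 100.0))
    dets = tq.detect_spots(img, 1.1, px, quality_threshold=1.0)
    assert len(dets) == 2


# ------------------------------------------------------------- link_tracks


def _det(x, y):
    return (x, y, 1.0)


def test_static_spot_single_complete_track():
    dets = [[_det(3.0, 4.0)] for _ in range(20)]
    tracks = tq.link_tracks(dets, max_disp=0.5)
    assert len(tracks) == 1
    assert tracks[0].complete and len(tracks[0]) == 20


def test_gap_terminates_track_and_marks_incomplete():
    dets = [[_det(3.0, 4.0)] for _ in range(20)]
    dets[10] = []
    tracks = tq.link_tracks(dets, max_disp=0.5)
    assert all(not t.complete for t in tracks)
    first = [t for t in tracks if t.frames[0] == 0][0]
    assert first.frames[-1] == 9


def test_separating_pair_two_complete_tracks_no_swaps():
    dets = []
    for f in range(20):
        off = 0.5 + 0.1 * f
        dets.append([_det(5.0 - off / 2, 5.0), _det(5.0 + off / 2, 5.0)])
    tracks = tq.link_tracks(dets, max_disp=0.5)
    complete = [t for t in tracks if t.complete]
    assert len(complete) == 2
    # no identity swaps: each track is monotone in x
    for t in complete:
        dx = np.diff(t.x)
        assert np.all(dx <= 0) or np.all(dx >= 0)


def test_equidistant_tie_broken_deterministically():
    dets = [[_det(0.0, 0.0)], [_det(-0.3, 0.0), _det(0.3, 0.0)]]
    tracks = tq.link_tracks(dets, max_disp=0.5)
    linked = [t for t in tracks if len(t) == 2][0]
    assert linked.x[1] == -0.3  # lower detection index wins


# ------------------------------------------------------- extract_intensity


def test_intensity_constant_for_static_spot():
    px = 0.2
    frames = np.stack([gaussian_spot((64, 64), 32, 32, 1.25, 100.0)] * 10)
    track = tq.SpotTrack(frames=np.arange(10), x=np.full(10, (32 + 0.5) * px),
                         y=np.full(10, (32 + 0.5) * px), complete=True)
    vals = tq.extract_intensity(frames, track, 1.1, px)
    assert np.all(np.abs(vals - vals[0]) / vals[0] < 0.01)


def test_intensity_linear_in_amplitude():
    px = 0.2
    base = gaussian_spot((64, 64), 32, 32, 1.25, 100.0)
    frames = np.stack([base, 2 * base])
    track = tq.SpotTrack(frames=np.arange(2), x=np.full(2, 6.5), y=np.full(2, 6.5),
                         complete=True)
    vals = tq.extract_intensity(frames, track, 1.1, px)
    assert vals[1] == pytest.approx(2 * vals[0], rel=1e-12)


def test_incomplete_track_rejected_for_intensity():
    track = tq.SpotTrack(frames=np.arange(3), x=np.zeros(3), y=np.zeros(3), complete=False)
    with pytest.raises(ValueError, match="complete"):
        tq.extract_intensity(np.zeros((3, 8, 8)), track, 1.1, 0.2)


# ------------------------------------------------- average_centriole_image


def test_single_track_average_is_the_crop():
    px = 0.2
    img = gaussian_spot((64, 64), 32, 32, 1.25, 100.0)
    frames = np.stack([img] * 3)
    track = tq.SpotTrack(frames=np.arange(3), x=np.full(3, (32 + 0.5) * px),
                         y=np.full(3, (32 + 0.5) * px), complete=True)
    avg = tq.average_centriole_image(frames, [track], window=11, pixel_size=px)
    assert np.array_equal(avg[0], img[27:38, 27:38])


def test_two_identical_spots_average_equals_either_crop():
    px = 0.2
    img = (gaussian_spot((64, 64), 16, 32, 1.25, 100.0)
           + gaussian_spot((64, 64), 48, 32, 1.25, 100.0))
    frames = img[None]
    t1 = tq.SpotTrack(frames=np.zeros(1, int), x=[(16 + 0.5) * px], y=[(32 + 0.5) * px], complete=True)
    t2 = tq.SpotTrack(frames=np.zeros(1, int), x=[(48 + 0.5) * px], y=[(32 + 0.5) * px], complete=True)
    avg = tq.average_centriole_image(frames, [t1, t2], window=9, pixel_size=px)
    crop1 = img[28:37, 12:21]
    assert np.allclose(avg[0], crop1, rtol=1e-6, atol=1e-9)


def test_averaging_improves_snr_like_sqrt_n():
    rng = np.random.default_rng(7)
    px = 0.2
    clean = gaussian_spot((96, 96), 0, 0, 1.25, 0.0)  # zeros; spots added per site
    n_tracks = 16
    img = np.zeros((96, 96))
    centers = [(12 + 20 * (i % 5), 12 + 20 * (i // 5)) for i in range(n_tracks)]
    for cx, cy in centers:
        img += gaussian_spot((96, 96), cx, cy, 1.25, 50.0)
    noisy = rng.poisson(img + 10.0).astype(float)
    tracks = [
        tq.SpotTrack(frames=np.zeros(1, int), x=[(cx + 0.5) * px], y=[(cy + 0.5) * px], complete=True)
        for cx, cy in centers
    ]
    avg = tq.average_centriole_image(noisy[None], tracks, window=9, pixel_size=px)
    # residual noise in the background corners of the averaged crop
    single_crop = noisy[12 - 4 : 12 + 5, 12 - 4 : 12 + 5]
    noise_single = np.std(single_crop[0])  # top row: background
    noise_avg = np.std(avg[0][0])
    assert noise_avg < noise_single / np.sqrt(n_tracks) * 2.0


# ---------------------------------------------------- normalize_and_align


def _series(embryo, first):
    t = np.arange(0, 10, 0.5)
    return CentrioleSeries(t, np.linspace(first, first * 2, t.size), embryo_id=embryo)


def test_wt_first_timepoint_mean_set_to_one():
    series = [_series("e1", 150.0), _series("e2", 250.0)]
    ann = {"e1": {"NEB": 9.5}, "e2": {"NEB": 9.0}}
    out, ref = tq.normalize_and_align(series, ann, anchor="NEB")
    assert ref == pytest.approx(200.0)
    assert np.mean([s.intensities[0] for s in out]) == pytest.approx(1.0)


def test_anchor_event_maps_to_time_zero():
    series = [_series("e1", 100.0)]
    ann = {"e1": {"NEB": 9.5}}
    out, _ = tq.normalize_and_align(series, ann, anchor="NEB")
    idx = np.argmin(np.abs(series[0].times - 9.5))
    assert out[0].times[idx] == pytest.approx(series[0].times[idx] - 9.5)
    assert out[0].anchor == "NEB"


def test_missing_annotation_names_embryo():
    with pytest.raises(KeyError, match="e2"):
        tq.normalize_and_align([_series("e2", 100.0)], {"e1": {"NEB": 9.0}})


def test_mutant_normalized_by_wt_reference_preserves_ratios():
    wt = [_series("e1", 200.0)]
    mut = [_series("e3", 100.0)]
    ann = {"e1": {"NEB": 9.0}, "e3": {"NEB": 9.0}}
    _, ref = tq.normalize_and_align(wt, ann)
    out_mut, _ = tq.normalize_and_align(mut, ann, reference=ref)
    assert out_mut[0].intensities[0] == pytest.approx(0.5)
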