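"""Ground-truth generators: image ensembles, voxel populations, responses."""

import numpy as np
import pytest

from orientmap import encoding, pipeline
from orientmap.pyramid import center_frequencies, channel_energy_sums
from orientmap.synthetic import (
    GroundTruthVoxel,
    calibrate_noise,
    make_image_ensemble,
    make_voxel_population,
    noise_sd_for_target_r2,
    simulate_responses,
    true_channel_weights,
    vignetting_demo_stimuli,
    voxel_table,
)
from orientmap.prf import PRF


def test_ensembles_are_deterministic():
    for kind in ("filtered_noise", "oriented_noise", "grating_mix"):
        a = make_image_ensemble(3, kind, size_px=64, seed=7)
        b = make_image_ensemble(3, kind, size_px=64, seed=7)
        np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        make_image_ensemble(2, "photos", size_px=64)
    with pytest.raises(ValueError):
        make_image_ensemble(0, "filtered_noise", size_px=64)


def test_filtered_noise_has_one_over_f_spectrum():
    """Log-log fit of the radially averaged amplitude spectrum: slope -1."""
    imgs = make_image_ensemble(6, "filtered_noise", size_px=128, seed=3)
    f = np.fft.fftfreq(128) * 128
    r = np.hypot(f[np.newaxis, :], f[:, np.newaxis])
    slopes = []
    for img in imgs:
        amp = np.abs(np.fft.fft2(img - img.mean()))
        bins = np.arange(1, 60)
        radial = [amp[(r >= b) & (r < b + 1)].mean() for b in bins]
        slope = np.polyfit(np.log(bins + 0.5), np.log(radial), 1)[0]
        slopes.append(slope)
    assert np.mean(slopes) == pytest.approx(-1.0, abs=0.1)


def test_oriented_noise_is_orientation_biased(spec64):
    imgs = make_image_ensemble(20, "oriented_noise", size_px=64, seed=4)
    n_aniso = 0
    for img in imgs:
        sums = channel_energy_sums(img, spec64).reshape(spec64.n_levels, -1)
        prof = sums[1]  # a mid-frequency level
        n_aniso += prof.max() / prof.min() > 1.5
    assert n_aniso >= 18  # >= 90% of images


def test_true_channel_weights_orientation_profiles(spec128):
    prf = PRF(x_deg=1, y_deg=0, sigma_deg=1)
    untuned = GroundTruthVoxel(prf=prf, ori_pref_rad=float("nan"), kappa=0.0, sf_pref_cpd=1.0)
    w = true_channel_weights(untuned, spec128).reshape(spec128.n_levels, -1)
    np.testing.assert_allclose(w, w[:, :1] * np.ones((1, spec128.n_orientations)))

    sharp = GroundTruthVoxel(prf=prf, ori_pref_rad=float(spec128.orientations[3]), kappa=50.0, sf_pref_cpd=1.0)
    ws = true_channel_weights(sharp, spec128).reshape(spec128.n_levels, -1)
    assert np.all(ws.argmax(axis=1) == 3)
    assert ws.max() / np.partition(ws[2], -2)[-2] > 10  # concentrated

    with pytest.raises(ValueError):
        GroundTruthVoxel(prf=prf, ori_pref_rad=0.0, kappa=-1.0, sf_pref_cpd=1.0)


def test_true_weights_sf_profile_peaks_at_nearest_level(spec128):
    cpds = np.array([c for _, c in center_frequencies(spec128)])
    vox = GroundTruthVoxel(
        prf=PRF(x_deg=1, y_deg=0, sigma_deg=1),
        ori_pref_rad=0.0,
        kappa=1.0,
        sf_pref_cpd=float(cpds[2]),
    )
    w = true_channel_weights(vox, spec128).reshape(spec128.n_levels, -1)
    assert w.sum(axis=1).argmax() == 2


def test_population_kinds_and_table():
    for kind in ("radial", "vertical", "cardinal", "saltpepper", "untuned"):
        vox = make_voxel_population(20, kind, seed=5)
        tab = voxel_table(vox)
        assert len(tab) == 20
        if kind == "untuned":
            assert np.isnan(tab["true_ori_rad"]).all()
        if kind == "radial":
            np.testing.assert_allclose(
                tab["true_ori_rad"], tab["polar_angle_rad"] % np.pi
            )
        if kind == "vertical":
            np.testing.assert_allclose(tab["true_ori_rad"], np.pi / 2)
    with pytest.raises(ValueError):
        make_voxel_population(5, "spiral")


def test_noiseless_responses_are_fit_exactly(spec64):
    imgs = make_image_ensemble(80, "oriented_noise", size_px=64, seed=6)
    vox = make_voxel_population(8, "saltpepper", seed=7)
    feats = pipeline.compute_feature_matrix(imgs, [v.prf for v in vox], spec64)
    resp = simulate_responses(feats, vox, spec64, seed=8)
    part = encoding.split_partitions(80, np.random.default_rng(9))
    for v in range(8):
        fit = encoding.cross_validated_fit(feats[:, v, :], resp[:, v], part)
        assert fit.cv_r2 == pytest.approx(1.0, abs=1e-6)
        # identifiable projection: planted weights recovered exactly
        np.testing.assert_allclose(
            fit.channel_beta, true_channel_weights(vox[v], spec64), atol=1e-6
        )


def test_untuned_voxels_gain_nothing_from_full_model(rng):
    """kappa = 0 responses are generated by the constrained model, so full
    and constrained cross-validated R^2 agree (here with synthetic features,
    2000 images, additive noise)."""
    part = encoding.split_partitions(2000, rng)
    deltas = []
    for _ in range(30):
        X = rng.random((2000, 40))
        level_w = rng.random(5) + 0.5
        signal = X.reshape(2000, 5, 8).sum(2) @ level_w
        # high-SNR regime so the two models' overfitting penalties are small
        y = signal + 0.1 * signal.std() * rng.standard_normal(2000)
        full = encoding.cross_validated_fit(X, y, part).cv_r2
        con = encoding.cross_validated_fit(
            encoding.constrain_features(X, 8), y, part
        ).cv_r2
        deltas.append(full - con)
    assert abs(np.mean(deltas)) < 0.005


def test_gain_doubling_quadruples_signal_variance(spec64):
    imgs = make_image_ensemble(60, "oriented_noise", size_px=64, seed=10)
    vox = make_voxel_population(5, "radial", seed=11, gain=1.0)
    vox2 = [
        GroundTruthVoxel(
            prf=v.prf,
            ori_pref_rad=v.ori_pref_rad,
            kappa=v.kappa,
            sf_pref_cpd=v.sf_pref_cpd,
            sf_bw_octaves=v.sf_bw_octaves,
            gain=2.0,
        )
        for v in vox
    ]
    feats = pipeline.compute_feature_matrix(imgs, [v.prf for v in vox], spec64)
    r1 = simulate_responses(feats, vox, spec64, seed=12)
    r2 = simulate_responses(feats, vox2, spec64, seed=12)
    ratio = r2.var(axis=0) / r1.var(axis=0)
    np.testing.assert_allclose(ratio, 4.0, rtol=0.05)


def test_noise_calibration_hits_target_variance_fraction(rng):
    signal = rng.standard_normal(5000)
    sd = noise_sd_for_target_r2(signal, 0.25)
    noisy = signal + rng.normal(0, sd, 5000)
    achieved = 1 - sd**2 / noisy.var()
    assert achieved == pytest.approx(0.25, abs=0.03)
    with pytest.raises(ValueError):
        noise_sd_for_target_r2(signal, 1.5)


def test_vignetting_stimuli_geometry():
    imgs, oris, phases = vignetting_demo_stimuli(
        1.0, 2.0, n_orientations=4, n_phases=2, size_px=64
    )
    assert imgs.shape == (8, 64, 64)
    # outside the aperture everything is background gray
    from orientmap.stimulus import pixel_grid_deg

    x, y = pixel_grid_deg(64, 8.4 * 1024 / 714)
    outside = np.hypot(x, y) > 2.1
    assert np.all(imgs[:, outside] == 0.5)
    assert np.any(imgs[0] != 0.5)
    with pytest.raises(ValueError):
        vignetting_demo_stimuli(1.0, -1.0, size_px=64)
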