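"""Ideal-map deviations, binning, group tests, and circular statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orientmap.map_analysis import (
    angular_deviation,
    bin_edges,
    bin_summary,
    circular_correlation,
    circular_correlation_test,
    compare_deviations,
    deviation_meridian_correlation,
    distance_from_meridian,
    ideal_orientation,
    rayleigh_test,
)


@pytest.mark.parametrize(
    "pol_deg,kind,expected_deg",
    [
        (30, "radial", 30),
        (210, "radial", 30),
        (30, "vertical", 90),
        (30, "cardinal", 0),
        (60, "cardinal", 90),
        (45, "cardinal", 90),  # tie at 45 deg resolves to vertical
    ],
)
def test_ideal_orientation_definitions(pol_deg, kind, expected_deg):
    out = ideal_orientation(np.radians(pol_deg), 2.0, kind)
    assert np.degrees(out) == pytest.approx(expected_deg)


def test_ideal_orientation_undefined_at_fixation():
    assert np.isnan(ideal_orientation(0.3, 0.0, "radial"))
    assert np.isnan(ideal_orientation(0.3, 0.0, "cardinal"))
    assert ideal_orientation(0.3, 0.0, "vertical") == pytest.approx(np.pi / 2)
    with pytest.raises(ValueError):
        ideal_orientation(0.3, 1.0, "spiral")


@pytest.mark.parametrize(
    "a_deg,b_deg,expected",
    [(0, 0, 0), (10, 170, 20), (0, 90, 90), (89, 91, 2), (45, 135, 90)],
)
def test_angular_deviation_axial_wraparound(a_deg, b_deg, expected):
    assert angular_deviation(np.radians(a_deg), np.radians(b_deg)) == pytest.approx(expected)


def test_perfect_radial_map_has_zero_radial_deviation(rng):
    pol = rng.uniform(0, 2 * np.pi, 500)
    ideal = ideal_orientation(pol, np.ones(500), "radial")
    np.testing.assert_allclose(angular_deviation(pol % np.pi, ideal), 0.0, atol=1e-10)


@pytest.mark.parametrize("pol_deg,expected", [(0, 0), (45, 45), (100, 10), (260, 10), (359, 1)])
def test_distance_from_meridian(pol_deg, expected):
    assert distance_from_meridian(np.radians(pol_deg)) == pytest.approx(expected)


def test_ideal_maps_coincide_on_meridians(rng):
    """On the vertical meridian radial == vertical; on any meridian
    radial == cardinal — so their deviations agree there for any preference."""
    pref = rng.uniform(0, np.pi, 50)
    ecc = np.ones(50)
    up = np.full(50, np.pi / 2)
    assert np.allclose(
        angular_deviation(pref, ideal_orientation(up, ecc, "radial")),
        angular_deviation(pref, ideal_orientation(up, ecc, "vertical")),
    )
    for pol in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
        p = np.full(50, pol)
        assert np.allclose(
            angular_deviation(pref, ideal_orientation(p, ecc, "radial")),
            angular_deviation(pref, ideal_orientation(p, ecc, "cardinal")),
        )


def test_salt_and_pepper_map_deviates_45_from_every_ideal(rng):
    n = 2000
    pol = rng.uniform(0, 2 * np.pi, n)
    pref = rng.uniform(0, np.pi, n)
    for kind in ("radial", "vertical", "cardinal"):
        dev = angular_deviation(pref, ideal_orientation(pol, np.ones(n), kind))
        assert np.mean(dev) == pytest.approx(45.0, abs=2.0)


def _records(rng, n_sub=4, n_vox=300, noise_deg=20.0):
    rows = []
    for s in range(n_sub):
        pol = rng.uniform(0, 2 * np.pi, n_vox)
        ecc = rng.uniform(0.3, 6.0, n_vox)
        pref = (pol + np.radians(noise_deg) * rng.standard_normal(n_vox)) % np.pi
        rec = pd.DataFrame(
            {
                "subject": s,
                "prf_r2": rng.uniform(0.1, 0.9, n_vox),
                "eccentricity_deg": ecc,
                "polar_angle_rad": pol,
            }
        )
        for kind in ("radial", "vertical", "cardinal"):
            rec[f"dev_{kind}"] = angular_deviation(
                pref, ideal_orientation(pol, ecc, kind)
            )
        rows.append(rec)
    return pd.concat(rows, ignore_index=True)


def test_bin_edges_shapes():
    ecc = bin_edges("eccentricity", max_ecc=8.0)
    assert len(ecc) == 21 and ecc[0] == 0.0
    ratios = ecc[2:] / ecc[1:-1]
    np.testing.assert_allclose(ratios, ratios[0])  # exponential widths
    assert len(bin_edges("polar_angle")) == 21
    assert len(bin_edges("prf_r2")) == 21
    with pytest.raises(ValueError):
        bin_edges("voxel_volume")


def test_bin_summary_noisy_radial_map(rng):
    recs = _records(rng)
    summ = bin_summary(recs, axis="eccentricity")
    assert set(summ["kind"]) == {"radial", "vertical", "cardinal"}
    piv = summ.pivot_table(index="bin", columns="kind", values="group_mean")
    # radial deviation beats vertical in the (large) majority of bins
    assert (piv["radial"] < piv["vertical"]).mean() > 0.8


def test_bin_summary_excludes_negative_prf_r2(rng):
    recs = _records(rng, n_sub=2, n_vox=50)
    recs["prf_r2"] = -0.1
    assert bin_summary(recs).empty


def test_compare_deviations_identity_and_degenerate():
    res = compare_deviations(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
    assert res.t == 0.0 and res.p == 1.0
    res = compare_deviations(np.array([2.0, 3, 4]), np.array([1.0, 2, 3]))
    assert res.degenerate and res.p == 0.0 and np.isinf(res.t)
    with pytest.raises(ValueError):
        compare_deviations(np.array([1.0]), np.array([2.0]))


def test_compare_deviations_matches_t_distribution_power(rng):
    """Rejection rate for a 1-sigma mean difference at n = 8 matches the
    closed-form power of the one-sample t-test."""
    n, alpha, reps = 8, 0.05, 3000
    rejections = 0
    for _ in range(reps):
        d = rng.standard_normal(n) + 1.0
        res = compare_deviations(d, np.zeros(n))
        rejections += res.p < alpha
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    ncp = 1.0 * np.sqrt(n)
    power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp)
    assert rejections / reps == pytest.approx(power, abs=0.03)


def test_compare_deviations_df_is_subjects_minus_one(rng):
    res = compare_deviations(rng.random(8), rng.random(8))
    assert res.df == 7


def test_partial_correlation_against_two_stage_oracle(rng):
    n = 500
    z = rng.standard_normal(n)
    x = 0.8 * z + rng.standard_normal(n)
    y = 0.5 * z + rng.standard_normal(n)
    r, pr = deviation_meridian_correlation(x, y, z)
    # independent oracle: residualize both on z, then correlate
    rx = x - np.polyval(np.polyfit(z, x, 1), z)
    ry = y - np.polyval(np.polyfit(z, y, 1), z)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert pr == pytest.approx(oracle, abs=1e-10)
    assert pr < r  # planted confound inflates the raw correlation


def test_partial_correlation_edge_cases(rng):
    x = rng.standard_normal(200)
    z = rng.standard_normal(200)
    r, pr = deviation_meridian_correlation(x, x, z)
    assert r == pytest.approx(1.0)
    r2, pr2 = deviation_meridian_correlation(x, 0.5 * x + rng.standard_normal(200), z)
    assert pr2 == pytest.approx(r2, abs=0.05)  # z unrelated: partial ~ raw
    with pytest.raises(ValueError):
        deviation_meridian_correlation(x, np.zeros(200), z)
    with pytest.raises(ValueError):
        deviation_meridian_correlation(x[:5], x[:5], z[:5])


def test_circular_correlation_detects_axial_association(rng):
    a = rng.uniform(0, np.pi, 150)
    noisy = (a + 0.1 * rng.standard_normal(150)) % np.pi
    assert circular_correlation(a, a) == pytest.approx(1.0)
    r, p = circular_correlation_test(a, noisy, rng=0, n_perm=199)
    assert r > 0.8 and p < 0.01
    r_ind, p_ind = circular_correlation_test(a, rng.uniform(0, np.pi, 150), rng=0, n_perm=199)
    assert abs(r_ind) < 0.2 and p_ind > 0.01


def test_rayleigh_test_uniform_vs_concentrated(rng):
    _, p_unif = rayleigh_test(rng.uniform(0, np.pi, 200))
    assert p_unif > 0.01
    _, p_conc = rayleigh_test((0.8 + 0.1 * rng.standard_normal(200)) % np.pi)
    assert p_conc < 1e-6
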