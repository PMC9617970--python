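"""Quantifying coarse-scale orientation maps against ideal maps.

Three ideal maps are compared against measured orientation preferences:

* radial — each voxel prefers the orientation collinear with the line from
  fixation through its pRF center (preference = pRF polar angle mod pi);
* vertical — every voxel prefers pi/2;
* cardinal — vertical for pRFs whose polar angle is nearer the vertical
  meridian, horizontal for those nearer the horizontal meridian.

Per-voxel angular deviations (axial distance, degrees in [0, 90]) are binned
(20 bins) along eccentricity, polar angle, or pRF R^2; per-subject bin means
feed a paired t-test across subjects (df = n_subjects - 1, uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ideal_orientation",
    "angular_deviation",
    "distance_from_meridian",
    "bin_edges",
    "bin_summary",
    "compare_deviations",
    "deviation_meridian_correlation",
    "circular_correlation",
    "rayleigh_test",
    "plot_orientation_map",
]

MAP_KINDS = ("radial", "vertical", "cardinal")
N_BINS = 20


def ideal_orientation(polar_angle_rad, eccentricity_deg, kind: str):
    """Ideal-map preferred orientation (axial, [0, pi)) for pRF positions.

    At zero eccentricity the radial and cardinal predictions are undefined
    and NaN is returned for those entries. Polar angles exactly 45 degrees
    from both meridians are assigned vertical under the cardinal map
    (deterministic tie-break on a measure-zero set).
    """
    ang = np.asarray(polar_angle_rad, dtype=np.float64)
    ecc = np.asarray(eccentricity_deg, dtype=np.float64)
    if kind == "vertical":
        return np.full_like(ang, np.pi / 2)
    if kind == "radial":
        out = ang % np.pi
    elif kind == "cardinal":
        d_h = _axial_dist(ang % np.pi, 0.0)
        d_v = _axial_dist(ang % np.pi, np.pi / 2)
        out = np.where(d_v <= d_h, np.pi / 2, 0.0)
    else:
        raise ValueError(f"unknown ideal map kind {kind!r}")
    return np.where(ecc > 0, out, np.nan)


def _axial_dist(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % np.pi
    return np.minimum(d, np.pi - d)


def angular_deviation(a, b) -> np.ndarray | float:
    """Axial angular distance between two orientations, degrees in [0, 90]."""
    return np.degrees(_axial_dist(a, b))


def distance_from_meridian(polar_angle_rad) -> np.ndarray | float:
    """Angular distance of a pRF polar angle to the nearest meridian.

    Meridians are at 0, 90, 180 and 270 degrees; the result lies in [0, 45].
    """
    d = np.asarray(polar_angle_rad, dtype=np.float64) % (np.pi / 2)
    return np.degrees(np.minimum(d, np.pi / 2 - d))


def bin_edges(axis: str, values: np.ndarray | None = None, max_ecc: float | None = None) -> np.ndarray:
    """Edges of the 20 analysis bins for a given binning axis.

    Eccentricity bins widen exponentially (geometric edges from 0.1 deg up to
    ``max_ecc``, with the first bin extended down to 0); polar-angle bins are
    uniform over the full circle; pRF-R^2 bins uniform over [0, 1].
    """
    if axis == "eccentricity":
        if max_ecc is None:
            max_ecc = float(np.nanmax(values)) if values is not None else 8.52
        edges = np.geomspace(0.1, max_ecc, N_BINS)
        return np.concatenate([[0.0], edges])
    if axis == "polar_angle":
        return np.linspace(0.0, 2 * np.pi, N_BINS + 1)
    if axis == "prf_r2":
        return np.linspace(0.0, 1.0, N_BINS + 1)
    raise ValueError(f"unknown binning axis {axis!r}")


def bin_summary(
    records: pd.DataFrame,
    axis: str = "eccentricity",
    kinds: tuple[str, ...] = MAP_KINDS,
    max_ecc: float | None = None,
) -> pd.DataFrame:
    """Per-subject, per-bin mean deviations from each ideal map.

    ``records`` needs columns ``subject``, ``prf_r2``, the axis column
    (``eccentricity_deg``, ``polar_angle_rad`` or ``prf_r2``) and a
    ``dev_<kind>`` column per requested map kind. Voxels with negative pRF
    R^2 are excluded before binning. Returns a tidy frame with one row per
    (bin, kind): per-subject means as columns ``subject_<s>``, the group mean,
    and the paired-test result of each alternative kind against the first.
    """
    df = records.loc[records["prf_r2"] >= 0].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["bin", "bin_lo", "bin_hi", "bin_center", "kind", "n_voxels", "group_mean"]
        )
    axis_col = {
        "eccentricity": "eccentricity_deg",
        "polar_angle": "polar_angle_rad",
        "prf_r2": "prf_r2",
    }[axis]
    edges = bin_edges(axis, df[axis_col].to_numpy(), max_ecc=max_ecc)
    df["bin"] = pd.cut(df[axis_col], bins=edges, labels=False, include_lowest=True)
    df = df.dropna(subset=["bin"])

    subjects = sorted(df["subject"].unique())
    rows = []
    for b, grp in df.groupby("bin"):
        lo, hi = edges[int(b)], edges[int(b) + 1]
        for kind in kinds:
            col = f"dev_{kind}"
            means = {
                s: grp.loc[grp["subject"] == s, col].mean() for s in subjects
            }
            vals = np.array([means[s] for s in subjects], dtype=np.float64)
            rows.append(
                {
                    "bin": int(b),
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "bin_center": 0.5 * (lo + hi),
                    "kind": kind,
                    "n_voxels": int(len(grp)),
                    "group_mean": float(np.nanmean(vals)),
                    **{f"subject_{s}": means[s] for s in subjects},
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    p: float
    df: int
    mean_difference: float
    degenerate: bool = False


def compare_deviations(a_means: np.ndarray, b_means: np.ndarray) -> PairedTestResult:
    """Paired t-test on per-subject mean deviations (df = n - 1).

    Equivalently a one-sample t-test on the per-subject differences. A
    zero-variance difference is flagged degenerate (t = 0, p = 1 when the
    difference is identically zero; |t| = inf, p = 0 otherwise).
    """
    a = np.asarray(a_means, dtype=np.float64)
    b = np.asarray(b_means, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1D arrays")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        raise ValueError(f"paired test needs >= 2 subjects, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedTestResult(0.0, 1.0, n - 1, 0.0, degenerate=True)
        t = np.inf * np.sign(d.mean())
        return PairedTestResult(float(t), 0.0, n - 1, float(d.mean()), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n - 1, float(d.mean()))


def deviation_meridian_correlation(
    deviation: np.ndarray, meridian_distance: np.ndarray, prf_r2: np.ndarray
) -> tuple[float, float]:
    """(Pearson r, partial r controlling pRF R^2) of deviation vs meridian distance.

    The partial correlation uses the standard first-order formula
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``.
    """
    x = np.asarray(deviation, dtype=np.float64)
    y = np.asarray(meridian_distance, dtype=np.float64)
    z = np.asarray(prf_r2, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 voxels")
    for v in (x, y, z):
        if np.std(v) == 0:
            raise ValueError("zero variance in a correlation variable")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    partial = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return r_xy, float(partial)


# ---------------------------------------------------------------------------
# circular statistics helpers (axial data)
# ---------------------------------------------------------------------------


def circular_correlation(a: np.ndarray, b: np.ndarray, axial: bool = True) -> float:
    """Fisher-Lee circular correlation between two angle samples.

    Axial data (orientations, period pi) are doubled first. NaN pairs are
    dropped; returns NaN when fewer than 3 pairs remain.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        return float("nan")
    if axial:
        a, b = 2 * a, 2 * b
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    num = np.sum(np.sin(da) * np.sin(db))
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    if den == 0:
        return float("nan")
    return float(num / den)


def circular_correlation_test(
    a: np.ndarray,
    b: np.ndarray,
    axial: bool = True,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Permutation test of the Fisher-Lee coefficient; returns (r, p)."""
    rng = np.random.default_rng(rng)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    r = circular_correlation(a, b, axial=axial)
    if not np.isfinite(r):
        return r, float("nan")
    count = 1
    for _ in range(n_perm):
        r_perm = circular_correlation(a, rng.permutation(b), axial=axial)
        if abs(r_perm) >= abs(r):
            count += 1
    return r, count / (n_perm + 1)


def rayleigh_test(angles: np.ndarray, axial: bool = True) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (z, p).

    Axial data are doubled. Uses the standard finite-n corrected p-value
    approximation.
    """
    a = np.asarray(angles, dtype=np.float64)
    a = a[np.isfinite(a)]
    n = a.size
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    if axial:
        a = 2 * a
    rbar = np.abs(np.mean(np.exp(1j * a)))
    z = n * rbar**2
    p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    return float(z), float(min(max(p, 0.0), 1.0))


def plot_orientation_map(
    records: pd.DataFrame,
    ax=None,
    length_col: str = "cv_r2",
    color_by_orientation: bool = True,
):
    """Visual-space line plot of preferred orientations (one line per voxel).

    Each line sits at the voxel's pRF center, its angle the preferred
    orientation, its length (and hue, on a cyclic map) scaled by
    ``length_col`` (e.g. model R^2).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = records.dropna(subset=["pref_ori_rad"])
    weight = df[length_col].clip(lower=0).to_numpy() if length_col in df else np.ones(len(df))
    wmax = weight.max() if len(weight) and weight.max() > 0 else 1.0
    length = 0.25 + 0.5 * weight / wmax
    theta = df["pref_ori_rad"].to_numpy()
    x, y = df["x_deg"].to_numpy(), df["y_deg"].to_numpy()
    dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
    colors = plt.cm.hsv(theta / np.pi) if color_by_orientation else "k"
    for i in range(len(df)):
        c = colors[i] if color_by_orientation else colors
        ax.plot([x[i] - dx[i], x[i] + dx[i]], [y[i] - dy[i], y[i] + dy[i]], color=c, lw=1)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_aspect("equal")
    return ax
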