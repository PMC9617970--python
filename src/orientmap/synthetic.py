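"""Synthetic image ensembles and voxel populations with known ground truth.

Every stage of the encoding pipeline is validated by parameter recovery on
data generated here. Images stand in for broadband natural scenes:

* ``filtered_noise`` — Gaussian noise with a 1/f amplitude spectrum, the
  canonical second-order statistics of natural images;
* ``oriented_noise`` — 1/f noise whose amplitude spectrum is additionally
  modulated by a random anisotropic orientation envelope per image, so the
  ensemble actually exercises the orientation channels;
* ``grating_mix`` — random-parameter full-field gratings.

Voxels carry a pRF plus planted tuning: a von Mises profile on doubled
orientation angles (kappa = 0 means untuned, i.e. exactly the
orientation-pooled generative case) and a log-Gaussian spatial-frequency
profile over the octave-spaced levels. Responses follow the generative
direction of the encoding model: features . true weights + Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .prf import PRF
from .pyramid import PyramidSpec, center_frequencies
from .stimulus import make_grating, pixel_grid_deg
from .map_analysis import ideal_orientation

__all__ = [
    "GroundTruthVoxel",
    "make_image_ensemble",
    "make_voxel_population",
    "true_channel_weights",
    "simulate_responses",
    "noise_sd_for_target_r2",
    "vignetting_demo_stimuli",
]


@dataclass(frozen=True)
class GroundTruthVoxel:
    """A simulated voxel with planted tuning.

    ``ori_pref_rad`` may be NaN (untuned); ``kappa`` is the von Mises
    concentration on doubled angles (0 = no orientation tuning);
    ``sf_bw_octaves`` the SD of the log2-frequency tuning profile.
    """

    prf: PRF
    ori_pref_rad: float
    kappa: float
    sf_pref_cpd: float
    sf_bw_octaves: float = 1.0
    gain: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


# ---------------------------------------------------------------------------
# image ensembles
# ---------------------------------------------------------------------------


def _spectral_noise(
    rng: np.random.Generator,
    size_px: int,
    anisotropy: float = 0.0,
    rms_contrast: float = 0.15,
) -> np.ndarray:
    """1/f-amplitude Gaussian noise, optionally orientation-biased."""
    white = rng.standard_normal((size_px, size_px))
    F = np.fft.fft2(white)
    f = np.fft.fftfreq(size_px) * size_px
    fx, fy = f[np.newaxis, :], -f[:, np.newaxis]
    r = np.hypot(fx, fy)
    amp = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), 0.0)
    if anisotropy > 0:
        phi0 = rng.uniform(0, np.pi)
        phi = np.arctan2(fy, fx)
        amp = amp * (1.0 + anisotropy * np.cos(2 * (phi - phi0)))
    img = np.fft.ifft2(F * amp).real
    img = img - img.mean()
    sd = img.std()
    if sd > 0:
        img = img * (rms_contrast / sd)
    return 0.5 + img


def make_image_ensemble(
    n: int,
    kind: str = "oriented_noise",
    size_px: int = 512,
    fov_deg: float = 8.4 * 1024 / 714,
    seed: np.random.Generator | int | None = 0,
    anisotropy: float = 0.8,
) -> np.ndarray:
    """Deterministic (seeded) ensemble of synthetic grayscale images.

    Returns an (n, size_px, size_px) array of normalized-intensity images.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nyq = (size_px / 2) / fov_deg
    out = np.empty((n, size_px, size_px))
    if kind == "filtered_noise":
        for i in range(n):
            out[i] = _spectral_noise(rng, size_px)
    elif kind == "oriented_noise":
        for i in range(n):
            out[i] = _spectral_noise(rng, size_px, anisotropy=anisotropy)
    elif kind == "grating_mix":
        for i in range(n):
            sf = np.exp(rng.uniform(np.log(1.0 / fov_deg), np.log(nyq / 2)))
            out[i] = make_grating(
                sf,
                rng.uniform(0, np.pi),
                phase=rng.uniform(0, 2 * np.pi),
                contrast=rng.uniform(0.3, 1.0),
                size_px=size_px,
                fov_deg=fov_deg,
            )
    else:
        raise ValueError(f"unknown ensemble kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# voxel populations
# ---------------------------------------------------------------------------


def make_voxel_population(
    n_voxels: int,
    map_kind: str = "radial",
    seed: np.random.Generator | int | None = 0,
    ecc_range: tuple[float, float] = (0.5, 5.0),
    kappa: float = 2.0,
    sf_pref_range_cpd: tuple[float, float] = (0.4, 2.0),
    sf_bw_octaves: float = 1.0,
    gain: float = 1.0,
) -> list[GroundTruthVoxel]:
    """Voxels with pRFs scattered over the field and a planted preference map.

    ``map_kind``: ``radial`` | ``vertical`` | ``cardinal`` | ``saltpepper``
    (uniform random preferences) | ``untuned`` (kappa forced to 0). pRF
    eccentricities are area-uniform within ``ecc_range``; sizes grow linearly
    with eccentricity (sigma = 0.25 + 0.1 ecc degrees, a V1-like scaling);
    planted pRF-fit R^2 values are uniform on [0.2, 0.8].
    """
    rng = np.random.default_rng(seed)
    lo, hi = ecc_range
    voxels = []
    for _ in range(n_voxels):
        ecc = np.sqrt(rng.uniform(lo**2, hi**2))
        pol = rng.uniform(0, 2 * np.pi)
        prf = PRF(
            x_deg=ecc * np.cos(pol),
            y_deg=ecc * np.sin(pol),
            sigma_deg=0.25 + 0.1 * ecc,
            r2=rng.uniform(0.2, 0.8),
        )
        if map_kind == "saltpepper":
            pref, k = rng.uniform(0, np.pi), kappa
        elif map_kind == "untuned":
            pref, k = float("nan"), 0.0
        elif map_kind in ("radial", "vertical", "cardinal"):
            pref = float(ideal_orientation(pol, ecc, map_kind))
            k = kappa
        else:
            raise ValueError(f"unknown map kind {map_kind!r}")
        sf = np.exp(rng.uniform(*np.log(sf_pref_range_cpd)))
        voxels.append(
            GroundTruthVoxel(
                prf=prf,
                ori_pref_rad=pref,
                kappa=k,
                sf_pref_cpd=float(sf),
                sf_bw_octaves=sf_bw_octaves,
                gain=gain,
            )
        )
    return voxels


def voxel_table(voxels: list[GroundTruthVoxel], subject: int = 0) -> pd.DataFrame:
    """Tidy pRF + ground-truth table for a voxel population."""
    rows = []
    for i, v in enumerate(voxels):
        rows.append(
            {
                "subject": subject,
                "voxel_id": i,
                "x_deg": v.prf.x_deg,
                "y_deg": v.prf.y_deg,
                "sigma_deg": v.prf.sigma_deg,
                "prf_r2": v.prf.r2,
                "eccentricity_deg": v.prf.eccentricity_deg,
                "polar_angle_rad": v.prf.polar_angle_rad,
                "true_ori_rad": v.ori_pref_rad,
                "true_sf_cpd": v.sf_pref_cpd,
                "kappa": v.kappa,
            }
        )
    return pd.DataFrame(rows)


def true_channel_weights(voxel: GroundTruthVoxel, spec: PyramidSpec) -> np.ndarray:
    """Planted channel weights, flattened level-major (length n_channels).

    Orientation profile: von Mises on doubled angles, peak-normalized
    (``exp(kappa (cos(2 dtheta) - 1))``; kappa = 0 gives equal weights, the
    orientation-pooled generative case). Spatial-frequency profile: Gaussian
    in log2 cpd across level center frequencies.
    """
    thetas = spec.orientations
    if voxel.kappa == 0 or not np.isfinite(voxel.ori_pref_rad):
        ori_w = np.ones(spec.n_orientations)
    else:
        d = 2 * (thetas - voxel.ori_pref_rad)
        ori_w = np.exp(voxel.kappa * (np.cos(d) - 1.0))
    cpds = np.array([cpd for _, cpd in center_frequencies(spec)])
    sf_w = np.exp(
        -((np.log2(cpds) - np.log2(voxel.sf_pref_cpd)) ** 2)
        / (2 * voxel.sf_bw_octaves**2)
    )
    return (voxel.gain * sf_w[:, np.newaxis] * ori_w[np.newaxis, :]).reshape(-1)


def simulate_responses(
    features_full: np.ndarray,
    voxels: list[GroundTruthVoxel],
    spec: PyramidSpec,
    seed: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Responses = features . true weights + Gaussian noise, seeded.

    ``features_full`` is (n_images, n_voxels, n_channels) — each voxel's
    pRF-sampled channel outputs (see :func:`orientmap.pipeline.compute_feature_matrix`).
    """
    rng = np.random.default_rng(seed)
    n_img, n_vox, _ = features_full.shape
    if n_vox != len(voxels):
        raise ValueError("feature matrix / voxel list mismatch")
    resp = np.empty((n_img, n_vox))
    for i, v in enumerate(voxels):
        w = true_channel_weights(v, spec)
        signal = features_full[:, i, :] @ w
        resp[:, i] = signal + rng.normal(0.0, v.noise_sd, size=n_img) if v.noise_sd > 0 else signal
    return resp


def noise_sd_for_target_r2(signal: np.ndarray, target_r2: float) -> float:
    """Noise SD that sets the expected explainable variance fraction.

    With additive white noise, R^2_max = var(signal) / (var(signal) +
    noise_sd^2); invert for noise_sd. Cross-validated R^2 comes out slightly
    below the target because weights are estimated.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    return float(np.std(signal) * np.sqrt(1.0 / target_r2 - 1.0))


def calibrate_noise(
    voxels: list[GroundTruthVoxel],
    features_full: np.ndarray,
    spec: PyramidSpec,
    target_r2: float,
) -> list[GroundTruthVoxel]:
    """Set each voxel's noise SD so its explainable variance is ``target_r2``."""
    out = []
    for i, v in enumerate(voxels):
        signal = features_full[:, i, :] @ true_channel_weights(v, spec)
        out.append(replace(v, noise_sd=noise_sd_for_target_r2(signal, target_r2)))
    return out


# ---------------------------------------------------------------------------
# vignetting demonstration stimuli
# ---------------------------------------------------------------------------


def vignetting_demo_stimuli(
    sf_cpd: float,
    aperture_radius_deg: float,
    n_orientations: int = 16,
    n_phases: int = 8,
    size_px: int = 512,
    fov_deg: float = 8.4 * 1024 / 714,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-field gratings hard-masked by a circular aperture on gray.

    Returns ``(images, orientations, phases)`` with images ordered
    orientation-major. The aperture edge is where the vignetting effect
    lives: locally, the windowed grating has excess energy at the orientation
    radial to the aperture center. A radius at or beyond the image
    half-diagonal leaves no edge in view (the gratings come out unmasked and
    no vignette-driven preference can arise).
    """
    if aperture_radius_deg <= 0:
        raise ValueError("aperture radius must be positive")
    x, y = pixel_grid_deg(size_px, fov_deg)
    mask = (x**2 + y**2) <= aperture_radius_deg**2
    oris = np.arange(n_orientations) * np.pi / n_orientations
    phases = np.arange(n_phases) * 2 * np.pi / n_phases
    images = np.empty((n_orientations * n_phases, size_px, size_px))
    i = 0
    for ori in oris:
        for ph in phases:
            g = make_grating(sf_cpd, ori, phase=ph, size_px=size_px, fov_deg=fov_deg)
            images[i] = 0.5 + mask * (g - 0.5)
            i += 1
    return images, oris, phases
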