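"""End-to-end drivers tying the pipeline stages together.

The expensive step is the pyramid transform, which is shared across voxels:
each image is decomposed once and sampled through every pRF in one matrix
product. Everything downstream (OLS fits, grating probes, map statistics)
works from the resulting feature matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import encoding, map_analysis, tuning
from .prf import PRF, weight_map_matrix
from .pyramid import PyramidSpec, decompose_energy
from .synthetic import GroundTruthVoxel

__all__ = [
    "compute_feature_matrix",
    "analyze_responses",
    "deviation_records",
    "run_vignetting_demo",
]


def compute_feature_matrix(
    images: np.ndarray,
    prfs: list[PRF],
    spec: PyramidSpec,
) -> np.ndarray:
    """pRF-sampled channel outputs for every (image, voxel) pair.

    Returns (n_images, n_voxels, n_channels), channels level-major. Each
    image is decomposed once; sampling through all pRFs is a single
    (channels x pixels) @ (pixels x voxels) product.
    """
    W = weight_map_matrix(prfs, spec.image_size_px, spec.fov_deg)
    n_img = len(images)
    feats = np.empty((n_img, len(prfs), spec.n_channels))
    for j in range(n_img):
        tensor = decompose_energy(images[j], spec)
        flat = tensor.data.reshape(spec.n_channels, -1)
        feats[j] = (flat @ W).T
    return feats


def analyze_responses(
    features_full: np.ndarray,
    responses: np.ndarray,
    spec: PyramidSpec,
    partition: tuple[np.ndarray, np.ndarray],
    probes: tuning.ProbeSet | None = None,
    control: str = "none",
) -> pd.DataFrame:
    """Fit both model forms per voxel and infer tuning from the full model.

    ``control`` selects the weights used for tuning inference: ``none``
    (plain cross-validated full-model fit), ``residual`` or ``prediction``
    (the two control analyses). Returns one row per voxel with cv R^2 of
    both models and the grating-probe tuning estimates.
    """
    n_img, n_vox, n_chan = features_full.shape
    feats_con = encoding.constrain_features(features_full, spec.n_orientations)
    if probes is None:
        probes = tuning.compute_probe_features(spec)

    rows = []
    for v in range(n_vox):
        Xf, Xc, y = features_full[:, v, :], feats_con[:, v, :], responses[:, v]
        fit_full = encoding.cross_validated_fit(Xf, y, partition)
        fit_con = encoding.cross_validated_fit(Xc, y, partition)
        if control == "none":
            beta = fit_full.beta
        elif control == "residual":
            beta = encoding.residual_control_fit(Xf, Xc, y, partition).beta
        elif control == "prediction":
            beta = encoding.prediction_control_fit(Xf, Xc, y, partition).beta
        else:
            raise ValueError(f"unknown control {control!r}")
        est = tuning.estimate_tuning(beta, probes)
        rows.append(
            {
                "voxel_id": v,
                "cv_r2_full": fit_full.cv_r2,
                "cv_r2_constrained": fit_con.cv_r2,
                "pref_ori_rad": est.preferred_orientation_rad,
                "pref_sf_cpd": est.preferred_sf_cpd,
                "ori_selectivity": est.orientation_selectivity,
            }
        )
    return pd.DataFrame(rows)


def run_vignetting_demo(
    spec: PyramidSpec,
    sf_cpd: float = 1.0,
    aperture_radius_deg: float = 3.5,
    interior_radius_deg: float = 1.2,
    n_stim_orientations: int = 24,
    n_phases: int = 6,
    n_voxels_per_ring: int = 24,
    sigma_deg: float = 0.5,
) -> pd.DataFrame:
    """Simulate apparent orientation preference of orientation-pooled voxels.

    Untuned (kappa = 0) voxels are placed on two rings — one on the aperture
    edge, one well inside it — and driven by apertured gratings at many
    orientations and phases. The apparent preference of each voxel is read
    directly off its phase-averaged response profile over stimulus
    orientation. Edge voxels acquire a radial apparent preference (stimulus
    vignetting); interior voxels see an unapertured grating locally and show
    only weak modulation.
    """
    from .synthetic import GroundTruthVoxel, simulate_responses, vignetting_demo_stimuli

    images, oris, phases = vignetting_demo_stimuli(
        sf_cpd,
        aperture_radius_deg,
        n_orientations=n_stim_orientations,
        n_phases=n_phases,
        size_px=spec.image_size_px,
        fov_deg=spec.fov_deg,
    )
    voxels, labels = [], []
    for ring, label in ((aperture_radius_deg, "edge"), (interior_radius_deg, "interior")):
        for k in range(n_voxels_per_ring):
            pol = k * 2 * np.pi / n_voxels_per_ring + 0.05
            voxels.append(
                GroundTruthVoxel(
                    prf=PRF(
                        x_deg=ring * np.cos(pol),
                        y_deg=ring * np.sin(pol),
                        sigma_deg=sigma_deg,
                        r2=0.5,
                    ),
                    ori_pref_rad=float("nan"),
                    kappa=0.0,
                    sf_pref_cpd=sf_cpd,
                )
            )
            labels.append(label)

    feats = compute_feature_matrix(images, [v.prf for v in voxels], spec)
    resp = simulate_responses(feats, voxels, spec, seed=0)  # noiseless
    profile = resp.reshape(n_stim_orientations, n_phases, len(voxels)).mean(axis=1)

    rows = []
    for i, v in enumerate(voxels):
        pref, depth = tuning.apparent_orientation_from_responses(
            profile[:, i], oris
        )
        pol = v.prf.polar_angle_rad
        rows.append(
            {
                "label": labels[i],
                "x_deg": v.prf.x_deg,
                "y_deg": v.prf.y_deg,
                "polar_angle_rad": pol,
                "apparent_pref_rad": pref,
                "modulation_depth": depth,
                "dev_radial": float(
                    map_analysis.angular_deviation(pref, pol % np.pi)
                ),
            }
        )
    return pd.DataFrame(rows)


def deviation_records(
    results: pd.DataFrame, prf_table: pd.DataFrame
) -> pd.DataFrame:
    """Join tuning results with pRF geometry and add map-deviation columns.

    Adds ``dev_radial`` / ``dev_vertical`` / ``dev_cardinal`` (degrees) and
    ``meridian_dist_deg`` per voxel; rows with undefined preference keep NaN
    deviations.
    """
    df = prf_table.merge(results, on="voxel_id", how="inner")
    pol = df["polar_angle_rad"].to_numpy()
    ecc = df["eccentricity_deg"].to_numpy()
    pref = df["pref_ori_rad"].to_numpy()
    for kind in map_analysis.MAP_KINDS:
        ideal = map_analysis.ideal_orientation(pol, ecc, kind)
        df[f"dev_{kind}"] = map_analysis.angular_deviation(pref, ideal)
    df["meridian_dist_deg"] = map_analysis.distance_from_meridian(pol)
    return df
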