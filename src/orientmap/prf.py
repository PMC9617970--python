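"""Population receptive fields and pRF-weighted sampling of energy maps.

A voxel's pRF is a 2D isotropic Gaussian in visual space; sampling a filter's
energy map through it is the plain (unnormalized) dot product

    f = sum_{x,y} F(x, y) * exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2))

evaluated at pixel centers. The Gaussian is deliberately *not* renormalized
and is truncated at the image border, matching the definition of the sampled
feature. The pRF "size" is used directly as the Gaussian standard deviation
(for datasets fit with a compressive spatial-summation model the published
size already folds in the exponent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pyramid import EnergyTensor
from .stimulus import pixel_grid_deg

__all__ = ["PRF", "prf_weight_map", "sample_features", "load_prf_table", "save_prf_table"]


@dataclass(frozen=True)
class PRF:
    """One voxel's population receptive field.

    Coordinates are visual degrees with the origin at fixation, x rightward,
    y upward. ``r2`` is the variance explained by the pRF model fit (may be
    negative for bad fits; used downstream as an inclusion criterion).
    """

    x_deg: float
    y_deg: float
    sigma_deg: float
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if not self.sigma_deg > 0:
            raise ValueError(f"sigma_deg must be > 0, got {self.sigma_deg}")

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))

    @property
    def polar_angle_rad(self) -> float:
        """Polar angle in [0, 2*pi), counterclockwise from the right horizontal."""
        return float(np.arctan2(self.y_deg, self.x_deg) % (2 * np.pi))


def prf_weight_map(prf: PRF, size_px: int, fov_deg: float) -> np.ndarray:
    """Unnormalized Gaussian pRF evaluated at pixel centers (peak value 1).

    Warns when the pRF is under-resolved (sigma below half a pixel).
    """
    deg_per_px = fov_deg / size_px
    if prf.sigma_deg < deg_per_px / 2:
        warnings.warn(
            f"pRF sigma {prf.sigma_deg:.4g} deg is below half a pixel "
            f"({deg_per_px / 2:.4g} deg); sampling is under-resolved",
            stacklevel=2,
        )
    x, y = pixel_grid_deg(size_px, fov_deg)
    return np.exp(
        -((x - prf.x_deg) ** 2 + (y - prf.y_deg) ** 2) / (2 * prf.sigma_deg**2)
    )


def sample_features(tensor: EnergyTensor, prf: PRF) -> np.ndarray:
    """Sample every channel of an energy tensor through one pRF.

    Returns the flattened (level-major) feature vector: length
    ``n_levels * n_orientations`` for a full tensor, ``n_levels`` for a
    constrained one. Constrained features equal the orientation-group sums of
    the full features because the dot product is linear.
    """
    spec = tensor.spec
    w = prf_weight_map(prf, spec.image_size_px, spec.fov_deg)
    return np.tensordot(tensor.data, w, axes=([-2, -1], [0, 1])).reshape(-1)


def weight_map_matrix(prfs: list[PRF], size_px: int, fov_deg: float) -> np.ndarray:
    """Stacked flattened pRF maps, shape (size_px**2, n_voxels)."""
    return np.stack(
        [prf_weight_map(p, size_px, fov_deg).ravel() for p in prfs], axis=1
    )


_PRF_COLUMNS = ["voxel_id", "x_deg", "y_deg", "sigma_deg", "prf_r2", "roi"]


def load_prf_table(path) -> pd.DataFrame:
    """Read a pRF table (CSV) and add derived eccentricity / polar angle."""
    df = pd.read_csv(path)
    missing = set(_PRF_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"pRF table missing columns: {sorted(missing)}")
    df["eccentricity_deg"] = np.hypot(df["x_deg"], df["y_deg"])
    df["polar_angle_rad"] = np.arctan2(df["y_deg"], df["x_deg"]) % (2 * np.pi)
    return df


def save_prf_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in _PRF_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)
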