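"""Preferred orientation and spatial frequency via a simulated grating probe.

A fitted voxel is "probed" the way a neuron would be in an electrophysiology
experiment: full-contrast gratings on a 30 x 30 grid (spatial frequencies
exponentially spaced from one cycle per image to Nyquist; orientations
uniform on [0, pi)) are passed through the pyramid, each channel's energy map
is summed over space (no pRF weighting), and the voxel's predicted response
is the dot product of those channel sums with its fitted weights. The
preferred orientation is the amplitude-weighted circular mean of the
orientation profile (axial data: angles doubled), and the preferred spatial
frequency the amplitude-weighted mean of the SF profile; the minimum is
subtracted from each profile first so weights are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pyramid import PyramidSpec, channel_energy_sums
from .stimulus import make_grating

__all__ = [
    "ProbeSet",
    "compute_probe_features",
    "probe_responses",
    "preferred_orientation",
    "preferred_sf",
    "TuningEstimate",
    "estimate_tuning",
    "apparent_orientation_from_responses",
    "orientation_selectivity",
]

# a profile whose peak-to-trough modulation is below this fraction of its
# absolute scale is treated as flat -> undefined preference
FLAT_TOL = 1e-9


@dataclass
class ProbeSet:
    """Grating probe grid with precomputed channel energy sums.

    ``features`` has shape (n_sf, n_ori, n_channels), channels level-major
    to match design-matrix ordering.
    """

    spec: PyramidSpec
    sfs_cpd: np.ndarray
    orientations: np.ndarray
    features: np.ndarray


def compute_probe_features(
    spec: PyramidSpec, n_sf: int = 30, n_ori: int = 30
) -> ProbeSet:
    """Channel energy sums for every probe grating (spectral fast path)."""
    if n_sf < 2 or n_ori < 2:
        raise ValueError("probe grid needs at least 2 points per axis")
    sfs = np.geomspace(1.0 / spec.fov_deg, spec.nyquist_cpd, n_sf)
    oris = np.arange(n_ori) * np.pi / n_ori
    feats = np.empty((n_sf, n_ori, spec.n_channels))
    for i, sf in enumerate(sfs):
        for j, ori in enumerate(oris):
            g = make_grating(sf, ori, size_px=spec.image_size_px, fov_deg=spec.fov_deg)
            feats[i, j] = channel_energy_sums(g, spec)
    return ProbeSet(spec=spec, sfs_cpd=sfs, orientations=oris, features=feats)


def probe_responses(beta: np.ndarray, probes: ProbeSet) -> np.ndarray:
    """Simulated response grid (n_sf, n_ori) = probe features . weights + const."""
    beta = np.asarray(beta, dtype=np.float64)
    n_chan = probes.features.shape[-1]
    if beta.shape[0] == n_chan + 1:
        channel_beta, const = beta[:-1], beta[-1]
    elif beta.shape[0] == n_chan:
        channel_beta, const = beta, 0.0
    else:
        raise ValueError(
            f"beta length {beta.shape[0]} does not match {n_chan} channels"
        )
    return probes.features @ channel_beta + const


def _min_subtracted(profile: np.ndarray) -> np.ndarray | None:
    w = profile - profile.min()
    scale = np.max(np.abs(profile))
    if scale == 0 or w.max() <= FLAT_TOL * scale:
        return None  # flat profile: preference undefined
    return w


def preferred_orientation(grid: np.ndarray, orientations: np.ndarray) -> float:
    """Amplitude-weighted axial circular mean of the orientation profile.

    The grid is averaged across SF rows, the minimum subtracted, and the
    circular mean computed on doubled angles:
    ``0.5 * arg(sum w exp(2i theta))`` mapped to [0, pi). Returns NaN when
    the profile is flat (zero resultant) — an undefined preference, not an
    error.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if not np.isfinite(grid).all():
        raise ValueError("probe response grid contains non-finite values")
    w = _min_subtracted(grid.mean(axis=0))
    if w is None:
        return float("nan")
    resultant = np.sum(w * np.exp(2j * np.asarray(orientations)))
    if np.abs(resultant) <= FLAT_TOL * w.sum():
        return float("nan")
    return float((np.angle(resultant) / 2) % np.pi)


def preferred_sf(
    grid: np.ndarray, sfs_cpd: np.ndarray, domain: str = "log"
) -> float:
    """Amplitude-weighted mean spatial frequency of the SF profile.

    The grid is averaged across orientation columns and the minimum
    subtracted. With ``domain="log"`` (default) the weighted mean is taken in
    log2 frequency and exponentiated back — the natural choice for
    exponentially spaced probes and octave-spaced channels; ``domain="linear"``
    averages in cpd directly. Returns NaN for a flat profile.
    """
    if domain not in ("log", "linear"):
        raise ValueError(f"unknown domain {domain!r}")
    grid = np.asarray(grid, dtype=np.float64)
    w = _min_subtracted(grid.mean(axis=1))
    if w is None:
        return float("nan")
    sfs = np.asarray(sfs_cpd, dtype=np.float64)
    if domain == "log":
        return float(2.0 ** (np.sum(w * np.log2(sfs)) / w.sum()))
    return float(np.sum(w * sfs) / w.sum())


def apparent_orientation_from_responses(
    responses: np.ndarray, stim_orientations: np.ndarray
) -> tuple[float, float]:
    """Apparent preferred orientation read directly off measured responses.

    ``responses`` are one voxel's (possibly phase-averaged) responses to
    oriented stimuli — the readout of a classic orientation-mapping
    experiment, with no encoding model in between. Returns ``(preference,
    modulation_depth)`` where the preference is the min-subtracted,
    amplitude-weighted axial circular mean over stimulus orientation (NaN if
    flat) and the modulation depth is ``(max - min) / |mean|`` of the
    response profile. Stimulus vignetting shows up here: orientation-pooled
    (untuned) voxels near an aperture edge acquire an apparent preference for
    the radial orientation.
    """
    r = np.asarray(responses, dtype=np.float64)
    oris = np.asarray(stim_orientations, dtype=np.float64)
    if r.shape != oris.shape:
        raise ValueError("responses and stim_orientations must align")
    mean_abs = np.abs(r.mean())
    depth = float((r.max() - r.min()) / mean_abs) if mean_abs > 0 else float("inf")
    w = _min_subtracted(r)
    if w is None:
        return float("nan"), depth
    resultant = np.sum(w * np.exp(2j * oris))
    if np.abs(resultant) <= FLAT_TOL * w.sum():
        return float("nan"), depth
    return float((np.angle(resultant) / 2) % np.pi), depth


@dataclass
class TuningEstimate:
    """Grating-probe tuning summary for one voxel."""

    preferred_orientation_rad: float
    preferred_sf_cpd: float
    response_max: float
    response_min: float
    orientation_selectivity: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.preferred_orientation_rad)


def orientation_selectivity(grid: np.ndarray, orientations: np.ndarray) -> float:
    """Normalized resultant length of the orientation profile (0 = flat/untuned)."""
    w = _min_subtracted(np.asarray(grid, dtype=np.float64).mean(axis=0))
    if w is None:
        return 0.0
    return float(np.abs(np.sum(w * np.exp(2j * np.asarray(orientations)))) / w.sum())


def estimate_tuning(
    beta: np.ndarray, probes: ProbeSet, sf_domain: str = "log"
) -> TuningEstimate:
    """Run the grating probe for one voxel's fitted weights."""
    grid = probe_responses(beta, probes)
    return TuningEstimate(
        preferred_orientation_rad=preferred_orientation(grid, probes.orientations),
        preferred_sf_cpd=preferred_sf(grid, probes.sfs_cpd, domain=sf_domain),
        response_max=float(grid.max()),
        response_min=float(grid.min()),
        orientation_selectivity=orientation_selectivity(grid, probes.orientations),
    )
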