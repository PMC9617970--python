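"""Stimulus preparation: display geometry, image preprocessing, gratings.

Images live in normalized intensity (0 = black, 1 = white, background gray
0.5) as plain float64 arrays. Visual-space coordinates put the origin at
fixation, x rightward and y upward; array row 0 is the *top* of the image, so
visual y decreases with row index. Pixel (i, j) is centered at
``x = (j + 0.5 - N/2) * deg_per_px``, ``y = -(i + 0.5 - N/2) * deg_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["DisplaySpec", "preprocess", "make_grating", "make_probe_grid", "pixel_grid_deg"]


@dataclass(frozen=True)
class DisplaySpec:
    """Geometry of the display chain that produced the working images.

    Native photographs (``native_px``) are upsampled for display, padded with
    a gray border to mimic the surrounding screen, then downsampled to the
    working resolution. The field of view of the working image follows from
    the padding ratio: ``stimulus_deg * padded_px / upsampled_px``.
    """

    native_px: int = 425
    upsampled_px: int = 714
    padded_px: int = 1024
    working_px: int = 512
    stimulus_deg: float = 8.4
    background_gray: float = 0.5
    fixation_radius_deg: float = 0.1
    fixation_gray: float = 0.25

    @property
    def fov_deg(self) -> float:
        return self.stimulus_deg * self.padded_px / self.upsampled_px

    @property
    def nyquist_cpd(self) -> float:
        return (self.working_px / 2) / self.fov_deg

    @property
    def deg_per_px(self) -> float:
        return self.fov_deg / self.working_px


def pixel_grid_deg(size_px: int, fov_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) visual-degree coordinates of pixel centers, broadcastable 2D."""
    step = fov_deg / size_px
    c = (np.arange(size_px) + 0.5 - size_px / 2) * step
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]
    return x, y


def preprocess(rgb_image: np.ndarray, display: DisplaySpec | None = None) -> np.ndarray:
    """Run the display-emulation chain on one RGB photograph.

    Upsample to the display resolution, pad with the background gray to the
    full screen, draw the central fixation disk, convert to grayscale by
    averaging the three channels, and downsample (anti-aliased) to the
    working resolution. Accepts a ``native_px`` or ``upsampled_px`` square
    input with 3 channels; values are assumed normalized to [0, 1].
    """
    display = display or DisplaySpec()
    img = np.asarray(rgb_image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square HxWx3 image, got shape {img.shape}")
    if img.shape[0] == display.native_px:
        img = resize(
            img,
            (display.upsampled_px, display.upsampled_px),
            anti_aliasing=False,
            order=1,
            preserve_range=True,
        )
    elif img.shape[0] != display.upsampled_px:
        raise ValueError(
            f"input side {img.shape[0]} is neither native ({display.native_px}) "
            f"nor upsampled ({display.upsampled_px})"
        )

    P = display.padded_px
    padded = np.full((P, P, 3), display.background_gray)
    off = (P - display.upsampled_px) // 2
    padded[off : off + display.upsampled_px, off : off + display.upsampled_px] = img

    # fixation disk, drawn before grayscale conversion
    x, y = pixel_grid_deg(P, display.fov_deg)
    disk = (x**2 + y**2) <= display.fixation_radius_deg**2
    padded[disk] = display.fixation_gray

    gray = padded.mean(axis=2)
    out = resize(
        gray,
        (display.working_px, display.working_px),
        anti_aliasing=True,
        preserve_range=True,
    )
    return out


def make_grating(
    sf_cpd: float,
    orientation: float,
    phase: float = 0.0,
    contrast: float = 1.0,
    display: DisplaySpec | None = None,
    size_px: int | None = None,
    fov_deg: float | None = None,
) -> np.ndarray:
    """Full-field sinusoidal grating in normalized intensity.

    ``orientation`` is the stripe orientation (radians, [0, pi)): 0 gives
    horizontal stripes (a single vertical cycle of modulation per 1/sf_cpd
    degrees), pi/2 vertical stripes. Mean luminance is the background gray;
    ``contrast = 1`` spans the full [0, 1] range.
    """
    display = display or DisplaySpec()
    size_px = size_px if size_px is not None else display.working_px
    fov_deg = fov_deg if fov_deg is not None else display.fov_deg
    nyq = (size_px / 2) / fov_deg
    if not 0 < sf_cpd <= nyq:
        raise ValueError(f"sf_cpd={sf_cpd} outside (0, Nyquist={nyq:.4g}]")
    x, y = pixel_grid_deg(size_px, fov_deg)
    carrier = np.cos(
        2 * np.pi * sf_cpd * (-x * np.sin(orientation) + y * np.cos(orientation))
        + phase
    )
    return 0.5 + 0.5 * contrast * carrier


def probe_grid_params(
    display: DisplaySpec | None = None, n_sf: int = 30, n_ori: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """(spatial frequencies, orientations) of the grating probe grid.

    SFs run exponentially from one cycle per image to the Nyquist frequency;
    orientations are uniform on [0, pi), excluding pi.
    """
    if n_sf < 2 or n_ori < 2:
        raise ValueError("probe grid needs at least 2 points per axis")
    display = display or DisplaySpec()
    sfs = np.geomspace(1.0 / display.fov_deg, display.nyquist_cpd, n_sf)
    oris = np.arange(n_ori) * np.pi / n_ori
    return sfs, oris


def make_probe_grid(
    display: DisplaySpec | None = None, n_sf: int = 30, n_ori: int = 30
):
    """Yield ``(image, sf_cpd, orientation)`` for the full probe grid.

    Generated lazily (900 images at the default 512 px would be ~2 GB if
    materialized). Iteration order is SF-major to match the probe response
    grid layout (rows = SFs, columns = orientations).
    """
    display = display or DisplaySpec()
    sfs, oris = probe_grid_params(display, n_sf, n_ori)
    for sf in sfs:
        for ori in oris:
            yield make_grating(sf, ori, display=display), float(sf), float(ori)
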