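"""Steerable-pyramid filter bank and quadrature-pair energy responses.

The bank is constructed directly in the frequency domain. Radial windows are
raised cosines in log2 spatial frequency (one per bandpass level, spaced by
the bandwidth in octaves so that their squared magnitudes tile the spectrum
exactly between the coarsest and finest center frequencies). Angular windows
are ``cos^(K-1)`` lobes restricted to a half plane, which makes each subband
an analytic (complex-valued) filter: the real and imaginary parts of its
spatial response form the even/odd quadrature pair, and the squared modulus
of the complex response is the phase-invariant energy.

Orientation convention (shared by every module): angles are radians in
``[0, pi)``, measured counterclockwise from the positive horizontal axis of
visual space, and refer to the *stripe* orientation of a grating
(0 = horizontal stripes, pi/2 = vertical). Channel centers sit at
``k * pi / n_orientations``. In the frequency plane the power of a grating
with stripe orientation ``theta`` lies along ``theta + pi/2``, which is where
the corresponding angular window is centered.

The residual high-pass and low-pass bands are discarded: only the bandpass
levels enter the encoding models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterator

import numpy as np

__all__ = [
    "PyramidSpec",
    "EnergyTensor",
    "n_levels_for",
    "center_frequencies",
    "decompose_energy",
    "constrain",
    "channel_energy_sums",
]


def n_levels_for(image_size_px: int, bandwidth_octaves: float) -> int:
    """Number of bandpass levels that fit for a given image size and bandwidth.

    Center frequencies start at ``image_size_px / 4`` cycles per image (half
    the Nyquist frequency) and descend by ``bandwidth_octaves`` octaves per
    level while they remain above one cycle per image.
    """
    if image_size_px < 8:
        raise ValueError(f"image_size_px must be >= 8, got {image_size_px}")
    if bandwidth_octaves <= 0:
        raise ValueError(f"bandwidth_octaves must be > 0, got {bandwidth_octaves}")
    top_octave = np.log2(image_size_px / 4.0)
    if top_octave <= 0:
        raise ValueError("image too small for any bandpass level")
    # centers 2**(top_octave - b*k) for k = 0.. while strictly above 1 c/i
    return int(np.ceil(top_octave / bandwidth_octaves - 1e-12))


@dataclass(frozen=True)
class PyramidSpec:
    """Parameters of the steerable-pyramid energy model.

    Defaults are the working configuration used throughout: 8 orientations,
    1-octave bandwidth on a 512-px image spanning 12.0471 degrees, which
    yields 7 bandpass levels (56 orientation x scale channels).
    """

    n_orientations: int = 8
    n_levels: int = 7
    bandwidth_octaves: float = 1.0
    image_size_px: int = 512
    fov_deg: float = 8.4 * 1024 / 714  # 12.0471...

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if self.fov_deg <= 0:
            raise ValueError("fov_deg must be > 0")
        expected = n_levels_for(self.image_size_px, self.bandwidth_octaves)
        if self.n_levels != expected:
            raise ValueError(
                f"n_levels={self.n_levels} inconsistent with image size "
                f"{self.image_size_px} and bandwidth {self.bandwidth_octaves} "
                f"octaves (expected {expected})"
            )

    @classmethod
    def for_image(
        cls,
        image_size_px: int,
        fov_deg: float | None = None,
        n_orientations: int = 8,
        bandwidth_octaves: float = 1.0,
    ) -> "PyramidSpec":
        """Spec with the level count derived from the image size."""
        kwargs = dict(
            n_orientations=n_orientations,
            n_levels=n_levels_for(image_size_px, bandwidth_octaves),
            bandwidth_octaves=bandwidth_octaves,
            image_size_px=image_size_px,
        )
        if fov_deg is not None:
            kwargs["fov_deg"] = fov_deg
        return cls(**kwargs)

    @property
    def n_channels(self) -> int:
        return self.n_orientations * self.n_levels

    @property
    def nyquist_cpd(self) -> float:
        return (self.image_size_px / 2) / self.fov_deg

    @property
    def orientations(self) -> np.ndarray:
        """Channel center orientations, radians in [0, pi)."""
        K = self.n_orientations
        return np.arange(K) * np.pi / K


def center_frequencies(spec: PyramidSpec) -> list[tuple[float, float]]:
    """Per-level center frequencies as ``(cycles_per_image, cpd)`` pairs.

    Levels are ordered finest to coarsest; cycles per image halve per octave
    of bandwidth starting from ``image_size_px / 4``. Cycles per degree is the
    plain division by the field of view.
    """
    top = spec.image_size_px / 4.0
    cpi = top * 2.0 ** (-spec.bandwidth_octaves * np.arange(spec.n_levels))
    return [(float(c), float(c / spec.fov_deg)) for c in cpi]


# ---------------------------------------------------------------------------
# filter-bank construction (cached per spec)
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[PyramidSpec, "FilterBank"] = {}


@dataclass
class FilterBank:
    """Frequency-domain masks for one :class:`PyramidSpec`.

    ``masks`` has shape (n_levels, n_orientations, N, N), complex-response
    masks supported on a half plane. ``tiling_map`` is the sum of squared
    magnitudes of the corresponding even+odd quadrature filters, which is
    flat (== 1) on the annulus covered by the bank.
    """

    spec: PyramidSpec
    masks: np.ndarray = field(repr=False)

    @property
    def tiling_map(self) -> np.ndarray:
        m2 = np.abs(self.masks) ** 2
        total = m2.sum(axis=(0, 1))
        # even/odd pair magnitude at +/-w averages the two half planes
        return 0.5 * (total + _point_reflect(total))

    @property
    def energy_masks(self) -> np.ndarray:
        """Symmetrized |mask|^2 per channel, for Parseval-style energy sums.

        For a real image, the spatial sum of a channel's energy equals
        ``sum(|FFT(image)|^2 * energy_mask) / N^2``.
        """
        m2 = np.abs(self.masks) ** 2
        return 0.5 * (m2 + _point_reflect(m2))


def _point_reflect(a: np.ndarray) -> np.ndarray:
    """Value at -w for an FFT-ordered frequency-domain array (last two axes)."""
    out = np.flip(a, axis=(-2, -1))
    return np.roll(out, shift=(1, 1), axis=(-2, -1))


def _build_bank(spec: PyramidSpec) -> FilterBank:
    N = spec.image_size_px
    K = spec.n_orientations
    b = spec.bandwidth_octaves

    f = np.fft.fftfreq(N) * N  # cycles per image
    fx = f[np.newaxis, :]
    fy = -f[:, np.newaxis]  # visual y points up; array rows increase downward
    r = np.hypot(fx, fy)
    phi = np.arctan2(fy, fx)

    with np.errstate(divide="ignore"):
        log_r = np.log2(np.where(r > 0, r, 1.0))

    centers_cpi = [c for c, _ in center_frequencies(spec)]

    # angular lobes: cos^(K-1) on a half plane, normalized so the squared
    # lobes of all orientations (both half planes together) sum to 1
    p = K - 1
    ang_norm = K * comb(2 * K - 2, K - 1) / 4.0 ** (K - 1)
    masks = np.empty((spec.n_levels, K, N, N), dtype=np.complex128)
    for k in range(K):
        theta_k = k * np.pi / K
        # grating with stripe orientation theta has power along theta + pi/2
        d = phi - (theta_k + np.pi / 2)
        c = np.cos(d)
        lobe = np.where(c > 0, c, 0.0) ** p * np.sqrt(2.0 / ang_norm)
        for l, c0 in enumerate(centers_cpi):
            x = (log_r - np.log2(c0)) / b
            rad = np.where(np.abs(x) < 1.0, np.cos(0.5 * np.pi * x), 0.0)
            rad[r == 0] = 0.0
            masks[l, k] = rad * lobe
    return FilterBank(spec=spec, masks=masks)


def get_bank(spec: PyramidSpec) -> FilterBank:
    bank = _BANK_CACHE.get(spec)
    if bank is None:
        bank = _BANK_CACHE[spec] = _build_bank(spec)
    return bank


# ---------------------------------------------------------------------------
# energy decomposition
# ---------------------------------------------------------------------------


@dataclass
class EnergyTensor:
    """Orientation x scale energy maps of one image.

    ``data`` has shape (n_levels, n_orientations, N, N) — level-major, so
    flattening the first two axes gives the channel ordering used by the
    encoding design matrices. For a constrained (orientation-pooled) tensor
    the orientation axis has length 1.
    """

    data: np.ndarray
    spec: PyramidSpec

    @property
    def constrained(self) -> bool:
        return self.data.shape[1] == 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def channel_sums(self) -> np.ndarray:
        """Spatial sum of each channel's energy map, flattened level-major."""
        return self.data.sum(axis=(-2, -1)).reshape(-1)


def _check_image(image: np.ndarray, spec: PyramidSpec) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2D image, got shape {image.shape}")
    if image.shape[0] != spec.image_size_px:
        raise ValueError(
            f"image size {image.shape[0]} does not match spec "
            f"({spec.image_size_px})"
        )
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return image


def decompose_energy(image: np.ndarray, spec: PyramidSpec) -> EnergyTensor:
    """Quadrature-pair energy maps for every orientation x scale channel.

    The image mean is removed before filtering (the bandpass bank rejects DC
    anyway; subtracting avoids leakage into the coarsest band). Each channel's
    map is the squared modulus of the complex analytic subband, i.e. the sum
    of squared even- and odd-phase filter responses, at full image resolution.
    """
    image = _check_image(image, spec)
    bank = get_bank(spec)
    F = np.fft.fft2(image - image.mean())
    L, K, N, _ = bank.masks.shape
    out = np.empty((L, K, N, N))
    for l in range(L):
        sub = np.fft.ifft2(F[np.newaxis] * bank.masks[l], axes=(-2, -1))
        out[l] = sub.real**2 + sub.imag**2
    return EnergyTensor(data=out, spec=spec)


def constrain(tensor: EnergyTensor) -> EnergyTensor:
    """Pool energy across orientations, leaving one map per scale level."""
    if tensor.constrained:
        raise ValueError("tensor is already orientation-pooled")
    return EnergyTensor(
        data=tensor.data.sum(axis=1, keepdims=True), spec=tensor.spec
    )


def channel_energy_sums(image: np.ndarray, spec: PyramidSpec) -> np.ndarray:
    """Whole-image energy sum per channel, computed spectrally.

    Equivalent to ``decompose_energy(image, spec).channel_sums()`` by
    Parseval's theorem, but avoids the inverse transforms; used for the
    grating-probe features where no receptive-field weighting is applied.
    """
    image = _check_image(image, spec)
    bank = get_bank(spec)
    F2 = np.abs(np.fft.fft2(image - image.mean())) ** 2
    N = spec.image_size_px
    sums = np.tensordot(bank.energy_masks, F2, axes=([-2, -1], [0, 1])) / N**2
    return sums.reshape(-1)


def iter_energy(images: Iterator[np.ndarray] | np.ndarray, spec: PyramidSpec):
    """Yield :class:`EnergyTensor` per image (streaming helper)."""
    for img in images:
        yield decompose_energy(img, spec)
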