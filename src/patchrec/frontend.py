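"""Shared V1-like front end: preprocessing, Gabor S1 filtering, C1 max pooling.

Both dictionary models consume the same C1 representation: a pyramid of
orientation x scale-band maps obtained by rectified normalized
cross-correlation with a Gabor bank (S1) followed by local max pooling over
position and over the two adjacent filter sizes of each band (C1).

Parameter tables follow the widely used HMAX configuration of Serre,
Wolf & Poggio: 4 orientations, 16 odd kernel sides from 7 to 37, and 8
scale bands whose pooling neighborhoods grow from 8 to 22 with stride equal
to half the neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve
from skimage.transform import resize

logger = logging.getLogger(__name__)

#: Image height (pixels) after preprocessing; width preserves aspect ratio.
TARGET_HEIGHT = 140

DEFAULT_ORIENTATIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
DEFAULT_SCALES: tuple[int, ...] = tuple(range(7, 39, 2))  # 7, 9, ..., 37


class InvalidImageError(ValueError):
    """Raised when an input image cannot be preprocessed."""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_image(raw: np.ndarray) -> np.ndarray:
    """Convert ``raw`` to a grayscale float image of height 140.

    Multi-channel input is averaged to a single luminance channel, integer
    intensities are rescaled to [0, 1], and the image is resized with
    bilinear interpolation so its height is exactly ``TARGET_HEIGHT`` while
    the aspect ratio is preserved.

    Parameters
    ----------
    raw
        2-D grayscale array or 3-D (H, W, C) color array.

    Returns
    -------
    np.ndarray
        Float64 array of shape ``(140, round(W * 140 / H))`` with values
        in [0, 1].
    """
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
    elif arr.ndim != 2:
        raise InvalidImageError(f"expected 2-D or 3-D image, got ndim={arr.ndim}")
    if arr.size == 0 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise InvalidImageError("zero-sized image")
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = arr / 255.0
    h, w = arr.shape
    new_w = max(1, round(w * TARGET_HEIGHT / h))
    out = resize(arr, (TARGET_HEIGHT, new_w), order=1, mode="edge",
                 anti_aliasing=h > TARGET_HEIGHT, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborFilterSpec:
    """One oriented Gabor kernel of the S1 bank.

    Attributes
    ----------
    orientation : float
        Preferred orientation in degrees (0 = horizontal bar).
    wavelength : float
        Carrier wavelength (pixels).
    sigma : float
        Gaussian envelope width (pixels).
    aspect : float
        Envelope aspect ratio gamma (dimensionless).
    side : int
        Odd kernel side length (pixels).
    """

    orientation: float
    wavelength: float
    sigma: float
    aspect: float
    side: int

    def kernel(self) -> np.ndarray:
        """Zero-mean, unit-L2-norm Gabor kernel of shape (side, side)."""
        half = self.side // 2
        y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
        theta = np.deg2rad(self.orientation)
        # u: carrier axis (perpendicular to the preferred bar), v: along it,
        # so orientation 0 responds to horizontal bars and gratings
        u = y * np.cos(theta) + x * np.sin(theta)
        v = x * np.cos(theta) - y * np.sin(theta)
        g = np.exp(-(u**2 + (self.aspect * v) ** 2) / (2 * self.sigma**2))
        g *= np.cos(2 * np.pi * u / self.wavelength)
        # kill support outside the circular envelope, as in the reference bank
        g[x**2 + y**2 > half**2] = 0.0
        g -= g.mean()
        norm = np.linalg.norm(g)
        if norm > 0:
            g /= norm
        return g


def _scale_params(side: int) -> tuple[float, float]:
    """Envelope width and wavelength for a given kernel side (HMAX table)."""
    sigma = 0.0036 * side**2 + 0.35 * side + 0.18
    wavelength = sigma / 0.8
    return sigma, wavelength


def build_gabor_bank(
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    scale_table: tuple[int, ...] = DEFAULT_SCALES,
    aspect: float = 0.3,
) -> list[GaborFilterSpec]:
    """Build the S1 filter bank: one Gabor per (orientation, kernel side).

    Raises
    ------
    ValueError
        If ``orientations`` is empty or any kernel side is even or < 3.
    """
    if not orientations:
        raise ValueError("orientations must be non-empty")
    for s in scale_table:
        if s % 2 == 0 or s < 3:
            raise ValueError(f"kernel side must be odd and >= 3, got {s}")
    bank = []
    for s in scale_table:
        sigma, lam = _scale_params(s)
        for theta in orientations:
            bank.append(GaborFilterSpec(theta, lam, sigma, aspect, s))
    return bank


# ---------------------------------------------------------------------------
# S1
# ---------------------------------------------------------------------------

@dataclass
class S1Maps:
    """Rectified S1 response maps indexed by (orientation, kernel side)."""

    maps: dict[tuple[float, int], np.ndarray]
    orientations: tuple[float, ...]
    scale_table: tuple[int, ...]


def s1_transform(img: np.ndarray, bank: list[GaborFilterSpec]) -> S1Maps:
    """Apply the Gabor bank to ``img`` by normalized cross-correlation.

    The response at each valid position is ``|k . w| / ||w||`` where ``k``
    is the zero-mean unit-norm kernel and ``w`` the underlying image window,
    clipped to [0, 1]; uniform windows respond 0.  Scales whose kernel does
    not fit in the image are omitted with a warning.
    """
    img = np.asarray(img, dtype=np.float64)
    sides = sorted({f.side for f in bank})
    # local window energy per side, shared by the orientations of that side
    sq = img**2
    denom: dict[int, np.ndarray] = {}
    kept: list[int] = []
    for s in sides:
        if s > min(img.shape):
            logger.warning("image %s smaller than kernel side %d; scale omitted",
                           img.shape, s)
            continue
        box = np.ones((s, s))
        d = fftconvolve(sq, box, mode="valid")
        denom[s] = np.sqrt(np.clip(d, 0.0, None))
        kept.append(s)
    maps: dict[tuple[float, int], np.ndarray] = {}
    oris: list[float] = []
    for f in bank:
        if f.side not in denom:
            continue
        if f.orientation not in oris:
            oris.append(f.orientation)
        k = f.kernel()
        num = fftconvolve(img, k[::-1, ::-1], mode="valid")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(num) / denom[f.side]
        r[~np.isfinite(r)] = 0.0
        maps[(f.orientation, f.side)] = np.clip(r, 0.0, 1.0)
    return S1Maps(maps=maps, orientations=tuple(oris), scale_table=tuple(kept))


# ---------------------------------------------------------------------------
# C1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleBand:
    """One C1 scale band: two adjacent S1 kernel sides pooled together."""

    scales: tuple[int, int]
    pool: int      # square max-pooling neighborhood (C1 grid cells are pool x pool)
    stride: int    # subsampling step, half the neighborhood


def default_bands(scale_table: tuple[int, ...] = DEFAULT_SCALES) -> tuple[ScaleBand, ...]:
    """Pair adjacent scales into bands with pooling 8..22 and stride = pool // 2."""
    bands = []
    for i in range(0, len(scale_table) - 1, 2):
        pool = 8 + i
        bands.append(ScaleBand((scale_table[i], scale_table[i + 1]), pool, pool // 2))
    return tuple(bands)


DEFAULT_BANDS = default_bands()


@dataclass
class C1Pyramid:
    """Pooled complex-cell maps indexed by (orientation, band index)."""

    maps: dict[tuple[float, int], np.ndarray]
    orientations: tuple[float, ...]
    bands: tuple[ScaleBand, ...]

    def band_stack(self, band_index: int) -> np.ndarray | None:
        """Return the (H, W, n_orientations) array for one band, or None."""
        arrs = [self.maps.get((o, band_index)) for o in self.orientations]
        if any(a is None for a in arrs):
            return None
        return np.stack(arrs, axis=-1)

    @property
    def band_indices(self) -> list[int]:
        return sorted({b for (_, b) in self.maps})


def _align_pair(a: np.ndarray, b: np.ndarray, sa: int, sb: int) -> tuple[np.ndarray, np.ndarray]:
    """Center-align two valid-convolution maps from kernel sides sa < sb."""
    d = (sb - sa) // 2
    a = a[d:d + b.shape[0], d:d + b.shape[1]]
    return a, b


def c1_pool(s1: S1Maps, bands: tuple[ScaleBand, ...] = DEFAULT_BANDS) -> C1Pyramid:
    """Max-pool S1 maps over position and over the two scales of each band.

    Each C1 cell is the maximum of all S1 cells inside a ``pool x pool``
    window (taken on the element-wise max of the band's two scale maps,
    center-aligned), subsampled at the band stride; only fully contained
    windows are kept.
    """
    out: dict[tuple[float, int], np.ndarray] = {}
    for bi, band in enumerate(bands):
        sa, sb = sorted(band.scales)
        for ori in s1.orientations:
            ma = s1.maps.get((ori, sa))
            mb = s1.maps.get((ori, sb))
            if ma is None and mb is None:
                continue
            if ma is not None and mb is not None:
                a, b = _align_pair(ma, mb, sa, sb)
                merged = np.maximum(a, b)
            else:
                merged = ma if ma is not None else mb
            if merged.shape[0] < band.pool or merged.shape[1] < band.pool:
                continue
            win = sliding_window_view(merged, (band.pool, band.pool))
            win = win[::band.stride, ::band.stride]
            out[(ori, bi)] = win.max(axis=(2, 3))
    return C1Pyramid(maps=out, orientations=s1.orientations, bands=bands)


def compute_c1(
    img: np.ndarray,
    bank: list[GaborFilterSpec] | None = None,
    bands: tuple[ScaleBand, ...] | None = None,
) -> C1Pyramid:
    """Convenience pipeline: Gabor bank -> S1 -> C1 for one preprocessed image."""
    if bank is None:
        bank = build_gabor_bank()
    if bands is None:
        scale_table = tuple(sorted({f.side for f in bank}))
        bands = default_bands(scale_table)
    return c1_pool(s1_transform(img, bank), bands)
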