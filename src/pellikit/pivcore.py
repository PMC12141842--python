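"""Particle image velocimetry on grey-value images.

A pair of images is sliced into small interrogation windows (default
32 x 32 px) that are matched inside larger search windows (default
50 x 50 px) of the second image by normalized cross-correlation of the
grey values.  The correlation peak, refined to sub-pixel precision,
gives one displacement vector per grid node; a neighbourhood-median
test flags and replaces spurious vectors.

Sign convention: a vector (u, v) is the motion of matter from image A
to image B, in pixels, with u along axis 1 (x, columns) and v along
axis 0 (y, rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Image", "PIVConfig", "DisplacementField", "FlatWindowError",
    "to_grayscale", "correlate", "subpixel_peak", "compute_field",
    "validate_field",
    "STATUS_OK", "STATUS_LOW_CONTRAST", "STATUS_BORDER_PEAK",
    "STATUS_REPLACED",
]

# per-vector status codes
STATUS_OK = 0
STATUS_LOW_CONTRAST = 1   # interrogation window below contrast threshold
STATUS_BORDER_PEAK = 2    # correlation peak on the search border
STATUS_REPLACED = 3       # outlier replaced by neighbourhood median

# ITU-R 601 luminance weights (the ImageJ default RGB-to-grey conversion)
_LUMA = np.array([0.299, 0.587, 0.114])


class FlatWindowError(ValueError):
    """Raised when a window has no grey-value contrast (undefined NCC)."""


@dataclass
class Image:
    """A 2-D grayscale image with optional physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of grey values (stored as float64).
    pixel_size : float, optional
        Physical size of one pixel in mm.
    bit_origin : str
        Source bit depth, one of ``{"8-bit", "32-bit", "float"}``.
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    bit_origin: str = "float"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got {self.pixels.ndim}-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PIVConfig:
    """Interrogation parameters for :func:`compute_field`.

    ``interrogation_px`` is the template side, ``search_px`` the side of
    the search window in the second image; the search window must be
    strictly larger.  ``overlap_fraction`` sets the grid stride
    (stride = interrogation * (1 - overlap)).  ``min_contrast`` is the
    minimum grey-value standard deviation for a template to be matched.
    """

    interrogation_px: int = 32
    search_px: int = 50
    overlap_fraction: float = 0.5
    subpixel: str = "gaussian3"
    min_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.interrogation_px < 8 or self.search_px < 8:
            raise ValueError("window sides must be >= 8 px")
        if self.search_px <= self.interrogation_px:
            raise ValueError("search window must exceed interrogation window")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel not in ("gaussian3", "parabolic", "none"):
            raise ValueError(f"unknown subpixel estimator {self.subpixel!r}")

    @property
    def stride(self) -> int:
        return max(1, round(self.interrogation_px * (1 - self.overlap_fraction)))


@dataclass
class DisplacementField:
    """Gridded displacement vectors from PIV.

    All arrays share one (rows, cols) shape.  ``valid`` is True for
    vectors that are usable (including replaced outliers); ``status``
    holds the per-vector status codes.  Invalid vectors carry NaN
    components.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    peak_quality: np.ndarray
    status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.status is None:
            self.status = np.where(self.valid, STATUS_OK, STATUS_LOW_CONTRAST)
        shapes = {a.shape for a in (self.grid_x, self.grid_y, self.u, self.v,
                                    self.valid, self.peak_quality, self.status)}
        if len(shapes) != 1:
            raise ValueError("field arrays must share one shape")


def to_grayscale(image) -> Image:
    """Convert a colour image to a single luminance channel.

    Accepts an ``Image``, a 2-D array (passed through) or an
    (H, W, 3) RGB array, which is reduced with the ITU-R 601 weights
    (0.299, 0.587, 0.114).  Any other channel count is an error.
    """
    if isinstance(image, Image):
        return image
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return Image(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return Image(arr @ _LUMA)
    raise ValueError(f"unsupported image shape {arr.shape}")


def correlate(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of a template over a search window.

    Scores are computed at every integer lag that places the template
    fully inside the search window; the returned surface has shape
    ``(Hs - Ht + 1, Ws - Wt + 1)`` with values in [-1, 1].  Surface
    index (0, 0) corresponds to the template aligned with the top-left
    corner of the search window.

    Raises
    ------
    FlatWindowError
        If the template grey values have zero variance.
    """
    template = np.asarray(template, dtype=float)
    search = np.asarray(search, dtype=float)
    if search.shape[0] <= template.shape[0] or search.shape[1] <= template.shape[1]:
        raise ValueError("search window must be strictly larger than template")
    t0 = template - template.mean()
    t_norm = np.sqrt((t0 * t0).sum())
    if t_norm == 0:
        raise FlatWindowError("template has zero grey-value variance")
    wins = sliding_window_view(search, template.shape)
    w_mean = wins.mean(axis=(2, 3), keepdims=True)
    w0 = wins - w_mean
    num = np.einsum("ijkl,kl->ij", w0, t0)
    w_norm = np.sqrt((w0 * w0).sum(axis=(2, 3)))
    den = t_norm * w_norm
    surface = np.zeros_like(num)
    np.divide(num, den, out=surface, where=den > 0)
    return np.clip(surface, -1.0, 1.0)


def _refine_1d(c_minus: float, c0: float, c_plus: float, method: str) -> float:
    """Fractional peak offset from three samples along one axis."""
    if method == "none":
        return 0.0
    if method == "gaussian3" and min(c_minus, c0, c_plus) > 0:
        lm, l0, lp = np.log(c_minus), np.log(c0), np.log(c_plus)
        denom = lm - 2 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))
    # parabolic fallback (also used when a neighbour is non-positive)
    denom = c_minus - 2 * c0 + c_plus
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (c_minus - c_plus) / denom, -0.5, 0.5))


def subpixel_peak(surface: np.ndarray, method: str = "gaussian3"
                  ) -> tuple[float, float, bool]:
    """Locate the correlation peak with sub-pixel precision.

    Returns ``(px, py, on_border)`` where (px, py) are the (column, row)
    coordinates of the refined peak on the surface.  A three-point
    Gaussian (or parabolic) fit is applied independently per axis; the
    fractional part is always within +/-0.5 px of the integer peak.
    A peak on the surface border is returned unrefined and flagged.
    """
    surface = np.asarray(surface, dtype=float)
    iy, ix = np.unravel_index(int(np.argmax(surface)), surface.shape)
    on_border = (iy == 0 or ix == 0 or
                 iy == surface.shape[0] - 1 or ix == surface.shape[1] - 1)
    if on_border or method == "none":
        return float(ix), float(iy), on_border
    dx = _refine_1d(surface[iy, ix - 1], surface[iy, ix], surface[iy, ix + 1],
                    method)
    dy = _refine_1d(surface[iy - 1, ix], surface[iy, ix], surface[iy + 1, ix],
                    method)
    return ix + dx, iy + dy, False


def _peak_quality(surface: np.ndarray, iy: int, ix: int) -> float:
    """First-to-second correlation peak ratio (>= 1)."""
    masked = surface.copy()
    y0, y1 = max(0, iy - 1), min(surface.shape[0], iy + 2)
    x0, x1 = max(0, ix - 1), min(surface.shape[1], ix + 2)
    masked[y0:y1, x0:x1] = -np.inf
    second = float(masked.max())
    first = float(surface[iy, ix])
    if not np.isfinite(second) or second <= 0:
        return np.inf if first > 0 else 1.0
    return max(first / second, 1.0)


def compute_field(imgA, imgB, config: PIVConfig | None = None
                  ) -> DisplacementField:
    """Compute a gridded displacement field between two images.

    Window centres are laid on a regular grid (stride from
    ``overlap_fraction``) with margins so the search window always fits
    inside image B.  Each vector is the NCC peak lag of the image-A
    template inside the image-B search window, refined to sub-pixel.
    """
    if config is None:
        config = PIVConfig()
    A = to_grayscale(imgA)
    B = to_grayscale(imgB)
    if A.shape != B.shape:
        raise ValueError("image shapes differ")
    hs = config.search_px // 2
    ht = config.interrogation_px // 2
    H, W = A.shape
    if H < config.search_px or W < config.search_px:
        raise ValueError("images too small for one search window")

    centers_y = np.arange(hs, H - (config.search_px - hs) + 1, config.stride)
    centers_x = np.arange(hs, W - (config.search_px - hs) + 1, config.stride)
    ny, nx = len(centers_y), len(centers_x)
    grid_x, grid_y = np.meshgrid(centers_x, centers_y)
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    quality = np.ones((ny, nx))
    status = np.full((ny, nx), STATUS_OK, dtype=np.int8)

    # surface lag at which the template sits at its original position
    # (zero displacement): template origin minus search origin
    lag0 = hs - ht

    for i, cy in enumerate(centers_y):
        for j, cx in enumerate(centers_x):
            tpl = A.pixels[cy - ht:cy - ht + config.interrogation_px,
                           cx - ht:cx - ht + config.interrogation_px]
            if tpl.std() < config.min_contrast:
                status[i, j] = STATUS_LOW_CONTRAST
                continue
            srch = B.pixels[cy - hs:cy - hs + config.search_px,
                            cx - hs:cx - hs + config.search_px]
            try:
                surface = correlate(tpl, srch)
            except FlatWindowError:
                status[i, j] = STATUS_LOW_CONTRAST
                continue
            px, py, on_border = subpixel_peak(surface, config.subpixel)
            iy, ix = np.unravel_index(int(np.argmax(surface)), surface.shape)
            quality[i, j] = _peak_quality(surface, iy, ix)
            if on_border:
                # displacement at or beyond the search range: untrustworthy
                status[i, j] = STATUS_BORDER_PEAK
            u[i, j] = px - lag0
            v[i, j] = py - lag0

    valid = status == STATUS_OK
    return DisplacementField(grid_x=grid_x.astype(float),
                             grid_y=grid_y.astype(float),
                             u=u, v=v, valid=valid, peak_quality=quality,
                             status=status)


def validate_field(field: DisplacementField, median_k: float = 3.0
                   ) -> DisplacementField:
    """Neighbourhood-median outlier test.

    A vector deviating from the median of its 3 x 3 neighbourhood by
    more than ``median_k`` times the local median absolute deviation
    (floored at 0.1 px, the typical sub-pixel noise level) is flagged
    ``STATUS_REPLACED`` and its components replaced by the
    neighbourhood median.  Pre-existing invalid flags are preserved.
    """
    u = field.u.copy()
    v = field.v.copy()
    status = field.status.copy()
    ny, nx = u.shape
    mad_floor = 0.1
    new_u, new_v = u.copy(), v.copy()
    for i in range(ny):
        for j in range(nx):
            if not field.valid[i, j]:
                continue
            ys = slice(max(0, i - 1), min(ny, i + 2))
            xs = slice(max(0, j - 1), min(nx, j + 2))
            nu = u[ys, xs].ravel()
            nv = v[ys, xs].ravel()
            mask = field.valid[ys, xs].ravel() & np.isfinite(nu)
            # drop the centre vector itself
            centre = (min(i, 1) * (xs.stop - xs.start)) + min(j, 1)
            mask[centre] = False
            if mask.sum() < 3:
                continue
            med_u = np.median(nu[mask])
            med_v = np.median(nv[mask])
            mad = np.median(np.hypot(nu[mask] - med_u, nv[mask] - med_v))
            mad = max(mad, mad_floor)
            dev = np.hypot(u[i, j] - med_u, v[i, j] - med_v)
            if dev > median_k * mad:
                new_u[i, j] = med_u
                new_v[i, j] = med_v
                status[i, j] = STATUS_REPLACED
    valid = (status == STATUS_OK) | (status == STATUS_REPLACED)
    return DisplacementField(grid_x=field.grid_x, grid_y=field.grid_y,
                             u=new_u, v=new_v, valid=valid,
                             peak_quality=field.peak_quality, status=status)
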