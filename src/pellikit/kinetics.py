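"""Morphogenesis kinetics from time-lapse stacks and colony tables.

Time-lapse frames of a growing pellicle are reduced to grey-level line
profiles, stacked into kymographs (space x time), and quantified as

* expansion-front speeds — the outermost threshold crossing of each
  kymograph row, fitted linearly against time;
* wrinkle wavelengths — the first significant peak of the spatial
  autocorrelation of a detrended profile, cross-checked against the
  spectral maximum;
* colony expansion rates from diameter tables, under an explicit
  radius or diameter convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "ImageStack", "Kymograph", "FrontTrack", "WrinkleSpectrum",
    "ColonyMeasurement", "ExpansionRate",
    "gray_profile", "build_kymograph", "track_front",
    "wrinkle_wavelength", "expansion_rate",
]


@dataclass
class ImageStack:
    """Ordered frames with acquisition times (hours) and pixel size (mm)."""

    frames: np.ndarray            # (n_frames, H, W)
    times: np.ndarray             # hours since inoculation
    pixel_size: float             # mm/px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.shape[0] != self.times.size:
            raise ValueError("one timestamp per frame required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Kymograph:
    """Grey values along a fixed probe stacked over time.

    ``values[t, s]`` is the grey level at position ``positions[s]``
    (mm along the probe) and time ``times[t]`` (hours).
    """

    values: np.ndarray
    positions: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.times.size, self.positions.size):
            raise ValueError("kymograph dimensions must match times/positions")


@dataclass
class FrontTrack:
    """Tracked front positions and their fitted speed."""

    times: np.ndarray          # h (rows with a detected crossing)
    front_position: np.ndarray  # mm along the probe
    speed: float               # mm/h, least-squares slope
    fit_r2: float


@dataclass
class WrinkleSpectrum:
    """Wavelength content of a grey-level profile.

    ``dominant_wavelength`` comes from the first significant
    autocorrelation peak inside the analysis band;
    ``spectral_wavelength`` is the periodogram maximum reported as a
    consistency check.  ``status`` is ``"periodic"`` or
    ``"aperiodic"``.
    """

    wavelengths: np.ndarray
    power: np.ndarray
    dominant_wavelength: float | None
    spectral_wavelength: float | None
    status: str


@dataclass
class ColonyMeasurement:
    """One colony diameter reading."""

    morphotype: str            # rough | smooth
    agar_pct: float
    time: float                # h
    diameter: float            # mm

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")
        if self.time <= 0:
            raise ValueError("time must be positive")


@dataclass
class ExpansionRate:
    """Colony expansion rate with the convention that produced it."""

    rate: float                # mm/h
    convention: str            # radius | diameter
    n: int


def gray_profile(frame: np.ndarray, probe: tuple, pixel_size: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Grey values along a line probe.

    ``probe`` is ``((x0, y0), (x1, y1))`` in mm coordinates.  Values
    are sampled with bilinear interpolation at ``pixel_size`` steps;
    returns ``(positions_mm, values)``.  A probe endpoint outside the
    frame is an error.
    """
    (x0, y0), (x1, y1) = probe
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x / pixel_size <= W - 1 and 0 <= y / pixel_size <= H - 1):
            raise ValueError("probe endpoint outside image")
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("zero-length probe")
    n = int(np.floor(length / pixel_size)) + 1
    s = np.linspace(0.0, length, n)
    xs = (x0 + (x1 - x0) * s / length) / pixel_size
    ys = (y0 + (y1 - y0) * s / length) / pixel_size
    vals = ndimage.map_coordinates(frame, [ys, xs], order=1, mode="nearest")
    return s, vals


def build_kymograph(stack: ImageStack, probe: tuple) -> Kymograph:
    """Stack the probe's grey profile over every frame (row t = frame t)."""
    rows = []
    positions = None
    for k in range(stack.n_frames):
        s, vals = gray_profile(stack.frames[k], probe, stack.pixel_size)
        positions = s
        rows.append(vals)
    return Kymograph(np.array(rows), positions, stack.times.copy())


def track_front(kym: Kymograph, level: float, side: str = "outer"
                ) -> FrontTrack:
    """Track the expansion front as a threshold crossing per row.

    For each row, the front is the outermost (largest-position, when
    ``side="outer"``) crossing of ``level``, refined by linear
    interpolation between the bracketing samples.  Rows without a
    crossing are skipped; more than 50 % skipped rows is an error.
    The speed is the least-squares slope of position on time.
    """
    if side not in ("outer", "inner"):
        raise ValueError("side must be 'outer' or 'inner'")
    ts, ps = [], []
    for t, row in zip(kym.times, kym.values):
        above = row >= level
        if not above.any() or above.all():
            continue
        idx = np.flatnonzero(above)
        if side == "outer":
            i = idx[-1]
            if i == row.size - 1:
                pos = kym.positions[i]
            else:
                frac = (row[i] - level) / (row[i] - row[i + 1])
                pos = kym.positions[i] + frac * (kym.positions[i + 1]
                                                 - kym.positions[i])
        else:
            i = idx[0]
            if i == 0:
                pos = kym.positions[0]
            else:
                frac = (row[i] - level) / (row[i] - row[i - 1])
                pos = kym.positions[i] - frac * (kym.positions[i]
                                                 - kym.positions[i - 1])
        ts.append(t)
        ps.append(pos)
    if len(ts) < max(2, kym.times.size // 2):
        raise ValueError("front crossing found in fewer than half the rows")
    ts = np.array(ts)
    ps = np.array(ps)
    if np.ptp(ts) == 0:
        raise ValueError("degenerate time spread")
    slope, intercept = np.polyfit(ts, ps, 1)
    resid = ps - (slope * ts + intercept)
    ss_tot = float(np.sum((ps - ps.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return FrontTrack(ts, ps, float(slope), float(r2))


def wrinkle_wavelength(profile: np.ndarray, pixel_size: float,
                       band: tuple[float, float] = (1.0, 4.0),
                       min_acf: float = 0.1) -> WrinkleSpectrum:
    """Dominant spatial period of a grey-level profile.

    The profile is detrended by subtracting a moving-average baseline
    (window = 2 x the band maximum).  The dominant wavelength is the
    first autocorrelation peak inside ``band`` with height >=
    ``min_acf`` (parabolically refined); the periodogram maximum in
    the band is reported alongside as a consistency check.  With no
    qualifying peak the status is ``"aperiodic"``.
    """
    profile = np.asarray(profile, dtype=float)
    lo_mm, hi_mm = band
    if not 0 < lo_mm < hi_mm:
        raise ValueError("band must satisfy 0 < min < max")
    n = profile.size
    if n < 4 * hi_mm / pixel_size:
        raise ValueError("profile too short for the requested band")

    win = int(round(2 * hi_mm / pixel_size)) | 1   # odd window
    baseline = ndimage.uniform_filter1d(profile, win, mode="nearest")
    x = profile - baseline

    # normalized autocorrelation over positive lags
    x0 = x - x.mean()
    acf = signal.correlate(x0, x0, mode="full")[n - 1:]
    if acf[0] <= 0:
        return WrinkleSpectrum(np.array([]), np.array([]), None, None,
                               "aperiodic")
    acf = acf / acf[0]
    lag_lo = max(1, int(np.floor(lo_mm / pixel_size)))
    lag_hi = min(n - 2, int(np.ceil(hi_mm / pixel_size)))
    seg = acf[:lag_hi + 2]
    peaks, props = signal.find_peaks(seg, height=min_acf)
    peaks = peaks[(peaks >= lag_lo) & (peaks <= lag_hi)]

    # periodogram cross-check inside the band
    freqs = np.fft.rfftfreq(n, d=pixel_size)
    power = np.abs(np.fft.rfft(x0)) ** 2
    with np.errstate(divide="ignore"):
        wavelengths = np.where(freqs > 0, 1.0 / freqs, np.inf)
    in_band = (wavelengths >= lo_mm) & (wavelengths <= hi_mm)
    spectral = None
    if in_band.any() and power[in_band].max() > 0:
        spectral = float(wavelengths[in_band][np.argmax(power[in_band])])

    if peaks.size == 0:
        return WrinkleSpectrum(wavelengths[1:], power[1:], None, spectral,
                               "aperiodic")
    p = int(peaks[0])
    # parabolic sub-lag refinement
    delta = 0.0
    if 0 < p < acf.size - 1:
        denom = acf[p - 1] - 2 * acf[p] + acf[p + 1]
        if denom < 0:
            delta = float(np.clip(0.5 * (acf[p - 1] - acf[p + 1]) / denom,
                                  -0.5, 0.5))
    dominant = (p + delta) * pixel_size
    return WrinkleSpectrum(wavelengths[1:], power[1:], float(dominant),
                           spectral, "periodic")


def expansion_rate(measurements: list[ColonyMeasurement],
                   convention: str = "radius",
                   baseline_diameter: float = 0.0) -> ExpansionRate:
    """Colony expansion rate from diameter readings.

    Under the radius convention the rate is
    (diameter - baseline) / (2 t); under the diameter convention,
    (diameter - baseline) / t.  The mean over measurements is returned
    with the convention recorded — the literature does not fix one.
    Homogeneous: doubling (diameter - baseline) doubles the rate.
    """
    if convention not in ("radius", "diameter"):
        raise ValueError("convention must be 'radius' or 'diameter'")
    if baseline_diameter < 0:
        raise ValueError("baseline_diameter must be >= 0")
    if not measurements:
        raise ValueError("at least one measurement required")
    div = 2.0 if convention == "radius" else 1.0
    rates = [(m.diameter - baseline_diameter) / (div * m.time)
             for m in measurements]
    return ExpansionRate(float(np.mean(rates)), convention, len(measurements))
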