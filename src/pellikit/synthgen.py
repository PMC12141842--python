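"""Seeded synthetic inputs for every stage of the pipeline.

Three generators emulate the three kinds of raw records the analysis
chain consumes:

* :func:`generate_speckle` + :func:`apply_displacement` — speckle
  textured pellicle images warped by a prescribed displacement profile
  (ground truth for the PIV and deformation stages).  Real pellicles
  are not uniform; their optically visible inhomogeneities act as the
  "particles" of the velocimetry.  Here the texture is a field of
  seeded Gaussian blobs on a flat background, which gives a
  controllable correlation length.
* :func:`generate_force_trace` — force-elongation recordings that are
  linear in the elastic regime, carry a configurable zero-force offset
  and terminate in an abrupt failure drop.
* :func:`generate_timelapse` — image stacks with an outward-moving
  bright front and, after an onset time, a periodic wrinkle pattern.

Every generator is a pure function of its spec (which includes the
seed): identical spec, identical output.  Grey values live in [0, 255]
with float64 internal representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from pellikit.pivcore import Image

__all__ = [
    "SpeckleSpec", "ProfileNodes", "ForceTraceSpec", "TimelapseSpec",
    "CANONICAL_ROUGH_NODES", "AFFINE_NODES",
    "generate_speckle", "evaluate_profile", "apply_displacement",
    "generate_force_trace", "generate_timelapse",
]

GREY_MIN, GREY_MAX = 0.0, 255.0


@dataclass
class SpeckleSpec:
    """Parameters of a synthetic speckle texture.

    ``grain_density`` is the expected number of grains per 1000 px²;
    ``contrast`` scales grain amplitude relative to the grey range.
    """

    width_px: int = 512
    height_px: int = 512
    grain_density: float = 5.0
    grain_radius_px: float = 2.0
    contrast: float = 0.8
    background_level: float = 128.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.grain_density < 0:
            raise ValueError("grain_density must be >= 0")
        if self.grain_radius_px <= 0:
            raise ValueError("grain_radius_px must be positive")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ProfileNodes:
    """Piecewise-linear displacement profile in relative coordinates.

    ``nodes`` is an ordered list of (x_rel, u_rel) pairs with x_rel
    strictly increasing from 0 (immobile plate) to 1 (mobile plate).
    """

    nodes: tuple

    def __post_init__(self) -> None:
        nodes = tuple((float(x), float(u)) for x, u in self.nodes)
        if len(nodes) < 2:
            raise ValueError("at least two nodes required")
        xs = np.array([n[0] for n in nodes])
        if not np.all(np.diff(xs) > 0):
            raise ValueError("node positions must be strictly increasing")
        if xs[0] != 0.0 or xs[-1] != 1.0:
            raise ValueError("nodes must span relative positions 0 to 1")
        object.__setattr__(self, "nodes", nodes)

    @property
    def x(self) -> np.ndarray:
        return np.array([n[0] for n in self.nodes])

    @property
    def u(self) -> np.ndarray:
        return np.array([n[1] for n in self.nodes])


#: Minimal piecewise-linear profile of a stretched rough pellicle: a
#: soft region near the immobile plate rising to 0.33, a central region
#: absorbing 27 % of the elongation, a rigid translation plateau at
#: 0.60, and a narrow quasi-discontinuous step next to the mobile plate.
CANONICAL_ROUGH_NODES = ProfileNodes(
    ((0.0, 0.0), (0.15, 0.33), (0.70, 0.60), (0.95, 0.60), (1.0, 1.0)))

#: Affine (homogeneous elastic) profile: displacement proportional to
#: position.
AFFINE_NODES = ProfileNodes(((0.0, 0.0), (1.0, 1.0)))


def generate_speckle(spec: SpeckleSpec) -> Image:
    """Render a seeded speckle image.

    A Poisson-distributed number of Gaussian grains (sigma =
    ``grain_radius_px``) is placed by uniform sampling; grain amplitude
    is ``contrast`` x 110 grey levels with random sign and a uniform
    magnitude factor in [0.5, 1].  Seeded Gaussian noise is added and
    values are clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    W, H = spec.width_px, spec.height_px
    img = np.full((H, W), float(spec.background_level))
    n_grains = rng.poisson(spec.grain_density * W * H / 1000.0)
    xs = rng.uniform(0, W, n_grains)
    ys = rng.uniform(0, H, n_grains)
    signs = rng.choice([-1.0, 1.0], n_grains)
    mags = rng.uniform(0.5, 1.0, n_grains)
    sigma = spec.grain_radius_px
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    for x, y, s, m in zip(xs, ys, signs, mags):
        cx, cy = int(round(x)), int(round(y))
        fx, fy = x - cx, y - cy
        blob = np.exp(-(((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * sigma ** 2)))
        amp = s * m * spec.contrast * 110.0
        y0, y1 = max(0, cy - r), min(H, cy + r + 1)
        x0, x1 = max(0, cx - r), min(W, cx + r + 1)
        img[y0:y1, x0:x1] += amp * blob[y0 - (cy - r):y1 - (cy - r),
                                        x0 - (cx - r):x1 - (cx - r)]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return Image(np.clip(img, GREY_MIN, GREY_MAX))


def evaluate_profile(nodes: ProfileNodes, x_rel) -> np.ndarray | float:
    """Relative displacement at relative position(s) ``x_rel``.

    Linear interpolation between bracketing nodes; exact at nodes.
    ``x_rel`` outside [0, 1] is an error.
    """
    x = np.asarray(x_rel, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x_rel must lie in [0, 1]")
    out = np.interp(x, nodes.x, nodes.u)
    return float(out) if np.isscalar(x_rel) else out


def apply_displacement(image: Image, nodes: ProfileNodes,
                       total_elongation_px: float,
                       axis: str = "horizontal") -> Image:
    """Warp an image by a piecewise-linear displacement profile.

    The warp is backward: each output pixel at position x samples the
    source at ``x - u(x)`` with bilinear interpolation, where
    ``u(x) = total_elongation_px * profile(x / (L - 1))`` along the
    elongation axis.  Edge samples use clamped coordinates.  Zero
    elongation returns the input up to interpolation error.
    """
    if total_elongation_px < 0:
        raise ValueError("total_elongation_px must be >= 0")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    H, W = image.shape
    if axis == "horizontal":
        coords_axis = np.arange(W)
        u = total_elongation_px * evaluate_profile(nodes, coords_axis / (W - 1))
        Y, X = np.mgrid[0:H, 0:W].astype(float)
        X = X - u[np.newaxis, :]
        sampled = ndimage.map_coordinates(image.pixels, [Y, X], order=1,
                                          mode="nearest")
    else:
        coords_axis = np.arange(H)
        u = total_elongation_px * evaluate_profile(nodes, coords_axis / (H - 1))
        Y, X = np.mgrid[0:H, 0:W].astype(float)
        Y = Y - u[:, np.newaxis]
        sampled = ndimage.map_coordinates(image.pixels, [Y, X], order=1,
                                          mode="nearest")
    return Image(sampled, pixel_size=image.pixel_size)


@dataclass
class ForceTraceSpec:
    """Ground-truth parameters of a synthetic force-elongation trace.

    ``stiffness_true`` (N/m, identically mN/mm) and ``intercept_true``
    (mN) define the elastic regime on the pellicle-elongation axis
    ``e = central_fraction * plate_displacement``; the physical force
    drops to zero when ``e`` reaches ``failure_elongation`` (mm).
    ``post_failure_level`` (mN) is the raw-signal zero-force offset of
    the sensor, present over the whole record; the zero calibration of
    the mechanics stage removes it.
    """

    stiffness_true: float = 0.51
    intercept_true: float = -1.2
    failure_elongation: float = 5.0
    post_failure_level: float = 0.3
    noise_sd: float = 0.05
    central_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.failure_elongation <= 0:
            raise ValueError("failure_elongation must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.central_fraction <= 1:
            raise ValueError("central_fraction must be in (0, 1]")


def generate_force_trace(spec: ForceTraceSpec, protocol=None):
    """Simulate a stretching-device recording.

    Samples at the protocol rate: plate displacement ``d = speed * t``,
    pellicle elongation ``e = central_fraction * d``; raw signal =
    offset + intercept + stiffness * e (+ noise) before failure and
    offset (+ noise) after, rendered as a single-sample drop.  Stiffness
    in N/m applied to mm yields mN (1 N/m = 1 mN/mm).  If the failure
    elongation exceeds the protocol travel the trace carries
    ``meta["failed"] = False``.
    """
    from pellikit.mechanics import PullProtocol, ForceTrace
    if protocol is None:
        protocol = PullProtocol()
    rng = np.random.default_rng(spec.seed)
    dt = protocol.sampling_interval / 1000.0          # ms -> s
    speed = protocol.speed / 1000.0                   # um/s -> mm/s
    n = int(np.floor(protocol.max_travel / speed / dt)) + 1
    t = np.arange(n) * dt
    d = speed * t
    e = spec.central_fraction * d
    pre = e < spec.failure_elongation
    phys = np.where(pre, spec.intercept_true + spec.stiffness_true * e, 0.0)
    raw = spec.post_failure_level + phys
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, n)
    failed = bool(np.any(~pre))
    return ForceTrace(
        time=t, plate_displacement=d, raw_signal=raw, channel="force_mN",
        meta={"failed": failed, "spec": spec, "protocol": protocol})


@dataclass
class TimelapseSpec:
    """Parameters of a synthetic morphogenesis time-lapse.

    The dish defaults to the 62 x 46 mm rectangular format; frames are
    taken every ``frame_interval`` minutes for ``duration`` hours.  A
    bright pellicle region expands from ``front_start`` (mm from the
    left dish edge) at ``front_speed`` mm/h after ``front_onset``;
    after ``wrinkle_onset`` a sinusoidal grey modulation of wavelength
    ``wrinkle_wavelength`` mm is superimposed inside the bright region.
    """

    frame_interval: float = 15.0      # minutes
    duration: float = 9.0             # hours
    pixel_size: float = 0.05          # mm/px
    front_speed: float = 0.25         # mm/h
    front_onset: float = 0.0          # hours
    front_start: float = 5.0          # mm
    wrinkle_wavelength: float = 2.0   # mm
    wrinkle_onset: float = np.inf     # hours (inf = never)
    wrinkle_amplitude: float = 30.0   # grey levels
    dish_width: float = 62.0          # mm
    dish_height: float = 46.0         # mm
    background_level: float = 40.0
    bright_level: float = 160.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wrinkle_wavelength <= 0:
            raise ValueError("wrinkle_wavelength must be positive")
        if self.wrinkle_wavelength < 2 * self.pixel_size:
            raise ValueError("wrinkle_wavelength below 2 px is unresolvable")
        if self.dish_width <= 0 or self.dish_height <= 0:
            raise ValueError("dish dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_timelapse(spec: TimelapseSpec):
    """Render a seeded time-lapse stack of an expanding pellicle front."""
    from pellikit.kinetics import ImageStack
    rng = np.random.default_rng(spec.seed)
    W = int(round(spec.dish_width / spec.pixel_size))
    H = int(round(spec.dish_height / spec.pixel_size))
    n_frames = int(np.floor(spec.duration * 60.0 / spec.frame_interval)) + 1
    times = np.arange(n_frames) * spec.frame_interval / 60.0   # hours
    x_mm = (np.arange(W) + 0.5) * spec.pixel_size
    frames = np.empty((n_frames, H, W))
    for k, t in enumerate(times):
        front = spec.front_start + spec.front_speed * max(0.0, t - spec.front_onset)
        row = np.where(x_mm <= front, spec.bright_level, spec.background_level)
        if t >= spec.wrinkle_onset:
            wr = spec.wrinkle_amplitude * np.sin(
                2 * np.pi * x_mm / spec.wrinkle_wavelength)
            row = row + np.where(x_mm <= front, wr, 0.0)
        frame = np.broadcast_to(row, (H, W)).copy()
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, (H, W))
        frames[k] = np.clip(frame, GREY_MIN, GREY_MAX)
    return ImageStack(frames=frames, times=times, pixel_size=spec.pixel_size)
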