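"""Tensile mechanics of pellicles from force-sensor recordings.

The stretching device holds the pellicle between two vertical plates:
one on a motorized translation stage (the mobile plate) and one on a
double-cantilever force sensor of stiffness 19.5 mN/mm (the "immobile"
plate, which in fact deflects slightly under load — a 1 mN force moves
it by 0.05 mm).  The analysis chain is:

1. convert the raw sensor channel (deflection or pre-converted force)
   to force in mN;
2. detect the abrupt failure drop and calibrate the zero-force value
   on a post-failure window, when the plate is no longer connected to
   the pellicle;
3. correct the pellicle elongation for the sensor-plate deflection;
4. fit the elastic regime for stiffness (N/m) and the zero-elongation
   intercept (mN) — a negative intercept is a residual compressive
   force from growth under confinement;
5. optionally rescale via the true-strain correction (only a fraction
   of the plate travel is absorbed by the region whose stiffness is
   reported) and the inverse-length stiffness scaling of a uniform
   strip.

``TensileTest`` / ``TensileResults`` wrap the chain in fit/results
objects with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorModel", "PullProtocol", "ForceTrace", "FailureInfo",
    "MechanicalSummary", "TensileTest", "TensileResults",
    "CalibrationError",
    "deflection_to_force", "to_force", "zero_calibrate",
    "pellicle_elongation", "detect_failure", "fit_elastic",
    "correct_true_strain", "rescale_stiffness", "failure_strain",
    "summarize_replicates",
]


class CalibrationError(RuntimeError):
    """Raised when the zero-force calibration window is unusable."""


@dataclass
class SensorModel:
    """Double-cantilever force sensor.

    ``cantilever_stiffness`` in mN/mm; ``deflection_resolution`` in µm
    (the capacitive gauge resolution, i.e. a force floor of
    stiffness x resolution).
    """

    cantilever_stiffness: float = 19.5
    deflection_resolution: float = 0.40

    def __post_init__(self) -> None:
        if self.cantilever_stiffness <= 0:
            raise ValueError("cantilever_stiffness must be positive")


@dataclass
class PullProtocol:
    """Constant-speed uniaxial pull.

    ``speed`` in µm/s, ``sampling_interval`` in ms, ``max_travel`` and
    ``plate_gap`` (initial plate separation) in mm, ``plate_width`` in
    mm.
    """

    speed: float = 160.0
    sampling_interval: float = 100.0
    max_travel: float = 12.0
    plate_gap: float = 13.5
    plate_width: float = 41.0

    def __post_init__(self) -> None:
        for name in ("speed", "sampling_interval", "max_travel",
                     "plate_gap", "plate_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ForceTrace:
    """A stretching-device recording.

    ``raw_signal`` is the as-recorded channel, declared by ``channel``
    (``"deflection_um"`` or ``"force_mN"``).  ``force`` (mN) appears
    after conversion/calibration, ``elongation`` (mm) after the
    sensor-plate correction.  ``meta`` carries failure info and
    provenance.
    """

    time: np.ndarray
    plate_displacement: np.ndarray
    raw_signal: np.ndarray
    channel: str = "force_mN"
    force: np.ndarray | None = None
    elongation: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.plate_displacement = np.asarray(self.plate_displacement,
                                             dtype=float)
        self.raw_signal = np.asarray(self.raw_signal, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.channel not in ("deflection_um", "force_mN"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n(self) -> int:
        return self.time.size


@dataclass
class FailureInfo:
    """Detected failure event."""

    index: int
    failure_force: float       # mN, running maximum before the drop
    failure_elongation: float  # mm, on the elongation axis at the drop


@dataclass
class MechanicalSummary:
    """Per-condition replicate summary (mean ± s.d. over pellicles)."""

    stiffness: float
    intercept: float
    failure_force: float
    failure_elongation: float
    failure_strain_pct: float
    n_replicates: int
    dispersion: dict = field(default_factory=dict)


def deflection_to_force(deflection_um, sensor: SensorModel | None = None):
    """Convert a cantilever deflection (µm) to force (mN).

    force = stiffness (mN/mm) x deflection (mm); the sign is
    preserved, so pulling (positive deflection) and pushing forces are
    discriminated.  Homogeneous of degree 1.
    """
    if sensor is None:
        sensor = SensorModel()
    d = np.asarray(deflection_um, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("deflection must be finite")
    out = sensor.cantilever_stiffness * d / 1000.0
    return float(out) if out.ndim == 0 else out


def to_force(trace: ForceTrace, sensor: SensorModel | None = None
             ) -> ForceTrace:
    """Populate ``trace.force`` (uncalibrated) from the raw channel."""
    if sensor is None:
        sensor = SensorModel()
    if trace.channel == "force_mN":
        force = trace.raw_signal.copy()
    else:
        force = deflection_to_force(trace.raw_signal, sensor)
    return replace(trace, force=force, meta=dict(trace.meta))


def detect_failure(trace: ForceTrace, drop_fraction: float = 0.5,
                   window_samples: int = 5, min_peak_mN: float = 0.5
                   ) -> FailureInfo | None:
    """Locate the abrupt failure drop.

    Failure is the first sample where the force stays below
    ``drop_fraction`` x the running maximum for ``window_samples``
    consecutive samples, requiring the running maximum to have reached
    ``min_peak_mN`` (so baseline noise before loading cannot trigger).
    Returns None when no qualifying drop exists.  Deterministic.
    """
    force = trace.force if trace.force is not None else trace.raw_signal
    runmax = np.maximum.accumulate(force)
    n = force.size
    below = force < drop_fraction * runmax
    below &= runmax >= min_peak_mN
    for i in np.flatnonzero(below):
        j = min(n, i + window_samples)
        if np.all(below[i:j]) and j - i == min(window_samples, n - i):
            if trace.elongation is not None:
                fe = float(trace.elongation[i])
            else:
                fe = float(trace.plate_displacement[i])
            return FailureInfo(int(i), float(runmax[i]), fe)
    return None


def zero_calibrate(trace: ForceTrace, post_failure_window: float = 2.0,
                   **detect_kwargs) -> ForceTrace:
    """Subtract the zero-force value measured after failure.

    The offset is the mean force over the last ``post_failure_window``
    seconds of the record, when the sensor plate is no longer connected
    to the pellicle.  The window must lie entirely after the detected
    failure; otherwise a :class:`CalibrationError` is raised.
    Idempotent up to the noise in the window: calibrating twice equals
    once (the second offset is zero).
    """
    work = trace if trace.force is not None else to_force(trace)
    failure = detect_failure(work, **detect_kwargs)
    if failure is None:
        raise CalibrationError("no failure detected; cannot zero-calibrate")
    t_end = work.time[-1]
    window = work.time >= t_end - post_failure_window
    if work.time[window][0] < work.time[failure.index]:
        raise CalibrationError("calibration window overlaps pre-failure data")
    if not np.any(window):
        raise CalibrationError("no samples in the post-failure window")
    offset = float(work.force[window].mean())
    meta = dict(work.meta)
    meta["zero_offset_mN"] = offset
    force = work.force - offset
    fi = replace(failure, failure_force=failure.failure_force - offset)
    meta["failure"] = fi
    return replace(work, force=force, meta=meta)


def pellicle_elongation(trace: ForceTrace,
                        sensor: SensorModel | None = None) -> ForceTrace:
    """Correct elongation for the sensor-plate deflection.

    elongation = plate displacement - force / cantilever stiffness: a
    tensile (positive) force pulls the "immobile" plate toward the
    mobile one, reducing the true pellicle elongation.
    """
    if sensor is None:
        sensor = SensorModel()
    if trace.force is None:
        raise ValueError("calibrated force required; run zero_calibrate first")
    elong = trace.plate_displacement - trace.force / sensor.cantilever_stiffness
    out = replace(trace, elongation=elong, meta=dict(trace.meta))
    fi = out.meta.get("failure")
    if fi is not None:
        out.meta["failure"] = replace(fi,
                                      failure_elongation=float(elong[fi.index]))
    return out


def fit_elastic(trace: ForceTrace,
                fit_range: tuple[float, float] = (0.05, 0.90),
                elongation: np.ndarray | None = None
                ) -> tuple[float, float]:
    """Fit the elastic regime: force = stiffness x elongation + intercept.

    Least squares of force (mN) on elongation (mm) over ``fit_range``
    expressed as fractions of the failure elongation (default 5-90 %,
    excluding seating transients and pre-failure crack initiation).
    The slope in mN/mm is reported as stiffness in N/m (numerically
    identical); the intercept is the force at zero elongation.

    ``elongation`` overrides the trace's elongation axis (e.g. a
    true-strain-corrected series).
    """
    if trace.force is None:
        raise ValueError("calibrated force required")
    x = elongation if elongation is not None else trace.elongation
    if x is None:
        x = trace.plate_displacement
    x = np.asarray(x, dtype=float)
    fi = trace.meta.get("failure")
    if fi is None:
        fi = detect_failure(trace)
    if fi is None:
        raise ValueError("failure unknown; pass an explicit fit range axis")
    e_fail = x[fi.index]
    lo, hi = fit_range
    mask = (x >= lo * e_fail) & (x <= hi * e_fail) & \
           (np.arange(x.size) < fi.index)
    if mask.sum() < 10:
        raise ValueError("fewer than 10 samples in the fit range")
    slope, intercept = np.polyfit(x[mask], trace.force[mask], 1)
    return float(slope), float(intercept)


def correct_true_strain(elongation_series, central_fraction: float):
    """Rescale an elongation axis by the fraction actually absorbed.

    When only ``central_fraction`` of the applied plate displacement is
    absorbed by the region whose stiffness is reported, the true
    elongation of that region is central_fraction x elongation.
    """
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must be in (0, 1]")
    out = central_fraction * np.asarray(elongation_series, dtype=float)
    return float(out) if out.ndim == 0 else out


def rescale_stiffness(k_segment: float, segment_length_fraction: float
                      ) -> float:
    """Rescale a segment stiffness to the full strip length.

    Stiffness of a uniform strip scales inversely with its length, so
    k_full = k_segment x fraction; the product k x L is conserved.
    """
    if not 0 < segment_length_fraction <= 1:
        raise ValueError("segment_length_fraction must be in (0, 1]")
    return k_segment * segment_length_fraction


def failure_strain(failure_elongation: float, initial_gap: float) -> float:
    """Failure elongation as a percentage of the initial plate gap."""
    if initial_gap <= 0:
        raise ValueError("initial_gap must be positive")
    return 100.0 * failure_elongation / initial_gap


def summarize_replicates(results: list["TensileResults"]
                         ) -> MechanicalSummary:
    """Unweighted mean ± s.d. over replicate pellicles."""
    if not results:
        raise ValueError("no replicates")
    ks = np.array([r.stiffness for r in results])
    cs = np.array([r.intercept for r in results])
    ff = np.array([r.failure_force for r in results])
    fe = np.array([r.failure_elongation for r in results])
    fs = np.array([r.failure_strain_pct for r in results])
    sd = (lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0)
    return MechanicalSummary(
        stiffness=float(ks.mean()), intercept=float(cs.mean()),
        failure_force=float(ff.mean()), failure_elongation=float(fe.mean()),
        failure_strain_pct=float(fs.mean()), n_replicates=len(results),
        dispersion={"stiffness": sd(ks), "intercept": sd(cs),
                    "failure_force": sd(ff), "failure_elongation": sd(fe),
                    "failure_strain_pct": sd(fs)})


class TensileTest:
    """Tensile-test model for one pellicle recording.

    Parameters
    ----------
    trace : ForceTrace
        The raw recording (deflection or force channel).
    sensor, protocol : SensorModel, PullProtocol
        Device constants; defaults are the double-cantilever sensor
        (19.5 mN/mm) and the standard 160 µm/s pull.
    central_fraction : float
        True-strain correction factor (1 = whole pellicle deforms;
        0.27 for the rough-pellicle central region).
    """

    def __init__(self, trace: ForceTrace, sensor: SensorModel | None = None,
                 protocol: PullProtocol | None = None,
                 central_fraction: float = 1.0):
        self.trace = trace
        self.sensor = sensor if sensor is not None else SensorModel()
        self.protocol = protocol if protocol is not None else PullProtocol()
        self.central_fraction = central_fraction

    def fit(self, fit_range: tuple[float, float] = (0.05, 0.90),
            post_failure_window: float = 2.0, drop_fraction: float = 0.5,
            window_samples: int = 5, plate_correction: bool = True
            ) -> "TensileResults":
        """Run the full chain and return a :class:`TensileResults`."""
        trace = to_force(self.trace, self.sensor)
        trace = zero_calibrate(trace, post_failure_window,
                               drop_fraction=drop_fraction,
                               window_samples=window_samples)
        if plate_correction:
            trace = pellicle_elongation(trace, self.sensor)
        else:
            trace = replace(trace,
                            elongation=trace.plate_displacement.copy(),
                            meta=dict(trace.meta))
        axis = correct_true_strain(trace.elongation, self.central_fraction)
        fi: FailureInfo = trace.meta["failure"]
        fi = replace(fi, failure_elongation=float(axis[fi.index]))
        trace.meta["failure"] = fi
        stiffness, intercept = fit_elastic(trace, fit_range, elongation=axis)
        strain = failure_strain(fi.failure_elongation, self.protocol.plate_gap)
        return TensileResults(self, trace, stiffness, intercept,
                              fi.failure_force, fi.failure_elongation, strain)


@dataclass
class TensileResults:
    """Fitted tensile test: stiffness, intercept, failure quantities."""

    model: TensileTest
    trace: ForceTrace
    stiffness: float            # N/m on the (corrected) elongation axis
    intercept: float            # mN at zero elongation
    failure_force: float        # mN
    failure_elongation: float   # mm (corrected axis)
    failure_strain_pct: float

    def rescaled_stiffness(self, segment_length_fraction: float) -> float:
        return rescale_stiffness(self.stiffness, segment_length_fraction)

    def summary(self) -> str:
        lines = [
            "Tensile test fit",
            "=" * 52,
            f"samples: {self.trace.n}   zero offset: "
            f"{self.trace.meta.get('zero_offset_mN', 0.0):.3f} mN",
            f"central fraction (true strain): "
            f"{self.model.central_fraction:g}",
            f"stiffness:          {self.stiffness:8.3f} N/m",
            f"intercept:          {self.intercept:8.3f} mN",
            f"failure force:      {self.failure_force:8.3f} mN",
            f"failure elongation: {self.failure_elongation:8.3f} mm",
            f"failure strain:     {self.failure_strain_pct:8.1f} %",
            "=" * 52,
        ]
        return "\n".join(lines)
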