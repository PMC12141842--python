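"""Deformation profiles of stretched pellicles and their segmentation.

A PIV displacement field from an image pair taken at two elongation
states is reduced to a 1-D profile of relative displacement u_rel
versus relative position x_rel along the elongation axis (0 at the
immobile plate, 1 at the mobile plate).  A homogeneous elastic strip
gives the affine profile u_rel = x_rel; composite pellicles deviate
from it and are modelled by a continuous piecewise-linear fit whose
breakpoints are found by exhaustive search on a position grid.

From the fitted model, each interval's *elongation fraction* — the
share of the total applied elongation absorbed inside the interval —
is u_rel(x_hi) - u_rel(x_lo), and segments are classified as soft /
central / rigid translation / step regions.

``DeformationModel`` / ``DeformationResults`` wrap these operations in
fit/results objects with a ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from pellikit.pivcore import DisplacementField
from pellikit.synthgen import ProfileNodes

__all__ = [
    "DeformationProfile", "AffineFit", "PiecewiseFit", "RegionSummary",
    "DeformationModel", "DeformationResults",
    "profile_from_field", "fit_affine", "fit_piecewise",
    "region_elongation_fraction", "classify_regions",
]


@dataclass
class DeformationProfile:
    """Relative displacement vs. relative position along the pull axis.

    ``error_rel`` is the per-point uncertainty — one pixel expressed in
    relative displacement units (1 / applied elongation in px).
    """

    x_rel: np.ndarray
    u_rel: np.ndarray
    applied_elongation_mm: float
    error_rel: float

    def __post_init__(self) -> None:
        self.x_rel = np.asarray(self.x_rel, dtype=float)
        self.u_rel = np.asarray(self.u_rel, dtype=float)
        if self.x_rel.shape != self.u_rel.shape:
            raise ValueError("x_rel and u_rel must share one shape")
        if np.any(self.x_rel < 0) or np.any(self.x_rel > 1):
            raise ValueError("x_rel must lie in [0, 1]")
        if self.error_rel <= 0:
            raise ValueError("error_rel must be positive")

    @classmethod
    def from_nodes(cls, nodes: ProfileNodes, n_points: int = 41,
                   applied_elongation_mm: float = 1.0,
                   error_rel: float = 1e-3) -> "DeformationProfile":
        """Sample a noiseless profile from a piecewise node set."""
        from pellikit.synthgen import evaluate_profile
        x = np.linspace(0.0, 1.0, n_points)
        return cls(x, evaluate_profile(nodes, x), applied_elongation_mm,
                   error_rel)


@dataclass
class AffineFit:
    """Least-squares line u_rel = slope * x_rel + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear fit of a deformation profile."""

    nodes: ProfileNodes
    sse: float
    n_segments: int

    def predict(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.nodes.x, self.nodes.u)
        return float(out) if out.ndim == 0 else out

    @property
    def breakpoints(self) -> np.ndarray:
        return self.nodes.x[1:-1]

    def segment_slopes(self) -> np.ndarray:
        return np.diff(self.nodes.u) / np.diff(self.nodes.x)


@dataclass
class RegionSummary:
    """One interval of the fitted profile and what it does mechanically."""

    interval: tuple[float, float]
    elongation_fraction: float
    label: str  # soft | central | rigid_translation | step


def profile_from_field(field: DisplacementField, immobile_x_px: float,
                       mobile_x_px: float, applied_elongation_mm: float,
                       pixel_size: float,
                       sensor_correction_mm: float = 0.0
                       ) -> DeformationProfile:
    """Reduce a displacement field to a 1-D deformation profile.

    Vectors are collapsed across the transverse direction by taking the
    median of valid vectors at each longitudinal station (robust to
    edge menisci).  Positions are mapped to [0, 1] between the plate
    positions, with the immobile plate shifted toward the mobile one by
    ``sensor_correction_mm`` (= force / sensor stiffness, the slight
    displacement of the force-sensor plate under load).  Displacements
    are divided by the applied elongation.  Stations with no valid
    vector, or falling outside [0, 1] after correction, are omitted.
    """
    if mobile_x_px <= immobile_x_px:
        raise ValueError("mobile plate must lie beyond the immobile plate")
    if applied_elongation_mm <= 0:
        raise ValueError("applied elongation must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    corr_px = sensor_correction_mm / pixel_size
    origin = immobile_x_px + corr_px
    span = mobile_x_px - origin
    applied_px = applied_elongation_mm / pixel_size

    xs, us = [], []
    for j in range(field.u.shape[1]):
        col_u = field.u[:, j][field.valid[:, j]]
        col_u = col_u[np.isfinite(col_u)]
        if col_u.size == 0:
            continue
        x_rel = (field.grid_x[0, j] - origin) / span
        if not 0.0 <= x_rel <= 1.0:
            continue
        xs.append(x_rel)
        us.append(np.median(col_u) / applied_px)
    if not xs:
        raise ValueError("no valid stations in field")
    return DeformationProfile(np.array(xs), np.array(us),
                              applied_elongation_mm,
                              error_rel=1.0 / applied_px)


def fit_affine(profile: DeformationProfile) -> AffineFit:
    """Least-squares line of u_rel on x_rel with r²."""
    x, y = profile.x_rel, profile.u_rel
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x spread")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return AffineFit(float(slope), float(intercept), float(max(0.0, min(1.0, r2))))


def _hinge_design(x: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Design matrix [1, x, (x-b1)+, ...] of the continuous PWL model."""
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.maximum(x - b, 0.0))
    return np.column_stack(cols)


def _coef_to_nodes(coef: np.ndarray, breaks: np.ndarray) -> ProfileNodes:
    node_x = np.concatenate(([0.0], breaks, [1.0]))
    node_u = _hinge_design(node_x, breaks) @ coef
    return ProfileNodes(tuple(zip(node_x, node_u)))


def fit_piecewise(profile: DeformationProfile, n_segments: int = 4,
                  grid_step: float = 0.01) -> PiecewiseFit:
    """Continuous piecewise-linear fit with exhaustively searched breaks.

    Interior breakpoints are restricted to a regular grid of step
    ``grid_step`` in (0, 1); every admissible breakpoint combination
    (each open segment must contain at least two sample points) is
    scored by the sum of squared residuals of the continuous
    hinge-basis least-squares fit, and the minimum is returned.  Ties
    break to the leftmost (lexicographically smallest) breakpoints.

    The search is exact — identical to brute force over the same grid —
    but runs on precomputed Gram matrices so all combinations are
    solved in one batched pass.
    """
    x, y = profile.x_rel, profile.u_rel
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if x.size < 3 * n_segments:
        raise ValueError(
            f"{x.size} points cannot support {n_segments} segments")

    if n_segments == 1:
        A = _hinge_design(x, np.array([]))
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ coef - y) ** 2))
        return PiecewiseFit(_coef_to_nodes(coef, np.array([])), sse, 1)

    k = n_segments - 1
    grid = np.arange(grid_step, 1.0, grid_step)
    grid = grid[(grid > x[0]) & (grid < x[-1])]
    if grid.size < k:
        raise ValueError("breakpoint grid too coarse for n_segments")

    # Gram-matrix pieces shared by every breakpoint combination.
    Hm = np.maximum(x[np.newaxis, :] - grid[:, np.newaxis], 0.0)  # (g, n)
    s00 = float(x.size)
    s01 = float(x.sum())
    s11 = float((x * x).sum())
    g0 = Hm.sum(axis=1)                 # <1, h_b>
    g1 = Hm @ x                         # <x, h_b>
    G = Hm @ Hm.T                       # <h_b, h_b'>
    y0 = float(y.sum())
    y1 = float(x @ y)
    hy = Hm @ y
    yy = float(y @ y)

    # admissible combos: >= 2 sample points strictly inside each segment
    counts = np.searchsorted(x, grid)   # points with x < b (grid off-sample)
    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(grid.size), k)),
        dtype=np.intp).reshape(-1, k)
    edges = np.column_stack([
        np.zeros(combos.shape[0], dtype=np.intp),
        counts[combos],
        np.full(combos.shape[0], x.size, dtype=np.intp)])
    combos = combos[np.all(np.diff(edges, axis=1) >= 2, axis=1)]
    if combos.size == 0:
        raise ValueError("no admissible breakpoint combination")
    m = combos.shape[0]
    p = k + 2

    ATA = np.empty((m, p, p))
    ATy = np.empty((m, p))
    ATA[:, 0, 0] = s00
    ATA[:, 0, 1] = ATA[:, 1, 0] = s01
    ATA[:, 1, 1] = s11
    ATy[:, 0] = y0
    ATy[:, 1] = y1
    for a in range(k):
        idx = combos[:, a]
        ATA[:, 0, 2 + a] = ATA[:, 2 + a, 0] = g0[idx]
        ATA[:, 1, 2 + a] = ATA[:, 2 + a, 1] = g1[idx]
        ATy[:, 2 + a] = hy[idx]
        for b in range(k):
            ATA[:, 2 + a, 2 + b] = G[idx, combos[:, b]]
    try:
        coefs = np.linalg.solve(ATA, ATy[..., np.newaxis])[..., 0]
        sses = yy - np.einsum("ij,ij->i", coefs, ATy)
    except np.linalg.LinAlgError:       # rare rank deficiency: per-combo
        coefs = np.empty((m, p))
        sses = np.full(m, np.inf)
        for i, c in enumerate(combos):
            A = _hinge_design(x, grid[c])
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            coefs[i] = sol
            sses[i] = np.sum((A @ sol - y) ** 2)
    best = int(np.argmin(np.maximum(sses, 0.0)))
    breaks = grid[combos[best]]
    return PiecewiseFit(_coef_to_nodes(coefs[best], breaks),
                        float(max(sses[best], 0.0)), n_segments)


def region_elongation_fraction(fit: PiecewiseFit,
                               interval: tuple[float, float]) -> float:
    """Share of the total elongation absorbed inside ``interval``.

    Evaluated on the fitted model as u_rel(x_hi) - u_rel(x_lo); over a
    partition of [0, 1] the fractions sum to u_rel(1) - u_rel(0).
    """
    x_lo, x_hi = interval
    if not 0.0 <= x_lo < x_hi <= 1.0:
        raise ValueError("interval must satisfy 0 <= x_lo < x_hi <= 1")
    return float(fit.predict(x_hi) - fit.predict(x_lo))


def classify_regions(fit: PiecewiseFit, rigid_slope_max: float = 0.1,
                     step_width_max: float = 0.1) -> list[RegionSummary]:
    """Label each fitted segment mechanically.

    Rules, in order: local slope <= ``rigid_slope_max`` — a rigid
    translation (matter moves without deforming); width <=
    ``step_width_max`` and slope > 1 — a quasi-discontinuous step;
    first segment adjoining x = 0 with slope > 1 — a soft region
    absorbing more than its share; otherwise central.  "slope > 1" is
    applied with a small numerical tolerance so an exactly affine fit
    classifies as central.
    """
    out = []
    node_x = fit.nodes.x
    slopes = fit.segment_slopes()
    above_one = 1.0 + 1e-6
    for i, slope in enumerate(slopes):
        lo, hi = node_x[i], node_x[i + 1]
        width = hi - lo
        if slope <= rigid_slope_max:
            label = "rigid_translation"
        elif width <= step_width_max and slope > above_one:
            label = "step"
        elif i == 0 and slope > above_one:
            label = "soft"
        else:
            label = "central"
        out.append(RegionSummary((float(lo), float(hi)),
                                 region_elongation_fraction(fit, (lo, hi)),
                                 label))
    return out


class DeformationModel:
    """Deformation-profile model in the fit/results idiom.

    Parameters
    ----------
    profile : DeformationProfile
        The 1-D relative-displacement profile to model.

    ``fit()`` always computes the affine reference fit and, unless the
    profile is affine enough, a piecewise-linear segmentation; it
    returns a :class:`DeformationResults`.
    """

    def __init__(self, profile: DeformationProfile):
        self.profile = profile

    @classmethod
    def from_field(cls, field: DisplacementField, immobile_x_px: float,
                   mobile_x_px: float, applied_elongation_mm: float,
                   pixel_size: float, sensor_correction_mm: float = 0.0
                   ) -> "DeformationModel":
        return cls(profile_from_field(field, immobile_x_px, mobile_x_px,
                                      applied_elongation_mm, pixel_size,
                                      sensor_correction_mm))

    def fit(self, n_segments: int | None = None, grid_step: float = 0.01,
            max_segments: int = 4, sse_drop: float = 0.25
            ) -> "DeformationResults":
        """Fit affine and piecewise models.

        If ``n_segments`` is None the segment count is selected by
        adding segments while the SSE drops by more than ``sse_drop``
        (fractionally) per added segment, up to ``max_segments``; an
        SSE already at numerical zero (< 1e-10) stops the search.
        """
        affine = fit_affine(self.profile)
        if n_segments is not None:
            pw = fit_piecewise(self.profile, n_segments, grid_step)
        else:
            pw = fit_piecewise(self.profile, 1, grid_step)
            for n in range(2, max_segments + 1):
                if pw.sse <= 1e-10:
                    break
                cand = fit_piecewise(self.profile, n, grid_step)
                if (pw.sse - cand.sse) / pw.sse > sse_drop:
                    pw = cand
                else:
                    break
        regions = classify_regions(pw)
        return DeformationResults(self, affine, pw, regions)


@dataclass
class DeformationResults:
    """Fitted deformation profile: affine reference, segmentation, regions."""

    model: DeformationModel
    affine: AffineFit
    piecewise: PiecewiseFit
    regions: list[RegionSummary] = field(default_factory=list)

    def elongation_fraction(self, interval: tuple[float, float]) -> float:
        return region_elongation_fraction(self.piecewise, interval)

    def summary(self) -> str:
        lines = [
            "Deformation profile fit",
            "=" * 58,
            f"points: {self.model.profile.x_rel.size}   "
            f"applied elongation: "
            f"{self.model.profile.applied_elongation_mm:g} mm",
            f"affine fit:    slope {self.affine.slope:8.4f}   "
            f"intercept {self.affine.intercept:8.4f}   "
            f"r2 {self.affine.r_squared:6.4f}",
            f"piecewise fit: {self.piecewise.n_segments} segments   "
            f"sse {self.piecewise.sse:.3e}",
            "-" * 58,
            f"{'interval':>16} {'fraction':>10} {'slope':>8}  label",
        ]
        slopes = self.piecewise.segment_slopes()
        for reg, slope in zip(self.regions, slopes):
            lines.append(
                f"[{reg.interval[0]:5.2f}, {reg.interval[1]:5.2f}] "
                f"{reg.elongation_fraction:10.3f} {slope:8.3f}  {reg.label}")
        lines.append("=" * 58)
        return "\n".join(lines)
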