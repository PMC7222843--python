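"""The buffer-capacity determination model.

Pipeline, applied per titration record:

1. restrict to the direction-specific pH fit window,
2. least-squares polynomial regression of pH on titrant amount (degree 6),
3. analytic differentiation of the fitted polynomial,
4. reciprocal absolute slope: CBC(pH) = |1 / (dpH/damount)|, sampled on a
   uniform amount grid,
5. locate per-buffer-system peaks of CBC within configurable pH windows.

CBC (current buffer capacity) is the amount of strong acid or base, in mol
per kg slurry, needed to shift the sample's pH by one unit at a given pH.
Its physico-chemical counterpart is the buffer index beta = dC_B/dpH.

Fit windows follow the protocol: acidification uses pH 7.0-3.0; direct
alkalization uses pH 7.8-11.5, starting from the reading nearest 7.8 when
the sample is already more alkaline than 7.8; alkalization performed after a
prior acidification uses pH 7.0-11.5.

Grid points where the fitted slope falls below ``eps_slope`` are excluded
from the reciprocal (and counted); losing more than 10% of the grid marks
the fit degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple

import numpy as np
from numpy.polynomial import Polynomial

from .errors import (
    CoverageError,
    DegenerateFitError,
    FitError,
    InsufficientDataError,
)
from .titration_io import Direction, TitrationRecord, normalize_amount

DEFAULT_DEGREE = 6
DEFAULT_N_GRID = 512
DEFAULT_EPS_SLOPE = 1e-3  # pH kg mol^-1; below this the reciprocal blows up
MIN_FIT_POINTS_MARGIN = 4  # need degree + margin points

ACID_FIT_WINDOW = (3.0, 7.0)
ALKALI_FIT_WINDOW = (7.8, 11.5)
ALKALI_AFTER_ACID_FIT_WINDOW = (7.0, 11.5)

#: Default pH windows of the four slurry buffer systems. The VFA and first
#: carbonate windows are where those peaks appear in slurry; the ammonia
#: window is centred on pKa 9.25; the second carbonate system peaks high.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "VFA": (4.0, 4.5),
    "HCO3": (6.0, 6.5),
    "NH3": (8.5, 10.0),
    "CO3": (9.5, 11.5),
}


class FitRange(NamedTuple):
    """Points selected for regression: amounts (mol/kg slurry), pH values,
    the pH fit window actually applied, and the titration direction."""

    amount: np.ndarray
    ph: np.ndarray
    window: tuple[float, float]
    direction: Direction


@dataclass(frozen=True)
class CurveFit:
    """Polynomial titration curve pH = p(amount) over a fit window."""

    poly: Polynomial
    degree: int
    fit_window: tuple[float, float]
    amount_window: tuple[float, float]
    n_points: int
    rmse_ph: float
    direction: Direction
    monotone: bool

    def __call__(self, amount):
        return self.poly(amount)

    def slope(self) -> Polynomial:
        return self.poly.deriv()


@dataclass(frozen=True)
class CBCCurve:
    """Sampled current-buffer-capacity curve on a uniform amount grid."""

    amount: np.ndarray  # mol titrant per kg slurry
    ph: np.ndarray
    cbc: np.ndarray  # mol kg^-1 slurry pH^-1
    direction: Direction
    n_dropped: int  # grid points lost to |slope| < eps_slope
    fit: CurveFit

    @property
    def drop_fraction(self) -> float:
        n_total = len(self.cbc) + self.n_dropped
        return self.n_dropped / n_total if n_total else 0.0


@dataclass(frozen=True)
class BufferPeak:
    """Peak CBC of one buffer system inside its pH window.

    When no interior local maximum exists (``is_local_max=False``) the
    reported value is the window-boundary supremum and must be treated as
    non-quantifiable: the buffer could not be separated from its neighbours.
    """

    buffer: str
    window: tuple[float, float]
    peak_ph: float
    max_cbc: float
    is_local_max: bool


def select_fit_range(record: TitrationRecord) -> FitRange:
    """Select the direction-specific pH window of a record for regression.

    Acidification keeps readings with pH in [3.0, 7.0]; alkalization keeps
    [7.8, 11.5] except that a sample starting above pH 7.8 is fitted from
    the reading nearest 7.8 (its first step); alkalization after a prior
    acidification keeps [7.0, 11.5]. Points are returned in dosing order.
    """
    ph = record.steps["ph"].to_numpy(float)
    amount = normalize_amount(record)
    if record.direction is Direction.ACIDIFY:
        window = ACID_FIT_WINDOW
        mask = (ph >= window[0]) & (ph <= window[1])
    elif record.direction is Direction.ALKALIZE:
        window = ALKALI_FIT_WINDOW
        if ph[0] > window[0]:
            # already more alkaline than 7.8: start from the reading nearest
            # 7.8 and keep everything up to the top of the window
            start = int(np.argmin(np.abs(ph - window[0])))
            mask = np.zeros_like(ph, dtype=bool)
            mask[start:] = ph[start:] <= window[1]
            window = (float(ph[start]), window[1])
        else:
            mask = (ph >= window[0]) & (ph <= window[1])
    else:  # ALKALIZE_AFTER_ACID
        window = ALKALI_AFTER_ACID_FIT_WINDOW
        mask = (ph >= window[0]) & (ph <= window[1])
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"{record.sample_id}: only {int(mask.sum())} points inside "
            f"pH window {window}; need >= 10"
        )
    order = np.argsort(amount[mask], kind="stable")
    return FitRange(amount[mask][order], ph[mask][order], window, record.direction)


def fit_titration_curve(points: FitRange, degree: int = DEFAULT_DEGREE) -> CurveFit:
    """Least-squares polynomial of pH on titrant amount.

    The default degree is 6 — the reference configuration of the model;
    other degrees are accepted but leave the reference path. Monotonicity of
    the fit (decreasing for acidification, increasing for alkalization) is
    checked on a 512-point grid and recorded in ``monotone``.
    """
    amount, ph = np.asarray(points.amount, float), np.asarray(points.ph, float)
    if len(amount) < degree + MIN_FIT_POINTS_MARGIN:
        raise InsufficientDataError(
            f"need >= {degree + MIN_FIT_POINTS_MARGIN} points for degree "
            f"{degree}, got {len(amount)}"
        )
    if np.ptp(amount) == 0:
        raise FitError("all titrant amounts equal; cannot regress pH on amount")
    try:
        poly = Polynomial.fit(amount, ph, deg=degree)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy internal
        raise FitError(f"rank-deficient design; try a lower degree: {exc}") from exc
    resid = ph - poly(amount)
    rmse = float(np.sqrt(np.mean(resid**2)))
    grid = np.linspace(amount.min(), amount.max(), DEFAULT_N_GRID)
    slopes = poly.deriv()(grid)
    expected_sign = -1.0 if points.direction is Direction.ACIDIFY else 1.0
    monotone = bool(np.all(expected_sign * slopes > 0))
    return CurveFit(
        poly=poly,
        degree=degree,
        fit_window=points.window,
        amount_window=(float(amount.min()), float(amount.max())),
        n_points=len(amount),
        rmse_ph=rmse,
        direction=points.direction,
        monotone=monotone,
    )


def slope_curve(fit: CurveFit) -> Callable[[np.ndarray], np.ndarray]:
    """Exact analytic derivative of the fitted polynomial, dpH/damount."""
    return fit.poly.deriv()


def compute_cbc(
    fit: CurveFit,
    n_grid: int = DEFAULT_N_GRID,
    eps_slope: float = DEFAULT_EPS_SLOPE,
) -> CBCCurve:
    """Sample CBC(pH) = |1/slope| on a uniform amount grid over the fit.

    Grid points with |slope| < ``eps_slope`` (reciprocal singularities from
    fit wiggle) are dropped and counted; more than 10% dropped raises
    :class:`DegenerateFitError`. Points whose fitted pH strays outside the
    fit window are likewise excluded from the returned curve.
    """
    a_min, a_max = fit.amount_window
    grid = np.linspace(a_min, a_max, n_grid)
    ph = fit.poly(grid)
    slope = fit.poly.deriv()(grid)
    keep_slope = np.abs(slope) >= eps_slope
    n_dropped = int((~keep_slope).sum())
    if n_dropped > 0.10 * n_grid:
        raise DegenerateFitError(
            f"{n_dropped}/{n_grid} grid points have |slope| < {eps_slope}; "
            "the titration curve is too flat for a reciprocal-slope CBC"
        )
    lo, hi = fit.fit_window
    keep = keep_slope & (ph >= lo) & (ph <= hi)
    return CBCCurve(
        amount=grid[keep],
        ph=ph[keep],
        cbc=1.0 / np.abs(slope[keep]),
        direction=fit.direction,
        n_dropped=n_dropped,
        fit=fit,
    )


def _quadratic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points; falls back to the middle
    point when the points are collinear."""
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (
        x[2] ** 2 * (y[0] - y[1])
        + x[1] ** 2 * (y[2] - y[0])
        + x[0] ** 2 * (y[1] - y[2])
    ) / denom
    if a >= 0:  # not concave; no refinement possible
        return float(x[1]), float(y[1])
    xv = -b / (2 * a)
    xv = float(np.clip(xv, min(x), max(x)))
    c = y[1] - a * x[1] ** 2 - b * x[1]
    return xv, float(a * xv**2 + b * xv + c)


def find_peak(curve: CBCCurve, window: tuple[float, float], buffer: str = "") -> BufferPeak:
    """Locate the peak CBC inside a buffer system's pH window.

    An interior local maximum on the sampled grid is refined by quadratic
    interpolation of the three bracketing points; competing maxima of equal
    height break toward the window midpoint. Without an interior maximum the
    boundary supremum is returned with ``is_local_max=False`` (the buffer is
    present but not separable in this window).
    """
    lo, hi = window
    order = np.argsort(curve.ph, kind="stable")
    ph, cbc = curve.ph[order], curve.cbc[order]
    mask = (ph >= lo) & (ph <= hi)
    if not mask.any():
        raise CoverageError(
            f"CBC curve (pH {ph.min():.2f}-{ph.max():.2f}) does not cover "
            f"window {window}"
        )
    idx = np.flatnonzero(mask)
    sub_ph, sub_cbc = ph[idx], cbc[idx]
    # interior local maxima: strictly above at least one neighbour, not below either
    maxima = []
    for i in range(1, len(idx) - 1):
        left, mid, right = sub_cbc[i - 1], sub_cbc[i], sub_cbc[i + 1]
        if mid >= left and mid >= right and (mid > left or mid > right):
            maxima.append(i)
    if maxima:
        midpoint = 0.5 * (lo + hi)
        best = max(maxima, key=lambda i: (sub_cbc[i], -abs(sub_ph[i] - midpoint)))
        peak_ph, peak_cbc = _quadratic_vertex(
            sub_ph[best - 1 : best + 2], sub_cbc[best - 1 : best + 2]
        )
        peak_ph = float(np.clip(peak_ph, lo, hi))
        return BufferPeak(buffer, window, peak_ph, peak_cbc, is_local_max=True)
    # monotone over the window: report the boundary supremum, flagged
    best = int(np.argmax(sub_cbc))
    return BufferPeak(
        buffer, window, float(sub_ph[best]), float(sub_cbc[best]), is_local_max=False
    )


def find_peaks(
    curve: CBCCurve, windows: Mapping[str, tuple[float, float]] | None = None
) -> dict[str, BufferPeak]:
    """Peaks for every buffer window the curve covers; uncovered windows are
    silently omitted (an acidification record cannot show the ammonia peak)."""
    windows = DEFAULT_WINDOWS if windows is None else windows
    peaks = {}
    for name, window in windows.items():
        try:
            peaks[name] = find_peak(curve, window, buffer=name)
        except CoverageError:
            continue
    return peaks


def integrate_cbc(curve: CBCCurve, ph_low: float, ph_high: float) -> float:
    """Area under CBC(pH) between two pH values (mol titrant per kg slurry).

    Because CBC is |damount/dpH|, this area is the titrant amount consumed
    between the two pH values — the conservation property that ties the
    fitted model back to the raw dosing data.
    """
    if ph_high <= ph_low:
        raise CoverageError("ph_high must exceed ph_low")
    order = np.argsort(curve.ph, kind="stable")
    ph, cbc = curve.ph[order], curve.cbc[order]
    if ph_low < ph.min() - 1e-9 or ph_high > ph.max() + 1e-9:
        raise CoverageError(
            f"integration bounds ({ph_low}, {ph_high}) outside curve "
            f"coverage ({ph.min():.3f}, {ph.max():.3f})"
        )
    grid = np.linspace(max(ph_low, ph.min()), min(ph_high, ph.max()), 1024)
    vals = np.interp(grid, ph, cbc)
    return float(np.trapezoid(vals, grid))


def analyze_record(
    record: TitrationRecord,
    degree: int = DEFAULT_DEGREE,
    windows: Mapping[str, tuple[float, float]] | None = None,
    n_grid: int = DEFAULT_N_GRID,
    eps_slope: float = DEFAULT_EPS_SLOPE,
) -> tuple[CurveFit, CBCCurve, dict[str, BufferPeak]]:
    """Run the full determination model on one record."""
    points = select_fit_range(record)
    fit = fit_titration_curve(points, degree=degree)
    curve = compute_cbc(fit, n_grid=n_grid, eps_slope=eps_slope)
    return fit, curve, find_peaks(curve, windows)
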