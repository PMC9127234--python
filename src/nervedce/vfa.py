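"""Variable-flip-angle (VFA) T1 relaxometry for spoiled gradient-echo data.

The spoiled-GRE steady-state signal at flip angle ``a`` and repetition time
``TR`` is ``SI(a) = M0 sin(a) (1 - E1) / (1 - E1 cos(a))`` with
``E1 = exp(-TR/T1)``.  Dividing by ``tan(a)`` and ``sin(a)`` linearizes the
model: the points ``x(a) = SI/tan(a)``, ``y(a) = SI/sin(a)`` lie on the line
``y = E1 * x + M0 (1 - E1)``, so an ordinary least-squares fit of y on x
yields the slope ``m = E1`` and the pre-contrast relaxation time follows as
``T1_0 = -TR / log(m)``.

Estimation is unweighted OLS over the nominal prescribed angles; no B1+
correction is applied.  A voxelwise driver is provided for parameter maps;
voxels whose estimate falls outside a plausibility window (0.05-10 s by
default) are flagged invalid and excluded from ROI aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAngle, InsufficientAngles, NonphysicalSlope

__all__ = [
    "FlipAngleSeries",
    "VfaRegressionPoints",
    "T1Estimate",
    "spgr_signal",
    "linearize_vfa",
    "estimate_t1",
    "estimate_t1_voxelwise",
    "T1_VALID_RANGE_S",
]

#: Plausibility window for voxelwise T1 estimates, seconds.
T1_VALID_RANGE_S = (0.05, 10.0)


@dataclass(frozen=True)
class FlipAngleSeries:
    """Pre-contrast ROI signal at each flip angle of the VFA block.

    Parameters
    ----------
    angles_deg:
        Flip angles in degrees, each strictly inside (0, 90).
    signal:
        Mean ROI signal intensity at each angle (arbitrary units, > 0).
    tr_s:
        Repetition time in seconds.
    """

    angles_deg: np.ndarray
    signal: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "signal", signal)
        if angles.ndim != 1 or signal.shape != angles.shape:
            raise ValueError("angles_deg and signal must be 1-D and aligned")
        if angles.size < 2 or np.unique(angles).size < 2:
            raise InsufficientAngles("need at least 2 distinct flip angles")
        if np.any(angles <= 0.0) or np.any(angles >= 90.0):
            raise DegenerateAngle("flip angles must lie strictly in (0, 90) deg")
        if np.any(signal <= 0.0) or not np.all(np.isfinite(signal)):
            raise ValueError("signals must be finite and positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")


@dataclass(frozen=True)
class VfaRegressionPoints:
    """Linearized VFA coordinates x = SI/tan(a), y = SI/sin(a)."""

    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class T1Estimate:
    """Result of the linearized VFA regression.

    ``t1_0_s`` is the pre-contrast spin-lattice relaxation time; ``slope_m``
    is the regression slope (equal to exp(-TR/T1) for noiseless data);
    ``intercept`` scales with M0; ``r_squared`` is the coefficient of
    determination of the line fit.
    """

    t1_0_s: float
    slope_m: float
    intercept: float
    r_squared: float


def spgr_signal(
    t1_s: float | np.ndarray,
    tr_s: float,
    alpha_deg: float | np.ndarray,
    m0: float = 1.0,
) -> np.ndarray:
    """Forward spoiled-GRE steady-state signal.

    Used by the acquisition simulator to generate synthetic raw signal;
    T1 estimation itself never evaluates this (it uses the linearized
    regression above).
    """
    t1 = np.asarray(t1_s, dtype=float)
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-tr_s / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def linearize_vfa(series: FlipAngleSeries) -> VfaRegressionPoints:
    """Map each (angle, signal) pair to the linearized (x, y) coordinates."""
    a = np.deg2rad(series.angles_deg)
    x = series.signal / np.tan(a)
    y = series.signal / np.sin(a)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateAngle("linearization produced non-finite coordinates")
    return VfaRegressionPoints(x=x, y=y)


def estimate_t1(series: FlipAngleSeries) -> T1Estimate:
    """Estimate T1_0 by OLS on the linearized VFA points.

    Raises
    ------
    NonphysicalSlope
        If the fitted slope lies outside (0, 1), where ``-TR/log(m)`` is
        not a positive finite relaxation time.
    """
    pts = linearize_vfa(series)
    x, y = pts.x, pts.y
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0.0:
        raise InsufficientAngles("regression abscissae are all identical")
    m = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - m * xm)
    resid = y - (m * x + intercept)
    syy = float(np.sum((y - ym) ** 2))
    r_squared = 1.0 if syy == 0.0 else float(1.0 - np.sum(resid**2) / syy)
    if m >= 1.0 or m <= 0.0:
        raise NonphysicalSlope(f"slope m={m:.6g} outside (0, 1)")
    t1_0 = -series.tr_s / np.log(m)
    return T1Estimate(t1_0_s=float(t1_0), slope_m=m, intercept=intercept,
                      r_squared=r_squared)


def estimate_t1_voxelwise(
    signals: np.ndarray,
    angles_deg: np.ndarray,
    tr_s: float,
    valid_range_s: tuple[float, float] = T1_VALID_RANGE_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel T1 estimation for parameter maps.

    Parameters
    ----------
    signals:
        Array of shape ``(n_angles, n_voxels)``.
    angles_deg, tr_s:
        As in :class:`FlipAngleSeries`.
    valid_range_s:
        Estimates outside this window (or failed regressions) become NaN.

    Returns
    -------
    t1_s, valid:
        ``t1_s`` of shape ``(n_voxels,)`` with NaN where invalid, and the
        boolean validity mask.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be (n_angles, n_voxels)")
    n_vox = signals.shape[1]
    t1 = np.full(n_vox, np.nan)
    lo, hi = valid_range_s
    for j in range(n_vox):
        col = signals[:, j]
        if np.any(col <= 0) or not np.all(np.isfinite(col)):
            continue
        try:
            est = estimate_t1(FlipAngleSeries(angles_deg, col, tr_s))
        except (NonphysicalSlope, InsufficientAngles):
            continue
        if lo < est.t1_0_s < hi:
            t1[j] = est.t1_0_s
    return t1, np.isfinite(t1)
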