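"""Arterial input function (AIF) extraction from an artery ROI.

The AIF is obtained from a manually segmented femoral-artery ROI on a
representative slice of the dynamic series:

1. average the signal of all artery voxels at each time point;
2. detect the end of the pre-bolus baseline: scanning k = 1, 2, ..., the
   first frame whose signal exceeds the mean of all preceding frames by
   more than 25% marks bolus arrival, and the frame before it is the
   baseline end ("more than" is strict — a rise of exactly 25% does not
   trigger);
3. convert the averaged signal to concentration using the artery's own
   pre-contrast T1 and baseline signal;
4. smooth the resulting concentration curve with a 3-point moving average.

All indices are 0-based.  The moving average is centered by default with a
shrinking window at the edges (a trailing window is available for
sensitivity checks); output length always equals input length.  Detection
runs on the raw averaged signal, before smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concentration import (
    ConcentrationCurve,
    DynamicSeries,
    Relaxivity,
    signal_to_concentration,
)
from .errors import EmptyRoi, NoBolusDetected

__all__ = [
    "ArteryRoiSeries",
    "AIF",
    "average_artery_signal",
    "detect_baseline_end",
    "smooth_moving_average",
    "extract_aif",
]


@dataclass(frozen=True)
class ArteryRoiSeries:
    """Per-voxel signal time courses of the artery ROI."""

    times_s: np.ndarray
    voxel_signals: np.ndarray  # (n_voxels, n_times)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.atleast_2d(np.asarray(self.voxel_signals, dtype=float))
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "voxel_signals", v)
        if v.shape[0] < 1:
            raise EmptyRoi("artery ROI contains no voxels")
        if v.shape[1] != t.size:
            raise ValueError("voxel time courses must align with times_s")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_signals.shape[0])


@dataclass(frozen=True)
class AIF:
    """Arterial concentration time course driving the kinetic model."""

    times_s: np.ndarray
    conc_mmol_per_l: np.ndarray
    baseline_end_idx: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.conc_mmol_per_l, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conc_mmol_per_l", c)
        if c.shape != t.shape:
            raise ValueError("conc_mmol_per_l must align with times_s")
        if self.baseline_end_idx is not None and not (
            0 <= self.baseline_end_idx < t.size - 1
        ):
            raise ValueError("baseline_end_idx must precede the last frame")


def average_artery_signal(roi: ArteryRoiSeries) -> np.ndarray:
    """Pointwise mean signal across all artery voxels."""
    if roi.n_voxels < 1:  # unreachable through the dataclass, kept for rigor
        raise EmptyRoi("artery ROI contains no voxels")
    return roi.voxel_signals.mean(axis=0)


def detect_baseline_end(signal: np.ndarray) -> int:
    """Index of the last pre-bolus frame under the 25% running-mean rule.

    Scanning k = 1, 2, ...: with ``m_k`` the mean of frames ``0 .. k-1``,
    the first k with ``signal[k] > 1.25 * m_k`` is bolus arrival; the
    returned baseline end is ``k - 1``.

    Raises
    ------
    NoBolusDetected
        If no frame ever exceeds the running baseline by more than 25%.
    """
    s = np.asarray(signal, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 time points for bolus detection")
    csum = np.cumsum(s)
    for k in range(1, s.size):
        m_k = csum[k - 1] / k
        if s[k] > 1.25 * m_k:
            return k - 1
    raise NoBolusDetected("no frame exceeds 1.25x the running baseline mean")


def smooth_moving_average(
    curve: np.ndarray, window: int = 3, mode: str = "centered"
) -> np.ndarray:
    """Moving-average filter preserving curve length.

    ``centered`` uses a symmetric window that shrinks to the available
    points at the edges; ``trailing`` averages the current and previous
    ``window - 1`` points.
    """
    c = np.asarray(curve, dtype=float)
    if c.size < 1:
        raise ValueError("empty curve")
    if window < 1 or window % 2 == 0 and mode == "centered":
        raise ValueError("centered smoothing needs an odd window >= 1")
    out = np.empty_like(c)
    half = window // 2
    for i in range(c.size):
        if mode == "centered":
            lo, hi = max(0, i - half), min(c.size, i + half + 1)
        elif mode == "trailing":
            lo, hi = max(0, i - window + 1), i + 1
        else:
            raise ValueError(f"unknown smoothing mode {mode!r}")
        out[i] = c[lo:hi].mean()
    return out


def extract_aif(
    roi: ArteryRoiSeries,
    artery_t1_0_s: float,
    r1: Relaxivity,
    alpha_r_deg: float,
    tr_s: float,
    *,
    smooth: bool = True,
    smooth_mode: str = "centered",
) -> AIF:
    """Full AIF chain: average, detect baseline, convert, smooth."""
    mean_signal = average_artery_signal(roi)
    baseline_end = detect_baseline_end(mean_signal)
    series = DynamicSeries(
        times_s=roi.times_s,
        signal=mean_signal,
        alpha_r_deg=alpha_r_deg,
        tr_s=tr_s,
        baseline_end_idx=baseline_end,
    )
    curve: ConcentrationCurve = signal_to_concentration(
        series, artery_t1_0_s, r1, on_out_of_range="raise"
    )
    conc = curve.conc_mmol_per_l
    if smooth:
        conc = smooth_moving_average(conc, window=3, mode=smooth_mode)
    return AIF(
        times_s=roi.times_s,
        conc_mmol_per_l=conc,
        baseline_end_idx=baseline_end,
        smoothed=smooth,
    )
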