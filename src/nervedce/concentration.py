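"""Signal-to-concentration conversion for spoiled-GRE dynamic series.

Given a dynamic spoiled-GRE series at flip angle ``alpha_R`` and the
pre-contrast relaxation time ``T1_0`` of the same tissue, the conversion
proceeds in three steps for each time point t:

1. the enhancement factor
   ``Ca = (SI_t / SI_0) * (1 - exp(-TR/T1_0)) / (1 - cos(a) exp(-TR/T1_0))``
2. the instantaneous relaxation rate
   ``1/T1_t = -log((1 - Ca) / (1 - cos(a) Ca)) / TR``
3. the tracer concentration
   ``C(t) = (1/r1) * (1/T1_t - 1/T1_0)``

where ``SI_0`` is the pre-bolus baseline signal and ``r1`` the longitudinal
relaxivity of the gadolinium agent (default 3.43 L/mmol/s at 3 T).  The
baseline signal is the mean over all detected pre-bolus frames.  Time points
whose enhancement leaves the invertible spoiled-GRE domain are flagged
invalid (NaN) rather than aborting the curve; downstream fitting excludes
them.

``concentration_to_signal`` is the exact functional inverse and is what the
acquisition simulator uses to turn model concentration curves back into raw
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingBaseline, NonphysicalConcentration, SignalOutOfRange

__all__ = [
    "DynamicSeries",
    "ConcentrationCurve",
    "Relaxivity",
    "baseline_signal",
    "signal_to_concentration",
    "concentration_to_signal",
]


@dataclass(frozen=True)
class Relaxivity:
    """Longitudinal relaxivity r1 of the contrast agent, L/mmol/s."""

    r1_l_per_mmol_s: float = 3.43

    def __post_init__(self) -> None:
        if self.r1_l_per_mmol_s <= 0:
            raise ValueError("relaxivity must be positive")


@dataclass(frozen=True)
class DynamicSeries:
    """Dynamic post-contrast signal time course (ROI mean or single voxel).

    ``baseline_end_idx`` is the 0-based index of the last pre-bolus frame;
    it may be left unset until bolus detection has run.
    """

    times_s: np.ndarray
    signal: np.ndarray
    alpha_r_deg: float
    tr_s: float
    baseline_end_idx: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times_s and signal must be 1-D and aligned")
        if t.size < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("signals must be finite and positive")
        if not 0 < self.alpha_r_deg < 90:
            raise ValueError("alpha_r_deg must lie in (0, 90)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.baseline_end_idx is not None and not (
            0 <= self.baseline_end_idx < t.size
        ):
            raise ValueError("baseline_end_idx out of range")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tracer concentration over time, with per-point validity flags.

    ``conc_mmol_per_l`` and ``t1_t_s`` are NaN where ``valid`` is False
    (enhancement outside the invertible domain).
    """

    times_s: np.ndarray
    conc_mmol_per_l: np.ndarray
    t1_t_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.conc_mmol_per_l, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conc_mmol_per_l", c)
        if c.shape != t.shape:
            raise ValueError("conc_mmol_per_l must align with times_s")
        t1t = self.t1_t_s
        t1t = np.full_like(c, np.nan) if t1t is None else np.asarray(t1t, float)
        object.__setattr__(self, "t1_t_s", t1t)
        v = self.valid
        v = np.isfinite(c) if v is None else np.asarray(v, bool)
        object.__setattr__(self, "valid", v)
        if t1t.shape != t.shape or v.shape != t.shape:
            raise ValueError("t1_t_s and valid must align with times_s")


def baseline_signal(series: DynamicSeries) -> float:
    """Mean signal over the pre-bolus frames ``[0 .. baseline_end_idx]``."""
    if series.baseline_end_idx is None:
        raise MissingBaseline("baseline_end_idx is unset; run bolus detection")
    return float(series.signal[: series.baseline_end_idx + 1].mean())


def _enhancement_factor(
    si_ratio: np.ndarray, t1_0_s: float, alpha_r_deg: float, tr_s: float
) -> np.ndarray:
    e10 = np.exp(-tr_s / t1_0_s)
    cos_a = np.cos(np.deg2rad(alpha_r_deg))
    return si_ratio * (1.0 - e10) / (1.0 - cos_a * e10)


def signal_to_concentration(
    series: DynamicSeries,
    t1_0_s: float,
    r1: Relaxivity = Relaxivity(),
    *,
    si0: float | None = None,
    on_out_of_range: str = "flag",
) -> ConcentrationCurve:
    """Convert a dynamic signal series to tracer concentration.

    Parameters
    ----------
    series:
        Dynamic series with ``baseline_end_idx`` set (unless ``si0`` given).
    t1_0_s:
        Pre-contrast T1 of the same tissue/vessel, seconds.
    r1:
        Contrast-agent relaxivity.
    si0:
        Baseline signal override; default is the pre-bolus mean.
    on_out_of_range:
        ``"flag"`` (default) marks out-of-domain points NaN/invalid;
        ``"raise"`` raises :class:`SignalOutOfRange` at the first offender.
    """
    if t1_0_s <= 0:
        raise ValueError("t1_0_s must be positive")
    if si0 is None:
        si0 = baseline_signal(series)
    cos_a = np.cos(np.deg2rad(series.alpha_r_deg))
    ca = _enhancement_factor(series.signal / si0, t1_0_s, series.alpha_r_deg,
                             series.tr_s)
    num = 1.0 - ca
    den = 1.0 - cos_a * ca
    invertible = (num > 0.0) & (den > 0.0)
    if not np.all(invertible) and on_out_of_range == "raise":
        bad = int(np.argmax(~invertible))
        raise SignalOutOfRange(
            f"enhancement at frame {bad} outside the invertible domain"
        )
    # -log(num/den)/TR, evaluated as (-log num + log den)/TR on the valid set
    r1t = np.where(
        invertible,
        (-np.log(np.where(invertible, num, 1.0))
         + np.log(np.where(invertible, den, 1.0))) / series.tr_s,
        np.nan,
    )
    t1_t = 1.0 / r1t
    conc = (r1t - 1.0 / t1_0_s) / r1.r1_l_per_mmol_s
    return ConcentrationCurve(
        times_s=series.times_s,
        conc_mmol_per_l=conc,
        t1_t_s=t1_t,
        valid=invertible,
    )


def concentration_to_signal(
    curve: ConcentrationCurve,
    t1_0_s: float,
    r1: Relaxivity,
    alpha_r_deg: float,
    tr_s: float,
    si0: float,
) -> DynamicSeries:
    """Exact inverse of :func:`signal_to_concentration`.

    Maps concentration to the post-contrast relaxation rate
    ``1/T1_t = 1/T1_0 + r1 C``, then to the spoiled-GRE signal ratio.
    """
    if t1_0_s <= 0 or si0 <= 0:
        raise ValueError("t1_0_s and si0 must be positive")
    c = np.asarray(curve.conc_mmol_per_l, dtype=float)
    r1t = 1.0 / t1_0_s + r1.r1_l_per_mmol_s * c
    if np.any(r1t <= 0):
        raise NonphysicalConcentration(
            "concentration drives post-contrast T1 non-positive"
        )
    cos_a = np.cos(np.deg2rad(alpha_r_deg))
    e1t = np.exp(-tr_s * r1t)
    e10 = np.exp(-tr_s / t1_0_s)
    ca = (1.0 - e1t) / (1.0 - cos_a * e1t)
    si = si0 * ca * (1.0 - cos_a * e10) / (1.0 - e10)
    return DynamicSeries(
        times_s=curve.times_s,
        signal=si,
        alpha_r_deg=alpha_r_deg,
        tr_s=tr_s,
    )
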