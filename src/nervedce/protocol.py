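"""Acquisition protocol constants shared by every physics stage.

The default values describe a 3 T spoiled gradient-echo (VIBE) dynamic
contrast-enhanced protocol for peripheral-nerve imaging: a pre-contrast
variable-flip-angle block (5-17 degrees) for T1 mapping, followed by a
dynamic series of 50 repetitions at 15 degrees with the contrast bolus
administered after completion of the sixth repetition.  Dynamic frames are
assumed uniformly spaced; with a total acquisition time of 4:09 min over 50
repetitions the frame interval is 249 s / 50 = 4.98 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionProtocol", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Constants of the spoiled-GRE DCE acquisition.

    Attributes
    ----------
    tr_s:
        Repetition time of the spoiled gradient-echo readout, in seconds.
    vfa_angles_deg:
        Prescribed flip angles of the pre-contrast variable-flip-angle block.
    alpha_r_deg:
        Flip angle of the dynamic (post-contrast) series, degrees.
    n_dynamics:
        Number of dynamic repetitions (frames).
    dt_s:
        Frame spacing of the dynamic series, seconds.
    bolus_frame:
        Index (0-based) of the first frame that may contain contrast; the
        bolus is injected after completion of frame ``bolus_frame - 1``.
    r1_l_per_mmol_s:
        Longitudinal relaxivity of the contrast agent at 3 T, L/mmol/s.
    """

    tr_s: float = 3.3e-3
    vfa_angles_deg: tuple[float, ...] = (5.0, 8.0, 11.0, 14.0, 17.0)
    alpha_r_deg: float = 15.0
    n_dynamics: int = 50
    dt_s: float = 249.0 / 50.0
    bolus_frame: int = 6
    r1_l_per_mmol_s: float = 3.43

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.n_dynamics < 2:
            raise ValueError("n_dynamics must be at least 2")
        if not 0 < self.alpha_r_deg < 90:
            raise ValueError("alpha_r_deg must lie in (0, 90)")
        if self.r1_l_per_mmol_s <= 0:
            raise ValueError("relaxivity must be positive")
        if not 0 <= self.bolus_frame < self.n_dynamics:
            raise ValueError("bolus_frame must index a dynamic frame")

    def dynamic_times_s(self) -> np.ndarray:
        """Time stamps of the dynamic frames (frame 0 at t = 0)."""
        return np.arange(self.n_dynamics, dtype=float) * self.dt_s


DEFAULT_PROTOCOL = AcquisitionProtocol()
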