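"""Readers and writers for the pipeline's interchange formats.

Volumes and masks travel as NIfTI (via nibabel); curves, cohorts and
results tables as CSV; configuration, fit results and run manifests as
JSON.  Units are carried in column-name suffixes (``time_s``,
``conc_mmol_per_l``, ``ktrans_per_min``...) so files are unambiguous on
their own.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import AIF, ArteryRoiSeries
from .concentration import ConcentrationCurve, DynamicSeries
from .errors import EmptyRoi, ShapeError
from .etm import ETMFitResult

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_aif_csv",
    "read_aif_csv",
    "write_fit_json",
    "read_fit_json",
    "write_nifti",
    "read_nifti",
    "read_dynamic_volume",
    "write_cohort_csv",
    "read_cohort_csv",
]


# --- curves ----------------------------------------------------------------

def write_curve_csv(path: str | Path, curve: ConcentrationCurve) -> None:
    pd.DataFrame(
        {
            "time_s": curve.times_s,
            "conc_mmol_per_l": curve.conc_mmol_per_l,
            "valid_flag": curve.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> ConcentrationCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "conc_mmol_per_l"):
        if col not in df.columns:
            raise ShapeError(f"curve file {path} lacks column {col!r}")
    valid = (
        df["valid_flag"].to_numpy().astype(bool)
        if "valid_flag" in df.columns
        else None
    )
    return ConcentrationCurve(
        times_s=df["time_s"].to_numpy(),
        conc_mmol_per_l=df["conc_mmol_per_l"].to_numpy(),
        valid=valid,
    )


def write_aif_csv(path: str | Path, aif: AIF) -> None:
    """AIF as CSV plus a JSON sidecar with extraction provenance."""
    pd.DataFrame(
        {"time_s": aif.times_s, "conc_mmol_per_l": aif.conc_mmol_per_l}
    ).to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "baseline_end_idx": aif.baseline_end_idx,
                "smoothed": aif.smoothed,
            },
            indent=2,
        )
    )


def read_aif_csv(path: str | Path) -> AIF:
    df = pd.read_csv(path)
    for col in ("time_s", "conc_mmol_per_l"):
        if col not in df.columns:
            raise ShapeError(f"AIF file {path} lacks column {col!r}")
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return AIF(
        times_s=df["time_s"].to_numpy(),
        conc_mmol_per_l=df["conc_mmol_per_l"].to_numpy(),
        baseline_end_idx=meta.get("baseline_end_idx"),
        smoothed=bool(meta.get("smoothed", False)),
    )


# --- fit results -----------------------------------------------------------

def write_fit_json(path: str | Path, fit: ETMFitResult) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "params": fit.params.as_dict(),
                "rss": fit.rss,
                "n_iter": fit.n_iter,
                "converged": fit.converged,
                "n_points_used": fit.n_points_used,
            },
            indent=2,
        )
    )


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --- volumes ---------------------------------------------------------------

def write_nifti(path: str | Path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)),
             str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # malformed file → uniform error family
        raise ShapeError(f"cannot read NIfTI volume {path}: {exc}") from exc


def read_dynamic_volume(
    path: str | Path,
    mask_path: str | Path,
    dt_s: float,
    alpha_r_deg: float,
    tr_s: float,
    *,
    per_voxel: bool = False,
) -> DynamicSeries | ArteryRoiSeries:
    """Load a 4-D dynamic volume restricted to a mask.

    Returns the ROI-mean :class:`DynamicSeries` by default, or the
    per-voxel :class:`ArteryRoiSeries` with ``per_voxel=True``.  Frame
    time stamps are ``0, dt_s, 2 dt_s, ...`` (0-based frames).
    """
    vol = read_nifti(path)
    mask = read_nifti(mask_path) != 0
    if vol.ndim != 4:
        raise ShapeError(f"expected a 4-D volume, got shape {vol.shape}")
    if mask.shape != vol.shape[:3]:
        raise ShapeError(
            f"mask shape {mask.shape} does not match volume {vol.shape[:3]}"
        )
    if not mask.any():
        raise EmptyRoi("mask selects no voxels")
    courses = vol[mask, :]  # (n_voxels, n_t)
    times = np.arange(vol.shape[3], dtype=float) * dt_s
    if per_voxel:
        return ArteryRoiSeries(times_s=times, voxel_signals=courses)
    return DynamicSeries(
        times_s=times,
        signal=courses.mean(axis=0),
        alpha_r_deg=alpha_r_deg,
        tr_s=tr_s,
    )


# --- cohorts ---------------------------------------------------------------

def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
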