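"""Synthetic cohorts and simulated acquisitions.

Because the clinical dataset behind this pipeline is not public, every
stage is exercised on synthetic data with the same structure:

* ``simulate_covariates`` draws a cohort (default 44 type-2-diabetes
  subjects + 12 controls) from a Gaussian copula whose correlation matrix
  plants the study's reported associations (e.g. hsTNT vs Ktrans r = -0.38
  within the T2D group) and whose marginals are rescaled to the reported
  group means/SDs (truncated at zero).  True extended-Tofts parameters per
  subject come from the same latent field, so biomarker-perfusion
  correlations are planted by construction.
* ``simulate_population_aif`` provides a generative arterial input
  function (gamma-variate first pass plus a slowly decaying tail), zero
  before bolus arrival.
* ``simulate_acquisition`` forward-simulates the full measurement chain
  per subject: spoiled-GRE variable-flip-angle block for nerve and artery,
  then the dynamic series in which the artery embeds the population AIF
  and the nerve embeds the extended-Tofts response to it, both mapped to
  raw signal through the exact concentration-to-signal inverse, with
  Gaussian noise added in the signal domain.

Determinism: all randomness flows from a single integer seed through
``numpy.random.default_rng``; the same seed reproduces the cohort and the
acquisitions bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aif import AIF
from .concentration import ConcentrationCurve, Relaxivity, concentration_to_signal
from .etm import ETMParams, etm_forward
from .errors import InvalidBolusTime, InvalidCorrelationTarget, InvalidNoise
from .protocol import DEFAULT_PROTOCOL, AcquisitionProtocol
from .vfa import spgr_signal

__all__ = [
    "AifShape",
    "SimulationConfig",
    "SyntheticTruth",
    "SubjectAcquisition",
    "simulate_covariates",
    "simulate_population_aif",
    "simulate_acquisition",
    "COVARIATE_MARGINALS",
    "PLANTED_CORRELATIONS",
]


# Group marginals (mean, SD) per covariate: (T2D, control).  Values mirror
# the cohort the generator emulates; units in the column names.
COVARIATE_MARGINALS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "hstnt_pg_ml": ((9.93, 4.04), (7.25, 2.18)),
    "probnp_pg_ml": ((115.30, 121.60), (75.92, 52.20)),
    "age_years": ((66.14, 7.12), (61.58, 7.79)),
    "bmi_kg_m2": ((28.68, 4.11), (27.47, 3.64)),
    "hba1c_pct": ((6.88, 1.23), (5.58, 0.55)),
    "gfr_ml_min": ((87.55, 15.05), (87.50, 13.88)),
    "nds": ((3.56, 3.08), (1.33, 1.44)),
    "nss": ((4.14, 3.43), (2.33, 3.60)),
    "sural_ncv_m_s": ((45.13, 7.06), (45.83, 4.82)),
    "sural_snap_uv": ((5.54, 3.20), (7.89, 4.71)),
    "peroneal_ncv_m_s": ((39.59, 5.40), (45.08, 4.60)),
    "peroneal_cmap_mv": ((5.02, 4.01), (8.88, 6.96)),
    "peroneal_dml_ms": ((7.37, 13.13), (3.94, 0.69)),
    "tibial_ncv_m_s": ((40.81, 5.02), (44.75, 4.00)),
    "tibial_cmap_mv": ((9.68, 6.41), (16.58, 8.24)),
    "tibial_dml_ms": ((5.00, 3.01), (3.62, 0.53)),
    # true perfusion parameters, in reporting units (min^-1 and percent)
    "true_ktrans_per_min": ((0.040, 0.011), (0.035, 0.011)),
    "true_ve_pct": ((3.28, 2.0), (1.64, 1.0)),
    "true_vp_pct": ((4.74, 0.82), (4.63, 0.56)),
}

# Planted pairwise correlations of the latent Gaussian field (shared by
# both groups).  Pairs not listed are independent at the latent level.
PLANTED_CORRELATIONS: dict[tuple[str, str], float] = {
    ("hstnt_pg_ml", "true_ktrans_per_min"): -0.38,
    ("hstnt_pg_ml", "true_ve_pct"): -0.30,
    ("hstnt_pg_ml", "true_vp_pct"): -0.16,
    ("hstnt_pg_ml", "age_years"): 0.35,
    ("hstnt_pg_ml", "nds"): 0.45,
    ("hstnt_pg_ml", "peroneal_ncv_m_s"): -0.53,
    ("hstnt_pg_ml", "tibial_ncv_m_s"): -0.51,
    ("hstnt_pg_ml", "tibial_cmap_mv"): -0.55,
    ("hstnt_pg_ml", "sural_ncv_m_s"): -0.33,
    ("true_ktrans_per_min", "true_ve_pct"): 0.75,
    ("true_ktrans_per_min", "bmi_kg_m2"): 0.55,
    ("true_ktrans_per_min", "peroneal_ncv_m_s"): 0.49,
    ("true_ktrans_per_min", "tibial_ncv_m_s"): 0.42,
    ("true_ktrans_per_min", "sural_ncv_m_s"): 0.45,
    ("true_ve_pct", "bmi_kg_m2"): 0.47,
    ("true_ve_pct", "peroneal_ncv_m_s"): 0.39,
    ("true_ve_pct", "tibial_ncv_m_s"): 0.40,
    ("true_ve_pct", "true_vp_pct"): 0.36,
    ("true_vp_pct", "age_years"): -0.34,
    ("nds", "nss"): 0.55,
    ("nds", "tibial_ncv_m_s"): -0.45,
    ("nds", "peroneal_ncv_m_s"): -0.45,
    ("tibial_ncv_m_s", "peroneal_ncv_m_s"): 0.60,
    ("tibial_ncv_m_s", "sural_ncv_m_s"): 0.45,
    ("peroneal_ncv_m_s", "sural_ncv_m_s"): 0.45,
    ("tibial_cmap_mv", "tibial_ncv_m_s"): 0.45,
    ("peroneal_cmap_mv", "peroneal_ncv_m_s"): 0.45,
    ("sural_snap_uv", "sural_ncv_m_s"): 0.40,
    ("tibial_dml_ms", "tibial_ncv_m_s"): -0.40,
    ("peroneal_dml_ms", "peroneal_ncv_m_s"): -0.40,
}


@dataclass(frozen=True)
class AifShape:
    """Parameters of the generative population AIF.

    First pass: gamma-variate ``(tau/tp)^a exp(a (1 - tau/tp))`` peaking at
    ``time_to_peak_s`` after bolus arrival.  Tail: a washout term rising
    with time constant ``tail_rise_s`` and decaying at ``tail_decay_per_s``,
    emulating distributed recirculation.  The femoral-artery first pass is
    deliberately dispersed (time to peak ~30 s, FWHM ~1 min), consistent
    with an antecubital injection observed far downstream in the leg; a
    dispersed first pass also keeps the 3-point moving-average filter of
    the AIF stage nearly transparent at the 4.98 s frame spacing.
    """

    amplitude_mmol_l: float = 5.0
    bolus_time_s: float = 26.0
    time_to_peak_s: float = 30.0
    sharpness: float = 2.0
    tail_fraction: float = 0.3
    tail_rise_s: float = 12.0
    tail_decay_per_s: float = 1.0 / 350.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort and acquisition."""

    n_t2d: int = 44
    n_control: int = 12
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL
    aif_shape: AifShape = AifShape()
    marginals: dict = field(default_factory=lambda: dict(COVARIATE_MARGINALS))
    correlations: dict = field(
        default_factory=lambda: dict(PLANTED_CORRELATIONS)
    )
    #: per-voxel signal SNR (baseline signal / noise SD); 0 disables noise
    snr: float = 40.0
    nerve_t1_s: float = 1.2
    artery_t1_s: float = 1.4
    m0: float = 1000.0
    n_nerve_voxels: int = 25
    n_artery_voxels: int = 9

    def __post_init__(self) -> None:
        if self.n_t2d < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.snr < 0:
            raise InvalidNoise("snr must be >= 0 (0 disables noise)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    covariates: pd.DataFrame  # one row per subject, incl. group + true params
    correlation_matrix: pd.DataFrame  # latent matrix actually used (post-repair)
    correlation_repaired: bool
    seed: int

    def true_params(self, subject: int) -> ETMParams:
        row = self.covariates.iloc[subject]
        return ETMParams(
            ktrans_per_s=float(row["true_ktrans_per_min"]) / 60.0,
            ve_frac=float(row["true_ve_pct"]) / 100.0,
            vp_frac=float(row["true_vp_pct"]) / 100.0,
        )


@dataclass(frozen=True)
class SubjectAcquisition:
    """Raw simulated data for one subject, ready for the analysis chain."""

    subject: int
    vfa_angles_deg: np.ndarray
    vfa_nerve_signal: np.ndarray  # ROI-mean signal per angle
    vfa_artery_signal: np.ndarray
    times_s: np.ndarray
    nerve_signal: np.ndarray  # ROI-mean dynamic course
    artery_voxel_signals: np.ndarray  # (n_artery_voxels, n_t)


def _build_latent_matrix(
    names: list[str], planted: dict[tuple[str, str], float]
) -> tuple[np.ndarray, bool]:
    """Assemble the latent correlation matrix; repair to the nearest
    positive semi-definite matrix (eigenvalue clipping + diagonal
    renormalization) when the planted entries are jointly inconsistent."""
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for (a, b), r in planted.items():
        if a not in idx or b not in idx:
            continue
        if not -1.0 < r < 1.0:
            raise InvalidCorrelationTarget(f"|r|must be < 1 for ({a}, {b})")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    eigval, eigvec = np.linalg.eigh(corr)
    repaired = bool(eigval.min() < -1e-10)
    if repaired:
        eigval = np.clip(eigval, 1e-6, None)
        corr = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        eigval2 = np.linalg.eigvalsh(corr)
        if eigval2.min() < -1e-8:
            raise InvalidCorrelationTarget("correlation matrix not repairable")
    return corr, repaired


#: Lower truncation floors applied after marginal rescaling.  Perfusion
#: fractions must stay strictly positive for the forward model; the ve
#: floor additionally keeps the exchange rate Ktrans/ve well below the
#: frame rate, since tissues with a vanishing interstitium are not
#: resolvable by tracer kinetics at ~5 s sampling.
_FLOORS = {
    "true_ktrans_per_min": 1e-3,
    "true_ve_pct": 0.8,
    "true_vp_pct": 0.2,
}


def simulate_covariates(
    config: SimulationConfig = SimulationConfig(), seed: int = 0
) -> SyntheticTruth:
    """Draw a synthetic cohort with planted correlations.

    A single latent standard-normal field with the planted correlation
    matrix is drawn per subject (Gaussian copula); each margin is then
    rescaled to its group mean/SD and truncated at zero (clinical scores
    are additionally rounded to integers).
    """
    rng = np.random.default_rng(seed)
    names = list(config.marginals.keys())
    corr, repaired = _build_latent_matrix(names, config.correlations)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))

    frames = []
    for group, n in (("T2D", config.n_t2d), ("control", config.n_control)):
        z = rng.standard_normal((n, len(names))) @ chol.T
        cols = {}
        gi = 0 if group == "T2D" else 1
        for j, name in enumerate(names):
            mean, sd = config.marginals[name][gi]
            v = mean + sd * z[:, j]
            v = np.maximum(v, _FLOORS.get(name, 0.0))
            if name in ("nds", "nss"):
                v = np.round(v)
            cols[name] = v
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        frames.append(df)
    covariates = pd.concat(frames, ignore_index=True)
    covariates.insert(0, "subject", np.arange(len(covariates)))
    return SyntheticTruth(
        covariates=covariates,
        correlation_matrix=pd.DataFrame(corr, index=names, columns=names),
        correlation_repaired=repaired,
        seed=seed,
    )


def simulate_population_aif(
    times_s: np.ndarray, shape: AifShape = AifShape()
) -> AIF:
    """Generative arterial concentration curve on the given time grid.

    Zero before bolus arrival; gamma-variate first pass plus a
    rising-then-decaying recirculation tail after it.  Linear in
    ``amplitude_mmol_l``.
    """
    t = np.asarray(times_s, dtype=float)
    if not np.isfinite(shape.bolus_time_s) or shape.bolus_time_s < 0:
        raise InvalidBolusTime("bolus_time_s must be finite and >= 0")
    tau = t - shape.bolus_time_s
    conc = np.zeros_like(t)
    pos = tau > 0
    tp, a = shape.time_to_peak_s, shape.sharpness
    tp_ = tau[pos] / tp
    first_pass = tp_**a * np.exp(a * (1.0 - tp_))
    tail = (
        shape.tail_fraction
        * (1.0 - np.exp(-tau[pos] / shape.tail_rise_s))
        * np.exp(-shape.tail_decay_per_s * tau[pos])
    )
    conc[pos] = shape.amplitude_mmol_l * (first_pass + tail)
    return AIF(times_s=t, conc_mmol_per_l=conc, smoothed=False)


def simulate_acquisition(
    truth: SyntheticTruth,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> list[SubjectAcquisition]:
    """Forward-simulate the raw measurement chain for every subject.

    For each subject: (i) spoiled-GRE VFA signals for nerve and artery at
    the protocol angles; (ii) the dynamic series at the dynamic flip angle,
    in which the artery carries the population AIF and the nerve carries
    the extended-Tofts response to that AIF, both converted to raw signal
    with the exact inverse of the concentration equation; (iii) Gaussian
    noise of SD = baseline / snr added per voxel, then averaged over the
    ROI (the nerve course is returned ROI-mean; artery voxels are returned
    individually for the AIF stage).
    """
    rng = np.random.default_rng(seed)
    proto = config.protocol
    times = proto.dynamic_times_s()
    aif = simulate_population_aif(times, config.aif_shape)
    r1 = Relaxivity(proto.r1_l_per_mmol_s)
    angles = np.asarray(proto.vfa_angles_deg, dtype=float)

    si0_nerve = float(
        spgr_signal(config.nerve_t1_s, proto.tr_s, proto.alpha_r_deg, config.m0)
    )
    si0_artery = float(
        spgr_signal(config.artery_t1_s, proto.tr_s, proto.alpha_r_deg, config.m0)
    )
    vfa_nerve_clean = spgr_signal(
        config.nerve_t1_s, proto.tr_s, angles, config.m0
    )
    vfa_artery_clean = spgr_signal(
        config.artery_t1_s, proto.tr_s, angles, config.m0
    )
    artery_clean = concentration_to_signal(
        ConcentrationCurve(times_s=times, conc_mmol_per_l=aif.conc_mmol_per_l),
        config.artery_t1_s, r1, proto.alpha_r_deg, proto.tr_s, si0_artery,
    ).signal

    out = []
    for s in range(len(truth.covariates)):
        params = truth.true_params(s)
        nerve_conc = etm_forward(params, aif)
        nerve_clean = concentration_to_signal(
            nerve_conc, config.nerve_t1_s, r1, proto.alpha_r_deg,
            proto.tr_s, si0_nerve,
        ).signal

        def roi_mean(clean: np.ndarray, si0: float, n_vox: int) -> np.ndarray:
            if config.snr == 0:
                return clean.copy()
            sd = si0 / config.snr
            noise = rng.normal(0.0, sd, size=(n_vox,) + clean.shape)
            return np.maximum(clean + noise.mean(axis=0), 1e-6)

        artery_vox = artery_clean[None, :].repeat(config.n_artery_voxels, 0)
        if config.snr > 0:
            artery_vox = np.maximum(
                artery_vox + rng.normal(
                    0.0, si0_artery / config.snr, size=artery_vox.shape
                ),
                1e-6,
            )
        out.append(
            SubjectAcquisition(
                subject=s,
                vfa_angles_deg=angles,
                vfa_nerve_signal=roi_mean(
                    vfa_nerve_clean, si0_nerve, config.n_nerve_voxels
                ),
                vfa_artery_signal=roi_mean(
                    vfa_artery_clean, si0_artery, config.n_artery_voxels
                ),
                times_s=times,
                nerve_signal=roi_mean(
                    nerve_clean, si0_nerve, config.n_nerve_voxels
                ),
                artery_voxel_signals=artery_vox,
            )
        )
    return out
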