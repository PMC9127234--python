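"""Extended Tofts model: forward accuracy, fitting, parameter recovery."""

import numpy as np
import pytest

from nervedce.aif import AIF
from nervedce.concentration import ConcentrationCurve
from nervedce.errors import DegenerateVe, EmptyRoi, NoValidData
from nervedce.etm import (
    DEFAULT_START,
    ETMParams,
    etm_forward,
    fit_etm,
    fit_roi_map,
)


def fine_grid_forward(params, aif, refine=100):
    """Independent oracle: dense trapezoid quadrature of the convolution
    with a linearly interpolated AIF (refinement factor per frame)."""
    t = aif.times_s
    kep = params.ktrans_per_s / params.ve_frac
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        if i == 0:
            continue
        td = np.linspace(0.0, ti, i * refine + 1)
        a = np.interp(td, t, aif.conc_mmol_per_l)
        out[i] = params.ktrans_per_s * np.trapezoid(
            a * np.exp(-kep * (ti - td)), td
        )
    return out + params.vp_frac * aif.conc_mmol_per_l


class TestForward:
    def test_ktrans_zero_is_pure_plasma_term(self, population_aif):
        p = ETMParams(0.0, 0.15, 0.06)
        cm = etm_forward(p, population_aif).conc_mmol_per_l
        np.testing.assert_allclose(
            cm, 0.06 * population_aif.conc_mmol_per_l, rtol=1e-14
        )

    def test_zero_aif_gives_zero_curve(self, dynamic_times):
        aif = AIF(dynamic_times, np.zeros_like(dynamic_times))
        cm = etm_forward(DEFAULT_START, aif).conc_mmol_per_l
        np.testing.assert_array_equal(cm, 0.0)

    def test_boxcar_matches_closed_form(self):
        # constant AIF of amplitude A: C_M = A ve (1 - exp(-Ktrans t/ve)) + vp A
        A, p = 2.0, DEFAULT_START
        t = np.arange(0.0, 121.0, 1.0)
        box = AIF(t, np.full_like(t, A))
        cm = etm_forward(p, box).conc_mmol_per_l
        closed = (
            A * p.ve_frac * (1.0 - np.exp(-p.ktrans_per_s * t / p.ve_frac))
            + p.vp_frac * A
        )
        np.testing.assert_allclose(cm, closed, rtol=5e-3)

    @pytest.mark.parametrize(
        "ktrans, ve",
        [(0.0005, 0.5), (0.007, 0.15), (0.01, 0.05), (0.0008, 0.008)],
    )
    def test_agrees_with_fine_grid_oracle(self, population_aif, ktrans, ve):
        p = ETMParams(ktrans, ve, 0.04)
        cm = etm_forward(p, population_aif).conc_mmol_per_l
        oracle = fine_grid_forward(p, population_aif)
        assert np.abs(cm - oracle).max() < 0.005 * np.abs(oracle).max()

    def test_monotone_in_vp(self, population_aif):
        prev = None
        for vp in (0.0, 0.02, 0.05, 0.1):
            cm = etm_forward(
                ETMParams(0.002, 0.2, vp), population_aif
            ).conc_mmol_per_l
            if prev is not None:
                assert np.all(cm >= prev - 1e-15)
            prev = cm

    def test_degenerate_ve(self, population_aif):
        with pytest.raises(DegenerateVe):
            etm_forward(ETMParams(0.002, 0.0, 0.04), population_aif)


class TestFit:
    def test_optimum_at_initialization(self, population_aif):
        tissue = etm_forward(DEFAULT_START, population_aif)
        fit = fit_etm(tissue, population_aif, start=DEFAULT_START)
        assert fit.rss < 1e-16
        assert fit.params.ktrans_per_s == pytest.approx(0.007, rel=1e-4)
        assert fit.params.ve_frac == pytest.approx(0.15, rel=1e-4)
        assert fit.params.vp_frac == pytest.approx(0.025, rel=1e-4)

    def test_recovery_from_default_start(self, population_aif):
        true = ETMParams(0.002, 0.30, 0.04)
        tissue = etm_forward(true, population_aif)
        fit = fit_etm(tissue, population_aif)  # protocol-default start
        assert fit.params.ktrans_per_s == pytest.approx(0.002, rel=0.01)
        assert fit.params.ve_frac == pytest.approx(0.30, rel=0.01)
        assert fit.params.vp_frac == pytest.approx(0.04, rel=0.01)
        assert fit.converged

    def test_recovery_initialized_at_twice_truth(self, population_aif):
        true = DEFAULT_START
        tissue = etm_forward(true, population_aif)
        start = ETMParams(0.014, 0.30, 0.05)
        fit = fit_etm(tissue, population_aif, start=start)
        assert fit.params.ktrans_per_s == pytest.approx(0.007, rel=0.01)
        assert fit.params.ve_frac == pytest.approx(0.15, rel=0.01)
        assert fit.params.vp_frac == pytest.approx(0.025, rel=0.01)

    def test_raw_parameter_space_mode(self, population_aif):
        true = ETMParams(0.003, 0.25, 0.03)
        tissue = etm_forward(true, population_aif)
        fit = fit_etm(tissue, population_aif, transform=False)
        assert fit.params.ktrans_per_s == pytest.approx(0.003, rel=0.01)

    def test_rss_self_consistent(self, population_aif, rng):
        true = ETMParams(0.004, 0.2, 0.05)
        cm = etm_forward(true, population_aif).conc_mmol_per_l
        noisy = cm + rng.normal(0, 0.01, cm.size)
        tissue = ConcentrationCurve(population_aif.times_s, noisy)
        fit = fit_etm(tissue, population_aif)
        model = etm_forward(fit.params, population_aif).conc_mmol_per_l
        rss = float(np.sum((model - noisy) ** 2))
        assert fit.rss == pytest.approx(rss, abs=1e-12)
        assert fit.n_points_used == noisy.size

    def test_parameter_recovery_sweep(self, population_aif, rng):
        """Noiseless fits recover within 2%; at 2% noise the median
        absolute relative error stays below 10%."""
        noiseless_err, noisy_err = [], []
        peak_scale = None
        for _ in range(100):
            true = ETMParams(
                rng.uniform(5e-4, 0.01),
                rng.uniform(0.05, 0.5),
                rng.uniform(0.01, 0.1),
            )
            cm = etm_forward(true, population_aif).conc_mmol_per_l
            fit = fit_etm(
                ConcentrationCurve(population_aif.times_s, cm), population_aif
            )
            vals = np.array([
                fit.params.ktrans_per_s, fit.params.ve_frac, fit.params.vp_frac
            ])
            tv = np.array([true.ktrans_per_s, true.ve_frac, true.vp_frac])
            noiseless_err.append(np.abs(vals - tv) / tv)

            noisy = cm + rng.normal(0.0, 0.02 * np.abs(cm).max(), cm.size)
            fitn = fit_etm(
                ConcentrationCurve(population_aif.times_s, noisy),
                population_aif,
            )
            valsn = np.array([
                fitn.params.ktrans_per_s, fitn.params.ve_frac,
                fitn.params.vp_frac,
            ])
            noisy_err.append(np.abs(valsn - tv) / tv)
        assert np.max(noiseless_err) < 0.02
        assert np.median(noisy_err) < 0.10

    def test_invalid_points_excluded_and_too_few_raises(self, population_aif):
        cm = etm_forward(DEFAULT_START, population_aif).conc_mmol_per_l
        conc = cm.copy()
        conc[7] = np.nan  # one flagged frame must not kill the fit
        fit = fit_etm(
            ConcentrationCurve(population_aif.times_s, conc), population_aif
        )
        assert fit.n_points_used == cm.size - 1
        assert fit.params.ktrans_per_s == pytest.approx(0.007, rel=0.01)

        sparse = np.full_like(cm, np.nan)
        sparse[:5] = cm[:5]
        with pytest.raises(NoValidData):
            fit_etm(
                ConcentrationCurve(population_aif.times_s, sparse),
                population_aif,
            )


class TestRoiMap:
    def _phantom(self, params_by_voxel, aif):
        n = len(params_by_voxel)
        conc = np.zeros((n, 1, 1, aif.times_s.size))
        for i, p in enumerate(params_by_voxel):
            conc[i, 0, 0, :] = etm_forward(p, aif).conc_mmol_per_l
        return conc

    def test_homogeneous_phantom_constant_map(self, population_aif):
        p = ETMParams(0.003, 0.2, 0.04)
        conc = self._phantom([p, p, p, p], population_aif)
        mask = np.ones((4, 1, 1), dtype=bool)
        maps = fit_roi_map(conc, mask, population_aif, population_aif.times_s)
        k = maps["ktrans_per_s"][mask]
        np.testing.assert_allclose(k, 0.003, rtol=0.01)
        assert maps["summary"]["ktrans_per_s"] == pytest.approx(0.003, rel=0.01)

    def test_two_compartment_phantom(self, population_aif):
        pa = ETMParams(0.002, 0.15, 0.03)
        pb = ETMParams(0.006, 0.35, 0.06)
        conc = self._phantom([pa, pa, pb, pb], population_aif)
        mask_a = np.zeros((4, 1, 1), bool); mask_a[:2] = True
        mask_b = np.zeros((4, 1, 1), bool); mask_b[2:] = True
        all_mask = mask_a | mask_b
        maps = fit_roi_map(conc, all_mask, population_aif,
                           population_aif.times_s)
        assert np.nanmean(maps["ktrans_per_s"][mask_a]) == pytest.approx(
            0.002, rel=0.02
        )
        assert np.nanmean(maps["ktrans_per_s"][mask_b]) == pytest.approx(
            0.006, rel=0.02
        )

    def test_empty_mask(self, population_aif):
        conc = np.zeros((2, 1, 1, population_aif.times_s.size))
        with pytest.raises(EmptyRoi):
            fit_roi_map(conc, np.zeros((2, 1, 1)), population_aif,
                        population_aif.times_s)
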