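"""Cohort statistics: classification rules, gated tests, correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nervedce.errors import (
    CollinearControls,
    InsufficientData,
    InvalidScore,
    MissingMeasurement,
    SchemaError,
    UndefinedCorrelation,
    UseTwoGroupPath,
)
from nervedce.stats import (
    assign_dn_group,
    compare_multi_groups,
    compare_two_groups,
    correlate,
    correlation_table,
    partial_correlation,
    run_cohort_tables,
    severity_score,
)


class TestClassification:
    @pytest.mark.parametrize(
        "nds, expected", [(3, "DN"), (0, "no_DN"), (2, "no_DN"), (9, "DN")]
    )
    def test_dn_threshold(self, nds, expected):
        assert assign_dn_group(nds) == expected

    def test_negative_nds(self):
        with pytest.raises(InvalidScore):
            assign_dn_group(-1)

    @pytest.mark.parametrize(
        "snap, cmap, expected",
        [
            (6.0, 1.0, 1),   # preserved sural response dominates
            (4.0, 6.0, 2),
            (4.0, 3.0, 3),
            (4.0, 1.9, 4),
            (5.0, 0.0, 1),   # boundary: SNAP exactly 5
            (4.0, 5.0, 2),   # boundary overlap resolves to the milder score
            (4.0, 2.0, 3),
        ],
    )
    def test_severity_rules(self, snap, cmap, expected):
        assert severity_score(snap, cmap) == expected

    def test_severity_missing_input(self):
        with pytest.raises(MissingMeasurement):
            severity_score(np.nan, 3.0)

    def test_severity_exhaustive_sweep_monotone(self):
        """Scores are only 1-4 and never decrease as amplitudes drop."""
        snaps = np.arange(0.0, 10.05, 0.1)
        cmaps = np.arange(0.0, 10.05, 0.1)
        grid = np.array(
            [[severity_score(s, c) for c in cmaps] for s in snaps]
        )
        assert set(np.unique(grid)) <= {1, 2, 3, 4}
        # higher SNAP (rows) or CMAP (cols) never worsens the score
        assert np.all(np.diff(grid, axis=0) <= 0)
        assert np.all(np.diff(grid, axis=1) <= 0)


class TestTwoGroups:
    def test_gaussian_samples_take_t_path(self):
        rng = np.random.default_rng(11)
        n_t, n_keep = 0, 0
        for _ in range(100):
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 60)
            res = compare_two_groups(x, y)
            n_t += res.test_name == "t"
            n_keep += res.p > 0.05
        assert n_t >= 85   # ~0.95^2 of seeds pass both normality gates
        assert n_keep >= 90

    def test_skewed_samples_take_mann_whitney(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1.0, 80)
        y = rng.lognormal(0.2, 1.0, 80)
        res = compare_two_groups(x, y)
        assert res.test_name == "mann_whitney"

    def test_identical_constant_groups_degenerate_path(self):
        res = compare_two_groups(np.full(10, 3.0), np.full(12, 3.0))
        assert res.p == 1.0

    def test_too_small_group(self):
        with pytest.raises(InsufficientData):
            compare_two_groups(np.array([1.0, 2.0]), np.arange(10.0))

    def test_small_group_warns_and_goes_nonparametric(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            res = compare_two_groups(rng.normal(0, 1, 5), rng.normal(0, 1, 30))
        assert res.test_name == "mann_whitney"


class TestMultiGroups:
    def test_planted_ordering_power(self):
        """Biomarker means rising across control / no-DN / DN groups are
        detected by the omnibus and the extreme pairwise comparison."""
        rng = np.random.default_rng(42)
        omnibus_hits, pairwise_hits = 0, 0
        n_seeds = 200
        for _ in range(n_seeds):
            co = rng.normal(7.25, 2.18, 12)
            nodn = rng.normal(8.65, 4.05, 18)
            dn = rng.normal(11.67, 3.50, 26)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = compare_multi_groups([co, nodn, dn])
                omnibus_hits += res.p < 0.05
                pair = compare_two_groups(dn, co)
                pairwise_hits += pair.p < 0.05
        assert omnibus_hits >= 0.9 * n_seeds
        assert pairwise_hits >= 0.9 * n_seeds

    def test_null_omnibus_p_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            pvals.append(compare_multi_groups(groups).p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_skewed_groups_take_kruskal_with_dunn(self):
        rng = np.random.default_rng(3)
        groups = [rng.lognormal(m, 1.0, 40) for m in (0.0, 0.0, 1.0)]
        res = compare_multi_groups(groups, labels=("a", "b", "c"))
        assert res.test_name == "kruskal_wallis_dunn"
        assert set(res.posthoc) == {("a", "b"), ("a", "c"), ("b", "c")}
        # Bonferroni-adjusted pairwise p-values live in [0, 1]
        assert all(0.0 <= v["p"] <= 1.0 for v in res.posthoc.values())
        assert res.posthoc[("a", "c")]["p"] < 0.05

    def test_two_groups_rejected(self):
        with pytest.raises(UseTwoGroupPath):
            compare_multi_groups([np.arange(5.0), np.arange(5.0)])

    def test_empty_group(self):
        with pytest.raises(InsufficientData):
            compare_multi_groups(
                [np.arange(10.0), np.arange(10.0), np.array([])]
            )


class TestCorrelate:
    def test_perfect_linear(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        res = correlate(x, 2.0 * x + 1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-20

    def test_monotone_transform_rank_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        res = correlate(x, np.exp(3.0 * x))  # lognormal y fails the gate
        assert res.method == "spearman_bonferroni"
        assert res.r == pytest.approx(1.0)

    def test_bonferroni_caps_and_never_shrinks(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 1, 40)
        y = rng.lognormal(0, 1, 40)
        raw = correlate(x, y, m_tests=1)
        adj = correlate(x, y, m_tests=7)
        assert adj.p >= raw.p
        assert adj.p == pytest.approx(min(1.0, 7.0 * raw.p))

    def test_monte_carlo_mean_r(self):
        """Bivariate normal rho = -0.38 at n = 44: the mean estimate is
        close to the population value (small finite-n bias)."""
        rng = np.random.default_rng(99)
        cov = np.array([[1.0, -0.38], [-0.38, 1.0]])
        rs = []
        for _ in range(300):
            xy = rng.multivariate_normal([0, 0], cov, size=44)
            rs.append(correlate(xy[:, 0], xy[:, 1]).r)
        assert np.mean(rs) == pytest.approx(-0.38, abs=0.04)

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelation):
            correlate(np.full(10, 2.0), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientData):
            correlate(np.arange(4.0), np.arange(4.0))

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan, 7])
        y = 2 * x
        y[2] = np.nan
        res = correlate(x, y)
        assert res.n == 5


def partial_r_matrix_oracle(x, y, z):
    """Independent oracle: partial correlation via inversion of the joint
    correlation matrix."""
    data = np.column_stack([x, y] + list(z))
    prec = np.linalg.inv(np.corrcoef(data, rowvar=False))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


class TestPartialCorrelation:
    def test_orthogonal_controls_equal_marginal(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=(40, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x, y = q[:, 0], 0.6 * q[:, 0] + 0.8 * q[:, 1]
        controls = q[:, 2:].T  # exactly orthogonal to x and y
        res = partial_correlation(x, y, controls)
        marginal = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(marginal, abs=1e-10)

    def test_confounder_explains_everything(self):
        rng = np.random.default_rng(6)
        z = rng.normal(0, 1, 60)
        x = 2.0 * z + rng.normal(0, 0.05, 60)
        y = -3.0 * z + rng.normal(0, 0.05, 60)
        # strong marginal correlation, near-zero after controlling for z
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.9
        res = partial_correlation(x, y, z[None, :], control_names=("z",))
        assert abs(res.r) < 0.3

    def test_matches_matrix_inversion_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.normal(size=(4, 4))
            cov = a @ a.T + 0.5 * np.eye(4)
            data = rng.multivariate_normal(np.zeros(4), cov, size=60)
            x, y, z = data[:, 0], data[:, 1], data[:, 2:].T
            res = partial_correlation(x, y, z)
            assert res.r == pytest.approx(
                partial_r_matrix_oracle(x, y, z), abs=1e-10
            )

    def test_collinear_controls(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=60), rng.normal(size=60)
        z1 = rng.normal(size=60)
        with pytest.raises(CollinearControls):
            partial_correlation(x, y, np.vstack([z1, 2.0 * z1]))

    def test_insufficient_n(self):
        with pytest.raises(InsufficientData):
            partial_correlation(
                np.arange(4.0), np.arange(4.0), np.ones((2, 4))
            )


class TestCohortTables:
    def _cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        return pd.DataFrame({
            "group": ["T2D"] * (n // 2) + ["control"] * (n - n // 2),
            "hstnt_pg_ml": 9.0 + 3.0 * z + rng.normal(0, 1, n),
            "probnp_pg_ml": rng.normal(100, 40, n),
            "ktrans_per_min": 0.04 - 0.01 * z + rng.normal(0, 0.002, n),
            "age_years": rng.normal(65, 7, n),
            "bmi_kg_m2": rng.normal(28, 4, n),
        })

    def test_planted_sign_recovered(self):
        df = self._cohort(n=60, seed=3)
        out = correlation_table(
            df, ["hstnt_pg_ml"], ["ktrans_per_min"], group="T2D"
        )
        assert out.loc[0, "r"] < 0

    def test_empty_cohort_raises(self):
        with pytest.raises(SchemaError):
            run_cohort_tables(pd.DataFrame())

    def test_missing_column_raises(self):
        df = self._cohort()
        with pytest.raises(SchemaError):
            correlation_table(df, ["hstnt_pg_ml"], ["not_a_column"])

    def test_controls_only_cohort_no_crash(self):
        df = self._cohort(n=24, seed=5)
        df["group"] = "control"
        out = run_cohort_tables(df)
        assert "correlations" in out
        assert "group_comparison" not in out

    def test_full_driver_produces_tables(self):
        df = self._cohort(n=60, seed=7)
        out = run_cohort_tables(
            df,
            biomarker_cols=["hstnt_pg_ml", "probnp_pg_ml"],
            outcome_cols=["ktrans_per_min"],
            controls=["age_years", "bmi_kg_m2"],
        )
        assert {"group_comparison", "correlations",
                "partial_correlations"} <= set(out)
        pc = out["partial_correlations"]
        assert (pc["method"] == "partial_pearson").all()
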