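"""Cohort statistics for nerve-perfusion studies.

Implements the study's classification rules and its statistics protocol:

* diabetic-polyneuropathy (DN) group assignment by neuropathy disability
  score (NDS >= 3);
* an electrophysiology-based neuropathy severity score (1-4) from sural
  SNAP and tibial CMAP amplitudes;
* normality-gated two-group comparisons (D'Agostino-Pearson omnibus test;
  Student's t if both groups Gaussian, otherwise Mann-Whitney U);
* normality-gated multi-group comparisons (one-way ANOVA, otherwise
  Kruskal-Wallis with post-hoc Dunn pairwise tests, Bonferroni-adjusted);
* normality-gated correlations (Pearson, otherwise Bonferroni-corrected
  Spearman);
* partial correlation controlling for confounders (age, BMI), computed by
  correlating the least-squares residuals of each variable regressed on
  the controls, with p from a t statistic on n - 2 - k degrees of freedom.

Conventions (documented, not tunable per call unless noted): normality gate
at alpha = 0.05; all tests two-sided; pairwise deletion of missing values
for correlations, listwise within each comparison; Bonferroni family size
``m_tests`` is the number of correlations in one table column and is the
caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearControls,
    InsufficientData,
    InvalidScore,
    MissingMeasurement,
    SchemaError,
    UndefinedCorrelation,
    UseTwoGroupPath,
)

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "assign_dn_group",
    "severity_score",
    "compare_two_groups",
    "compare_multi_groups",
    "correlate",
    "partial_correlation",
    "group_comparison_table",
    "correlation_table",
    "run_cohort_tables",
]

#: Significance level of the D'Agostino-Pearson normality gate.
ALPHA_NORMALITY = 0.05

#: Minimum per-group n for the D'Agostino-Pearson omnibus test.
_DAGOSTINO_MIN_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its provenance."""

    r: float
    p: float
    method: str  # pearson | spearman_bonferroni | partial_pearson
    n: int
    controls: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparisonResult:
    """A two- or multi-group location comparison."""

    statistic: float
    p: float
    test_name: str  # t | mann_whitney | anova | kruskal_wallis_dunn
    groups: tuple[str, ...]
    normality_p: tuple[float, ...]
    posthoc: dict = field(default_factory=dict)


# --- classification rules --------------------------------------------------

def assign_dn_group(nds: int) -> str:
    """Assign DN status from the neuropathy disability score: DN iff NDS >= 3."""
    if nds is None or (isinstance(nds, float) and np.isnan(nds)):
        raise MissingMeasurement("NDS is missing")
    if nds < 0:
        raise InvalidScore(f"NDS must be >= 0, got {nds}")
    return "DN" if nds >= 3 else "no_DN"


def severity_score(sural_snap_uv: float, tibial_cmap_mv: float) -> int:
    """Electrophysiology-based neuropathy severity score (1 = mild, 4 = severe).

    Score 1: sural SNAP >= 5 uV.  For SNAP < 5 uV the tibial CMAP decides:
    score 2 for CMAP >= 5 mV, score 3 for 2 <= CMAP < 5 mV, score 4 for
    CMAP < 2 mV.  The published category bounds overlap at exactly 5 mV
    ("">= 2 and <= 5"" vs "">= 5""); the higher category listed first wins,
    so CMAP = 5 mV scores 2.
    """
    for name, v in (("sural_snap_uv", sural_snap_uv),
                    ("tibial_cmap_mv", tibial_cmap_mv)):
        if v is None or np.isnan(v):
            raise MissingMeasurement(f"{name} is missing")
        if v < 0:
            raise InvalidScore(f"{name} must be >= 0, got {v}")
    if sural_snap_uv >= 5.0:
        return 1
    if tibial_cmap_mv >= 5.0:
        return 2
    if tibial_cmap_mv >= 2.0:
        return 3
    return 4


# --- normality gate --------------------------------------------------------

def _normality_p(x: np.ndarray) -> float:
    """D'Agostino-Pearson omnibus p-value; NaN when n is below the test's
    minimum or the sample is degenerate (treated as non-Gaussian)."""
    x = np.asarray(x, dtype=float)
    if x.size < _DAGOSTINO_MIN_N or np.ptp(x) == 0.0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(sps.normaltest(x).pvalue)
        except ValueError:
            return np.nan


def _gaussian(p_norm: float, alpha: float) -> bool:
    return bool(np.isfinite(p_norm) and p_norm > alpha)


# --- group comparisons -----------------------------------------------------

def compare_two_groups(
    x: np.ndarray,
    y: np.ndarray,
    alpha_norm: float = ALPHA_NORMALITY,
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparisonResult:
    """Two-sided two-group comparison with a normality gate.

    Student's t test if both groups pass the D'Agostino-Pearson gate at
    ``alpha_norm``, otherwise Mann-Whitney U.  Groups below the omnibus
    test's minimum n fall back to the nonparametric branch (a warning is
    emitted).  Two identical constant groups return p = 1 on the
    nonparametric path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if min(x.size, y.size) < 3:
        raise InsufficientData("each group needs at least 3 observations")
    if min(x.size, y.size) < _DAGOSTINO_MIN_N:
        warnings.warn(
            "group below the D'Agostino-Pearson minimum n; "
            "using the nonparametric branch",
            stacklevel=2,
        )
    p_norm = (_normality_p(x), _normality_p(y))
    if all(_gaussian(p, alpha_norm) for p in p_norm):
        res = sps.ttest_ind(x, y)
        return GroupComparisonResult(
            statistic=float(res.statistic),
            p=float(res.pvalue),
            test_name="t",
            groups=labels,
            normality_p=p_norm,
        )
    if np.ptp(np.concatenate([x, y])) == 0.0:
        # degenerate: both groups constant and equal
        return GroupComparisonResult(
            statistic=np.nan, p=1.0, test_name="mann_whitney",
            groups=labels, normality_p=p_norm,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        test_name="mann_whitney",
        groups=labels,
        normality_p=p_norm,
    )


def _dunn_posthoc(groups: list[np.ndarray], labels: tuple[str, ...]) -> dict:
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis, with a
    tie correction and Bonferroni adjustment over all pairs."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            out[(labels[i], labels[j])] = {
                "z": float(z),
                "p": float(min(1.0, p_raw * n_pairs)),
            }
    return out


def compare_multi_groups(
    groups: list[np.ndarray],
    alpha_norm: float = ALPHA_NORMALITY,
    labels: tuple[str, ...] | None = None,
) -> GroupComparisonResult:
    """Multi-group comparison: one-way ANOVA if every group passes the
    normality gate, otherwise Kruskal-Wallis with Dunn post-hoc pairwise
    tests (Bonferroni-adjusted over all pairs)."""
    if len(groups) < 3:
        raise UseTwoGroupPath("fewer than 3 groups; use compare_two_groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(arrs)))
    if min(a.size for a in arrs) < 3:
        raise InsufficientData("each group needs at least 3 observations")
    p_norm = tuple(_normality_p(a) for a in arrs)
    if all(_gaussian(p, alpha_norm) for p in p_norm):
        res = sps.f_oneway(*arrs)
        return GroupComparisonResult(
            statistic=float(res.statistic),
            p=float(res.pvalue),
            test_name="anova",
            groups=labels,
            normality_p=p_norm,
        )
    res = sps.kruskal(*arrs)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        test_name="kruskal_wallis_dunn",
        groups=labels,
        normality_p=p_norm,
        posthoc=_dunn_posthoc(arrs, labels),
    )


# --- correlations ----------------------------------------------------------

def correlate(
    x: np.ndarray,
    y: np.ndarray,
    alpha_norm: float = ALPHA_NORMALITY,
    m_tests: int = 1,
) -> CorrelationResult:
    """Normality-gated correlation of two paired variables.

    Pearson if both marginals pass the D'Agostino-Pearson gate, otherwise
    Spearman with the p-value Bonferroni-multiplied by ``m_tests``
    (capped at 1).  Missing values are removed pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 5:
        raise InsufficientData(f"need >= 5 complete pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelation("zero variance in one of the variables")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    p_norm_x, p_norm_y = _normality_p(x), _normality_p(y)
    if _gaussian(p_norm_x, alpha_norm) and _gaussian(p_norm_y, alpha_norm):
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(r=float(r), p=float(p), method="pearson", n=n)
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(
        r=float(r),
        p=float(min(1.0, p * m_tests)),
        method="spearman_bonferroni",
        n=n,
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray,
    control_names: tuple[str, ...] = ("age", "bmi"),
) -> CorrelationResult:
    """Partial Pearson correlation of x and y given control covariates.

    Computed as the Pearson correlation of the least-squares residuals of
    x and y each regressed (with intercept) on the controls; the p-value
    comes from ``t = r sqrt((n - 2 - k) / (1 - r^2))`` with ``n - 2 - k``
    degrees of freedom, k the number of controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(controls, dtype=float))
    if z.shape[0] == x.size and z.shape[1] != x.size:
        z = z.T  # accept (n, k) or (k, n)
    if z.shape[1] != x.size or y.shape != x.shape:
        raise ValueError("x, y and controls must share the sample axis")
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(z), axis=0)
    x, y, z = x[keep], y[keep], z[:, keep]
    n, k = int(x.size), int(z.shape[0])
    if n <= k + 2:
        raise InsufficientData(f"need n > k + 2, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), z.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearControls("control covariates are collinear")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise UndefinedCorrelation("a variable is fully explained by controls")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return CorrelationResult(
        r=r, p=p, method="partial_pearson", n=n, controls=tuple(control_names)
    )


# --- cohort-level table drivers -------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")


def group_comparison_table(
    cohort: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("T2D", "control"),
    alpha_norm: float = ALPHA_NORMALITY,
) -> pd.DataFrame:
    """Two-group comparison of each variable, one tidy row per variable.

    Variables with too few observations in either group are reported with
    NaN statistics and a note instead of raising.
    """
    _require_columns(cohort, [group_col] + variables)
    rows = []
    for var in variables:
        sub = {
            g: cohort.loc[cohort[group_col] == g, var].dropna().to_numpy()
            for g in groups
        }
        row = {
            "variable": var,
            "n_" + groups[0]: sub[groups[0]].size,
            "n_" + groups[1]: sub[groups[1]].size,
            "mean_" + groups[0]: (
                float(np.mean(sub[groups[0]])) if sub[groups[0]].size else np.nan
            ),
            "mean_" + groups[1]: (
                float(np.mean(sub[groups[1]])) if sub[groups[1]].size else np.nan
            ),
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = compare_two_groups(
                    sub[groups[0]], sub[groups[1]],
                    alpha_norm=alpha_norm, labels=groups,
                )
            row.update(statistic=res.statistic, p=res.p, test=res.test_name,
                       note="")
        except InsufficientData as exc:
            row.update(statistic=np.nan, p=np.nan, test="", note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(
    cohort: pd.DataFrame,
    x_cols: list[str],
    y_cols: list[str],
    group_col: str = "group",
    group: str | None = None,
    alpha_norm: float = ALPHA_NORMALITY,
    m_tests: int | None = None,
    controls: list[str] | None = None,
) -> pd.DataFrame:
    """Correlations of every x column against every y column, tidy rows.

    ``m_tests`` defaults to ``len(y_cols)`` — one Bonferroni family per
    biomarker column.  With ``controls`` set, partial correlations are
    computed instead of gated marginal ones.
    """
    need = x_cols + y_cols + ([group_col] if group is not None else [])
    _require_columns(cohort, need + (controls or []))
    df = cohort if group is None else cohort[cohort[group_col] == group]
    if m_tests is None:
        m_tests = len(y_cols)
    rows = []
    for xc in x_cols:
        for yc in y_cols:
            if xc == yc:
                continue
            row = {"x": xc, "y": yc, "group": group or "all"}
            try:
                if controls:
                    res = partial_correlation(
                        df[xc].to_numpy(), df[yc].to_numpy(),
                        df[controls].to_numpy().T,
                        control_names=tuple(controls),
                    )
                else:
                    res = correlate(
                        df[xc].to_numpy(), df[yc].to_numpy(),
                        alpha_norm=alpha_norm, m_tests=m_tests,
                    )
                row.update(r=res.r, p=res.p, method=res.method, n=res.n,
                           note="")
            except (InsufficientData, UndefinedCorrelation) as exc:
                row.update(r=np.nan, p=np.nan, method="", n=0, note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def run_cohort_tables(
    cohort: pd.DataFrame,
    comparison_vars: list[str] | None = None,
    biomarker_cols: list[str] | None = None,
    outcome_cols: list[str] | None = None,
    controls: list[str] | None = None,
    group_col: str = "group",
) -> dict[str, pd.DataFrame]:
    """Drive the full results layout on any cohort table.

    Produces a group-comparison table over ``comparison_vars`` and, within
    each group present, a correlation table of biomarkers against outcomes;
    if ``controls`` is given, a partial-correlation table (T2D group) is
    added.  Empty cohorts raise :class:`SchemaError`.
    """
    if cohort.empty:
        raise SchemaError("cohort table is empty")
    _require_columns(cohort, [group_col])
    numeric = [
        c for c in cohort.columns
        if c != group_col and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    comparison_vars = comparison_vars or numeric
    biomarker_cols = biomarker_cols or [
        c for c in ("hstnt_pg_ml", "probnp_pg_ml") if c in cohort.columns
    ]
    outcome_cols = outcome_cols or [
        c for c in numeric if c not in biomarker_cols
    ]
    out: dict[str, pd.DataFrame] = {}
    present = list(cohort[group_col].unique())
    if {"T2D", "control"} <= set(present):
        out["group_comparison"] = group_comparison_table(
            cohort, comparison_vars, group_col=group_col
        )
    corr_frames = []
    for g in present:
        corr_frames.append(
            correlation_table(
                cohort, biomarker_cols, outcome_cols,
                group_col=group_col, group=g,
            )
        )
    out["correlations"] = pd.concat(corr_frames, ignore_index=True)
    if controls:
        target = "T2D" if "T2D" in present else present[0]
        out["partial_correlations"] = correlation_table(
            cohort, biomarker_cols,
            [c for c in outcome_cols if c not in controls],
            group_col=group_col, group=target, controls=controls,
        )
    return out
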