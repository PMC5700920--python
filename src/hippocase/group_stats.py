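"""Group-level comparisons, clinical correlations and reliability.

Shapiro-Wilk normality gating (Box-Cox applied jointly across groups when
either group fails), ANCOVA with age as covariate, paired-t symmetry
gating of control hemispheres before ipsi/contra pooling, one-/two-tailed
Pearson and age-adjusted partial correlations, and repeated-measures
ANOVA + ICC for repeat-segmentation reliability.

No multiple-testing correction is applied at the group level; every
report header records this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

from .core_io import ValidationError
from .single_case_inference import boxcox_transform

logger = logging.getLogger(__name__)

GROUP_LEVEL_CORRECTION_NOTE = "group-level p-values are uncorrected for multiple comparisons"


@dataclass
class GroupComparison:
    variable: str
    n_control: int
    n_patient: int
    f_statistic: float
    p: float
    covariates: list[str] = field(default_factory=lambda: ["age"])
    transform_applied: str = "none"  # "none" | "boxcox"


@dataclass
class ReliabilityReport:
    variables: list[str]
    rm_anova_time_F: float
    rm_anova_time_p: float
    rm_anova_interaction_F: float
    rm_anova_interaction_p: float
    icc: float
    icc_ci: tuple[float, float]
    icc_model: str = "two-way mixed, consistency, single measurement (ICC3)"
    per_subregion_icc: dict[str, float] = field(default_factory=dict)


def normality_gate(control_values, patient_values, alpha: float = 0.05) -> str:
    """Shapiro-Wilk in each group; ``transform_required`` if either fails.

    A required transform must then be applied to both groups jointly to
    keep the variable comparable.
    """
    out = []
    for name, vals in (("control", control_values), ("patient", patient_values)):
        x = np.asarray(vals, float)
        if x.size < 3:
            raise ValidationError(f"normality_gate: {name} group has n={x.size} < 3")
        if np.ptp(x) == 0:
            raise ValidationError(f"normality_gate: {name} group is constant")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.shapiro(x)
        out.append(p)
    return "transform_required" if min(out) < alpha else "normal"


def ancova_group(values, groups, ages, variable: str = "",
                 apply_boxcox: bool | None = None) -> GroupComparison:
    """value ~ intercept + group + age; F and p for the group term.

    With one binary factor and one covariate and no interaction, type-I,
    -II and -III sums of squares coincide for the group term as computed
    here (partial F of dropping group from the full model). A covariate
    with zero variance is dropped with a warning rather than failing.

    ``apply_boxcox=None`` auto-gates on Shapiro-Wilk; the transform, when
    applied, spans both groups jointly.
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    age = np.asarray(ages, float)
    if y.size != g.size or y.size != age.size:
        raise ValidationError("values, groups and ages must be equal length")
    is_patient = (g == "patient").astype(float)
    n_pat = int(is_patient.sum())
    n_ctl = int(y.size - n_pat)
    if n_pat == 0 or n_ctl == 0:
        raise ValidationError("both groups must be nonempty")

    transform = "none"
    if apply_boxcox is None:
        try:
            apply_boxcox = normality_gate(y[is_patient == 0], y[is_patient == 1]) == "transform_required"
        except ValidationError:
            apply_boxcox = False
    if apply_boxcox:
        y, _ = boxcox_transform(y, "mle")
        transform = "boxcox"

    cols = [np.ones_like(y), is_patient]
    names = ["intercept", "group"]
    covariates = []
    if np.ptp(age) == 0:
        logger.warning("ancova_group(%s): age has zero variance; covariate dropped", variable)
    else:
        cols.append(age)
        names.append("age")
        covariates = ["age"]
        if np.ptp(age[is_patient == 1]) == 0 and np.ptp(age[is_patient == 0]) == 0:
            logger.warning("ancova_group(%s): age constant within each group "
                           "(collinear with group); model still fit", variable)

    X_full = np.column_stack(cols)
    X_red = np.column_stack([c for c, nm in zip(cols, names) if nm != "group"])
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_num = full.df_model - red.df_model
    if df_num <= 0 or full.df_resid <= 0:
        raise ValidationError("degenerate ANCOVA design")
    f = float((red.ssr - full.ssr) / df_num / (full.ssr / full.df_resid))
    p = float(stats.f.sf(f, df_num, full.df_resid))
    return GroupComparison(variable=variable, n_control=n_ctl, n_patient=n_pat,
                           f_statistic=max(f, 0.0), p=p, covariates=covariates,
                           transform_applied=transform)


def symmetry_gate(left_values, right_values, alpha: float = 0.05) -> str:
    """Paired t-test of control hemispheres; ``asymmetric`` blocks pooling."""
    left = np.asarray(left_values, float)
    right = np.asarray(right_values, float)
    if left.size != right.size:
        raise ValidationError("symmetry_gate: unpaired lengths")
    if left.size < 3:
        raise ValidationError(f"symmetry_gate: need >= 3 pairs, got {left.size}")
    diff = left - right
    if np.ptp(diff) == 0:
        # zero within-pair variance: either perfectly symmetric or a pure shift
        return "poolable" if diff[0] == 0 else "asymmetric"
    _, p = stats.ttest_rel(left, right)
    return "asymmetric" if p < alpha else "poolable"


def correlate(x, y, tails: str = "two", age_adjust: bool = False,
              age=None, expected_sign: int = 1) -> tuple[float, float]:
    """Pearson r and p, optionally one-tailed or age-partialled.

    One-tailed p tests the association in the ``expected_sign`` direction
    (+1: positive expected, as for volume-memory pairs). ``age_adjust``
    computes the partial correlation controlling for age by residualizing
    both variables on age.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValidationError("correlate: unequal lengths")
    n = x.size
    min_n = 5 if age_adjust else 4
    if n < min_n:
        raise ValidationError(f"correlate: need >= {min_n} complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlate: zero variance")

    dof_loss = 2
    if age_adjust:
        if age is None:
            raise ValidationError("correlate: age_adjust requires ages")
        a = np.asarray(age, float)
        if a.size != n:
            raise ValidationError("correlate: age length mismatch")
        design = np.column_stack([np.ones(n), a])
        x_tol, y_tol = 1e-10 * max(np.ptp(x), 1.0), 1e-10 * max(np.ptp(y), 1.0)
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        if np.ptp(x) <= x_tol or np.ptp(y) <= y_tol:
            return 0.0, 1.0  # one variable fully explained by age
        dof_loss = 3

    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    dof = n - dof_loss
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
    if tails == "two":
        p = float(2 * stats.t.sf(abs(t), dof))
    elif tails == "one":
        p = float(stats.t.sf(expected_sign * t, dof))
    else:
        raise ValidationError(f"tails must be two|one, got {tails!r}")
    return r, min(p, 1.0)


def reliability(time1: pd.DataFrame, time2: pd.DataFrame) -> ReliabilityReport:
    """Repeat-segmentation reliability over subjects x subregions.

    Inputs are wide tables (rows = subjects, columns = subregions) for the
    two segmentation passes. Subjects with any missing cell are dropped
    with a log message. Reports a repeated-measures ANOVA with within
    factors time and subregion, the pooled ICC(3,1) across all
    subject-subregion units, its 95% CI, and per-subregion ICCs.
    """
    if list(time1.columns) != list(time2.columns):
        raise ValidationError("reliability: subregion columns differ between time points")
    if len(time1) < 3:
        raise ValidationError("reliability: need >= 3 subjects")
    keep = time1.notna().all(axis=1) & time2.notna().all(axis=1)
    dropped = list(time1.index[~keep])
    if dropped:
        logger.warning("reliability: dropping subjects with missing cells: %s", dropped)
    t1 = time1.loc[keep]
    t2 = time2.loc[keep]
    if len(t1) < 3:
        raise ValidationError("reliability: fewer than 3 complete subjects")

    long = []
    for t, frame in (("t1", t1), ("t2", t2)):
        for subject, row in frame.iterrows():
            for subregion, value in row.items():
                long.append({"subject": subject, "time": t,
                             "subregion": subregion, "volume": float(value)})
    df = pd.DataFrame(long)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = AnovaRM(df, depvar="volume", subject="subject",
                      within=["time", "subregion"]).fit().anova_table

    def _f_p(row: str) -> tuple[float, float]:
        f = float(aov.loc[row, "F Value"])
        p = float(aov.loc[row, "Pr > F"])
        # zero residual variance (e.g. identical repeats) yields nan or a
        # roundoff-negative F; report a null effect
        if not np.isfinite(f) or f < 0:
            return 0.0, 1.0
        return f, min(p, 1.0) if np.isfinite(p) else 1.0

    time_F, time_p = _f_p("time")
    inter_F, inter_p = _f_p("time:subregion")

    # pooled ICC: units are subject x subregion, raters are time points
    df["unit"] = df["subject"].astype(str) + ":" + df["subregion"].astype(str)
    icc, ci = _icc3_single(df, "unit", "time", "volume")

    per_sub = {}
    for subregion, sub in df.groupby("subregion", sort=False):
        try:
            per_sub[str(subregion)] = _icc3_single(sub, "subject", "time", "volume")[0]
        except (ValidationError, ValueError):
            per_sub[str(subregion)] = float("nan")

    return ReliabilityReport(
        variables=list(map(str, time1.columns)),
        rm_anova_time_F=time_F, rm_anova_time_p=time_p,
        rm_anova_interaction_F=inter_F, rm_anova_interaction_p=inter_p,
        icc=icc, icc_ci=ci, per_subregion_icc=per_sub,
    )


def _icc3_single(df: pd.DataFrame, targets: str, raters: str,
                 ratings: str) -> tuple[float, tuple[float, float]]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=df, targets=targets, raters=raters,
                                   ratings=ratings, nan_policy="omit")
    table = table.set_index("Type")
    # pingouin labels the two-way mixed consistency single-rater ICC as
    # "ICC3" or "ICC(C,1)" depending on version
    key = "ICC3" if "ICC3" in table.index else "ICC(C,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    icc = float(row["ICC"])
    if not np.isfinite(icc):  # zero error variance: perfect agreement
        icc, lo, hi = 1.0, 1.0, 1.0
    # pingouin rounds the CI to 2 decimals; keep the point estimate inside
    lo, hi = min(float(lo), icc), max(float(hi), icc)
    return icc, (lo, hi)
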