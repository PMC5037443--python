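"""Group and longitudinal statistics for layer-specific cartilage T2.

The analysis plan mirrors the reference study: crude between-group contrasts
with unpaired two-sided t-tests (pooled variance by default, Welch behind a
flag), Cohen's D on the pooled SD, ANCOVA adjustment for age, sex and BMI
via ordinary least squares, Bonferroni multiplicity over the six primary
comparisons (3 group pairs x 2 layers, alpha 0.05/6 = 0.00833), paired
within-knee change tests, and the superficial-vs-deep change contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError, UndefinedEffectError

ALPHA = 0.05
PRIMARY_FAMILY_SIZE = 6


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group contrast: difference (A - B), CI, p, effect size."""

    mean_diff_ms: float
    ci95: tuple[float, float]
    p_value: float
    cohens_d: float
    n_a: int
    n_b: int
    adjusted: bool = False
    significant_bonferroni: bool = False


@dataclass(frozen=True)
class ChangeResult:
    """A within-subject change (or change contrast): mean, SD, CI, p."""

    mean_change_ms: float
    sd_change_ms: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def significance_flag(p: float, family_size: int = PRIMARY_FAMILY_SIZE) -> bool:
    """Bonferroni significance: strict p < alpha / family_size."""
    if family_size < 1:
        raise InvalidParameterError("family_size must be >= 1")
    return bool(p < ALPHA / family_size)


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Standardized mean difference (A - B) over the pooled SD.

    Uses the classical pooled-SD form without small-sample (Hedges)
    correction.  Zero pooled SD with equal means gives 0; with unequal
    means the effect is undefined and raises.
    """
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise InvalidParameterError("SDs must be >= 0")
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    pooled_sd = math.sqrt(pooled_var)
    diff = mean_a - mean_b
    if pooled_sd == 0.0:
        if diff == 0.0:
            return 0.0
        raise UndefinedEffectError("pooled SD is 0 with unequal means")
    return diff / pooled_sd


def comparison_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    equal_var: bool = True,
    family_size: int = PRIMARY_FAMILY_SIZE,
) -> ComparisonResult:
    """Two-sample inference computed from summary statistics alone.

    With ``equal_var`` (default) the pooled-variance Student t is used: the
    printed contrasts of the reference study are exact functions of its
    printed group means/SDs/n under this form.  ``equal_var=False`` switches
    to Welch-Satterthwaite.
    """
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise InvalidParameterError("SDs must be >= 0")
    diff = mean_a - mean_b
    if equal_var:
        pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        ci = (diff, diff)
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        half = float(sps.t.ppf(1.0 - ALPHA / 2.0, df)) * se
        ci = (diff - half, diff + half)
    d = cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    return ComparisonResult(
        mean_diff_ms=diff, ci95=ci, p_value=p, cohens_d=d,
        n_a=n_a, n_b=n_b, adjusted=False,
        significant_bonferroni=significance_flag(p, family_size),
    )


def crude_group_difference(
    values_a, values_b,
    equal_var: bool = True,
    family_size: int = PRIMARY_FAMILY_SIZE,
) -> ComparisonResult:
    """Unpaired two-sided t comparison of two samples (A - B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need n >= 2 per group")
    return comparison_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        equal_var=equal_var, family_size=family_size,
    )


def _pivot_visits(cohort: pd.DataFrame, group: str, plate: str, layer: str) -> pd.DataFrame:
    sel = cohort[
        (cohort["group"] == group) & (cohort["plate"] == plate) & (cohort["layer"] == layer)
    ]
    wide = sel.pivot(index="subject_id", columns="visit", values="t2_ms")
    if "baseline" not in wide or "year1" not in wide:
        return wide.iloc[0:0]
    return wide.dropna(subset=["baseline", "year1"])


def paired_change(cohort: pd.DataFrame, group: str, plate: str, layer: str) -> ChangeResult:
    """Within-knee one-year change, tested against zero with a paired t.

    Only subjects observed at both visits contribute.
    """
    wide = _pivot_visits(cohort, group, plate, layer)
    diffs = (wide["year1"] - wide["baseline"]).to_numpy() if len(wide) else np.array([])
    if diffs.size < 2:
        raise InsufficientDataError(
            f"group {group!r} {plate}/{layer}: need >= 2 subjects with both visits"
        )
    return change_from_samples(diffs)


def change_from_samples(diffs) -> ChangeResult:
    """One-sample t inference on per-subject changes."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise InsufficientDataError("need >= 2 paired observations")
    return change_from_summary(
        float(diffs.mean()), float(diffs.std(ddof=1)), diffs.size
    )


def change_from_summary(mean_change: float, sd_change: float, n: int) -> ChangeResult:
    """One-sample t inference from the change mean/SD/n alone."""
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if sd_change < 0:
        raise InvalidParameterError("SD must be >= 0")
    se = sd_change / math.sqrt(n)
    df = n - 1
    if se == 0.0:
        p = 1.0 if mean_change == 0.0 else 0.0
        ci = (mean_change, mean_change)
    else:
        t = mean_change / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        half = float(sps.t.ppf(1.0 - ALPHA / 2.0, df)) * se
        ci = (mean_change - half, mean_change + half)
    return ChangeResult(
        mean_change_ms=mean_change, sd_change_ms=sd_change, ci95=ci, p_value=p, n=n
    )


def layer_change_contrast(cohort: pd.DataFrame, group: str, plate: str = "Avg") -> ChangeResult:
    """Superficial minus deep one-year change, paired within subject.

    Tests whether longitudinal change is stronger in the superficial than
    the deep layer.  Requires both layers at both visits for every included
    subject.
    """
    sup = _pivot_visits(cohort, group, plate, "superficial")
    deep = _pivot_visits(cohort, group, plate, "deep")
    common = sup.index.intersection(deep.index)
    sel = cohort[(cohort["group"] == group) & (cohort["plate"] == plate)]
    subjects_fu = set(
        sel[sel["visit"] == "year1"]["subject_id"].unique()
    )
    if subjects_fu - set(common):
        missing = sorted(subjects_fu - set(common))[:5]
        raise InsufficientDataError(
            f"group {group!r}: layer missing at a visit for subjects {missing}"
        )
    contrast = (
        (sup.loc[common, "year1"] - sup.loc[common, "baseline"])
        - (deep.loc[common, "year1"] - deep.loc[common, "baseline"])
    ).to_numpy()
    if contrast.size < 2:
        raise InsufficientDataError(f"group {group!r}: need >= 2 subjects with both visits")
    return change_from_samples(contrast)


def ancova_adjusted_difference(
    cohort: pd.DataFrame,
    plate: str,
    layer: str,
    group_pair: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    outcome: str = "baseline",
    family_size: int = PRIMARY_FAMILY_SIZE,
) -> ComparisonResult:
    """Covariate-adjusted group difference from an OLS ANCOVA.

    Fits ``outcome ~ group + age + sex + bmi`` on the two groups (sex coded
    female = 1) and reports the group coefficient (A - B) with its 95% CI
    and p.  ``outcome='baseline'`` uses baseline T2; ``'change'`` uses the
    per-subject year-1 minus baseline difference.  Cohen's D is reported
    from the unadjusted group samples for reference.
    """
    ga, gb = group_pair
    frames = {}
    for g in group_pair:
        if outcome == "baseline":
            sel = cohort[
                (cohort["group"] == g) & (cohort["plate"] == plate)
                & (cohort["layer"] == layer) & (cohort["visit"] == "baseline")
            ].set_index("subject_id")
            y = sel["t2_ms"]
            covs = sel[list(covariates)].copy() if covariates else sel[[]].copy()
        elif outcome == "change":
            wide = _pivot_visits(cohort, g, plate, layer)
            y = wide["year1"] - wide["baseline"]
            sel = (
                cohort[(cohort["group"] == g) & (cohort["visit"] == "baseline")]
                .drop_duplicates("subject_id").set_index("subject_id")
            )
            covs = sel.loc[y.index, list(covariates)].copy() if covariates else None
        else:
            raise InvalidParameterError("outcome must be 'baseline' or 'change'")
        frame = covs if covariates else pd.DataFrame(index=y.index)
        frame["y"] = y
        frame["is_a"] = 1.0 if g == ga else 0.0
        frames[g] = frame
    data = pd.concat([frames[ga], frames[gb]])
    if data["is_a"].nunique() < 2 or len(data) < len(covariates) + 3:
        raise InsufficientDataError("both groups must be present with enough subjects")

    X = pd.DataFrame(index=data.index)
    X["group"] = data["is_a"]
    for c in covariates:
        X[c] = (data[c] == "female").astype(float) if c == "sex" else data[c].astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        sd = X.drop(columns="const").std()
        degenerate = sd.index[sd == 0].tolist()
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = degenerate if degenerate else list(corr.stack().idxmax())
        raise InvalidParameterError(
            f"rank-deficient ANCOVA design (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {worst}"
        )
    fit = sm.OLS(data["y"].astype(float), X).fit()
    diff = float(fit.params["group"])
    ci_low, ci_high = (float(v) for v in fit.conf_int(alpha=ALPHA).loc["group"])
    p = float(fit.pvalues["group"])

    a_vals = data.loc[data["is_a"] == 1.0, "y"].to_numpy(dtype=float)
    b_vals = data.loc[data["is_a"] == 0.0, "y"].to_numpy(dtype=float)
    d = cohens_d(
        a_vals.mean(), a_vals.std(ddof=1), a_vals.size,
        b_vals.mean(), b_vals.std(ddof=1), b_vals.size,
    )
    return ComparisonResult(
        mean_diff_ms=diff, ci95=(ci_low, ci_high), p_value=p, cohens_d=d,
        n_a=a_vals.size, n_b=b_vals.size, adjusted=True,
        significant_bonferroni=significance_flag(p, family_size),
    )


def crude_difference_from_cohort(
    cohort: pd.DataFrame,
    plate: str,
    layer: str,
    group_pair: tuple[str, str],
    outcome: str = "baseline",
    equal_var: bool = True,
    family_size: int = PRIMARY_FAMILY_SIZE,
) -> ComparisonResult:
    """Crude (unadjusted) group contrast pulled from a cohort table."""
    ga, gb = group_pair
    vals = {}
    for g in group_pair:
        if outcome == "baseline":
            sel = cohort[
                (cohort["group"] == g) & (cohort["plate"] == plate)
                & (cohort["layer"] == layer) & (cohort["visit"] == "baseline")
            ]
            vals[g] = sel["t2_ms"].to_numpy(dtype=float)
        elif outcome == "change":
            wide = _pivot_visits(cohort, g, plate, layer)
            vals[g] = (wide["year1"] - wide["baseline"]).to_numpy(dtype=float)
        else:
            raise InvalidParameterError("outcome must be 'baseline' or 'change'")
    return crude_group_difference(
        vals[ga], vals[gb], equal_var=equal_var, family_size=family_size
    )
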