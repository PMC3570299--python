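"""Statistical contrasts: linear models, single-SNP scans, confounder scans,
and the diabetes/glycosuria classification rules.

Regressions are ordinary least squares with conventional standard errors and
listwise deletion of incomplete rows; the 95% CI is the normal-approximation
``beta ± 1.96 se``. Confounder scans choose the test by covariable type —
chi-square for categorical-categorical pairs (uncorrected), an OLS F-test
otherwise — and report the observed number of nominal associations next to
the chance expectation ``alpha × n_tests`` (rounded half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .catalog import MISSING, GenotypeMatrix

__all__ = [
    "RegressionResult",
    "ScanResult",
    "RankDeficiencyError",
    "ols_fit",
    "single_snp_scan",
    "confounder_scan",
    "expected_nominal_count",
    "maternal_effect_fit",
    "classify_diabetes",
    "classify_glycosuria",
    "mgdl_to_mmoll",
    "diabetes_category",
    "GLUCOSE_MGDL_PER_MMOLL",
    "WHO_FG_THRESHOLD",
    "WHO_HBA1C_THRESHOLD",
    "GLYCOSURIA_THRESHOLD_MMOLL",
]

#: Glucose molar-mass conversion: mg/dl per mmol/l.
GLUCOSE_MGDL_PER_MMOLL = 18.016
#: WHO diagnostic thresholds: fasting glucose (mmol/l) and HbA1c (%).
WHO_FG_THRESHOLD = 7.0
WHO_HBA1C_THRESHOLD = 6.5
#: Plasma glucose threshold for a qualifying glycosuria occasion, as printed
#: in each unit (13.9 mmol/l and 250 mg/dl are the published equivalents).
GLYCOSURIA_THRESHOLD_MMOLL = 13.9
GLYCOSURIA_THRESHOLD_MGDL = 250.0


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; carries the collinear column names."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")


@dataclass(frozen=True)
class RegressionResult:
    """One fitted linear contrast: the exposure coefficient and its uncertainty."""

    outcome: str
    exposure: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    covariates: tuple[str, ...] = ()

    def summary_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "outcome": self.outcome, "exposure": self.exposure, "n": self.n,
            "beta": self.beta, "se": self.se, "ci_low": lo, "ci_high": hi,
            "p_value": self.p_value, "covariates": ",".join(self.covariates),
        }


def _design(exposure: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({exposure.name or "exposure": exposure.astype(float)})
    if covariates is not None and covariates.shape[1] > 0:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = pd.concat([X, cov], axis=1)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, R = np.linalg.qr(arr)
        diag = np.abs(np.diag(R))
        tol = diag.max() * 1e-10 if diag.max() > 0 else 1e-10
        bad = [X.columns[j] for j in range(arr.shape[1]) if diag[j] < tol]
        raise RankDeficiencyError(bad or list(X.columns))


def ols_fit(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    outcome_label: str | None = None,
    exposure_label: str | None = None,
) -> RegressionResult:
    """OLS of *outcome* on *exposure* plus covariates, listwise deletion.

    Categorical covariate columns are dummy-coded (first level dropped).
    Raises :class:`RankDeficiencyError` naming collinear columns.
    """
    y = pd.Series(outcome, name=outcome_label or getattr(outcome, "name", None) or "outcome")
    x = pd.Series(exposure, name=exposure_label or getattr(exposure, "name", None) or "exposure")
    y = y.astype(float).reset_index(drop=True)
    x = x.reset_index(drop=True)
    cov = covariates.reset_index(drop=True) if covariates is not None else None

    X = _design(x, cov)
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n = len(data)
    if n < X.shape[1] + 1:
        raise ValueError(f"only {n} complete rows for {X.shape[1]} parameters")
    Xc = data.drop(columns="__y__")
    _check_rank(Xc)
    fit = sm.OLS(data["__y__"], Xc).fit()
    term = x.name
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    return RegressionResult(
        outcome=y.name, exposure=term, beta=beta, se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        p_value=float(fit.pvalues[term]), n=n,
        covariates=tuple(c for c in Xc.columns if c not in ("const", term)),
    )


def single_snp_scan(
    genotypes: GenotypeMatrix,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[list[RegressionResult], list[dict]]:
    """Additive per-SNP OLS scan (minor-allele count, major homozygote baseline).

    Returns (results, skipped) where skipped lists SNPs that could not be
    tested (monomorphic or otherwise degenerate) with the reason; a failing
    SNP never aborts the scan. A Bonferroni display threshold over the tested
    SNPs is attached to each call site via :func:`duoscore.qc.bonferroni_threshold`.
    """
    results: list[RegressionResult] = []
    skipped: list[dict] = []
    out = pd.Series(outcome).astype(float).reset_index(drop=True)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    for rsid in genotypes.variant_ids:
        g = genotypes.column(rsid).astype(float)
        g[g == MISSING] = np.nan
        nonmiss = g[~np.isnan(g)]
        if nonmiss.size == 0 or np.unique(nonmiss).size < 2:
            skipped.append({"rsid": rsid, "reason": "monomorphic or all-missing"})
            continue
        try:
            res = ols_fit(out, pd.Series(g, name=rsid), cov)
        except (ValueError, RankDeficiencyError) as exc:
            skipped.append({"rsid": rsid, "reason": str(exc)})
            continue
        results.append(res)
    return results, skipped


def expected_nominal_count(alpha: float, n_tests: int) -> int:
    """Chance expectation of nominal associations, rounded half away from zero."""
    return int(math.floor(alpha * n_tests + 0.5))


@dataclass
class ScanResult:
    """Exposure x covariable p-value grid with expected/observed nominal counts."""

    p_values: pd.DataFrame  # rows = exposures, columns = covariables
    alpha: float
    n_tests: int
    expected_nominal: int
    observed_nominal: int
    untestable: list = field(default_factory=list)

    @property
    def observed_fraction(self) -> float:
        return self.observed_nominal / self.n_tests if self.n_tests else float("nan")


def _pair_p_value(a: pd.Series, b: pd.Series) -> float:
    """Association p-value for one (exposure, covariable) pair, test by type.

    Categorical-categorical: Pearson chi-square on the contingency table
    (no continuity correction). Otherwise: OLS F-test of the association,
    regressing the continuous member on the other (dummy-coded if needed).
    """
    df = pd.concat([a.rename("a"), b.rename("b")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("too few complete pairs")
    a, b = df["a"], df["b"]
    a_cat = a.dtype == object or isinstance(a.dtype, pd.CategoricalDtype)
    b_cat = b.dtype == object or isinstance(b.dtype, pd.CategoricalDtype)
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("constant column")
    if a_cat and b_cat:
        table = pd.crosstab(a, b)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p)
    # make y the continuous member
    y, x = (b, a) if b_cat is False and a_cat else (a, b)
    X = pd.get_dummies(pd.DataFrame({"x": x}), drop_first=True, dtype=float) \
        if (x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype)) \
        else pd.DataFrame({"x": x.astype(float)})
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y.astype(float), X).fit()
    hyp = [f"{c} = 0" for c in X.columns if c != "const"]
    return float(fit.f_test(hyp).pvalue)


def confounder_scan(
    exposures: pd.DataFrame, covariables: pd.DataFrame, alpha: float = 0.05
) -> ScanResult:
    """Test every exposure against every covariable; tally nominal associations.

    Untestable pairs (constant columns, too few complete rows) are recorded
    and excluded from ``n_tests``.
    """
    grid = pd.DataFrame(
        np.nan, index=list(exposures.columns), columns=list(covariables.columns)
    )
    untestable = []
    for e in exposures.columns:
        for c in covariables.columns:
            try:
                grid.loc[e, c] = _pair_p_value(exposures[e], covariables[c])
            except ValueError as exc:
                untestable.append({"exposure": e, "covariable": c, "reason": str(exc)})
    n_tests = int(grid.notna().sum().sum())
    observed = int((grid < alpha).sum().sum())
    return ScanResult(
        p_values=grid, alpha=alpha, n_tests=n_tests,
        expected_nominal=expected_nominal_count(alpha, n_tests),
        observed_nominal=observed, untestable=untestable,
    )


def maternal_effect_fit(
    child_outcome: pd.Series,
    maternal_score: pd.Series,
    child_score: pd.Series,
    pcs: pd.DataFrame | None = None,
    outcome_label: str = "iq",
    exposure_label: str = "maternal_score",
) -> dict[str, RegressionResult]:
    """Duo-design contrast: maternal score on child outcome, unadjusted and
    adjusted for the child's own score (+ optional PCs).

    The adjusted fit is the one that isolates the intrauterine (maternal)
    pathway: the mother-child score correlation of ~0.5 otherwise transmits
    any offspring genetic effect into the maternal coefficient.
    """
    ms = pd.Series(maternal_score).reset_index(drop=True).rename(exposure_label)
    cs = pd.Series(child_score).reset_index(drop=True).rename("offspring_score")
    y = pd.Series(child_outcome).reset_index(drop=True)
    adj = pd.DataFrame({"offspring_score": cs})
    if pcs is not None:
        adj = pd.concat([adj, pcs.reset_index(drop=True)], axis=1)
    return {
        "unadjusted": ols_fit(y, ms, None, outcome_label, exposure_label),
        "adjusted": ols_fit(y, ms, adj, outcome_label, exposure_label),
    }


def classify_diabetes(fasting_glucose: float | None, hba1c: float | None) -> bool | None:
    """WHO rule: diabetes iff fasting glucose >= 7.0 mmol/l or HbA1c >= 6.5 %.

    A missing measurement never qualifies; both missing yields a missing
    classification (None).
    """
    fg_missing = fasting_glucose is None or (isinstance(fasting_glucose, float) and math.isnan(fasting_glucose))
    hb_missing = hba1c is None or (isinstance(hba1c, float) and math.isnan(hba1c))
    if fg_missing and hb_missing:
        return None
    return (not fg_missing and fasting_glucose >= WHO_FG_THRESHOLD) or \
           (not hb_missing and hba1c >= WHO_HBA1C_THRESHOLD)


def mgdl_to_mmoll(x: float) -> float:
    """Convert plasma glucose from mg/dl to mmol/l (molar mass 18.016 g/mol)."""
    if x < 0:
        raise ValueError("glucose concentration cannot be negative")
    return x / GLUCOSE_MGDL_PER_MMOLL


def classify_glycosuria(measurements, unit: str = "mmol/l") -> bool:
    """Glycosuria: plasma glucose >= 13.9 mmol/l (250 mg/dl) on >= 2 occasions.

    Measurements are compared against the threshold printed for their own
    unit (250/18.016 = 13.88 rounds to the printed 13.9, so converting before
    comparing would wrongly reject readings of exactly 250 mg/dl).
    """
    if unit == "mg/dl":
        threshold = GLYCOSURIA_THRESHOLD_MGDL
    elif unit == "mmol/l":
        threshold = GLYCOSURIA_THRESHOLD_MMOLL
    else:
        raise ValueError(f"unknown unit {unit!r}")
    qualifying = sum(1 for m in measurements
                     if m is not None and not math.isnan(m) and m >= threshold)
    return qualifying >= 2


def diabetes_category(
    pre_existing: bool, gestational: bool, glycosuria: bool
) -> tuple[str, int]:
    """Mutually exclusive maternal category plus the combined 0/1 exposure.

    Precedence: pre-existing > gestational > glycosuria > none.
    """
    if pre_existing:
        cat = "pre_existing"
    elif gestational:
        cat = "gestational"
    elif glycosuria:
        cat = "glycosuria"
    else:
        cat = "none"
    return cat, int(pre_existing or gestational or glycosuria)
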