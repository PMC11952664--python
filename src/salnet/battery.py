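"""The moderated linear-model battery and its summary decompositions.

Eight fixed-effects OLS models relate past-year violence exposure (X2), a
female indicator (X1), the two salience-network metrics (M1 expansion, M2
connectivity), and depression severity (Y):

    1:  X2 ~ X1
    2:  Y  ~ X1 + X2 + X1:X2
    3:  M1 ~ X1 + X2 + X1:X2
    4:  M2 ~ X1 + X2 + X1:X2
    5:  Y  ~ X1 + M1 + X1:M1
    6:  Y  ~ X1 + M2 + X1:M2
    7:  Y  ~ X1 + X2 + M1 + X1:M1
    8:  Y  ~ X1 + X2 + M2 + X1:M2

Each model is fit with four covariate sets (none; demographics; the lagged
dependent variable from the visit two years prior; both). All non-indicator
variables are z-scored on the analysis sample before fitting, and
interaction columns are built after scaling (scale-then-multiply). No
multiple-testing correction is applied across the battery; the report
carries the count of tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelFit",
    "BatteryReport",
    "MODEL_TERMS",
    "COVARIATE_SETS",
    "standardize",
    "fit_battery_model",
    "stratified_correlation",
    "two_group_f",
    "impute_metrics_time1",
    "run_battery",
]

INDICATOR_COLUMNS = ("sex", "black", "white", "hispanic")

# dependent variable and regressor terms per model index
MODEL_TERMS: dict[int, tuple[str, list[str]]] = {
    1: ("violence", ["sex"]),
    2: ("depression", ["sex", "violence", "sex:violence"]),
    3: ("expansion", ["sex", "violence", "sex:violence"]),
    4: ("connectivity", ["sex", "violence", "sex:violence"]),
    5: ("depression", ["sex", "expansion", "sex:expansion"]),
    6: ("depression", ["sex", "connectivity", "sex:connectivity"]),
    7: ("depression", ["sex", "violence", "expansion", "sex:expansion"]),
    8: ("depression", ["sex", "violence", "connectivity", "sex:connectivity"]),
}

DEMOGRAPHIC_COVARIATES = ["age", "black", "white", "hispanic", "bmi_pct", "puberty", "ipr"]

# lagged dependent variable per model (the visit two years prior)
LAGGED_OUTCOME = {
    1: "violence_t1",
    2: "depression_t1",
    3: "expansion_t1",
    4: "connectivity_t1",
    5: "depression_t1",
    6: "depression_t1",
    7: "depression_t1",
    8: "depression_t1",
}

COVARIATE_SETS = ("none", "lagged", "demographic", "both")

# coefficient label per term, following the beta_j^(k) naming of the battery
_BETA_INDEX = {
    "const": 0,
    "sex": 1,
    "violence": 2,
    "sex:violence": 3,
    "expansion": 4,
    "connectivity": 4,
    "sex:expansion": 5,
    "sex:connectivity": 5,
}


@dataclass
class ModelFit:
    """One fitted battery model with its coefficient table."""

    model_index: int
    covariate_set: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    sigma2: float
    n_obs: int

    def beta_label(self, term: str) -> str:
        j = _BETA_INDEX.get(term)
        return f"beta{j}({self.model_index})" if j is not None else term

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_index,
                "covariate_set": self.covariate_set,
                "term": self.params.index,
                "beta_label": [self.beta_label(t) for t in self.params.index],
                "estimate": self.params.values,
                "se": self.bse.values,
                "t": self.tvalues.values,
                "p": self.pvalues.values,
                "df_resid": self.df_resid,
            }
        )


def standardize(
    table: pd.DataFrame,
    indicator_columns: tuple[str, ...] = INDICATOR_COLUMNS,
) -> pd.DataFrame:
    """z-score every non-indicator numeric column on the analysis sample.

    Indicator columns pass through untouched; interaction terms must be
    built AFTER this step. Zero-variance columns raise an error naming the
    column. NaN entries are ignored in the moments and preserved.
    """
    out = table.copy()
    for col in out.columns:
        if col in indicator_columns or not pd.api.types.is_numeric_dtype(out[col]):
            continue
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column '{col}' has zero variance; cannot standardize")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def _interaction(table: pd.DataFrame, term: str) -> pd.Series:
    left, right = term.split(":")
    return table[left] * table[right]


def _design(table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for term in terms:
        X[term] = _interaction(table, term) if ":" in term else table[term]
    return sm.add_constant(X, has_constant="add")


def fit_battery_model(
    k: int,
    table: pd.DataFrame,
    covariate_set: str = "none",
    standardized: bool = True,
) -> ModelFit:
    """OLS fit of model ``k`` on exactly its equation terms plus covariates.

    ``standardized=True`` (the battery's reporting convention) z-scores all
    non-indicator columns on the complete-case analysis sample first;
    interaction products are formed afterwards.
    """
    if k not in MODEL_TERMS:
        raise ValueError(f"model index {k} outside 1..8")
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate set '{covariate_set}'")
    outcome, terms = MODEL_TERMS[k]
    covariates: list[str] = []
    if covariate_set in ("demographic", "both"):
        covariates += DEMOGRAPHIC_COVARIATES
    if covariate_set in ("lagged", "both"):
        covariates.append(LAGGED_OUTCOME[k])

    base_terms = [t for t in terms if ":" not in t]
    needed = sorted({outcome, *base_terms, *covariates})
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    data = table[needed].dropna()
    if standardized:
        data = standardize(data)
    X = _design(data, terms + covariates)
    y = data[outcome]
    if len(data) <= X.shape[1]:
        raise ValueError("not enough observations for the parameter count")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.values[:, 1:], rowvar=False)
        bad = [X.columns[1:][i] for i in range(corr.shape[0])
               if np.any(np.abs(np.delete(corr[i], i)) > 1 - 1e-10)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        model_index=k,
        covariate_set=covariate_set,
        terms=terms + covariates,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        df_resid=int(res.df_resid),
        sigma2=float(res.mse_resid),
        n_obs=int(res.nobs),
    )


def stratified_correlation(
    table: pd.DataFrame, x: str, y: str, group: int
) -> tuple[float, float, int, float]:
    """Pearson r of (x, y) within one sex stratum, with its t test.

    Returns (r, t, df, p) with t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2, and a
    two-sided p from the t distribution.
    """
    sub = table.loc[table["sex"] == group, [x, y]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"stratum sex=={group} has fewer than 3 complete cases")
    xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in a correlation input column")
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return r, float(np.inf) * np.sign(r), df, 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), df, float(p)


def two_group_f(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, int, int]:
    """One-way two-group ANOVA F from summary statistics.

    F is the between-group mean square over the pooled within-group mean
    square, with df (1, n1+n2-2). Degenerate pooled variance: F = 0 when
    the means are equal, infinity otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df2 = n1 + n2 - 2
    grand = (n1 * mean1 + n2 * mean2) / (n1 + n2)
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    msw = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df2
    if msw == 0:
        return (0.0 if ssb == 0 else float("inf")), 1, df2
    return float(ssb / msw), 1, df2


def impute_metrics_time1(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("expansion_t1", "connectivity_t1"),
    predictors: list[str] | None = None,
    min_complete: int = 10,
) -> pd.DataFrame:
    """Single regression imputation of missing time-1 network metrics.

    Each missing metric is filled with the OLS prediction from time-1-only
    predictors fit on complete cases; time-2 columns are never used. Adds a
    boolean ``<metric>_imputed`` flag column per imputed metric.
    """
    if predictors is None:
        candidates = ["sex", "black", "white", "hispanic", "ipr",
                      "depression_t1", "violence_t1"]
        predictors = [c for c in candidates if c in table.columns]
    out = table.copy()
    for metric in metrics:
        if metric not in out.columns:
            continue
        missing = out[metric].isna()
        out[f"{metric}_imputed"] = missing
        if not missing.any():
            continue
        preds = [p for p in predictors if p != metric]
        complete = out.loc[~missing, [metric, *preds]].dropna()
        if len(complete) == 0:
            raise ValueError(f"no complete cases to impute '{metric}'")
        if len(complete) < min_complete:
            raise ValueError(
                f"only {len(complete)} complete cases for '{metric}' "
                f"(need >= {min_complete})"
            )
        X = sm.add_constant(complete[preds], has_constant="add")
        res = sm.OLS(complete[metric], X).fit()
        Xmiss = sm.add_constant(out.loc[missing, preds], has_constant="add")
        Xmiss = Xmiss[X.columns]
        out.loc[missing, metric] = res.predict(Xmiss)
    return out


@dataclass
class BatteryReport:
    """All fits, decompositions, and bookkeeping from one battery run."""

    fits: list[ModelFit]
    coefficients: pd.DataFrame
    correlations: pd.DataFrame
    violence_anova: dict
    group_means: dict
    n_tests: int
    n_subjects: int
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"battery: {len(self.fits)} model fits on n={self.n_subjects} subjects",
            f"hypothesis tests performed (uncorrected): {self.n_tests}",
            "raw violence means by sex: "
            f"female={self.group_means['female']:.2f}, male={self.group_means['male']:.2f}",
            "violence-by-sex ANOVA: F(%d,%d)=%.2f, p=%.4g"
            % (
                self.violence_anova["df1"],
                self.violence_anova["df2"],
                self.violence_anova["F"],
                self.violence_anova["p"],
            ),
        ]
        for _, row in self.correlations.iterrows():
            lines.append(
                f"r({row['x']}, {row['y']} | {row['stratum']}) = {row['r']:.3f}, "
                f"t({row['df']}) = {row['t']:.3f}, p = {row['p']:.4g}"
            )
        key = self.coefficients
        focal = key[(key["model"] == 2) & (key["covariate_set"] == "none")
                    & (key["term"] == "sex:violence")]
        if len(focal):
            row = focal.iloc[0]
            lines.append(
                f"sex-by-violence interaction on depression: "
                f"{row['beta_label']} = {row['estimate']:.3f}, p = {row['p']:.4g}"
            )
        return "\n".join(lines)


def run_battery(table: pd.DataFrame, impute: bool = True) -> BatteryReport:
    """Fit all 8 models x 4 covariate sets plus the stratified decompositions.

    Missing time-1 network metrics are imputed first (time-1 predictors
    only). The stratified decompositions are the violence-depression and
    connectivity-depression correlations within each sex, and the two-group
    ANOVA of violence counts by sex computed from the raw subsample
    summaries.
    """
    data = impute_metrics_time1(table) if impute else table.copy()

    fits = [
        fit_battery_model(k, data, covariate_set=cs)
        for k in MODEL_TERMS
        for cs in COVARIATE_SETS
    ]
    coefficients = pd.concat([f.tidy() for f in fits], ignore_index=True)

    corr_rows = []
    for x, y in (("violence", "depression"), ("connectivity", "depression")):
        for group, name in ((1, "female"), (0, "male")):
            r, t, df, p = stratified_correlation(data, x, y, group)
            corr_rows.append(
                {"x": x, "y": y, "stratum": name, "r": r, "t": t, "df": df, "p": p}
            )
    correlations = pd.DataFrame(corr_rows)

    fem = data.loc[data["sex"] == 1, "violence"].dropna()
    mal = data.loc[data["sex"] == 0, "violence"].dropna()
    F, df1, df2 = two_group_f(
        len(fem), fem.mean(), fem.std(ddof=1), len(mal), mal.mean(), mal.std(ddof=1)
    )
    anova = {"F": F, "df1": df1, "df2": df2, "p": float(stats.f.sf(F, df1, df2))}

    n_tests = int(sum(len(f.params) for f in fits)) + len(corr_rows) + 1
    return BatteryReport(
        fits=fits,
        coefficients=coefficients,
        correlations=correlations,
        violence_anova=anova,
        group_means={"female": float(fem.mean()), "male": float(mal.mean())},
        n_tests=n_tests,
        n_subjects=int(len(data)),
        notes=["no multiple-testing correction applied across the battery"],
    )
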