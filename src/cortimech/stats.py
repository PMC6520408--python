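"""Cohort statistics: normality gate, correlation matrices, regression.

Reproduces the study's analysis chain on the eight-measurement cohort
table: Shapiro-Wilk normality per column decides between Spearman rank
correlations (full cohort, robust to the single highly porous specimen)
and Pearson correlations (after excluding that specimen); a porosity-cutoff
exclusion rule; ordinary-least-squares multiple regression of strength on
selected predictors; and per-column summary statistics.  Correlations are
labelled strong (|r| > 0.6), moderate (0.4-0.6) or weak (< 0.4).

Missing values (e.g. the RUS column of a gated specimen) are handled by
pairwise deletion, so the RUS correlations run on n = 19 while the rest
keep n = 20, as in the study.  p-values are two-sided with no
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ANALYSIS_COLUMNS",
    "load_cohort_csv",
    "normality_gate",
    "strength_label",
    "CorrelationReport",
    "correlation_matrix",
    "exclusion_rule",
    "RegressionSummary",
    "multiple_regression",
    "cohort_summary",
    "CorrelationStudy",
    "CorrelationStudyResults",
]

#: Measurement columns of the cohort table, in reporting order.
ANALYSIS_COLUMNS = [
    "density", "ct_porosity", "rus_E3", "bwus_C33",
    "indentation_E", "compression_E", "ucs", "bmda",
]

_COLUMN_UNITS = {
    "density": "mg/mm^3", "ct_porosity": "%", "rus_E3": "GPa",
    "bwus_C33": "GPa", "indentation_E": "GPa", "compression_E": "GPa",
    "ucs": "MPa", "bmda": "mg/mm^3",
}


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-specimen cohort table (one row per specimen).

    Accepts either a plain header or the two-row name/units header written
    by the pipeline.
    """
    df = pd.read_csv(path)
    if df.iloc[0].astype(str).str.contains("GPa|MPa|mg/mm|%|-").any():
        df = pd.read_csv(path, header=[0, 1])
        df.columns = df.columns.get_level_values(0)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().any():
            df[col] = converted
    return df


def normality_gate(table: pd.DataFrame, alpha: float = 0.05,
                   columns: list[str] | None = None) -> tuple[str, dict]:
    """Shapiro-Wilk per analysis column; any failure selects Spearman.

    Returns ("pearson" | "spearman", per-column p-values).  Non-normal
    data (typically caused by one highly porous specimen) force the
    rank-based branch for the full-cohort analysis; Pearson remains
    permitted on the exclusion subset.
    """
    columns = columns or [c for c in ANALYSIS_COLUMNS if c in table.columns]
    pvals = {}
    for c in columns:
        x = table[c].dropna().to_numpy(float)
        if x.size < 3 or np.ptp(x) == 0:
            pvals[c] = np.nan
            continue
        pvals[c] = float(sps.shapiro(x).pvalue)
    method = "spearman" if any(p < alpha for p in pvals.values()
                               if np.isfinite(p)) else "pearson"
    return method, pvals


def strength_label(r: float) -> str:
    """Study convention: strong > 0.6, moderate 0.4-0.6, weak < 0.4 (|r|)."""
    a = abs(r)
    if a > 0.6:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


@dataclass
class CorrelationReport:
    """Pairwise correlation matrix with p-values, n and strength labels."""

    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    excluded_ids: list = field(default_factory=list)
    exact_p: pd.DataFrame | None = None  # permutation p-values (optional)

    def labels(self) -> pd.DataFrame:
        return self.r.map(strength_label)

    def summary(self) -> str:
        lines = [f"Correlation matrix ({self.method}, pairwise complete)",
                 "-" * 60]
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[:i]:
                r, p, n = self.r.loc[a, b], self.p.loc[a, b], self.n.loc[a, b]
                stars = "**" if p < 0.01 else "*" if p < 0.05 else "  "
                lines.append(f"{a:>14} ~ {b:<14} r={r:+.2f}{stars} "
                             f"p={p:.3g} n={int(n)} ({strength_label(r)})")
        if self.excluded_ids:
            lines.append(f"excluded specimens: {self.excluded_ids}")
        return "\n".join(lines)


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       exclusions: list | None = None,
                       columns: list[str] | None = None,
                       exact_p: bool = False,
                       n_permutations: int = 10000,
                       seed: int = 0) -> CorrelationReport:
    """Pairwise-complete correlation matrix with two-sided p-values.

    Spearman uses average ranks for ties.  ``exclusions`` lists specimen
    ids to drop first.  With ``exact_p`` a permutation p-value is also
    computed per pair (useful at n <= 20 where the asymptotic Spearman
    p-value is approximate).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    excluded = list(exclusions or [])
    if excluded and "specimen_id" in table.columns:
        table = table[~table["specimen_id"].isin(excluded)]
    columns = columns or [c for c in ANALYSIS_COLUMNS if c in table.columns]
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    ep = np.eye(k) if exact_p else None
    rng = np.random.default_rng(seed)
    fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i in range(k):
        n[i, i] = table[columns[i]].notna().sum()
        for j in range(i):
            sub = table[[columns[i], columns[j]]].dropna()
            x, y = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            n[i, j] = n[j, i] = x.size
            if x.size < 3:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                continue
            res = fn(x, y)
            r[i, j] = r[j, i] = res.statistic if hasattr(res, "statistic") \
                else res[0]
            p[i, j] = p[j, i] = res.pvalue if hasattr(res, "pvalue") else res[1]
            if exact_p:
                obs = r[i, j]
                perm = np.empty(n_permutations)
                for t in range(n_permutations):
                    perm[t] = fn(x, rng.permutation(y))[0]
                ep[i, j] = ep[j, i] = (np.sum(np.abs(perm) >= abs(obs)) + 1) \
                    / (n_permutations + 1)
    idx = pd.Index(columns)
    return CorrelationReport(
        method=method,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        excluded_ids=excluded,
        exact_p=None if ep is None else pd.DataFrame(ep, index=idx, columns=idx),
    )


def exclusion_rule(table: pd.DataFrame, porosity_cutoff: float = 0.35,
                   porosity_column: str = "ct_porosity",
                   as_fraction: bool | None = None,
                   ) -> tuple[pd.DataFrame, list]:
    """Drop rows whose porosity exceeds the cutoff; report the excluded ids.

    The cutoff is a fraction; a table storing porosity in percent is
    detected automatically (override with ``as_fraction``).
    """
    por = table[porosity_column].to_numpy(float)
    if as_fraction is None:
        as_fraction = np.nanmax(por) <= 1.0
    cutoff = porosity_cutoff if as_fraction else porosity_cutoff * 100.0
    drop = table[porosity_column] > cutoff
    ids = (table.loc[drop, "specimen_id"].tolist()
           if "specimen_id" in table.columns else list(table.index[drop]))
    return table[~drop].copy(), ids


@dataclass
class RegressionSummary:
    """OLS fit of a response on several predictors, study conventions."""

    response: str
    predictors: list[str]
    r_signed: float          # multiple R, sign from the porosity coefficient
    r_squared: float
    p_model: float
    p_predictors: dict[str, float]
    coefficients: dict[str, float]
    n: int
    condition_number: float
    collinear: bool

    def summary(self) -> str:
        lines = [f"OLS: {self.response} ~ {' + '.join(self.predictors)}",
                 "-" * 60,
                 f"n = {self.n}   R = {self.r_signed:+.2f}   "
                 f"R^2 = {self.r_squared:.3f}   p(model) = {self.p_model:.3g}"]
        for name in self.predictors:
            lines.append(f"  {name:>14}: coef {self.coefficients[name]:+.4g}"
                         f"  p = {self.p_predictors[name]:.3g}")
        if self.collinear:
            lines.append(f"  warning: predictors nearly collinear "
                         f"(condition number {self.condition_number:.3g})")
        return "\n".join(lines)


def multiple_regression(table: pd.DataFrame, response: str = "ucs",
                        predictors: list[str] | None = None,
                        cond_threshold: float = 1e3) -> RegressionSummary:
    """OLS with intercept; signed multiple correlation per study convention.

    The study reports the multiple correlation with the sign of the
    dominant (porosity) predictor, so R = sqrt(R^2) carries the sign of
    the ``ct_porosity`` coefficient when present (otherwise of the
    largest-|t| predictor).  Nearly collinear predictors are flagged via
    the standardised design's condition number.
    """
    predictors = predictors or ["ct_porosity", "bmda"]
    sub = table[[response] + predictors].dropna()
    y = sub[response].to_numpy(float)
    X = sub[predictors].to_numpy(float)
    Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    cond = float(np.linalg.cond(Xs))
    collinear = cond > cond_threshold
    if collinear:
        warnings.warn(f"predictors nearly collinear (condition number "
                      f"{cond:.3g})", RuntimeWarning, stacklevel=2)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = dict(zip(predictors, fit.params[1:]))
    pvals = dict(zip(predictors, fit.pvalues[1:]))
    if "ct_porosity" in predictors:
        sign = np.sign(coefs["ct_porosity"])
    else:
        tvals = dict(zip(predictors, fit.tvalues[1:]))
        sign = np.sign(coefs[max(tvals, key=lambda k: abs(tvals[k]))])
    sign = sign if sign != 0 else 1.0
    return RegressionSummary(
        response=response, predictors=predictors,
        r_signed=float(sign * np.sqrt(fit.rsquared)),
        r_squared=float(fit.rsquared),
        p_model=float(fit.f_pvalue),
        p_predictors=pvals, coefficients=coefs,
        n=int(sub.shape[0]), condition_number=cond, collinear=collinear)


def cohort_summary(table: pd.DataFrame,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Mean / median / SD / range per measurement column (non-missing n)."""
    columns = columns or [c for c in ANALYSIS_COLUMNS if c in table.columns]
    rows = []
    for c in columns:
        x = table[c].dropna().to_numpy(float)
        rows.append({
            "measurement": c, "unit": _COLUMN_UNITS.get(c, ""),
            "n": x.size, "mean": x.mean() if x.size else np.nan,
            "median": np.median(x) if x.size else np.nan,
            "sd": x.std(ddof=1) if x.size > 1 else 0.0,
            "min": x.min() if x.size else np.nan,
            "max": x.max() if x.size else np.nan,
        })
    return pd.DataFrame(rows).set_index("measurement")


@dataclass
class CorrelationStudyResults:
    """Full statistics stage: gate decision, matrices, regression, summary."""

    method_full: str
    shapiro_p: dict
    full_cohort: CorrelationReport
    excluded_subset: CorrelationReport
    excluded_ids: list
    regression: RegressionSummary | None
    table_summary: pd.DataFrame

    def summary(self) -> str:
        parts = [
            f"Normality gate: full-cohort method = {self.method_full}",
            "",
            self.full_cohort.summary(),
            "",
            f"Exclusion subset (porosity gate, n excluded = "
            f"{len(self.excluded_ids)}):",
            self.excluded_subset.summary(),
        ]
        if self.regression is not None:
            parts += ["", self.regression.summary()]
        parts += ["", "Cohort summary:", self.table_summary.to_string()]
        return "\n".join(parts)


class CorrelationStudy:
    """Statistics stage of the measurement chain, as a fit-able model.

    ``fit()`` runs: Shapiro-Wilk gate -> full-cohort correlations (Spearman
    when any column is non-normal) -> porosity-cutoff exclusion -> Pearson
    correlations on the subset -> multiple regression of strength on
    porosity and ash density -> per-column summary.
    """

    def __init__(self, table: pd.DataFrame, porosity_cutoff: float = 0.35,
                 alpha: float = 0.05,
                 regression_predictors: list[str] | None = None):
        self.table = table
        self.porosity_cutoff = porosity_cutoff
        self.alpha = alpha
        self.regression_predictors = regression_predictors or \
            ["ct_porosity", "bmda"]

    def fit(self) -> CorrelationStudyResults:
        method, shapiro_p = normality_gate(self.table, self.alpha)
        full = correlation_matrix(self.table, method=method)
        reduced, excluded = exclusion_rule(self.table, self.porosity_cutoff)
        subset = correlation_matrix(reduced, method="pearson")
        subset.excluded_ids = excluded
        regression = None
        preds = [p for p in self.regression_predictors
                 if p in reduced.columns]
        if preds and "ucs" in reduced.columns and reduced.shape[0] > len(preds) + 2:
            regression = multiple_regression(reduced, "ucs", preds)
        return CorrelationStudyResults(
            method_full=method, shapiro_p=shapiro_p, full_cohort=full,
            excluded_subset=subset, excluded_ids=excluded,
            regression=regression, table_summary=cohort_summary(self.table))
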