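"""Group-level statistics: one-way MANOVA (Pillai), Bonferroni-corrected
univariate follow-up ANOVAs with partial eta-squared, assumption screening,
partial Spearman correlations and demographic comparisons.

Conventions
-----------
* All tests are two-sided; the demographic t-test assumes equal variances.
* The omnibus test is Pillai's trace with its standard F approximation; for
  a two-group design all four classical multivariate statistics yield the
  same F, and Pillai is the conventional choice for its robustness to
  normality violations.
* Follow-up ANOVAs use pairwise inclusion (each DV keeps every subject that
  has it) and a Bonferroni per-test threshold alpha/m.
* Partial Spearman: both variables are rank-transformed, residualized on the
  (rank-transformed) covariates by least squares, and the product-moment
  correlation of the residuals is reported with a t-based p-value on
  n - 2 - k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError, ParameterError
from .features import DV_FOLLOWUP, DV_MANOVA, CohortTable

GROUP_COL = "group"


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ManovaResult:
    statistic_name: str
    statistic_value: float
    F_approx: float
    df_between: int
    df_error: int
    p_value: float
    n: int
    dvs: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.statistic_value,
            "F": self.F_approx,
            "df": [self.df_between, self.df_error],
            "p": self.p_value,
            "n": self.n,
            "dvs": list(self.dvs),
        }


@dataclass
class AnovaResult:
    dv_name: str
    F: float
    df1: int
    df2: int
    p_raw: float
    p_threshold_bonferroni: float
    significant: bool
    partial_eta2: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "dv": self.dv_name,
            "F": self.F,
            "df": [self.df1, self.df2],
            "p": self.p_raw,
            "p_threshold": self.p_threshold_bonferroni,
            "significant": self.significant,
            "partial_eta2": self.partial_eta2,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "group_ns": self.group_ns,
        }


@dataclass
class AssumptionReport:
    shapiro: dict[tuple[str, str], tuple[float, float]]
    levene: dict[str, tuple[float, float]]
    mahalanobis_d2: np.ndarray
    mahalanobis_cutoff: float
    outlier_subjects: list[str]
    max_abs_pearson_r: float
    multicollinearity_flag: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "shapiro": {f"{dv}|{g}": list(wp) for (dv, g), wp in self.shapiro.items()},
            "levene": {dv: list(fp) for dv, fp in self.levene.items()},
            "mahalanobis_max_d2": float(np.max(self.mahalanobis_d2))
            if self.mahalanobis_d2.size else float("nan"),
            "mahalanobis_cutoff": self.mahalanobis_cutoff,
            "outlier_subjects": self.outlier_subjects,
            "max_abs_pearson_r": self.max_abs_pearson_r,
            "multicollinearity_flag": self.multicollinearity_flag,
            "notes": self.notes,
        }


@dataclass
class PartialCorrelationResult:
    x: str
    y: str
    covariates: tuple[str, ...]
    rho: float
    n: int
    p_value: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "x": self.x, "y": self.y, "covariates": list(self.covariates),
            "rho": self.rho, "n": self.n, "p": self.p_value, "note": self.note,
        }


# ---------------------------------------------------------------------------
# helpers


def _as_frame(cohort, which: str = "data") -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return getattr(cohort, "analysis" if which == "analysis" else "data")
    return cohort


def _group_arrays(df: pd.DataFrame, dv: str) -> dict[str, np.ndarray]:
    sub = df[[GROUP_COL, dv]].dropna()
    return {g: grp[dv].to_numpy(dtype=float) for g, grp in sub.groupby(GROUP_COL)}


# ---------------------------------------------------------------------------
# operations


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m (family-wise error control)."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return alpha / m


def anova_two_group(x: np.ndarray, y: np.ndarray) -> tuple[float, int, int, float, float]:
    """One-way two-group ANOVA on raw arrays.

    Returns ``(F, df1, df2, p, partial_eta2)`` with the sums of squares
    computed directly: SSB between groups, SSW within, F = SSB / (SSW/df2),
    partial eta2 = SSB / (SSB + SSW).  Zero within-group variance yields
    F = 0 for equal means and an infinite-F flag otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InputError("need >= 2 observations per group")
    n = n1 + n2
    grand = (x.sum() + y.sum()) / n
    ssb = n1 * (x.mean() - grand) ** 2 + n2 * (y.mean() - grand) ** 2
    ssw = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0, 0.0
        return float("inf"), df1, df2, 0.0, 1.0
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ssb / (ssb + ssw)
    return float(f), df1, df2, p, float(eta2)


def run_anova(
    cohort, dv: str, m_tests: int = len(DV_FOLLOWUP), alpha: float = 0.05
) -> AnovaResult:
    """Two-group one-way ANOVA for one DV, with pairwise (per-DV) inclusion."""
    df = _as_frame(cohort, "data")
    groups = _group_arrays(df, dv)
    if len(groups) != 2:
        raise InputError(f"need exactly 2 groups with data for DV {dv!r}, got {len(groups)}")
    (g1, x), (g2, y) = sorted(groups.items())
    f, df1, df2, p, eta2 = anova_two_group(x, y)
    thr = bonferroni_threshold(alpha, m_tests)
    return AnovaResult(
        dv_name=dv, F=f, df1=df1, df2=df2, p_raw=p,
        p_threshold_bonferroni=thr, significant=bool(p < thr), partial_eta2=eta2,
        group_means={g1: float(x.mean()), g2: float(y.mean())},
        group_sds={g1: float(x.std(ddof=1)), g2: float(y.std(ddof=1))},
        group_ns={g1: int(x.size), g2: int(y.size)},
    )


def run_manova(cohort, dvs: Sequence[str] | None = None) -> ManovaResult:
    """One-way MANOVA (Pillai's trace) on complete cases.

    Pillai's trace V = tr[B (B + W)^-1] from the between/within SSCP
    matrices, with the standard F approximation; for two groups the F is
    exact with df (p, N - p - 1) and coincides with the Hotelling T^2
    transform.
    """
    df = _as_frame(cohort, "analysis")
    if dvs is None:
        dvs = list(cohort.dv_names) if isinstance(cohort, CohortTable) else list(DV_MANOVA)
    dvs = list(dvs)
    sub = df[[GROUP_COL] + dvs].dropna()
    labels = sub[GROUP_COL].to_numpy()
    X = sub[dvs].to_numpy(dtype=float)
    n_total, p = X.shape
    group_names = np.unique(labels)
    g = group_names.size
    if g < 2:
        raise InputError("need at least 2 groups for MANOVA")
    if n_total < p + g:
        raise InputError(f"need >= {p + g} complete cases for {p} DVs, have {n_total}")

    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for name in group_names:
        Xi = X[labels == name]
        d = Xi.mean(axis=0) - grand
        B += Xi.shape[0] * np.outer(d, d)
        R = Xi - Xi.mean(axis=0)
        W += R.T @ R
    T = B + W
    try:
        V = float(np.trace(np.linalg.solve(T, B)))
    except np.linalg.LinAlgError as exc:
        raise InputError(
            "singular total SSCP matrix: DVs are linearly dependent; "
            "reduce or decorrelate the DV set"
        ) from exc
    V = min(max(V, 0.0), float(min(p, g - 1)))

    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n_total - g - p - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    if df2 <= 0:
        raise InputError("not enough error degrees of freedom for the F approximation")
    ratio = (V / s) / (1.0 - V / s) if V < s else float("inf")
    F = (df2 / df1) * ratio if np.isfinite(ratio) else float("inf")
    pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ManovaResult(
        statistic_name="Pillai's trace", statistic_value=V, F_approx=float(F),
        df_between=df1, df_error=df2, p_value=pval, n=n_total, dvs=tuple(dvs),
    )


def check_assumptions(
    cohort,
    dvs: Sequence[str] | None = None,
    outlier_p: float = 0.001,
    levene_center: str = "mean",
    collinearity_r: float = 0.9,
) -> AssumptionReport:
    """Screen the standard MANOVA assumptions.

    Shapiro-Wilk on per-group residuals per DV (skipped below n = 3);
    Levene (mean-centered by default) per DV; Mahalanobis distance of each
    complete case to the pooled centroid with a chi-squared cutoff at
    ``outlier_p``; maximum absolute pairwise Pearson r among the DVs with a
    multicollinearity flag above ``collinearity_r``.
    """
    df = _as_frame(cohort, "analysis")
    if dvs is None:
        dvs = list(cohort.dv_names) if isinstance(cohort, CohortTable) else list(DV_MANOVA)
    dvs = list(dvs)
    notes: list[str] = []

    shapiro: dict[tuple[str, str], tuple[float, float]] = {}
    levene: dict[str, tuple[float, float]] = {}
    for dv in dvs:
        groups = _group_arrays(df, dv)
        for gname, arr in groups.items():
            if arr.size < 3:
                notes.append(f"Shapiro-Wilk skipped for {dv}|{gname}: n < 3")
                continue
            w, p = sps.shapiro(arr)
            shapiro[(dv, gname)] = (float(w), float(p))
        if len(groups) >= 2 and all(a.size >= 2 for a in groups.values()):
            f, p = sps.levene(*groups.values(), center=levene_center)
            levene[dv] = (float(f), float(p))
        else:
            notes.append(f"Levene skipped for {dv}: insufficient group data")

    sub = df[["subject_id"] + dvs].dropna() if "subject_id" in df else df[dvs].dropna()
    X = sub[dvs].to_numpy(dtype=float)
    p_dim = len(dvs)
    cutoff = float(sps.chi2.ppf(1.0 - outlier_p, p_dim))
    if X.shape[0] > p_dim + 1:
        S = np.cov(X, rowvar=False)
        centered = X - X.mean(axis=0)
        try:
            d2 = np.einsum("ij,ij->i", centered, np.linalg.solve(S, centered.T).T)
        except np.linalg.LinAlgError:
            d2 = np.full(X.shape[0], np.nan)
            notes.append("Mahalanobis skipped: singular covariance")
    else:
        d2 = np.full(X.shape[0], np.nan)
        notes.append("Mahalanobis skipped: too few complete cases")
    out_mask = np.nan_to_num(d2, nan=0.0) > cutoff
    if "subject_id" in sub:
        outliers = list(sub.loc[out_mask, "subject_id"]) if out_mask.any() else []
    else:
        outliers = list(np.flatnonzero(out_mask).astype(str))

    C = np.corrcoef(df[dvs].dropna().to_numpy(dtype=float), rowvar=False)
    if p_dim > 1 and np.ndim(C) == 2:
        off = np.abs(C[~np.eye(p_dim, dtype=bool)])
        max_r = float(np.nanmax(off)) if off.size else 0.0
    else:
        max_r = 0.0
    return AssumptionReport(
        shapiro=shapiro, levene=levene, mahalanobis_d2=d2,
        mahalanobis_cutoff=cutoff, outlier_subjects=outliers,
        max_abs_pearson_r=max_r,
        multicollinearity_flag=bool(max_r > collinearity_r), notes=notes,
    )


def partial_spearman(
    df: pd.DataFrame, x: str, y: str, covariates: Sequence[str] = ("iq", "sex_code")
) -> PartialCorrelationResult:
    """Spearman rank correlation of ``x`` and ``y`` partialling out covariates.

    Ranks are residualized on the (ranked) covariates by least squares; the
    Pearson correlation of the residuals is the partial rho, with a t-based
    p-value on n - 2 - k degrees of freedom.
    """
    covariates = tuple(covariates)
    cols = [x, y, *covariates]
    sub = df[cols].dropna()
    n = len(sub)
    k = len(covariates)
    if n < 4 or n - 2 - k < 1:
        return PartialCorrelationResult(x, y, covariates, float("nan"), n,
                                        float("nan"), note="too few complete rows")
    R = np.column_stack([sps.rankdata(sub[c].to_numpy(dtype=float)) for c in cols])
    if np.ptp(R[:, 0]) == 0 or np.ptp(R[:, 1]) == 0:
        return PartialCorrelationResult(x, y, covariates, float("nan"), n,
                                        float("nan"), note="constant variable")
    Z = np.column_stack([np.ones(n), R[:, 2:]])
    resid = []
    for j in (0, 1):
        beta, *_ = np.linalg.lstsq(Z, R[:, j], rcond=None)
        resid.append(R[:, j] - Z @ beta)
    rx, ry = resid
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return PartialCorrelationResult(x, y, covariates, float("nan"), n,
                                        float("nan"), note="degenerate residuals")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(rho) >= 1.0:
        pval = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho ** 2))
        pval = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrelationResult(x, y, covariates, rho, n, pval)


def compare_demographics(
    cohort,
    continuous: Sequence[str] = ("age_months", "usable_seconds"),
    categorical: Sequence[str] = ("sex",),
) -> pd.DataFrame:
    """Descriptive group comparisons: equal-variance t for continuous
    descriptors, Pearson chi-squared (uncorrected) for categorical counts."""
    df = _as_frame(cohort, "data")
    groups = sorted(df[GROUP_COL].dropna().unique())
    if len(groups) != 2:
        raise InputError("demographic comparison requires exactly 2 non-empty groups")
    g1, g2 = groups
    rows = []
    for var in continuous:
        if var not in df:
            continue
        a = df.loc[df[GROUP_COL] == g1, var].dropna().to_numpy(dtype=float)
        b = df.loc[df[GROUP_COL] == g2, var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append({"variable": var, "test": "t", "statistic": float("nan"),
                         "p": float("nan"), "note": "insufficient data"})
            continue
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append({"variable": var, "test": "t", "statistic": float(t),
                     "p": float(p), "note": ""})
    for var in categorical:
        if var not in df:
            continue
        table = pd.crosstab(df[GROUP_COL], df[var])
        if table.shape[1] < 2:
            rows.append({"variable": var, "test": "chi2", "statistic": float("nan"),
                         "p": float("nan"), "note": "category absent in both groups"})
            continue
        chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "p": float(p), "note": ""})
    return pd.DataFrame(rows)
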