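"""statsmodels-style model interface over the group statistics battery.

``SmileGroupModel`` is built from a :class:`~smiletrace.features.CohortTable`
(or a features DataFrame); ``fit()`` runs the omnibus MANOVA, the
Bonferroni-corrected follow-up ANOVAs, the assumption screen, the partial
Spearman correlations against IQ and sex within the clinical group, and the
demographic comparisons, returning a ``SmileGroupResults`` with a
``summary()`` table and a JSON-serializable ``to_dict()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .features import DV_FOLLOWUP, DV_MANOVA, CohortTable, assemble_cohort
from .stats import (
    AnovaResult,
    AssumptionReport,
    ManovaResult,
    PartialCorrelationResult,
    bonferroni_threshold,
    check_assumptions,
    compare_demographics,
    partial_spearman,
    run_anova,
    run_manova,
)

SEX_CODES = {"M": 0.0, "F": 1.0}


@dataclass
class SmileGroupResults:
    """Fitted results: estimates, effect sizes, diagnostics and summaries."""

    manova: ManovaResult
    anovas: list[AnovaResult]
    assumptions: AssumptionReport
    partial_correlations: list[PartialCorrelationResult]
    demographics: pd.DataFrame
    alpha: float
    m_tests: int
    n_analyzed: int
    n_excluded: int
    excluded: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_tests)

    def anova(self, dv: str) -> AnovaResult:
        for a in self.anovas:
            if a.dv_name == dv:
                return a
        raise KeyError(dv)

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "excluded": [{"subject_id": s, "missing": m} for s, m in self.excluded],
            "alpha": self.alpha,
            "m_tests": self.m_tests,
            "bonferroni_threshold": self.bonferroni_threshold,
            "manova": self.manova.to_dict(),
            "anovas": [a.to_dict() for a in self.anovas],
            "assumptions": self.assumptions.to_dict(),
            "partial_correlations": [c.to_dict() for c in self.partial_correlations],
            "demographics": self.demographics.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Smile dynamics group comparison".center(w))
        lines.append("=" * w)
        m = self.manova
        lines.append(
            f"Omnibus MANOVA ({m.statistic_name}): V = {m.statistic_value:.4f}, "
            f"F({m.df_between}, {m.df_error}) = {m.F_approx:.3f}, p = {m.p_value:.4g}"
        )
        lines.append(f"Complete cases analyzed: {self.n_analyzed}"
                     f"  (excluded listwise: {self.n_excluded})")
        lines.append("-" * w)
        thr = self.bonferroni_threshold
        lines.append(f"Follow-up ANOVAs (Bonferroni: p < {round(thr, 5)} for "
                     f"alpha = {self.alpha}, m = {self.m_tests})")
        hdr = f"{'DV':<14}{'F':>10}{'df':>10}{'p':>12}{'part.eta2':>11}{'sig':>5}"
        lines.append(hdr)
        for a in self.anovas:
            lines.append(
                f"{a.dv_name:<14}{a.F:>10.3f}{f'({a.df1},{a.df2})':>10}"
                f"{a.p_raw:>12.4g}{a.partial_eta2:>11.3f}{'*' if a.significant else '':>5}"
            )
        lines.append("-" * w)
        rep = self.assumptions
        lines.append(f"Assumptions: max |pairwise r| = {rep.max_abs_pearson_r:.3f}"
                     f"{' (collinearity flag)' if rep.multicollinearity_flag else ''};"
                     f" multivariate outliers: {len(rep.outlier_subjects)}")
        lev_viol = [dv for dv, (_, p) in rep.levene.items() if p < 0.05]
        lines.append("Levene p < 0.05 for: " + (", ".join(lev_viol) if lev_viol else "none"))
        if self.partial_correlations:
            lines.append("-" * w)
            lines.append("Partial Spearman correlations (within clinical group):")
            for c in self.partial_correlations:
                if np.isnan(c.rho):
                    lines.append(f"  {c.x} ~ {c.y} | {','.join(c.covariates)}: "
                                 f"unavailable ({c.note})")
                else:
                    lines.append(f"  {c.x} ~ {c.y} | {','.join(c.covariates)}: "
                                 f"rho = {c.rho:+.3f}, p = {c.p_value:.3f}, n = {c.n}")
        lines.append("=" * w)
        return "\n".join(lines)


class SmileGroupModel:
    """Two-group comparison of per-subject smile features.

    Parameters
    ----------
    cohort
        A :class:`CohortTable` (see :func:`smiletrace.features.assemble_cohort`).
    dvs
        DVs for the omnibus MANOVA (default: the 6-DV set with composite
        Social intensity).
    followup_dvs
        DV family for the univariate follow-ups (default: 7 DVs, Social
        intensity split into AU12 and AU06).
    correlation_group
        Group within which partial correlations against IQ/sex are computed
        (default "ASD"); skipped if absent.
    """

    def __init__(
        self,
        cohort: CohortTable,
        dvs: Sequence[str] = DV_MANOVA,
        followup_dvs: Sequence[str] = DV_FOLLOWUP,
        alpha: float = 0.05,
        correlation_group: str = "ASD",
    ) -> None:
        if not isinstance(cohort, CohortTable):
            raise InputError("cohort must be a CohortTable; see from_features_frame")
        counts = cohort.data["group"].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise InputError("need >= 2 subjects in each of 2 groups")
        self.cohort = cohort
        self.dvs = tuple(dvs)
        self.followup_dvs = tuple(followup_dvs)
        self.alpha = float(alpha)
        self.correlation_group = correlation_group

    @classmethod
    def from_features_frame(cls, df: pd.DataFrame, dvs: Sequence[str] = DV_MANOVA,
                            **kwargs) -> "SmileGroupModel":
        """Build from a features DataFrame (one row per subject)."""
        df = df.copy()
        if "int_SO_comp" not in df:
            df["int_SO_comp"] = (df["int_SO_au12"] + df["int_SO_au06"]) / 2.0
        missing = df[list(dvs)].isna()
        exclusions = [
            (str(df.loc[i, "subject_id"]), list(row.index[row]))
            for i, row in missing.iterrows() if row.any()
        ]
        cohort = CohortTable(
            data=df,
            analysis=df.loc[~missing.any(axis=1)].reset_index(drop=True),
            dv_names=tuple(dvs),
            exclusions=exclusions,
        )
        return cls(cohort, dvs=dvs, **kwargs)

    def fit(self) -> SmileGroupResults:
        cohort = self.cohort
        manova = run_manova(cohort, self.dvs)
        m = len(self.followup_dvs)
        anovas = [run_anova(cohort, dv, m_tests=m, alpha=self.alpha)
                  for dv in self.followup_dvs]
        assumptions = check_assumptions(cohort, self.dvs)

        correlations: list[PartialCorrelationResult] = []
        sub = cohort.data[cohort.data["group"] == self.correlation_group].copy()
        if len(sub) >= 4 and {"iq", "sex"}.issubset(sub.columns):
            sub["sex_code"] = sub["sex"].map(SEX_CODES)
            for dv in self.followup_dvs:
                # two series: IQ vs DV controlling sex, sex vs DV controlling IQ
                correlations.append(partial_spearman(sub, "iq", dv, ("sex_code",)))
                correlations.append(partial_spearman(sub, "sex_code", dv, ("iq",)))
        demographics = compare_demographics(cohort)
        return SmileGroupResults(
            manova=manova,
            anovas=anovas,
            assumptions=assumptions,
            partial_correlations=correlations,
            demographics=demographics,
            alpha=self.alpha,
            m_tests=m,
            n_analyzed=manova.n,
            n_excluded=len(cohort.exclusions),
            excluded=list(cohort.exclusions),
        )
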