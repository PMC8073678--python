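"""Per-subject smile features and the cohort analysis table.

For each smile type (Social SO / Simple SI) three measures are computed per
subject: mean event duration (s), mean of event mean AU intensities (0-5),
and frequency as events per 120 s of usable interaction time.  Duration and
intensity are *missing* (not zero) for a subject with no events of that
type -- a mean over zero events is undefined and coding it as 0 would bias
intensity downward -- while frequency is genuinely 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import SIMPLE, SOCIAL, SmileEvent
from .exceptions import InputError

#: Frequency normalization basis, in seconds of usable interaction.
FREQ_BASIS_S = 120.0

#: Dependent variables entering the omnibus multivariate comparison.  The two
#: Social-smile intensities are collapsed into one composite so the DV count
#: matches the multivariate design; the follow-up family splits them again.
DV_MANOVA = ("dur_SI", "dur_SO", "freq_SI", "freq_SO", "int_SI_au12", "int_SO_comp")

#: Dependent variables of the univariate follow-up family (7 tests).
DV_FOLLOWUP = (
    "dur_SI", "dur_SO", "freq_SI", "freq_SO",
    "int_SI_au12", "int_SO_au12", "int_SO_au06",
)


@dataclass
class SubjectFeatureVector:
    """The per-subject measures plus covariates."""

    subject_id: str
    group: str
    sex: str
    age_months: float
    iq: float  # NaN when unavailable
    dur_SI: float
    dur_SO: float
    int_SI_au12: float
    int_SO_au12: float
    int_SO_au06: float
    freq_SI: float
    freq_SO: float
    usable_seconds: float
    n_events_SI: int
    n_events_SO: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def subject_features(
    events: Iterable[SmileEvent],
    usable_seconds: float,
    metadata: Mapping[str, object],
) -> SubjectFeatureVector:
    """Aggregate one subject's events into the feature vector.

    Per-type means are unweighted by event length; frequency is normalized
    to the 120 s basis: ``freq = 120 * n_events / usable_seconds``.
    """
    if not usable_seconds > 0:
        raise InputError("usable_seconds must be positive")
    events = list(events)
    by_type: dict[str, list[SmileEvent]] = {SIMPLE: [], SOCIAL: []}
    for e in events:
        by_type[e.smile_type].append(e)

    def _mean(values: list[float]) -> float:
        return float(np.mean(values)) if values else float("nan")

    si, so = by_type[SIMPLE], by_type[SOCIAL]
    return SubjectFeatureVector(
        subject_id=str(metadata["subject_id"]),
        group=str(metadata["group"]),
        sex=str(metadata.get("sex", "")),
        age_months=float(metadata.get("age_months", float("nan"))),
        iq=float(metadata.get("iq", float("nan"))) if metadata.get("iq") is not None else float("nan"),
        dur_SI=_mean([e.duration_s for e in si]),
        dur_SO=_mean([e.duration_s for e in so]),
        int_SI_au12=_mean([e.mean_au12 for e in si]),
        int_SO_au12=_mean([e.mean_au12 for e in so]),
        int_SO_au06=_mean([e.mean_au06 for e in so]),
        freq_SI=FREQ_BASIS_S * len(si) / usable_seconds,
        freq_SO=FREQ_BASIS_S * len(so) / usable_seconds,
        usable_seconds=float(usable_seconds),
        n_events_SI=len(si),
        n_events_SO=len(so),
    )


@dataclass
class CohortTable:
    """Cohort feature table: the unit of group statistical analysis.

    ``data`` keeps every subject; ``analysis`` is the complete-case subset
    over ``dv_names`` (listwise policy); ``exclusions`` logs who was dropped
    and which DV was missing, so no subject disappears silently.
    """

    data: pd.DataFrame
    analysis: pd.DataFrame
    dv_names: tuple[str, ...]
    exclusions: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


def assemble_cohort(
    vectors: Iterable[SubjectFeatureVector],
    dv_names: tuple[str, ...] = DV_MANOVA,
    dv_policy: str = "listwise",
) -> CohortTable:
    """Build the cohort table, applying the missing-DV exclusion policy.

    ``listwise`` (default) excludes any subject missing any DV from the
    multivariate analysis table; ``none`` keeps everyone.  The composite
    Social-intensity DV ``int_SO_comp`` (mean of the AU12 and AU06 Social
    intensities) is derived here.
    """
    rows = [v.to_dict() for v in vectors]
    if not rows:
        raise InputError("no subjects to assemble")
    df = pd.DataFrame(rows)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise InputError(f"duplicate subject_id(s): {sorted(dup.unique())}")
    df["int_SO_comp"] = (df["int_SO_au12"] + df["int_SO_au06"]) / 2.0
    df = df.reset_index(drop=True)

    if dv_policy not in ("listwise", "none"):
        raise InputError(f"unknown dv_policy {dv_policy!r}")
    exclusions: list[tuple[str, list[str]]] = []
    if dv_policy == "listwise":
        missing = df[list(dv_names)].isna()
        for i, row in missing.iterrows():
            if row.any():
                exclusions.append((df.loc[i, "subject_id"], list(row.index[row])))
        analysis = df.loc[~missing.any(axis=1)].reset_index(drop=True)
    else:
        analysis = df
    return CohortTable(data=df, analysis=analysis, dv_names=tuple(dv_names),
                       exclusions=exclusions)
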