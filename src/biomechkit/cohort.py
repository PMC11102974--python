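"""Cohort-level pooling of per-subject biomechanical parameters.

Per-subject scalars (MVIC torques, CAR, CCI, muscle volumes, walking
speed, ROMs, contact-force peaks, hand-grip strength, demographics) are
pooled per cohort into mean +/- SD tables, and the relationship between
hand-grip strength and maximal extension torque is summarized with an
ordinary least-squares trend line.  Descriptive statistics only: with a
handful of subjects per cohort, inferential tests on the scalar
parameters are not meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = ["SubjectRecord", "summarize", "trend_line", "TrendLine"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics and extracted parameters.

    All parameter fields are optional; missing values are excluded
    pairwise at summary time.  When height, mass and BMI are all present
    they are cross-checked for consistency (BMI = mass / height^2).
    """

    id: str
    cohort: str  # e.g. "HYA" (healthy young adults) or "OLD" (elderly)
    height_m: Optional[float] = None
    mass_kg: Optional[float] = None
    bmi: Optional[float] = None
    age_y: Optional[float] = None
    sex: Optional[str] = None
    mvic_75_nm: Optional[float] = None
    mvic_90_nm: Optional[float] = None
    car: Optional[float] = None
    cci_mvic: Optional[float] = None
    cci_ss_walk: Optional[float] = None
    handgrip_kg: Optional[float] = None
    quad_volume_cm3: Optional[float] = None
    pws_m_s: Optional[float] = None
    rom_ankle_deg: Optional[float] = None
    rom_knee_deg: Optional[float] = None
    rom_hip_deg: Optional[float] = None
    jcf_peak1_bw: Optional[float] = None
    jcf_peak2_bw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.height_m and self.mass_kg and self.bmi:
            implied = self.mass_kg / self.height_m**2
            if abs(implied - self.bmi) / self.bmi > 0.005:
                raise InvalidParameterError(
                    f"{self.id}: BMI {self.bmi} inconsistent with mass/height^2 "
                    f"({implied:.2f})"
                )


_NON_PARAMETERS = {"id", "cohort", "sex"}


def summarize(records: Sequence[SubjectRecord],
              cohorts: Sequence[str] | None = None) -> pd.DataFrame:
    """Pool subject records into a per-cohort mean +/- SD table.

    Returns a DataFrame indexed by parameter with a column MultiIndex
    (cohort, {mean, sd, n}).  The SD uses the sample (n-1) denominator;
    with a single subject it is reported as 0 and the n column makes the
    degenerate case explicit.  Missing values are excluded per parameter.
    """
    if not records:
        raise InvalidParameterError("no subject records supplied")
    df = pd.DataFrame([r.__dict__ for r in records])
    cohorts = list(cohorts) if cohorts is not None else sorted(df["cohort"].unique())
    for cohort in cohorts:
        if not (df["cohort"] == cohort).any():
            raise InvalidParameterError(f"cohort {cohort!r} has no records")

    parameters = [f.name for f in fields(SubjectRecord) if f.name not in _NON_PARAMETERS]
    columns: dict[tuple[str, str], list[float]] = {}
    for cohort in cohorts:
        sub = df[df["cohort"] == cohort]
        means, sds, ns = [], [], []
        for parameter in parameters:
            values = sub[parameter].dropna().astype(float)
            n = len(values)
            ns.append(n)
            if n == 0:
                means.append(np.nan)
                sds.append(np.nan)
            else:
                means.append(float(values.mean()))
                sds.append(0.0 if n == 1 else float(values.std(ddof=1)))
        columns[(cohort, "mean")] = means
        columns[(cohort, "sd")] = sds
        columns[(cohort, "n")] = ns
    out = pd.DataFrame(columns, index=parameters)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cohort", "stat"])
    return out


@dataclass(frozen=True)
class TrendLine:
    slope: float
    intercept: float
    r: float


def trend_line(x: Sequence[float], y: Sequence[float]) -> TrendLine:
    """OLS trend line (slope, intercept) and Pearson r for paired scalars.

    Used for the hand-grip strength vs maximal extension torque
    relationship; requires at least 3 paired points and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need >= 3 paired points")
    if np.std(x) == 0:
        raise InvalidParameterError("x has zero variance; trend line undefined")
    fit = stats.linregress(x, y)
    return TrendLine(slope=float(fit.slope), intercept=float(fit.intercept),
                     r=float(fit.rvalue))
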