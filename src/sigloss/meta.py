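"""Hazard-ratio meta-analysis across cohorts.

Per-cohort hazard ratios with 95% confidence intervals (as printed in
forest tables) are pooled on the log scale: inverse-variance fixed effects
and DerSimonian-Laird random effects, with Cochran's Q, tau-squared and
I-squared heterogeneity summaries. Standard errors are back-calculated from
the CI bounds when not given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt, exp

import numpy as np
import pandas as pd

from .io import SiglossError

Z95 = 1.959964


@dataclass
class StudyEffect:
    study_id: str
    hr: float
    ci_low: float
    ci_high: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_low < self.hr < self.ci_high):
            raise SiglossError(
                f"study {self.study_id!r}: need 0 < ci_low < hr < ci_high, "
                f"got ({self.ci_low}, {self.hr}, {self.ci_high})")
        if self.se is None:
            self.se = se_from_ci(self.hr, self.ci_low, self.ci_high)
        if self.se <= 0:
            raise SiglossError(f"study {self.study_id!r}: se must be positive")

    @property
    def log_hr(self) -> float:
        return log(self.hr)


@dataclass
class MetaResult:
    pooled_hr_fixed: float
    ci_fixed: tuple[float, float]
    pooled_hr_random: float
    ci_random: tuple[float, float]
    Q: float
    df: int
    I2: float
    tau2: float
    weights_fixed: pd.Series = field(repr=False)
    weights_random: pd.Series = field(repr=False)


def se_from_ci(hr: float, ci_low: float, ci_high: float) -> float:
    """Standard error of log(HR) back-calculated from a printed 95% CI."""
    if not (0 < ci_low < ci_high):
        raise SiglossError("CI bounds must be positive with ci_low < ci_high")
    return (log(ci_high) - log(ci_low)) / (2 * Z95)


def pool(studies: list[StudyEffect] | pd.DataFrame) -> MetaResult:
    """Fixed- and random-effects pooling of per-study log hazard ratios.

    Fixed effects weight by inverse squared SE; random effects add the
    DerSimonian-Laird tau-squared to each study's variance. tau2 = 0
    whenever Q <= df, in which case random equals fixed.
    """
    if isinstance(studies, pd.DataFrame):
        studies = [StudyEffect(str(r.study_id), float(r.hr), float(r.ci_low),
                               float(r.ci_high),
                               float(r.se) if "se" in studies.columns and pd.notna(getattr(r, "se", None)) else None)
                   for r in studies.itertuples()]
    if not studies:
        raise SiglossError("meta-analysis needs at least 1 study")
    ids = [s.study_id for s in studies]
    y = np.array([s.log_hr for s in studies])
    v = np.array([s.se ** 2 for s in studies])
    w = 1.0 / v
    sw = w.sum()

    mu_f = float(np.sum(w * y) / sw)
    se_f = sqrt(1.0 / sw)
    Q = float(np.sum(w * (y - mu_f) ** 2))
    df = len(studies) - 1
    c = sw - np.sum(w ** 2) / sw
    tau2 = max(0.0, (Q - df) / c) if df > 0 and c > 0 else 0.0
    I2 = max(0.0, (Q - df) / Q) if Q > 0 and df > 0 else 0.0

    w_r = 1.0 / (v + tau2)
    mu_r = float(np.sum(w_r * y) / w_r.sum())
    se_r = sqrt(1.0 / w_r.sum())

    return MetaResult(
        pooled_hr_fixed=exp(mu_f),
        ci_fixed=(exp(mu_f - Z95 * se_f), exp(mu_f + Z95 * se_f)),
        pooled_hr_random=exp(mu_r),
        ci_random=(exp(mu_r - Z95 * se_r), exp(mu_r + Z95 * se_r)),
        Q=Q, df=df, I2=I2, tau2=tau2,
        weights_fixed=pd.Series(w / sw, index=ids, name="weight_fixed"),
        weights_random=pd.Series(w_r / w_r.sum(), index=ids, name="weight_random"),
    )


def forest_table(studies: list[StudyEffect], result: MetaResult,
                 model: str = "random") -> pd.DataFrame:
    """Study rows plus a pooled row, as written to the forest TSV export."""
    rows = [{
        "study_id": s.study_id, "hr": s.hr, "ci_low": s.ci_low,
        "ci_high": s.ci_high, "weight": float(
            (result.weights_random if model == "random" else result.weights_fixed)[s.study_id]),
    } for s in studies]
    pooled_hr = result.pooled_hr_random if model == "random" else result.pooled_hr_fixed
    ci = result.ci_random if model == "random" else result.ci_fixed
    rows.append({"study_id": f"pooled_{model}", "hr": pooled_hr,
                 "ci_low": ci[0], "ci_high": ci[1], "weight": 1.0})
    return pd.DataFrame(rows)
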