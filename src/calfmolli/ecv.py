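"""Extracellular volume fraction from pre/post-contrast T1 and hematocrit.

For each muscle compartment,

    ECV = (1 - Hct) * [1/T1m_post - 1/T1m_pre] / [1/T1b_post - 1/T1b_pre]

where T1m is the compartment's peak (maximum) T1 and T1b the averaged peak
arterial blood T1, each measured natively (pre) and after gadolinium
contrast (post).  Hematocrit enters as a fraction; percent inputs (> 1)
are divided by 100 and logged.  Results outside [0, 1] are returned and
flagged implausible, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["EcvInputs", "EcvResult", "compute_ecv", "cohort_ecv",
           "muscle_post_t1_for_ecv"]


class EcvError(ValueError):
    pass


def _hct_fraction(hct: float) -> float:
    h = float(hct)
    if h > 1.0:
        logger.info("hematocrit %.3g interpreted as percent", h)
        h = h / 100.0
    if not (0.0 < h < 1.0):
        raise EcvError(f"hematocrit must lie in (0, 1) as a fraction, got {hct}")
    return h


@dataclass(frozen=True)
class EcvInputs:
    """Peak T1 values (ms) pre/post contrast for muscle and blood, plus Hct."""

    t1m_pre_ms: float
    t1m_post_ms: float
    t1b_pre_ms: float
    t1b_post_ms: float
    hematocrit: float

    def __post_init__(self) -> None:
        vals = (self.t1m_pre_ms, self.t1m_post_ms, self.t1b_pre_ms, self.t1b_post_ms)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise EcvError("all T1 values must be positive and finite")
        object.__setattr__(self, "hematocrit", _hct_fraction(self.hematocrit))
        if self.t1b_post_ms == self.t1b_pre_ms:
            raise EcvError("blood T1 unchanged by contrast; ECV denominator is zero")
        if self.t1m_post_ms > self.t1m_pre_ms or self.t1b_post_ms > self.t1b_pre_ms:
            logger.warning(
                "post-contrast T1 above native T1 (muscle %.0f->%.0f, blood %.0f->%.0f)",
                self.t1m_pre_ms, self.t1m_post_ms, self.t1b_pre_ms, self.t1b_post_ms,
            )


@dataclass(frozen=True)
class EcvResult:
    ecv: float  # fraction
    plausible: bool

    @property
    def percent(self) -> float:
        return 100.0 * self.ecv


def compute_ecv(inputs: EcvInputs) -> EcvResult:
    """ECV as a fraction; ``plausible`` is False outside [0, 1]."""
    num = 1.0 / inputs.t1m_post_ms - 1.0 / inputs.t1m_pre_ms
    den = 1.0 / inputs.t1b_post_ms - 1.0 / inputs.t1b_pre_ms
    ecv = (1.0 - inputs.hematocrit) * num / den
    return EcvResult(ecv=float(ecv), plausible=bool(0.0 <= ecv <= 1.0))


def muscle_post_t1_for_ecv(
    ecv: float, t1m_pre_ms: float, t1b_pre_ms: float, t1b_post_ms: float, hct: float
) -> float:
    """Invert the ECV formula for the post-contrast muscle T1.

    Used by the synthetic generator to build ground truth that is exactly
    consistent with the forward formula.
    """
    h = _hct_fraction(hct)
    den = 1.0 / t1b_post_ms - 1.0 / t1b_pre_ms
    r1_post = 1.0 / t1m_pre_ms + ecv * den / (1.0 - h)
    return 1.0 / r1_post


def cohort_ecv(
    metrics: pd.DataFrame,
    blood: pd.DataFrame,
    subjects: pd.DataFrame,
    use_mean: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Per-subject, per-compartment ECV over a cohort.

    Parameters
    ----------
    metrics
        One row per subject x compartment with columns ``subject``,
        ``compartment``, ``peak_t1_pre_ms``, ``peak_t1_post_ms`` (and
        ``mean_t1_pre_ms``/``mean_t1_post_ms`` when ``use_mean``).
    blood
        One row per subject: ``subject``, ``blood_t1_pre_ms``,
        ``blood_t1_post_ms``.
    subjects
        One row per subject with ``subject``, ``group``, ``hematocrit``
        (fraction or percent) and any further covariates.
    use_mean
        Sensitivity option: use compartment mean instead of peak T1.

    Returns the ECV table (``subject``, ``group``, ``compartment``,
    ``ecv_percent``, ``plausible``) and the count of subjects excluded
    for missing inputs; exclusions are logged, not errors.
    """
    pre_col = "mean_t1_pre_ms" if use_mean else "peak_t1_pre_ms"
    post_col = "mean_t1_post_ms" if use_mean else "peak_t1_post_ms"
    df = metrics.merge(blood, on="subject", how="left").merge(
        subjects[["subject", "group", "hematocrit"]], on="subject", how="left"
    )
    needed = [pre_col, post_col, "blood_t1_pre_ms", "blood_t1_post_ms", "hematocrit"]
    by_subject_ok = df.groupby("subject")[needed].apply(
        lambda g: bool(np.isfinite(g.to_numpy(dtype=float)).all())
    )
    complete = set(by_subject_ok[by_subject_ok].index)
    excluded = sorted(set(df["subject"]) - complete)
    if excluded:
        logger.info("excluding %d subject(s) with incomplete ECV inputs: %s",
                    len(excluded), ", ".join(excluded))
    rows = []
    for _, r in df[df["subject"].isin(complete)].iterrows():
        res = compute_ecv(EcvInputs(
            t1m_pre_ms=r[pre_col], t1m_post_ms=r[post_col],
            t1b_pre_ms=r["blood_t1_pre_ms"], t1b_post_ms=r["blood_t1_post_ms"],
            hematocrit=r["hematocrit"],
        ))
        rows.append({"subject": r["subject"], "group": r["group"],
                     "compartment": r["compartment"],
                     "ecv_percent": res.percent, "plausible": res.plausible})
    out = pd.DataFrame(rows, columns=["subject", "group", "compartment",
                                      "ecv_percent", "plausible"])
    return out, len(excluded)
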