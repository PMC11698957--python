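"""Clinical rule engines for smoldering multiple myeloma (SMM).

Risk-model classifiers (IMWG 20/2/20, Mayo 2008), evolving-pattern
detection over pre-screening lab series, biochemical-progression onset
detection on follow-up series, and a serum-based IMWG response-depth
classifier.

Units throughout: serum M protein in g/dL, free light chains (FLC) in
mg/L, bone marrow plasma cells (BMPC) in percent, times in days relative
to screening (negative = before screening).

The response engine is a serum-based simplification: urine and imaging
components of the IMWG criteria are not representable from serum series
and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BaselineLabs",
    "ResponseAssessment",
    "RiskGroup",
    "Response",
    "InsufficientDataError",
    "classify_20_2_20",
    "count_mayo2008_factors",
    "detect_evolving_pattern",
    "detect_biochemical_progression",
    "classify_imwg_response",
]

#: IMWG absolute-increase minimums for biochemical progression
M_PROTEIN_ABS_MIN = 0.5  # g/dL
DFLC_ABS_MIN = 100.0  # mg/L


class InsufficientDataError(ValueError):
    """Fewer measurements than the rule needs."""


class RiskGroup(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class Response(str, Enum):
    """IMWG response depth, serum-based subset."""

    SCR = "sCR"
    CR = "CR"
    VGPR = "VGPR"
    PR = "PR"
    MR = "MR"
    SD = "SD"


@dataclass(frozen=True)
class BaselineLabs:
    """Baseline disease-burden labs: BMPC %, M protein g/dL, involved/uninvolved FLC ratio."""

    bmpc: float
    m_protein: float
    flc_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bmpc <= 100.0:
            raise ValueError("bmpc must be a percentage in [0, 100]")
        if self.m_protein < 0:
            raise ValueError("m_protein must be >= 0")
        if self.flc_ratio <= 0:
            raise ValueError("flc_ratio must be > 0")


def classify_20_2_20(labs: BaselineLabs) -> tuple[int, RiskGroup]:
    """IMWG 20/2/20 risk model with strict cutoffs.

    Counts FLC ratio > 20, M protein > 2 g/dL, BMPC > 20%; two or more
    factors is high risk, one intermediate, none low. Boundary values
    (exactly 20 / 2 / 20) do not count.
    """
    n = int(labs.flc_ratio > 20) + int(labs.m_protein > 2) + int(labs.bmpc > 20)
    risk = RiskGroup.HIGH if n >= 2 else RiskGroup.INTERMEDIATE if n == 1 else RiskGroup.LOW
    return n, risk


def count_mayo2008_factors(labs: BaselineLabs) -> int:
    """Mayo 2008 SMM risk factors with inclusive cutoffs.

    Counts BMPC >= 10%, M protein >= 3 g/dL, and FLC ratio >= 8 or <= 0.125.
    """
    flc_abnormal = labs.flc_ratio >= 8 or labs.flc_ratio <= 0.125
    return int(labs.bmpc >= 10) + int(labs.m_protein >= 3) + int(flc_abnormal)


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"time_days", "m_protein", "involved_flc", "uninvolved_flc"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"lab series missing columns: {sorted(missing)}")
    s = series.sort_values("time_days").reset_index(drop=True)
    if s["time_days"].duplicated().any():
        raise ValueError("lab series times must be strictly increasing")
    return s


def _rises_by_fraction(values: np.ndarray, frac: float) -> bool:
    # running-minimum to later-value comparison
    if len(values) < 2:
        return False
    running_min = np.minimum.accumulate(values)[:-1]
    later = values[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = later >= (1.0 + frac) * running_min
    return bool(np.any(ok[running_min > 0]))


def detect_evolving_pattern(series: pd.DataFrame, window_days: int = 183) -> bool:
    """Evolving-pattern detection over the pre-screening window.

    True iff serum M protein **or** involved FLC rises by >= 10%
    (relative, running-minimum to any later value) within the
    ``window_days`` before screening (time <= 0). Requires at least two
    in-window measurements.
    """
    s = _validate_series(series)
    win = s[(s["time_days"] <= 0) & (s["time_days"] >= -window_days)]
    if len(win) < 2:
        raise InsufficientDataError(
            f"need >= 2 measurements in the {window_days}-day pre-screening window"
        )
    return (
        _rises_by_fraction(win["m_protein"].to_numpy(float), 0.10)
        or _rises_by_fraction(win["involved_flc"].to_numpy(float), 0.10)
    )


def detect_biochemical_progression(series: pd.DataFrame) -> Optional[float]:
    """Earliest biochemical-progression onset time (days), or ``None``.

    IMWG-style rule on post-baseline measurements (time >= 0): a >= 25%
    rise of M protein from its running nadir with an absolute increase of
    at least 0.5 g/dL, OR a >= 25% rise of the involved-minus-uninvolved
    FLC difference from its nadir with an absolute increase of at least
    100 mg/L. Urine M protein is not modeled.
    """
    s = _validate_series(series)
    post = s[s["time_days"] >= 0]
    if len(post) < 2:
        raise InsufficientDataError("need >= 2 post-baseline measurements")
    times = post["time_days"].to_numpy(float)
    onsets = []
    for values, abs_min in (
        (post["m_protein"].to_numpy(float), M_PROTEIN_ABS_MIN),
        ((post["involved_flc"] - post["uninvolved_flc"]).to_numpy(float), DFLC_ABS_MIN),
    ):
        nadir = np.minimum.accumulate(values)[:-1]
        later = values[1:]
        hit = (later - nadir >= 0.25 * nadir) & (later - nadir >= abs_min)
        if np.any(hit):
            onsets.append(float(times[1:][hit][0]))
    return min(onsets) if onsets else None


@dataclass(frozen=True)
class ResponseAssessment:
    """Serum-based disease assessment at one timepoint.

    ``ife_negative`` is serum immunofixation negativity; ``flc_ratio_normal``
    marks a normalized involved/uninvolved FLC ratio (used only to upgrade
    CR to stringent CR).
    """

    m_protein: float
    ife_negative: bool = False
    bmpc: float = 100.0
    flc_ratio_normal: bool = False

    def __post_init__(self) -> None:
        if self.m_protein < 0:
            raise ValueError("m_protein must be >= 0")


def classify_imwg_response(
    baseline: ResponseAssessment, followup: ResponseAssessment
) -> Response:
    """Serum-based IMWG best-response depth.

    CR requires negative immunofixation and BMPC < 5% (sCR additionally a
    normalized FLC ratio); VGPR a >= 90% M-protein reduction, or positive
    immunofixation with M protein no longer measurable; PR >= 50%; MR
    >= 25%; otherwise SD. Baseline disease must be serum-measurable.
    """
    if baseline.m_protein <= 0:
        raise ValueError("baseline disease not serum-measurable (m_protein <= 0)")
    if followup.ife_negative and followup.bmpc < 5.0:
        return Response.SCR if followup.flc_ratio_normal else Response.CR
    reduction = 1.0 - followup.m_protein / baseline.m_protein
    if reduction >= 0.90 or (followup.m_protein == 0.0 and not followup.ife_negative):
        return Response.VGPR
    if reduction >= 0.50:
        return Response.PR
    if reduction >= 0.25:
        return Response.MR
    return Response.SD
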