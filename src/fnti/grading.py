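"""Rule-assisted FCI hip grading from the Norberg angle and categorical flags.

The FCI (Fédération Cynologique Internationale) five-grade scheme runs from
A (normal) to E (severe dysplasia).  Scoring combines the Norberg angle (NA)
with qualitative judgements — joint congruency, osteoarthritic signs, and
whether the femoral head centre lies outside the dorsal acetabular margin
(DAM).  Those qualitative judgements cannot be derived from landmarks here,
so the classifier is an *assist*: it takes them as explicit inputs and
encodes the published criteria with every threshold configurable.

The published grade criteria overlap (the moderate grade requires NA > 90°,
which also holds for all better grades), so the classifier evaluates worst
criterion first, severity descending.  It is a total function: combinations
no primary rule covers fall back to NA bands so every input yields exactly
one grade, and decreasing NA at fixed flags never improves the grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class FciGrade(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


class Congruency(str, Enum):
    EXCELLENT = "excellent"
    MILD_INCONGRUENT = "mild_incongruent"
    MODERATE_INCONGRUENT = "moderate_incongruent"
    OBVIOUS_INCONGRUENT = "obvious_incongruent"
    SEVERE_INCONGRUENT = "severe_incongruent"


@dataclass(frozen=True)
class GradeCriteria:
    """Configurable NA thresholds for the five FCI grades.

    Defaults follow the published criteria: A needs NA > 105° and excellent
    congruency; B sits around 105°; C around 100°; D requires NA > 90°; E is
    NA < 90°.  "Around" bands carry a half-width (default ±2°).
    """

    a_min_na: float = 105.0
    b_center_na: float = 105.0
    c_center_na: float = 100.0
    e_max_na: float = 90.0
    band_halfwidth: float = 2.0

    def __post_init__(self) -> None:
        for v in (self.a_min_na, self.b_center_na, self.c_center_na, self.e_max_na):
            if not 0.0 < v < 180.0:
                raise ValueError("NA thresholds must lie in (0, 180)")
        if self.band_halfwidth < 0:
            raise ValueError("band_halfwidth must be non-negative")


DEFAULT_CRITERIA = GradeCriteria()


def assign_grade(
    na: float,
    congruency: Congruency | str = Congruency.EXCELLENT,
    oa_signs: bool = False,
    head_centre_outside_dam: bool = False,
    criteria: GradeCriteria = DEFAULT_CRITERIA,
) -> FciGrade:
    """Assign an FCI grade; worst criterion wins.

    Precedence (severity descending):

    - E: NA below the E ceiling (default 90°) or severe incongruency;
    - D: osteoarthritic signs together with obvious incongruency;
    - C: head centre outside the DAM, or moderate incongruency, or NA in
      the C band (default 100° ± 2°);
    - B: mild incongruency or NA in the B band (default 105° ± 2°);
    - A: NA above the A threshold (default 105°) with excellent congruency
      and no osteoarthritic or subluxation flags.

    Remaining combinations are graded by NA band alone, keeping the function
    total and monotone in NA.
    """
    congruency = Congruency(congruency)
    if not 0.0 <= na < 180.0:
        raise ValueError(f"Norberg angle {na} out of range [0, 180)")
    c = criteria
    if na < c.e_max_na or congruency is Congruency.SEVERE_INCONGRUENT:
        return FciGrade.E
    if oa_signs and congruency is Congruency.OBVIOUS_INCONGRUENT:
        return FciGrade.D
    if (
        head_centre_outside_dam
        or congruency is Congruency.MODERATE_INCONGRUENT
        or abs(na - c.c_center_na) <= c.band_halfwidth
    ):
        return FciGrade.C
    if congruency is Congruency.MILD_INCONGRUENT or abs(na - c.b_center_na) <= c.band_halfwidth:
        return FciGrade.B
    if (
        na > c.a_min_na
        and congruency is Congruency.EXCELLENT
        and not oa_signs
        and not head_centre_outside_dam
    ):
        return FciGrade.A
    # NA-band fallback: no primary rule fired
    if na >= c.b_center_na - c.band_halfwidth:
        return FciGrade.B
    if na >= c.c_center_na - c.band_halfwidth:
        return FciGrade.C
    if na > c.e_max_na:
        return FciGrade.D
    return FciGrade.E


GRADE_ORDER = [FciGrade.A, FciGrade.B, FciGrade.C, FciGrade.D, FciGrade.E]
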