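"""Opacification scoring: the P(ABCD) ratio with its grade bands, the
ostiomeatal-complex (OMC) patency score, and the Lund-Mackay (LMS) and
modified Lund-Mackay staging systems.

The P(ABCD) score of a region is the soft-tissue fraction of its
patency-relevant volume::

    P(ABCD) = V_soft / (V_soft + V_air)

a continuous ratio in [0, 1], graded into six bands: P0 (no inflammation,
score 0), A mild (0, 0.15), B moderate [0.15, 0.35), C advanced
[0.35, 0.55), D severe [0.55, 0.9) and P1 pansinusitis [0.9, 1]. The
printed band edges are shared between adjacent grades; bands are realised
half-open (an edge belongs to the upper grade) so the map is total and
deterministic.

The LMS scores each of five sinus pairs 0/1/2 (none/partial/total
opacification) plus 0/2 per OMC side, maximum 24; the modified (Zinreich)
LMS refines the partial range into 25% intervals, scoring each sinus 0-5,
maximum 54. Totals are also normalised to percent of their scale maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .densitometry import DensitometricProfile, ThresholdScheme, DEFAULT_SCHEME, profile
from .io import CTVolume
from .voi import RegionSet, SINUS_NAMES

__all__ = [
    "GradeBands",
    "DEFAULT_GRADE_BANDS",
    "PABCDResult",
    "LMSResult",
    "ModifiedLMSResult",
    "pabcd_score",
    "assign_grade",
    "omc_score",
    "lms_sinus_score",
    "modified_lms_sinus_score",
    "lms_total",
    "modified_lms_total",
    "score_ct",
    "LMS_MAX",
    "MODIFIED_LMS_MAX",
    "TOTAL_OPACIFICATION_EPS",
]

LMS_MAX = 24  # 10 sinuses x 2 + 2 OMC x 2
MODIFIED_LMS_MAX = 54  # 10 sinuses x 5 + 2 OMC x 2

#: Tolerance below which an opacification fraction counts as 0 ("none") and
#: above 1 - eps as total; keeps the 99%-filled-sinus-scores-partial rule
#: while letting voxel noise ride on a visually total opacification.
TOTAL_OPACIFICATION_EPS = 0.005


@dataclass(frozen=True)
class GradeBands:
    """P(ABCD) grade band edges; each edge belongs to the upper grade."""

    a_upper: float = 0.15
    b_upper: float = 0.35
    c_upper: float = 0.55
    d_upper: float = 0.90
    zero_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.a_upper < self.b_upper < self.c_upper < self.d_upper <= 1):
            raise ValueError("grade band edges must be strictly increasing within (0, 1]")


DEFAULT_GRADE_BANDS = GradeBands()

DEFAULT_OMC_THRESHOLDS = (1.0 / 3.0, 2.0 / 3.0)


@dataclass
class PABCDResult:
    """P(ABCD) score, grade and OMC scores for one CT study."""

    score: float
    grade: str
    omc_left: int | None = None
    omc_right: int | None = None
    profile: DensitometricProfile | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "score": self.score,
            "grade": self.grade,
            "omc_left": self.omc_left,
            "omc_right": self.omc_right,
        }
        if self.profile is not None:
            d["profile"] = self.profile.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PABCDResult":
        prof = d.get("profile")
        return cls(
            score=float(d["score"]),
            grade=str(d["grade"]),
            omc_left=None if d.get("omc_left") is None else int(d["omc_left"]),
            omc_right=None if d.get("omc_right") is None else int(d["omc_right"]),
            profile=None if prof is None else DensitometricProfile.from_dict(prof),
        )


@dataclass
class LMSResult:
    """Lund-Mackay staging: per-sinus 0/1/2, OMC 0/2 per side, total of 24."""

    per_sinus: dict[str, int]
    omc_left: int
    omc_right: int
    total: int = field(init=False)
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.per_sinus.values()) + self.omc_left + self.omc_right
        self.percent = 100.0 * self.total / LMS_MAX

    def to_dict(self) -> dict:
        return {
            "per_sinus": dict(self.per_sinus),
            "omc_left": self.omc_left,
            "omc_right": self.omc_right,
            "total": self.total,
            "percent": self.percent,
        }


@dataclass
class ModifiedLMSResult:
    """Modified (Zinreich) staging: per-sinus 0-5, OMC 0/2, total of 54."""

    per_sinus: dict[str, int]
    omc_left: int
    omc_right: int
    total: int = field(init=False)
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.per_sinus.values()) + self.omc_left + self.omc_right
        self.percent = 100.0 * self.total / MODIFIED_LMS_MAX

    def to_dict(self) -> dict:
        return {
            "per_sinus": dict(self.per_sinus),
            "omc_left": self.omc_left,
            "omc_right": self.omc_right,
            "total": self.total,
            "percent": self.percent,
        }


# ---------------------------------------------------------------------------


def pabcd_score(p: DensitometricProfile) -> float:
    """The soft-tissue fraction V_soft / (V_soft + V_air) of a region."""
    denom = p.v_soft_mm3 + p.v_air_mm3
    if denom <= 0:
        raise ValueError("no patency-relevant volume in VOI (V_soft + V_air is zero)")
    return p.v_soft_mm3 / denom


def assign_grade(score: float, bands: GradeBands = DEFAULT_GRADE_BANDS) -> str:
    """Map a P(ABCD) score in [0, 1] to its unique grade."""
    if not (0.0 <= score <= 1.0) or math.isnan(score):
        raise ValueError(f"P(ABCD) score must lie in [0, 1], got {score}")
    if score <= bands.zero_tol:
        return "P0"
    if score < bands.a_upper:
        return "A"
    if score < bands.b_upper:
        return "B"
    if score < bands.c_upper:
        return "C"
    if score < bands.d_upper:
        return "D"
    return "P1"


def omc_score(
    p_omc: DensitometricProfile,
    thresholds: tuple[float, float] = DEFAULT_OMC_THRESHOLDS,
) -> int:
    """Score an ostiomeatal-complex channel 0 (patent) to 2 (obstructed).

    The degree of involvement is the channel's soft-tissue fraction f:
    0 when f < t_patent, 2 when f >= t_obstructed, 1 in between
    (defaults split [0, 1] into thirds).
    """
    t_patent, t_obstructed = thresholds
    if not (0 <= t_patent <= t_obstructed <= 1):
        raise ValueError(f"invalid OMC thresholds {thresholds}")
    f = pabcd_score(p_omc)
    if f < t_patent:
        return 0
    if f >= t_obstructed:
        return 2
    return 1


def _check_fraction(fraction: float) -> None:
    if not (0.0 <= fraction <= 1.0) or math.isnan(fraction):
        raise ValueError(f"opacification fraction must lie in [0, 1], got {fraction}")


def lms_sinus_score(
    opacification_fraction: float, eps: float = TOTAL_OPACIFICATION_EPS
) -> int:
    """Lund-Mackay per-sinus score: 0 none, 1 partial, 2 total opacification.

    Total requires a fraction of at least ``1 - eps``; a 99%-opacified sinus
    still scores 1 (partial).
    """
    _check_fraction(opacification_fraction)
    if opacification_fraction <= eps:
        return 0
    if opacification_fraction >= 1.0 - eps:
        return 2
    return 1


def modified_lms_sinus_score(
    opacification_fraction: float, eps: float = TOTAL_OPACIFICATION_EPS
) -> int:
    """Modified-LMS per-sinus score 0-5 by 25% opacification intervals.

    0 for none, 5 for total, otherwise the 25% band: (0, .25] -> 1,
    (.25, .5] -> 2, (.5, .75] -> 3, (.75, 1) -> 4. A 99%-opacified sinus
    scores 4.
    """
    _check_fraction(opacification_fraction)
    if opacification_fraction <= eps:
        return 0
    if opacification_fraction >= 1.0 - eps:
        return 5
    band = math.ceil(opacification_fraction / 0.25 - 1e-12)
    return min(4, max(1, band))


def _check_components(
    per_sinus: Sequence[int] | dict[str, int],
    omc: Sequence[int],
    sinus_range: range,
) -> tuple[dict[str, int], tuple[int, int]]:
    if isinstance(per_sinus, dict):
        if set(per_sinus) != set(SINUS_NAMES):
            raise ValueError(
                f"expected scores for exactly the {len(SINUS_NAMES)} sinuses, got {sorted(per_sinus)}"
            )
        items = dict(per_sinus)
    else:
        if len(per_sinus) != len(SINUS_NAMES):
            raise ValueError(f"expected {len(SINUS_NAMES)} per-sinus scores, got {len(per_sinus)}")
        items = dict(zip(SINUS_NAMES, per_sinus))
    for name, s in items.items():
        if s not in sinus_range:
            raise ValueError(f"sinus score {s} for {name} outside {sinus_range}")
    if len(omc) != 2:
        raise ValueError(f"expected 2 OMC scores (left, right), got {len(omc)}")
    for s in omc:
        if s not in (0, 2):
            raise ValueError(f"OMC component score must be 0 or 2, got {s}")
    return items, (int(omc[0]), int(omc[1]))


def lms_total(per_sinus: Sequence[int] | dict[str, int], omc: Sequence[int]) -> LMSResult:
    """Sum ten 0/1/2 sinus scores and two 0/2 OMC scores into an LMS total."""
    items, (l, r) = _check_components(per_sinus, omc, range(0, 3))
    return LMSResult(per_sinus=items, omc_left=l, omc_right=r)


def modified_lms_total(
    per_sinus: Sequence[int] | dict[str, int], omc: Sequence[int]
) -> ModifiedLMSResult:
    """Sum ten 0-5 sinus scores and two 0/2 OMC scores into a modified-LMS total."""
    items, (l, r) = _check_components(per_sinus, omc, range(0, 6))
    return ModifiedLMSResult(per_sinus=items, omc_left=l, omc_right=r)


def score_ct(
    ct: CTVolume,
    regions: RegionSet,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
    grade_bands: GradeBands = DEFAULT_GRADE_BANDS,
    omc_thresholds: tuple[float, float] = DEFAULT_OMC_THRESHOLDS,
) -> tuple[PABCDResult, LMSResult | None, ModifiedLMSResult | None]:
    """Score one CT study end to end.

    The P(ABCD) score comes from the total-VOI profile; OMC scores from the
    OMC sub-ROIs when present. LMS and modified-LMS totals are produced only
    when all ten per-sinus masks are present, using each sinus's soft
    fraction; OMC sides without a mask contribute 0 to the totals. The
    three-level OMC score collapses to the binary LMS convention as
    obstructed (2) only at level 2, patent (0) otherwise.
    """
    total_profile = profile(ct, regions.total, scheme, region_name="total")
    score = pabcd_score(total_profile)
    grade = assign_grade(score, grade_bands)

    omc_scores: dict[str, int | None] = {"left": None, "right": None}
    for side, mask in regions.omc.items():
        omc_scores[side] = omc_score(
            profile(ct, mask, scheme, region_name=f"omc_{side}"), omc_thresholds
        )

    result = PABCDResult(
        score=score,
        grade=grade,
        omc_left=omc_scores["left"],
        omc_right=omc_scores["right"],
        profile=total_profile,
    )

    lms = mlms = None
    if regions.has_all_sinuses:
        fractions = {
            name: pabcd_score(profile(ct, mask, scheme, region_name=name))
            for name, mask in regions.sinuses.items()
        }
        omc_binary = tuple(
            2 if omc_scores[side] == 2 else 0 for side in ("left", "right")
        )
        lms = lms_total({n: lms_sinus_score(f) for n, f in fractions.items()}, omc_binary)
        mlms = modified_lms_total(
            {n: modified_lms_sinus_score(f) for n, f in fractions.items()}, omc_binary
        )
    return result, lms, mlms
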