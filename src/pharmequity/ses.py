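"""Composite socioeconomic-status (SES) scoring.

Five indicators — monthly household income, occupation rank, education
level, home status and family size — are each mapped to a small integer
score by tabulated rules, then combined by simple additive weighting
(SAW): the composite is ``sum(weight_i * score_i)`` with expert-elicited
impact weights (percent) that default to 30, 27, 20, 13 and 10.

Income banding is anchored to the city poverty line (CPL) and tenant
rent banding to the national minimum wage (NMW), which makes the scores
comparable across places and survey years: only the two anchors change,
never the tables.

Under the default weights the composite ranges from 100 (every indicator
at its minimum score of 1) to 722, and is mapped to one of five SES
classes from ``extremely_poor`` to ``wealthy``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EconomicAnchors",
    "SESWeights",
    "DEFAULT_WEIGHTS",
    "RAW_SAW_WEIGHTS",
    "OccupationRank",
    "EducationLevel",
    "Tenure",
    "SESClass",
    "IndividualSES",
    "SESScore",
    "score_income",
    "score_occupation",
    "score_education",
    "score_home_owner",
    "score_tenant",
    "score_family_size",
    "composite_score",
    "classify_ses",
    "score_individual",
    "COMPOSITE_MIN",
    "COMPOSITE_MAX",
]


@dataclass(frozen=True)
class EconomicAnchors:
    """Monetary anchors, in local currency per month.

    cpl
        City poverty line: the monthly income a household needs to
        escape poverty in the study city. Anchors the income bands.
    nmw
        National minimum wage. Anchors the tenant rent bands.
    """

    cpl: float
    nmw: float

    def __post_init__(self) -> None:
        if not self.cpl > 0:
            raise ValidationError(f"city poverty line must be positive, got {self.cpl!r}")
        if not self.nmw > 0:
            raise ValidationError(f"national minimum wage must be positive, got {self.nmw!r}")


@dataclass(frozen=True)
class SESWeights:
    """Impact weights (percent) applied to the five indicator scores.

    The defaults are the expert-elicited impact percentages; the raw SAW
    weights they were derived from (4.5 … 1.5, proportional to these) are
    kept as :data:`RAW_SAW_WEIGHTS` for documentation only and play no
    part in the arithmetic.
    """

    income_w: float = 30.0
    occupation_w: float = 27.0
    education_w: float = 20.0
    home_w: float = 13.0
    family_w: float = 10.0

    def __post_init__(self) -> None:
        for name, w in self.as_dict().items():
            if w < 0:
                raise ValidationError(f"weight {name} must be nonnegative, got {w!r}")
        total = sum(self.as_dict().values())
        if total != 100:
            # Overrides are permitted, but class bands are calibrated to 100.
            logger.warning(
                "SES weights sum to %s, not 100; the composite scale and the "
                "five class bands are only meaningful under the default weights",
                total,
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "income": self.income_w,
            "occupation": self.occupation_w,
            "education": self.education_w,
            "home": self.home_w,
            "family": self.family_w,
        }


DEFAULT_WEIGHTS = SESWeights()

#: Raw SAW weights from the expert elicitation (descending importance).
#: Proportional to the impact percentages (e.g. 4.5/15 = 30%); metadata only.
RAW_SAW_WEIGHTS = {
    "income": 4.5,
    "occupation": 4.0,
    "education": 3.0,
    "home": 2.0,
    "family": 1.5,
}


class OccupationRank(str, Enum):
    HIGH = "high"
    AVERAGE = "average"
    LOW = "low"


class EducationLevel(str, Enum):
    UNDER_DIPLOMA = "under_diploma"
    DIPLOMA_TO_BACHELOR = "diploma_to_bachelor"
    MASTER_AND_ABOVE = "master_and_above"


class Tenure(str, Enum):
    OWNER = "owner"
    TENANT = "tenant"


class SESClass(str, Enum):
    """Five ordered SES classes, poorest first."""

    EXTREMELY_POOR = "extremely_poor"
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    WEALTHY = "wealthy"

    @property
    def rank(self) -> int:
        """0-based position in the poorest-to-wealthiest order."""
        return list(SESClass).index(self)


# Class bands on the composite scale (default weights): lower bounds of
# [100,225), [225,349), [349,473), [473,597), [597, +inf). The printed
# ceiling of the top band is 720, but the tables admit 722, so the band
# is open above (see docs/methods.md).
_CLASS_LOWER_BOUNDS = (100.0, 225.0, 349.0, 473.0, 597.0)

COMPOSITE_MIN = 100.0
#: Largest composite attainable from the tables under default weights
#: (indicator scores 7, 6, 7, 10, 8). The source tables quote 720; the
#: arithmetic gives 722 — a documented discrepancy, not enforced.
COMPOSITE_MAX = 722.0

_OCCUPATION_SCORES = {
    OccupationRank.HIGH: 6,
    OccupationRank.AVERAGE: 3,
    OccupationRank.LOW: 1,
}

_EDUCATION_SCORES = {
    EducationLevel.UNDER_DIPLOMA: 1,
    EducationLevel.DIPLOMA_TO_BACHELOR: 4,
    EducationLevel.MASTER_AND_ABOVE: 7,
}

#: Price-per-m2 quintile (1 = cheapest locally) -> price score.
_PRICE_QUINTILE_SCORES = {1: 1, 2: 3, 3: 5, 4: 7, 5: 9}

#: Homeowner product-score ranges -> final home-status score.
#: Product s*p of surface score (1-5) and price score (1,3,5,7,9) falls
#: in 1..45; ranges 1-5, 6-15, 16-29, 30-39, 40-45 define homeowner
#: groups 1-5 which score 4, 5, 7, 9, 10 on the merged tenure scale.
_HOMEOWNER_GROUP_RANGES = ((1, 5), (6, 15), (16, 29), (30, 39), (40, 45))
_HOMEOWNER_GROUP_SCORES = (4, 5, 7, 9, 10)

#: Tenant groups 1-5 -> final home-status score on the merged scale.
_TENANT_GROUP_SCORES = (1, 2, 3, 6, 8)

_FAMILY_SCORES = {1: 8, 2: 8, 3: 5, 4: 3}  # >= 5 scores 1


def score_income(income: float, anchors: EconomicAnchors) -> int:
    """Score monthly household income 1-7 against CPL multiples.

    Bands are upper-inclusive: income <= CPL/2 scores 1, then each
    successive band ( k*CPL, (k+1)*CPL ] scores one more, with income
    above 5*CPL scoring 7.
    """
    if income < 0:
        raise ValidationError(f"income must be nonnegative, got {income!r}")
    r = income / anchors.cpl
    if r <= 0.5:
        return 1
    if r <= 1:
        return 2
    if r <= 2:
        return 3
    if r <= 3:
        return 4
    if r <= 4:
        return 5
    if r <= 5:
        return 6
    return 7


def score_occupation(rank: OccupationRank | str) -> int:
    """Score occupation rank: high 6, average 3, low 1."""
    try:
        rank = OccupationRank(rank)
    except ValueError:
        valid = ", ".join(r.value for r in OccupationRank)
        raise ValidationError(f"unknown occupation rank {rank!r}; expected one of: {valid}") from None
    return _OCCUPATION_SCORES[rank]


def score_education(level: EducationLevel | str) -> int:
    """Score education level: under diploma 1, diploma-bachelor 4, master+ 7."""
    try:
        level = EducationLevel(level)
    except ValueError:
        valid = ", ".join(lv.value for lv in EducationLevel)
        raise ValidationError(f"unknown education level {level!r}; expected one of: {valid}") from None
    return _EDUCATION_SCORES[level]


def surface_score(surface: float) -> int:
    """Home-surface score 1-5: <=100 m2 scores 1, each further 100 m2
    band one more, >400 m2 scores 5."""
    if not surface > 0:
        raise ValidationError(f"home surface must be positive, got {surface!r}")
    if surface <= 100:
        return 1
    if surface <= 200:
        return 2
    if surface <= 300:
        return 3
    if surface <= 400:
        return 4
    return 5


def price_score(price_quintile: int) -> int:
    """Price score from the local price-per-m2 quintile: 1,3,5,7,9."""
    if price_quintile not in _PRICE_QUINTILE_SCORES:
        raise ValidationError(
            f"price quintile must be an integer 1-5, got {price_quintile!r}"
        )
    return _PRICE_QUINTILE_SCORES[price_quintile]


def score_home_owner(surface: float, price_quintile: int) -> int:
    """Score a homeowner 4-10 on the merged home-status scale.

    The surface score (1-5) and the price score (1,3,5,7,9) are
    multiplied; the product, in 1..45, selects one of five homeowner
    groups which maps to the merged tenure scale.
    """
    product = surface_score(surface) * price_score(price_quintile)
    for (lo, hi), final in zip(_HOMEOWNER_GROUP_RANGES, _HOMEOWNER_GROUP_SCORES):
        if lo <= product <= hi:
            return final
    raise AssertionError(f"homeowner product {product} outside 1..45")  # pragma: no cover


def score_tenant(rent: float, anchors: EconomicAnchors) -> int:
    """Score a tenant 1-8 on the merged home-status scale from rent in
    NMW multiples: <NMW/3, [NMW/3, NMW), [NMW, 2NMW), [2NMW, 5NMW], >5NMW.
    """
    if rent < 0:
        raise ValidationError(f"rent must be nonnegative, got {rent!r}")
    r = rent / anchors.nmw
    if r < 1 / 3:
        group = 1
    elif r < 1:
        group = 2
    elif r < 2:
        group = 3
    elif r <= 5:
        group = 4
    else:
        group = 5
    return _TENANT_GROUP_SCORES[group - 1]


def score_family_size(fs: int) -> int:
    """Score family size: 1-2 members 8, three 5, four 3, five or more 1.

    Smaller households score higher because a given income stretches
    further per person.
    """
    if fs < 1 or int(fs) != fs:
        raise ValidationError(f"family size must be a positive integer, got {fs!r}")
    return _FAMILY_SCORES.get(int(fs), 1)


def composite_score(
    income_score: int,
    occupation_score: int,
    education_score: int,
    home_score: int,
    family_score: int,
    weights: SESWeights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted SAW composite: sum of weight_i * indicator score_i.

    With the default weights (30, 27, 20, 13, 10) the minimum over the
    tables is 100 and the maximum 722.
    """
    return (
        weights.income_w * income_score
        + weights.occupation_w * occupation_score
        + weights.education_w * education_score
        + weights.home_w * home_score
        + weights.family_w * family_score
    )


def classify_ses(composite: float) -> SESClass:
    """Map a composite score to the five-class SES label.

    Bands: [100,225) extremely_poor, [225,349) poor, [349,473) moderate,
    [473,597) good, >=597 wealthy. The top band has no upper cap. The
    bands are calibrated to the default weights; a composite below 100
    is rejected.
    """
    if composite < COMPOSITE_MIN:
        raise ValidationError(
            f"composite {composite!r} is below the scale minimum {COMPOSITE_MIN}; "
            "class bands are only defined for the default weights"
        )
    cls = SESClass.EXTREMELY_POOR
    for bound, candidate in zip(_CLASS_LOWER_BOUNDS, SESClass):
        if composite >= bound:
            cls = candidate
    return cls


@dataclass(frozen=True)
class IndividualSES:
    """Raw SES attributes of one surveyed person.

    Owners carry ``home_surface`` and ``price_quintile``; tenants carry
    ``monthly_rent``. The unused tenure branch must be left as None.
    """

    monthly_income: float
    occupation_rank: OccupationRank
    education_level: EducationLevel
    tenure: Tenure
    family_size: int
    home_surface: Optional[float] = None
    price_quintile: Optional[int] = None
    monthly_rent: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupation_rank", OccupationRank(self.occupation_rank))
        object.__setattr__(self, "education_level", EducationLevel(self.education_level))
        object.__setattr__(self, "tenure", Tenure(self.tenure))
        if self.tenure is Tenure.OWNER:
            if self.home_surface is None or self.price_quintile is None:
                raise ValidationError(
                    "owner records require home_surface and price_quintile"
                )
        else:
            if self.monthly_rent is None:
                raise ValidationError("tenant records require monthly_rent")


@dataclass(frozen=True)
class SESScore:
    """Per-indicator scores, the weighted composite, and the class label."""

    income_score: int
    occupation_score: int
    education_score: int
    home_score: int
    family_score: int
    composite: float
    ses_class: SESClass


def score_individual(
    ind: IndividualSES,
    anchors: EconomicAnchors,
    weights: SESWeights = DEFAULT_WEIGHTS,
) -> SESScore:
    """Score one individual end to end: indicators, composite, class."""
    inc = score_income(ind.monthly_income, anchors)
    occ = score_occupation(ind.occupation_rank)
    edu = score_education(ind.education_level)
    if ind.tenure is Tenure.OWNER:
        home = score_home_owner(ind.home_surface, ind.price_quintile)
    else:
        home = score_tenant(ind.monthly_rent, anchors)
    fam = score_family_size(ind.family_size)
    comp = composite_score(inc, occ, edu, home, fam, weights)
    return SESScore(inc, occ, edu, home, fam, comp, classify_ses(comp))
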