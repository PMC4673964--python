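"""Tabulated SES scorers, the weighted composite, and the class bands."""

import itertools
import logging

import numpy as np
import pytest

from pharmequity import (
    DEFAULT_WEIGHTS,
    EconomicAnchors,
    IndividualSES,
    SESClass,
    SESWeights,
    ValidationError,
    classify_ses,
    composite_score,
    score_education,
    score_family_size,
    score_home_owner,
    score_income,
    score_individual,
    score_occupation,
    score_tenant,
)
from pharmequity.ses import COMPOSITE_MAX, COMPOSITE_MIN

# ---------------------------------------------------------------------------
# Literal transcriptions of the published tables, used as independent oracles.

# Income bands in CPL multiples: (lower, upper, upper_inclusive) -> score.
INCOME_BANDS = [
    (0.0, 0.5, True, 1),
    (0.5, 1.0, True, 2),
    (1.0, 2.0, True, 3),
    (2.0, 3.0, True, 4),
    (3.0, 4.0, True, 5),
    (4.0, 5.0, True, 6),
    (5.0, np.inf, False, 7),
]

# Tenant bands in NMW multiples: (lower, lower_incl, upper, upper_incl) -> score.
TENANT_BANDS = [
    (0.0, True, 1 / 3, False, 1),
    (1 / 3, True, 1.0, False, 2),
    (1.0, True, 2.0, False, 3),
    (2.0, True, 5.0, True, 6),
    (5.0, False, np.inf, False, 8),
]

SURFACE_BANDS = [(0, 100, 1), (100, 200, 2), (200, 300, 3), (300, 400, 4), (400, np.inf, 5)]
PRICE_SCORES = {1: 1, 2: 3, 3: 5, 4: 7, 5: 9}
HOMEOWNER_RANGES = [(1, 5, 4), (6, 15, 5), (16, 29, 7), (30, 39, 9), (40, 45, 10)]


def income_band_oracle(ratio: float) -> list[int]:
    """All band scores whose interval contains income = ratio * CPL."""
    hits = []
    for lo, hi, hi_incl, score in INCOME_BANDS:
        above = ratio > lo or (lo == 0.0 and ratio >= 0.0)
        below = ratio <= hi if hi_incl else ratio < hi
        if above and below:
            hits.append(score)
    return hits


def tenant_band_oracle(ratio: float) -> list[int]:
    hits = []
    for lo, lo_incl, hi, hi_incl, score in TENANT_BANDS:
        above = ratio >= lo if lo_incl else ratio > lo
        below = ratio <= hi if hi_incl else ratio < hi
        if above and below:
            hits.append(score)
    return hits


def home_owner_oracle(surface: float, quintile: int) -> int:
    s = next(sc for lo, hi, sc in SURFACE_BANDS if lo < surface <= hi)
    product = s * PRICE_SCORES[quintile]
    return next(final for lo, hi, final in HOMEOWNER_RANGES if lo <= product <= hi)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ratio, expected",
    [(0.4, 1), (0.5, 1), (1.0, 2), (1.5, 3), (2.0, 3), (3.5, 5), (5.0, 6), (6.0, 7)],
)
def test_income_bands(anchors, ratio, expected):
    assert score_income(ratio * anchors.cpl, anchors) == expected


def test_income_bands_partition_the_axis(anchors):
    """Every income multiple falls in exactly one band; the scorer agrees."""
    for ratio in np.arange(0.0, 7.0001, 0.005):
        hits = income_band_oracle(round(float(ratio), 10))
        assert len(hits) == 1, f"ratio {ratio}: bands {hits}"
        assert score_income(ratio * anchors.cpl, anchors) == hits[0]


def test_income_negative_rejected(anchors):
    with pytest.raises(ValidationError):
        score_income(-1.0, anchors)


@pytest.mark.parametrize("rank, expected", [("high", 6), ("average", 3), ("low", 1)])
def test_occupation_scores(rank, expected):
    assert score_occupation(rank) == expected


@pytest.mark.parametrize(
    "level, expected",
    [("under_diploma", 1), ("diploma_to_bachelor", 4), ("master_and_above", 7)],
)
def test_education_scores(level, expected):
    assert score_education(level) == expected


@pytest.mark.parametrize("bad", ["manager", "", "phd"])
def test_categorical_scorers_reject_unknown_labels(bad):
    with pytest.raises(ValidationError):
        score_occupation(bad)
    with pytest.raises(ValidationError):
        score_education(bad)


@pytest.mark.parametrize(
    "surface, quintile, expected",
    [
        (250, 4, 7),   # surface score 3 x price 7 = 21 -> third homeowner group
        (50, 1, 4),    # minimum product 1
        (500, 5, 10),  # maximum product 45
        (100, 1, 4),   # boundary: 100 m2 is in the lowest band
        (100.5, 1, 4), # just above: band 2, product 3, still first group
    ],
)
def test_home_owner_scores(surface, quintile, expected):
    assert score_home_owner(surface, quintile) == expected


def test_home_owner_full_grid_matches_table_transcription():
    """All 25 surface-band x price-quintile cells agree with the tables;
    products stay in 1..45 and final scores in {4,5,7,9,10}."""
    reps = [50, 150, 250, 350, 450]  # one representative surface per band
    for surface, quintile in itertools.product(reps, range(1, 6)):
        got = score_home_owner(surface, quintile)
        assert got == home_owner_oracle(surface, quintile)
        assert got in {4, 5, 7, 9, 10}


@pytest.mark.parametrize("surface, quintile", [(0, 1), (-5, 2), (100, 0), (100, 6)])
def test_home_owner_rejects_bad_inputs(surface, quintile):
    with pytest.raises(ValidationError):
        score_home_owner(surface, quintile)


@pytest.mark.parametrize(
    "ratio, expected",
    [(0.0, 1), (1 / 3, 2), (0.9, 2), (1.0, 3), (1.5, 3), (2.0, 6), (5.0, 6), (6.0, 8)],
)
def test_tenant_bands(anchors, ratio, expected):
    assert score_tenant(ratio * anchors.nmw, anchors) == expected


def test_tenant_bands_partition_the_axis(anchors):
    for ratio in np.arange(0.0, 7.0001, 0.005):
        hits = tenant_band_oracle(round(float(ratio), 10))
        assert len(hits) == 1, f"ratio {ratio}: bands {hits}"
        assert score_tenant(ratio * anchors.nmw, anchors) == hits[0]


def test_tenant_negative_rent_rejected(anchors):
    with pytest.raises(ValidationError):
        score_tenant(-0.01, anchors)


@pytest.mark.parametrize("fs, expected", [(1, 8), (2, 8), (3, 5), (4, 3), (5, 1), (9, 1)])
def test_family_size_scores(fs, expected):
    assert score_family_size(fs) == expected


def test_family_size_rejects_nonpositive():
    with pytest.raises(ValidationError):
        score_family_size(0)


# ---------------------------------------------------------------------------
# Composite and classification.

INDICATOR_DOMAINS = {
    "income": range(1, 8),
    "occupation": (1, 3, 6),
    "education": (1, 4, 7),
    "home": range(1, 11),
    "family": (1, 3, 5, 8),
}


def test_worked_example_composite():
    assert composite_score(6, 3, 7, 5, 5) == 516
    assert classify_ses(516) is SESClass.GOOD


def test_minimum_composite():
    assert composite_score(1, 1, 1, 1, 1) == 100
    assert classify_ses(100) is SESClass.EXTREMELY_POOR


def test_table_maximum_composite():
    assert composite_score(7, 6, 7, 10, 8) == 722
    assert classify_ses(722) is SESClass.WEALTHY


def test_exhaustive_enumeration_range_and_classifier_totality():
    """Brute force over all 2,520 indicator-score combinations: the
    composite equals the literal weighted sum, stays in [100, 722], and
    every value gets exactly one class label."""
    weights = (30, 27, 20, 13, 10)
    values = []
    for combo in itertools.product(*INDICATOR_DOMAINS.values()):
        expected = sum(w * s for w, s in zip(weights, combo))
        got = composite_score(*combo)
        assert got == expected
        cls = classify_ses(got)
        assert isinstance(cls, SESClass)
        values.append(got)
    assert len(values) == 2520
    assert min(values) == COMPOSITE_MIN == 100
    assert max(values) == COMPOSITE_MAX == 722


def test_composite_strictly_increasing_in_each_indicator():
    base = [4, 3, 4, 5, 3]
    for i, domain in enumerate(INDICATOR_DOMAINS.values()):
        prev = None
        for s in sorted(domain):
            combo = list(base)
            combo[i] = s
            val = composite_score(*combo)
            if prev is not None:
                assert val > prev
            prev = val


@pytest.mark.parametrize(
    "composite, expected",
    [
        (100, SESClass.EXTREMELY_POOR),
        (224, SESClass.EXTREMELY_POOR),
        (225, SESClass.POOR),
        (348, SESClass.POOR),
        (349, SESClass.MODERATE),
        (472, SESClass.MODERATE),
        (473, SESClass.GOOD),
        (596, SESClass.GOOD),
        (597, SESClass.WEALTHY),
        (722, SESClass.WEALTHY),
    ],
)
def test_class_band_boundaries(composite, expected):
    assert classify_ses(composite) is expected


def test_classify_rejects_below_scale_minimum():
    with pytest.raises(ValidationError):
        classify_ses(99.9)


def test_weight_override_warns_but_is_permitted(caplog):
    with caplog.at_level(logging.WARNING, logger="pharmequity.ses"):
        w = SESWeights(income_w=40, occupation_w=27, education_w=20, home_w=13, family_w=10)
    assert "110" in caplog.text
    assert composite_score(1, 1, 1, 1, 1, weights=w) == 110


def test_default_weights_sum_to_100():
    assert sum(DEFAULT_WEIGHTS.as_dict().values()) == 100


@pytest.mark.parametrize("cpl, nmw", [(0, 8), (10, 0), (-1, 8)])
def test_anchors_must_be_positive(cpl, nmw):
    with pytest.raises(ValidationError):
        EconomicAnchors(cpl=cpl, nmw=nmw)


def test_individual_tenure_branches(anchors):
    with pytest.raises(ValidationError):
        IndividualSES(
            monthly_income=10, occupation_rank="low", education_level="under_diploma",
            tenure="owner", family_size=2,
        )
    with pytest.raises(ValidationError):
        IndividualSES(
            monthly_income=10, occupation_rank="low", education_level="under_diploma",
            tenure="tenant", family_size=2,
        )
    owner = IndividualSES(
        monthly_income=45, occupation_rank="average", education_level="master_and_above",
        tenure="owner", family_size=3, home_surface=150, price_quintile=2,
    )
    score = score_individual(owner, anchors)
    assert (score.income_score, score.occupation_score, score.education_score,
            score.home_score, score.family_score) == (6, 3, 7, 5, 5)
    assert score.composite == 516
    assert score.ses_class is SESClass.GOOD
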