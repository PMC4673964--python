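"""Nine-level pharmaceutical-access scoring.

Each surveyed person reports how they obtained (or failed to obtain)
their prescribed medicines; the nine ordered statuses are scored by how
comfortable the access was, from 100 (everything available in any
pharmacy) down to 1 (not available at all). The scores weight the
discomfort of each route — a trip to the capital (30) is a much bigger
burden than a few extra pharmacy visits (70), and resorting to the
black market (10) is barely better than no access.

These scores form the access quantity on the concentration curve's
Y-axis. They are treated as an interval scale when access mass is
accumulated; whether that was the elicitors' intent is unknowable from
the published tables, so a count-based alternative is offered (see
:mod:`pharmequity.concentration`).
"""

from __future__ import annotations

from enum import Enum

from .errors import ValidationError

__all__ = ["AccessStatus", "ACCESS_SCORES", "score_access"]


class AccessStatus(str, Enum):
    """Ordered access statuses, most comfortable first."""

    ALL_AVAILABLE = "all_available"
    ALTERNATIVE_AVAILABLE = "alternative_available"
    SPECIFIC_PUBLIC_PHARMACY = "specific_public_pharmacy"
    SEVERAL_PHARMACY_VISITS = "several_pharmacy_visits"
    TRIP_BIGGER_CITY = "trip_bigger_city"
    TRIP_BIGGER_CITY_PUBLIC_PHARMACY = "trip_bigger_city_public_pharmacy"
    TRIP_CAPITAL = "trip_capital"
    BLACK_MARKET = "black_market"
    NOT_AVAILABLE = "not_available"


#: Status -> access score; strictly decreasing across the enum order.
ACCESS_SCORES: dict[AccessStatus, int] = {
    AccessStatus.ALL_AVAILABLE: 100,
    AccessStatus.ALTERNATIVE_AVAILABLE: 90,
    AccessStatus.SPECIFIC_PUBLIC_PHARMACY: 80,
    AccessStatus.SEVERAL_PHARMACY_VISITS: 70,
    AccessStatus.TRIP_BIGGER_CITY: 60,
    AccessStatus.TRIP_BIGGER_CITY_PUBLIC_PHARMACY: 50,
    AccessStatus.TRIP_CAPITAL: 30,
    AccessStatus.BLACK_MARKET: 10,
    AccessStatus.NOT_AVAILABLE: 1,
}

_LEVELS = list(AccessStatus)


def score_access(status: AccessStatus | str | int) -> int:
    """Return the access score for a status.

    Accepts the canonical label, an :class:`AccessStatus` member, or the
    1-based row number of the status table (1 = all available,
    9 = not available).
    """
    if isinstance(status, bool):
        raise ValidationError(f"unrecognized access status {status!r}")
    if isinstance(status, int):
        if not 1 <= status <= 9:
            raise ValidationError(
                f"access status number must be in 1..9, got {status!r}"
            )
        return ACCESS_SCORES[_LEVELS[status - 1]]
    try:
        status = AccessStatus(status)
    except ValueError:
        valid = ", ".join(s.value for s in AccessStatus)
        raise ValidationError(
            f"unrecognized access status {status!r}; valid labels: {valid}"
        ) from None
    return ACCESS_SCORES[status]
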