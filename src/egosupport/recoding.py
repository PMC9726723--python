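"""Categorical recodings used throughout the analysis.

The survey collects contact and support frequency on a six-level categorical
scale.  For aggregation these are converted to an approximate count of
event-days per 30-day month — monthly = 1, a few times a month = 2, weekly =
4, a few times a week = 10, daily = 30 — which adjusts for the unequal gaps
between the categories as collected.  "Less than once a month" contributes 0
days so that the monthly dichotomisation classifies it as not monthly.

Emotional and informational support are pooled (by summing event-days) into
*non-material* support; material support stands alone.
"""

from __future__ import annotations

from .data_model import AGE_BRACKET_BOUNDS, FREQUENCY_CATEGORIES, GENDERS

__all__ = [
    "DEFAULT_FREQUENCY_DAYS", "frequency_to_days", "scale_ordinal",
    "pool_nonmaterial", "dichotomize_monthly", "classify_alter_age",
    "homophily_age", "homophily_gender",
]

#: Event-days per month assigned to each frequency category.
DEFAULT_FREQUENCY_DAYS = {
    "every_day": 30.0,
    "few_times_week": 10.0,
    "once_week": 4.0,
    "few_times_month": 2.0,
    "once_month": 1.0,
    "less_than_monthly": 0.0,
}


def frequency_to_days(cat: str, frequency_map=None) -> float:
    """Map a frequency category to event-days per month.

    A custom ``frequency_map`` (category -> days) may override the default
    coding; it must cover the full vocabulary.
    """
    table = DEFAULT_FREQUENCY_DAYS if frequency_map is None else frequency_map
    if cat not in FREQUENCY_CATEGORIES or cat not in table:
        raise ValueError(f"unknown frequency category {cat!r}")
    return float(table[cat])


def scale_ordinal(level_index: int, n_levels: int) -> float:
    """Linearly scale an ordinal level to [0, 1]: rank / (n_levels - 1)."""
    if n_levels < 2:
        raise ValueError(f"need at least 2 levels, got {n_levels}")
    if not (0 <= level_index < n_levels):
        raise ValueError(f"level index {level_index} outside 0..{n_levels - 1}")
    return level_index / (n_levels - 1)


def pool_nonmaterial(emotional_days: float, informational_days: float) -> float:
    """Pool emotional and informational event-days into non-material support
    by summation (the pooled value counts events and may exceed 30)."""
    if emotional_days < 0 or informational_days < 0:
        raise ValueError("support days must be non-negative")
    return emotional_days + informational_days


def dichotomize_monthly(days: float) -> bool:
    """True iff support arrives at least monthly (>= 1 event-day/month)."""
    if days < 0:
        raise ValueError("support days must be non-negative")
    return days >= 1.0


def _bracket_bounds(bracket: str):
    try:
        return AGE_BRACKET_BOUNDS[bracket]
    except KeyError:
        raise ValueError(f"unknown age bracket {bracket!r}") from None


def classify_alter_age(ego_age: int, bracket: str) -> str:
    """Dichotomise alter age relative to the ego.

    ``younger`` iff the bracket's upper bound is <= the ego's age — the only
    rule expressible from bracketed alter ages; brackets straddling the
    ego's age count as ``same_or_older`` (conservative toward "older"); the
    open-ended top bracket is never younger.
    """
    if ego_age < 18:
        raise ValueError(f"ego age {ego_age} < 18")
    _, upper = _bracket_bounds(bracket)
    return "younger" if upper <= ego_age else "same_or_older"


def homophily_age(ego_age: int, bracket: str) -> bool:
    """True iff the ego's own age falls inside the alter's half-open age
    bracket [lower, upper)."""
    if ego_age < 18:
        raise ValueError(f"ego age {ego_age} < 18")
    lower, upper = _bracket_bounds(bracket)
    return lower <= ego_age < upper


def homophily_gender(ego_gender: str, alter_gender: str) -> bool:
    """True iff ego and alter report the same gender."""
    for g in (ego_gender, alter_gender):
        if g not in GENDERS:
            raise ValueError(f"unknown gender {g!r}")
    return ego_gender == alter_gender
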