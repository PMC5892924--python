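"""Canonical developmental age axis.

Every sample age is expressed in post-conceptual days (pcd) so that fetal
specimens (measured in post-conceptual weeks) and postnatal specimens
(measured in days or years after birth) sit on a single monotone axis.
Term birth is fixed at 38 post-conceptual weeks = 266 days; a sample is
*postnatal* iff its age exceeds this threshold. The threshold is a module
constant but every public function accepts ``birth_pcd`` for sensitivity
analyses.
"""

from __future__ import annotations

import math
import re

from .errors import DomainError, ParseError

#: Term birth, in post-conceptual days (38 weeks).
BIRTH_PCD: float = 266.0

DAYS_PER_YEAR: float = 365.25

#: Canonical age units and their accepted aliases.
_UNIT_ALIASES = {
    "pcw": "pcw",
    "pcd": "pcd",
    "days_postnatal": "days_postnatal",
    "days": "days_postnatal",
    "d": "days_postnatal",
    "years_postnatal": "years_postnatal",
    "years": "years_postnatal",
    "year": "years_postnatal",
    "y": "years_postnatal",
}


def canonical_unit(unit: str) -> str:
    """Resolve a unit alias to one of pcw / pcd / days_postnatal / years_postnatal."""
    key = str(unit).strip().lower()
    if key not in _UNIT_ALIASES:
        raise DomainError(f"unknown age unit {unit!r}")
    return _UNIT_ALIASES[key]


def convert_age(raw_age: float, unit: str, birth_pcd: float = BIRTH_PCD) -> float:
    """Convert an age to post-conceptual days.

    Prenatal units (``pcw``, ``pcd``) count from conception and must be
    strictly positive. Postnatal units count from birth and may be zero
    (a neonate at birth maps exactly to ``birth_pcd``).

    >>> convert_age(5.7, "pcw")
    39.9
    >>> convert_age(0, "years_postnatal")
    266.0
    """
    unit = canonical_unit(unit)
    value = float(raw_age)
    if not math.isfinite(value):
        raise DomainError(f"age must be finite, got {raw_age!r}")
    if unit in ("pcw", "pcd"):
        if value <= 0:
            raise DomainError(f"post-conceptual age must be > 0, got {value}")
        return value * 7.0 if unit == "pcw" else value
    # postnatal units
    if value < 0:
        raise DomainError(f"postnatal age must be >= 0, got {value}")
    days = value if unit == "days_postnatal" else value * DAYS_PER_YEAR
    return birth_pcd + days


_AGE_STRING = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Z_]+)\s*$")


def parse_age(text: str) -> tuple[float, str]:
    """Split an age string such as ``"20 pcw"`` or ``"25 years"`` into (value, unit)."""
    m = _AGE_STRING.match(str(text))
    if m is None:
        raise ParseError(f"cannot parse age {text!r}; expected '<number> <unit>'")
    try:
        value = float(m.group(1))
    except ValueError as exc:
        raise ParseError(f"cannot parse age value in {text!r}") from exc
    return value, canonical_unit(m.group(2))


def is_postnatal(age_pcd: float, birth_pcd: float = BIRTH_PCD) -> bool:
    """True iff an age (in post-conceptual days) falls after term birth."""
    return float(age_pcd) > float(birth_pcd)
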