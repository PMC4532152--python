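"""Age-sex strata: 5-year age bands (open-topped at 85+) crossed with sex."""

from __future__ import annotations

import re
from dataclasses import dataclass

SEXES: tuple[str, str] = ("female", "male")

_BAND_RE = re.compile(r"^(\d{1,3})-(\d{1,3})$")
_OPEN_RE = re.compile(r"^(\d{1,3})\+$")


def parse_age_lower(age_group: str) -> int:
    """Return the numeric lower bound of an age-band label ("60-64" -> 60, "85+" -> 85)."""
    m = _BAND_RE.match(age_group)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"age band {age_group!r} has upper bound below lower bound")
        return lo
    m = _OPEN_RE.match(age_group)
    if m:
        return int(m.group(1))
    raise ValueError(f"unparseable age band label: {age_group!r}")


def default_age_groups(start: int = 15, stop: int = 85, width: int = 5) -> list[str]:
    """Standard non-overlapping bands from ``start`` up to an open top band ``stop+``."""
    bands = [f"{lo}-{lo + width - 1}" for lo in range(start, stop, width)]
    bands.append(f"{stop}+")
    return bands


@dataclass(frozen=True, slots=True)
class StratumSpec:
    """One age-band x sex cell of the population."""

    age_group: str
    sex: str

    def __post_init__(self) -> None:
        parse_age_lower(self.age_group)  # raises on bad label
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def age_lower(self) -> int:
        return parse_age_lower(self.age_group)


def validate_partition(age_groups: list[str]) -> None:
    """Check that age bands are disjoint, contiguous 5-year bands with one open top."""
    lowers = sorted(parse_age_lower(g) for g in age_groups)
    if len(set(lowers)) != len(lowers):
        raise ValueError("age bands overlap: duplicate lower bounds")
    for a, b in zip(lowers, lowers[1:]):
        if b - a != 5:
            raise ValueError(f"age bands not contiguous 5-year intervals near {a}")
    opens = [g for g in age_groups if g.endswith("+")]
    if len(opens) != 1:
        raise ValueError("exactly one open top band (e.g. '85+') required")
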