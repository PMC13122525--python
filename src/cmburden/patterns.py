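"""Maltreatment types, the 32 joint exposure patterns, and exposure-level codings.

Five binary maltreatment types are considered: physical abuse (PA), sexual
abuse (SA), emotional abuse (EA), neglect (N) and exposure to domestic
violence (EDV).  Their joint experience defines 2**5 = 32 mutually exclusive
exposure patterns.  Relative risks are not estimated per pattern (most are too
rare); instead each pattern is mapped to an exposure *level* under a coding:

``count_of_types``
    levels "0".."5", the number of maltreatment types experienced;
``six_common_patterns``
    the six most frequently observed multi-type patterns get their own named
    level; every other pattern falls back to its count-of-types level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "TYPE_NAMES",
    "TYPE_ABBREV",
    "MaltreatmentPattern",
    "ExposureCoding",
    "COUNT_CODING",
    "SIX_PATTERN_CODING",
    "SIX_COMMON_PATTERN_CODES",
    "enumerate_patterns",
    "count_types",
    "map_to_level",
    "pattern_codes",
]

#: canonical bit order of the five maltreatment types
TYPE_NAMES = ("physical_abuse", "sexual_abuse", "emotional_abuse", "neglect", "exposure_dv")
TYPE_ABBREV = ("PA", "SA", "EA", "N", "EDV")


@dataclass(frozen=True, order=True)
class MaltreatmentPattern:
    """One of the 32 joint maltreatment-exposure patterns.

    The canonical string code is five characters of 0/1 in the fixed bit
    order PA, SA, EA, N, EDV — e.g. ``"10110"`` is physical abuse + emotional
    abuse + neglect.
    """

    physical_abuse: bool
    sexual_abuse: bool
    emotional_abuse: bool
    neglect: bool
    exposure_dv: bool

    @property
    def flags(self) -> tuple[bool, ...]:
        return (
            self.physical_abuse,
            self.sexual_abuse,
            self.emotional_abuse,
            self.neglect,
            self.exposure_dv,
        )

    @property
    def code(self) -> str:
        """Five-character 0/1 code in bit order PA, SA, EA, N, EDV."""
        return "".join("1" if f else "0" for f in self.flags)

    @classmethod
    def from_code(cls, code: str) -> "MaltreatmentPattern":
        if len(code) != 5 or set(code) - {"0", "1"}:
            raise ValueError(f"pattern code must be 5 chars of 0/1, got {code!r}")
        return cls(*(c == "1" for c in code))

    @property
    def n_types(self) -> int:
        return sum(self.flags)

    def abbrev(self) -> str:
        """Human-readable label, e.g. ``"PA+EA"``; ``"none"`` for all-zero."""
        parts = [a for a, f in zip(TYPE_ABBREV, self.flags) if f]
        return "+".join(parts) if parts else "none"

    def __iter__(self) -> Iterator[bool]:
        return iter(self.flags)


def enumerate_patterns() -> list[MaltreatmentPattern]:
    """All 32 patterns in canonical order (code "00000" first, "11111" last).

    Ordering is by the integer value of the code string with PA as the most
    significant bit, so the all-unexposed pattern is always first.
    """
    return [MaltreatmentPattern.from_code(format(i, "05b")) for i in range(32)]


def pattern_codes() -> list[str]:
    """Canonical pattern code strings, same order as :func:`enumerate_patterns`."""
    return [format(i, "05b") for i in range(32)]


def count_types(pattern: MaltreatmentPattern) -> int:
    """Number of maltreatment types experienced (0–5)."""
    return pattern.n_types


# The six most common multi-type patterns, each an RR level of its own under
# the six_common_patterns coding.  Codes are in PA,SA,EA,N,EDV bit order.
SIX_COMMON_PATTERN_CODES: dict[str, str] = {
    "11101": "EDV+EA+PA+SA",
    "10101": "EDV+EA+PA",
    "00101": "EDV+EA",
    "11111": "ALL5",
    "10001": "EDV+PA",
    "01001": "EDV+SA",
}


@dataclass(frozen=True)
class ExposureCoding:
    """A total mapping from the 32 patterns to RR exposure-level labels."""

    mode: str  # "count_of_types" | "six_common_patterns"

    def __post_init__(self) -> None:
        if self.mode not in ("count_of_types", "six_common_patterns"):
            raise ValueError(f"unknown coding mode {self.mode!r}")

    @property
    def levels(self) -> list[str]:
        """All level labels this coding can emit, reference level first."""
        counts = [str(k) for k in range(6)]
        if self.mode == "count_of_types":
            return counts
        # rare patterns fall back to their type count; count-5 is always ALL5
        return counts[:5] + list(SIX_COMMON_PATTERN_CODES.values())

    def pattern_to_level(self, pattern: MaltreatmentPattern) -> str:
        if self.mode == "count_of_types":
            return str(pattern.n_types)
        named = SIX_COMMON_PATTERN_CODES.get(pattern.code)
        if named is not None:
            return named
        # the 26 rare patterns carry the RR of their type count
        return str(pattern.n_types)

    def level_map(self) -> dict[str, str]:
        """Mapping pattern code -> level label over all 32 patterns."""
        return {p.code: self.pattern_to_level(p) for p in enumerate_patterns()}


COUNT_CODING = ExposureCoding("count_of_types")
SIX_PATTERN_CODING = ExposureCoding("six_common_patterns")


def map_to_level(pattern: MaltreatmentPattern, coding: ExposureCoding) -> str:
    """Exposure level label of *pattern* under *coding* (total, deterministic)."""
    return coding.pattern_to_level(pattern)
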