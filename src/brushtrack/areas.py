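"""The dentition area code system.

The dentition is divided into six sextants and three surfaces per sextant,
giving 18 brushable areas.  Codes are 4-digit strings: the first pair is the
sextant, the second pair the surface.

Sextants (first digit pair)
    01  upper right posterior      04  lower left posterior
    02  upper anterior             05  lower anterior
    03  upper left posterior       06  lower right posterior

so the vertically opposing pairs are (01,06), (02,05) and (03,04).  Three
*combined* sextant codes — 16, 25, 34 — denote vestibular brushing across an
opposing pair with the jaws closed; they are only valid with the vestibular
surface.

Surfaces (second digit pair)
    01  occlusal/incisal (chewing/biting edge)
    02  vestibular (cheek/lip side)
    03  oral (tongue/palate side)
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AreaCodeFormatError, AreaCodeValidationError

#: Sentinel label for time covered by no coded behaviour.  It is excluded
#: from agreement denominators and from all duration sums.
UNCODED = "uncoded"

OCCLUSAL = "01"
VESTIBULAR = "02"
ORAL = "03"

SINGLE_SEXTANTS = ("01", "02", "03", "04", "05", "06")
SURFACES = (OCCLUSAL, VESTIBULAR, ORAL)

#: Combined closed-jaw sextant codes and the opposing pairs they span.
COMBINED_SEXTANT_MEMBERS = {
    "16": ("01", "06"),
    "25": ("02", "05"),
    "34": ("03", "04"),
}
COMBINED_CODES = ("1602", "2502", "3402")

UPPER_ARCH = ("01", "02", "03")
LOWER_ARCH = ("04", "05", "06")

#: Posterior (molar) sextants use the 20 deg brush-angle threshold,
#: anterior sextants the 13 deg one.
MOLAR_SEXTANTS = ("01", "03", "04", "06")
ANTERIOR_SEXTANTS = ("02", "05")


@dataclass(frozen=True)
class AreaCode:
    """One dentition area: a sextant (single or combined pair) x a surface."""

    sextant: str
    surface: str

    def __post_init__(self):
        if self.sextant in COMBINED_SEXTANT_MEMBERS:
            if self.surface != VESTIBULAR:
                raise AreaCodeValidationError(
                    f"combined sextant {self.sextant!r} is only defined for the "
                    f"vestibular surface, got surface {self.surface!r}"
                )
        elif self.sextant not in SINGLE_SEXTANTS:
            raise AreaCodeValidationError(f"unknown sextant {self.sextant!r}")
        elif self.surface not in SURFACES:
            raise AreaCodeValidationError(f"unknown surface {self.surface!r}")

    @property
    def is_combined(self) -> bool:
        return self.sextant in COMBINED_SEXTANT_MEMBERS

    @property
    def member_sextants(self) -> tuple[str, ...]:
        """The single sextants this code touches (two for combined codes)."""
        if self.is_combined:
            return COMBINED_SEXTANT_MEMBERS[self.sextant]
        return (self.sextant,)

    @property
    def code(self) -> str:
        return self.sextant + self.surface

    def __str__(self) -> str:
        return self.code


def parse_area_code(code: str) -> AreaCode:
    """Parse a 4-digit area code string into an :class:`AreaCode`.

    The first digit pair is the sextant (01-06, or combined 16/25/34), the
    second pair the surface (01 occlusal/incisal, 02 vestibular, 03 oral).

    Raises
    ------
    AreaCodeFormatError
        If ``code`` is not a string of exactly 4 decimal digits.
    AreaCodeValidationError
        If the sextant or surface pair is unknown, or a combined sextant is
        used with a non-vestibular surface.
    """
    if not isinstance(code, str) or len(code) != 4 or not code.isdigit():
        raise AreaCodeFormatError(
            f"area code must be 4 decimal digits, got {code!r}"
        )
    return AreaCode(sextant=code[:2], surface=code[2:])


def enumerate_areas(include_combined: bool = False) -> list[AreaCode]:
    """All areas in sextant-major order: 0101, 0102, 0103, 0201, ...

    Without combined codes this is exactly the 18 single-sextant areas;
    with them, the three closed-jaw codes 1602, 2502, 3402 are appended.
    """
    out = [AreaCode(s, f) for s in SINGLE_SEXTANTS for f in SURFACES]
    if include_combined:
        out.extend(parse_area_code(c) for c in COMBINED_CODES)
    return out


#: The 18 single-sextant area labels, sextant-major.
ALL_AREAS: tuple[str, ...] = tuple(a.code for a in enumerate_areas(False))

#: The same plus the three combined codes (confusion-matrix axis order).
ALL_AREAS_WITH_COMBINED: tuple[str, ...] = tuple(
    a.code for a in enumerate_areas(True)
)

#: The 12 smooth-surface areas the systematics index is computed over
#: (occlusal/incisal areas are ignored by the index).
SMOOTH_AREAS: tuple[str, ...] = tuple(
    a.code for a in enumerate_areas(False) if a.surface != OCCLUSAL
)

#: Labels admissible in a smooth-surface restriction: the 12 smooth areas
#: plus the combined closed-jaw codes (which are vestibular by definition).
SMOOTH_AREAS_WITH_COMBINED: tuple[str, ...] = SMOOTH_AREAS + COMBINED_CODES


def sextants_adjacent(a: str, b: str) -> bool:
    """Whether two *single* sextants are neighbours.

    Neighbouring means consecutive within the same arch (e.g. 01-02) or
    vertically opposing (01-06, 02-05, 03-04; a closed jaw puts these in
    contact, and closed-jaw brushing spans them).
    """
    if a == b:
        return True
    for arch in (UPPER_ARCH, LOWER_ARCH):
        if a in arch and b in arch:
            return abs(arch.index(a) - arch.index(b)) == 1
    return {a, b} in ({"01", "06"}, {"02", "05"}, {"03", "04"})


def region_of_sextant(sextant: str) -> str:
    """Angle-threshold region of a sextant: ``molar`` or ``anterior``.

    Combined codes inherit the region of their member sextants (16 and 34
    span posterior sextants, 25 the anterior ones).
    """
    if sextant in COMBINED_SEXTANT_MEMBERS:
        sextant = COMBINED_SEXTANT_MEMBERS[sextant][0]
    return "anterior" if sextant in ANTERIOR_SEXTANTS else "molar"
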