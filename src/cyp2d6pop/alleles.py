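"""Star-allele haplotypes, activity scores and CPIC phenotype translation.

CYP2D6 haplotypes are named with star (*) allele nomenclature.  Beyond
simple single-copy alleles (``*4``), one chromosome may carry a gene
duplication (``*4x2`` = two copies of *4) or a tandem arrangement of
different gene copies (``*36+*10`` = one *36 copy followed by one *10
copy; ``*36x2+*10`` = two *36 copies plus one *10 copy).  A haplotype is
therefore an ordered list of (core allele, copy count) components.

Each core allele has an activity value in {0, 0.25, 0.5, 1.0}; a
haplotype's value is the sum of base value x copy count over its
components, which implements the rule that a duplicated allele counts
double its single-copy counterpart.  A diplotype's activity score (AS)
is the sum of its two haplotype values, and the AS maps to the CPIC
metabolizer phenotype: PM (AS = 0), IM (0 < AS <= 1), NM
(1 < AS <= 2.25), UM (AS > 2.25).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AlleleDefinitionTable",
    "AlleleModelError",
    "ClassificationError",
    "Diplotype",
    "Haplotype",
    "LabelParseError",
    "PhenotypeClass",
    "UndefinedAlleleError",
    "canonical_diplotype_label",
    "diplotype_activity_score",
    "format_haplotype",
    "haplotype_activity_value",
    "haplotype_function_class",
    "parse_diplotype_label",
    "parse_haplotype_label",
    "phenotype_from_score",
]


class AlleleModelError(ValueError):
    """Base class for allele-model failures."""


class LabelParseError(AlleleModelError):
    """A star-allele label does not match the expected grammar."""


class UndefinedAlleleError(AlleleModelError, KeyError):
    """A core allele is absent from the definition table."""


class ClassificationError(AlleleModelError):
    """An activity value does not fall into any function class."""


# One haplotype component: "*" core ["x" copies], copies >= 2 when present.
# The core may not contain "*", "+", "/" or "x" (those are structural).
_COMPONENT_RE = re.compile(r"^\*([^*+/x]+)(?:x(\d+))?$")


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's CYP2D6 arrangement: ordered (core, copies) pairs.

    ``components`` preserves the order written in the label, e.g.
    ``*36x2+*10`` -> (("36", 2), ("10", 1)).  ``raw_label`` keeps the
    text as parsed and does not participate in equality.
    """

    components: tuple[tuple[str, int], ...]
    raw_label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.components:
            raise AlleleModelError("a haplotype needs at least one component")
        for core, copies in self.components:
            if not core or "x" in core or "+" in core:
                raise AlleleModelError(f"invalid core allele identifier {core!r}")
            if copies < 1:
                raise AlleleModelError(f"copy count must be >= 1, got {copies} for core {core!r}")

    @property
    def label(self) -> str:
        return format_haplotype(self)

    def cores(self) -> tuple[str, ...]:
        return tuple(core for core, _ in self.components)

    def sort_key(self) -> tuple:
        """Deterministic ordering: numeric core rank, then copies, per component."""
        return tuple((_core_rank(core), copies) for core, copies in self.components)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _core_rank(core: str) -> tuple:
    # Numeric cores (the PharmVar norm) sort by value; anything else after, lexically.
    return (0, int(core), "") if core.isdigit() else (1, 0, core)


def parse_haplotype_label(label: str) -> Haplotype:
    """Parse a star-allele label like ``*36x2+*10`` into a :class:`Haplotype`.

    Grammar: components joined by ``+``; each component is ``*`` + core +
    optional ``xN`` with N >= 2.  Copy count defaults to 1.

    Raises
    ------
    LabelParseError
        If the label (or one component) does not match the grammar; the
        message names the offending token.
    """
    if not isinstance(label, str):
        raise LabelParseError(f"expected a text label, got {type(label).__name__}")
    text = label.strip()
    if not text:
        raise LabelParseError("empty haplotype label")
    components: list[tuple[str, int]] = []
    for token in text.split("+"):
        m = _COMPONENT_RE.match(token.strip())
        if m is None:
            raise LabelParseError(f"malformed haplotype component {token.strip()!r} in label {label!r}")
        core, copies_s = m.groups()
        copies = 1 if copies_s is None else int(copies_s)
        if copies_s is not None and copies < 2:
            raise LabelParseError(f"copy suffix must be >= 2 in component {token.strip()!r}")
        components.append((core, copies))
    return Haplotype(tuple(components), raw_label=label)


def format_haplotype(h: Haplotype) -> str:
    """Canonical text form; ``parse_haplotype_label(format_haplotype(h)) == h``."""
    parts = []
    for core, copies in h.components:
        parts.append(f"*{core}" if copies == 1 else f"*{core}x{copies}")
    return "+".join(parts)


_ALLOWED_BASE_VALUES = (0.0, 0.25, 0.5, 1.0)
_CLASS_FOR_VALUE = {0.0: "none", 0.25: "decreased", 0.5: "decreased", 1.0: "normal"}


class AlleleDefinitionTable:
    """Maps a core star allele to its base activity value and function class.

    Values follow the CPIC CYP2D6 activity-score system: 0 (no function),
    0.25 or 0.5 (decreased function), 1.0 (normal function).  The class is
    redundant with the value and is validated against it.  Lookups of
    undefined cores raise; nothing is ever defaulted.
    """

    def __init__(self, entries: Mapping[str, tuple[float, str]]):
        self._entries: dict[str, tuple[float, str]] = {}
        for core, (value, fclass) in entries.items():
            if not core or "x" in core or "+" in core or "*" in core:
                raise AlleleModelError(f"invalid core allele identifier {core!r}")
            value = float(value)
            if value not in _ALLOWED_BASE_VALUES:
                raise AlleleModelError(
                    f"activity value {value} for *{core} not in {sorted(_ALLOWED_BASE_VALUES)}"
                )
            expected = _CLASS_FOR_VALUE[value]
            if fclass != expected:
                raise AlleleModelError(
                    f"function class {fclass!r} for *{core} inconsistent with value {value} "
                    f"(expected {expected!r})"
                )
            if core in self._entries:
                raise AlleleModelError(f"duplicate definition for core allele *{core}")
            self._entries[core] = (value, fclass)

    @classmethod
    def from_values(cls, values: Mapping[str, float]) -> "AlleleDefinitionTable":
        """Build a table from core -> base value, deriving the class."""
        return cls({c: (float(v), _CLASS_FOR_VALUE[float(v)]) for c, v in values.items()})

    def base_value(self, core: str) -> float:
        try:
            return self._entries[core][0]
        except KeyError:
            raise UndefinedAlleleError(f"core allele *{core} is not defined") from None

    def function_class(self, core: str) -> str:
        try:
            return self._entries[core][1]
        except KeyError:
            raise UndefinedAlleleError(f"core allele *{core} is not defined") from None

    def cores(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def __contains__(self, core: str) -> bool:
        return core in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterable[tuple[str, tuple[float, str]]]:
        return self._entries.items()


def haplotype_activity_value(h: Haplotype, defs: AlleleDefinitionTable) -> float:
    """Activity value of one haplotype: sum of base value x copies.

    A duplication (``*1x2``) therefore scores double its single-copy
    counterpart, and a tandem arrangement sums its gene copies
    (``*36x2+*10`` -> 0 x 2 + 0.25 = 0.25).
    """
    return float(sum(defs.base_value(core) * copies for core, copies in h.components))


def haplotype_function_class(h: Haplotype, defs: AlleleDefinitionTable) -> str:
    """Function class of a whole haplotype, from its summed activity value.

    0 -> "none"; 0.25 or 0.5 -> "decreased"; 1.0 -> "normal";
    >= 2.0 -> "increased" (duplications of a normal-function allele).
    """
    value = haplotype_activity_value(h, defs)
    if value == 0.0:
        return "none"
    if value in (0.25, 0.5):
        return "decreased"
    if value == 1.0:
        return "normal"
    if value >= 2.0:
        return "increased"
    raise ClassificationError(
        f"haplotype {format_haplotype(h)} has activity value {value}, outside the recognised classes"
    )


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotypes carried by one subject."""

    hap1: Haplotype
    hap2: Haplotype

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return self.haplotypes() == other.haplotypes()

    def __hash__(self) -> int:
        return hash(self.haplotypes())

    @property
    def label(self) -> str:
        return canonical_diplotype_label(self)

    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return tuple(sorted((self.hap1, self.hap2), key=Haplotype.sort_key))


def parse_diplotype_label(label: str) -> Diplotype:
    """Parse ``"*1/*10"``-style labels (two haplotypes joined by ``/``)."""
    parts = label.strip().split("/")
    if len(parts) != 2:
        raise LabelParseError(f"a diplotype label needs exactly two '/'-separated haplotypes: {label!r}")
    return Diplotype(parse_haplotype_label(parts[0]), parse_haplotype_label(parts[1]))


def canonical_diplotype_label(d: Diplotype) -> str:
    """Canonical ``hap1/hap2`` label, invariant under swapping the pair.

    Haplotypes are ordered by numeric rank of the first core, then copy
    count, then the remaining components — the ordering used in published
    genotype tables (``*4x2/*36+*10``, ``*1x2/*10``).
    """
    a, b = sorted((d.hap1, d.hap2), key=Haplotype.sort_key)
    return f"{format_haplotype(a)}/{format_haplotype(b)}"


def diplotype_activity_score(d: Diplotype, defs: AlleleDefinitionTable) -> float:
    """Activity score (AS) of a diplotype: sum of its two haplotype values."""
    return haplotype_activity_value(d.hap1, defs) + haplotype_activity_value(d.hap2, defs)


class PhenotypeClass(enum.IntEnum):
    """CPIC metabolizer phenotype, ordered PM < IM < NM < UM."""

    PM = 0
    IM = 1
    NM = 2
    UM = 3

    def __str__(self) -> str:
        return self.name


def phenotype_from_score(score: float) -> PhenotypeClass:
    """Translate an activity score into the CPIC metabolizer phenotype.

    The CPIC assignment enumerates grid values (PM: 0; IM: 0.25-1.0;
    NM: 1.25-2.25; UM: > 2.25); here the bins are the half-open intervals
    that agree with every grid value, so arbitrary scores classify:
    PM iff AS = 0, IM iff 0 < AS <= 1, NM iff 1 < AS <= 2.25, UM iff
    AS > 2.25.
    """
    if score < 0:
        raise AlleleModelError(f"activity score must be >= 0, got {score}")
    if score == 0:
        return PhenotypeClass.PM
    if score <= 1.0:
        return PhenotypeClass.IM
    if score <= 2.25:
        return PhenotypeClass.NM
    return PhenotypeClass.UM
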