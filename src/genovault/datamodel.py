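"""Core domain types for the genotype vault.

Genotypes are unordered pairs of single-character allele codes; ``0/0`` is
the missing genotype, used both for untyped cells and for masked conflicts.
Members are named by a (pedigree, person) pair; samples, markers and traits
reference members/markers through opaque integer ids assigned by the store.
Alternate names for members and markers are carried by alias tables and
resolved through the functions in this module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

#: Single-character allele codes accepted anywhere in the system.  Digits
#: cover lab-style numeric labels (1/2), letters cover base calls; "0" is
#: reserved for the missing allele.
ALLELE_ALPHABET = frozenset("0123456789ACGT")

MISSING_ALLELE = "0"


class GenotypeError(ValueError):
    """Malformed genotype input (bad code or half-missing pair)."""


class LookupFailure(KeyError):
    """A name (member, marker, sample...) does not resolve to a record."""


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """An unordered allele pair, stored sorted by code point.

    ``GenotypeCall("0", "0")`` is the missing genotype.  Instances should be
    built through :func:`normalize_call`, which validates the alphabet and
    the no-half-missing rule.
    """

    allele1: str
    allele2: str

    @property
    def is_missing(self) -> bool:
        return self.allele1 == MISSING_ALLELE

    def alleles(self) -> Tuple[str, str]:
        return (self.allele1, self.allele2)

    def __str__(self) -> str:  # "A/C" display form used in logs and matrices
        return f"{self.allele1}/{self.allele2}"


MISSING_CALL = GenotypeCall(MISSING_ALLELE, MISSING_ALLELE)


def normalize_call(a1: str, a2: str) -> GenotypeCall:
    """Normalize a raw allele pair into a canonical :class:`GenotypeCall`.

    Alleles are sorted ascending by code point (digits before letters), so
    the pair is unordered for comparison purposes.  Exactly one "0" allele
    is rejected: a half-missing genotype signals malformed input.
    Normalization is idempotent.
    """
    if a1 not in ALLELE_ALPHABET or a2 not in ALLELE_ALPHABET:
        raise GenotypeError(f"allele code outside alphabet: {a1!r}/{a2!r}")
    if (a1 == MISSING_ALLELE) != (a2 == MISSING_ALLELE):
        raise GenotypeError(f"half-missing genotype {a1}/{a2}")
    if a1 > a2:
        a1, a2 = a2, a1
    return GenotypeCall(a1, a2)


def parse_call(text: str, missing_codes: Sequence[str] = ()) -> GenotypeCall:
    """Parse ``"A/C"``, ``"A C"`` or ``"AC"`` into a normalized call.

    ``missing_codes`` lists input tokens (e.g. ``"-"``, ``"N"``) translated
    to the missing allele before validation.
    """
    t = text.strip()
    for sep in ("/", "|", " ", "\t"):
        if sep in t:
            a, b = (p.strip() for p in t.split(sep, 1))
            break
    else:
        if len(t) != 2:
            raise GenotypeError(f"cannot parse genotype {text!r}")
        a, b = t[0], t[1]
    if a in missing_codes:
        a = MISSING_ALLELE
    if b in missing_codes:
        b = MISSING_ALLELE
    return normalize_call(a, b)


class Sex(enum.Enum):
    MALE = 1
    FEMALE = 2
    UNKNOWN = 0


_SEX_TOKENS = {
    "1": Sex.MALE, "m": Sex.MALE, "male": Sex.MALE,
    "2": Sex.FEMALE, "f": Sex.FEMALE, "female": Sex.FEMALE,
    "0": Sex.UNKNOWN, "u": Sex.UNKNOWN, "unknown": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}


def parse_sex(token: str) -> Sex:
    """Accept PLINK-style 1/2/0 as well as M/F/U spellings."""
    try:
        return _SEX_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise GenotypeError(f"unrecognized sex code {token!r}") from None


class TraitKind(enum.Enum):
    QUALITATIVE = "qualitative"
    QUANTITATIVE = "quantitative"


@dataclass(frozen=True)
class MemberRecord:
    """One subject: a (pedigree, person) name pair plus parent links.

    Parents are referenced by person name within the same pedigree; absent
    parents are ``None``.
    """

    pedigree: str
    person: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Sex = Sex.UNKNOWN

    @property
    def key(self) -> Tuple[str, str]:
        return (self.pedigree, self.person)


@dataclass(frozen=True)
class MemberAlias:
    alias_pedigree: str
    alias_person: str
    pedigree: str
    person: str


@dataclass(frozen=True)
class SampleRecord:
    """A physical sample taken from a member.

    When a member has several samples, at most one may be flagged
    preferred; merging then ignores the others.
    """

    sample_name: str
    pedigree: str
    person: str
    plate: Optional[str] = None
    well: Optional[str] = None
    preferred: bool = False


@dataclass(frozen=True)
class MarkerAlias:
    alias_name: str
    marker_name: str


@dataclass(frozen=True)
class MarkerInfoRecord:
    """Map position of a marker under a named build (bp plus optional cM)."""

    marker_name: str
    build: str
    chromosome: int
    bp_position: int
    avg_cm: Optional[float] = None
    female_cm: Optional[float] = None
    male_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 26:
            raise ValueError(f"chromosome {self.chromosome} outside 1-26")
        if self.bp_position < 1:
            raise ValueError("bp_position must be >= 1")


@dataclass(frozen=True)
class TraitValue:
    pedigree: str
    person: str
    trait: str
    value: str


@dataclass(frozen=True)
class AlleleMapEntry:
    """Per-(experiment, marker) relabeling of one allele code.

    The missing allele "0" is never remapped.
    """

    experiment: str
    marker_name: str
    from_allele: str
    to_allele: str

    def __post_init__(self) -> None:
        if self.from_allele == MISSING_ALLELE or self.to_allele == MISSING_ALLELE:
            raise ValueError('"0" cannot appear in an allele map')
        if self.from_allele not in ALLELE_ALPHABET or self.to_allele not in ALLELE_ALPHABET:
            raise ValueError("allele map codes must be in the allele alphabet")


def validate_pedigree(members: Iterable[MemberRecord]) -> None:
    """Check parent references and acyclicity of a member set.

    Raises ``ValueError`` naming the first offending member if a parent is
    named but not present in the same pedigree, or if parentage contains a
    cycle (a member being its own ancestor).
    """
    by_key = {}
    for m in members:
        if m.key in by_key:
            raise ValueError(f"duplicate member {m.key}")
        by_key[m.key] = m
    for m in by_key.values():
        for parent in (m.father, m.mother):
            if parent is not None and (m.pedigree, parent) not in by_key:
                raise ValueError(
                    f"member {m.key}: parent {parent!r} not in pedigree {m.pedigree!r}"
                )
    # iterative DFS for ancestor cycles
    WHITE, GREY, BLACK = 0, 1, 2
    color = {k: WHITE for k in by_key}

    def parents(key):
        m = by_key[key]
        return [
            (m.pedigree, p) for p in (m.father, m.mother) if p is not None
        ]

    for start in by_key:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(parents(start)))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GREY:
                    raise ValueError(f"parentage cycle involving {nxt}")
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(parents(nxt))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()


def resolve_member(
    name_pair: Tuple[str, str],
    members: Mapping[Tuple[str, str], int],
    aliases: Mapping[Tuple[str, str], Tuple[str, str]] = {},
) -> int:
    """Resolve a (pedigree, person) name to a member id.

    Canonical names resolve to themselves; alias pairs resolve to their
    target's id.  Aliases point only at canonical names (no chains).
    """
    if name_pair in members:
        return members[name_pair]
    if name_pair in aliases:
        target = aliases[name_pair]
        if target in members:
            return members[target]
    raise LookupFailure(f"unknown member {name_pair}")


def resolve_marker(
    name: str,
    markers: Mapping[str, int],
    aliases: Mapping[str, str] = {},
) -> int:
    """Resolve a marker name (canonical or alias) to a marker id."""
    if name in markers:
        return markers[name]
    if name in aliases and aliases[name] in markers:
        return markers[aliases[name]]
    raise LookupFailure(f"unknown marker {name!r}")
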