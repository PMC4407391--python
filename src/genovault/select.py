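"""Subsetting filters applied at extraction time.

Members can be included/excluded by pedigree or person, filtered on trait
values, and closed under pedigree co-membership so family structures stay
intact.  Markers can be picked by name (through aliases), chromosome, or
inclusive position ranges in bp or cM against a chosen map build — always
the *current* build's coordinates, independent of where the genotypes were
physically stored.  Exclusion ranges mask individual cells to missing
before merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import (
    Callable,
    Dict,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

from .datamodel import LookupFailure, resolve_marker


@dataclass(frozen=True)
class PositionRange:
    """Inclusive coordinate range on one chromosome, in bp or cM."""

    chromosome: int
    lo: float
    hi: float
    units: str = "bp"  # "bp" | "cM"

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"range lo {self.lo} > hi {self.hi}")
        if self.units not in ("bp", "cM"):
            raise ValueError(f"unknown range units {self.units!r}")


@dataclass(frozen=True)
class ExclusionRange:
    """bp range whose genotypes are masked to 0/0 before merging.

    ``members`` limits the mask to listed (pedigree, person) pairs; empty
    means all members.
    """

    chromosome: int
    lo: int
    hi: int
    members: frozenset = frozenset()


@dataclass
class SelectionSpec:
    """Everything the extraction command can filter on."""

    include_pedigrees: Set[str] = field(default_factory=set)
    exclude_pedigrees: Set[str] = field(default_factory=set)
    include_persons: Set[Tuple[str, str]] = field(default_factory=set)
    exclude_persons: Set[Tuple[str, str]] = field(default_factory=set)
    complete_pedigrees: bool = False
    trait_filters: List[Tuple[str, Callable[[str], bool]]] = field(
        default_factory=list
    )
    marker_names: Optional[Set[str]] = None
    chromosomes: Optional[Set[int]] = None
    ranges: List[PositionRange] = field(default_factory=list)
    exclusion_ranges: List[ExclusionRange] = field(default_factory=list)
    experiments: Optional[Set[str]] = None
    technologies: Optional[Set[str]] = None
    require_member_typed_in: Optional[Set[str]] = None
    drop_untyped_markers: bool = False
    build: str = "default"


class SelectionError(ValueError):
    pass


def select_members(
    spec: SelectionSpec,
    members: Sequence[Mapping[str, object]],
    trait_values: Mapping[Tuple[str, str], Mapping[str, str]] = {},
) -> Set[Tuple[str, str]]:
    """Apply the member-level filters; returns selected (pedigree, person).

    Include sets (pedigree ∪ person) start the pool (everyone if both are
    empty); exclusion wins on overlap; each trait filter keeps members whose
    value satisfies its predicate (members lacking the trait are dropped).
    With ``complete_pedigrees``, the pool is finally closed under pedigree
    co-membership of any selected member, which may reinstate relatives
    removed by filters — family structures take precedence.
    """
    all_keys = [(m["pedigree"], m["person"]) for m in members]
    known_peds = {p for p, _ in all_keys}
    key_set = set(all_keys)

    offenders = [
        p for p in (spec.include_pedigrees | spec.exclude_pedigrees)
        if p not in known_peds
    ]
    offenders += [
        f"{p}/{i}"
        for (p, i) in (spec.include_persons | spec.exclude_persons)
        if (p, i) not in key_set
    ]
    if offenders:
        raise SelectionError(f"unknown pedigrees/persons in spec: {offenders}")

    if spec.include_pedigrees or spec.include_persons:
        pool = {
            k
            for k in all_keys
            if k[0] in spec.include_pedigrees or k in spec.include_persons
        }
    else:
        pool = set(all_keys)
    pool = {
        k
        for k in pool
        if k[0] not in spec.exclude_pedigrees and k not in spec.exclude_persons
    }
    for trait, pred in spec.trait_filters:
        pool = {
            k
            for k in pool
            if trait in trait_values.get(k, {}) and pred(trait_values[k][trait])
        }
    if spec.complete_pedigrees:
        peds = {p for p, _ in pool}
        pool = {k for k in all_keys if k[0] in peds}
    return pool


def select_markers(
    spec: SelectionSpec,
    marker_info: Sequence[Mapping[str, object]],
    markers: Mapping[str, int],
    aliases: Mapping[str, str] = {},
) -> List[Tuple[int, str, int, int]]:
    """Apply marker-level filters against one build's map.

    ``marker_info`` rows need marker_id, name, build, chromosome, bp and
    optionally avg_cm.  Returns (marker_id, canonical_name, chromosome, bp)
    ordered by (chromosome, bp, name) — a total, deterministic order.
    Named markers are resolved through aliases; a requested marker with no
    map info under ``spec.build`` is an error naming it.
    """
    info_by_id: Dict[int, Mapping[str, object]] = {
        r["marker_id"]: r for r in marker_info if r["build"] == spec.build
    }

    if spec.marker_names is not None:
        wanted_ids = []
        missing = []
        for name in sorted(spec.marker_names):
            try:
                mid = resolve_marker(name, markers, aliases)
            except LookupFailure:
                missing.append(name)
                continue
            if mid not in info_by_id:
                missing.append(name)
            else:
                wanted_ids.append(mid)
        if missing:
            raise SelectionError(
                f"markers without map info for build {spec.build!r}: {missing}"
            )
        candidates = set(wanted_ids)
    else:
        candidates = set(info_by_id)

    if spec.chromosomes is not None or spec.ranges:
        kept = set()
        for mid in candidates:
            r = info_by_id[mid]
            chrom = r["chromosome"]
            if spec.chromosomes is not None and chrom in spec.chromosomes:
                kept.add(mid)
                continue
            for rng in spec.ranges:
                if rng.chromosome != chrom:
                    continue
                if rng.units == "bp":
                    pos = r["bp"]
                else:
                    pos = r.get("avg_cm")
                    if pos is None:
                        continue  # no genetic position: excluded from cM ranges
                if rng.lo <= pos <= rng.hi:
                    kept.add(mid)
                    break
        candidates = kept

    name_by_id = {v: k for k, v in markers.items()}
    out = [
        (mid, name_by_id[mid], info_by_id[mid]["chromosome"], info_by_id[mid]["bp"])
        for mid in candidates
    ]
    out.sort(key=lambda t: (t[2], t[3], t[1]))
    return out


def excluded(
    spec: SelectionSpec,
    member: Tuple[str, str],
    chromosome: int,
    bp: int,
) -> bool:
    """True if this member's call at (chromosome, bp) falls in an exclusion
    range (member-specific or global)."""
    for rng in spec.exclusion_ranges:
        if rng.chromosome != chromosome or not (rng.lo <= bp <= rng.hi):
            continue
        if not rng.members or member in rng.members:
            return True
    return False


def apply_exclusions(
    spec: SelectionSpec,
    stream: Iterable[Tuple[Tuple[str, str], int, int, object]],
    missing,
) -> Iterable[Tuple[Tuple[str, str], int, int, object]]:
    """Mask excluded cells in a (member, chromosome, bp, call) stream."""
    for member, chrom, bp, call in stream:
        if excluded(spec, member, chrom, bp):
            yield (member, chrom, bp, missing)
        else:
            yield (member, chrom, bp, call)
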