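"""Reconciling multiple genotype calls per (member, marker).

When a member is typed at the same marker by more than one experiment (or
twice within one), the calls must be merged into a single output genotype:

1. per-experiment allele maps relabel allele codes (e.g. 1/2 → A/C);
2. inactive rows and non-preferred samples are dropped;
3. missing (0/0) calls are discarded;
4. only calls at the maximal trust level survive;
5. if the survivors agree, their common value is output; otherwise the
   output is masked to 0/0 and the conflict is logged.

Agreement matrices — joint genotype counts for an experiment pair at a
marker — are the diagnostic view of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .datamodel import (
    GenotypeCall,
    MISSING_ALLELE,
    MISSING_CALL,
    normalize_call,
)


class AlleleMapError(ValueError):
    """An allele map is not injective or touches the missing code."""


@dataclass
class MergePolicy:
    """Knobs governing conflict resolution.

    ``trust`` ranks experiments (default 0); ``marker_trust`` overrides the
    experiment rank for specific (experiment, marker) pairs and takes
    precedence.  Only maximal-trust calls enter resolution.
    """

    trust: Dict[str, int] = field(default_factory=dict)
    marker_trust: Dict[Tuple[str, str], int] = field(default_factory=dict)
    honor_active: bool = True
    honor_preferred_sample: bool = True

    def trust_of(self, experiment: str, marker: Optional[str] = None) -> int:
        if marker is not None and (experiment, marker) in self.marker_trust:
            return self.marker_trust[(experiment, marker)]
        return self.trust.get(experiment, 0)


@dataclass
class ConflictEntry:
    pedigree: str
    person: str
    marker: str
    calls: List[Tuple[str, str]]  # (experiment, call text)


@dataclass
class ConflictLog:
    entries: List[ConflictEntry] = field(default_factory=list)

    def add(self, pedigree, person, marker, calls) -> None:
        self.entries.append(ConflictEntry(pedigree, person, marker, list(calls)))

    def __len__(self) -> int:
        return len(self.entries)

    def lines(self) -> List[str]:
        return [
            f"conflict {e.pedigree}/{e.person} at {e.marker}: "
            + ", ".join(f"{x}={g}" for x, g in e.calls)
            for e in self.entries
        ]


def validate_allele_map(mapping: Mapping[str, str]) -> None:
    """An allele map must be injective and must not touch "0"."""
    if MISSING_ALLELE in mapping or MISSING_ALLELE in mapping.values():
        raise AlleleMapError('"0" cannot be remapped')
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        raise AlleleMapError(f"allele map collapses alleles: {dict(mapping)}")
    # a mapped-to code that is itself remapped elsewhere would collapse
    # labels depending on application order
    for frm, to in mapping.items():
        if to in mapping and mapping[to] != to and to != frm:
            raise AlleleMapError(f"allele map chains {frm}→{to}→{mapping[to]}")


def apply_allele_map(
    call: GenotypeCall, mapping: Mapping[str, str]
) -> GenotypeCall:
    """Relabel a call's alleles; unmapped codes pass through, 0/0 is fixed."""
    if not mapping or call.is_missing:
        return call
    validate_allele_map(mapping)
    a1 = mapping.get(call.allele1, call.allele1)
    a2 = mapping.get(call.allele2, call.allele2)
    return normalize_call(a1, a2)


def resolve(
    calls: Iterable[Tuple[GenotypeCall, int]]
) -> Tuple[GenotypeCall, bool]:
    """Merge measured calls into one output genotype.

    ``calls`` is any iterable of (call, trust) pairs — allele maps applied,
    inactive rows already removed.  Missing calls are discarded; among the
    rest only maximal-trust calls survive; if they all agree that value is
    returned, otherwise (0/0, True) signals a masked conflict.  Total
    function, independent of input order.
    """
    survivors: List[Tuple[GenotypeCall, int]] = [
        (c, t) for c, t in calls if not c.is_missing
    ]
    if not survivors:
        return (MISSING_CALL, False)
    top = max(t for _c, t in survivors)
    vals = {c for c, t in survivors if t == top}
    if len(vals) == 1:
        return (next(iter(vals)), False)
    return (MISSING_CALL, True)


@dataclass
class AgreementMatrix:
    """Joint genotype counts for two experiments at a marker (or marker set).

    Rows are labeled by the first experiment's genotypes, columns by the
    second's; a member typed in only one experiment counts under 0/0 on the
    other axis.  The genotype alphabet is ordered 0/0 first, then sorted.
    """

    experiment_a: str
    experiment_b: str
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def add(self, call_a: GenotypeCall, call_b: GenotypeCall, n: int = 1) -> None:
        key = (str(call_a), str(call_b))
        self.counts[key] = self.counts.get(key, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def alphabet(self) -> List[str]:
        seen = {g for pair in self.counts for g in pair}
        seen.discard("0/0")
        return ["0/0"] + sorted(seen)

    def cell(self, row: str, col: str) -> int:
        return self.counts.get((row, col), 0)

    def row_missing_total(self) -> int:
        """Members typed in experiment B only (row 0/0, excluding [0/0,0/0])."""
        return sum(
            n for (r, c), n in self.counts.items() if r == "0/0" and c != "0/0"
        )

    def col_missing_total(self) -> int:
        """Members typed in experiment A only (column 0/0, excluding [0/0,0/0])."""
        return sum(
            n for (r, c), n in self.counts.items() if c == "0/0" and r != "0/0"
        )

    def discordant(self) -> Dict[Tuple[str, str], int]:
        """Off-diagonal cells where both experiments measured a genotype."""
        return {
            (r, c): n
            for (r, c), n in self.counts.items()
            if r != c and r != "0/0" and c != "0/0"
        }

    def n_discordant(self) -> int:
        return sum(self.discordant().values())

    def to_lines(self) -> List[str]:
        alpha = self.alphabet()
        head = f"{self.experiment_a} \\ {self.experiment_b}"
        lines = ["\t".join([head, *alpha])]
        for r in alpha:
            lines.append(
                "\t".join([r, *(str(self.cell(r, c)) for c in alpha)])
            )
        return lines


def agreement_matrix(
    experiment_a: str,
    experiment_b: str,
    calls_a: Mapping[object, GenotypeCall],
    calls_b: Mapping[object, GenotypeCall],
) -> AgreementMatrix:
    """Build the joint count matrix for one experiment pair at one marker.

    ``calls_a``/``calls_b`` map member → call (post-remapping); the members
    counted are the union of both maps, with absent calls treated as 0/0.
    """
    if experiment_a == experiment_b:
        raise ValueError("agreement matrix needs two distinct experiments")
    mat = AgreementMatrix(experiment_a, experiment_b)
    for member in set(calls_a) | set(calls_b):
        mat.add(
            calls_a.get(member, MISSING_CALL), calls_b.get(member, MISSING_CALL)
        )
    return mat


def select_sample_calls(
    samples: Sequence[Tuple[str, bool]],
    calls_per_sample: Mapping[str, Sequence[Tuple[GenotypeCall, int]]],
    honor_preferred: bool = True,
) -> List[Tuple[GenotypeCall, int]]:
    """Choose which samples' calls represent a member.

    ``samples`` lists (sample_name, preferred) for one member.  If a
    preferred sample exists (and is honored), only its calls pass; otherwise
    all samples' calls flow into :func:`resolve` together.
    """
    chosen = [s for s, pref in samples if pref] if honor_preferred else []
    if not chosen:
        chosen = [s for s, _pref in samples]
    out: List[Tuple[GenotypeCall, int]] = []
    for s in chosen:
        out.extend(calls_per_sample.get(s, ()))
    return out
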