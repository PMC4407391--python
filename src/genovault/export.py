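"""Merged, filtered extraction and the output dialects.

``extract`` is the heart of the system: it pulls every stored call for the
selected members × markers — from the targeted row store and from genotype
blocks — applies allele maps, sample preference, active flags and exclusion
ranges, resolves multi-experiment measurements by trust, and returns one
consistent genotype matrix plus conflict and agreement diagnostics.

``export`` writes that matrix as delimited columnar text, PLINK ped/map,
PLINK bed/bim/fam, or a Mega2-style fileset, with optional per-marker
allele/genotype frequency statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import blockcodec, plink
from .datamodel import GenotypeCall, MISSING_CALL
from .merge import (
    AgreementMatrix,
    ConflictLog,
    MergePolicy,
    apply_allele_map,
    resolve,
)
from .select import SelectionSpec, excluded, select_markers, select_members
from .store import Database


@dataclass
class ExportSpec:
    """Output dialect and statistics switches.

    ``per_person_streaming`` writes one person at a time and implies no
    statistics gathering (the large-run mode); it is only meaningful for
    row-oriented dialects (columnar, ped).
    """

    format: str = "plink_ped"  # columnar | plink_ped | plink_bed | mega2
    prefix: str = "genovault_out"
    delimiter: str = "tab"  # for columnar
    per_person_streaming: bool = False
    collect_stats: bool = True

    def __post_init__(self) -> None:
        if self.format not in ("columnar", "plink_ped", "plink_bed", "mega2"):
            raise ValueError(f"unknown export format {self.format!r}")
        if self.per_person_streaming:
            self.collect_stats = False


@dataclass
class FrequencyReport:
    """Per-marker allele/genotype counts over the exported matrix.

    Frequencies are over non-missing alleles and sum to 1 wherever any
    allele was observed.
    """

    allele_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    genotype_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    missing: Dict[str, int] = field(default_factory=dict)

    def allele_freqs(self, marker: str) -> Dict[str, float]:
        counts = self.allele_counts.get(marker, {})
        total = sum(counts.values())
        if total == 0:
            return {}
        return {a: n / total for a, n in counts.items()}

    def genotype_freqs(self, marker: str) -> Dict[str, float]:
        counts = self.genotype_counts.get(marker, {})
        total = sum(counts.values())
        if total == 0:
            return {}
        return {g: n / total for g, n in counts.items()}


@dataclass
class ExtractResult:
    members: List[dict]  # ordered; pedigree, person, father, mother, sex
    markers: List[Tuple[int, str, int, int]]  # (id, name, chromosome, bp)
    geno: np.ndarray  # (n_markers, n_members, 2) allele codes
    conflicts: ConflictLog
    agreements: Dict[Tuple[str, str], AgreementMatrix]
    stats: Optional[FrequencyReport]

    def call(self, marker_index: int, member_index: int) -> GenotypeCall:
        a = self.geno[marker_index, member_index]
        return GenotypeCall(chr(a[0]), chr(a[1]))


class ExportError(RuntimeError):
    pass


def _member_rows(db: Database) -> List[dict]:
    return [
        dict(r)
        for r in db.conn.execute(
            "SELECT id, pedigree, person, father, mother, sex FROM members"
        )
    ]


def _trait_values(db: Database) -> Dict[Tuple[str, str], Dict[str, str]]:
    out: Dict[Tuple[str, str], Dict[str, str]] = {}
    for r in db.conn.execute(
        "SELECT m.pedigree, m.person, t.name AS trait, v.value "
        "FROM traits v JOIN members m ON m.id = v.member_id "
        "JOIN traitmeta t ON t.id = v.trait_id"
    ):
        out.setdefault((r["pedigree"], r["person"]), {})[r["trait"]] = r["value"]
    return out


def _allowed_experiments(
    db: Database, spec: SelectionSpec
) -> Dict[int, Tuple[str, int]]:
    """experiment_id → (name, store trust), honoring experiment/technology
    restrictions."""
    out = {}
    for r in db.conn.execute(
        "SELECT e.id, e.name, e.trust, t.name AS tech FROM experiments e "
        "LEFT JOIN technologies t ON t.id = e.technology_id"
    ):
        if spec.experiments is not None and r["name"] not in spec.experiments:
            continue
        if spec.technologies is not None and r["tech"] not in spec.technologies:
            continue
        out[r["id"]] = (r["name"], r["trust"])
    return out


def _allele_maps(db: Database) -> Dict[Tuple[int, int], Dict[str, str]]:
    out: Dict[Tuple[int, int], Dict[str, str]] = {}
    for r in db.conn.execute(
        "SELECT experiment_id, marker_id, from_allele, to_allele FROM allele_map"
    ):
        out.setdefault((r["experiment_id"], r["marker_id"]), {})[
            r["from_allele"]
        ] = r["to_allele"]
    return out


def gather_calls(
    db: Database,
    spec: SelectionSpec,
    policy: MergePolicy,
    member_ids: Mapping[int, Tuple[str, str]],
    marker_ids: Sequence[int],
) -> Dict[Tuple[int, int], List[Tuple[GenotypeCall, str]]]:
    """Collect raw (call, experiment) measurements per (member_id, marker_id).

    Allele maps are applied here; trust, exclusions and resolution are left
    to the caller.  Inactive rows are skipped when the policy honors the
    active flag; block calls flow through sample preference.
    """
    allowed = _allowed_experiments(db, spec)
    amaps = _allele_maps(db)
    marker_set = set(marker_ids)
    calls: Dict[Tuple[int, int], List[Tuple[GenotypeCall, str]]] = {}

    def record(member_id, marker_id, call, exp_id):
        mapping = amaps.get((exp_id, marker_id))
        if mapping:
            call = apply_allele_map(call, mapping)
        calls.setdefault((member_id, marker_id), []).append(
            (call, allowed[exp_id][0])
        )

    # targeted rows
    active_clause = "AND active = 1" if policy.honor_active else ""
    for r in db.conn.execute(
        f"SELECT member_id, marker_id, experiment_id, allele1, allele2 "
        f"FROM genotypes WHERE 1=1 {active_clause}"
    ):
        if (
            r["member_id"] not in member_ids
            or r["marker_id"] not in marker_set
            or r["experiment_id"] not in allowed
        ):
            continue
        record(
            r["member_id"],
            r["marker_id"],
            GenotypeCall(r["allele1"], r["allele2"]),
            r["experiment_id"],
        )

    # blocks: member ← samples (preferred wins) ← block slots
    samples_by_member: Dict[int, List[Tuple[int, bool]]] = {}
    for r in db.conn.execute(
        "SELECT id, member_id, preferred FROM samples ORDER BY sample_name"
    ):
        if r["member_id"] in member_ids:
            samples_by_member.setdefault(r["member_id"], []).append(
                (r["id"], bool(r["preferred"]))
            )
    chosen_samples: Dict[int, int] = {}  # sample_id → member_id
    for mid, sam in samples_by_member.items():
        pref = [s for s, p in sam if p] if policy.honor_preferred_sample else []
        for s in pref or [s for s, _p in sam]:
            chosen_samples[s] = mid

    pairs = db.conn.execute(
        "SELECT DISTINCT experiment_id, layout FROM genotypeblocks"
    ).fetchall()
    for pr in pairs:
        eid, layout = pr["experiment_id"], pr["layout"]
        if eid not in allowed:
            continue
        index = blockcodec.load_index(db, layout)
        wanted = {m: index[m] for m in marker_set if m in index}
        if not wanted:
            continue
        # group by (chromosome-at-load, block) to read each block once
        by_chrom: Dict[int, Set[int]] = {}
        for m, (c, b, o) in wanted.items():
            by_chrom.setdefault(c, set()).add(b)
        sample_list = list(chosen_samples)
        for c, blocks in by_chrom.items():
            span = (min(blocks), max(blocks))
            got = blockcodec.read_range(
                db, sample_list, eid, layout, c, span, index
            )
            for sid, per_marker in got.items():
                member = chosen_samples[sid]
                for m, call in per_marker.items():
                    if m in marker_set:
                        record(member, m, call, eid)
    return calls


def extract(
    db: Database,
    spec: SelectionSpec,
    policy: Optional[MergePolicy] = None,
    collect_stats: bool = True,
) -> ExtractResult:
    """Run the full selection → merge pipeline; see the module docstring."""
    policy = policy or MergePolicy()
    members_all = _member_rows(db)
    traits = _trait_values(db)
    selected_keys = select_members(spec, members_all, traits)
    members = sorted(
        (m for m in members_all if (m["pedigree"], m["person"]) in selected_keys),
        key=lambda m: (m["pedigree"], m["person"]),
    )
    member_ids = {m["id"]: (m["pedigree"], m["person"]) for m in members}

    info = [
        dict(r)
        for r in db.conn.execute(
            "SELECT marker_id, build, chromosome, bp, avg_cm FROM marker_info"
        )
    ]
    markers_map = db.marker_ids()
    marker_aliases = db.marker_alias_map()
    markers = select_markers(spec, info, markers_map, marker_aliases)
    marker_ids = [m[0] for m in markers]

    raw = gather_calls(db, spec, policy, member_ids, marker_ids)

    if spec.require_member_typed_in is not None:
        typed: Set[int] = set()
        for (mid, _kid), lst in raw.items():
            if any(e in spec.require_member_typed_in for _c, e in lst):
                typed.add(mid)
        members = [m for m in members if m["id"] in typed]
        member_ids = {m["id"]: (m["pedigree"], m["person"]) for m in members}

    n_m, n_s = len(markers), len(members)
    geno = np.full((n_m, n_s, 2), ord("0"), dtype=np.uint8)
    conflicts = ConflictLog()
    agreements: Dict[Tuple[str, str], AgreementMatrix] = {}
    member_index = {m["id"]: i for i, m in enumerate(members)}

    exp_names = {
        name for _eid, (name, _t) in _allowed_experiments(db, spec).items()
    }

    for j, (kid, name, chrom, bp) in enumerate(markers):
        per_member_by_exp: Dict[str, Dict[int, GenotypeCall]] = {}
        for m in members:
            mid = m["id"]
            lst = raw.get((mid, kid), [])
            if not lst:
                continue
            key = (member_ids[mid], chrom, bp)
            if excluded(spec, member_ids[mid], chrom, bp):
                continue  # masked before merging
            trusted = [
                (call, policy.trust_of(exp, name)) for call, exp in lst
            ]
            merged, is_conflict = resolve(trusted)
            if is_conflict:
                conflicts.add(
                    member_ids[mid][0],
                    member_ids[mid][1],
                    name,
                    [(exp, str(call)) for call, exp in lst],
                )
            i = member_index[mid]
            geno[j, i, 0] = ord(merged.allele1)
            geno[j, i, 1] = ord(merged.allele2)
            if collect_stats:
                for call, exp in lst:
                    per_member_by_exp.setdefault(exp, {})[mid] = call
        if collect_stats:
            exps = sorted(per_member_by_exp)
            for ia in range(len(exps)):
                for ib in range(ia + 1, len(exps)):
                    a, b = exps[ia], exps[ib]
                    doubly = set(per_member_by_exp[a]) | set(per_member_by_exp[b])
                    both = set(per_member_by_exp[a]) & set(per_member_by_exp[b])
                    if not both:
                        continue  # no member measured by the pair here
                    key = (a, b)
                    mat = agreements.setdefault(key, AgreementMatrix(a, b))
                    for mid in doubly:
                        mat.add(
                            per_member_by_exp[a].get(mid, MISSING_CALL),
                            per_member_by_exp[b].get(mid, MISSING_CALL),
                        )

    if spec.drop_untyped_markers:
        keep = [
            j for j in range(n_m) if (geno[j, :, 0] != ord("0")).any()
        ]
        markers = [markers[j] for j in keep]
        geno = geno[keep]

    stats = _frequency_report(markers, geno) if collect_stats else None
    return ExtractResult(
        members=members,
        markers=markers,
        geno=geno,
        conflicts=conflicts,
        agreements=agreements,
        stats=stats,
    )


def _frequency_report(
    markers: Sequence[Tuple[int, str, int, int]], geno: np.ndarray
) -> FrequencyReport:
    rep = FrequencyReport()
    for j, (_kid, name, _c, _bp) in enumerate(markers):
        col = geno[j]
        miss = col[:, 0] == ord("0")
        rep.missing[name] = int(miss.sum())
        typed = col[~miss]
        acounts: Dict[str, int] = {}
        for code, n in zip(*np.unique(typed.reshape(-1), return_counts=True)):
            acounts[chr(code)] = int(n)
        gcounts: Dict[str, int] = {}
        for row in typed:
            g = f"{chr(row[0])}/{chr(row[1])}"
            gcounts[g] = gcounts.get(g, 0) + 1
        rep.allele_counts[name] = acounts
        rep.genotype_counts[name] = gcounts
    return rep


# ---------------------------------------------------------------------------
# writers


_DELIMS = {"tab": "\t", "comma": ",", "whitespace": " "}


def _fam_records(members: Sequence[dict], traits=None) -> List[plink.FamRecord]:
    out = []
    for m in members:
        pheno = "0"
        if traits:
            pheno = traits.get((m["pedigree"], m["person"]), {}).get(
                "affection", "0"
            )
        out.append(
            plink.FamRecord(
                pedigree=m["pedigree"],
                person=m["person"],
                father=m["father"] or "0",
                mother=m["mother"] or "0",
                sex=m["sex"],
                phenotype=pheno,
            )
        )
    return out


def export(
    db: Database,
    spec: SelectionSpec,
    policy: Optional[MergePolicy] = None,
    export_spec: Optional[ExportSpec] = None,
) -> Tuple[List[str], ExtractResult]:
    """Extract, merge and write; returns (paths written, extract result)."""
    export_spec = export_spec or ExportSpec()
    res = extract(db, spec, policy, collect_stats=export_spec.collect_stats)
    if not res.markers and export_spec.format != "columnar":
        raise ExportError("selection matched no markers")
    traits = _trait_values(db)
    fam = _fam_records(res.members, traits)
    map_rows = [
        (chrom, name, _avg_cm(db, kid, spec.build), bp)
        for kid, name, chrom, bp in res.markers
    ]
    prefix = export_spec.prefix
    paths: List[str]
    if export_spec.format == "plink_ped":
        p, m = plink.write_ped_map(prefix, fam, map_rows, res.geno)
        paths = [p, m]
    elif export_spec.format == "plink_bed":
        bim = []
        for j, (chrom, name, cm, bp) in enumerate(map_rows):
            a1, a2 = plink.choose_alleles(res.geno[j], name)
            bim.append(plink.BimRecord(chrom, name, cm, bp, a1, a2))
        paths = list(plink.write_bed(prefix, fam, bim, res.geno))
    elif export_spec.format == "columnar":
        paths = [_write_columnar(prefix, fam, res, export_spec)]
    elif export_spec.format == "mega2":
        paths = _write_mega2(prefix, fam, map_rows, res)
    else:  # pragma: no cover - guarded by ExportSpec
        raise ExportError(f"unknown format {export_spec.format!r}")
    return paths, res


def _avg_cm(db: Database, marker_id: int, build: str) -> float:
    row = db.conn.execute(
        "SELECT avg_cm FROM marker_info WHERE marker_id = ? AND build = ?",
        (marker_id, build),
    ).fetchone()
    return float(row["avg_cm"]) if row and row["avg_cm"] is not None else 0.0


def _write_columnar(
    prefix: str, fam: Sequence[plink.FamRecord], res: ExtractResult,
    export_spec: ExportSpec,
) -> str:
    """One row per person, one genotype column per marker ("A/C" cells).

    Streaming mode formats and writes one person at a time; the emitted
    bytes are identical to the buffered path.
    """
    d = _DELIMS[export_spec.delimiter]
    path = f"{prefix}.txt"
    names = [name for _kid, name, _c, _bp in res.markers]
    with open(path, "w") as fh:
        fh.write(d.join(["pedigree", "person", *names]) + "\n")
        for i, rec in enumerate(fam):
            col = res.geno[:, i, :]
            cells = [rec.pedigree, rec.person]
            cells.extend(
                f"{chr(col[j, 0])}/{chr(col[j, 1])}" for j in range(len(names))
            )
            fh.write(d.join(cells) + "\n")
    return path


def _write_mega2(
    prefix: str,
    fam: Sequence[plink.FamRecord],
    map_rows: Sequence[Tuple[int, str, float, int]],
    res: ExtractResult,
) -> List[str]:
    """Annotated three-file dialect (pedigree / names / map).

    The trio mirrors the classic linkage-package layout consumed by the
    Mega2 converter: a pedigree file with per-person allele pairs, a names
    file declaring the trait and marker order, and a map file with genetic
    and physical positions.  A version header marks the dialect.
    """
    ped_path = f"{prefix}.mega2.ped"
    names_path = f"{prefix}.mega2.names"
    map_path = f"{prefix}.mega2.map"
    with open(names_path, "w") as fh:
        fh.write("# genovault mega2-style names v1\n")
        fh.write("affection A\n")
        for _c, name, _cm, _bp in map_rows:
            fh.write(f"{name} M\n")
    with open(map_path, "w") as fh:
        fh.write("# genovault mega2-style map v1\n")
        fh.write("CHROMOSOME\tNAME\tAVG_POS\tBP_POS\n")
        for chrom, name, cm, bp in map_rows:
            fh.write(f"{chrom}\t{name}\t{cm:g}\t{bp}\n")
    with open(ped_path, "w") as fh:
        fh.write("# genovault mega2-style pedigree v1\n")
        for i, rec in enumerate(fam):
            cells = [
                rec.pedigree, rec.person, rec.father, rec.mother,
                str(rec.sex), rec.phenotype,
            ]
            col = res.geno[:, i, :]
            for j in range(len(map_rows)):
                cells.append(f"{chr(col[j, 0])}/{chr(col[j, 1])}")
            fh.write("\t".join(cells) + "\n")
    return [ped_path, names_path, map_path]
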