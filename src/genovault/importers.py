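"""Flat-file parsers feeding the store and the block codec.

Auxiliary tables (members, aliases, samples, traits, marker maps, allele
maps) arrive as delimited columnar files; a :class:`ColumnMap` names which
column holds what, so vendor exports can be consumed without reshaping.
Genotypes arrive in four dialects:

* targeted   — one genotype per line (or one line per person), into the
  row store;
* per-sample — one file per sample plus a marker mapping file, into blocks;
* multi-sample — several samples' columns in one file, into blocks;
* PLINK binary — bed/bim/fam, populating members/samples/traits/markers and
  blocks in one run.

Every importer is transactional: if errors are detected, the data are
rolled back and the store is left exactly as it was.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import blockcodec, plink
from .datamodel import (
    GenotypeError,
    LookupFailure,
    MemberRecord,
    TraitKind,
    normalize_call,
    parse_sex,
    resolve_marker,
    resolve_member,
    validate_pedigree,
)
from .store import Database, LoadMode, LoadReport

#: input tokens translated to the missing allele before validation
DEFAULT_MISSING_CODES = ("-", "N", ".", "NA")

_SEPS = {"tab": "\t", "comma": ",", "whitespace": r"\s+"}


class ImportError_(RuntimeError):
    """Import aborted; the run was rolled back."""


@dataclass
class ColumnMap:
    """Where each named field lives in a delimited file (1-based columns)."""

    columns: Dict[str, int]
    delimiter: str = "whitespace"
    skip_rows: int = 0

    def __post_init__(self) -> None:
        if self.delimiter not in _SEPS:
            raise ValueError(f"delimiter must be one of {sorted(_SEPS)}")
        pos = list(self.columns.values())
        if len(set(pos)) != len(pos):
            raise ValueError("column positions must be distinct")
        if any(p < 1 for p in pos):
            raise ValueError("column positions are 1-based")

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.columns]
        if missing:
            raise ValueError(f"column map lacks required columns {missing}")


def read_columns(path: str, colmap: ColumnMap) -> pd.DataFrame:
    """Read the mapped columns of a delimited file into named columns."""
    df = pd.read_csv(
        path,
        sep=_SEPS[colmap.delimiter],
        header=None,
        skiprows=colmap.skip_rows,
        dtype=str,
        comment="#",
        engine="python" if colmap.delimiter == "whitespace" else "c",
    )
    out = pd.DataFrame()
    for name, pos in colmap.columns.items():
        if pos - 1 >= df.shape[1]:
            raise ImportError_(
                f"{path}: column {pos} ({name}) beyond {df.shape[1]} columns"
            )
        out[name] = df.iloc[:, pos - 1].str.strip()
    return out


def _opt(row, col) -> Optional[str]:
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v in ("", "0", "."):
        return None
    return v


# ---------------------------------------------------------------------------
# auxiliary table loaders (the dbvor-subcommand family)


def load_members(
    db: Database, path: str, colmap: ColumnMap, mode: LoadMode = LoadMode.DRY_RUN
) -> LoadReport:
    """Load pedigree structure; parents are validated against the union of
    the file and the store, and parentage must be acyclic."""
    colmap.require("pedigree", "person")
    df = read_columns(path, colmap)
    records, errors = [], []
    parsed = []
    for _, row in df.iterrows():
        try:
            sex = parse_sex(row["sex"]) if "sex" in df.columns else parse_sex("0")
        except GenotypeError as exc:
            errors.append(str(exc))
            continue
        rec = MemberRecord(
            pedigree=row["pedigree"],
            person=row["person"],
            father=_opt(row, "father"),
            mother=_opt(row, "mother"),
            sex=sex,
        )
        parsed.append(rec)
        records.append(
            {
                "pedigree": rec.pedigree,
                "person": rec.person,
                "father": rec.father,
                "mother": rec.mother,
                "sex": rec.sex.value,
            }
        )
    combined = {r.key: r for r in parsed}
    for r in db.conn.execute("SELECT pedigree, person, father, mother, sex FROM members"):
        key = (r["pedigree"], r["person"])
        combined.setdefault(
            key,
            MemberRecord(
                r["pedigree"], r["person"], r["father"], r["mother"]
            ),
        )
    try:
        validate_pedigree(combined.values())
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        return LoadReport(
            table="members", mode=mode, n_parsed=len(df), errors=errors
        )
    return db.load_table("members", records, mode)


def load_member_aliases(
    db: Database, path: str, colmap: ColumnMap, mode: LoadMode = LoadMode.DRY_RUN
) -> LoadReport:
    colmap.require("alias_pedigree", "alias_person", "pedigree", "person")
    df = read_columns(path, colmap)
    members = db.member_ids()
    records, errors = [], []
    for _, row in df.iterrows():
        key = (row["pedigree"], row["person"])
        if key not in members:
            errors.append(f"alias target {key} is not a member")
            continue
        records.append(
            {
                "alias_pedigree": row["alias_pedigree"],
                "alias_person": row["alias_person"],
                "member_id": members[key],
            }
        )
    if errors:
        return LoadReport(
            table="member_aliases", mode=mode, n_parsed=len(df), errors=errors
        )
    return db.load_table("member_aliases", records, mode)


def load_samples(
    db: Database, path: str, colmap: ColumnMap, mode: LoadMode = LoadMode.DRY_RUN
) -> LoadReport:
    colmap.require("sample", "pedigree", "person")
    df = read_columns(path, colmap)
    members = db.member_ids()
    aliases = db.member_alias_map()
    records, errors = [], []
    preferred_seen: Dict[int, str] = {
        r["member_id"]: r["sample_name"]
        for r in db.conn.execute(
            "SELECT member_id, sample_name FROM samples WHERE preferred = 1"
        )
    }
    for _, row in df.iterrows():
        try:
            mid = resolve_member((row["pedigree"], row["person"]), members, aliases)
        except LookupFailure as exc:
            errors.append(str(exc))
            continue
        pref = str(row.get("preferred", "0")).strip().lower() in ("1", "y", "yes", "true")
        if pref:
            if mid in preferred_seen and preferred_seen[mid] != row["sample"]:
                errors.append(
                    f"member {(row['pedigree'], row['person'])} already has "
                    f"preferred sample {preferred_seen[mid]!r}"
                )
                continue
            preferred_seen[mid] = row["sample"]
        records.append(
            {
                "sample_name": row["sample"],
                "member_id": mid,
                "plate": _opt(row, "plate"),
                "well": _opt(row, "well"),
                "preferred": int(pref),
            }
        )
    if errors:
        return LoadReport(
            table="samples", mode=mode, n_parsed=len(df), errors=errors
        )
    return db.load_table("samples", records, mode)


def load_markers(
    db: Database,
    names: Sequence[str],
    mode: LoadMode = LoadMode.DRY_RUN,
) -> LoadReport:
    """Define new markers (the newmarker subcommand)."""
    return db.load_table("markers", [{"name": n} for n in names], mode)


def load_marker_aliases(
    db: Database, path: str, colmap: ColumnMap, mode: LoadMode = LoadMode.DRY_RUN
) -> LoadReport:
    colmap.require("alias", "marker")
    df = read_columns(path, colmap)
    markers = db.marker_ids()
    records, errors = [], []
    for _, row in df.iterrows():
        if row["marker"] not in markers:
            errors.append(f"alias target marker {row['marker']!r} not registered")
            continue
        if row["alias"] in markers:
            errors.append(f"alias {row['alias']!r} collides with a canonical name")
            continue
        records.append(
            {"alias_name": row["alias"], "marker_id": markers[row["marker"]]}
        )
    if errors:
        return LoadReport(
            table="marker_aliases", mode=mode, n_parsed=len(df), errors=errors
        )
    return db.load_table("marker_aliases", records, mode)


def load_marker_info(
    db: Database,
    path: str,
    colmap: ColumnMap,
    build: str,
    mode: LoadMode = LoadMode.DRY_RUN,
    create_markers: bool = True,
) -> LoadReport:
    """Load map positions for one build; unknown markers are registered
    first when ``create_markers`` (otherwise they are errors)."""
    colmap.require("marker", "chromosome", "bp")
    df = read_columns(path, colmap)
    errors: List[str] = []
    names = list(df["marker"])
    markers = db.marker_ids()
    new_names = [n for n in dict.fromkeys(names) if n not in markers]
    if new_names and not create_markers:
        errors.append(f"markers not registered: {new_names[:10]}")
        return LoadReport(table="marker_info", mode=mode, n_parsed=len(df), errors=errors)

    records = []
    for _, row in df.iterrows():
        try:
            chrom = int(row["chromosome"])
            bp = int(row["bp"])
            if not 1 <= chrom <= 26 or bp < 1:
                raise ValueError
        except (TypeError, ValueError):
            errors.append(
                f"marker {row['marker']!r}: bad chromosome/bp "
                f"({row['chromosome']!r}, {row['bp']!r})"
            )
            continue
        rec = {
            "marker_name": row["marker"],
            "build": build,
            "chromosome": chrom,
            "bp": bp,
        }
        for col in ("avg_cm", "female_cm", "male_cm"):
            v = _opt(row, col)
            rec[col] = float(v) if v is not None else None
        records.append(rec)
    if errors:
        return LoadReport(
            table="marker_info", mode=mode, n_parsed=len(df), errors=errors
        )

    report = LoadReport(table="marker_info", mode=mode, n_parsed=len(df))
    try:
        with db.transaction():
            if mode in (LoadMode.COMMIT, LoadMode.COMMIT_REPLACE, LoadMode.COMMIT_UPDATE):
                sub = db.load_table(
                    "markers", [{"name": n} for n in new_names], LoadMode.COMMIT
                )
                if not sub.ok:
                    raise ImportError_("; ".join(sub.errors))
                markers = db.marker_ids()
            else:
                # pretend-register so dry runs can classify the info rows
                markers = dict(markers)
                for i, n in enumerate(new_names):
                    markers[n] = -(i + 1)
            rows = []
            for rec in records:
                rows.append(
                    {
                        "marker_id": markers[rec["marker_name"]],
                        "build": rec["build"],
                        "chromosome": rec["chromosome"],
                        "bp": rec["bp"],
                        "avg_cm": rec["avg_cm"],
                        "female_cm": rec["female_cm"],
                        "male_cm": rec["male_cm"],
                    }
                )
            report = db.load_table("marker_info", rows, mode)
            if not report.ok:
                raise ImportError_("; ".join(report.errors))
    except ImportError_ as exc:
        report.errors.append(f"marker_info: rolled back: {exc}")
        report.committed = False
    return report


def missing_marker_info(db: Database, build: str) -> List[str]:
    """Markers with no map info for the named build."""
    rows = db.conn.execute(
        "SELECT m.name FROM markers m WHERE NOT EXISTS ("
        "  SELECT 1 FROM marker_info i WHERE i.marker_id = m.id AND i.build = ?"
        ") ORDER BY m.name",
        (build,),
    )
    return [r["name"] for r in rows]


def load_traits(
    db: Database,
    path: str,
    colmap: ColumnMap,
    trait: str,
    kind: TraitKind = TraitKind.QUALITATIVE,
    mode: LoadMode = LoadMode.DRY_RUN,
) -> LoadReport:
    """Load one trait's values; quantitative values must parse as numbers."""
    colmap.require("pedigree", "person", "value")
    df = read_columns(path, colmap)
    members = db.member_ids()
    aliases = db.member_alias_map()
    errors: List[str] = []
    values: List[Tuple[int, str]] = []
    for _, row in df.iterrows():
        try:
            mid = resolve_member((row["pedigree"], row["person"]), members, aliases)
        except LookupFailure as exc:
            errors.append(str(exc))
            continue
        v = row["value"]
        if kind is TraitKind.QUANTITATIVE:
            try:
                float(v)
            except ValueError:
                errors.append(f"trait {trait!r}: non-numeric value {v!r}")
                continue
        values.append((mid, v))
    if errors:
        return LoadReport(table="traits", mode=mode, n_parsed=len(df), errors=errors)

    report = LoadReport(table="traits", mode=mode, n_parsed=len(df))
    try:
        with db.transaction():
            if mode in (LoadMode.COMMIT, LoadMode.COMMIT_REPLACE, LoadMode.COMMIT_UPDATE):
                sub = db.load_table(
                    "traitmeta", [{"name": trait, "kind": kind.value}], LoadMode.COMMIT
                )
                if not sub.ok:
                    raise ImportError_("; ".join(sub.errors))
                tid = db.conn.execute(
                    "SELECT id, kind FROM traitmeta WHERE name = ?", (trait,)
                ).fetchone()
                if tid["kind"] != kind.value:
                    raise ImportError_(
                        f"trait {trait!r} already registered as {tid['kind']}"
                    )
                tid = tid["id"]
            else:
                row = db.conn.execute(
                    "SELECT id FROM traitmeta WHERE name = ?", (trait,)
                ).fetchone()
                tid = row["id"] if row else -1
            report = db.load_table(
                "traits",
                [{"member_id": m, "trait_id": tid, "value": v} for m, v in values],
                mode,
            )
            if not report.ok:
                raise ImportError_("; ".join(report.errors))
    except ImportError_ as exc:
        report.errors.append(f"traits: rolled back: {exc}")
        report.committed = False
    return report


def load_allele_maps(
    db: Database, path: str, colmap: ColumnMap, mode: LoadMode = LoadMode.DRY_RUN
) -> LoadReport:
    """Load per-(experiment, marker) allele relabelings; each map must be
    injective and must not touch the missing code."""
    colmap.require("experiment", "marker", "from_allele", "to_allele")
    df = read_columns(path, colmap)
    markers = db.marker_ids()
    amap = db.marker_alias_map()
    errors: List[str] = []
    records = []
    per_pair: Dict[Tuple[str, str], Dict[str, str]] = {}
    for _, row in df.iterrows():
        try:
            eid = db.experiment_id(row["experiment"])
            mid = resolve_marker(row["marker"], markers, amap)
        except LookupFailure as exc:
            errors.append(str(exc))
            continue
        frm, to = row["from_allele"], row["to_allele"]
        if "0" in (frm, to):
            errors.append(f'allele map for {row["marker"]}: "0" cannot be remapped')
            continue
        pair = per_pair.setdefault((row["experiment"], row["marker"]), {})
        if to in pair.values():
            errors.append(
                f"allele map for ({row['experiment']}, {row['marker']}) "
                f"collapses two alleles onto {to!r}"
            )
            continue
        pair[frm] = to
        records.append(
            {
                "experiment_id": eid,
                "marker_id": mid,
                "from_allele": frm,
                "to_allele": to,
            }
        )
    if errors:
        return LoadReport(
            table="allele_map", mode=mode, n_parsed=len(df), errors=errors
        )
    return db.load_table("allele_map", records, mode)


# ---------------------------------------------------------------------------
# targeted genotypes (the geno program)


def import_targeted_genotypes(
    db: Database,
    path: str,
    colmap: ColumnMap,
    experiment: str,
    technology: str,
    mode: LoadMode = LoadMode.DRY_RUN,
    fmt: str = "two_allele",
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    store_missing: bool = True,
) -> LoadReport:
    """Load targeted genotypes into the row store.

    ``fmt`` selects the layout: ``two_allele`` (columns pedigree, person,
    marker, allele1, allele2), ``genotype`` (single "A/C" column), or
    ``wide`` (one line per person; the header row names the markers, cells
    are "A/C").  Every marker must already be registered; unknown markers or
    persons abort the run with nothing inserted.  A record for a
    (member, marker) already present in this experiment with a *different*
    call raises a warning and is stored as a within-experiment duplicate, so
    the disagreement surfaces in merge reports.
    """
    report = LoadReport(table="genotypes", mode=mode)
    members = db.member_ids()
    mem_aliases = db.member_alias_map()
    markers = db.marker_ids()
    mk_aliases = db.marker_alias_map()

    triples: List[Tuple[int, int, object]] = []  # (member_id, marker_id, call)
    errors: List[str] = []

    def add(ped: str, person: str, marker: str, a1: str, a2: str) -> None:
        try:
            mid = resolve_member((ped, person), members, mem_aliases)
        except LookupFailure:
            errors.append(f"unknown person ({ped}, {person})")
            return
        try:
            kid = resolve_marker(marker, markers, mk_aliases)
        except LookupFailure:
            errors.append(f"unknown marker {marker!r}")
            return
        if a1 in missing_codes:
            a1 = "0"
        if a2 in missing_codes:
            a2 = "0"
        try:
            call = normalize_call(a1, a2)
        except GenotypeError as exc:
            errors.append(f"({ped}, {person}) at {marker}: {exc}")
            return
        triples.append((mid, kid, call))

    if fmt in ("two_allele", "genotype"):
        if fmt == "two_allele":
            colmap.require("pedigree", "person", "marker", "allele1", "allele2")
        else:
            colmap.require("pedigree", "person", "marker", "genotype")
        df = read_columns(path, colmap)
        report.n_parsed = len(df)
        for _, row in df.iterrows():
            if fmt == "two_allele":
                a1, a2 = row["allele1"], row["allele2"]
            else:
                g = row["genotype"]
                if g in missing_codes:
                    a1 = a2 = "0"
                else:
                    parts = g.replace("|", "/").split("/")
                    if len(parts) != 2:
                        errors.append(f"malformed genotype {g!r}")
                        continue
                    a1, a2 = parts
            add(row["pedigree"], row["person"], row["marker"], a1, a2)
    elif fmt == "wide":
        colmap.require("pedigree", "person")
        sep = _SEPS[colmap.delimiter]
        df = pd.read_csv(
            path,
            sep=sep,
            skiprows=colmap.skip_rows,
            dtype=str,
            engine="python" if colmap.delimiter == "whitespace" else "c",
        )
        report.n_parsed = len(df)
        ped_col = df.columns[colmap.columns["pedigree"] - 1]
        per_col = df.columns[colmap.columns["person"] - 1]
        id_cols = {ped_col, per_col}
        marker_cols = [c for c in df.columns if c not in id_cols]
        for _, row in df.iterrows():
            for mk in marker_cols:
                g = str(row[mk]).strip()
                if g in missing_codes or g == "nan":
                    a1 = a2 = "0"
                else:
                    parts = g.replace("|", "/").split("/")
                    if len(parts) != 2:
                        errors.append(f"malformed genotype {g!r} at {mk}")
                        continue
                    a1, a2 = parts
                add(row[ped_col], row[per_col], mk, a1, a2)
    else:
        raise ValueError(f"unknown targeted-genotype format {fmt!r}")

    if errors:
        report.errors = errors
        return report

    # existing calls for duplicate detection
    eid = db.experiment_id(experiment, create=mode is not LoadMode.DRY_RUN)
    tid = db.technology_id(technology, create=mode is not LoadMode.DRY_RUN)
    existing: Dict[Tuple[int, int], set] = {}
    for r in db.conn.execute(
        "SELECT member_id, marker_id, allele1, allele2 FROM genotypes "
        "WHERE experiment_id = ?",
        (eid,),
    ):
        existing.setdefault((r["member_id"], r["marker_id"]), set()).add(
            (r["allele1"], r["allele2"])
        )

    to_insert = []
    seen_now: Dict[Tuple[int, int], set] = {}
    for mid, kid, call in triples:
        if not store_missing and call.is_missing:
            continue
        pair = call.alleles()
        prior = existing.get((mid, kid), set()) | seen_now.get((mid, kid), set())
        if pair in prior:
            continue  # identical duplicate: idempotent
        if prior:
            report.warnings.append(
                f"member {mid} marker {kid}: duplicate measurement "
                f"{call} differs from {sorted(prior)} within {experiment!r}"
            )
        seen_now.setdefault((mid, kid), set()).add(pair)
        to_insert.append((mid, kid, eid, tid, call.allele1, call.allele2))

    report.n_new = len(to_insert)
    if mode is LoadMode.DRY_RUN or mode is LoadMode.COMPARE:
        return report
    try:
        with db.transaction():
            db.conn.executemany(
                "INSERT INTO genotypes "
                "(member_id, marker_id, experiment_id, technology_id, allele1, allele2) "
                "VALUES (?, ?, ?, ?, ?, ?)",
                to_insert,
            )
        report.committed = True
    except Exception as exc:
        report.errors.append(f"genotypes: rolled back: {exc}")
        report.committed = False
    return report


# ---------------------------------------------------------------------------
# block-wise genotypes (genoi / genoa / genok share this base)


def _alleles_to_codes(values: np.ndarray, missing_codes: Sequence[str]) -> np.ndarray:
    """Translate an array of single-character allele strings to uint8 codes."""
    arr = values.astype(str)
    for mc in missing_codes:
        arr[arr == mc] = "0"
    lengths = np.char.str_len(arr)
    if (lengths != 1).any():
        bad = arr[lengths != 1][0]
        raise ImportError_(f"allele token {bad!r} is not a single code")
    return arr.astype("S1").view(np.uint8)


def _read_mapping(path: str, colmap: ColumnMap) -> pd.DataFrame:
    colmap.require("marker", "chromosome", "bp")
    df = read_columns(path, colmap)
    df["chromosome"] = df["chromosome"].astype(int)
    df["bp"] = df["bp"].astype(int)
    return df


class _BlockImportBase:
    """Shared machinery: mapping file → markers/marker_info/snpblocks, then
    per-sample call arrays → genotype blocks."""

    def __init__(
        self,
        db: Database,
        mapping_path: str,
        experiment: str,
        technology: str,
        map_colmap: ColumnMap,
        build: str = "default",
        block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
        layout_name: Optional[str] = None,
        missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    ):
        self.db = db
        self.experiment = experiment
        self.technology = technology
        self.build = build
        self.block_size = block_size
        self.missing_codes = missing_codes
        self.mapping = _read_mapping(mapping_path, map_colmap)
        self.layout_name = layout_name or os.path.splitext(
            os.path.basename(mapping_path)
        )[0]
        # row indices of the mapping grouped by chromosome, preserving order
        self.chrom_rows: Dict[int, np.ndarray] = {
            int(c): g.index.to_numpy()
            for c, g in self.mapping.groupby("chromosome", sort=True)
        }

    def register_map(self) -> None:
        """markers + marker_info + slot index, all under commit semantics."""
        db = self.db
        names = list(self.mapping["marker"])
        sub = db.load_table(
            "markers",
            [{"name": n} for n in dict.fromkeys(names)],
            LoadMode.COMMIT,
        )
        if not sub.ok:
            raise ImportError_("; ".join(sub.errors))
        markers = db.marker_ids()
        info_rows = [
            {
                "marker_id": markers[r.marker],
                "build": self.build,
                "chromosome": int(r.chromosome),
                "bp": int(r.bp),
                "avg_cm": None,
                "female_cm": None,
                "male_cm": None,
            }
            for r in self.mapping.itertuples()
        ]
        sub = db.load_table("marker_info", info_rows, LoadMode.COMMIT)
        if not sub.ok:
            raise ImportError_("; ".join(sub.errors))
        by_chrom = {
            c: [markers[self.mapping["marker"].iloc[i]] for i in rows]
            for c, rows in self.chrom_rows.items()
        }
        blockcodec.write_index(db, self.layout_name, by_chrom, self.block_size)

    def arrays_for(self, pairs: np.ndarray) -> Dict[int, np.ndarray]:
        """Split an (n_markers, 2) code array (mapping order) by chromosome."""
        return {c: pairs[rows] for c, rows in self.chrom_rows.items()}

    def samples_with_blocks(self, experiment_id: int) -> set:
        return {
            r["sample_id"]
            for r in self.db.conn.execute(
                "SELECT DISTINCT sample_id FROM genotypeblocks "
                "WHERE experiment_id = ? AND layout = ?",
                (experiment_id, self.layout_name),
            )
        }

    def run(
        self,
        sample_arrays: Mapping[str, np.ndarray],
        mode: LoadMode,
    ) -> LoadReport:
        """Commit mapping + blocks for named samples' (m, 2) code arrays."""
        db = self.db
        report = LoadReport(table="genotypeblocks", mode=mode)
        report.n_parsed = len(sample_arrays)
        sample_ids = db.sample_ids()
        unknown = [s for s in sample_arrays if s not in sample_ids]
        if unknown:
            report.errors.append(f"samples not registered: {sorted(unknown)[:10]}")
            return report
        n_map = len(self.mapping)
        for s, arr in sample_arrays.items():
            if arr.shape != (n_map, 2):
                report.errors.append(
                    f"sample {s!r}: {arr.shape[0]} genotypes but the mapping "
                    f"file lists {n_map} markers"
                )
        if report.errors:
            return report
        if mode in (LoadMode.DRY_RUN, LoadMode.COMPARE):
            return report
        try:
            with db.transaction():
                self.register_map()
                eid = db.experiment_id(self.experiment, create=True)
                tid = db.technology_id(self.technology, create=True)
                db.conn.execute(
                    "UPDATE experiments SET technology_id = ? "
                    "WHERE id = ? AND technology_id IS NULL",
                    (tid, eid),
                )
                done = self.samples_with_blocks(eid)
                for s, arr in sample_arrays.items():
                    sid = sample_ids[s]
                    if sid in done:
                        continue  # idempotent re-run: no new blocks
                    n = blockcodec.write_sample_arrays(
                        db, sid, eid, self.layout_name,
                        self.arrays_for(arr), self.block_size,
                    )
                    report.n_new += n
            report.committed = True
        except Exception as exc:
            report.errors.append(f"genotypeblocks: rolled back: {exc}")
            report.n_new = 0
            report.committed = False
        return report


def import_per_sample_files(
    db: Database,
    mapping_path: str,
    sample_files: Mapping[str, str],
    experiment: str,
    technology: str = "illumina",
    map_colmap: Optional[ColumnMap] = None,
    sample_colmap: Optional[ColumnMap] = None,
    build: str = "default",
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
    layout_name: Optional[str] = None,
    mode: LoadMode = LoadMode.DRY_RUN,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> LoadReport:
    """One genotype file per sample plus a marker mapping file.

    ``sample_files`` maps registered sample names to file paths.  Sample
    files carry marker, allele1, allele2 columns; markers must match the
    mapping file (same set; order may differ).  A sample whose marker count
    disagrees with the mapping aborts the run.
    """
    map_colmap = map_colmap or ColumnMap(
        {"marker": 1, "chromosome": 2, "bp": 3}, delimiter="tab"
    )
    sample_colmap = sample_colmap or ColumnMap(
        {"marker": 1, "allele1": 2, "allele2": 3}, delimiter="tab"
    )
    sample_colmap.require("marker", "allele1", "allele2")
    base = _BlockImportBase(
        db, mapping_path, experiment, technology, map_colmap,
        build, block_size, layout_name, missing_codes,
    )
    map_names = base.mapping["marker"].to_numpy()
    order_index = {n: i for i, n in enumerate(map_names)}
    arrays: Dict[str, np.ndarray] = {}
    report = LoadReport(table="genotypeblocks", mode=mode)
    sep = _SEPS[sample_colmap.delimiter]
    cols = sample_colmap.columns
    usecols = [cols["marker"] - 1, cols["allele1"] - 1, cols["allele2"] - 1]
    for s, path in sample_files.items():
        df = pd.read_csv(
            path,
            sep=sep,
            header=None,
            skiprows=sample_colmap.skip_rows,
            dtype=str,
            usecols=usecols,
            engine="python" if sample_colmap.delimiter == "whitespace" else "c",
        )
        df.columns = range(df.shape[1])
        names = df[usecols.index(cols["marker"] - 1)].to_numpy()
        try:
            a1 = _alleles_to_codes(
                df[usecols.index(cols["allele1"] - 1)].to_numpy(), missing_codes
            )
            a2 = _alleles_to_codes(
                df[usecols.index(cols["allele2"] - 1)].to_numpy(), missing_codes
            )
        except ImportError_ as exc:
            report.errors.append(f"sample {s!r}: {exc}")
            continue
        pairs = np.stack([a1, a2], axis=1)
        if len(names) != len(map_names):
            report.errors.append(
                f"sample {s!r}: {len(names)} genotypes but the mapping file "
                f"lists {len(map_names)} markers"
            )
            continue
        if not np.array_equal(names, map_names):  # reorder by marker name
            try:
                perm = np.array([order_index[n] for n in names])
            except KeyError as exc:
                report.errors.append(f"sample {s!r}: marker {exc} not in mapping")
                continue
            if len(set(perm.tolist())) != len(perm):
                report.errors.append(f"sample {s!r}: duplicated markers")
                continue
            reordered = np.empty_like(pairs)
            reordered[perm] = pairs
            pairs = reordered
        arrays[s] = pairs
    if report.errors:
        return report
    return base.run(arrays, mode)


def import_multi_sample_file(
    db: Database,
    path: str,
    mapping_path: str,
    experiment: str,
    technology: str = "affymetrix",
    map_colmap: Optional[ColumnMap] = None,
    build: str = "default",
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
    layout_name: Optional[str] = None,
    mode: LoadMode = LoadMode.DRY_RUN,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    delimiter: str = "tab",
) -> LoadReport:
    """Several samples' genotypes in one file.

    The file has a header row — ``marker`` then one column per sample named
    by its registered sample name — and "A/C"-style genotype cells.  Marker
    rows must match the mapping file.
    """
    map_colmap = map_colmap or ColumnMap(
        {"marker": 1, "chromosome": 2, "bp": 3}, delimiter="tab"
    )
    base = _BlockImportBase(
        db, mapping_path, experiment, technology, map_colmap,
        build, block_size, layout_name, missing_codes,
    )
    sep = _SEPS[delimiter]
    df = pd.read_csv(
        path, sep=sep, dtype=str,
        engine="python" if delimiter == "whitespace" else "c",
    )
    report = LoadReport(table="genotypeblocks", mode=mode)
    if df.shape[1] < 1:
        report.errors.append(f"{path}: empty file")
        return report
    names = df.iloc[:, 0].str.strip().to_numpy()
    map_names = base.mapping["marker"].to_numpy()
    if len(names) != len(map_names) or not np.array_equal(names, map_names):
        report.errors.append(
            f"{path}: marker rows do not match the mapping file"
        )
        return report
    arrays: Dict[str, np.ndarray] = {}
    for col in df.columns[1:]:
        cells = df[col].str.strip().to_numpy(dtype=str)
        for mc in missing_codes:
            cells[cells == mc] = "0/0"
        ok = np.char.str_len(cells) == 3
        if not ok.all():
            report.errors.append(
                f"sample {col!r}: malformed genotype {cells[~ok][0]!r}"
            )
            continue
        flat = cells.astype("S3").view(np.uint8).reshape(-1, 3)
        if not (flat[:, 1] == ord("/")).all():
            report.errors.append(f"sample {col!r}: genotype cells must be X/Y")
            continue
        arrays[str(col)] = flat[:, [0, 2]].copy()
    if report.errors:
        return report
    return base.run(arrays, mode)


def import_ped_rows(
    db: Database,
    ped_path: str,
    map_path: str,
    experiment: str,
    technology: str = "flatfile",
    build: str = "default",
    mode: LoadMode = LoadMode.DRY_RUN,
) -> LoadReport:
    """Read a text ped/map pair into the targeted row store.

    Members and samples are registered from the pedigree columns; markers
    and map info come from the map file.  Missing genotypes (0/0) are not
    stored in this representation — absent rows read back as missing.
    """
    markers_rows: List[Tuple[int, str, float, int]] = []
    with open(map_path) as fh:
        for line in fh:
            f = line.split()
            if f:
                markers_rows.append((int(f[0]), f[1], float(f[2]), int(f[3])))
    fam, geno = plink.read_ped(ped_path, len(markers_rows))
    report = LoadReport(table="genotypes", mode=mode, n_parsed=len(fam))
    if mode in (LoadMode.DRY_RUN, LoadMode.COMPARE):
        return report
    try:
        with db.transaction():
            member_rows = [
                {
                    "pedigree": f.pedigree,
                    "person": f.person,
                    "father": None if f.father == "0" else f.father,
                    "mother": None if f.mother == "0" else f.mother,
                    "sex": f.sex,
                }
                for f in fam
            ]
            for table, rows in (
                ("members", member_rows),
                ("markers", [{"name": n} for _c, n, _cm, _bp in markers_rows]),
            ):
                sub = db.load_table(table, rows, LoadMode.COMMIT)
                if not sub.ok:
                    raise ImportError_("; ".join(sub.errors))
            markers = db.marker_ids()
            info_rows = [
                {
                    "marker_id": markers[n],
                    "build": build,
                    "chromosome": c,
                    "bp": bp,
                    "avg_cm": cm if cm else None,
                    "female_cm": None,
                    "male_cm": None,
                }
                for c, n, cm, bp in markers_rows
            ]
            sub = db.load_table("marker_info", info_rows, LoadMode.COMMIT)
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))
            members = db.member_ids()
            eid = db.experiment_id(experiment, create=True)
            tid = db.technology_id(technology, create=True)
            inserts = []
            for i, f in enumerate(fam):
                mid = members[(f.pedigree, f.person)]
                col = geno[:, i, :]
                for j, (_c, name, _cm, _bp) in enumerate(markers_rows):
                    a1, a2 = chr(col[j, 0]), chr(col[j, 1])
                    if a1 == "0" and a2 == "0":
                        continue  # missing rows are not stored
                    call = normalize_call(a1, a2)
                    inserts.append(
                        (mid, markers[name], eid, tid, call.allele1, call.allele2)
                    )
            db.conn.executemany(
                "INSERT INTO genotypes "
                "(member_id, marker_id, experiment_id, technology_id, allele1, allele2) "
                "VALUES (?, ?, ?, ?, ?, ?)",
                inserts,
            )
            report.n_new = len(inserts)
        report.committed = True
    except Exception as exc:
        report.errors.append(f"ped import: rolled back: {exc}")
        report.n_new = 0
        report.committed = False
    return report


def import_plink_binary(
    db: Database,
    prefix: str,
    experiment: str,
    technology: str = "plink",
    build: str = "default",
    trait_name: str = "affection",
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
    layout_name: Optional[str] = None,
    mode: LoadMode = LoadMode.DRY_RUN,
) -> LoadReport:
    """Import a PLINK 1 binary fileset (SNP-major bed + bim + fam).

    Markers, map info and the slot index come from the bim; pedigree rows
    become members and one auto-named sample per person; the fam phenotype
    column is stored as one qualitative trait; the bed is decoded into
    genotype blocks.
    """
    bim = plink.read_bim(f"{prefix}.bim")
    fam = plink.read_fam(f"{prefix}.fam")
    geno = plink.read_bed(f"{prefix}.bed", bim, fam)

    report = LoadReport(table="genotypeblocks", mode=mode)
    report.n_parsed = len(fam)
    if mode in (LoadMode.DRY_RUN, LoadMode.COMPARE):
        report.n_new = len(bim) * 0
        return report

    layout = layout_name or os.path.basename(prefix)
    try:
        with db.transaction():
            member_rows = [
                {
                    "pedigree": f.pedigree,
                    "person": f.person,
                    "father": None if f.father == "0" else f.father,
                    "mother": None if f.mother == "0" else f.mother,
                    "sex": f.sex,
                }
                for f in fam
            ]
            sub = db.load_table("members", member_rows, LoadMode.COMMIT)
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))
            members = db.member_ids()
            sample_rows = [
                {
                    "sample_name": f"{f.pedigree}:{f.person}",
                    "member_id": members[(f.pedigree, f.person)],
                    "plate": None,
                    "well": None,
                    "preferred": 0,
                }
                for f in fam
            ]
            sub = db.load_table("samples", sample_rows, LoadMode.COMMIT)
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))
            sub = db.load_table(
                "traitmeta", [{"name": trait_name, "kind": "qualitative"}],
                LoadMode.COMMIT,
            )
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))
            trait_id = db.conn.execute(
                "SELECT id FROM traitmeta WHERE name = ?", (trait_name,)
            ).fetchone()["id"]
            trait_rows = [
                {
                    "member_id": members[(f.pedigree, f.person)],
                    "trait_id": trait_id,
                    "value": f.phenotype,
                }
                for f in fam
                if f.phenotype not in ("0", "-9")
            ]
            sub = db.load_table("traits", trait_rows, LoadMode.COMMIT)
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))

            sub = db.load_table(
                "markers",
                [{"name": r.name} for r in bim],
                LoadMode.COMMIT,
            )
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))
            markers = db.marker_ids()
            info_rows = [
                {
                    "marker_id": markers[r.name],
                    "build": build,
                    "chromosome": r.chromosome,
                    "bp": r.bp,
                    "avg_cm": r.cm if r.cm else None,
                    "female_cm": None,
                    "male_cm": None,
                }
                for r in bim
            ]
            sub = db.load_table("marker_info", info_rows, LoadMode.COMMIT)
            if not sub.ok:
                raise ImportError_("; ".join(sub.errors))

            by_chrom: Dict[int, List[int]] = {}
            chrom_rows: Dict[int, List[int]] = {}
            for j, r in enumerate(bim):
                by_chrom.setdefault(r.chromosome, []).append(markers[r.name])
                chrom_rows.setdefault(r.chromosome, []).append(j)
            blockcodec.write_index(db, layout, by_chrom, block_size)

            eid = db.experiment_id(experiment, create=True)
            tid = db.technology_id(technology, create=True)
            db.conn.execute(
                "UPDATE experiments SET technology_id = ? "
                "WHERE id = ? AND technology_id IS NULL",
                (tid, eid),
            )
            sample_ids = db.sample_ids()
            done = {
                r["sample_id"]
                for r in db.conn.execute(
                    "SELECT DISTINCT sample_id FROM genotypeblocks "
                    "WHERE experiment_id = ? AND layout = ?",
                    (eid, layout),
                )
            }
            for i, f in enumerate(fam):
                sid = sample_ids[f"{f.pedigree}:{f.person}"]
                if sid in done:
                    continue
                arrays = {
                    c: np.ascontiguousarray(geno[rows, i, :])
                    for c, rows in chrom_rows.items()
                }
                report.n_new += blockcodec.write_sample_arrays(
                    db, sid, eid, layout, arrays, block_size
                )
        report.committed = True
    except Exception as exc:
        report.errors.append(f"plink import: rolled back: {exc}")
        report.n_new = 0
        report.committed = False
    return report
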