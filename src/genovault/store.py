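"""Transactional relational persistence over sqlite3.

The store keeps every table of the vault schema and implements the
load-flag protocol shared by all data-entry commands:

* ``dry_run``   — validate and report; the store is never touched.
* ``commit``    — insert only records absent from the store; records whose
  natural key exists with different values produce a warning and are NOT
  modified.
* ``commit_replace`` — changed records are deleted then re-inserted.
* ``commit_update``  — changed records are modified in place (for rows
  whose ids are referenced elsewhere).
* ``compare``   — report differences between the input and the store.
* ``delete``    — remove every listed record.

Any error during a committing mode rolls back every change of the run.
"""

from __future__ import annotations

import contextlib
import enum
import hashlib
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .datamodel import LookupFailure


class LoadMode(enum.Enum):
    DRY_RUN = "dry_run"
    COMMIT = "commit"
    COMMIT_REPLACE = "commit_replace"
    COMMIT_UPDATE = "commit_update"
    COMPARE = "compare"
    DELETE = "delete"


#: Modes that may write to the store.
_WRITING = {LoadMode.COMMIT, LoadMode.COMMIT_REPLACE, LoadMode.COMMIT_UPDATE, LoadMode.DELETE}


@dataclass
class LoadReport:
    """Outcome of one load run.

    ``committed`` implies ``errors`` is empty; a dry run leaves the store
    unchanged whatever the report says.
    """

    table: str = ""
    mode: LoadMode = LoadMode.DRY_RUN
    n_parsed: int = 0
    n_new: int = 0
    n_changed: int = 0
    n_deleted: int = 0
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    committed: bool = False

    @property
    def ok(self) -> bool:
        return not self.errors


_SCHEMA = """
CREATE TABLE IF NOT EXISTS members (
    id INTEGER PRIMARY KEY,
    pedigree TEXT NOT NULL,
    person TEXT NOT NULL,
    father TEXT,
    mother TEXT,
    sex INTEGER NOT NULL DEFAULT 0,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (pedigree, person)
);
CREATE TABLE IF NOT EXISTS member_aliases (
    id INTEGER PRIMARY KEY,
    alias_pedigree TEXT NOT NULL,
    alias_person TEXT NOT NULL,
    member_id INTEGER NOT NULL REFERENCES members(id),
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (alias_pedigree, alias_person)
);
CREATE TABLE IF NOT EXISTS samples (
    id INTEGER PRIMARY KEY,
    sample_name TEXT NOT NULL UNIQUE,
    member_id INTEGER NOT NULL REFERENCES members(id),
    plate TEXT,
    well TEXT,
    preferred INTEGER NOT NULL DEFAULT 0,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS markers (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS marker_aliases (
    id INTEGER PRIMARY KEY,
    alias_name TEXT NOT NULL UNIQUE,
    marker_id INTEGER NOT NULL REFERENCES markers(id),
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS marker_info (
    id INTEGER PRIMARY KEY,
    marker_id INTEGER NOT NULL REFERENCES markers(id),
    build TEXT NOT NULL,
    chromosome INTEGER NOT NULL,
    bp INTEGER NOT NULL,
    avg_cm REAL,
    female_cm REAL,
    male_cm REAL,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (marker_id, build)
);
CREATE TABLE IF NOT EXISTS traitmeta (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    kind TEXT NOT NULL CHECK (kind IN ('qualitative','quantitative')),
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS traits (
    id INTEGER PRIMARY KEY,
    member_id INTEGER NOT NULL REFERENCES members(id),
    trait_id INTEGER NOT NULL REFERENCES traitmeta(id),
    value TEXT NOT NULL,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (member_id, trait_id)
);
CREATE TABLE IF NOT EXISTS technologies (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS experiments (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    date TEXT,
    technology_id INTEGER REFERENCES technologies(id),
    trust INTEGER NOT NULL DEFAULT 0,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS allele_map (
    id INTEGER PRIMARY KEY,
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    marker_id INTEGER NOT NULL REFERENCES markers(id),
    from_allele TEXT NOT NULL,
    to_allele TEXT NOT NULL,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (experiment_id, marker_id, from_allele)
);
CREATE TABLE IF NOT EXISTS genotypes (
    id INTEGER PRIMARY KEY,
    member_id INTEGER NOT NULL REFERENCES members(id),
    marker_id INTEGER NOT NULL REFERENCES markers(id),
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    technology_id INTEGER REFERENCES technologies(id),
    allele1 TEXT NOT NULL,
    allele2 TEXT NOT NULL,
    active INTEGER NOT NULL DEFAULT 1,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE INDEX IF NOT EXISTS idx_genotypes_mm ON genotypes (marker_id, member_id);
CREATE TABLE IF NOT EXISTS snpblocks (
    id INTEGER PRIMARY KEY,
    layout TEXT NOT NULL,
    marker_id INTEGER NOT NULL REFERENCES markers(id),
    chromosome INTEGER NOT NULL,
    block_index INTEGER NOT NULL,
    offset INTEGER NOT NULL,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (layout, marker_id)
);
CREATE INDEX IF NOT EXISTS idx_snpblocks_loc ON snpblocks (layout, chromosome, block_index);
CREATE TABLE IF NOT EXISTS genotypeblocks (
    id INTEGER PRIMARY KEY,
    sample_id INTEGER NOT NULL REFERENCES samples(id),
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    layout TEXT NOT NULL,
    chromosome INTEGER NOT NULL,
    block_index INTEGER NOT NULL,
    block_size INTEGER NOT NULL,
    payload BLOB NOT NULL,
    stamp TEXT NOT NULL DEFAULT (datetime('now')),
    UNIQUE (sample_id, experiment_id, layout, chromosome, block_index)
);
CREATE TABLE IF NOT EXISTS notes (
    id INTEGER PRIMARY KEY,
    keywords TEXT NOT NULL,
    comment TEXT,
    payload TEXT,
    stamp TEXT NOT NULL DEFAULT (datetime('now'))
);
"""

#: natural key and value columns per logical table (id/stamp excluded)
_TABLE_KEYS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "members": (("pedigree", "person"), ("father", "mother", "sex")),
    "member_aliases": (("alias_pedigree", "alias_person"), ("member_id",)),
    "samples": (("sample_name",), ("member_id", "plate", "well", "preferred")),
    "markers": (("name",), ()),
    "marker_aliases": (("alias_name",), ("marker_id",)),
    "marker_info": (
        ("marker_id", "build"),
        ("chromosome", "bp", "avg_cm", "female_cm", "male_cm"),
    ),
    "traitmeta": (("name",), ("kind",)),
    "traits": (("member_id", "trait_id"), ("value",)),
    "technologies": (("name",), ()),
    "experiments": (("name",), ("date", "technology_id", "trust")),
    "allele_map": (
        ("experiment_id", "marker_id", "from_allele"),
        ("to_allele",),
    ),
    "genotypes": (
        ("member_id", "marker_id", "experiment_id", "technology_id"),
        ("allele1", "allele2", "active"),
    ),
}


class StoreError(RuntimeError):
    pass


class Database:
    """One connection to a vault database (a file path or ``":memory:"``)."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.isolation_level = None  # manual (savepoint) transactions
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.row_factory = sqlite3.Row
        self._sp_counter = 0

    # -- lifecycle ---------------------------------------------------------

    @contextlib.contextmanager
    def transaction(self):
        """Savepoint-based transaction; nests inside enclosing transactions.

        On exception everything since entry is rolled back and the exception
        propagates — the unit every committing run relies on.
        """
        self._sp_counter += 1
        name = f"sp_{self._sp_counter}"
        self.conn.execute(f"SAVEPOINT {name}")
        try:
            yield
        except Exception:
            self.conn.execute(f"ROLLBACK TO {name}")
            self.conn.execute(f"RELEASE {name}")
            raise
        else:
            self.conn.execute(f"RELEASE {name}")

    def create_schema(self) -> None:
        # executescript manages its own transaction
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def checksum(self) -> str:
        """Content hash of all rows (timestamps excluded) — used to assert
        that a run left the store untouched."""
        h = hashlib.sha256()
        tables = [
            r["name"]
            for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
            )
        ]
        for t in tables:
            cols = [
                r["name"]
                for r in self.conn.execute(f"PRAGMA table_info({t})")
                if r["name"] != "stamp"
            ]
            col_expr = ", ".join(cols)
            h.update(t.encode())
            for row in self.conn.execute(
                f"SELECT {col_expr} FROM {t} ORDER BY {col_expr}"
            ):
                h.update(repr(tuple(row)).encode())
        return h.hexdigest()

    # -- name/id lookups ---------------------------------------------------

    def member_ids(self) -> Dict[Tuple[str, str], int]:
        return {
            (r["pedigree"], r["person"]): r["id"]
            for r in self.conn.execute("SELECT id, pedigree, person FROM members")
        }

    def member_alias_map(self) -> Dict[Tuple[str, str], Tuple[str, str]]:
        return {
            (r["alias_pedigree"], r["alias_person"]): (r["pedigree"], r["person"])
            for r in self.conn.execute(
                "SELECT a.alias_pedigree, a.alias_person, m.pedigree, m.person "
                "FROM member_aliases a JOIN members m ON m.id = a.member_id"
            )
        }

    def marker_ids(self) -> Dict[str, int]:
        return {
            r["name"]: r["id"]
            for r in self.conn.execute("SELECT id, name FROM markers")
        }

    def marker_alias_map(self) -> Dict[str, str]:
        return {
            r["alias_name"]: r["name"]
            for r in self.conn.execute(
                "SELECT a.alias_name, m.name FROM marker_aliases a "
                "JOIN markers m ON m.id = a.marker_id"
            )
        }

    def _name_id(self, table: str, name: str) -> Optional[int]:
        row = self.conn.execute(
            f"SELECT id FROM {table} WHERE name = ?", (name,)
        ).fetchone()
        return None if row is None else row["id"]

    def experiment_id(self, name: str, create: bool = False) -> int:
        eid = self._name_id("experiments", name)
        if eid is None:
            if not create:
                raise LookupFailure(f"unknown experiment {name!r}")
            with self.transaction():
                eid = self.conn.execute(
                    "INSERT INTO experiments (name) VALUES (?)", (name,)
                ).lastrowid
        return eid

    def technology_id(self, name: str, create: bool = False) -> int:
        tid = self._name_id("technologies", name)
        if tid is None:
            if not create:
                raise LookupFailure(f"unknown technology {name!r}")
            with self.transaction():
                tid = self.conn.execute(
                    "INSERT INTO technologies (name) VALUES (?)", (name,)
                ).lastrowid
        return tid

    def sample_ids(self) -> Dict[str, int]:
        return {
            r["sample_name"]: r["id"]
            for r in self.conn.execute("SELECT id, sample_name FROM samples")
        }

    # -- generic load protocol ---------------------------------------------

    def load_table(
        self,
        table: str,
        records: Sequence[Mapping[str, object]],
        mode: LoadMode = LoadMode.DRY_RUN,
        _fail_after: Optional[int] = None,
    ) -> LoadReport:
        """Apply ``records`` to ``table`` under the load-flag protocol.

        Records are dicts keyed by column name; foreign keys must already be
        resolved to ids (the importers do this).  ``_fail_after`` aborts the
        run after N row writes — an internal hook for exercising the
        rollback guarantee.
        """
        if table not in _TABLE_KEYS:
            raise StoreError(f"no load protocol for table {table!r}")
        key_cols, val_cols = _TABLE_KEYS[table]
        report = LoadReport(table=table, mode=mode, n_parsed=len(records))

        def key_of(rec: Mapping[str, object]):
            return tuple(rec.get(c) for c in key_cols)

        # current state keyed by natural key
        existing: Dict[tuple, dict] = {}
        for row in self.conn.execute(f"SELECT * FROM {table}"):
            d = dict(row)
            existing[tuple(d[c] for c in key_cols)] = d

        new, changed, same, missing = [], [], [], []
        seen = set()
        for rec in records:
            k = key_of(rec)
            if any(v is None for v in k) and table != "genotypes":
                report.errors.append(f"{table}: record with incomplete key {k}")
                continue
            if k in seen:
                report.warnings.append(f"{table}: duplicate input record {k}")
                continue
            seen.add(k)
            if k not in existing:
                new.append(rec)
                missing.append(k)
                continue
            cur = existing[k]
            if any(_norm(rec.get(c)) != _norm(cur.get(c)) for c in val_cols):
                changed.append((rec, cur))
            else:
                same.append(rec)

        report.n_new = len(new)
        report.n_changed = len(changed)

        if mode is LoadMode.COMPARE:
            for rec, cur in changed:
                report.warnings.append(
                    f"{table}: differs at {key_of(rec)}: "
                    f"file={_vals(rec, val_cols)} store={_vals(cur, val_cols)}"
                )
            return report
        if mode is LoadMode.DRY_RUN:
            for rec, cur in changed:
                report.warnings.append(
                    f"{table}: would not modify changed record {key_of(rec)}"
                )
            return report
        if report.errors:
            return report

        cols = list(dict.fromkeys([*key_cols, *val_cols]))
        placeholders = ", ".join("?" for _ in cols)
        insert_sql = (
            f"INSERT INTO {table} ({', '.join(cols)}) VALUES ({placeholders})"
        )
        writes = 0

        def bump():
            nonlocal writes
            writes += 1
            if _fail_after is not None and writes > _fail_after:
                raise StoreError("injected failure")

        where = " AND ".join(f"{c} = ?" for c in key_cols)
        try:
            with self.transaction():
                if mode is LoadMode.DELETE:
                    for rec in records:
                        cur = self.conn.execute(
                            f"DELETE FROM {table} WHERE {where}", key_of(rec)
                        )
                        report.n_deleted += cur.rowcount
                        bump()
                else:
                    for rec in new:
                        self.conn.execute(
                            insert_sql, [_norm(rec.get(c)) for c in cols]
                        )
                        bump()
                    if mode is LoadMode.COMMIT:
                        for rec, cur in changed:
                            report.warnings.append(
                                f"{table}: record {key_of(rec)} differs from store; "
                                "not modified (use replace or update)"
                            )
                    elif mode is LoadMode.COMMIT_REPLACE:
                        for rec, cur in changed:
                            self.conn.execute(
                                f"DELETE FROM {table} WHERE {where}", key_of(rec)
                            )
                            self.conn.execute(
                                insert_sql, [_norm(rec.get(c)) for c in cols]
                            )
                            bump()
                    elif mode is LoadMode.COMMIT_UPDATE:
                        sets = ", ".join(f"{c} = ?" for c in val_cols)
                        for rec, cur in changed:
                            self.conn.execute(
                                f"UPDATE {table} SET {sets}, stamp = datetime('now') "
                                f"WHERE {where}",
                                [_norm(rec.get(c)) for c in val_cols]
                                + list(key_of(rec)),
                            )
                            bump()
            report.committed = True
        except Exception as exc:  # any failure rolls back the whole run
            report.errors.append(f"{table}: rolled back: {exc}")
            report.n_deleted = 0
            report.committed = False
        return report

    # -- genotype-level operations ------------------------------------------

    def delete_experiment(self, name: str) -> int:
        """Remove every genotype row and genotype block of an experiment.

        Returns the number of genotype records removed (rows plus blocks).
        The experiment record itself is kept.
        """
        eid = self.experiment_id(name)
        with self.transaction():
            c1 = self.conn.execute(
                "DELETE FROM genotypes WHERE experiment_id = ?", (eid,)
            ).rowcount
            c2 = self.conn.execute(
                "DELETE FROM genotypeblocks WHERE experiment_id = ?", (eid,)
            ).rowcount
        return c1 + c2

    def set_active(
        self,
        experiment: str,
        flag: bool,
        marker_names: Optional[Iterable[str]] = None,
        member_pairs: Optional[Iterable[Tuple[str, str]]] = None,
    ) -> int:
        """Flip the active flag on targeted genotype rows.

        ``marker_names``/``member_pairs`` restrict the selection; both absent
        means the whole experiment.  Returns the number of rows updated
        (an empty selection is 0, not an error).
        """
        eid = self.experiment_id(experiment)
        sql = "UPDATE genotypes SET active = ? WHERE experiment_id = ?"
        params: List[object] = [1 if flag else 0, eid]
        if marker_names is not None:
            mids = self.marker_ids()
            amap = self.marker_alias_map()
            from .datamodel import resolve_marker

            ids = [resolve_marker(n, mids, amap) for n in marker_names]
            sql += f" AND marker_id IN ({', '.join('?' * len(ids))})"
            params.extend(ids)
        if member_pairs is not None:
            members = self.member_ids()
            aliases = self.member_alias_map()
            from .datamodel import resolve_member

            ids = [resolve_member(p, members, aliases) for p in member_pairs]
            sql += f" AND member_id IN ({', '.join('?' * len(ids))})"
            params.extend(ids)
        with self.transaction():
            return self.conn.execute(sql, params).rowcount

    # -- notes ---------------------------------------------------------------

    def store_note(
        self, keywords: Sequence[str], comment: str = "", payload: str = ""
    ) -> int:
        """File a note (e.g. the log of a committing run) under keywords."""
        with self.transaction():
            return self.conn.execute(
                "INSERT INTO notes (keywords, comment, payload) VALUES (?, ?, ?)",
                (" ".join(keywords), comment, payload),
            ).lastrowid

    def find_notes(self, keyword: str) -> List[dict]:
        rows = self.conn.execute("SELECT * FROM notes ORDER BY id")
        out = []
        for r in rows:
            if keyword in r["keywords"].split():
                out.append(dict(r))
        return out


def _norm(v):
    """Canonicalize values for comparison/storage (bools → ints)."""
    if isinstance(v, bool):
        return int(v)
    return v


def _vals(rec: Mapping[str, object], cols: Sequence[str]) -> tuple:
    return tuple(_norm(rec.get(c)) for c in cols)
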