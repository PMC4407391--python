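import pytest

from genovault import Database, ExportSpec, SelectionSpec
from genovault.export import export
from genovault.importers import import_targeted_genotypes, load_members
from genovault.store import LoadMode

from conftest import (
    fresh_db,
    load_study_people,
    member_colmap,
    targeted_colmap,
)


def members_file(tmp_path, rows):
    p = tmp_path / "members.tsv"
    p.write_text("".join(f"{r}\n" for r in rows))
    return str(p)


ROWS = ["F1\tdad\t0\t0\t1", "F1\tmum\t0\t0\t2", "F1\tkid\tdad\tmum\t1"]


def test_commit_twice_is_idempotent(tmp_path):
    db = fresh_db()
    path = members_file(tmp_path, ROWS)
    rep1 = load_members(db, path, member_colmap(), LoadMode.COMMIT)
    assert rep1.committed and rep1.n_new == 3
    before = db.checksum()
    rep2 = load_members(db, path, member_colmap(), LoadMode.COMMIT)
    assert rep2.committed and rep2.n_new == 0 and rep2.n_changed == 0
    assert db.checksum() == before


def test_commit_extended_file_adds_just_new_rows(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    extended = ROWS + ["F1\tkid2\tdad\tmum\t2", "F2\tsolo\t0\t0\t0"]
    rep = load_members(
        db, members_file(tmp_path, extended), member_colmap(), LoadMode.COMMIT
    )
    assert rep.n_new == 2 and rep.committed
    assert len(db.member_ids()) == 5


def test_commit_does_not_modify_changed_rows(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    changed = [ROWS[0], ROWS[1], "F1\tkid\tdad\tmum\t2"]  # sex flipped
    rep = load_members(
        db, members_file(tmp_path, changed), member_colmap(), LoadMode.COMMIT
    )
    assert rep.committed and rep.n_changed == 1 and rep.warnings
    row = db.conn.execute(
        "SELECT sex FROM members WHERE pedigree='F1' AND person='kid'"
    ).fetchone()
    assert row["sex"] == 1  # untouched


def test_replace_and_update_modify_changed_rows(tmp_path):
    changed = [ROWS[0], ROWS[1], "F1\tkid\tdad\tmum\t2"]
    for mode in (LoadMode.COMMIT_REPLACE, LoadMode.COMMIT_UPDATE):
        db = fresh_db()
        load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
        rep = load_members(db, members_file(tmp_path, changed), member_colmap(), mode)
        assert rep.committed and rep.n_changed == 1, rep.errors
        row = db.conn.execute(
            "SELECT sex FROM members WHERE pedigree='F1' AND person='kid'"
        ).fetchone()
        assert row["sex"] == 2


def test_update_preserves_ids_referenced_elsewhere(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    kid_id = db.member_ids()[("F1", "kid")]
    db.load_table(
        "traitmeta", [{"name": "aff", "kind": "qualitative"}], LoadMode.COMMIT
    )
    db.load_table(
        "traits", [{"member_id": kid_id, "trait_id": 1, "value": "2"}], LoadMode.COMMIT
    )
    changed = [ROWS[0], ROWS[1], "F1\tkid\tdad\tmum\t2"]
    rep = load_members(
        db, members_file(tmp_path, changed), member_colmap(), LoadMode.COMMIT_UPDATE
    )
    assert rep.committed
    assert db.member_ids()[("F1", "kid")] == kid_id


def test_compare_reports_differences_without_writing(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    before = db.checksum()
    clean = load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMPARE)
    assert not clean.warnings  # compare after clean commit: zero differences
    changed = [ROWS[0], ROWS[1], "F1\tkid\tdad\tmum\t2"]
    rep = load_members(
        db, members_file(tmp_path, changed), member_colmap(), LoadMode.COMPARE
    )
    assert rep.n_changed == 1 and rep.warnings
    assert db.checksum() == before


def test_dry_run_never_touches_store(tmp_path):
    db = fresh_db()
    before = db.checksum()
    rep = load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.DRY_RUN)
    assert rep.n_new == 3 and not rep.committed
    assert db.checksum() == before


def test_delete_mode_removes_listed_records(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    rep = load_members(
        db, members_file(tmp_path, ["F1\tkid\tdad\tmum\t1"]), member_colmap(),
        LoadMode.DELETE,
    )
    assert rep.n_deleted == 1
    assert ("F1", "kid") not in db.member_ids()


def test_midrun_failure_rolls_back_to_snapshot(tmp_path):
    db = fresh_db()
    load_members(db, members_file(tmp_path, ROWS), member_colmap(), LoadMode.COMMIT)
    before = db.checksum()
    records = [
        {"pedigree": "F9", "person": f"p{i}", "father": None, "mother": None, "sex": 0}
        for i in range(10)
    ]
    rep = db.load_table("members", records, LoadMode.COMMIT, _fail_after=4)
    assert not rep.committed and rep.errors
    assert db.checksum() == before


def test_integrity_violation_rolls_back_whole_run():
    db = fresh_db()
    before = db.checksum()
    # second record violates the FK: no member 999
    rep = db.load_table(
        "samples",
        [
            {"sample_name": "s1", "member_id": 999, "plate": None, "well": None,
             "preferred": 0},
        ],
        LoadMode.COMMIT,
    )
    assert not rep.committed and rep.errors
    assert db.checksum() == before


# -- experiment-level operations --------------------------------------------


def _load_targeted(db, study, experiment):
    rep = import_targeted_genotypes(
        db, study.targeted_path, targeted_colmap(), experiment, "custom",
        LoadMode.COMMIT,
    )
    assert rep.ok, rep.errors
    return rep


def _setup_two_experiments(study, tmp_path):
    from genovault.importers import load_marker_info
    from conftest import map_colmap

    db = fresh_db()
    load_study_people(db, study)
    load_marker_info(db, study.map_path, map_colmap(), "default", LoadMode.COMMIT)
    _load_targeted(db, study, "expA")
    _load_targeted(db, study, "expB")
    return db


def _export_text(db, tmp_path, name, spec=None):
    paths, _res = export(
        db, spec or SelectionSpec(), None,
        ExportSpec(format="plink_ped", prefix=str(tmp_path / name)),
    )
    return open(paths[0]).read()


def test_delete_experiment_counts_and_leaves_others(study, tmp_path):
    db = _setup_two_experiments(study, tmp_path)
    n_b = db.conn.execute(
        "SELECT COUNT(*) AS n FROM genotypes WHERE experiment_id = "
        "(SELECT id FROM experiments WHERE name='expB')"
    ).fetchone()["n"]
    assert db.delete_experiment("expB") == n_b
    assert db.delete_experiment("expB") == 0  # now empty

    # oracle: remaining export equals a single-experiment store's export
    single = fresh_db()
    load_study_people(single, study)
    from genovault.importers import load_marker_info
    from conftest import map_colmap

    load_marker_info(single, study.map_path, map_colmap(), "default", LoadMode.COMMIT)
    _load_targeted(single, study, "expA")
    assert _export_text(db, tmp_path, "after_delete") == _export_text(
        single, tmp_path, "single"
    )


def test_delete_unknown_experiment_errors():
    db = fresh_db()
    with pytest.raises(KeyError):
        db.delete_experiment("nope")


def test_set_active_hides_and_restores_genotypes(study, tmp_path):
    db = _setup_two_experiments(study, tmp_path)
    original = _export_text(db, tmp_path, "orig")
    marker = study.marker_names[0]
    n = db.set_active("expA", False, marker_names=[marker])
    assert n > 0
    db.set_active("expB", False, marker_names=[marker])
    masked = _export_text(db, tmp_path, "masked")
    assert masked != original
    # the deactivated marker's column reads missing
    spec = SelectionSpec(marker_names={marker})
    _paths, res = export(
        db, spec, None, ExportSpec(format="columnar", prefix=str(tmp_path / "col"))
    )
    assert (res.geno == ord("0")).all()
    # reactivate restores the original export byte for byte
    db.set_active("expA", True, marker_names=[marker])
    db.set_active("expB", True, marker_names=[marker])
    assert _export_text(db, tmp_path, "restored") == original
    # empty selector match is a zero count, not an error
    assert db.set_active("expA", False, member_pairs=[]) == 0


def test_notes_round_trip():
    db = fresh_db()
    n1 = db.store_note(["load", "exp1"], "first load", "log text")
    n2 = db.store_note(["exp1"], "second", "more text")
    hits = db.find_notes("exp1")
    assert [h["id"] for h in hits] == [n1, n2]
    assert db.find_notes("load")[0]["payload"] == "log text"
    assert db.find_notes("nothing") == []
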