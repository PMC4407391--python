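import numpy as np
import pytest

from genovault import Database, SelectionSpec
from genovault.export import ExportSpec, export, extract
from genovault.importers import (
    ColumnMap,
    import_multi_sample_file,
    import_per_sample_files,
    import_plink_binary,
    import_targeted_genotypes,
    load_allele_maps,
    load_marker_aliases,
    load_marker_info,
    load_members,
    load_traits,
    missing_marker_info,
)
from genovault.store import LoadMode
from genovault.datamodel import TraitKind

from conftest import (
    fresh_db,
    load_study_people,
    map_colmap,
    member_colmap,
    targeted_colmap,
)


def _with_map(study):
    db = fresh_db()
    load_study_people(db, study)
    rep = load_marker_info(db, study.map_path, map_colmap(), "default", LoadMode.COMMIT)
    assert rep.ok, rep.errors
    return db


def _matrix(db, build="default"):
    res = extract(db, SelectionSpec(build=build))
    return res.geno, [m[1] for m in res.markers], [
        (m["pedigree"], m["person"]) for m in res.members
    ]


def test_targeted_two_allele_import_counts_rows(study):
    db = _with_map(study)
    rep = import_targeted_genotypes(
        db, study.targeted_path, targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    n_nonmissing_cells = len(study.member_keys) * len(study.marker_names)
    assert rep.committed and rep.n_new == n_nonmissing_cells


def test_targeted_unknown_marker_rolls_back(study, tmp_path):
    db = fresh_db()
    load_study_people(db, study)  # no markers registered
    before = db.checksum()
    rep = import_targeted_genotypes(
        db, study.targeted_path, targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    assert not rep.committed and rep.errors
    assert db.checksum() == before


def test_targeted_unknown_person_rolls_back(study, tmp_path):
    db = _with_map(study)
    bad = tmp_path / "bad.tsv"
    bad.write_text(f"F9\tnobody\t{study.marker_names[0]}\tA\tC\n")
    before = db.checksum()
    rep = import_targeted_genotypes(
        db, str(bad), targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    assert not rep.committed and "unknown person" in rep.errors[0]
    assert db.checksum() == before


def test_targeted_discordant_duplicate_warns_and_is_kept(study, tmp_path):
    db = _with_map(study)
    mk = study.marker_names[0]
    first = tmp_path / "a.tsv"
    first.write_text(f"F1\tdad\t{mk}\tA\tC\n")
    import_targeted_genotypes(
        db, str(first), targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    # identical re-import: idempotent, no warning
    rep = import_targeted_genotypes(
        db, str(first), targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    assert rep.n_new == 0 and not rep.warnings
    # discordant duplicate under the SAME experiment: warned and recorded
    second = tmp_path / "b.tsv"
    second.write_text(f"F1\tdad\t{mk}\tG\tG\n")
    rep = import_targeted_genotypes(
        db, str(second), targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    assert rep.committed and rep.warnings and rep.n_new == 1
    # the within-experiment disagreement masks the merged output
    res = extract(db, SelectionSpec(marker_names={mk}))
    assert len(res.conflicts) == 1
    assert str(res.call(0, 0)) == "0/0"


def test_wide_and_genotype_layouts_match_two_allele(study, tmp_path):
    db = _with_map(study)
    import_targeted_genotypes(
        db, study.targeted_path, targeted_colmap(), "expA", "custom", LoadMode.COMMIT
    )
    truth, names, keys = _matrix(db)

    # one-genotype-column layout
    gpath = tmp_path / "geno.tsv"
    with open(gpath, "w") as fh:
        for i, (ped, person) in enumerate(study.member_keys):
            for j, name in enumerate(names):
                a, b = study.geno[j, i]
                fh.write(f"{ped}\t{person}\t{name}\t{chr(a)}/{chr(b)}\n")
    db2 = _with_map(study)
    rep = import_targeted_genotypes(
        db2, str(gpath),
        ColumnMap({"pedigree": 1, "person": 2, "marker": 3, "genotype": 4}, "tab"),
        "expA", "custom", LoadMode.COMMIT, fmt="genotype",
    )
    assert rep.ok, rep.errors
    assert (_matrix(db2)[0] == truth).all()

    # wide layout (header row names the markers)
    wpath = tmp_path / "wide.tsv"
    with open(wpath, "w") as fh:
        fh.write("\t".join(["ped", "person", *names]) + "\n")
        for i, (ped, person) in enumerate(study.member_keys):
            cells = [ped, person]
            for j in range(len(names)):
                a, b = study.geno[j, i]
                cells.append(f"{chr(a)}/{chr(b)}")
            fh.write("\t".join(cells) + "\n")
    db3 = _with_map(study)
    rep = import_targeted_genotypes(
        db3, str(wpath), ColumnMap({"pedigree": 1, "person": 2}, "tab"),
        "expA", "custom", LoadMode.COMMIT, fmt="wide",
    )
    assert rep.ok, rep.errors
    assert (_matrix(db3)[0] == truth).all()


# -- block importers ----------------------------------------------------------


def test_per_sample_import_block_count_and_idempotence(study):
    db = fresh_db()
    load_study_people(db, study)
    rep = import_per_sample_files(
        db, study.map_path, study.per_sample_paths, "gw1", mode=LoadMode.COMMIT
    )
    n_chroms = len(set(study.marker_chroms))
    assert rep.committed
    assert rep.n_new == len(study.sample_names) * n_chroms  # few markers: 1 block/chrom
    # re-run without changes: no new blocks
    rep2 = import_per_sample_files(
        db, study.map_path, study.per_sample_paths, "gw1", mode=LoadMode.COMMIT
    )
    assert rep2.committed and rep2.n_new == 0


def test_per_sample_marker_count_mismatch_rolls_back(study, tmp_path):
    db = fresh_db()
    load_study_people(db, study)
    before = db.checksum()
    truncated = tmp_path / "short.tsv"
    lines = open(next(iter(study.per_sample_paths.values()))).readlines()
    truncated.write_text("".join(lines[:-2]))
    files = dict(study.per_sample_paths)
    files[study.sample_names[0]] = str(truncated)
    rep = import_per_sample_files(
        db, study.map_path, files, "gw1", mode=LoadMode.COMMIT
    )
    assert not rep.committed and "mapping" in rep.errors[0]
    assert db.checksum() == before


def test_unregistered_sample_rolls_back(study):
    db = fresh_db()
    load_members(db, study.members_path, member_colmap(), LoadMode.COMMIT)
    before = db.checksum()
    rep = import_per_sample_files(
        db, study.map_path, study.per_sample_paths, "gw1", mode=LoadMode.COMMIT
    )
    assert not rep.committed and "not registered" in rep.errors[0]
    assert db.checksum() == before


def test_cross_dialect_imports_store_identical_data(study):
    db_i = fresh_db()
    load_study_people(db_i, study)
    import_per_sample_files(
        db_i, study.map_path, study.per_sample_paths, "gw1", mode=LoadMode.COMMIT
    )
    db_a = fresh_db()
    load_study_people(db_a, study)
    rep = import_multi_sample_file(
        db_a, study.multi_sample_path, study.map_path, "gw1", mode=LoadMode.COMMIT
    )
    assert rep.ok, rep.errors
    gi, ni, ki = _matrix(db_i)
    ga, na, ka = _matrix(db_a)
    assert ni == na and ki == ka
    assert (gi == ga).all()
    # block payloads themselves are identical
    rows_i = db_i.conn.execute(
        "SELECT chromosome, block_index, payload FROM genotypeblocks ORDER BY 1,2,id"
    ).fetchall()
    rows_a = db_a.conn.execute(
        "SELECT chromosome, block_index, payload FROM genotypeblocks ORDER BY 1,2,id"
    ).fetchall()
    assert [tuple(r) for r in rows_i] == [tuple(r) for r in rows_a]


def test_multi_sample_zero_samples_is_report_only(study, tmp_path):
    db = fresh_db()
    load_study_people(db, study)
    p = tmp_path / "empty.tsv"
    with open(p, "w") as fh:
        fh.write("marker\n")
        for name in study.marker_names:
            fh.write(f"{name}\n")
    rep = import_multi_sample_file(
        db, str(p), study.map_path, "gw1", mode=LoadMode.COMMIT
    )
    assert rep.ok and rep.n_new == 0
    assert db.conn.execute("SELECT COUNT(*) AS n FROM genotypeblocks").fetchone()["n"] == 0


# -- PLINK binary --------------------------------------------------------------


def test_plink_binary_round_trip(blocked_db, study, tmp_path):
    rep = load_traits(
        blocked_db, study.traits_path,
        ColumnMap({"pedigree": 1, "person": 2, "value": 3}, "tab"),
        "affection", TraitKind.QUALITATIVE, LoadMode.COMMIT,
    )
    assert rep.ok, rep.errors
    prefix = str(tmp_path / "out")
    export(blocked_db, SelectionSpec(), None, ExportSpec("plink_bed", prefix))
    truth, names, keys = _matrix(blocked_db)

    db2 = fresh_db()
    rep = import_plink_binary(db2, prefix, "kexp", mode=LoadMode.COMMIT)
    assert rep.ok, rep.errors
    g2, n2, k2 = _matrix(db2)
    assert n2 == names and k2 == keys
    assert (g2 == truth).all()
    # fam parental links materialize as member records
    dad = db2.conn.execute(
        "SELECT father, mother FROM members WHERE person = 'kid1'"
    ).fetchone()
    assert (dad["father"], dad["mother"]) == ("dad", "mum")
    # fam phenotype lands in one qualitative trait
    n_traits = db2.conn.execute("SELECT COUNT(*) AS n FROM traits").fetchone()["n"]
    assert n_traits == len(study.member_keys)


def test_plink_bad_magic_and_mode_rejected(tmp_path):
    from genovault.plink import PlinkFormatError, read_bed, BimRecord, FamRecord

    bim = [BimRecord(1, "m1", 0.0, 100, "A", "C")]
    fam = [FamRecord("F", "p", "0", "0", 1, "0")]
    bad = tmp_path / "bad.bed"
    bad.write_bytes(b"\x00\x00\x01\x00")
    with pytest.raises(PlinkFormatError, match="magic"):
        read_bed(str(bad), bim, fam)
    indiv = tmp_path / "indiv.bed"
    indiv.write_bytes(b"\x6c\x1b\x00\x00")
    with pytest.raises(PlinkFormatError, match="individual-major"):
        read_bed(str(indiv), bim, fam)


def test_plink_missing_code_decodes_to_missing(tmp_path):
    from genovault import plink

    bim = [plink.BimRecord(1, "m1", 0.0, 100, "A", "C")]
    fam = [
        plink.FamRecord("F", f"p{i}", "0", "0", 1, "2") for i in range(3)
    ]
    geno = np.array(
        [[[ord("A"), ord("A")], [ord("0"), ord("0")], [ord("A"), ord("C")]]],
        dtype=np.uint8,
    )
    prefix = str(tmp_path / "t")
    plink.write_bed(prefix, fam, bim, geno)
    back = plink.read_bed(
        prefix + ".bed", plink.read_bim(prefix + ".bim"),
        plink.read_fam(prefix + ".fam"),
    )
    assert (back == geno).all()


# -- auxiliary loaders ---------------------------------------------------------


def test_marker_alias_and_allele_map_loaders(study, tmp_path):
    db = _with_map(study)
    target = study.marker_names[0]
    ap = tmp_path / "alias.tsv"
    ap.write_text(f"rsALIAS\t{target}\n")
    rep = load_marker_aliases(
        db, str(ap), ColumnMap({"alias": 1, "marker": 2}, "tab"), LoadMode.COMMIT
    )
    assert rep.ok and db.marker_alias_map() == {"rsALIAS": target}

    db.experiment_id("expA", create=True)
    mp = tmp_path / "amap.tsv"
    mp.write_text(f"expA\trsALIAS\t1\tA\nexpA\trsALIAS\t2\tC\n")
    rep = load_allele_maps(
        db, str(mp),
        ColumnMap({"experiment": 1, "marker": 2, "from_allele": 3, "to_allele": 4},
                  "tab"),
        LoadMode.COMMIT,
    )
    assert rep.ok and rep.n_new == 2

    collapsing = tmp_path / "bad.tsv"
    collapsing.write_text(f"expA\t{target}\t1\tA\nexpA\t{target}\t2\tA\n")
    rep = load_allele_maps(
        db, str(collapsing),
        ColumnMap({"experiment": 1, "marker": 2, "from_allele": 3, "to_allele": 4},
                  "tab"),
        LoadMode.COMMIT,
    )
    assert not rep.ok and "collapses" in rep.errors[0]


def test_missing_marker_info_lists_gaps(study):
    db = _with_map(study)
    from genovault.importers import load_markers

    load_markers(db, ["rsNEW"], LoadMode.COMMIT)
    assert missing_marker_info(db, "default") == ["rsNEW"]
    assert missing_marker_info(db, "otherbuild") == sorted(
        study.marker_names + ["rsNEW"]
    )


def test_quantitative_trait_values_validated(study, tmp_path):
    db = fresh_db()
    load_study_people(db, study)
    p = tmp_path / "bmi.tsv"
    p.write_text("F1\tdad\t27.5\nF1\tmum\tnot-a-number\n")
    cm = ColumnMap({"pedigree": 1, "person": 2, "value": 3}, "tab")
    rep = load_traits(db, str(p), cm, "bmi", TraitKind.QUANTITATIVE, LoadMode.COMMIT)
    assert not rep.ok and "non-numeric" in rep.errors[0]
    p.write_text("F1\tdad\t27.5\n")
    rep = load_traits(db, str(p), cm, "bmi", TraitKind.QUANTITATIVE, LoadMode.COMMIT)
    assert rep.ok and rep.n_new == 1
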