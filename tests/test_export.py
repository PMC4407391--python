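import numpy as np
import pytest

from genovault import (
    Database,
    ExportSpec,
    MergePolicy,
    PositionRange,
    SelectionSpec,
)
from genovault import plink
from genovault.export import ExportError, export, extract
from genovault.fixtures import load_marker_lookup_example
from genovault.importers import import_ped_rows
from genovault.store import LoadMode

from conftest import fresh_db


def test_marker_lookup_worked_example():
    """Range selection, alias lookup, moved-chromosome retrieval and the
    three-way merge of a doubly-genotyped member."""
    db = Database()
    info = load_marker_lookup_example(db)
    build = info["build"]

    # chr1 10–20 Mb picks exactly the two mid-range markers
    res = extract(
        db, SelectionSpec(build=build, ranges=[PositionRange(1, *info["range_chr1"])])
    )
    assert [m[1] for m in res.markers] == info["expected_range_markers"]

    # the moved marker is reachable by whole-chr3 selection although its
    # blocks were stored under chr2, and by either of its names
    for spec in (
        SelectionSpec(build=build, chromosomes={3}),
        SelectionSpec(build=build, marker_names={"rs34567"}),
        SelectionSpec(build=build, marker_names={"rs456784"}),
    ):
        res = extract(db, spec)
        assert [m[1] for m in res.markers] == ["rs456784"]
        assert str(res.call(0, 0)) == "G/T"

    # merged output for the three doubly-measured markers:
    # A/C (one side missing), 0/0 (1/2 vs G/T conflict), A/C (agreement)
    res = extract(
        db,
        SelectionSpec(
            build=build, marker_names={"rs123401", "rs123451", "rs123452"}
        ),
    )
    assert [str(res.call(j, 0)) for j in range(3)] == ["A/C", "0/0", "A/C"]
    assert len(res.conflicts) == 1
    entry = res.conflicts.entries[0]
    assert entry.marker == "rs123451"
    assert sorted(g for _e, g in entry.calls) == ["1/2", "G/T"]


def test_trust_resolves_the_worked_example_conflict():
    db = Database()
    info = load_marker_lookup_example(db)
    policy = MergePolicy(trust={"Exp F": 2, "Exp D": 1})
    res = extract(
        db, SelectionSpec(build=info["build"], marker_names={"rs123451"}), policy
    )
    assert str(res.call(0, 0)) == "G/T" and len(res.conflicts) == 0


def test_ped_line_of_worked_example(tmp_path):
    db = Database()
    info = load_marker_lookup_example(db)
    spec = SelectionSpec(
        build=info["build"], marker_names={"rs123401", "rs123451", "rs123452"}
    )
    paths, _ = export(
        db, spec, None, ExportSpec("plink_ped", str(tmp_path / "fig"))
    )
    line = open(paths[0]).read().strip().split()
    assert line[:6] == ["F1", "P1", "0", "0", "1", "0"]
    assert line[6:] == ["A", "C", "0", "0", "A", "C"]


def test_cross_format_exports_decode_identically(blocked_db, tmp_path):
    spec = SelectionSpec()
    p_ped = str(tmp_path / "x1")
    p_bed = str(tmp_path / "x2")
    p_col = str(tmp_path / "x3")
    paths_ped, res = export(blocked_db, spec, None, ExportSpec("plink_ped", p_ped))
    paths_bed, _ = export(blocked_db, spec, None, ExportSpec("plink_bed", p_bed))
    paths_col, _ = export(blocked_db, spec, None, ExportSpec("columnar", p_col))

    n_m = len(res.markers)
    _fams, g_ped = plink.read_ped(paths_ped[0], n_m)
    bim = plink.read_bim(paths_bed[1])
    fam = plink.read_fam(paths_bed[2])
    g_bed = plink.read_bed(paths_bed[0], bim, fam)
    assert (g_ped == res.geno).all()
    assert (g_bed == res.geno).all()

    lines = open(paths_col[0]).read().splitlines()
    header = lines[0].split("\t")
    assert header[2:] == [m[1] for m in res.markers]
    for i, ln in enumerate(lines[1:]):
        cells = ln.split("\t")[2:]
        expect = [
            f"{chr(res.geno[j, i, 0])}/{chr(res.geno[j, i, 1])}"
            for j in range(n_m)
        ]
        assert cells == expect


def test_bed_file_magic_and_mode_bytes(blocked_db, tmp_path):
    paths, _ = export(
        blocked_db, SelectionSpec(), None, ExportSpec("plink_bed", str(tmp_path / "m"))
    )
    with open(paths[0], "rb") as fh:
        assert fh.read(3) == b"\x6c\x1b\x01"


def test_blocked_to_ped_to_rows_to_ped_identity(blocked_db, tmp_path):
    """Exporting from blocks, re-importing the ped into an empty row store
    and exporting again reproduces the files byte for byte."""
    p1 = str(tmp_path / "round1")
    paths1, _ = export(blocked_db, SelectionSpec(), None, ExportSpec("plink_ped", p1))
    rows_db = fresh_db()
    rep = import_ped_rows(
        rows_db, paths1[0], paths1[1], "rows", mode=LoadMode.COMMIT
    )
    assert rep.ok, rep.errors
    # missing genotypes are not stored in the row representation
    n_rows = rows_db.conn.execute("SELECT COUNT(*) AS n FROM genotypes").fetchone()["n"]
    assert n_rows == rep.n_new < rows_db.conn.execute(
        "SELECT (SELECT COUNT(*) FROM members) * (SELECT COUNT(*) FROM markers) AS n"
    ).fetchone()["n"]
    p2 = str(tmp_path / "round2")
    paths2, _ = export(rows_db, SelectionSpec(), None, ExportSpec("plink_ped", p2))
    assert open(paths1[0]).read() == open(paths2[0]).read()
    assert open(paths1[1]).read() == open(paths2[1]).read()


def test_frequency_report_matches_brute_force(blocked_db):
    res = extract(blocked_db, SelectionSpec())
    for j, (_kid, name, _c, _bp) in enumerate(res.markers):
        col = res.geno[j]
        brute_alleles = {}
        brute_genos = {}
        brute_missing = 0
        for i in range(col.shape[0]):
            a, b = chr(col[i, 0]), chr(col[i, 1])
            if a == "0":
                brute_missing += 1
                continue
            brute_alleles[a] = brute_alleles.get(a, 0) + 1
            brute_alleles[b] = brute_alleles.get(b, 0) + 1
            g = f"{a}/{b}"
            brute_genos[g] = brute_genos.get(g, 0) + 1
        assert res.stats.allele_counts[name] == brute_alleles
        assert res.stats.genotype_counts[name] == brute_genos
        assert res.stats.missing[name] == brute_missing
        freqs = res.stats.allele_freqs(name)
        if freqs:
            assert sum(freqs.values()) == pytest.approx(1.0)


def test_single_het_member_frequencies():
    db = Database()
    info = load_marker_lookup_example(db)
    res = extract(db, SelectionSpec(build=info["build"], marker_names={"rs123452"}))
    assert res.stats.allele_freqs("rs123452") == {"A": 0.5, "C": 0.5}


def test_streaming_columnar_identical_to_buffered(blocked_db, tmp_path):
    pa = str(tmp_path / "buf")
    pb = str(tmp_path / "stream")
    paths_a, _ = export(
        blocked_db, SelectionSpec(), None,
        ExportSpec("columnar", pa, collect_stats=True),
    )
    spec_stream = ExportSpec("columnar", pb, per_person_streaming=True)
    assert spec_stream.collect_stats is False  # streaming implies no stats
    paths_b, res = export(blocked_db, SelectionSpec(), None, spec_stream)
    assert open(paths_a[0]).read() == open(paths_b[0]).read()
    assert res.stats is None


def test_multiallelic_marker_rejected_by_bed_export(tmp_path):
    db = fresh_db()
    db.load_table("members", [
        {"pedigree": "F", "person": f"p{i}", "father": None, "mother": None, "sex": 0}
        for i in range(3)
    ], LoadMode.COMMIT)
    db.load_table("markers", [{"name": "tri"}], LoadMode.COMMIT)
    db.load_table("marker_info", [
        {"marker_id": 1, "build": "default", "chromosome": 1, "bp": 100,
         "avg_cm": None, "female_cm": None, "male_cm": None},
    ], LoadMode.COMMIT)
    eid = db.experiment_id("e", create=True)
    with db.transaction():
        db.conn.executemany(
            "INSERT INTO genotypes (member_id, marker_id, experiment_id, "
            "allele1, allele2) VALUES (?, 1, ?, ?, ?)",
            [(1, eid, "A", "A"), (2, eid, "C", "C"), (3, eid, "G", "G")],
        )
    with pytest.raises(plink.PlinkFormatError, match="tri"):
        export(db, SelectionSpec(), None, ExportSpec("plink_bed", str(tmp_path / "t")))


def test_empty_marker_selection_errors_unless_columnar(blocked_db, tmp_path):
    spec = SelectionSpec(chromosomes={21})  # nothing stored there
    with pytest.raises(ExportError):
        export(blocked_db, spec, None, ExportSpec("plink_ped", str(tmp_path / "e")))
    paths, res = export(blocked_db, spec, None, ExportSpec("columnar", str(tmp_path / "c")))
    assert res.markers == []


def test_exclusion_range_masks_and_drop_untyped_removes(blocked_db, study, tmp_path):
    from genovault.select import ExclusionRange

    # mask one marker for one member
    kid = ("F1", "kid1")
    target_j = 0
    chrom = study.marker_chroms[target_j]
    bp = 1_000_000  # first marker's position
    spec = SelectionSpec(exclusion_ranges=[ExclusionRange(chrom, bp, bp, frozenset({kid}))])
    res = extract(blocked_db, spec)
    i = [(m["pedigree"], m["person"]) for m in res.members].index(kid)
    assert str(res.call(target_j, i)) == "0/0"

    # masking all carriers + drop_untyped_markers removes the marker entirely
    spec_all = SelectionSpec(
        exclusion_ranges=[ExclusionRange(chrom, bp, bp)], drop_untyped_markers=True
    )
    res_all = extract(blocked_db, spec_all)
    assert study.marker_names[target_j] not in [m[1] for m in res_all.markers]


def test_mega2_trio_written(blocked_db, tmp_path):
    paths, res = export(
        blocked_db, SelectionSpec(), None, ExportSpec("mega2", str(tmp_path / "mg"))
    )
    assert len(paths) == 3
    names = open(paths[1]).read().splitlines()
    assert names[0].startswith("#") and names[1] == "affection A"
    assert [ln.split()[0] for ln in names[2:]] == [m[1] for m in res.markers]
    ped_lines = open(paths[0]).read().splitlines()[1:]
    assert len(ped_lines) == len(res.members)
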