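import pytest

from genovault import Database
from genovault.importers import (
    ColumnMap,
    import_per_sample_files,
    load_members,
    load_samples,
)
from genovault.fixtures import FixtureSpec, StudyFiles, make_study
from genovault.store import LoadMode

MEMBER_COLMAP = dict(
    columns={"pedigree": 1, "person": 2, "father": 3, "mother": 4, "sex": 5},
    delimiter="tab",
)
SAMPLE_COLMAP = dict(
    columns={
        "sample": 1, "pedigree": 2, "person": 3,
        "plate": 4, "well": 5, "preferred": 6,
    },
    delimiter="tab",
)
MAP_COLMAP = dict(columns={"marker": 1, "chromosome": 2, "bp": 3}, delimiter="tab")
TARGETED_COLMAP = dict(
    columns={"pedigree": 1, "person": 2, "marker": 3, "allele1": 4, "allele2": 5},
    delimiter="tab",
)


def member_colmap() -> ColumnMap:
    return ColumnMap(**MEMBER_COLMAP)


def sample_colmap() -> ColumnMap:
    return ColumnMap(**SAMPLE_COLMAP)


def map_colmap() -> ColumnMap:
    return ColumnMap(**MAP_COLMAP)


def targeted_colmap() -> ColumnMap:
    return ColumnMap(**TARGETED_COLMAP)


@pytest.fixture
def study(tmp_path) -> StudyFiles:
    """A small synthetic study: 2 pedigrees × 4 members, 10 markers."""
    return make_study(FixtureSpec(seed=7, missing_rate=0.1), str(tmp_path / "study"))


def fresh_db() -> Database:
    db = Database()
    db.create_schema()
    return db


def load_study_people(db: Database, study: StudyFiles) -> None:
    rep = load_members(db, study.members_path, member_colmap(), LoadMode.COMMIT)
    assert rep.ok, rep.errors
    rep = load_samples(db, study.samples_path, sample_colmap(), LoadMode.COMMIT)
    assert rep.ok, rep.errors


@pytest.fixture
def blocked_db(study) -> Database:
    """Store with the study imported through the per-sample (block) route."""
    db = fresh_db()
    load_study_people(db, study)
    rep = import_per_sample_files(
        db, study.map_path, study.per_sample_paths, "gw1", mode=LoadMode.COMMIT
    )
    assert rep.ok, rep.errors
    return db
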