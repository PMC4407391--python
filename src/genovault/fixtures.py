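"""Deterministic synthetic study data.

Everything the importers read can be generated here: pedigree, sample,
trait and marker-map tables, plus the same genotype matrix written in every
import dialect (targeted rows, one-file-per-sample, multi-sample columns),
so cross-dialect equivalence is testable end to end without any external
data.  A single integer seed drives all randomness; equal seeds give
byte-identical files.

Two special-purpose builders create exact realizations of diagnostic
scenarios: an agreement-matrix fixture whose recomputed joint counts equal
a requested count table cell for cell, and a marker map realizing a
requested per-chromosome block occupancy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import blockcodec
from .datamodel import GenotypeCall, parse_call
from .store import Database


@dataclass
class FixtureSpec:
    """Shape of a synthetic study.

    ``marker_counts`` maps chromosome → marker count; genotypes are drawn
    from per-marker biallelic frequencies sampled uniformly on (0.1, 0.9),
    with cells missing independently at ``missing_rate``.  Pedigrees are
    two founders plus ``children_per_pedigree`` children (parent links set,
    no Mendelian transmission — the generator tests plumbing, not genetics).
    """

    n_pedigrees: int = 2
    children_per_pedigree: int = 2
    marker_counts: Dict[int, int] = field(default_factory=lambda: {1: 6, 2: 4})
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_pedigrees < 1 or self.children_per_pedigree < 0:
            raise ValueError("impossible pedigree spec")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class StudyFiles:
    """Paths of the generated files plus the underlying truth."""

    spec: FixtureSpec
    members_path: str
    samples_path: str
    traits_path: str
    map_path: str
    targeted_path: str
    per_sample_paths: Dict[str, str]
    multi_sample_path: str
    member_keys: List[Tuple[str, str]]  # ordered as file rows
    sample_names: List[str]
    marker_names: List[str]  # map order
    marker_chroms: List[int]
    geno: np.ndarray  # (n_markers, n_members, 2) allele codes, "0" missing


def make_study(spec: FixtureSpec, outdir: str) -> StudyFiles:
    """Write a mutually consistent set of input files under ``outdir``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)

    members: List[Tuple[str, str, str, str, int]] = []  # ped, person, fa, mo, sex
    for p in range(1, spec.n_pedigrees + 1):
        ped = f"F{p}"
        members.append((ped, "dad", "0", "0", 1))
        members.append((ped, "mum", "0", "0", 2))
        for c in range(1, spec.children_per_pedigree + 1):
            sex = 1 + int(rng.integers(0, 2))
            members.append((ped, f"kid{c}", "dad", "mum", sex))
    member_keys = [(m[0], m[1]) for m in members]
    sample_names = [f"S_{p}_{i}" for p, i in member_keys]
    n = len(members)

    # marker map ordered by (chromosome, bp)
    marker_names, marker_chroms, marker_bps = [], [], []
    for chrom in sorted(spec.marker_counts):
        for i in range(spec.marker_counts[chrom]):
            marker_names.append(f"c{chrom:02d}m{i + 1:06d}")
            marker_chroms.append(chrom)
            marker_bps.append(1_000_000 + i * 50_000)
    m = len(marker_names)

    # biallelic genotypes per marker
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    geno = np.zeros((m, n, 2), dtype=np.uint8)
    for j in range(m):
        pair = rng.choice(4, size=2, replace=False)
        a, b = bases[pair[0]], bases[pair[1]]
        p_a = rng.uniform(0.1, 0.9)
        draws = rng.random((n, 2)) < p_a
        geno[j] = np.where(draws, a, b)
        geno[j] = np.sort(geno[j], axis=1)
    if spec.missing_rate > 0:
        miss = rng.random((m, n)) < spec.missing_rate
        geno[miss] = ord("0")

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    members_path = path("members.tsv")
    with open(members_path, "w") as fh:
        for ped, person, fa, mo, sex in members:
            fh.write(f"{ped}\t{person}\t{fa}\t{mo}\t{sex}\n")

    samples_path = path("samples.tsv")
    with open(samples_path, "w") as fh:
        for (ped, person), s in zip(member_keys, sample_names):
            fh.write(f"{s}\t{ped}\t{person}\tplateA\tw1\t0\n")

    traits_path = path("traits.tsv")
    affection = 1 + (rng.random(n) < 0.5).astype(int)
    with open(traits_path, "w") as fh:
        for (ped, person), v in zip(member_keys, affection):
            fh.write(f"{ped}\t{person}\t{v}\n")

    map_path = path("map.tsv")
    with open(map_path, "w") as fh:
        for name, chrom, bp in zip(marker_names, marker_chroms, marker_bps):
            fh.write(f"{name}\t{chrom}\t{bp}\n")

    targeted_path = path("targeted.tsv")
    with open(targeted_path, "w") as fh:
        for i, (ped, person) in enumerate(member_keys):
            for j, name in enumerate(marker_names):
                a1, a2 = chr(geno[j, i, 0]), chr(geno[j, i, 1])
                fh.write(f"{ped}\t{person}\t{name}\t{a1}\t{a2}\n")

    per_dir = path("persample")
    os.makedirs(per_dir, exist_ok=True)
    per_sample_paths = {}
    for i, s in enumerate(sample_names):
        sp = os.path.join(per_dir, f"{s}.tsv")
        per_sample_paths[s] = sp
        with open(sp, "w") as fh:
            for j, name in enumerate(marker_names):
                fh.write(f"{name}\t{chr(geno[j, i, 0])}\t{chr(geno[j, i, 1])}\n")

    multi_sample_path = path("multisample.tsv")
    with open(multi_sample_path, "w") as fh:
        fh.write("\t".join(["marker", *sample_names]) + "\n")
        for j, name in enumerate(marker_names):
            cells = [name]
            for i in range(n):
                cells.append(f"{chr(geno[j, i, 0])}/{chr(geno[j, i, 1])}")
            fh.write("\t".join(cells) + "\n")

    return StudyFiles(
        spec=spec,
        members_path=members_path,
        samples_path=samples_path,
        traits_path=traits_path,
        map_path=map_path,
        targeted_path=targeted_path,
        per_sample_paths=per_sample_paths,
        multi_sample_path=multi_sample_path,
        member_keys=member_keys,
        sample_names=sample_names,
        marker_names=marker_names,
        marker_chroms=marker_chroms,
        geno=geno,
    )


# ---------------------------------------------------------------------------
# agreement-matrix fixtures


def make_agreement_fixture(
    matrix: Mapping[Tuple[str, str], int],
) -> Tuple[Dict[str, GenotypeCall], Dict[str, GenotypeCall], List[str]]:
    """Realize a joint genotype count table exactly.

    ``matrix`` maps (genotype in experiment A, genotype in experiment B) →
    member count, genotypes as text ("1/2", "A/C", "0/0").  Returns two
    member → call maps (explicit 0/0 entries represent assayed-but-missing
    measurements) and the ordered member list.  Recomputing the agreement
    matrix over the outputs reproduces ``matrix`` cell for cell.
    """
    calls_a: Dict[str, GenotypeCall] = {}
    calls_b: Dict[str, GenotypeCall] = {}
    members: List[str] = []
    k = 0
    for (ga, gb) in sorted(matrix):
        n = matrix[(ga, gb)]
        if n < 0:
            raise ValueError("counts must be non-negative")
        ca, cb = parse_call(ga), parse_call(gb)
        for _ in range(n):
            k += 1
            member = f"M{k:05d}"
            members.append(member)
            calls_a[member] = ca
            calls_b[member] = cb
    return calls_a, calls_b, members


#: Joint counts printed for the duplicate-genotyping audit of two
#: same-labeled experiments: mostly concordant, 130 members typed only in
#: the first, 2 only in the second, 3 discordant.
TABLE_EXP1_EXP2: Dict[Tuple[str, str], int] = {
    ("0/0", "0/0"): 2, ("0/0", "1/1"): 1, ("0/0", "1/2"): 1, ("0/0", "2/2"): 0,
    ("1/1", "0/0"): 19, ("1/1", "1/1"): 194, ("1/1", "1/2"): 1, ("1/1", "2/2"): 0,
    ("1/2", "0/0"): 58, ("1/2", "1/1"): 2, ("1/2", "1/2"): 549, ("1/2", "2/2"): 0,
    ("2/2", "0/0"): 53, ("2/2", "1/1"): 0, ("2/2", "1/2"): 0, ("2/2", "2/2"): 534,
}

#: Joint counts for two experiments that labeled the same alleles
#: differently (1/2 vs A/C): every doubly-typed member appears discordant
#: until the allele map {1→A, 2→C} is applied to the first experiment.
TABLE_EXP3_EXP4: Dict[Tuple[str, str], int] = {
    ("0/0", "0/0"): 0, ("0/0", "A/A"): 0, ("0/0", "A/C"): 0, ("0/0", "C/C"): 0,
    ("1/1", "0/0"): 0, ("1/1", "A/A"): 1900, ("1/1", "A/C"): 0, ("1/1", "C/C"): 0,
    ("1/2", "0/0"): 0, ("1/2", "A/A"): 0, ("1/2", "A/C"): 504, ("1/2", "C/C"): 0,
    ("2/2", "0/0"): 0, ("2/2", "A/A"): 0, ("2/2", "A/C"): 0, ("2/2", "C/C"): 359,
}


def load_agreement_study(
    db: Database,
    table: Mapping[Tuple[str, str], int],
    experiment_a: str,
    experiment_b: str,
    marker: str = "rs1",
    allele_map_a: Optional[Mapping[str, str]] = None,
) -> List[str]:
    """Load a joint count table into a store as two targeted experiments.

    Each member gets one genotype row per experiment at ``marker``; explicit
    0/0 rows represent assayed-but-missing measurements, so the agreement
    matrix recomputed at extraction reproduces ``table`` exactly.
    ``allele_map_a`` optionally installs an allele map for the first
    experiment at this marker.  Returns the member names.
    """
    from .store import LoadMode

    db.create_schema()
    calls_a, calls_b, members = make_agreement_fixture(table)
    db.load_table(
        "members",
        [
            {"pedigree": "AG", "person": p, "father": None, "mother": None, "sex": 0}
            for p in members
        ],
        LoadMode.COMMIT,
    )
    db.load_table("markers", [{"name": marker}], LoadMode.COMMIT)
    mid = db.marker_ids()[marker]
    db.load_table(
        "marker_info",
        [{"marker_id": mid, "build": "default", "chromosome": 1, "bp": 1000,
          "avg_cm": None, "female_cm": None, "male_cm": None}],
        LoadMode.COMMIT,
    )
    member_ids = db.member_ids()
    ea = db.experiment_id(experiment_a, create=True)
    eb = db.experiment_id(experiment_b, create=True)
    tech = db.technology_id("custom", create=True)
    rows = []
    for p in members:
        for eid, call in ((ea, calls_a[p]), (eb, calls_b[p])):
            rows.append(
                (member_ids[("AG", p)], mid, eid, tech, call.allele1, call.allele2)
            )
    with db.transaction():
        db.conn.executemany(
            "INSERT INTO genotypes "
            "(member_id, marker_id, experiment_id, technology_id, allele1, allele2) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            rows,
        )
        if allele_map_a:
            db.conn.executemany(
                "INSERT INTO allele_map (experiment_id, marker_id, from_allele, "
                "to_allele) VALUES (?, ?, ?, ?)",
                [(ea, mid, f, t) for f, t in sorted(allele_map_a.items())],
            )
    return members


# ---------------------------------------------------------------------------
# block-layout fixtures


def make_layout_fixture(
    per_chromosome_block_counts: Mapping[int, int],
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
    total_markers: Optional[int] = None,
) -> List[Tuple[str, int, int]]:
    """Build a marker map realizing a requested block occupancy.

    Each chromosome with k blocks must hold between (k−1)·B+1 and k·B
    markers; ``total_markers`` (default: the minimum) is distributed
    deterministically across chromosomes within those intervals, smallest
    chromosome number first.  Returns (marker, chromosome, bp) rows in map
    order; an infeasible total is an error.
    """
    for c, k in per_chromosome_block_counts.items():
        if k < 1:
            raise ValueError(f"chromosome {c}: block count must be positive")
    chroms = sorted(per_chromosome_block_counts)
    lo = {c: (per_chromosome_block_counts[c] - 1) * block_size + 1 for c in chroms}
    hi = {c: per_chromosome_block_counts[c] * block_size for c in chroms}
    min_total, max_total = sum(lo.values()), sum(hi.values())
    if total_markers is None:
        total_markers = min_total
    if not min_total <= total_markers <= max_total:
        raise ValueError(
            f"{total_markers} markers infeasible for this layout "
            f"(feasible range {min_total}..{max_total} at B={block_size})"
        )
    counts = dict(lo)
    spare = total_markers - min_total
    for c in chroms:
        room = hi[c] - counts[c]
        take = min(room, spare)
        counts[c] += take
        spare -= take
        if spare == 0:
            break

    rows: List[Tuple[str, int, int]] = []
    for c in chroms:
        for i in range(counts[c]):
            rows.append((f"c{c:02d}m{i + 1:06d}", c, 1_000 + i * 1_000))
    layout = blockcodec.allocate_layout(
        {c: counts[c] for c in chroms}, block_size
    )
    assert layout.block_counts == dict(per_chromosome_block_counts)
    return rows


#: Per-chromosome genotype-block occupancy of a 25,143-marker exome-chip
#: subset at 500 genotypes per block: 63 blocks per sample.
EXOME_SUBSET_BLOCKS: Dict[int, int] = {
    1: 5,
    2: 4, 6: 4, 11: 4,
    3: 3, 4: 3, 5: 3, 7: 3, 9: 3, 12: 3, 16: 3, 17: 3, 19: 3,
    8: 2, 10: 2, 14: 2, 15: 2, 20: 2, 22: 2, 23: 2,
    13: 1, 18: 1, 21: 1, 24: 1, 26: 1,
}

EXOME_SUBSET_MARKERS = 25_143


def make_exome_subset_study(
    outdir: str,
    n_samples: int,
    seed: int = 0,
    block_counts: Mapping[int, int] = EXOME_SUBSET_BLOCKS,
    total_markers: int = EXOME_SUBSET_MARKERS,
    block_size: int = blockcodec.DEFAULT_BLOCK_SIZE,
    missing_rate: float = 0.02,
) -> Tuple[str, str, str, Dict[str, str]]:
    """Emulate a chip run: one genotype file per sample over a marker map
    realizing ``block_counts`` at ``block_size``.

    Returns (map_path, members_path, samples_path, sample_name → file path).
    Members are unrelated singletons; genotypes are biallelic draws with a
    small missing fraction.
    """
    rows = make_layout_fixture(block_counts, block_size, total_markers)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    m = len(rows)
    names = np.array([r[0] for r in rows])

    map_path = os.path.join(outdir, "map.tsv")
    with open(map_path, "w") as fh:
        for name, chrom, bp in rows:
            fh.write(f"{name}\t{chrom}\t{bp}\n")

    members_path = os.path.join(outdir, "members.tsv")
    samples_path = os.path.join(outdir, "samples.tsv")
    sample_names = [f"S{i:05d}" for i in range(n_samples)]
    with open(members_path, "w") as fh:
        for i in range(n_samples):
            fh.write(f"COHORT\tI{i:05d}\t0\t0\t0\n")
    with open(samples_path, "w") as fh:
        for i, s in enumerate(sample_names):
            fh.write(f"{s}\tCOHORT\tI{i:05d}\n")

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pair_idx = np.array(
        [rng.choice(4, size=2, replace=False) for _ in range(m)]
    )
    a_allele, b_allele = bases[pair_idx[:, 0]], bases[pair_idx[:, 1]]
    p_a = rng.uniform(0.1, 0.9, size=m)

    sample_dir = os.path.join(outdir, "samples")
    os.makedirs(sample_dir, exist_ok=True)
    sample_files: Dict[str, str] = {}
    name_list = names.tolist()
    for i, s in enumerate(sample_names):
        draws = rng.random((m, 2)) < p_a[:, None]
        g = np.sort(np.where(draws, a_allele[:, None], b_allele[:, None]), axis=1)
        if missing_rate > 0:
            g[rng.random(m) < missing_rate] = ord("0")
        path = os.path.join(sample_dir, f"{s}.tsv")
        a1 = g[:, 0].tobytes().decode("ascii")
        a2 = g[:, 1].tobytes().decode("ascii")
        with open(path, "w") as fh:
            fh.write(
                "\n".join(
                    f"{n}\t{x}\t{y}" for n, x, y in zip(name_list, a1, a2)
                )
                + "\n"
            )
        sample_files[s] = path
    return map_path, members_path, samples_path, sample_files


# ---------------------------------------------------------------------------
# the marker-lookup / conflict-resolution worked example


def load_marker_lookup_example(db: Database) -> Dict[str, object]:
    """Populate a store with the canonical marker-lookup scenario.

    One member is genotyped by a targeted experiment ("Exp D", row store)
    and a genome-wide experiment ("Exp F", blocks).  Under the current map
    build, rs123451 and rs123452 sit on chr1 between 10 Mb and 20 Mb;
    rs456784 has moved to chr3 and gained the alias rs34567, but its blocks
    were written when it was on chr2 — its slot keeps the load-time
    chromosome.  The three doubly-measured markers resolve to A/C (one
    experiment missing), 0/0 (a 1/2 vs G/T conflict) and A/C (agreement).
    """
    from .store import LoadMode

    db.create_schema()
    db.load_table("members", [
        {"pedigree": "F1", "person": "P1", "father": None, "mother": None, "sex": 1},
    ], LoadMode.COMMIT)
    members = db.member_ids()
    db.load_table("samples", [
        {"sample_name": "S1", "member_id": members[("F1", "P1")],
         "plate": None, "well": None, "preferred": 0},
    ], LoadMode.COMMIT)
    db.load_table("markers", [
        {"name": "rs123401"}, {"name": "rs123451"},
        {"name": "rs123452"}, {"name": "rs456784"},
    ], LoadMode.COMMIT)
    markers = db.marker_ids()
    db.load_table("marker_aliases", [
        {"alias_name": "rs34567", "marker_id": markers["rs456784"]},
    ], LoadMode.COMMIT)
    info = [
        ("rs123401", 1, 5_000_000),
        ("rs123451", 1, 12_000_000),
        ("rs123452", 1, 13_000_000),
        ("rs456784", 3, 30_000_000),  # current build: moved to chr3
    ]
    db.load_table("marker_info", [
        {"marker_id": markers[n], "build": "current", "chromosome": c,
         "bp": bp, "avg_cm": None, "female_cm": None, "male_cm": None}
        for n, c, bp in info
    ], LoadMode.COMMIT)

    exp_d = db.experiment_id("Exp D", create=True)
    exp_f = db.experiment_id("Exp F", create=True)
    tech = db.technology_id("custom", create=True)
    mid = members[("F1", "P1")]
    rows = [
        (mid, markers["rs123401"], exp_d, tech, "0", "0"),  # assayed, missing
        (mid, markers["rs123451"], exp_d, tech, "1", "2"),
        (mid, markers["rs123452"], exp_d, tech, "A", "C"),
    ]
    with db.transaction():
        db.conn.executemany(
            "INSERT INTO genotypes "
            "(member_id, marker_id, experiment_id, technology_id, allele1, allele2) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            rows,
        )

    # blocks written when rs456784 was still on chr2
    blockcodec.write_index(
        db, "chip1",
        {
            1: [markers["rs123401"], markers["rs123451"], markers["rs123452"]],
            2: [markers["rs456784"]],
        },
        block_size=500,
    )
    sample_id = db.sample_ids()["S1"]
    blockcodec.write_sample(
        db, sample_id, exp_f, "chip1",
        {
            markers["rs123401"]: parse_call("A/C"),
            markers["rs123451"]: parse_call("G/T"),
            markers["rs123452"]: parse_call("A/C"),
            markers["rs456784"]: parse_call("G/T"),
        },
        block_size=500,
    )
    return {
        "member": ("F1", "P1"),
        "markers": markers,
        "experiments": ("Exp D", "Exp F"),
        "build": "current",
        "range_chr1": (10_000_000, 20_000_000),
        "expected_range_markers": ["rs123451", "rs123452"],
        "expected_merged": {
            "rs123401": "A/C",
            "rs123451": "0/0",
            "rs123452": "A/C",
            "rs456784": "G/T",
        },
    }
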