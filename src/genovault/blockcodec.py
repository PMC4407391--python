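"""Block-packed storage for genome-wide genotypes.

Chip-scale experiments store one record per (sample, experiment,
chromosome, block) holding up to B consecutive markers' genotypes, instead
of one record per genotype.  A separate index (the ``snpblocks`` table)
maps each marker to the (chromosome, block, offset) slot where its genotype
lives; the chromosome recorded there is the chromosome *at load time* and
never changes afterwards, even if a later map build moves the marker.

The payload encoding is two bytes per genotype — the two single-character
allele codes, slot-sorted — so a block of B genotypes is a 2B-byte blob.
Unused trailing slots hold ``0/0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    ALLELE_ALPHABET,
    GenotypeCall,
    GenotypeError,
    MISSING_CALL,
    normalize_call,
)
from .store import Database

DEFAULT_BLOCK_SIZE = 500

_ZERO = ord("0")
_ALLOWED = np.zeros(256, dtype=bool)
for _c in ALLELE_ALPHABET:
    _ALLOWED[ord(_c)] = True


class NotStored(KeyError):
    """Marker has no slot in the block index (caller may fall back to the
    row store)."""


@dataclass(frozen=True)
class BlockLayout:
    """Per-chromosome block allocation for a marker map.

    ``marker_counts`` maps chromosome → number of markers; each chromosome
    gets ``ceil(m_c / B)`` blocks of ``block_size`` slots.
    """

    block_size: int
    marker_counts: Mapping[int, int]

    @property
    def block_counts(self) -> Dict[int, int]:
        return {
            c: math.ceil(m / self.block_size)
            for c, m in self.marker_counts.items()
            if m > 0
        }

    @property
    def total_blocks(self) -> int:
        return sum(self.block_counts.values())

    @property
    def total_slots(self) -> int:
        return self.total_blocks * self.block_size

    @property
    def total_markers(self) -> int:
        return sum(self.marker_counts.values())


def allocate_layout(
    marker_counts: Mapping[int, int], block_size: int = DEFAULT_BLOCK_SIZE
) -> BlockLayout:
    """Compute the block allocation for per-chromosome marker counts."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    for c, m in marker_counts.items():
        if m < 0:
            raise ValueError(f"negative marker count for chromosome {c}")
    return BlockLayout(block_size=block_size, marker_counts=dict(marker_counts))


# ---------------------------------------------------------------------------
# payload codec


def normalize_pair_array(arr: np.ndarray) -> np.ndarray:
    """Validate and slot-sort an (m, 2) uint8 array of allele codes.

    Vectorized counterpart of :func:`genovault.datamodel.normalize_call`:
    codes must be in the allele alphabet and "0" may only pair with "0".
    """
    arr = np.ascontiguousarray(arr, dtype=np.uint8)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (m, 2) array of allele codes")
    if not _ALLOWED[arr].all():
        bad = arr[~_ALLOWED[arr].all(axis=1)][0]
        raise GenotypeError(f"allele code outside alphabet: {bytes(bad)!r}")
    half = (arr[:, 0] == _ZERO) != (arr[:, 1] == _ZERO)
    if half.any():
        bad = arr[half][0]
        raise GenotypeError(f"half-missing genotype {bytes(bad)!r}")
    return np.sort(arr, axis=1)


def encode_payload(pairs: np.ndarray, block_size: int) -> bytes:
    """Encode up to ``block_size`` genotypes into a 2·B byte payload.

    ``pairs`` is an (m, 2) uint8 array of already-normalized allele codes
    (m ≤ B); trailing slots are padded with the missing genotype.
    """
    m = pairs.shape[0]
    if m > block_size:
        raise ValueError("more genotypes than slots in a block")
    buf = np.full(2 * block_size, _ZERO, dtype=np.uint8)
    buf[: 2 * m] = pairs.reshape(-1)
    return buf.tobytes()


def decode_payload(payload: bytes) -> List[GenotypeCall]:
    """Decode a block payload back into its list of B calls."""
    if len(payload) % 2:
        raise ValueError("payload length must be even")
    s = payload.decode("ascii")
    return [GenotypeCall(s[i], s[i + 1]) for i in range(0, len(s), 2)]


def payload_array(payload: bytes) -> np.ndarray:
    """Decode a block payload into a (B, 2) uint8 array (fast path)."""
    return np.frombuffer(payload, dtype=np.uint8).reshape(-1, 2)


def calls_to_array(calls: Sequence[GenotypeCall]) -> np.ndarray:
    out = np.empty((len(calls), 2), dtype=np.uint8)
    for i, c in enumerate(calls):
        out[i, 0] = ord(c.allele1)
        out[i, 1] = ord(c.allele2)
    return out


# ---------------------------------------------------------------------------
# marker → slot index


def assign_slots(
    markers_by_chrom: Mapping[int, Sequence[int]], block_size: int
) -> List[Tuple[int, int, int, int]]:
    """Assign (marker_id, chromosome, block_index, offset) in map order.

    Markers are laid out consecutively within each chromosome: the i-th
    marker of a chromosome goes to block ``i // B`` at offset ``i % B``.
    """
    out = []
    for chrom in sorted(markers_by_chrom):
        for i, mid in enumerate(markers_by_chrom[chrom]):
            out.append((mid, chrom, i // block_size, i % block_size))
    return out


def write_index(
    db: Database,
    layout_name: str,
    markers_by_chrom: Mapping[int, Sequence[int]],
    block_size: int,
) -> int:
    """Persist the slot index for a mapping-file load; returns entries written.

    Re-running with the same assignment is a no-op; a marker already indexed
    under this layout keeps its original slot (and chromosome) even if the
    new map moved it.
    """
    slots = assign_slots(markers_by_chrom, block_size)
    existing = {
        r["marker_id"]
        for r in db.conn.execute(
            "SELECT marker_id FROM snpblocks WHERE layout = ?", (layout_name,)
        )
    }
    rows = [s for s in slots if s[0] not in existing]
    with db.transaction():
        db.conn.executemany(
            "INSERT INTO snpblocks (layout, marker_id, chromosome, block_index, offset) "
            "VALUES (?, ?, ?, ?, ?)",
            [(layout_name, mid, c, b, o) for mid, c, b, o in rows],
        )
    return len(rows)


def load_index(db: Database, layout_name: str) -> Dict[int, Tuple[int, int, int]]:
    """marker_id → (chromosome-at-load, block_index, offset)."""
    return {
        r["marker_id"]: (r["chromosome"], r["block_index"], r["offset"])
        for r in db.conn.execute(
            "SELECT marker_id, chromosome, block_index, offset FROM snpblocks "
            "WHERE layout = ?",
            (layout_name,),
        )
    }


def locate(marker_id: int, index: Mapping[int, Tuple[int, int, int]]) -> Tuple[int, int, int]:
    """Return the (chromosome, block, offset) storage slot of a marker."""
    try:
        return index[marker_id]
    except KeyError:
        raise NotStored(f"marker id {marker_id} not in block index") from None


def index_layout(
    index: Mapping[int, Tuple[int, int, int]], block_size: int
) -> BlockLayout:
    """Recover the block layout implied by an index (slot counts/chromosome)."""
    counts: Dict[int, int] = {}
    for chrom, _b, _o in index.values():
        counts[chrom] = counts.get(chrom, 0) + 1
    return BlockLayout(block_size=block_size, marker_counts=counts)


# ---------------------------------------------------------------------------
# block reads/writes


def write_sample_arrays(
    db: Database,
    sample_id: int,
    experiment_id: int,
    layout_name: str,
    arrays_by_chrom: Mapping[int, np.ndarray],
    block_size: int,
) -> int:
    """Write one sample's genotypes, given per-chromosome (m, 2) code arrays
    in slot order.  Returns the number of block records written.

    One record is written per block the layout allocates on each chromosome,
    including blocks whose slots are all missing.
    """
    rows = []
    for chrom in sorted(arrays_by_chrom):
        pairs = normalize_pair_array(arrays_by_chrom[chrom])
        m = pairs.shape[0]
        n_blocks = math.ceil(m / block_size) if m else 0
        for b in range(n_blocks):
            chunk = pairs[b * block_size : (b + 1) * block_size]
            rows.append(
                (
                    sample_id,
                    experiment_id,
                    layout_name,
                    chrom,
                    b,
                    block_size,
                    encode_payload(chunk, block_size),
                )
            )
    with db.transaction():
        db.conn.executemany(
            "INSERT INTO genotypeblocks "
            "(sample_id, experiment_id, layout, chromosome, block_index, block_size, payload) "
            "VALUES (?, ?, ?, ?, ?, ?, ?)",
            rows,
        )
    return len(rows)


def write_sample(
    db: Database,
    sample_id: int,
    experiment_id: int,
    layout_name: str,
    calls: Mapping[int, GenotypeCall],
    block_size: int = DEFAULT_BLOCK_SIZE,
    index: Optional[Mapping[int, Tuple[int, int, int]]] = None,
) -> int:
    """Write one sample's genotypes given a marker_id → call map.

    Every marker must already have an index entry under ``layout_name``
    (the mapping file is loaded first); unreferenced slots stay missing.
    Blocks are allocated for the whole layout, so an all-missing sample
    still writes the full block set.
    """
    if index is None:
        index = load_index(db, layout_name)
    layout = index_layout(index, block_size)
    arrays: Dict[int, np.ndarray] = {
        c: np.full((m, 2), _ZERO, dtype=np.uint8)
        for c, m in layout.marker_counts.items()
    }
    for mid, call in calls.items():
        if mid not in index:
            raise NotStored(f"marker id {mid} has no index entry in {layout_name!r}")
        chrom, b, o = index[mid]
        slot = b * block_size + o
        arrays[chrom][slot, 0] = ord(call.allele1)
        arrays[chrom][slot, 1] = ord(call.allele2)
    return write_sample_arrays(
        db, sample_id, experiment_id, layout_name, arrays, block_size
    )


def read_range(
    db: Database,
    sample_ids: Sequence[int],
    experiment_id: int,
    layout_name: str,
    chromosome: int,
    block_span: Optional[Tuple[int, int]] = None,
    index: Optional[Mapping[int, Tuple[int, int, int]]] = None,
) -> Dict[int, Dict[int, GenotypeCall]]:
    """Fetch calls for samples over a span of blocks on one chromosome.

    ``block_span`` is an inclusive (lo, hi) pair of block indices; ``None``
    reads the whole chromosome.  Returns sample_id → {marker_id → call} with
    exactly the slots whose index entries fall in the span; a span outside
    the layout yields empty maps.  Adjacent markers sharing a block cost a
    single block read.
    """
    if not sample_ids:
        return {}
    if index is None:
        index = load_index(db, layout_name)
    wanted: Dict[Tuple[int, int], int] = {}  # (block, offset) -> marker_id
    for mid, (chrom, b, o) in index.items():
        if chrom != chromosome:
            continue
        if block_span is not None and not (block_span[0] <= b <= block_span[1]):
            continue
        wanted[(b, o)] = mid
    out: Dict[int, Dict[int, GenotypeCall]] = {s: {} for s in sample_ids}
    if not wanted:
        return out
    blocks_needed = sorted({b for b, _ in wanted})
    qmarks = ", ".join("?" * len(sample_ids))
    bmarks = ", ".join("?" * len(blocks_needed))
    cur = db.conn.execute(
        f"SELECT sample_id, block_index, payload FROM genotypeblocks "
        f"WHERE experiment_id = ? AND layout = ? AND chromosome = ? "
        f"AND sample_id IN ({qmarks}) AND block_index IN ({bmarks})",
        [experiment_id, layout_name, chromosome, *sample_ids, *blocks_needed],
    )
    by_block: Dict[int, List[Tuple[int, int]]] = {}
    for (b, o), mid in wanted.items():
        by_block.setdefault(b, []).append((o, mid))
    for row in cur:
        sample_calls = out[row["sample_id"]]
        payload = row["payload"]
        for o, mid in by_block.get(row["block_index"], ()):
            a1 = chr(payload[2 * o])
            a2 = chr(payload[2 * o + 1])
            sample_calls[mid] = GenotypeCall(a1, a2)
    return out


def read_sample(
    db: Database,
    sample_id: int,
    experiment_id: int,
    layout_name: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
    index: Optional[Mapping[int, Tuple[int, int, int]]] = None,
) -> Dict[int, GenotypeCall]:
    """All indexed calls of one sample (union over chromosomes)."""
    if index is None:
        index = load_index(db, layout_name)
    chroms = sorted({c for c, _b, _o in index.values()})
    calls: Dict[int, GenotypeCall] = {}
    for chrom in chroms:
        got = read_range(
            db, [sample_id], experiment_id, layout_name, chrom, None, index
        )
        calls.update(got[sample_id])
    return calls


def count_blocks(db: Database, experiment_id: Optional[int] = None) -> int:
    sql = "SELECT COUNT(*) AS n FROM genotypeblocks"
    params: tuple = ()
    if experiment_id is not None:
        sql += " WHERE experiment_id = ?"
        params = (experiment_id,)
    return db.conn.execute(sql, params).fetchone()["n"]
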