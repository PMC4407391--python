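"""PLINK 1 fileset I/O: text ped/map and binary bed/bim/fam.

The .bed codec implements the v1 binary layout: magic bytes 0x6C 0x1B, a
mode byte (0x01 = SNP-major), then one row of ceil(n_samples/4) bytes per
variant.  Each sample occupies two bits, least-significant pair first:

    00  homozygous A1        10  heterozygous
    01  missing               11  homozygous A2

Genotypes travel through this module as an (n_markers, n_samples, 2) uint8
array of allele character codes, the same representation the block codec
uses; ``0`` is the missing allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"

_ZERO = ord("0")


class PlinkFormatError(ValueError):
    pass


@dataclass(frozen=True)
class BimRecord:
    chromosome: int
    name: str
    cm: float
    bp: int
    a1: str  # allele coded 00 (conventionally the minor allele)
    a2: str


@dataclass(frozen=True)
class FamRecord:
    pedigree: str
    person: str
    father: str  # "0" when absent
    mother: str
    sex: int  # 1/2/0
    phenotype: str


def choose_alleles(column: np.ndarray, name: str) -> Tuple[str, str]:
    """Pick (A1, A2) for one marker from its (n, 2) code column.

    A1 is the minor allele by count, ties broken by code point; unknown
    alleles (monomorphic or all-missing markers) are "0".  More than two
    distinct alleles is an error naming the marker.
    """
    codes, counts = np.unique(column[column != _ZERO], return_counts=True)
    if len(codes) > 2:
        raise PlinkFormatError(
            f"marker {name!r} has >2 alleles: {[chr(c) for c in codes]}"
        )
    if len(codes) == 0:
        return "0", "0"
    if len(codes) == 1:
        return "0", chr(codes[0])
    order = np.lexsort((codes, counts))  # minor (then lower code) first
    return chr(codes[order[0]]), chr(codes[order[1]])


def _codes_for_marker(column: np.ndarray, a1: str, a2: str) -> np.ndarray:
    """Translate an (n, 2) allele-code column to 2-bit bed codes."""
    n = column.shape[0]
    out = np.full(n, 0b01, dtype=np.uint8)  # missing by default
    c1, c2 = ord(a1), ord(a2)
    miss = column[:, 0] == _ZERO
    hom1 = (column[:, 0] == c1) & (column[:, 1] == c1) & ~miss
    hom2 = (column[:, 0] == c2) & (column[:, 1] == c2) & ~miss
    het = ~miss & ~hom1 & ~hom2
    out[hom1] = 0b00
    out[het] = 0b10
    out[hom2] = 0b11
    return out


def _pack(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    q = codes.reshape(-1, 4)
    return (q[:, 0] | (q[:, 1] << 2) | (q[:, 2] << 4) | (q[:, 3] << 6)).astype(
        np.uint8
    )


def _unpack(row: np.ndarray, n: int) -> np.ndarray:
    out = np.empty(row.shape[0] * 4, dtype=np.uint8)
    out[0::4] = row & 0b11
    out[1::4] = (row >> 2) & 0b11
    out[2::4] = (row >> 4) & 0b11
    out[3::4] = (row >> 6) & 0b11
    return out[:n]


def write_bed(
    prefix: str,
    fam: Sequence[FamRecord],
    bim: Sequence[BimRecord],
    geno: np.ndarray,
) -> Tuple[str, str, str]:
    """Write a bed/bim/fam trio; returns the three paths.

    ``geno`` is (n_markers, n_samples, 2) allele codes, marker order matching
    ``bim`` and sample order matching ``fam``; each marker must be
    biallelic-or-missing and consistent with its bim alleles.
    """
    n_m, n_s = len(bim), len(fam)
    if geno.shape != (n_m, n_s, 2):
        raise PlinkFormatError(
            f"genotype array shape {geno.shape} != ({n_m}, {n_s}, 2)"
        )
    bed_path, bim_path, fam_path = (
        f"{prefix}.bed",
        f"{prefix}.bim",
        f"{prefix}.fam",
    )
    rows = [MAGIC + SNP_MAJOR]
    for j, rec in enumerate(bim):
        codes = _codes_for_marker(geno[j], rec.a1, rec.a2)
        rows.append(_pack(codes).tobytes())
    with open(bed_path, "wb") as fh:
        fh.write(b"".join(rows))
    with open(bim_path, "w") as fh:
        for rec in bim:
            cm = f"{rec.cm:g}"
            fh.write(
                f"{rec.chromosome}\t{rec.name}\t{cm}\t{rec.bp}\t{rec.a1}\t{rec.a2}\n"
            )
    with open(fam_path, "w") as fh:
        for rec in fam:
            fh.write(
                f"{rec.pedigree} {rec.person} {rec.father} {rec.mother} "
                f"{rec.sex} {rec.phenotype}\n"
            )
    return bed_path, bim_path, fam_path


def read_bim(path: str) -> List[BimRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            out.append(
                BimRecord(
                    chromosome=int(f[0]),
                    name=f[1],
                    cm=float(f[2]),
                    bp=int(f[3]),
                    a1=f[4],
                    a2=f[5],
                )
            )
    return out


def read_fam(path: str) -> List[FamRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            out.append(
                FamRecord(
                    pedigree=f[0],
                    person=f[1],
                    father=f[2],
                    mother=f[3],
                    sex=int(f[4]) if f[4] in ("0", "1", "2") else 0,
                    phenotype=f[5] if len(f) > 5 else "0",
                )
            )
    return out


def read_bed(
    bed_path: str, bim: Sequence[BimRecord], fam: Sequence[FamRecord]
) -> np.ndarray:
    """Decode a SNP-major .bed into (n_markers, n_samples, 2) allele codes."""
    with open(bed_path, "rb") as fh:
        blob = fh.read()
    if blob[:2] != MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {blob[:2]!r}")
    if blob[2:3] != SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: individual-major mode is not supported"
        )
    n_m, n_s = len(bim), len(fam)
    bpm = (n_s + 3) // 4  # bytes per marker row
    body = np.frombuffer(blob, dtype=np.uint8, offset=3)
    if body.shape[0] != n_m * bpm:
        raise PlinkFormatError(
            f"{bed_path}: expected {n_m * bpm} data bytes, found {body.shape[0]}"
        )
    geno = np.full((n_m, n_s, 2), _ZERO, dtype=np.uint8)
    for j, rec in enumerate(bim):
        codes = _unpack(body[j * bpm : (j + 1) * bpm], n_s)
        c1, c2 = ord(rec.a1), ord(rec.a2)
        lo, hi = min(c1, c2), max(c1, c2)
        geno[j][codes == 0b00] = (c1, c1)
        geno[j][codes == 0b11] = (c2, c2)
        geno[j][codes == 0b10] = (lo, hi)
        # 0b01 rows stay missing
    return geno


def write_ped_map(
    prefix: str,
    fam: Sequence[FamRecord],
    markers: Sequence[Tuple[int, str, float, int]],
    geno: np.ndarray,
    delimiter: str = " ",
) -> Tuple[str, str]:
    """Write text ped/map; ``markers`` rows are (chrom, name, cM, bp)."""
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    n_m = len(markers)
    with open(map_path, "w") as fh:
        for chrom, name, cm, bp in markers:
            fh.write(f"{chrom}\t{name}\t{cm:g}\t{bp}\n")
    with open(ped_path, "w") as fh:
        for i, rec in enumerate(fam):
            cells = [
                rec.pedigree,
                rec.person,
                rec.father,
                rec.mother,
                str(rec.sex),
                rec.phenotype,
            ]
            col = geno[:, i, :]  # (n_markers, 2)
            for j in range(n_m):
                cells.append(chr(col[j, 0]))
                cells.append(chr(col[j, 1]))
            fh.write(delimiter.join(cells) + "\n")
    return ped_path, map_path


def read_ped(
    path: str, n_markers: int
) -> Tuple[List[FamRecord], np.ndarray]:
    """Parse a ped file back into fam records + (n_markers, n, 2) codes."""
    fams: List[FamRecord] = []
    cols: List[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"ped line for {f[:2]} has {len(f) - 6} allele fields, "
                    f"expected {2 * n_markers}"
                )
            fams.append(
                FamRecord(f[0], f[1], f[2], f[3], int(f[4]) if f[4] in "012" else 0, f[5])
            )
            alleles = np.array(
                [ord(a[0]) for a in f[6:]], dtype=np.uint8
            ).reshape(n_markers, 2)
            cols.append(alleles)
    geno = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((n_markers, 0, 2), dtype=np.uint8)
    )
    return fams, geno
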