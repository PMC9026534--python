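"""PLINK 1 genotype file I/O.

Supports the text dialect (``.ped``/``.map``) and the SNP-major binary
dialect (``.bed``/``.bim``/``.fam``, magic bytes ``6c 1b``, mode ``01``).
The 2-bit genotype encoding of the binary format is::

    00  hom a1/a1   -> dosage 0
    01  missing     -> MISSING
    10  het         -> dosage 1
    11  hom a2/a2   -> dosage 2

Individual-major ``.bed`` files (mode byte ``00``) are rejected, not
transposed.  VCF/BCF and PLINK 2 ``.pgen`` are out of scope.

The text format carries no allele-order metadata, so ``read_plink_text``
assigns a1/a2 per marker as the lexicographically sorted pair of observed
alleles (monomorphic markers get a2 = "0").  Binary files preserve the
allele order stored in the ``.bim``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .dataset import (
    MISSING,
    GenotypeDataset,
    MarkerRecord,
    SampleRecord,
    ValidationError,
)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
# 2-bit code -> dosage
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage (index MISSING==-1 wraps to the last slot) -> 2-bit code
_ENCODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """Malformed PLINK file content."""


def _parse_sex(code: str) -> str:
    return {"1": "male", "2": "female"}.get(code, "unknown")


def _sex_code(sex: str) -> str:
    return {"male": "1", "female": "2"}.get(sex, "0")


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def read_plink_map(map_path: str | os.PathLike) -> list[MarkerRecord]:
    """Parse a ``.map`` file (chrom, id, cM, bp) into marker records."""
    markers: list[MarkerRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, marker_id, _cm, pos = fields
            try:
                markers.append(
                    MarkerRecord(
                        marker_id=marker_id,
                        chromosome=int(chrom),
                        position_bp=int(pos),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise PlinkFormatError(f"{map_path}:{lineno}: {exc}") from exc
    return markers


def read_plink_text(
    ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> GenotypeDataset:
    """Read a ``.ped``/``.map`` pair into a validated dataset.

    ``0 0`` allele pairs become MISSING.  Markers are re-sorted by
    (chromosome, position) with the call matrix permuted consistently.
    """
    markers = read_plink_map(map_path)
    m = len(markers)

    samples: list[SampleRecord] = []
    seen: set[str] = set()
    rows: list[np.ndarray] = []
    # observed alleles per marker, insertion-ordered
    alleles: list[dict[str, None]] = [dict() for _ in range(m)]
    raw_pairs: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} markers), got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex, _pheno = fields[:6]
            if iid in seen:
                raise ValidationError(
                    f"{ped_path}:{lineno}: duplicate sample_id {iid!r}"
                )
            seen.add(iid)
            samples.append(SampleRecord(sample_id=iid, sex=_parse_sex(sex)))
            pairs = list(zip(fields[6::2], fields[7::2]))
            raw_pairs.append(pairs)
            for j, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        alleles[j][al] = None

    # fix per-marker allele order: lexicographically sorted observed alleles
    resolved: list[MarkerRecord] = []
    for j, rec in enumerate(markers):
        obs = sorted(alleles[j])
        if len(obs) > 2:
            raise PlinkFormatError(
                f"{ped_path}: marker {rec.marker_id} has >2 alleles: {obs}"
            )
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) == 2 else "0"
        resolved.append(
            MarkerRecord(rec.marker_id, rec.chromosome, rec.position_bp, a1, a2)
        )

    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw_pairs):
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == resolved[j].allele_a2) + (b == resolved[j].allele_a2)

    ds = GenotypeDataset(samples=samples, markers=resolved, calls=calls)
    return ds.sorted_by_position().validate()


def write_plink_text(ds: GenotypeDataset, prefix: str | os.PathLike) -> None:
    """Write ``.ped``/``.map`` files for a dataset.

    Raises if a non-missing call needs an allele letter the marker does not
    carry (e.g. dosage 2 at a marker whose a2 is the placeholder "0").
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for rec in ds.markers:
            fh.write(f"{rec.chromosome}\t{rec.marker_id}\t0\t{rec.position_bp}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(ds.samples):
            out = [s.sample_id, s.sample_id, "0", "0", _sex_code(s.sex), "-9"]
            for j, rec in enumerate(ds.markers):
                g = ds.calls[i, j]
                if g == MISSING:
                    out += ["0", "0"]
                    continue
                pair = {
                    0: (rec.allele_a1, rec.allele_a1),
                    1: (rec.allele_a1, rec.allele_a2),
                    2: (rec.allele_a2, rec.allele_a2),
                }[int(g)]
                if "0" in pair:
                    raise PlinkFormatError(
                        f"marker {rec.marker_id}: call {g} requires an allele "
                        f"letter the marker does not define"
                    )
                out += list(pair)
            fh.write(" ".join(out) + "\n")


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> GenotypeDataset:
    """Read a ``.bed``/``.bim``/``.fam`` triple into a validated dataset."""
    markers: list[MarkerRecord] = []
    with open(bim_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PlinkFormatError(
                    f"{bim_path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, marker_id, _cm, pos, a1, a2 = fields
            try:
                markers.append(
                    MarkerRecord(marker_id, int(chrom), int(pos), a1, a2)
                )
            except (ValueError, ValidationError) as exc:
                raise PlinkFormatError(f"{bim_path}:{lineno}: {exc}") from exc

    samples: list[SampleRecord] = []
    seen: set[str] = set()
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PlinkFormatError(
                    f"{fam_path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex, _pheno = fields
            if iid in seen:
                raise ValidationError(
                    f"{fam_path}:{lineno}: duplicate sample_id {iid!r}"
                )
            seen.add(iid)
            samples.append(SampleRecord(sample_id=iid, sex=_parse_sex(sex)))

    n, m = len(samples), len(markers)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2].hex()}, expected 6c1b"
        )
    if len(raw) < 3:
        raise PlinkFormatError(f"{bed_path}: truncated header")
    mode = raw[2]
    if mode != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: mode byte {mode:#04x} is not SNP-major (0x01); "
            "individual-major files are not supported"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} for "
            f"{n} samples x {m} markers (truncated or padded file)"
        )

    if m == 0 or n == 0:
        calls = np.zeros((n, m), dtype=np.int8)
    else:
        buf = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
            m, bytes_per_marker
        )
        # unpack 2-bit fields, little-endian within each byte
        codes = np.stack(
            [(buf >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
        ).reshape(m, -1)[:, :n]
        calls = _DECODE[codes].T.copy()

    ds = GenotypeDataset(samples=samples, markers=markers, calls=calls)
    return ds.sorted_by_position().validate()


def write_plink_binary(ds: GenotypeDataset, prefix: str | os.PathLike) -> None:
    """Write a ``.bed``/``.bim``/``.fam`` triple (SNP-major) for a dataset."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in ds.markers:
            fh.write(
                f"{rec.chromosome}\t{rec.marker_id}\t0\t{rec.position_bp}"
                f"\t{rec.allele_a1}\t{rec.allele_a2}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in ds.samples:
            fh.write(f"{s.sample_id} {s.sample_id} 0 0 {_sex_code(s.sex)} -9\n")

    n, m = ds.n_samples, ds.n_markers
    bytes_per_marker = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        if m == 0:
            return
        codes = _ENCODE[ds.calls]  # MISSING==-1 wraps to index 3 -> 0b01
        padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a dataset from a prefix, preferring binary over text files."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_plink_binary(
            prefix.with_suffix(".bed"),
            prefix.with_suffix(".bim"),
            prefix.with_suffix(".fam"),
        )
    if prefix.with_suffix(".ped").exists():
        return read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    raise FileNotFoundError(f"no .bed or .ped file found at prefix {prefix}")
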