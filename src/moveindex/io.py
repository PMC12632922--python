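"""Index container serialization and FASTA/FASTQ I/O.

One self-describing file per index: a fixed header, the bit-packed row array,
then the checkpoint table (blocked/sampled variants).  Row records are fixed
width, little-endian, fields packed LSB-first:

========  =====  =======================================================
variant   bytes  fields (bit widths)
========  =====  =======================================================
default     8    c:2  l:11  f:11  id:36  thr:3  spare:1
blocked     6    c:2  l:10  f:10  delta:23  thr:3
sampled     3    c:2  l:9   f:9   thr:3  spare:1
========  =====  =======================================================

Checkpoint ids are 40 bits each, four per checkpoint (one per DNA symbol).
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .id_compression import BlockTable, SampleTable
from .move_table import MoveTable

MAGIC = b"MV2I"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<4sHBBBBQQQIQQQ")
_VARIANT_CODE = {"default": 0, "blocked": 1, "sampled": 2}
_VARIANT_NAME = {v: k for k, v in _VARIANT_CODE.items()}

# (length_bits_on_disk, id_field_bits, record_bytes) per variant
_LAYOUT = {"default": (11, 36, 8), "blocked": (10, 23, 6), "sampled": (9, 0, 3)}

#: the three mismatch symbols for each stored code, ascending
_OTHERS = np.array([[y for y in range(4) if y != c] for c in range(4)], dtype=np.int64)

ID_BITS_DEFAULT = 36
DELTA_BITS = 23
CHECKPOINT_ID_BYTES = 5


class IndexFormatError(ValueError):
    pass


def bytes_per_row(variant: str) -> int:
    return _LAYOUT[variant][2]


def _check_fits(name: str, values: np.ndarray, bits: int) -> None:
    if values.size and (int(values.max()) >> bits) != 0:
        q = int(np.argmax(values))
        raise IndexFormatError(
            f"{name} field of row {q} ({int(values[q])}) exceeds {bits} bits"
        )


def _threshold_bits(table: MoveTable) -> np.ndarray:
    """3 trivial-threshold bits per row; errors on a non-trivial threshold."""
    rows = np.arange(table.row_count)
    others = _OTHERS[table.code]
    theta = table.thr[rows[:, None], others]
    l = table.length[:, None]
    bad = (theta != 0) & (theta != l)
    if bad.any():
        q = int(np.flatnonzero(bad.any(axis=1))[0])
        raise IndexFormatError(
            f"row {q} has a non-trivial threshold and cannot be serialized; "
            "build with thresholds-splitting enabled"
        )
    return ((theta == l).astype(np.uint64) << np.arange(3, dtype=np.uint64)).sum(axis=1)


def _pack_records(values: np.ndarray, nbytes: int) -> bytes:
    le = values.astype("<u8")
    if nbytes == 8:
        return le.tobytes()
    return le.view(np.uint8).reshape(-1, 8)[:, :nbytes].tobytes()


def _unpack_records(buf: bytes, nbytes: int, count: int) -> np.ndarray:
    raw = np.frombuffer(buf, dtype=np.uint8)
    if raw.size != nbytes * count:
        raise IndexFormatError("row array truncated")
    if nbytes == 8:
        return raw.view("<u8").astype(np.uint64)
    padded = np.zeros((count, 8), dtype=np.uint8)
    padded[:, :nbytes] = raw.reshape(count, nbytes)
    return padded.reshape(-1).view("<u8").astype(np.uint64)


def _pack_checkpoints(cp: np.ndarray) -> bytes:
    flat = cp.reshape(-1).astype(np.int64)
    _check_fits("checkpoint id", flat, 8 * CHECKPOINT_ID_BYTES)
    return _pack_records(flat.astype(np.uint64), CHECKPOINT_ID_BYTES)


def _unpack_checkpoints(buf: bytes, count: int) -> np.ndarray:
    vals = _unpack_records(buf, CHECKPOINT_ID_BYTES, count * 4)
    return vals.astype(np.int64).reshape(count, 4)


def serialize_index(table: MoveTable, path: str | Path) -> None:
    """Write the index container; every field is width-checked first."""
    variant = table.variant
    lbits, idbits, nbytes = _LAYOUT[variant]
    code = table.code.astype(np.uint64)
    l = table.length.astype(np.uint64)
    f = table.f.astype(np.uint64)
    _check_fits("length", table.length, lbits)
    _check_fits("offset", table.f, lbits)
    thr = _threshold_bits(table)

    if variant == "default":
        _check_fits("id", table.ids, idbits)
        values = (
            code
            | (l << np.uint64(2))
            | (f << np.uint64(13))
            | (table.ids.astype(np.uint64) << np.uint64(24))
            | (thr << np.uint64(60))
        )
        cp_blob = b""
        param, cp_count = 0, 0
    elif variant == "blocked":
        _check_fits("delta", table.delta, idbits)
        values = (
            code
            | (l << np.uint64(2))
            | (f << np.uint64(12))
            | (table.delta.astype(np.uint64) << np.uint64(22))
            | (thr << np.uint64(45))
        )
        cp_blob = _pack_checkpoints(table.block_table.checkpoints)
        param, cp_count = table.block_table.b, table.block_table.n_checkpoints
    else:
        values = code | (l << np.uint64(2)) | (f << np.uint64(11)) | (thr << np.uint64(20))
        cp_blob = _pack_checkpoints(table.sample_table.checkpoints)
        param, cp_count = table.sample_table.s, table.sample_table.n_checkpoints

    header = _HEADER.pack(
        MAGIC,
        FORMAT_VERSION,
        _VARIANT_CODE[variant],
        table.length_bits,
        ID_BITS_DEFAULT if variant == "default" else 0,
        DELTA_BITS if variant == "blocked" else 0,
        table.n,
        table.r_original,
        table.row_count,
        param,
        table.terminator_row,
        cp_count,
        table.ambiguous_substituted,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(_pack_records(values, nbytes))
        fh.write(cp_blob)


def deserialize_index(path: str | Path) -> MoveTable:
    """Load an index container; queries on the result equal the original's."""
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER.size:
        raise IndexFormatError("file shorter than the index header")
    (
        magic,
        version,
        variant_code,
        length_bits,
        id_bits,
        delta_bits,
        n,
        r_original,
        row_count,
        param,
        terminator_row,
        cp_count,
        ambig,
    ) = _HEADER.unpack_from(blob)
    if magic != MAGIC:
        raise IndexFormatError(f"bad magic {magic!r}")
    if version != FORMAT_VERSION:
        raise IndexFormatError(f"unsupported format version {version}")
    if variant_code not in _VARIANT_NAME:
        raise IndexFormatError(f"unknown variant code {variant_code}")
    variant = _VARIANT_NAME[variant_code]
    lbits, idbits, nbytes = _LAYOUT[variant]

    off = _HEADER.size
    row_blob = blob[off : off + nbytes * row_count]
    values = _unpack_records(row_blob, nbytes, row_count)
    off += nbytes * row_count
    cp_blob = blob[off : off + CHECKPOINT_ID_BYTES * 4 * cp_count]
    if len(cp_blob) < CHECKPOINT_ID_BYTES * 4 * cp_count:
        raise IndexFormatError("checkpoint table truncated")

    mask = lambda b: np.uint64((1 << b) - 1)
    code = (values & mask(2)).astype(np.uint8)
    if variant == "default":
        length = ((values >> np.uint64(2)) & mask(11)).astype(np.int64)
        f = ((values >> np.uint64(13)) & mask(11)).astype(np.int64)
        ids = ((values >> np.uint64(24)) & mask(36)).astype(np.int64)
        thr_bits = ((values >> np.uint64(60)) & mask(3)).astype(np.int64)
        delta = None
        ids_col = ids
    elif variant == "blocked":
        length = ((values >> np.uint64(2)) & mask(10)).astype(np.int64)
        f = ((values >> np.uint64(12)) & mask(10)).astype(np.int64)
        delta = ((values >> np.uint64(22)) & mask(23)).astype(np.int64)
        thr_bits = ((values >> np.uint64(45)) & mask(3)).astype(np.int64)
        ids_col = None
    else:
        length = ((values >> np.uint64(2)) & mask(9)).astype(np.int64)
        f = ((values >> np.uint64(11)) & mask(9)).astype(np.int64)
        thr_bits = ((values >> np.uint64(20)) & mask(3)).astype(np.int64)
        delta = None
        ids_col = None

    rows = np.arange(row_count)
    others = _OTHERS[code]
    thr = np.zeros((row_count, 4), dtype=np.int64)
    for k in range(3):
        bit = (thr_bits >> k) & 1
        thr[rows, others[:, k]] = bit * length
    table = MoveTable(
        variant=variant,
        n=n,
        r_original=r_original,
        code=code,
        length=length,
        f=f,
        thr=thr,
        terminator_row=terminator_row,
        length_bits=length_bits,
        ids=ids_col,
        delta=delta,
        ambiguous_substituted=ambig,
    )
    if variant == "blocked":
        table.block_table = BlockTable(b=param, checkpoints=_unpack_checkpoints(cp_blob, cp_count))
    elif variant == "sampled":
        table.sample_table = SampleTable(s=param, checkpoints=_unpack_checkpoints(cp_blob, cp_count))
    return table


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _open_text(path: str | Path) -> TextIO:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def _guess_format(path: str | Path) -> str:
    p = str(path)
    if p.endswith(".gz"):
        p = p[:-3]
    if p.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ (optionally gzipped) as (name, sequence) pairs."""
    fmt = fmt or _guess_format(path)
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
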