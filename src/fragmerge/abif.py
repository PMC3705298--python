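"""Minimal ABIF (AB1) trace I/O: base calls and quality scores.

The ABIF container is the binary format written by Applied Biosystems
capillary sequencers: a 4-byte ``ABIF`` magic, a 2-byte version, a header
directory entry pointing at a table of 28-byte directory entries, each
naming a typed data block.  Sanger assembly needs exactly two of those
blocks per trace:

* ``PBAS`` — the called bases (char array), and
* ``PCON`` — the per-base Phred-like quality scores (one byte per base).

Sequencers store two copies of each, entry number 1 (basecaller output as
edited by the user) and entry number 2 (raw basecaller output).  The reader
prefers entry 1 when both are present, falling back to entry 2.  All
integers are big-endian, per the ABIF specification.

:func:`write_abif` produces a minimal but syntactically valid trace — just
the header, directory, and PBAS/PCON entries (numbers 1 and 2, identical) —
sufficient for this reader and for ``Bio.SeqIO``'s ``abi`` parser.  It
exists so that chromatogram-driven pipelines can be exercised end-to-end
from simulated genomes without sequencer output; no electropherogram trace
data is written.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AbifError

_MAGIC = b"ABIF"
_VERSION = 101
# name(4s) number(i) elemtype(h) elemsize(h) numelements(i) datasize(i)
# dataoffset(i) datahandle(i)
_DIR_FMT = ">4sihhiiii"
_DIR_SIZE = struct.calcsize(_DIR_FMT)  # 28
_HEADER_SIZE = 128

_TYPE_BYTE = 1
_TYPE_CHAR = 2

MAX_QUALITY = 62


@dataclass
class Chromatogram:
    """Base calls plus per-base quality scores from one Sanger trace.

    Invariant: ``len(bases) == len(qualities)`` and every quality is >= 0.
    """

    name: str
    bases: str
    qualities: list[int]
    source_path: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise AbifError(
                f"corrupt trace: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise AbifError("corrupt trace: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)


def _read_entries(blob: bytes) -> dict[tuple[str, int], tuple[int, bytes]]:
    """Parse the ABIF directory into {(tag, number): (elemtype, data)}."""
    if len(blob) < _HEADER_SIZE:
        raise AbifError("not an ABIF file: truncated header")
    version, = struct.unpack(">H", blob[4:6])
    (name, number, etype, esize, nelem, dsize, doff, _h) = struct.unpack(
        _DIR_FMT, blob[6 : 6 + _DIR_SIZE]
    )
    if name != b"tdir":
        raise AbifError("not an ABIF file: missing directory entry")
    entries: dict[tuple[str, int], tuple[int, bytes]] = {}
    for i in range(nelem):
        start = doff + i * _DIR_SIZE
        raw = blob[start : start + _DIR_SIZE]
        if len(raw) < _DIR_SIZE:
            raise AbifError("corrupt trace: directory runs past end of file")
        (ename, enum, eetype, eesize, eenelem, edsize, edoff, _eh) = struct.unpack(
            _DIR_FMT, raw
        )
        if edsize <= 4:
            # data <= 4 bytes is stored inline, in the dataoffset field itself
            data = raw[20 : 20 + edsize]
        else:
            data = blob[edoff : edoff + edsize]
            if len(data) < edsize:
                raise AbifError("corrupt trace: data block runs past end of file")
        entries[(ename.decode("ascii", "replace"), enum)] = (eetype, data)
    return entries


def _pick(entries, tag: str) -> bytes | None:
    for number in (1, 2):
        hit = entries.get((tag, number))
        if hit is not None:
            return hit[1]
    return None


def read_abif(path: str | Path) -> Chromatogram:
    """Read base calls (PBAS) and quality scores (PCON) from an AB1 file.

    Raises
    ------
    AbifError
        ``"not an ABIF file"`` if the magic signature is absent;
        ``"incomplete trace"`` if either the base-call or the quality entry
        is missing; ``"corrupt trace"`` if their lengths disagree.
    """
    path = Path(path)
    blob = path.read_bytes()
    if blob[:4] != _MAGIC:
        raise AbifError(f"not an ABIF file: {path}")
    entries = _read_entries(blob)
    pbas = _pick(entries, "PBAS")
    pcon = _pick(entries, "PCON")
    if pbas is None or pcon is None:
        raise AbifError(f"incomplete trace: missing PBAS or PCON entry in {path}")
    bases = pbas.decode("ascii", "replace")
    qualities = list(pcon)
    if len(bases) != len(qualities):
        raise AbifError(
            f"corrupt trace: {len(bases)} bases vs {len(qualities)} qualities in {path}"
        )
    return Chromatogram(
        name=path.stem, bases=bases, qualities=qualities, source_path=str(path)
    )


def _entry(name: bytes, number: int, etype: int, data: bytes, offset: int) -> tuple[bytes, int]:
    """Build one 28-byte directory entry; returns (entry, bytes consumed)."""
    size = len(data)
    if size <= 4:
        inline = data.ljust(4, b"\x00")
        packed = struct.pack(">4sihhii", name, number, etype, 1, size, size)
        return packed + inline + struct.pack(">i", 0), 0
    packed = struct.pack(_DIR_FMT, name, number, etype, 1, size, size, offset, 0)
    return packed, size


def write_abif(bases: str, qualities: list[int], path: str | Path) -> Path:
    """Write a minimal valid AB1 trace that :func:`read_abif` inverts exactly.

    Qualities must be in ``[0, 62]`` and match ``bases`` in length.
    """
    if len(bases) != len(qualities):
        raise AbifError("bases/qualities length mismatch")
    if any(q < 0 or q > MAX_QUALITY for q in qualities):
        raise AbifError(f"quality scores must lie in [0, {MAX_QUALITY}]")
    path = Path(path)

    seq = bases.encode("ascii")
    qual = bytes(qualities)
    # Layout: 128-byte header | data blocks | directory
    blocks: list[bytes] = []
    dir_entries: list[bytes] = []
    offset = _HEADER_SIZE
    for number in (1, 2):
        for name, etype, data in ((b"PBAS", _TYPE_CHAR, seq), (b"PCON", _TYPE_CHAR, qual)):
            entry, consumed = _entry(name, number, etype, data, offset)
            dir_entries.append(entry)
            if consumed:
                blocks.append(data)
                offset += consumed
    dir_offset = offset
    header = _MAGIC + struct.pack(">H", _VERSION)
    header += struct.pack(
        _DIR_FMT,
        b"tdir",
        1,
        1023,
        _DIR_SIZE,
        len(dir_entries),
        len(dir_entries) * _DIR_SIZE,
        dir_offset,
        0,
    )
    header = header.ljust(_HEADER_SIZE, b"\x00")
    path.write_bytes(header + b"".join(blocks) + b"".join(dir_entries))
    return path


# Spec'd fixture-writer name, kept as an alias for discoverability in tests.
write_abif_fixture = write_abif
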