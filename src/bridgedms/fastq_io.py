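"""Streaming FASTQ I/O with Illumina cluster-coordinate parsing.

Illumina instruments embed the physical location of every cluster in the
sequence identifier of each read (CASAVA >= 1.8 dialect)::

    @<instrument>:<run>:<flowcell>:<lane>:<tile>:<x>:<y> <mate>:<filter>:<control>:<index>

Both mates generated from one template share the same ``(flowcell, lane,
tile, x, y)`` tuple, because bridge amplification places both strands of a
cluster at one physical spot on the flow cell.  That tuple — the
:class:`ClusterKey` — is what lets non-overlapping paired reads be matched
back to their cognate template without any sequence overlap.

Quality strings are decoded as Phred+33 only.  Phred+64 dialects are
rejected rather than auto-detected: silently mis-decoding qualities by 31
is far worse than a hard error, and every instrument writing coordinate
headers of this dialect also writes Phred+33.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "PHRED_OFFSET",
    "MAX_PHRED",
    "VALID_BASES",
    "ClusterKey",
    "SequenceRead",
    "FastqParseError",
    "FastqReader",
    "parse_fastq",
    "parse_illumina_header",
    "write_fastq",
]

PHRED_OFFSET = 33
#: Highest encodable Phred score under +33 (chr(33 + 93) == '~').
MAX_PHRED = 93
VALID_BASES = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Raised for records that cannot be interpreted as FASTQ at all."""


class ClusterKey(NamedTuple):
    """Flow-cell surface coordinate of one cluster; shared by both mates."""

    flowcell: str
    lane: int
    tile: int
    x: int
    y: int


@dataclass(frozen=True, slots=True)
class SequenceRead:
    """One FASTQ record with its Illumina identifier fields decoded.

    ``flagged`` marks reads whose bases contain characters outside
    {A, C, G, T, N}; such records are retained (downstream filters decide
    their fate) but can be counted by callers.
    """

    raw_id: str
    instrument: str
    run: int
    flowcell: str
    lane: int
    tile: int
    x: int
    y: int
    mate: int
    bases: str
    quals: tuple[int, ...]
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.raw_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    @property
    def key(self) -> ClusterKey:
        return ClusterKey(self.flowcell, self.lane, self.tile, self.x, self.y)


def parse_illumina_header(raw_id: str) -> tuple[ClusterKey, int]:
    """Extract the cluster coordinate and mate number from a read identifier.

    Only the CASAVA >= 1.8 dialect is supported: seven colon-delimited
    coordinate fields, then a space, then ``mate:filter:control:index``.
    Older dialects (mate encoded as ``/1``) raise :class:`FastqParseError`.
    """
    head, sep, tail = raw_id.partition(" ")
    if not sep or not tail:
        raise FastqParseError(
            f"identifier {raw_id!r}: no space-separated mate token "
            "(pre-CASAVA-1.8 headers are not supported)"
        )
    fields = head.split(":")
    if len(fields) < 7:
        raise FastqParseError(
            f"identifier {raw_id!r}: expected 7 colon-delimited coordinate "
            f"fields, found {len(fields)}"
        )
    try:
        lane, tile, x, y = (int(v) for v in fields[3:7])
        mate = int(tail.split(":", 1)[0])
    except ValueError as exc:
        raise FastqParseError(f"identifier {raw_id!r}: {exc}") from None
    if mate not in (1, 2):
        raise FastqParseError(f"identifier {raw_id!r}: mate {mate} not in (1, 2)")
    return ClusterKey(fields[2], lane, tile, x, y), mate


def _read_from_fastq_record(title: str, seq: str, qual: str) -> SequenceRead:
    key, mate = parse_illumina_header(title)
    head = title.split(" ", 1)[0].split(":")
    try:
        run = int(head[1])
    except ValueError:
        raise FastqParseError(f"identifier {title!r}: run field not an integer")
    seq = seq.upper()
    quals = tuple(ord(c) - PHRED_OFFSET for c in qual)
    if any(q < 0 or q > MAX_PHRED for q in quals):
        raise FastqParseError(
            f"read {title!r}: quality characters outside the Phred+33 range"
        )
    return SequenceRead(
        raw_id=title,
        instrument=head[0],
        run=run,
        flowcell=key.flowcell,
        lane=key.lane,
        tile=key.tile,
        x=key.x,
        y=key.y,
        mate=mate,
        bases=seq,
        quals=quals,
        flagged=not VALID_BASES.issuperset(seq),
    )


def _open_text(source: Union[str, Path, IO]) -> tuple[IO, bool]:
    """Open ``source`` as a text stream, transparently decompressing gzip."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
    return io.TextIOWrapper(raw), True


class FastqReader:
    """Lazy iterator over :class:`SequenceRead` with a malformed-record tally.

    ``malformed`` counts records whose identifier could not be decoded as an
    Illumina coordinate header; those records are skipped, not yielded.
    A structurally truncated file (EOF inside a record) raises
    :class:`FastqParseError` naming the approximate line.
    """

    def __init__(self, source: Union[str, Path, IO]):
        self._stream, self._owns = _open_text(source)
        self.malformed = 0
        self.parsed = 0
        self.flagged = 0

    def __iter__(self) -> Iterator[SequenceRead]:
        n = 0
        it = FastqGeneralIterator(self._stream)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ near line {4 * n + 1}: {exc}"
                ) from exc
            n += 1
            try:
                read = _read_from_fastq_record(title, seq, qual)
            except FastqParseError:
                self.malformed += 1
                continue
            self.parsed += 1
            if read.flagged:
                self.flagged += 1
            yield read
        if self._owns:
            self._stream.close()


def parse_fastq(source: Union[str, Path, IO]) -> FastqReader:
    """Stream a FASTQ file (optionally gzipped) as :class:`SequenceRead`.

    The returned :class:`FastqReader` is single-use; its ``malformed``
    counter is valid once iteration has finished.
    """
    return FastqReader(source)


def write_fastq(records: Iterable[SequenceRead], dest: Union[str, Path, IO]) -> int:
    """Write records as 4-line Phred+33 FASTQ; returns the count written.

    Refuses quality scores above :data:`MAX_PHRED` (not encodable in +33).
    Output is plain text; pass a ``.gz`` path for gzip compression.
    """
    stream: IO
    to_close: list[IO] = []
    if hasattr(dest, "write"):
        stream = dest
    else:
        path = Path(dest)
        if path.suffix == ".gz":
            # mtime pinned to 0 so identical content gives identical bytes
            raw = open(path, "wb")
            stream = io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="wb", mtime=0))
            to_close = [stream, raw]
        else:
            stream = open(path, "w")
            to_close = [stream]
    n = 0
    try:
        for rec in records:
            if any(q < 0 or q > MAX_PHRED for q in rec.quals):
                raise ValueError(
                    f"read {rec.raw_id!r}: quality outside the encodable "
                    f"Phred+33 range 0..{MAX_PHRED}"
                )
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            stream.write(f"@{rec.raw_id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    finally:
        for fh in to_close:
            fh.close()
    return n
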