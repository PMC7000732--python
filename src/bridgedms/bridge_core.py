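"""Match non-overlapping paired-end reads to their cognate templates.

The pipeline implemented here exploits the fact that both mates of one
Illumina cluster carry the same flow-cell surface coordinate in their
FASTQ identifiers.  Each mate is independently anchor-trimmed to the short
variable region near its 5' end (where per-base error rates are lowest),
rejected if the region between the anchors has the wrong length (an
insertion or deletion) or contains a base below the quality floor, and the
survivors from the two files are then joined by their
:class:`~bridgedms.fastq_io.ClusterKey` into bridged templates.  No
sequence overlap between the mates is required, so the two variable loci
of a template may sit arbitrarily far apart in the gene.

Trimming layout for one mate (positions 0-based, intervals half-open)::

    [0..search_window) spacer   five_prime_anchor   inner   three_prime_anchor   tail
                                ^ located by scan   ^ fixed length               ignored

The 3' anchor is first checked at the fixed offset implied by
``expected_inner_length``; a read whose 3' anchor is found elsewhere has
gained or lost bases in the inner region and is rejected as an indel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

from .fastq_io import ClusterKey, SequenceRead, parse_fastq

__all__ = [
    "RejectReason",
    "Rejection",
    "Locus",
    "AnchorSpec",
    "TrimmedRead",
    "BridgedTemplate",
    "PairingReport",
    "FilterReport",
    "reverse_complement",
    "trim_read",
    "quality_filter",
    "to_sense",
    "pair_by_coordinates",
    "bridge_files",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class RejectReason(str, enum.Enum):
    ANCHOR_NOT_FOUND = "anchor_not_found"
    INDEL = "indel"
    LOW_QUALITY = "low_quality"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass(frozen=True, slots=True)
class Rejection:
    """Typed rejection of one read, with the failing stage's reason."""

    reason: RejectReason
    detail: str = ""


class Locus(NamedTuple):
    """A mutated codon within the inner region of one mate.

    ``codon_offset`` is 0-based into the *sense-strand* inner sequence.
    """

    label: str
    codon_offset: int


@dataclass(frozen=True)
class AnchorSpec:
    """Where the variable region sits within one mate's reads.

    ``search_window`` is the maximum offset scanned for the 5' anchor; it
    absorbs the 0-3 nt frame-shifting spacers added during amplicon
    library preparation to aid cluster identification.
    """

    mate: int
    five_prime_anchor: str
    three_prime_anchor: str
    expected_inner_length: int
    search_window: int = 6
    loci: tuple[Locus, ...] = ()
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        for anchor in (self.five_prime_anchor, self.three_prime_anchor):
            if not anchor or set(anchor) - set("ACGT"):
                raise ValueError(f"invalid anchor {anchor!r}: need non-empty A/C/G/T")
        if self.expected_inner_length <= 0:
            raise ValueError("expected_inner_length must be positive")
        object.__setattr__(self, "loci", tuple(Locus(*l) for l in self.loci))
        for locus in self.loci:
            if not 0 <= locus.codon_offset <= self.expected_inner_length - 3:
                raise ValueError(
                    f"locus {locus.label}: codon at offset {locus.codon_offset} "
                    f"does not fit in inner length {self.expected_inner_length}"
                )


@dataclass(frozen=True, slots=True)
class TrimmedRead:
    """The inner (between-anchor) region of one read, anchors excluded.

    ``sense`` is ``'+'`` when ``inner_bases`` is already the sense strand
    (forward reads), ``'-'`` for raw reverse reads before
    :func:`to_sense`.
    """

    key: ClusterKey
    mate: int
    inner_bases: str
    inner_quals: tuple[int, ...]
    sense: str = "+"


@dataclass(frozen=True, slots=True)
class BridgedTemplate:
    """Sense-strand inner sequences of both mates of one cluster."""

    key: ClusterKey
    segments: tuple[str, ...]
    segment_quals: tuple[tuple[int, ...], ...]


class PairingReport(NamedTuple):
    matched: int
    unmatched_forward: int
    unmatched_reverse: int
    collisions: int


@dataclass
class FilterReport:
    """Per-mate rejection tallies plus pairing statistics."""

    total: dict[int, int] = field(default_factory=dict)
    malformed: dict[int, int] = field(default_factory=dict)
    rejected: dict[int, dict[str, int]] = field(default_factory=dict)
    passed: dict[int, int] = field(default_factory=dict)
    pairing: PairingReport | None = None

    def to_rows(self) -> list[dict]:
        rows = []
        for mate in sorted(self.total):
            row = {
                "mate": mate,
                "total": self.total[mate],
                "malformed": self.malformed.get(mate, 0),
                "passed": self.passed.get(mate, 0),
            }
            for reason in RejectReason:
                row[reason.value] = self.rejected.get(mate, {}).get(reason.value, 0)
            rows.append(row)
        return rows


def reverse_complement(seq: str) -> str:
    """Reverse-complement over {A,C,G,T,N}; an involution, N maps to N."""
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _matches(haystack: str, start: int, pattern: str, max_mismatches: int) -> bool:
    if start < 0 or start + len(pattern) > len(haystack):
        return False
    if max_mismatches == 0:
        return haystack.startswith(pattern, start)
    mm = 0
    for i, c in enumerate(pattern):
        if haystack[start + i] != c:
            mm += 1
            if mm > max_mismatches:
                return False
    return True


def _find(haystack: str, pattern: str, start: int, max_mismatches: int) -> int:
    if max_mismatches == 0:
        return haystack.find(pattern, start)
    for pos in range(start, len(haystack) - len(pattern) + 1):
        if _matches(haystack, pos, pattern, max_mismatches):
            return pos
    return -1


def trim_read(read: SequenceRead, spec: AnchorSpec) -> TrimmedRead | Rejection:
    """Cut out the sequence strictly between the two anchors of ``spec``.

    The 5' anchor is scanned over offsets ``0..search_window``; the 3'
    anchor must then sit exactly ``expected_inner_length`` bases further
    in.  If the 3' anchor exists but at a different spacing, the read
    carries an insertion or deletion and is rejected (``indel``); if
    either anchor is absent, ``anchor_not_found``.
    """
    if read.mate != spec.mate:
        raise ValueError(f"read is mate {read.mate}, spec is for mate {spec.mate}")
    bases = read.bases
    mm = spec.max_mismatches
    a5, a3 = spec.five_prime_anchor, spec.three_prime_anchor
    start5 = -1
    for off in range(spec.search_window + 1):
        if _matches(bases, off, a5, mm):
            start5 = off
            break
    if start5 < 0:
        return Rejection(RejectReason.ANCHOR_NOT_FOUND, "5' anchor not in window")
    inner_start = start5 + len(a5)
    inner_end = inner_start + spec.expected_inner_length
    if _matches(bases, inner_end, a3, mm):
        quals = read.quals[inner_start:inner_end]
        return TrimmedRead(
            key=read.key,
            mate=read.mate,
            inner_bases=bases[inner_start:inner_end],
            inner_quals=tuple(quals),
            sense="+" if read.mate == 1 else "-",
        )
    found = _find(bases, a3, inner_start, mm)
    if found >= 0:
        delta = found - inner_end
        return Rejection(
            RejectReason.INDEL,
            f"inner length {found - inner_start} != {spec.expected_inner_length} "
            f"({'+' if delta > 0 else ''}{delta})",
        )
    return Rejection(RejectReason.ANCHOR_NOT_FOUND, "3' anchor not found")


def quality_filter(tr: TrimmedRead, min_q: int = 20, mode: str = "min") -> bool:
    """True when the trimmed region meets the quality floor.

    ``mode='min'`` (default) requires every retained base to reach
    ``min_q`` — the reads are trimmed first precisely so that only the
    high-quality 5'-proximal bases are judged.  ``mode='mean'`` applies
    the floor to the arithmetic mean quality instead.
    """
    if not tr.inner_quals:
        return min_q <= 0
    if mode == "min":
        return min(tr.inner_quals) >= min_q
    if mode == "mean":
        return sum(tr.inner_quals) / len(tr.inner_quals) >= min_q
    raise ValueError(f"unknown quality mode {mode!r}")


def to_sense(tr: TrimmedRead) -> TrimmedRead:
    """Return the sense-strand version of a trimmed read.

    Reverse reads are reverse-complemented and their quality list
    reversed to stay base-aligned; sense reads pass through unchanged.
    """
    if tr.sense == "+":
        return tr
    return replace(
        tr,
        inner_bases=reverse_complement(tr.inner_bases),
        inner_quals=tuple(reversed(tr.inner_quals)),
        sense="+",
    )


def _index_unique(
    reads: Iterable[TrimmedRead],
) -> tuple[dict[ClusterKey, TrimmedRead], int]:
    """Index reads by ClusterKey, discarding every record of any duplicated key.

    A duplicated cluster coordinate within one file is physically
    impossible on a flow cell, so duplicates signal corrupt input; all
    records sharing the key are dropped and counted as collisions.
    """
    index: dict[ClusterKey, TrimmedRead] = {}
    dup_counts: dict[ClusterKey, int] = {}
    for tr in reads:
        if tr.key in dup_counts:
            dup_counts[tr.key] += 1
        elif tr.key in index:
            dup_counts[tr.key] = 2
            del index[tr.key]
        else:
            index[tr.key] = tr
    return index, sum(dup_counts.values())


def pair_by_coordinates(
    fwd: Iterable[TrimmedRead], rev: Iterable[TrimmedRead]
) -> tuple[list[BridgedTemplate], PairingReport]:
    """Join forward and reverse trimmed reads sharing one ClusterKey.

    Reverse reads must already be sense-strand (see :func:`to_sense`).
    Output is sorted by key, so the result is independent of record order
    within either input.
    """
    fwd_idx, fwd_coll = _index_unique(fwd)
    rev_idx, rev_coll = _index_unique(rev)
    for tr in rev_idx.values():
        if tr.sense != "+":
            raise ValueError("reverse reads must be converted to sense strand first")
    shared = sorted(fwd_idx.keys() & rev_idx.keys())
    templates = [
        BridgedTemplate(
            key=key,
            segments=(fwd_idx[key].inner_bases, rev_idx[key].inner_bases),
            segment_quals=(fwd_idx[key].inner_quals, rev_idx[key].inner_quals),
        )
        for key in shared
    ]
    report = PairingReport(
        matched=len(shared),
        unmatched_forward=len(fwd_idx) - len(shared),
        unmatched_reverse=len(rev_idx) - len(shared),
        collisions=fwd_coll + rev_coll,
    )
    return templates, report


def _filter_mate(
    path: Union[str, Path],
    spec: AnchorSpec,
    min_q: int,
    quality_mode: str,
    report: FilterReport,
) -> list[TrimmedRead]:
    reader = parse_fastq(path)
    survivors: list[TrimmedRead] = []
    rejected: dict[str, int] = {}
    total = 0
    for read in reader:
        total += 1
        result = trim_read(read, spec)
        if isinstance(result, Rejection):
            rejected[result.reason.value] = rejected.get(result.reason.value, 0) + 1
            continue
        if not quality_filter(result, min_q=min_q, mode=quality_mode):
            key = RejectReason.LOW_QUALITY.value
            rejected[key] = rejected.get(key, 0) + 1
            continue
        survivors.append(result)
    mate = spec.mate
    report.total[mate] = total + reader.malformed
    report.malformed[mate] = reader.malformed
    report.rejected[mate] = rejected
    report.passed[mate] = len(survivors)
    return survivors


def bridge_files(
    r1: Union[str, Path],
    r2: Union[str, Path],
    specs: Sequence[AnchorSpec],
    min_q: int = 20,
    quality_mode: str = "min",
) -> tuple[list[BridgedTemplate], FilterReport]:
    """Full per-mate pipeline: trim, quality-filter, orient, pair.

    ``specs`` must contain exactly one :class:`AnchorSpec` per mate.
    Each mate is filtered independently; survivors are then paired by
    cluster coordinate, so a read lost on one mate simply leaves its
    partner unmatched.
    """
    by_mate = {s.mate: s for s in specs}
    if set(by_mate) != {1, 2} or len(specs) != 2:
        raise ValueError("bridge_files needs exactly one AnchorSpec per mate")
    report = FilterReport()
    fwd = _filter_mate(r1, by_mate[1], min_q, quality_mode, report)
    rev = [
        to_sense(tr) for tr in _filter_mate(r2, by_mate[2], min_q, quality_mode, report)
    ]
    templates, pairing = pair_by_coordinates(fwd, rev)
    report.pairing = pairing
    return templates, report
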