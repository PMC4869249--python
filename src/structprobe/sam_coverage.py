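"""Alignment filtering and strand-aware coverage counting.

Structure-probing libraries encode their signal in read placement:
for PARS, DMS-seq and icSHAPE the 5'-most aligned nucleotide of each
read marks a nuclease cleavage site or reverse-transcriptase stop, so
coverage is counted at that single base; for ds/ssRNA-seq the surviving
(nuclease-protected) fragment is the signal, so every aligned base
counts.

Before counting, reads are filtered on alignment quality: at most two
mismatches, edit distance at most two, and at most five mapping
locations (all thresholds configurable).  Multi-mapped reads that pass
the location cutoff contribute full weight at each reported mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from structprobe.tracks import CoverageMode, CoverageTrack

log = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 2
DEFAULT_MAX_EDIT = 2
DEFAULT_MAX_HITS = 5


class MissingTagError(ValueError):
    """An alignment lacks a tag required under the strict filter policy."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read, reduced to what filtering and counting need.

    ``blocks`` lists the aligned segments of a spliced alignment as
    0-based half-open (start, end) pairs; for an unspliced read it is
    the single pair ``[(start, end)]``.  ``mismatches``/``edit_distance``
    /``n_hits`` are None when the source alignment carried no
    corresponding tag; the filter policy decides how to treat that.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: Optional[int] = None
    edit_distance: Optional[int] = None
    n_hits: Optional[int] = None
    blocks: tuple = field(default=())

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: invalid strand {self.strand!r}")
        for name in ("mismatches", "edit_distance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"read {self.read_id}: negative {name}")
        if self.n_hits is not None and self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits must be >= 1")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))

    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def five_prime_position(self) -> int:
        """Genomic position of the biological 5' end.

        For a plus-strand read this is the leftmost aligned base; for a
        minus-strand read the 5' end is the *rightmost* aligned base.
        """
        return self.start if self.strand == "+" else self.end - 1


def filter_alignments(
    records: Iterable[AlignmentRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_edit: int = DEFAULT_MAX_EDIT,
    max_hits: int = DEFAULT_MAX_HITS,
    policy: str = "strict",
) -> Iterator[AlignmentRecord]:
    """Yield records passing all three alignment-quality cutoffs, in order.

    A record is retained when mismatches <= max_mismatch AND
    edit_distance <= max_edit AND n_hits <= max_hits (all inclusive).

    policy governs missing tags: "strict" raises
    :class:`MissingTagError`; "lenient" substitutes mismatches=0,
    n_hits=1, and lets the mismatch and edit-distance tags stand in for
    each other when only one is present.
    """
    if min(max_mismatch, max_edit, max_hits) < 0:
        raise ValueError("filter thresholds must be non-negative")
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    for rec in records:
        mm, ed, nh = rec.mismatches, rec.edit_distance, rec.n_hits
        if policy == "lenient":
            if mm is None:
                mm = ed if ed is not None else 0
            if ed is None:
                ed = mm
            if nh is None:
                nh = 1
        else:
            missing = [
                name
                for name, v in (
                    ("mismatches", mm),
                    ("edit_distance", ed),
                    ("n_hits", nh),
                )
                if v is None
            ]
            if missing:
                raise MissingTagError(
                    f"read {rec.read_id}: missing {', '.join(missing)} "
                    "(use policy='lenient' to substitute defaults)"
                )
        if mm <= max_mismatch and ed <= max_edit and nh <= max_hits:
            yield rec


def _check_bounds(rec: AlignmentRecord, chrom_length: int) -> None:
    if rec.start < 0 or rec.end > chrom_length:
        raise ValueError(
            f"read {rec.read_id} spans [{rec.start}, {rec.end}) outside "
            f"chromosome of length {chrom_length}"
        )


def _empty_tracks(chrom: str, chrom_length: int, mode: CoverageMode):
    return {
        strand: CoverageTrack(
            chrom=chrom,
            strand=strand,
            counts=np.zeros(chrom_length, dtype=np.int64),
            mode=mode,
        )
        for strand in ("+", "-")
    }


def five_prime_end_coverage(
    records: Iterable[AlignmentRecord],
    chrom_length: int,
    chrom: str = "",
) -> dict[str, CoverageTrack]:
    """Count only the biological 5'-most nucleotide of each read.

    Returns one track per strand.  The sum over both tracks equals the
    number of counted reads.
    """
    tracks = _empty_tracks(chrom, chrom_length, CoverageMode.FIVE_PRIME_END)
    for rec in records:
        if chrom and rec.chrom != chrom:
            log.warning("read %s on unexpected chrom %s: skipped", rec.read_id, rec.chrom)
            continue
        _check_bounds(rec, chrom_length)
        tracks[rec.strand].counts[rec.five_prime_position()] += 1
    return tracks


def full_read_coverage(
    records: Iterable[AlignmentRecord],
    chrom_length: int,
    chrom: str = "",
) -> dict[str, CoverageTrack]:
    """Count every aligned base of each read (gaps of spliced reads excluded).

    Returns one track per strand.  The sum over both tracks equals the
    total aligned length of the counted reads.
    """
    tracks = _empty_tracks(chrom, chrom_length, CoverageMode.FULL_READ)
    for rec in records:
        if chrom and rec.chrom != chrom:
            log.warning("read %s on unexpected chrom %s: skipped", rec.read_id, rec.chrom)
            continue
        _check_bounds(rec, chrom_length)
        counts = tracks[rec.strand].counts
        for s, e in rec.blocks:
            counts[s:e] += 1
    return tracks


def read_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM/BAM file as AlignmentRecords.

    Tag conventions follow the spliced aligners of the bowtie/TopHat
    lineage: XM = mismatch count, NM = edit distance, NH = number of
    reported mapping locations.  Absent tags are carried as None and
    resolved by the filter policy.
    """
    import pysam

    with pysam.AlignmentFile(path, require_index=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue

            def tag(name: str) -> Optional[int]:
                return aln.get_tag(name) if aln.has_tag(name) else None

            blocks = tuple(aln.get_blocks()) or (
                (aln.reference_start, aln.reference_end),
            )
            yield AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mismatches=tag("XM"),
                edit_distance=tag("NM"),
                n_hits=tag("NH"),
                blocks=blocks,
            )
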