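"""Per-position track containers: coverage counts and structure scores.

A :class:`CoverageTrack` holds non-negative integer counts over one
chromosome (or transcript) on one strand, tagged with the counting mode
that produced it — 5'-end counting (one count at the 5'-most aligned
nucleotide of each read, marking an RT stop or nuclease cleavage site)
or full-read counting (one count at every aligned base, the ds/ssRNA-seq
signal).

A :class:`ScoreTrack` holds real-valued structure scores with explicit
missing positions (NaN).  Missingness is information — a position a
scorer could not evaluate is never reported as zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

#: Recognized assay/method tags.  icSHAPE appears twice because the
#: in vitro and in vivo experiments are separate datasets.
METHODS = ("pars", "dms", "icshape", "icshape_invitro", "icshape_invivo", "dsss")

#: Methods whose raw score is a *reactivity* (higher = more unpaired),
#: inverted for display so that higher always means more paired.
REACTIVITY_METHODS = ("dms", "icshape", "icshape_invitro", "icshape_invivo")


class CoverageMode(str, enum.Enum):
    FIVE_PRIME_END = "five_prime_end"
    FULL_READ = "full_read"


@dataclass
class CoverageTrack:
    """Integer counts per 0-based position on one chromosome strand."""

    chrom: str
    strand: str
    counts: np.ndarray
    mode: CoverageMode

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("coverage counts must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.mode = CoverageMode(self.mode)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return int(self.counts.sum())

    def write_bedgraph(self, handle: TextIO) -> None:
        """Write non-zero runs as bedGraph intervals (0-based half-open)."""
        write_bedgraph(handle, self.chrom, self.counts)


@dataclass
class ScoreTrack:
    """Structure scores per 0-based position; NaN marks missing."""

    chrom: str
    strand: str
    method: str
    scores: np.ndarray
    #: genomic coordinate of scores[0]; lets a track cover a sub-span
    offset: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def iter_records(self) -> Iterable[tuple[str, int, str, str, float]]:
        """Yield (chrom, pos0, strand, method, score) for defined positions."""
        for i in np.flatnonzero(self.defined_mask):
            yield (
                self.chrom,
                self.offset + int(i),
                self.strand,
                self.method,
                float(self.scores[i]),
            )

    def write_tsv(self, handle: TextIO, header: bool = True) -> None:
        """Write defined positions as ``chrom pos0 strand method score``."""
        if header:
            handle.write("#chrom\tpos0\tstrand\tmethod\tscore\n")
        for chrom, pos, strand, method, score in self.iter_records():
            handle.write(f"{chrom}\t{pos}\t{strand}\t{method}\t{score!r}\n")


def write_coverage_tsv(handle: TextIO, tracks: Iterable[CoverageTrack]) -> None:
    """Write coverage tracks as sparse TSV with length/mode headers.

    Layout: ``#track chrom=<c> strand=<s> mode=<m> length=<L>`` header
    lines followed by ``chrom  pos0  strand  count`` rows for non-zero
    positions.  Round-trips through :func:`read_coverage_tsv`.
    """
    tracks = list(tracks)
    for t in tracks:
        handle.write(
            f"#track chrom={t.chrom} strand={t.strand} "
            f"mode={t.mode.value} length={len(t)}\n"
        )
    for t in tracks:
        for pos in np.flatnonzero(t.counts):
            handle.write(f"{t.chrom}\t{int(pos)}\t{t.strand}\t{int(t.counts[pos])}\n")


def read_coverage_tsv(handle: TextIO) -> dict[tuple[str, str], CoverageTrack]:
    """Read the sparse coverage TSV back into per-(chrom, strand) tracks."""
    headers: dict[tuple[str, str], tuple[CoverageMode, int]] = {}
    rows: list[tuple[str, int, str, int]] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#track "):
            kv = dict(item.split("=", 1) for item in line[len("#track "):].split())
            key = (kv["chrom"], kv["strand"])
            headers[key] = (CoverageMode(kv["mode"]), int(kv["length"]))
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"line {lineno}: expected 4 fields, got {len(fields)}")
        rows.append((fields[0], int(fields[1]), fields[2], int(fields[3])))
    tracks = {
        key: CoverageTrack(
            chrom=key[0], strand=key[1], counts=np.zeros(length, dtype=np.int64),
            mode=mode,
        )
        for key, (mode, length) in headers.items()
    }
    for chrom, pos, strand, count in rows:
        key = (chrom, strand)
        if key not in tracks:
            raise ValueError(f"data row for undeclared track {key}")
        tracks[key].counts[pos] = count
    return tracks


def write_bedgraph(handle: TextIO, chrom: str, values: np.ndarray) -> None:
    """Write an array as bedGraph, merging runs of equal non-zero value."""
    values = np.asarray(values)
    n = len(values)
    i = 0
    while i < n:
        v = values[i]
        j = i + 1
        while j < n and values[j] == v:
            j += 1
        if v != 0 and not (isinstance(v, float) and np.isnan(v)):
            handle.write(f"{chrom}\t{i}\t{j}\t{v}\n")
        i = j
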