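"""Flat-file score store with strand-aware interval queries.

Persists per-position structure scores for any number of method
datasets and answers genomic-interval lookups in sublinear time, using
sorted position arrays and binary search per (chromosome, strand).  A
dataset is loaded from the score TSV written by the scoring stage
(``chrom  pos0  strand  method  score``) or from bedGraph, and can be
exported back byte-for-byte.

Interval semantics are 0-based half-open throughout; a query for
[a, b) never returns position b.  Querying strand "." returns both
strands keyed by strand.  Minus-strand query results are delivered in
genomic order with an orientation flag so consumers can reverse them
into transcript (5'->3') order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import numpy as np

from structprobe.intervals import GenomicInterval
from structprobe.tracks import METHODS, ScoreTrack

log = logging.getLogger(__name__)

Record = tuple[str, int, str, str, float]  # chrom, pos0, strand, method, score


class StoreFormatError(ValueError):
    """A score file fails to parse; the message names the line."""


@dataclass
class ManifestEntry:
    """One dataset of the store: a method in a species and condition."""

    method: str
    species: str = ""
    condition: str = ""  # e.g. in_vitro / in_vivo
    source: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.method, self.species, self.condition)


@dataclass
class IntervalScores:
    """Scores of one method over one queried interval, genomic order.

    ``by_strand`` maps strand to an array of length len(interval) with
    NaN at positions absent from the store.  When the query strand is
    "-", ``reverse_for_transcript`` signals that downstream consumers
    must reverse the arrays to obtain transcript (5'->3') orientation.
    """

    method: str
    interval: GenomicInterval
    by_strand: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def reverse_for_transcript(self) -> bool:
        return self.interval.strand == "-"


class _Dataset:
    """Sorted per-(chrom, strand) position/score arrays for one method."""

    def __init__(self, method: str):
        self.method = method
        self._records: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._pending: dict[tuple[str, str], tuple[list, list]] = {}

    def add(self, chrom: str, pos: int, strand: str, score: float) -> None:
        positions, scores = self._pending.setdefault((chrom, strand), ([], []))
        positions.append(pos)
        scores.append(score)

    def finalize(self, source: str = "") -> None:
        for key, (positions, scores) in self._pending.items():
            pos = np.asarray(positions, dtype=np.int64)
            sc = np.asarray(scores, dtype=np.float64)
            order = np.argsort(pos, kind="stable")
            pos, sc = pos[order], sc[order]
            dup = np.flatnonzero(np.diff(pos) == 0)
            if dup.size:
                chrom, strand = key
                raise StoreFormatError(
                    f"{source or 'input'}: duplicate position {pos[dup[0]]} "
                    f"on {chrom} strand {strand} for method {self.method}"
                )
            if key in self._records:
                old_pos, old_sc = self._records[key]
                pos = np.concatenate([old_pos, pos])
                sc = np.concatenate([old_sc, sc])
                order = np.argsort(pos, kind="stable")
                pos, sc = pos[order], sc[order]
                if (np.diff(pos) == 0).any():
                    raise StoreFormatError(
                        f"{source or 'input'}: position already present in "
                        f"dataset {self.method}"
                    )
            self._records[key] = (pos, sc)
        self._pending.clear()

    def slice(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        out = np.full(end - start, np.nan)
        entry = self._records.get((chrom, strand))
        if entry is None:
            return out
        pos, sc = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out[pos[lo:hi] - start] = sc[lo:hi]
        return out

    def iter_records(self) -> Iterable[Record]:
        for (chrom, strand) in sorted(self._records):
            pos, sc = self._records[(chrom, strand)]
            for p, s in zip(pos, sc):
                yield (chrom, int(p), strand, self.method, float(s))

    def chroms(self) -> set[str]:
        return {chrom for chrom, _ in self._records}


class ScoreStore:
    """In-memory, flat-file-backed replacement for a score database."""

    def __init__(self) -> None:
        self._datasets: dict[str, _Dataset] = {}
        self._manifest: dict[tuple[str, str, str], ManifestEntry] = {}

    @property
    def methods(self) -> list[str]:
        return sorted(self._datasets)

    @property
    def manifest(self) -> list[ManifestEntry]:
        return list(self._manifest.values())

    # ------------------------------------------------------------------ load

    def load_scores(
        self,
        path_or_handle: Union[str, Path, TextIO],
        entry: Optional[ManifestEntry] = None,
        method: Optional[str] = None,
    ) -> ManifestEntry:
        """Load a score TSV (``chrom pos0 strand method score``).

        ``method`` restricts/overrides the method column; otherwise the
        column value is used (and must be a known method tag).  Raises
        :class:`StoreFormatError` naming the offending line on parse
        errors or duplicate (chrom, pos, strand) within one dataset.
        """
        if entry is not None and entry.key in self._manifest:
            raise ValueError(f"dataset {entry.key} already loaded")
        close = False
        if isinstance(path_or_handle, (str, Path)):
            source = str(path_or_handle)
            handle = open(path_or_handle)
            close = True
        else:
            source = getattr(path_or_handle, "name", "<stream>")
            handle = path_or_handle
        touched: dict[str, _Dataset] = {}
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise StoreFormatError(
                        f"{source}:{lineno}: expected 5 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                chrom, pos_s, strand, meth, score_s = fields
                try:
                    pos = int(pos_s)
                    score = float(score_s)
                except ValueError as exc:
                    raise StoreFormatError(f"{source}:{lineno}: {exc}") from None
                if strand not in ("+", "-"):
                    raise StoreFormatError(
                        f"{source}:{lineno}: invalid strand {strand!r}"
                    )
                meth = method or meth
                if meth not in METHODS:
                    raise StoreFormatError(
                        f"{source}:{lineno}: unknown method {meth!r}"
                    )
                ds = touched.get(meth)
                if ds is None:
                    ds = touched[meth] = self._datasets.setdefault(
                        meth, _Dataset(meth)
                    )
                ds.add(chrom, pos, strand, score)
        finally:
            if close:
                handle.close()
        for ds in touched.values():
            ds.finalize(source)
        entry = entry or ManifestEntry(
            method=method or (next(iter(touched)) if len(touched) == 1 else "mixed"),
            source=source,
        )
        self._manifest[entry.key] = entry
        return entry

    def add_track(self, track: ScoreTrack, entry: Optional[ManifestEntry] = None) -> None:
        """Register an in-memory ScoreTrack as (part of) a dataset."""
        ds = self._datasets.setdefault(track.method, _Dataset(track.method))
        for chrom, pos, strand, _meth, score in track.iter_records():
            ds.add(chrom, pos, strand, score)
        ds.finalize(f"track:{track.chrom}:{track.strand}")
        if entry is not None:
            self._manifest.setdefault(entry.key, entry)

    # ----------------------------------------------------------------- query

    def query_interval(
        self,
        interval: GenomicInterval,
        methods: Optional[Iterable[str]] = None,
    ) -> dict[str, IntervalScores]:
        """Fetch per-method sparse score vectors over [start, end).

        Positions absent from the store are NaN.  An unknown chromosome
        yields an all-missing result with a warning, not an error —
        absence of scores is an ordinary, reportable outcome.
        """
        if methods is None:
            methods = self.methods
        strands = ("+", "-") if interval.strand == "." else (interval.strand,)
        out: dict[str, IntervalScores] = {}
        for meth in methods:
            ds = self._datasets.get(meth)
            result = IntervalScores(method=meth, interval=interval)
            for strand in strands:
                if ds is None:
                    result.by_strand[strand] = np.full(len(interval), np.nan)
                else:
                    if interval.chrom not in ds.chroms():
                        log.warning(
                            "no %s scores on %s: returning all-missing",
                            meth,
                            interval.chrom,
                        )
                    result.by_strand[strand] = ds.slice(
                        interval.chrom, strand, interval.start, interval.end
                    )
            out[meth] = result
        return out

    # ---------------------------------------------------------------- export

    def export_tsv(
        self, handle: TextIO, methods: Optional[Iterable[str]] = None, header: bool = True
    ) -> None:
        """Dump stored records as score TSV; a loaded file round-trips."""
        if header:
            handle.write("#chrom\tpos0\tstrand\tmethod\tscore\n")
        for meth in sorted(methods if methods is not None else self.methods):
            ds = self._datasets.get(meth)
            if ds is None:
                continue
            for chrom, pos, strand, m, score in ds.iter_records():
                handle.write(f"{chrom}\t{pos}\t{strand}\t{m}\t{score!r}\n")

    def records(self, method: str) -> list[Record]:
        ds = self._datasets.get(method)
        return list(ds.iter_records()) if ds else []


def write_manifest(handle: TextIO, entries: Iterable[ManifestEntry]) -> None:
    for e in entries:
        handle.write(
            f"method={e.method}\tspecies={e.species}\t"
            f"condition={e.condition}\tsource={e.source}\n"
        )


def read_manifest(handle: TextIO) -> list[ManifestEntry]:
    entries = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kv = dict(item.split("=", 1) for item in line.split("\t"))
        entries.append(
            ManifestEntry(
                method=kv.get("method", ""),
                species=kv.get("species", ""),
                condition=kv.get("condition", ""),
                source=kv.get("source", ""),
            )
        )
    return entries
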