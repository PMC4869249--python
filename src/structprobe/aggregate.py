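"""Strand-aware meta-profiles over collections of equal-length regions.

Individual loci often have sparse structure scores (score density
depends on expression and sequencing depth), but averaging the scores
at each *relative* position across many functionally related regions —
all start codons, all matches to an RNA-binding-protein motif —
recovers robust structural trends such as the dip in secondary
structure around translation start and stop sites.

Profiles are built in transcript orientation: scores of minus-strand
regions are reversed so offset 0 is always the 5'-most position of the
region.  Missing scores are excluded from both numerator and
denominator of the mean; the number of contributing regions at each
offset is reported alongside.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import numpy as np

from structprobe.intervals import GenomicInterval
from structprobe.store import ScoreStore

log = logging.getLogger(__name__)

#: IUPAC nucleotide codes to the DNA bases they match (RNA input is
#: handled by mapping U -> T before matching).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class RegionSet:
    """Equal-length genomic regions to be aggregated into one profile."""

    regions: list[GenomicInterval]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("empty region set")
        lengths = {len(r) for r in self.regions}
        if len(lengths) != 1:
            raise ValueError(
                f"regions must all have the same length, got {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.regions[0])

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class AggregateProfile:
    """Per-offset mean score and contributing-region count for one method."""

    method: str
    length: int
    mean_score: np.ndarray  # NaN where no region contributed
    n_contrib: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def write_tsv(self, handle: TextIO, header: bool = True) -> None:
        if header:
            handle.write("#offset\tmethod\tmean\tn\n")
        for k in range(self.length):
            mean = self.mean_score[k]
            mean_s = "NA" if np.isnan(mean) else repr(float(mean))
            handle.write(f"{k}\t{self.method}\t{mean_s}\t{int(self.n_contrib[k])}\n")


def read_bed(path_or_handle: Union[str, Path, TextIO]) -> RegionSet:
    """Parse BED3/BED6 into a length-uniform RegionSet.

    BED6 strand is honored; BED3 records default to "+".  Mixed region
    lengths are an error listing the offending lines, since a
    meta-profile is only meaningful over equal-length windows.
    """
    close = False
    if isinstance(path_or_handle, (str, Path)):
        handle = open(path_or_handle)
        close = True
        name = str(path_or_handle)
    else:
        handle = path_or_handle
        name = getattr(handle, "name", "<stream>")
    regions: list[GenomicInterval] = []
    lengths: dict[int, list[int]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{name}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            try:
                iv = GenomicInterval(chrom, int(start_s), int(end_s), strand)
            except ValueError as exc:
                raise ValueError(f"{name}:{lineno}: {exc}") from None
            regions.append(iv)
            lengths.setdefault(len(iv), []).append(lineno)
    finally:
        if close:
            handle.close()
    if not regions:
        raise ValueError(f"{name}: no regions")
    if len(lengths) > 1:
        detail = "; ".join(
            f"length {L} at lines {', '.join(map(str, ln[:5]))}"
            for L, ln in sorted(lengths.items())
        )
        raise ValueError(f"{name}: regions have mixed lengths ({detail})")
    return RegionSet(regions=regions, label=name)


def extract_oriented_profile(
    store: ScoreStore, interval: GenomicInterval, method: str
) -> np.ndarray:
    """Scores over one region, listed 5'->3' in transcript orientation.

    Minus-strand regions have their genomic-order score vector reversed;
    positions with no stored score are NaN.
    """
    strand = "+" if interval.strand == "." else interval.strand
    iv = GenomicInterval(interval.chrom, interval.start, interval.end, strand)
    result = store.query_interval(iv, methods=[method])[method]
    scores = result.by_strand[strand]
    if result.reverse_for_transcript:
        scores = scores[::-1]
    return scores


def aggregate_mean(
    store: ScoreStore, regionset: RegionSet, method: str
) -> AggregateProfile:
    """Unweighted per-offset mean of oriented scores across all regions.

    ``mean_score[k]`` averages the non-missing scores at offset k;
    ``n_contrib[k]`` counts the regions that supplied one.  An offset
    where every region is missing stays NaN with n_contrib 0.
    """
    L = regionset.length
    total = np.zeros(L)
    n = np.zeros(L, dtype=np.int64)
    for region in regionset.regions:
        scores = extract_oriented_profile(store, region, method)
        ok = ~np.isnan(scores)
        total[ok] += scores[ok]
        n[ok] += 1
    mean = np.full(L, np.nan)
    np.divide(total, n, out=mean, where=n > 0)
    return AggregateProfile(
        method=method,
        length=L,
        mean_score=mean,
        n_contrib=n,
        label=regionset.label,
        meta={"n_regions": len(regionset)},
    )


def make_feature_windows(
    anchors: Sequence[GenomicInterval],
    up: int,
    down: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    label: str = "",
) -> RegionSet:
    """Expand feature spans into fixed flanking windows, strand-aware.

    ``up`` nucleotides are added on the 5' side and ``down`` on the 3'
    side *in transcript orientation*: for a minus-strand anchor the 5'
    flank extends to higher genomic coordinates.  With 3-nt anchors and
    up = down = 9 the feature occupies 0-based offsets 9-11 of each
    21-nt window; with 7-nt anchors and 21-nt flanks, offsets 21-27 of
    a 49-nt window.

    Windows running past chromosome bounds are dropped with a warning
    (bounds below 0 always checked; upper bounds only when
    ``chrom_lengths`` is given).
    """
    if up < 0 or down < 0:
        raise ValueError("flank sizes must be non-negative")
    regions = []
    for anchor in anchors:
        if anchor.strand == "-":
            start, end = anchor.start - down, anchor.end + up
        else:
            start, end = anchor.start - up, anchor.end + down
        limit = None if chrom_lengths is None else chrom_lengths.get(anchor.chrom)
        if start < 0 or (limit is not None and end > limit):
            log.warning(
                "window [%d, %d) around %s anchor exceeds bounds of %s: dropped",
                start,
                end,
                anchor.strand,
                anchor.chrom,
            )
            continue
        regions.append(GenomicInterval(anchor.chrom, start, end, anchor.strand))
    if not regions:
        raise ValueError("no windows remain after bounds filtering")
    return RegionSet(regions=regions, label=label)


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif:
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_scan(
    sequences: Union[str, Path, Mapping[str, str]],
    motif: str,
) -> list[GenomicInterval]:
    """Exact IUPAC matches of ``motif`` on both strands of the sequences.

    ``sequences`` is a FASTA path or a mapping of name to sequence.
    RNA alphabets are accepted (U treated as T) in both motif and
    sequence.  Minus-strand hits — positions where the reverse
    complement of the sequence matches the motif — are reported as
    minus-strand intervals of the match span in plus-strand
    coordinates.  Overlapping matches are all reported.
    """
    if isinstance(sequences, (str, Path)):
        from pyfaidx import Fasta

        fasta = Fasta(str(sequences))
        seqs: Mapping[str, str] = {name: str(fasta[name]) for name in fasta.keys()}
    else:
        seqs = sequences
    motif_norm = motif.upper().replace("U", "T")
    fwd = re.compile(f"(?=({_iupac_regex(motif_norm)}))")
    rev = re.compile(f"(?=({_iupac_regex(reverse_complement(motif_norm))}))")
    m = len(motif_norm)
    hits: list[GenomicInterval] = []
    for name, seq in seqs.items():
        seq_norm = seq.upper().replace("U", "T")
        for match in fwd.finditer(seq_norm):
            hits.append(GenomicInterval(name, match.start(), match.start() + m, "+"))
        for match in rev.finditer(seq_norm):
            hits.append(GenomicInterval(name, match.start(), match.start() + m, "-"))
    hits.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return hits


def write_bed(handle: TextIO, regions: Iterable[GenomicInterval], name: str = ".") -> None:
    """Write intervals as BED6."""
    for i, iv in enumerate(regions):
        strand = iv.strand if iv.strand in ("+", "-") else "+"
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}{i}\t0\t{strand}\n")
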