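"""Genomic interval type and coordinate-convention helpers.

All internal coordinates are 0-based, half-open (BED convention).
User-facing region strings like ``chr19:9982728-9982762`` follow the
genome-browser convention (1-based, inclusive) and are converted at the
CLI/parse edge only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated genomic span, 0-based half-open.

    ``strand == "."`` means "both strands" in query contexts.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_region_string(cls, region: str, strand: str = ".") -> "GenomicInterval":
        """Parse a 1-based inclusive browser-style region string.

        ``chr19:9982728-9982762`` becomes the 0-based half-open span
        [9982727, 9982762), i.e. 35 positions.
        """
        m = _REGION_RE.match(region.replace(",", ""))
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        start1 = int(m.group("start"))
        end1 = int(m.group("end"))
        if start1 < 1 or end1 < start1:
            raise ValueError(f"invalid 1-based region {region!r}")
        return cls(m.group("chrom"), start1 - 1, end1, strand)

    def to_region_string(self) -> str:
        """Render as a 1-based inclusive browser-style string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"
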