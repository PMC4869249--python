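"""Synthetic probing data with known structure, for testing every stage.

The probing assays share one contract: the reagent reacts with (or the
nuclease cleaves) nucleotides according to their base-pairing status.
The simulator encodes exactly that contract — given a known
paired/unpaired mask (e.g. a hairpin: two stems flanking an unpaired
loop), it draws per-position Poisson counts whose means differ between
paired and unpaired positions in the direction each assay design
dictates.  Scoring simulated counts and checking that loop positions
rank below stem positions after polarity orientation exercises the full
pipeline without any external data.

Also provides a SAM generator with controlled mismatch/edit-distance/
mapping-location tags for testing alignment filtering, and a toy
annotation generator (codon anchors + matching FASTA) for the
aggregation machinery.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from structprobe.scoring import DmsInputs, DsSsInputs, IcShapeInputs, ParsInputs
from structprobe.tracks import CoverageMode, CoverageTrack

ASSAYS = ("dms_like", "icshape_like", "pars_like", "dsss_like")


@dataclass(frozen=True)
class StructureMask:
    """Known base-pairing state per position (True = paired)."""

    paired: tuple

    def __post_init__(self) -> None:
        if len(self.paired) < 1:
            raise ValueError("mask must have length >= 1")
        object.__setattr__(self, "paired", tuple(bool(p) for p in self.paired))

    def __len__(self) -> int:
        return len(self.paired)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.paired, dtype=bool)

    @classmethod
    def hairpin(cls, stem: int = 15, loop: int = 5) -> "StructureMask":
        """Stem-loop mask: ``stem`` paired, ``loop`` unpaired, ``stem`` paired.

        Defaults give a 35-nt hairpin with a 5-nt unpaired loop, the
        shape of an iron-response-element-like stem-loop.
        """
        if stem < 1 or loop < 1:
            raise ValueError("stem and loop must be >= 1")
        return cls(tuple([True] * stem + [False] * loop + [True] * stem))

    @property
    def loop_positions(self) -> np.ndarray:
        return np.flatnonzero(~self.array)

    @property
    def stem_positions(self) -> np.ndarray:
        return np.flatnonzero(self.array)


@dataclass
class SimulationConfig:
    """Count-model parameters.

    ``depth`` is the expected count per position in the unenriched
    state; ``signal_ratio`` multiplies the Poisson mean at positions
    the assay's reagent prefers (default 5-fold).  Fixing ``seed``
    makes output byte-identical.
    """

    depth: float = 200.0
    signal_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.signal_ratio <= 1:
            raise ValueError("signal_ratio must exceed 1")


def _track(counts: np.ndarray, mode: CoverageMode, chrom: str = "syn") -> CoverageTrack:
    return CoverageTrack(chrom=chrom, strand="+", counts=counts, mode=mode)


def simulate_probe_counts(mask: StructureMask, config: SimulationConfig, assay: str):
    """Draw the coverage tracks one assay's scorer consumes.

    Returns the matching scorer-input object:

    * ``dms_like`` -> :class:`DmsInputs` — treated 5'-end counts
      elevated at unpaired positions; denatured control flat (every
      position reactive once denatured).
    * ``icshape_like`` -> :class:`IcShapeInputs` — treated counts
      elevated at unpaired positions; DMSO control flat; background
      base density B drawn as the (larger) full-read depth of the DMSO
      library.
    * ``pars_like`` -> :class:`ParsInputs` — V1 cleavage elevated at
      paired positions, S1 at unpaired.
    * ``dsss_like`` -> :class:`DsSsInputs` — RNaseONE full-read
      coverage elevated over paired runs, V1 over unpaired runs.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    rng = np.random.default_rng(config.seed)
    paired = mask.array
    n = len(mask)
    base = config.depth
    hot = config.depth * config.signal_ratio
    fp = CoverageMode.FIVE_PRIME_END
    fr = CoverageMode.FULL_READ

    if assay == "dms_like":
        d_mean = np.where(paired, base, hot)
        D = rng.poisson(d_mean, n)
        C = rng.poisson(hot, n)  # denatured control: uniformly reactive
        return DmsInputs(D=_track(D, fp), C=_track(C, fp))

    if assay == "icshape_like":
        d_mean = np.where(paired, base, hot)
        D = rng.poisson(d_mean, n)
        C = rng.poisson(base, n)  # DMSO control: no reagent reactivity
        # full-read depth of the DMSO library; each read covers many
        # bases, so base density runs well above the 5'-end counts
        B = rng.poisson(base * 5, n)
        return IcShapeInputs(D=_track(D, fp), C=_track(C, fp), B=_track(B, fp))

    if assay == "pars_like":
        V1 = rng.poisson(np.where(paired, hot, base), n)
        S1 = rng.poisson(np.where(paired, base, hot), n)
        return ParsInputs(V1=_track(V1, fp), S1=_track(S1, fp))

    # dsss_like: exhaustive digestion — surviving fragments cover the
    # protected state, so ONE (ssRNase survivors) is high over paired runs
    ONE = rng.poisson(np.where(paired, hot, base), n)
    V1 = rng.poisson(np.where(paired, base, hot), n)
    return DsSsInputs(ONE=_track(ONE, fr), V1=_track(V1, fr))


def simulate_alignments(
    n_reads: int,
    read_length: int = 36,
    chrom_length: int = 1000,
    chrom: str = "syn",
    mismatches: Optional[Sequence[int]] = None,
    edit_distances: Optional[Sequence[int]] = None,
    n_hits: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> str:
    """Generate SAM text with controlled XM/NM/NH tag values.

    Tag sequences are cycled over the reads; by default mismatches and
    edit distance are 0 and every read maps uniquely.  Positions and
    strands are drawn uniformly.  Output is a syntactically valid,
    header-bearing SAM string, deterministic per seed.
    """
    if n_reads < 0 or read_length < 1 or chrom_length < read_length:
        raise ValueError("need n_reads >= 0 and 1 <= read_length <= chrom_length")
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{chrom_length}"]
    for i in range(n_reads):
        mm = int(mismatches[i % len(mismatches)]) if mismatches else 0
        ed = int(edit_distances[i % len(edit_distances)]) if edit_distances else mm
        nh = int(n_hits[i % len(n_hits)]) if n_hits else 1
        start = int(rng.integers(0, chrom_length - read_length + 1))
        flag = 16 if rng.random() < 0.5 else 0
        seq = "".join(rng.choice(list("ACGT"), size=read_length))
        lines.append(
            f"read{i}\t{flag}\t{chrom}\t{start + 1}\t255\t{read_length}M\t*\t0\t0\t"
            f"{seq}\t*\tXM:i:{mm}\tNM:i:{ed}\tNH:i:{nh}"
        )
    return "\n".join(lines) + "\n"


def make_toy_annotation(
    n_genes: int, seed: int = 0, spacing: int = 60, flank: int = 25
) -> tuple[str, str]:
    """Toy codon anchors (BED6) with a consistent chromosome FASTA.

    Places ``n_genes`` 3-nt start-codon anchors on alternating strands
    along one synthetic chromosome, with the codon sequence (ATG on the
    plus strand, CAT in plus-strand coordinates for minus-strand genes)
    embedded in otherwise random sequence.  Returns (bed_text,
    fasta_text); coordinates in the BED match the FASTA.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "toy1"
    length = flank * 2 + n_genes * spacing
    seq = list(rng.choice(list("ACGT"), size=length))
    bed_lines = []
    for g in range(n_genes):
        start = flank + g * spacing
        strand = "+" if g % 2 == 0 else "-"
        codon = "ATG" if strand == "+" else "CAT"  # ATG on the transcript
        seq[start : start + 3] = list(codon)
        bed_lines.append(f"{chrom}\t{start}\t{start + 3}\tgene{g}\t0\t{strand}")
    fasta = f">{chrom}\n"
    joined = "".join(seq)
    fasta += "\n".join(joined[i : i + 60] for i in range(0, length, 60)) + "\n"
    return "\n".join(bed_lines) + "\n", fasta
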