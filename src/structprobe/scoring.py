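"""Per-nucleotide structure scores for the four probing-assay designs.

Each assay gets its own scorer because each experimental design defines
its own signal:

* DMS-seq — reactivity of the native library relative to a denatured
  control, each normalized by its library maximum:
  ``R_i = (D_i / D_max) / (C_i / C_max)``.  High R = unpaired.
* icSHAPE — treated 5'-end counts minus DMSO-control counts, scaled by
  the per-base sequencing depth of the DMSO library:
  ``R_i = (D_i - C_i) / B_i``.  High R = unpaired.
* PARS — generalized log ratio of dsRNase-V1 over ssRNase-S1 cleavage
  counts, summed over a 5-nt rolling window around each position with a
  per-position pseudocount.  Positive S = paired.
* ds/ssRNA-seq — generalized log ratio of full-read coverage in the
  RNaseONE (dsRNA-protected) library over the V1 (ssRNA-protected)
  library: ``S_i = log2((ONE_i + 1) / (V1_i + 1))``.  Positive S = paired.

Positions a scorer cannot evaluate are NaN in the output ScoreTrack,
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from structprobe.tracks import CoverageMode, CoverageTrack, ScoreTrack

ArrayLike = Union[CoverageTrack, np.ndarray, list]


class UnscoreableError(ValueError):
    """The normalization scope contains no signal (library maximum zero)."""


def _counts(
    track: ArrayLike, expected_mode: Optional[CoverageMode] = None
) -> np.ndarray:
    """Extract a float count array, checking the counting mode when known."""
    if isinstance(track, CoverageTrack):
        if expected_mode is not None and track.mode != expected_mode:
            raise ValueError(
                f"expected a {expected_mode.value} track, got {track.mode.value}"
            )
        return track.counts.astype(np.float64)
    arr = np.asarray(track, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("count input must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _context(*tracks: ArrayLike) -> tuple[str, str]:
    """Pick up chrom/strand from the first CoverageTrack argument."""
    for t in tracks:
        if isinstance(t, CoverageTrack):
            return t.chrom, t.strand
    return "", "+"


def _check_aligned(*arrays: np.ndarray) -> int:
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"input tracks have differing lengths: {sorted(lengths)}")
    return lengths.pop()


@dataclass
class DmsInputs:
    """DMS-treated native library D and denatured control C (5'-end counts).

    ``d_max``/``c_max`` override the normalization maxima; by default
    they are the maxima over the supplied tracks, so the supplied span
    *is* the normalization scope (per-region normalization).  Pass
    whole-library maxima for global-track scope.
    """

    D: ArrayLike
    C: ArrayLike
    d_max: Optional[float] = None
    c_max: Optional[float] = None


def dms_reactivity(inputs: DmsInputs) -> ScoreTrack:
    """``R_i = (D_i/D_max) / (C_i/C_max)``; missing where C_i = 0.

    Raises :class:`UnscoreableError` when either library maximum over
    the normalization scope is zero.
    """
    D = _counts(inputs.D, CoverageMode.FIVE_PRIME_END)
    C = _counts(inputs.C, CoverageMode.FIVE_PRIME_END)
    _check_aligned(D, C)
    d_max = float(D.max()) if inputs.d_max is None else float(inputs.d_max)
    c_max = float(C.max()) if inputs.c_max is None else float(inputs.c_max)
    if d_max <= 0 or c_max <= 0:
        raise UnscoreableError(
            f"normalization scope has no signal (D_max={d_max}, C_max={c_max})"
        )
    if (D > d_max).any() or (C > c_max).any():
        raise ValueError("library maximum smaller than an observed count")
    scores = np.full(len(D), np.nan)
    defined = C > 0
    scores[defined] = (D[defined] / d_max) / (C[defined] / c_max)
    chrom, strand = _context(inputs.D, inputs.C)
    return ScoreTrack(
        chrom=chrom,
        strand=strand,
        method="dms",
        scores=scores,
        meta={"d_max": d_max, "c_max": c_max},
    )


@dataclass
class IcShapeInputs:
    """Reagent-treated library D, DMSO control C (5'-end counts), and the
    per-position background base density B (full-read depth of the DMSO
    library)."""

    D: ArrayLike
    C: ArrayLike
    B: ArrayLike
    floor_at_zero: bool = False


def icshape_reactivity(inputs: IcShapeInputs) -> ScoreTrack:
    """``R_i = (D_i - C_i) / B_i``; missing where B_i = 0.

    Negative reactivities (control exceeding treatment) are retained by
    default so downstream display inversion loses no information; set
    ``floor_at_zero`` to clip them.
    """
    D = _counts(inputs.D, CoverageMode.FIVE_PRIME_END)
    C = _counts(inputs.C, CoverageMode.FIVE_PRIME_END)
    B = _counts(inputs.B)
    _check_aligned(D, C, B)
    scores = np.full(len(D), np.nan)
    defined = B > 0
    scores[defined] = (D[defined] - C[defined]) / B[defined]
    if inputs.floor_at_zero:
        np.clip(scores, 0.0, None, out=scores)
    chrom, strand = _context(inputs.D, inputs.C)
    return ScoreTrack(chrom=chrom, strand=strand, method="icshape", scores=scores)


@dataclass
class ParsInputs:
    """dsRNase V1 and ssRNase S1 libraries (5'-end cleavage counts).

    The score at position i is a generalized log ratio over the window
    j = i-window_halfwidth .. i+window_halfwidth (5 nt at the default
    halfwidth of 2), with ``per_position_pseudocount`` added once per
    window position to numerator and denominator.  Any common constant
    divisor of the two window sums cancels in the ratio, so only this
    additive constant matters.
    """

    V1: ArrayLike
    S1: ArrayLike
    window_halfwidth: int = 2
    per_position_pseudocount: float = 1.0


def pars_score(inputs: ParsInputs) -> ScoreTrack:
    """Windowed generalized log2 ratio of V1 over S1 cleavage counts.

    With W_i the in-bounds positions of [i-h, i+h]:

        S_i = log2( (sum V1_j + |W_i| * c) / (sum S1_j + |W_i| * c) )

    Positions whose window has zero coverage in *both* libraries are
    missing.  Boundary windows are truncated to in-bounds positions,
    with the pseudocount scaled to the actual window size.
    """
    if inputs.window_halfwidth < 0:
        raise ValueError("window_halfwidth must be non-negative")
    if inputs.per_position_pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    V1 = _counts(inputs.V1, CoverageMode.FIVE_PRIME_END)
    S1 = _counts(inputs.S1, CoverageMode.FIVE_PRIME_END)
    n = _check_aligned(V1, S1)
    h = inputs.window_halfwidth
    c = inputs.per_position_pseudocount

    # cumulative sums give O(1) window sums; windows truncate at the ends
    cv = np.concatenate([[0.0], np.cumsum(V1)])
    cs = np.concatenate([[0.0], np.cumsum(S1)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    wsize = (hi - lo).astype(np.float64)
    v1_sum = cv[hi] - cv[lo]
    s1_sum = cs[hi] - cs[lo]

    scores = np.full(n, np.nan)
    defined = (v1_sum > 0) | (s1_sum > 0)
    scores[defined] = np.log2(
        (v1_sum[defined] + wsize[defined] * c)
        / (s1_sum[defined] + wsize[defined] * c)
    )
    chrom, strand = _context(inputs.V1, inputs.S1)
    return ScoreTrack(
        chrom=chrom,
        strand=strand,
        method="pars",
        scores=scores,
        meta={"window_halfwidth": h, "pseudocount": c},
    )


@dataclass
class DsSsInputs:
    """RNaseONE (ssRNase; survivors are dsRNA) and RNase V1 (dsRNase;
    survivors are ssRNA) exhaustive-digestion libraries, as full-read
    coverage tracks."""

    ONE: ArrayLike
    V1: ArrayLike
    pseudocount: float = 1.0


def dsss_score(inputs: DsSsInputs) -> ScoreTrack:
    """``S_i = log2((ONE_i + c) / (V1_i + c))``, defined everywhere.

    The pseudocount (default 1) keeps every position finite, so a
    position covered in only one library still carries directional
    structural evidence.
    """
    if inputs.pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ONE = _counts(inputs.ONE, CoverageMode.FULL_READ)
    V1 = _counts(inputs.V1, CoverageMode.FULL_READ)
    _check_aligned(ONE, V1)
    c = inputs.pseudocount
    scores = np.log2((ONE + c) / (V1 + c))
    chrom, strand = _context(inputs.ONE, inputs.V1)
    return ScoreTrack(chrom=chrom, strand=strand, method="dsss", scores=scores)
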