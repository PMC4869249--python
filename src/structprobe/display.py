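"""Harmonization of structure scores for cross-method comparison.

The four assays emit scores on incommensurable scales and with opposite
polarities: PARS and ds/ssRNA-seq scores grow with *pairing* evidence,
while DMS-seq and icSHAPE report *reactivity*, which grows with
unpairedness.  For display, each method's segment is z-scored over the
queried window (scaled and re-centered) and reactivity methods are
inverted, so that in every rendered series a higher value means more
evidence of base pairing.  Raw scores are always exported alongside the
plot — harmonization is a view, never a replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from structprobe.tracks import METHODS, REACTIVITY_METHODS


@dataclass
class DisplayTrack:
    """One method's harmonized series plus the untransformed raw scores.

    After harmonization the polarity contract holds for every method:
    higher displayed value = more evidence of pairing.
    """

    method: str
    values: np.ndarray  # harmonized, NaN preserved
    raw: np.ndarray  # pre-display scores, NaN preserved


def standardize(segment: Sequence[float]) -> np.ndarray:
    """Z-transform over the non-missing values of a window segment.

    Uses the population standard deviation; a zero-variance segment
    maps every defined value to 0.  NaN positions are preserved.
    """
    seg = np.asarray(segment, dtype=np.float64)
    out = np.full_like(seg, np.nan)
    ok = ~np.isnan(seg)
    if not ok.any():
        return out
    mean = seg[ok].mean()
    sd = seg[ok].std()  # population (ddof=0)
    if sd == 0:
        out[ok] = 0.0
    else:
        out[ok] = (seg[ok] - mean) / sd
    return out


def orient_polarity(segment: Sequence[float], method: str) -> np.ndarray:
    """Flip reactivity-type methods so higher always means more paired.

    DMS and icSHAPE segments are negated; PARS and ds/ssRNA-seq pass
    through unchanged.  Unknown method tags are an error.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method tag {method!r}")
    seg = np.asarray(segment, dtype=np.float64)
    return -seg if method in REACTIVITY_METHODS else seg.copy()


def harmonize(segment: Sequence[float], method: str) -> DisplayTrack:
    """Standardize and polarity-orient one method's window segment."""
    raw = np.asarray(segment, dtype=np.float64)
    return DisplayTrack(
        method=method,
        values=orient_polarity(standardize(raw), method),
        raw=raw.copy(),
    )


def write_raw_tsv(
    handle: TextIO, tracks: Iterable[DisplayTrack], header: bool = True
) -> None:
    """Export untransformed scores as ``offset method score`` (NA = missing)."""
    if header:
        handle.write("#offset\tmethod\tscore\n")
    for track in tracks:
        for k, v in enumerate(track.raw):
            v_s = "NA" if np.isnan(v) else repr(float(v))
            handle.write(f"{k}\t{track.method}\t{v_s}\n")


def read_raw_tsv(handle: TextIO) -> dict[str, np.ndarray]:
    """Parse a raw-score export back into per-method arrays."""
    rows: dict[str, dict[int, float]] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        offset_s, method, score_s = line.split("\t")
        rows.setdefault(method, {})[int(offset_s)] = (
            np.nan if score_s == "NA" else float(score_s)
        )
    out = {}
    for method, vals in rows.items():
        n = max(vals) + 1
        arr = np.full(n, np.nan)
        for k, v in vals.items():
            arr[k] = v
        out[method] = arr
    return out


def render(
    tracks: Sequence[DisplayTrack],
    svg_path: Union[str, Path],
    raw_tsv_path: Optional[Union[str, Path]] = None,
    title: str = "",
    annotations: Optional[dict] = None,
) -> list[str]:
    """Render harmonized series as a deterministic SVG line plot.

    All tracks share one x-axis and must have equal length.  Tracks
    with no defined values are omitted from the plot and noted in the
    legend.  The untransformed scores are written to ``raw_tsv_path``
    alongside the figure.  Returns the list of methods actually drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = {len(t.values) for t in tracks}
    if len(lengths) > 1:
        raise ValueError(f"tracks have differing lengths: {sorted(lengths)}")

    with matplotlib.rc_context({"svg.hashsalt": "structprobe"}):
        fig, ax = plt.subplots(figsize=(8, 4))
        drawn = []
        omitted = []
        for track in tracks:
            if np.isnan(track.values).all():
                omitted.append(track.method)
                continue
            x = np.arange(len(track.values))
            ax.plot(x, track.values, marker=".", label=track.method)
            drawn.append(track.method)
        ax.set_xlabel("position in window (0-based)")
        ax.set_ylabel("harmonized score (higher = more paired)")
        if title:
            ax.set_title(title)
        handles, labels = ax.get_legend_handles_labels()
        for meth in omitted:
            labels.append(f"{meth} (no scores)")
            handles.append(plt.Line2D([], [], linestyle="none"))
        if handles:
            ax.legend(handles, labels, fontsize="small")
        if annotations:
            for label, (lo, hi) in annotations.items():
                ax.axvspan(lo - 0.5, hi - 0.5, alpha=0.15, color="gray")
                ax.text(
                    (lo + hi - 1) / 2, ax.get_ylim()[1], label,
                    ha="center", va="top", fontsize="x-small",
                )
        fig.savefig(svg_path, format="svg", metadata={"Date": None})
        plt.close(fig)

    if raw_tsv_path is not None:
        with open(raw_tsv_path, "w") as fh:
            write_raw_tsv(fh, tracks)
    return drawn
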