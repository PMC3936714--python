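"""Nucleotide-disparity (GC/AT skew) corroboration of origin positions.

On a circular replicon replicated bidirectionally, the leading strand tends
to accumulate G over C, so the windowed GC skew (G-C)/(G+C) changes sign
near the origin and terminus, and the cumulative (G-C) curve has its global
extrema there.  The cumulative track is anchored at coordinate 0 of the
record; on a circle only the extrema positions, not the values, are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeIOError, Replicon


@dataclass(frozen=True)
class SkewTrack:
    replicon_id: str
    positions: np.ndarray  # window centers, bp
    starts: np.ndarray
    window: int
    gc_skew: np.ndarray  # (G-C)/(G+C) per window, 0 when G+C == 0
    at_skew: np.ndarray  # (A-T)/(A+T)
    #: cumulative per-base (G-C) from coordinate 0 up to each window's step
    #: boundary; the final value is the replicon's total G - C.
    cum_gc: np.ndarray


def compute_skew(replicon: Replicon, window: int = 1000,
                 step: int = 100) -> SkewTrack:
    """Windowed GC/AT skew and cumulative (G-C), circularly wrapped."""
    L = replicon.length
    if window > L:
        raise GenomeIOError("window exceeds replicon length")
    codes = np.frombuffer(replicon.sequence.encode("ascii"), dtype=np.uint8)
    circular = replicon.topology == "circular"

    def window_counts(base: str) -> np.ndarray:
        ind = (codes == ord(base)).astype(np.int64)
        ext = np.concatenate([ind, ind[:window]]) if circular else ind
        csum = np.concatenate([[0], np.cumsum(ext)])
        starts = np.arange(0, L if circular else L - window + 1, step)
        return csum[starts + window] - csum[starts]

    g = window_counts("G")
    c = window_counts("C")
    a = window_counts("A")
    t = window_counts("T")
    starts = np.arange(0, L if circular else L - window + 1, step)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
        at = np.where(a + t > 0, (a - t) / np.maximum(a + t, 1), 0.0)
    per_base = (codes == ord("G")).astype(np.int64) - (codes == ord("C"))
    base_csum = np.concatenate([[0], np.cumsum(per_base)])
    cum = base_csum[np.minimum(starts + step, L)]
    return SkewTrack(
        replicon_id=replicon.id,
        positions=(starts + window // 2) % L,
        starts=starts,
        window=window,
        gc_skew=gc,
        at_skew=at,
        cum_gc=cum,
    )


def skew_extrema(track: SkewTrack) -> tuple[int, int]:
    """Positions of the global minimum and maximum of cumulative (G-C).

    Ties resolve to the lowest coordinate (argmin/argmax take the first
    index and windows are enumerated from coordinate 0).
    """
    if track.cum_gc.size == 0:
        raise GenomeIOError("empty skew track")
    i_min = int(np.argmin(track.cum_gc))
    i_max = int(np.argmax(track.cum_gc))
    # the cumulative value at index i covers [0, starts[i] + step), so the
    # extremum is located at that step boundary
    step = int(track.starts[1] - track.starts[0]) if track.starts.size > 1 else 0
    return (
        int(track.starts[i_min]) + step,
        int(track.starts[i_max]) + step,
    )
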