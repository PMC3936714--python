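"""Marker-frequency analysis: ratio profiles, peaks, strain comparison and
origin-usage fitting.

A marker-frequency profile is the replicate-averaged ratio of exponential-
to stationary-phase signal per probe.  In an asynchronous exponentially
growing population the expected ratio decays log-linearly with replication
time away from each active origin, so origins appear as peaks whose height
reflects firing probability and fork travel time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome_io import circular_distance
from .synthetic_data import ReplicationProgram, expected_ratio_profile

logger = logging.getLogger(__name__)


class MFAError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerProfile:
    replicon_id: str
    positions: np.ndarray  # strictly increasing bp
    ratio: np.ndarray  # positive, replicate-averaged exp:stat ratio
    n_replicates: int
    replicon_length: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise MFAError("positions must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise MFAError("ratios must be positive")

    @property
    def length(self) -> int:
        """Replicon length, estimated from probe spacing when not given."""
        if self.replicon_length is not None:
            return self.replicon_length
        spacing = float(np.median(np.diff(self.positions)))
        return int(self.positions[-1] + spacing)

    @property
    def log2_ratio(self) -> np.ndarray:
        return np.log2(self.ratio)


@dataclass(frozen=True)
class MFAPeak:
    position: int
    height: float  # log2 units above the higher flanking trough
    span: tuple[int, int]
    prominence: float
    apex_index: int
    left_base_index: int
    right_base_index: int


@dataclass(frozen=True)
class UsageFit:
    firing_probs: tuple[float, ...]
    fork_time_scale: float  # t_ter / tau
    rss: float


def make_profile(signals: pd.DataFrame,
                 replicon_length: int | None = None) -> MarkerProfile:
    """Normalize and average a two-channel signal table into a profile.

    Per replicate, both channels are scaled so the stationary-channel
    median is 1, then ratio = exp/stat per probe; replicate ratios are
    averaged per probe.  Probes with non-positive signal in either channel
    are dropped with a warning.
    """
    rids = signals["replicon_id"].unique()
    if len(rids) != 1:
        raise MFAError("one profile per replicon: filter the table first")
    if signals.empty:
        raise MFAError("empty signal table")
    good = (signals["exp_signal"] > 0) & (signals["stat_signal"] > 0)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("dropping %d probes with non-positive signal", n_bad)
    signals = signals[good]
    if signals.empty:
        raise MFAError("all probes dropped (non-positive signals)")
    parts = []
    for rep, grp in signals.groupby("replicate"):
        scale = float(grp["stat_signal"].median())
        exp_n = grp["exp_signal"] / scale
        stat_n = grp["stat_signal"] / scale
        parts.append(pd.DataFrame({
            "position": grp["position"].to_numpy(),
            "ratio": (exp_n / stat_n).to_numpy(),
        }))
    n_replicates = len(parts)
    merged = pd.concat(parts).groupby("position")["ratio"].mean().sort_index()
    return MarkerProfile(
        replicon_id=str(rids[0]),
        positions=merged.index.to_numpy(dtype=int),
        ratio=merged.to_numpy(),
        n_replicates=n_replicates,
        replicon_length=replicon_length,
    )


def smooth_profile(p: MarkerProfile, window: int = 5) -> MarkerProfile:
    """Centered circular moving average on the log2 ratios."""
    if window % 2 == 0 or window < 1:
        raise MFAError("window must be odd and >= 1")
    if window == 1:
        return p
    n = len(p.positions)
    if window > n:
        raise MFAError("window larger than profile")
    y = p.log2_ratio
    half = window // 2
    padded = np.concatenate([y[-half:], y, y[:half]])
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return MarkerProfile(
        replicon_id=p.replicon_id,
        positions=p.positions,
        ratio=np.exp2(smoothed),
        n_replicates=p.n_replicates,
        replicon_length=p.replicon_length,
    )


def call_peaks(
    p: MarkerProfile,
    min_prominence: float = 0.1,
    min_separation: int = 50_000,
) -> list[MFAPeak]:
    """Local maxima of the circular log2 profile with prominence filtering.

    The profile is rotated so its global minimum sits at the boundary (a
    peak can then never straddle the seam), peaks are found with their
    prominences, and finally kept greedily in decreasing prominence subject
    to a circular min_separation.  Plateau apexes take the lowest
    coordinate.
    """
    y = p.log2_ratio
    n = len(y)
    if n < 3 or np.allclose(y, y[0]):
        return []
    L = p.length
    shift = int(np.argmin(y))
    yr = np.roll(y, -shift)
    idx, props = find_peaks(yr, prominence=min_prominence,
                            plateau_size=(1, None))
    if idx.size == 0:
        return []
    peaks = []
    for k in range(idx.size):
        apex_r = int(props["left_edges"][k])  # lowest coordinate on plateaus
        lb_r = int(props["left_bases"][k])
        rb_r = int(props["right_bases"][k])
        apex = (apex_r + shift) % n
        lb = (lb_r + shift) % n
        rb = (rb_r + shift) % n
        # unroll the span around the apex so span[0] <= position <= span[1]
        apex_pos = int(p.positions[apex])
        start = int(p.positions[lb])
        end = int(p.positions[rb])
        if start > apex_pos:
            start -= L
        if end < apex_pos:
            end += L
        prom = float(props["prominences"][k])
        peaks.append(MFAPeak(
            position=int(p.positions[apex]),
            height=prom,
            span=(start, end),
            prominence=prom,
            apex_index=apex,
            left_base_index=lb,
            right_base_index=rb,
        ))
    peaks.sort(key=lambda pk: -pk.prominence)
    kept: list[MFAPeak] = []
    for pk in peaks:
        if all(
            circular_distance(pk.position, other.position, L) >= min_separation
            for other in kept
        ):
            kept.append(pk)
    kept.sort(key=lambda pk: pk.position)
    return kept


def compare_strains(
    reference: MarkerProfile,
    mutant: MarkerProfile,
    peaks: list[MFAPeak],
    min_prominence: float = 0.1,
) -> list[tuple[MFAPeak, str]]:
    """Score each reference peak as retained or lost in a mutant profile.

    The mutant's height for a peak is its log2 ratio at the reference apex
    minus the larger of its log2 ratios at the reference peak's two
    prominence bases; a profile that is merely sloping through the span
    (origin gone, flank of another origin remains) scores <= 0.
    """
    if (
        len(reference.positions) != len(mutant.positions)
        or np.any(reference.positions != mutant.positions)
    ):
        raise MFAError("profiles are on different probe grids")
    y = mutant.log2_ratio
    out = []
    for pk in peaks:
        h_mut = float(
            y[pk.apex_index]
            - max(y[pk.left_base_index], y[pk.right_base_index])
        )
        lost = h_mut < 0.5 * pk.height and h_mut < min_prominence
        out.append((pk, "lost" if lost else "retained"))
    return out


def fit_origin_usage(
    p: MarkerProfile,
    origin_positions: list[int],
    p_step: float = 0.05,
    theta_grid: np.ndarray | None = None,
) -> UsageFit:
    """Grid-search firing probabilities and fork-time scale.

    The forward model is the closed-form subset mixture of the population
    simulator with all firing delays 0: for each candidate
    (p_1..p_k, theta = t_ter/tau), the expected ratio profile is computed
    and the squared log2 error against the observed profile is minimized.
    """
    if not origin_positions:
        raise MFAError("at least one origin position required")
    k = len(origin_positions)
    if k > 4:
        raise MFAError("grid search supports at most 4 origins")
    L = p.length
    pos = p.positions
    snapped = []
    for o in origin_positions:
        d = np.minimum(np.abs(pos - o), L - np.abs(pos - o))
        j = int(np.argmin(d))
        if d[j] > 0 and o not in pos:
            logger.warning("origin %d snapped to probe at %d", o, pos[j])
        snapped.append(int(pos[j]))

    d = np.empty((k, len(pos)), dtype=float)
    for i, o in enumerate(snapped):
        dd = np.abs(pos - o)
        d[i] = np.minimum(dd, L - dd)
    d_ter = float(np.max(np.min(d, axis=0)))
    if theta_grid is None:
        theta_grid = np.arange(0.2, 2.0 + 1e-9, 0.1)
    p_grid = np.arange(0.0, 1.0 + 1e-9, p_step)

    masks = list(range(1, 2 ** k))
    # all firing-probability combinations and their subset weights
    combos = np.array(np.meshgrid(*([p_grid] * k), indexing="ij"))
    combos = combos.reshape(k, -1).T  # (n_combos, k)
    weights = np.empty((combos.shape[0], len(masks) + 1))
    for mi, mask in enumerate(masks):
        w = np.ones(combos.shape[0])
        for i in range(k):
            w = w * (combos[:, i] if (mask >> i) & 1 else 1 - combos[:, i])
        weights[:, mi] = w
    weights[:, -1] = np.prod(1 - combos, axis=1)  # empty set

    y_obs = p.log2_ratio
    best = (np.inf, None, None)
    for theta in theta_grid:
        c = theta / d_ter if d_ter > 0 else 0.0
        profiles = np.empty((len(masks) + 1, len(pos)))
        for mi, mask in enumerate(masks):
            idx = [i for i in range(k) if (mask >> i) & 1]
            t_rel = c * np.min(d[idx], axis=0)
            profiles[mi] = np.maximum(1.0, 2.0 ** (1.0 - t_rel))
        profiles[-1] = 1.0
        models = weights @ profiles
        rss = np.sum((np.log2(models) - y_obs) ** 2, axis=1)
        j = int(np.argmin(rss))
        if rss[j] < best[0]:
            best = (float(rss[j]), tuple(float(x) for x in combos[j]),
                    float(theta))
    return UsageFit(firing_probs=best[1], fork_time_scale=best[2],
                    rss=best[0])


def profile_from_program(program: ReplicationProgram,
                         positions: np.ndarray) -> MarkerProfile:
    """Noiseless expected profile for a replication program (closed form)."""
    ratio = expected_ratio_profile(program, positions)
    return MarkerProfile(
        replicon_id=program.replicon_id,
        positions=np.asarray(positions, dtype=int),
        ratio=ratio,
        n_replicates=0,
        replicon_length=program.replicon_length,
    )
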