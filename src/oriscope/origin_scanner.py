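"""Sequence-level detection of the haloarchaeal origin architecture.

The scanner finds ORB (origin recognition box) motif hits on both strands,
measures their halophile-specific G-string extensions, locates AT-rich
cores, pairs inward-facing inverted ORBs into origin candidates, searches
the inter-ORB interval for a perfect G-rich inverted-repeat enhancer,
groups extra ORB hits into initiator-titration clusters, and classifies
candidates by proximity to an orc1/cdc6 gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import (
    GeneFeature,
    GenomeAssembly,
    GenomeIOError,
    IUPAC_SETS,
    Replicon,
    interval_distance,
    intervals_overlap,
    revcomp,
)

logger = logging.getLogger(__name__)

#: Packaged default ORB consensus (20 nt).  Modeled on the classic archaeal
#: origin-recognition-box motif with its short 3' G-run; in halophiles the
#: element is extended by an additional G-string, which the scanner measures
#: separately on the hit's 3' flank.  Override per genome via config.
DEFAULT_ORB_CONSENSUS = "TTCCAGTGGAAACGAAAGGG"

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(consensus: str) -> str:
    return consensus.upper().translate(_IUPAC_COMPLEMENT)[::-1]


_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class ORBHit:
    replicon_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    has_gstring: bool
    gstring_len: int


@dataclass(frozen=True)
class InvertedRepeat:
    arm_len: int
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    g_fraction: float
    loop_len: int


@dataclass
class OriginCandidate:
    replicon_id: str
    span: tuple[int, int]  # end may exceed replicon length when wrapping
    orb_pair: tuple[ORBHit, ORBHit]
    at_core: tuple[int, int, float]
    enhancer: InvertedRepeat | None = None
    nearest_initiator: GeneFeature | None = None
    initiator_distance: int | None = None
    classification: str | None = None


@dataclass(frozen=True)
class TitrationRegion:
    replicon_id: str
    span: tuple[int, int]
    orb_hits: tuple[ORBHit, ...]
    intergenic: bool

    @property
    def orb_count(self) -> int:
        return len(self.orb_hits)


# ---------------------------------------------------------------------------
# ORB scanning
# ---------------------------------------------------------------------------

def _allowed_matrix(consensus: str) -> np.ndarray:
    """(m, 5) bool: which base codes match each consensus position.

    Code 4 (N in the subject sequence) never matches.
    """
    m = len(consensus)
    allowed = np.zeros((m, 5), dtype=bool)
    for j, c in enumerate(consensus.upper()):
        try:
            bases = IUPAC_SETS[c]
        except KeyError:
            raise GenomeIOError(f"invalid consensus character {c!r}") from None
        for b in bases:
            allowed[j, _BASE_CODE[b]] = True
    return allowed


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        table[ord(b)] = i
    return table[codes]


def _mismatch_counts(codes: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    m = allowed.shape[0]
    windows = sliding_window_view(codes, m)
    mism = np.full(windows.shape[0], 0, dtype=np.int16)
    for j in range(m):
        mism += ~allowed[j][windows[:, j]]
    return mism


def _g_run(seq: str, start: int, circular: bool, base: str, step: int,
           cap: int = 100) -> int:
    """Length of a run of `base` walking from `start` in direction `step`."""
    L = len(seq)
    run = 0
    i = start
    while run < cap:
        if i < 0 or i >= L:
            if not circular:
                break
            i %= L
        if seq[i] != base:
            break
        run += 1
        i += step
    return run


def _resolve_overlaps(hits: list[ORBHit]) -> list[ORBHit]:
    """Within each strand, keep the lowest-mismatch hit of every chain of
    mutually overlapping hits (ties -> leftmost)."""
    out: list[ORBHit] = []
    for strand in ("+", "-"):
        strand_hits = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.start
        )
        cluster: list[ORBHit] = []
        cluster_end = -1
        for h in strand_hits:
            if cluster and h.start < cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.end)
            else:
                if cluster:
                    out.append(min(cluster, key=lambda x: (x.mismatches, x.start)))
                cluster = [h]
                cluster_end = h.end
        if cluster:
            out.append(min(cluster, key=lambda x: (x.mismatches, x.start)))
    return sorted(out, key=lambda h: (h.start, h.strand))


def scan_orbs(
    assembly: GenomeAssembly,
    consensus: str = DEFAULT_ORB_CONSENSUS,
    max_mismatch: int = 3,
    gstring_min: int = 6,
) -> list[ORBHit]:
    """Scan both strands of every replicon for ORB motif hits.

    A minus-strand hit at [start, end) means the reverse complement of that
    window matches the consensus; its G-string extension is then measured
    leftwards (strand-aware 3' flank).  Circular replicons are scanned with
    a wrap window of consensus length - 1.
    """
    if not consensus:
        raise GenomeIOError("empty consensus")
    m = len(consensus)
    if m < 10:
        raise GenomeIOError("consensus must be at least 10 nt")
    allowed_plus = _allowed_matrix(consensus)
    allowed_minus = _allowed_matrix(iupac_revcomp(consensus))

    all_hits: list[ORBHit] = []
    for rep in assembly.replicons:
        seq = rep.sequence
        circular = rep.topology == "circular"
        ext = seq + seq[: m - 1] if circular else seq
        if len(ext) < m:
            continue
        codes = _encode(ext)
        raw: list[ORBHit] = []
        for strand, allowed in (("+", allowed_plus), ("-", allowed_minus)):
            mism = _mismatch_counts(codes, allowed)
            for start in np.nonzero(mism <= max_mismatch)[0]:
                start = int(start)
                if start >= rep.length:
                    continue  # wrap duplicate
                end = start + m
                if strand == "+":
                    run = _g_run(seq, end % rep.length if circular else end,
                                 circular, "G", +1)
                else:
                    run = _g_run(seq, start - 1, circular, "C", -1)
                raw.append(ORBHit(
                    replicon_id=rep.id, start=start, end=end, strand=strand,
                    mismatches=int(mism[start]),
                    has_gstring=run >= gstring_min, gstring_len=run,
                ))
        all_hits.extend(_resolve_overlaps(raw))
    return all_hits


# ---------------------------------------------------------------------------
# AT-rich cores
# ---------------------------------------------------------------------------

def find_at_rich(
    replicon: Replicon,
    window: int = 100,
    min_at: float | None = None,
    step: int = 10,
) -> list[tuple[int, int, float]]:
    """Maximal merged runs of sliding windows with AT fraction >= min_at.

    Default threshold is the replicon's background AT fraction + 0.20
    (about four binomial standard deviations for a 100-bp window, so a
    uniform background sequence yields essentially no regions while a
    planted AT-rich core at 0.85 stands far above it).
    """
    L = replicon.length
    if window > L:
        raise GenomeIOError("window exceeds replicon length")
    is_at = np.frombuffer(replicon.sequence.encode("ascii"), dtype=np.uint8)
    is_at = (is_at == ord("A")) | (is_at == ord("T"))
    background = float(is_at.mean())
    if min_at is None:
        min_at = background + 0.20
    ext = np.concatenate([is_at, is_at[:window]]) if replicon.topology == "circular" else is_at
    csum = np.concatenate([[0], np.cumsum(ext)])
    starts = np.arange(0, L if replicon.topology == "circular" else L - window + 1, step)
    fracs = (csum[starts + window] - csum[starts]) / window
    qualifying = starts[fracs >= min_at]
    if qualifying.size == 0:
        return []

    regions: list[list[int]] = []
    for s in qualifying:
        if regions and s < regions[-1][1]:
            regions[-1][1] = s + window
        else:
            regions.append([int(s), int(s) + window])
    # merge across the circular seam
    if (
        replicon.topology == "circular"
        and len(regions) > 1
        and regions[-1][1] >= L
        and regions[0][0] < regions[-1][1] - L + window
        and regions[0][0] == 0
    ):
        first = regions.pop(0)
        regions[-1][1] = max(regions[-1][1], first[1] + L)

    out = []
    for s, e in regions:
        sub = replicon.fetch(s, e)
        frac = sum(1 for c in sub if c in "AT") / len(sub)
        out.append((s, e, frac))
    return out


# ---------------------------------------------------------------------------
# Inverted ORB pairing
# ---------------------------------------------------------------------------

def pair_inverted_orbs(
    hits: list[ORBHit],
    at_regions: dict[str, list[tuple[int, int, float]]],
    assembly: GenomeAssembly,
    min_gap: int = 20,
    max_gap: int = 500,
) -> list[OriginCandidate]:
    """Pair inward-facing opposite-strand ORB hits around an AT-rich core.

    Inward-facing means plus-strand hit upstream of the minus-strand hit
    (their G-strings then point into the gap).  Pairs are formed greedily by
    smallest inner gap; each hit joins at most one candidate.
    """
    candidates: list[OriginCandidate] = []
    for rep in assembly.replicons:
        L = rep.length
        plus = [h for h in hits if h.replicon_id == rep.id and h.strand == "+"]
        minus = [h for h in hits if h.replicon_id == rep.id and h.strand == "-"]
        regions = at_regions.get(rep.id, [])
        pairs = []
        for p in plus:
            for q in minus:
                gap = (q.start - p.end) % L
                if min_gap <= gap <= max_gap:
                    pairs.append((gap, p, q))
        pairs.sort(key=lambda x: (x[0], x[1].start))
        used: set[tuple[int, str]] = set()
        for gap, p, q in pairs:
            if (p.start, "+") in used or (q.start, "-") in used:
                continue
            gap_iv = (p.end, p.end + gap)
            inside = [
                r for r in regions
                if intervals_overlap(gap_iv, (r[0], r[1]), L)
            ]
            if not inside:
                continue
            core = max(
                inside, key=lambda r: _overlap_len(gap_iv, (r[0], r[1]), L)
            )
            used.add((p.start, "+"))
            used.add((q.start, "-"))
            span_end = q.end if q.end >= p.start else q.end + L
            candidates.append(OriginCandidate(
                replicon_id=rep.id,
                span=(p.start, span_end),
                orb_pair=(p, q),
                at_core=core,
            ))
    return sorted(candidates, key=lambda c: (c.replicon_id, c.span[0]))


def _overlap_len(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    def segments(iv):
        s, e = iv
        s %= L
        e = s + (iv[1] - iv[0])
        return [(s, min(e, L))] + ([(0, e - L)] if e > L else [])

    total = 0
    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


# ---------------------------------------------------------------------------
# Enhancer (perfect G-rich inverted repeat)
# ---------------------------------------------------------------------------

def find_enhancer(
    candidate: OriginCandidate,
    assembly: GenomeAssembly,
    arm_min: int = 8,
    g_rich_min: float = 0.8,
) -> InvertedRepeat | None:
    """Longest perfect G-rich inverted repeat inside the inter-ORB interval.

    The searched interval excludes the ORBs' G-string extensions (the
    G-string is part of the ORB element), otherwise the two inward-facing
    G-strings would themselves always qualify as a repeat.  Ties are broken
    toward the leftmost left arm, then the smallest loop.
    """
    p, q = candidate.orb_pair
    rep = assembly.replicon(candidate.replicon_id)
    L = rep.length
    start_i = p.end + (p.gstring_len if p.has_gstring else 0)
    end_i = q.start - (q.gstring_len if q.has_gstring else 0)
    if end_i < start_i:
        end_i += L
    n = end_i - start_i
    if n < 2 * arm_min:
        return None
    s = rep.fetch(start_i % L, start_i % L + n)
    rc = revcomp(s)
    s_codes = _encode(s)
    rc_codes = _encode(rc)

    best: tuple[int, int, int] | None = None  # (arm_len, left_start, right_start)
    prev = np.zeros(n, dtype=np.int32)
    for i in range(n):
        eq = (rc_codes == s_codes[i]) & (s_codes[i] != 4)
        row = np.where(eq, np.concatenate(([0], prev[:-1])) + 1, 0)
        for j in np.nonzero(row >= arm_min)[0]:
            max_arm = int(row[j])
            for arm in range(arm_min, max_arm + 1):
                left_start = i - arm + 1
                right_start = n - 1 - int(j)
                if right_start < i + 1:
                    continue
                arm_seq = s[left_start:left_start + arm]
                g = max(arm_seq.count("G"), arm_seq.count("C")) / arm
                if g < g_rich_min:
                    continue
                key = (arm, left_start, right_start)
                if (
                    best is None
                    or arm > best[0]
                    or (arm == best[0] and (left_start, right_start) <
                        (best[1], best[2]))
                ):
                    best = key
        prev = row
    if best is None:
        return None
    arm, left_start, right_start = best
    left_seq = s[left_start:left_start + arm]
    right_seq = s[right_start:right_start + arm]
    assert right_seq == revcomp(left_seq)
    g_frac = max(left_seq.count("G"), left_seq.count("C")) / arm
    return InvertedRepeat(
        arm_len=arm,
        left_arm=((start_i + left_start) % L, (start_i + left_start + arm - 1) % L + 1),
        right_arm=((start_i + right_start) % L, (start_i + right_start + arm - 1) % L + 1),
        g_fraction=g_frac,
        loop_len=right_start - (left_start + arm),
    )


# ---------------------------------------------------------------------------
# Titration clusters and classification
# ---------------------------------------------------------------------------

def find_titration_regions(
    hits: list[ORBHit],
    candidates: list[OriginCandidate],
    features: tuple[GeneFeature, ...],
    assembly: GenomeAssembly,
    cluster_min: int = 3,
    max_span: int = 1000,
) -> list[TitrationRegion]:
    """Group leftover ORB hits (outside origin candidates) into clusters.

    Hits join a cluster while consecutive gaps stay below
    max_span / cluster_min; clusters of >= cluster_min hits are reported.
    """
    gap_limit = max_span / cluster_min
    regions: list[TitrationRegion] = []
    for rep in assembly.replicons:
        L = rep.length
        spans = [c.span for c in candidates if c.replicon_id == rep.id]
        free = sorted(
            (
                h for h in hits
                if h.replicon_id == rep.id
                and not any(intervals_overlap((h.start, h.end), sp, L)
                            for sp in spans)
            ),
            key=lambda h: h.start,
        )
        if not free:
            continue
        groups: list[list[ORBHit]] = [[free[0]]]
        for h in free[1:]:
            if h.start - groups[-1][-1].end <= gap_limit:
                groups[-1].append(h)
            else:
                groups.append([h])
        if (
            rep.topology == "circular"
            and len(groups) > 1
            and (free[0].start + L - groups[-1][-1].end) <= gap_limit
        ):
            groups[0] = groups.pop() + groups[0]
        for grp in groups:
            if len(grp) < cluster_min:
                continue
            start = grp[0].start
            end = grp[-1].end if grp[-1].end > start else grp[-1].end + L
            span = (start, end)
            genic = any(
                intervals_overlap(span, (f.start, f.end), L)
                for f in features
                if f.replicon_id == rep.id
            )
            regions.append(TitrationRegion(
                replicon_id=rep.id, span=span, orb_hits=tuple(grp),
                intergenic=not genic,
            ))
    return regions


def classify_candidates(
    candidates: list[OriginCandidate],
    features: tuple[GeneFeature, ...],
    assembly: GenomeAssembly,
    max_initiator_dist: int = 2000,
) -> list[OriginCandidate]:
    """Attach the nearest orc1/cdc6 gene and call ori_cdc6 vs orphan."""
    for cand in candidates:
        L = assembly.replicon(cand.replicon_id).length
        initiators = [
            f for f in features
            if f.replicon_id == cand.replicon_id and f.is_initiator
        ]
        if not initiators:
            cand.nearest_initiator = None
            cand.initiator_distance = None
            cand.classification = "orphan"
            continue
        dists = [
            interval_distance(cand.span, (f.start, f.end), L)
            for f in initiators
        ]
        i = int(np.argmin(dists))
        cand.nearest_initiator = initiators[i]
        cand.initiator_distance = int(dists[i])
        cand.classification = (
            "ori_cdc6" if dists[i] <= max_initiator_dist else "orphan"
        )
    return candidates


# ---------------------------------------------------------------------------
# Whole-genome annotation convenience
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    hits: list[ORBHit]
    at_regions: dict[str, list[tuple[int, int, float]]]
    candidates: list[OriginCandidate]
    titration_regions: list[TitrationRegion]


def annotate_origins(
    assembly: GenomeAssembly,
    consensus: str = DEFAULT_ORB_CONSENSUS,
    max_mismatch: int = 3,
    gstring_min: int = 6,
    at_window: int = 100,
    min_at: float | None = None,
    min_gap: int = 20,
    max_gap: int = 500,
    arm_min: int = 8,
    g_rich_min: float = 0.8,
    cluster_min: int = 3,
    max_span: int = 1000,
    max_initiator_dist: int = 2000,
) -> ScanResult:
    """Run the full scanning chain with one call."""
    hits = scan_orbs(assembly, consensus, max_mismatch, gstring_min)
    at_regions = {
        rep.id: find_at_rich(rep, window=at_window, min_at=min_at)
        for rep in assembly.replicons
    }
    candidates = pair_inverted_orbs(hits, at_regions, assembly, min_gap, max_gap)
    for cand in candidates:
        cand.enhancer = find_enhancer(cand, assembly, arm_min, g_rich_min)
    classify_candidates(candidates, assembly.features, assembly,
                        max_initiator_dist)
    titration = find_titration_regions(
        hits, candidates, assembly.features, assembly, cluster_min, max_span
    )
    return ScanResult(hits, at_regions, candidates, titration)
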