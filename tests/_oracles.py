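"""Independent brute-force oracles used by the scanner tests.

These deliberately avoid the vectorized machinery of the package: plain
per-position loops over python strings, so that agreement with the package
is a genuine cross-check.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def hamming_vs_consensus(window: str, consensus: str) -> int:
    mism = 0
    for w, c in zip(window, consensus):
        if w == "N" or w not in IUPAC[c]:
            mism += 1
    return mism


def brute_force_orb_scan(seq: str, consensus: str, max_mismatch: int,
                         circular: bool = True):
    """All (start, strand, mismatches) hits, with the same overlap
    resolution rule as the scanner (lowest mismatch per overlapping chain,
    ties leftmost), reimplemented naively."""
    m = len(consensus)
    L = len(seq)
    ext = seq + seq[: m - 1] if circular else seq
    cons_minus = rc_iupac(consensus)
    raw = []
    for start in range(L if circular else L - m + 1):
        window = ext[start:start + m]
        for strand, cons in (("+", consensus), ("-", cons_minus)):
            mm = hamming_vs_consensus(window, cons)
            if mm <= max_mismatch:
                raw.append((start, strand, mm))
    out = []
    for strand in ("+", "-"):
        chain = []
        chain_end = -1
        for start, st, mm in sorted(raw):
            if st != strand:
                continue
            if chain and start < chain_end:
                chain.append((start, mm))
                chain_end = max(chain_end, start + m)
            else:
                if chain:
                    out.append(_best(chain, strand, m))
                chain = [(start, mm)]
                chain_end = start + m
        if chain:
            out.append(_best(chain, strand, m))
    return sorted(out)


def _best(chain, strand, m):
    best = min(chain, key=lambda x: (x[1], x[0]))
    return (best[0], best[0] + m, strand, best[1])


def rc_iupac(consensus: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(consensus))


def brute_force_inverted_repeat(s: str, arm_min: int, g_rich_min: float):
    """Longest perfect G-rich inverted repeat by innermost-pair extension.

    Every inverted repeat has a unique innermost base pair (left arm end e,
    right arm start r); arms of any length up to the maximal inward-out
    extension are enumerated and filtered on the G/C fraction.  Returns
    (arm_len, left_start, right_start) or None, with ties resolved toward
    the smallest left_start then right_start.
    """
    n = len(s)
    best = None
    for e in range(n):
        for r in range(e + 1, n):
            k = 0
            while e - k >= 0 and r + k < n and s[e - k] == COMP.get(s[r + k]):
                if s[e - k] == "N":
                    break
                k += 1
            for arm in range(arm_min, k + 1):
                left = s[e - arm + 1:e + 1]
                g = max(left.count("G"), left.count("C")) / arm
                if g < g_rich_min:
                    continue
                cand = (arm, e - arm + 1, r)
                if (
                    best is None
                    or cand[0] > best[0]
                    or (cand[0] == best[0] and (cand[1], cand[2]) <
                        (best[1], best[2]))
                ):
                    best = cand
    return best
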