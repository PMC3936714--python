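"""Genome containers, circular-coordinate primitives and FASTA/GFF3 I/O.

Every downstream stage (simulator, scanner, skew, MFA) works on a
:class:`GenomeAssembly`: a set of circular (or linear) replicons plus gene
features.  Coordinates are 0-based half-open internally; GFF3 is 1-based
closed at the file boundary, BED/bedGraph are 0-based half-open on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degeneracy: which concrete bases each consensus letter accepts.
#: An ``N`` in the *subject sequence* never matches any consensus letter
#: (conservative rule), which is why sequence-N is excluded at match time
#: rather than here.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class GenomeIOError(ValueError):
    """Raised for malformed sequences, annotations or coordinates."""


@dataclass(frozen=True)
class Replicon:
    """One circular or linear DNA molecule."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"unknown topology {self.topology!r}")
        bad = _first_invalid(self.sequence)
        if bad is not None:
            raise GenomeIOError(
                f"replicon {self.id!r}: invalid character "
                f"{self.sequence[bad]!r} at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps past the end on circular replicons."""
        L = self.length
        if end <= L:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise GenomeIOError(
                f"interval ({start}, {end}) exceeds linear replicon {self.id!r}"
            )
        return self.sequence[start:] + self.sequence[: end - L]


@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation on a replicon (0-based, half-open)."""

    replicon_id: str
    start: int
    end: int
    strand: str
    name: str
    is_initiator: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"feature {self.name!r}: bad interval ({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class GenomeAssembly:
    replicons: tuple[Replicon, ...]
    features: tuple[GeneFeature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicons", tuple(self.replicons))
        object.__setattr__(self, "features", tuple(self.features))
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise GenomeIOError("replicon ids are not unique")
        lengths = {r.id: r.length for r in self.replicons}
        for f in self.features:
            if f.replicon_id not in lengths:
                raise GenomeIOError(
                    f"feature {f.name!r} references unknown replicon {f.replicon_id!r}"
                )
            if f.end > lengths[f.replicon_id]:
                raise GenomeIOError(
                    f"feature {f.name!r} extends past replicon end "
                    f"({f.end} > {lengths[f.replicon_id]})"
                )

    def replicon(self, rid: str) -> Replicon:
        for r in self.replicons:
            if r.id == rid:
                return r
        raise GenomeIOError(f"no replicon {rid!r} in assembly")

    def features_on(self, rid: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.replicon_id == rid)

    def with_sequence(self, rid: str, sequence: str) -> "GenomeAssembly":
        reps = tuple(
            replace(r, sequence=sequence) if r.id == rid else r
            for r in self.replicons
        )
        return GenomeAssembly(reps, self.features)


def _first_invalid(s: str) -> int | None:
    for i, c in enumerate(s):
        if c not in VALID_BASES:
            return i
    return None


def revcomp(s: str) -> str:
    """Reverse complement of an ACGTN string (involution)."""
    bad = _first_invalid(s)
    if bad is not None:
        raise GenomeIOError(f"invalid character {s[bad]!r} at position {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def circular_distance(a: int, b: int, L: int) -> int:
    """Shortest walk between positions a and b on a circle of length L."""
    if L <= 0:
        raise GenomeIOError(f"non-positive replicon length {L}")
    d = (a - b) % L
    return min(d, L - d)


def interval_distance(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    """Edge-to-edge circular distance between two intervals; 0 if they overlap.

    Intervals are half-open and may wrap (end > L means the interval crosses
    the seam).
    """

    def points(iv: tuple[int, int]) -> tuple[int, int]:
        return iv[0] % L, (iv[1] - 1) % L

    a0, a1 = a
    b0, b1 = b
    if intervals_overlap(a, b, L):
        return 0
    # distance between closest edges, considering wrap
    cands = []
    for p in (a0 % L, (a1 - 1) % L):
        for q in (b0 % L, (b1 - 1) % L):
            cands.append(circular_distance(p, q, L))
    return min(cands)


def intervals_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    """Overlap test for half-open, possibly wrapping circular intervals."""

    def segments(iv):
        s, e = iv
        s %= L
        e = s + (iv[1] - iv[0])
        if e <= L:
            return [(s, e)]
        return [(s, L), (0, e - L)]

    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


# ---------------------------------------------------------------------------
# FASTA + GFF3 boundary
# ---------------------------------------------------------------------------

def load_genome(fasta_path, gff_path, initiator_tag: str = "cdc6") -> GenomeAssembly:
    """Read a multi-record FASTA and a GFF3 of gene rows into an assembly.

    A gene is flagged as a replication initiator when any of its GFF
    attribute values contains *initiator_tag* (case-insensitive): the
    annotation convention for orc1/cdc6 homologs varies between genomes, so
    the tag is a required, explicit choice rather than a guess.
    """
    replicons = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        topology = "circular"
        if "topology=linear" in rec.description:
            topology = "linear"
        replicons.append(Replicon(id=rec.id, sequence=seq, topology=topology))
    if not replicons:
        raise GenomeIOError(f"no FASTA records in {fasta_path}")
    known = {r.id: r.length for r in replicons}

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tag = initiator_tag.lower()
    features = []
    for f in db.all_features():
        if f.featuretype != "gene":
            continue
        if f.seqid not in known:
            raise GenomeIOError(
                f"GFF seqid {f.seqid!r} does not match any FASTA record"
            )
        values: list[str] = []
        for vals in f.attributes.values():
            values.extend(vals)
        is_init = any(tag in v.lower() for v in values)
        name = (
            f.attributes.get("Name", [None])[0]
            or f.attributes.get("ID", [None])[0]
            or f"gene_{f.seqid}_{f.start}"
        )
        features.append(
            GeneFeature(
                replicon_id=f.seqid,
                start=f.start - 1,  # GFF3 1-based closed -> 0-based half-open
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                name=name,
                is_initiator=is_init,
            )
        )
    return GenomeAssembly(tuple(replicons), tuple(features))


def write_genome(assembly: GenomeAssembly, fasta_path, gff_path) -> None:
    """Serialize an assembly to FASTA + GFF3 so that :func:`load_genome`
    round-trips it (initiator genes are written with a ``product`` attribute
    containing ``cdc6``)."""
    records = []
    for r in assembly.replicons:
        desc = f"topology={r.topology}"
        records.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")

    lines = ["##gff-version 3"]
    for r in assembly.replicons:
        lines.append(f"##sequence-region {r.id} 1 {r.length}")
    for i, f in enumerate(assembly.features):
        product = (
            "orc1/cdc6 family replication initiator"
            if f.is_initiator
            else "hypothetical protein"
        )
        attrs = f"ID=gene{i};Name={f.name};product={product}"
        lines.append(
            "\t".join(
                [
                    f.replicon_id,
                    "oriscope",
                    "gene",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    with open(gff_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bedgraph(path, replicon_id: str, starts, ends, values, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{replicon_id}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_bed6(path, rows) -> None:
    """rows: iterable of (chrom, start, end, name, score, strand)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{name}\t{int(score)}\t{strand}\n")
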