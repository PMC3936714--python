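"""Genetic logic of multi-origin replicons and the initiator-titration model.

Encodes four experimentally grounded rules for a multireplicon genome in
which every active origin depends on its co-located (cognate) orc1/cdc6
initiator gene:

* knockout viability - each replicon needs at least one functional origin
  (origin locus present, cognate initiator present, origin active); a
  titration region cannot be deleted while its regulated origin locus is
  retained (over-initiation proxy); some initiators are essential for
  reasons outside initiation and their loss gives sick-but-viable cells;
* ARS (autonomously replicating sequence) activity of origin plasmids -
  the cognate initiator must be available from the plasmid or the host
  genome (trans-supply allowed, non-cognate initiators never substitute);
* plasmid compatibility - an ARS plasmid whose origin is under
  titration-region control integrates when the host still carries that
  origin locus, and replicates episomally otherwise;
* an equilibrium initiator-titration model: free initiator F solves the
  mass balance T = F + (k + n_c) * F / (Kd + F) (identical independent
  sites, single occupancy), and initiation efficiency is the probability
  that all k origin sites are simultaneously occupied, (F/(Kd+F))**k.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml


class ModelError(ValueError):
    pass


OBTAINED = "obtained"
NOT_OBTAINED = "not_obtained"
OBTAINED_SICK = "obtained_sick"

ARS_POSITIVE = "ars_positive"
ARS_NEGATIVE = "ars_negative"

EPISOMAL = "episomal"
INTEGRATIVE = "integrative"


@dataclass(frozen=True)
class OriginEntry:
    name: str
    replicon: str
    cognate: str  # initiator gene id
    active: bool = True
    titration_region: str | None = None


@dataclass(frozen=True)
class ReplicationMap:
    origins: tuple[OriginEntry, ...]
    free_initiators: frozenset[str] = frozenset()  # cdc6 genes with no origin
    essential_other: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "origins", tuple(self.origins))
        cognates: dict[str, str] = {}
        for o in self.origins:
            if o.active and o.name in cognates:
                raise ModelError(f"duplicate origin {o.name}")
            cognates[o.name] = o.cognate

    @property
    def element_ids(self) -> frozenset[str]:
        ids = set(self.free_initiators)
        for o in self.origins:
            ids.add(o.name)
            ids.add(o.cognate)
            if o.titration_region:
                ids.add(o.titration_region)
        return frozenset(ids)

    @property
    def replicons(self) -> tuple[str, ...]:
        seen = []
        for o in self.origins:
            if o.replicon not in seen:
                seen.append(o.replicon)
        return tuple(seen)

    def origin(self, name: str) -> OriginEntry:
        for o in self.origins:
            if o.name == name:
                return o
        raise ModelError(f"unknown origin {name!r}")


@dataclass(frozen=True)
class Genotype:
    deleted: frozenset[str] = frozenset()

    @classmethod
    def of(cls, *ids: str) -> "Genotype":
        return cls(frozenset(ids))


@dataclass(frozen=True)
class PlasmidDesign:
    carried: frozenset[str] = frozenset()

    @classmethod
    def of(cls, *ids: str) -> "PlasmidDesign":
        return cls(frozenset(ids))


def _check_ids(rmap: ReplicationMap, ids) -> None:
    unknown = set(ids) - rmap.element_ids
    if unknown:
        raise ModelError(f"unknown element ids: {sorted(unknown)}")


def _functional(origin: OriginEntry, deleted: frozenset[str]) -> bool:
    return (
        origin.active
        and origin.name not in deleted
        and origin.cognate not in deleted
    )


def predict_knockout(rmap: ReplicationMap, genotype: Genotype) -> str:
    """Predict whether a combined deletion strain is obtainable.

    not_obtained when some replicon loses all functional origins, or when a
    titration region is deleted while its regulated origin locus is intact
    (runaway initiation proxy); obtained_sick when viable but an initiator
    with an essential role outside initiation is gone.
    """
    _check_ids(rmap, genotype.deleted)
    deleted = genotype.deleted
    for replicon in rmap.replicons:
        origins = [o for o in rmap.origins if o.replicon == replicon]
        if not any(_functional(o, deleted) for o in origins):
            return NOT_OBTAINED
    for o in rmap.origins:
        if (
            o.titration_region
            and o.titration_region in deleted
            and o.name not in deleted
        ):
            return NOT_OBTAINED
    if deleted & rmap.essential_other:
        return OBTAINED_SICK
    return OBTAINED


def predict_ars(rmap: ReplicationMap, plasmid: PlasmidDesign,
                host: Genotype) -> str:
    """ARS activity of an origin plasmid in a host genotype.

    Positive iff the carried origin's cognate initiator is supplied by the
    plasmid or still encoded in the host genome; initiators of other
    origins never substitute (cognate specificity).
    """
    _check_ids(rmap, plasmid.carried)
    _check_ids(rmap, host.deleted)
    origins = [o for o in rmap.origins if o.name in plasmid.carried]
    if len(origins) != 1:
        raise ModelError("plasmid must carry exactly one origin")
    origin = origins[0]
    available = (
        origin.cognate in plasmid.carried
        or origin.cognate not in host.deleted
    )
    return ARS_POSITIVE if available else ARS_NEGATIVE


def predict_compatibility(rmap: ReplicationMap, plasmid: PlasmidDesign,
                          host: Genotype) -> str:
    """Episomal maintenance vs chromosomal integration of an ARS plasmid.

    Integrative iff the carried origin is under titration-region control
    and the host genome retains that origin locus; otherwise episomal.
    """
    if predict_ars(rmap, plasmid, host) != ARS_POSITIVE:
        raise ModelError("compatibility is defined for ARS-positive plasmids")
    origin = next(o for o in rmap.origins if o.name in plasmid.carried)
    if origin.titration_region and origin.name not in host.deleted:
        return INTEGRATIVE
    return EPISOMAL


# ---------------------------------------------------------------------------
# Equilibrium titration model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationParams:
    """Total initiator T, site dissociation scale Kd (same molecule units),
    k origin sites, n_c competitor (titration-cluster) sites."""

    total_initiator: float = 20.0
    site_affinity: float = 1.0
    origin_sites: int = 2
    competitor_sites: int = 0

    def __post_init__(self) -> None:
        if self.total_initiator <= 0 or self.site_affinity <= 0:
            raise ModelError("T and Kd must be positive")
        if self.origin_sites < 1 or self.competitor_sites < 0:
            raise ModelError("need k >= 1 and n_c >= 0")


def free_initiator(params: TitrationParams, rel_tol: float = 1e-10) -> float:
    """Solve T = F + (k + n_c) * F/(Kd + F) for F by bisection on [0, T]."""
    T = params.total_initiator
    kd = params.site_affinity
    sites = params.origin_sites + params.competitor_sites

    def residual(f: float) -> float:
        return T - f - sites * f / (kd + f)

    lo, hi = 0.0, T
    assert residual(lo) > 0 >= residual(hi)
    while hi - lo > rel_tol * T:
        mid = (lo + hi) / 2
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def initiation_efficiency(params: TitrationParams) -> float:
    """Probability that all k origin sites are occupied at equilibrium."""
    f = free_initiator(params)
    occ = f / (params.site_affinity + f)
    return occ ** params.origin_sites


# ---------------------------------------------------------------------------
# Packaged Haloarcula hispanica replication map
# ---------------------------------------------------------------------------

def load_replication_map(path=None) -> ReplicationMap:
    """Load a replication map from YAML (default: the packaged
    H. hispanica map: 7 ori-cdc6 pairs over 3 replicons, 4 origin-less cdc6
    genes, the oriC2D titration region and the essential-beyond-replication
    cdc6A)."""
    if path is None:
        ref = importlib.resources.files("oriscope") / "data" / "hhis_map.yaml"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    origins = tuple(
        OriginEntry(
            name=o["name"],
            replicon=o["replicon"],
            cognate=o["cognate"],
            active=bool(o.get("active", True)),
            titration_region=o.get("titration_region"),
        )
        for o in raw["origins"]
    )
    return ReplicationMap(
        origins=origins,
        free_initiators=frozenset(raw.get("free_initiators", [])),
        essential_other=frozenset(raw.get("essential_other", [])),
    )


def hispanica_map() -> ReplicationMap:
    return load_replication_map()


def format_outcome_table(rows: list[tuple[str, str]]) -> str:
    """Plus/minus table: (label, outcome) -> aligned text lines."""
    signs = {OBTAINED: "+", NOT_OBTAINED: "-", OBTAINED_SICK: "+#",
             ARS_POSITIVE: "+", ARS_NEGATIVE: "-",
             EPISOMAL: "episomal", INTEGRATIVE: "integrative"}
    width = max((len(label) for label, _ in rows), default=0)
    return "\n".join(
        f"{label.ljust(width)}  {signs.get(outcome, outcome)}"
        for label, outcome in rows
    )
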