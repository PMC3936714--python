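"""Mimic-genome construction and marker-frequency simulation.

This module is the study-condition generator for the whole package: it
plants the haloarchaeal origin architecture (inverted ORB pair with
G-string extensions, AT-rich core, optional G-rich inverted-repeat enhancer
arms, an adjacent cdc6 gene, and an optional downstream ORB-rich titration
cluster) into random background sequence, designs tiling microarray probes,
and simulates two-channel marker-frequency signals from an asynchronous
exponentially growing population.

Population model
----------------
Cell age ``a`` follows the steady-state exponential age density
``f(a) = (2 ln2 / tau) * 2**(-a/tau)`` on ``[0, tau)``.  Each origin fires
independently at time ``s_o`` with probability ``p_o``; bidirectional forks
move at ``v`` bp/min and annihilate pairwise, so a locus ``x`` is replicated
at ``t(x) = min_o (s_o + d(x, o)/v)`` over the fired set.  Copy number is 2
where ``t(x) <= a``, else 1; a cell in which no origin fired stays
unreplicated.  For a single always-firing origin this gives the closed form
``M(x) = 2**(1 - t(x)/tau)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome_io import GeneFeature, GenomeAssembly, Replicon, revcomp
from .origin_scanner import DEFAULT_ORB_CONSENSUS


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Origin architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginArchitectureSpec:
    """Declarative description of one planted origin locus.

    ``orb_spacing`` is the length of the neutral A/T spacer inserted between
    adjacent planted blocks (between a G-string and an enhancer arm, and
    between an enhancer arm and the flanking G-string on the other side).
    Spacers are A/T-only so they can never extend a G-string run.
    """

    name: str
    orb_consensus: str = DEFAULT_ORB_CONSENSUS
    n_origin_orbs: int = 2
    orb_spacing: int = 5
    at_core_len: int = 150
    at_core_fraction: float = 0.85
    gstring_len: int = 8
    enhancer_arm: str | None = "GGGGAGGGGG"
    titration_orb_count: int = 0
    titration_region_len: int = 0
    cdc6_gene_len: int = 1200
    cdc6_offset: int = 100

    def __post_init__(self) -> None:
        if self.n_origin_orbs != 2:
            raise SyntheticDataError("only an inverted ORB pair (2) is supported")
        if not (0.5 < self.at_core_fraction <= 1.0):
            raise SyntheticDataError("at_core_fraction must be in (0.5, 1]")
        if self.titration_orb_count < 0:
            raise SyntheticDataError("titration_orb_count must be >= 0")
        if self.titration_orb_count > 0:
            need = self.titration_orb_count * len(self.orb_consensus)
            if self.titration_region_len < need:
                raise SyntheticDataError(
                    f"titration_region_len {self.titration_region_len} cannot hold "
                    f"{self.titration_orb_count} ORBs ({need} bp)"
                )
        if self.gstring_len < 0 or self.at_core_len <= 0:
            raise SyntheticDataError("bad element length")


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str


@dataclass
class GroundTruth:
    """Coordinates of every planted element, keyed by element id."""

    elements: dict[str, PlantedElement] = field(default_factory=dict)

    def add(self, elem: PlantedElement) -> None:
        if elem.element_id in self.elements:
            raise SyntheticDataError(f"duplicate element id {elem.element_id}")
        self.elements[elem.element_id] = elem

    def by_kind(self, kind: str) -> list[PlantedElement]:
        return [e for e in self.elements.values() if e.kind == kind]

    def __getitem__(self, element_id: str) -> PlantedElement:
        return self.elements[element_id]


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float,
                g_bias: float = 0.0) -> str:
    """i.i.d. background; g_bias shifts G/C balance for skewed replichores."""
    pg = gc / 2 * (1 + g_bias)
    pc = gc / 2 * (1 - g_bias)
    pa = pt = (1 - gc) / 2
    return "".join(_BASES[rng.choice(4, size=n, p=[pa, pc, pg, pt])])


def _at_rich_seq(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return "".join(_BASES[rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])])


def _at_spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("AT"))[rng.integers(0, 2, size=n)])


def _concrete_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracy to one concrete instance."""
    from .genome_io import IUPAC_SETS

    out = []
    for c in consensus.upper():
        choices = IUPAC_SETS.get(c)
        if choices is None:
            raise SyntheticDataError(f"bad consensus letter {c!r}")
        out.append(choices if len(choices) == 1 else rng.choice(list(choices)))
    return "".join(out)


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    s = list(seq)
    for i in rng.choice(len(s), size=n_mut, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def build_genome(
    specs: list[OriginArchitectureSpec],
    replicon_lens: list[int],
    gc_background: float = 0.6,
    seed: int = 0,
    placements: list[tuple[int, int]] | None = None,
    skew_amp: float = 0.0,
) -> tuple[GenomeAssembly, GroundTruth]:
    """Build a multi-replicon genome with planted origin loci.

    placements maps each spec to (replicon index, locus start).  By default
    specs are distributed round-robin over replicons at evenly spaced loci.
    With ``skew_amp > 0`` the background of each replicon carrying at least
    one origin gets a leading-strand G excess that flips at the first
    planted origin and at its antipode (a GC-skew mimic).
    """
    rng = np.random.default_rng(seed)
    n_rep = len(replicon_lens)
    if placements is None:
        per_rep: dict[int, list[int]] = {}
        for i in range(len(specs)):
            per_rep.setdefault(i % n_rep, []).append(i)
        placements_arr: list[tuple[int, int]] = [(0, 0)] * len(specs)
        for ri, spec_ids in per_rep.items():
            L = replicon_lens[ri]
            k = len(spec_ids)
            for j, si in enumerate(spec_ids):
                placements_arr[si] = (ri, L * (j + 1) // (k + 1))
        placements = placements_arr
    if len(placements) != len(specs):
        raise SyntheticDataError("placements length must match specs")

    # background sequences (skew flips at the first origin of each replicon)
    seqs: list[list[str]] = []
    first_origin: dict[int, int] = {}
    for si, (ri, pos) in enumerate(placements):
        first_origin.setdefault(ri, pos)
    for ri, L in enumerate(replicon_lens):
        if skew_amp > 0 and ri in first_origin:
            o = first_origin[ri] % L
            t = (o + L // 2) % L
            s = list(_random_seq(rng, L, gc_background, g_bias=skew_amp))
            # leading-strand G excess on the o->t replichore, C excess on t->o
            other = list(_random_seq(rng, L, gc_background, g_bias=-skew_amp))
            i = t
            while i != o:
                s[i] = other[i]
                i = (i + 1) % L
            seqs.append(s)
        else:
            seqs.append(list(_random_seq(rng, L, gc_background)))

    gt = GroundTruth()
    features: list[GeneFeature] = []
    occupied: dict[int, list[tuple[int, int]]] = {ri: [] for ri in range(n_rep)}
    rep_ids = [f"replicon_{ri + 1}" for ri in range(n_rep)]

    def claim(ri: int, start: int, end: int, what: str) -> None:
        if end > replicon_lens[ri]:
            raise SyntheticDataError(
                f"{what} ({start}, {end}) does not fit replicon of length "
                f"{replicon_lens[ri]}"
            )
        for s, e in occupied[ri]:
            if start < e and s < end:
                raise SyntheticDataError(f"{what} overlaps a previous element")
        occupied[ri].append((start, end))

    for spec, (ri, locus_start) in zip(specs, placements):
        L = replicon_lens[ri]
        rid = rep_ids[ri]
        rng_local = rng  # single stream: deterministic under the one seed
        inst = _concrete_consensus(spec.orb_consensus, rng_local)
        m = len(inst)
        gl = spec.gstring_len
        sp = spec.orb_spacing

        blocks: list[tuple[str | None, str, str, str]] = [
            ("orb_left", inst, "+", "orb"),
            ("gstring_left", "G" * gl, "+", "gstring"),
            (None, _at_spacer(rng_local, sp), ".", "spacer"),
        ]
        if spec.enhancer_arm:
            blocks += [
                ("enhancer_left", spec.enhancer_arm.upper(), "+", "enhancer"),
                (None, _at_spacer(rng_local, sp), ".", "spacer"),
            ]
        blocks.append(
            ("at_core", _at_rich_seq(rng_local, spec.at_core_len,
                                     spec.at_core_fraction), ".", "at_core")
        )
        if spec.enhancer_arm:
            blocks += [
                (None, _at_spacer(rng_local, sp), ".", "spacer"),
                ("enhancer_right", revcomp(spec.enhancer_arm.upper()), "-",
                 "enhancer"),
            ]
        blocks += [
            (None, _at_spacer(rng_local, sp), ".", "spacer"),
            ("gstring_right", "C" * gl, "-", "gstring"),
            ("orb_right", revcomp(inst), "-", "orb"),
        ]

        pos = locus_start
        for name, block_seq, strand, kind in blocks:
            end = pos + len(block_seq)
            if name is not None:
                gt.add(PlantedElement(f"{spec.name}.{name}", rid, pos, end,
                                      strand, kind))
            pos = end
        locus_end = pos
        claim(ri, locus_start, locus_end, f"{spec.name} origin locus")
        flat = "".join(b for _, b, _, _ in blocks)
        seqs[ri][locus_start:locus_end] = list(flat)
        gt.add(PlantedElement(f"{spec.name}.origin_locus", rid, locus_start,
                              locus_end, ".", "origin_locus"))

        gene_start = locus_end + spec.cdc6_offset
        gene_end = gene_start + spec.cdc6_gene_len
        claim(ri, gene_start, gene_end, f"{spec.name} cdc6 gene")
        gene_name = f"cdc6_{spec.name}"
        features.append(
            GeneFeature(rid, gene_start, gene_end, "+", gene_name,
                        is_initiator=True)
        )
        gt.add(PlantedElement(f"{spec.name}.cdc6", rid, gene_start, gene_end,
                              "+", "cdc6"))

        if spec.titration_orb_count > 0:
            k = spec.titration_orb_count
            region_start = gene_end + 10
            region_end = region_start + spec.titration_region_len
            claim(ri, region_start, region_end, f"{spec.name} titration region")
            slack = spec.titration_region_len - k * m
            gaps = rng_local.multinomial(slack, np.full(k + 1, 1 / (k + 1)))
            pos = region_start
            region_seq = []
            for i in range(k):
                gap = int(gaps[i])
                region_seq.append(_random_seq(rng_local, gap, gc_background))
                pos += gap
                orb = _mutate(inst, int(rng_local.integers(0, 3)), rng_local)
                strand = "+" if rng_local.random() < 0.5 else "-"
                planted = orb if strand == "+" else revcomp(orb)
                region_seq.append(planted)
                gt.add(PlantedElement(
                    f"{spec.name}.titration_orb_{i:02d}", rid, pos, pos + m,
                    strand, "titration_orb"))
                pos += m
            region_seq.append(_random_seq(rng_local, int(gaps[k]), gc_background))
            flat = "".join(region_seq)
            assert len(flat) == spec.titration_region_len
            seqs[ri][region_start:region_end] = list(flat)
            gt.add(PlantedElement(f"{spec.name}.titration_region", rid,
                                  region_start, region_end, ".",
                                  "titration_region"))

    replicons = tuple(
        Replicon(id=rep_ids[ri], sequence="".join(seqs[ri]))
        for ri in range(n_rep)
    )
    return GenomeAssembly(replicons, tuple(features)), gt


def apply_site_mutation(
    assembly: GenomeAssembly,
    site: PlantedElement,
    replacement: str,
) -> GenomeAssembly:
    """Replace exactly the site's bases (plus-strand notation)."""
    if len(replacement) != site.end - site.start:
        raise SyntheticDataError(
            f"replacement length {len(replacement)} != site length "
            f"{site.end - site.start}"
        )
    rep = assembly.replicon(site.replicon_id)
    seq = rep.sequence[: site.start] + replacement.upper() + rep.sequence[site.end:]
    return assembly.with_sequence(site.replicon_id, seq)


_SWAP_GA = str.maketrans("GA", "AG")
_SWAP_CT = str.maketrans("CT", "TC")

#: The four G-rich site mutations assayed at the minimal chromosomal origin:
#: the two G-strings within the ORBs (I: C-run -> T-run, II: G-run -> A-run)
#: and the two enhancer inverted-repeat arms (III: G<->A, IV: C<->T swaps,
#: preserving purine/pyrimidine identity while destroying the G-richness).
SITE_MUTATIONS = {
    "SMI": ("gstring_right", lambda s: s.translate(_SWAP_CT)),
    "SMII": ("gstring_left", lambda s: s.translate(_SWAP_GA)),
    "SMIII": ("enhancer_left", lambda s: s.translate(_SWAP_GA)),
    "SMIV": ("enhancer_right", lambda s: s.translate(_SWAP_CT)),
}


def apply_named_mutation(
    assembly: GenomeAssembly,
    gt: GroundTruth,
    origin_name: str,
    which: str,
) -> GenomeAssembly:
    """Apply one of SMI..SMIV to a planted origin locus."""
    element, transform = SITE_MUTATIONS[which]
    site = gt[f"{origin_name}.{element}"]
    rep = assembly.replicon(site.replicon_id)
    original = rep.sequence[site.start:site.end]
    return apply_site_mutation(assembly, site, transform(original))


# ---------------------------------------------------------------------------
# Microarray design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayDesign:
    probes: pd.DataFrame  # columns: replicon_id, position, length
    probe_len: int
    min_density: float

    def positions(self, replicon_id: str) -> np.ndarray:
        sub = self.probes[self.probes["replicon_id"] == replicon_id]
        return sub["position"].to_numpy()


def design_probes(
    assembly: GenomeAssembly,
    probe_len: int = 60,
    min_density: float = 1.0,
    seed: int = 0,
) -> ArrayDesign:
    """One probe per gene midpoint plus an evenly spaced tiling grid.

    The grid spacing is 1000 / ceil(min_density) bp so every sliding 1-kb
    window holds at least ``min_density`` probes; the grid phase is drawn
    from the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    spacing = max(1, int(1000 // int(np.ceil(min_density))))
    for rep in assembly.replicons:
        if rep.length < probe_len:
            raise SyntheticDataError(
                f"replicon {rep.id!r} shorter than probe length"
            )
        phase = int(rng.integers(0, spacing)) % max(1, min(spacing, rep.length))
        grid = np.arange(phase % spacing, rep.length, spacing, dtype=int)
        mids = [
            ((f.start + f.end) // 2) % rep.length
            for f in assembly.features_on(rep.id)
        ]
        pos = np.unique(np.concatenate([grid, np.asarray(mids, dtype=int)])
                        if mids else grid)
        for p in pos:
            rows.append((rep.id, int(p), probe_len))
    probes = pd.DataFrame(rows, columns=["replicon_id", "position", "length"])
    return ArrayDesign(probes=probes, probe_len=probe_len,
                       min_density=min_density)


# ---------------------------------------------------------------------------
# Replication program and population simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginActivity:
    position: int
    firing_prob: float
    firing_delay: float = 0.0  # minutes


@dataclass(frozen=True)
class ReplicationProgram:
    """Origins with firing probabilities on one circular replicon."""

    replicon_id: str
    replicon_length: int
    origins: tuple[OriginActivity, ...]
    fork_speed: float  # bp / minute
    doubling_time: float  # minutes

    def __post_init__(self) -> None:
        object.__setattr__(self, "origins", tuple(self.origins))
        if self.replicon_length <= 0:
            raise SyntheticDataError("replicon_length must be positive")
        if self.fork_speed <= 0 or self.doubling_time <= 0:
            raise SyntheticDataError("fork_speed and doubling_time must be > 0")
        if not self.origins:
            raise SyntheticDataError("at least one origin required")
        for o in self.origins:
            if not (0.0 <= o.firing_prob <= 1.0):
                raise SyntheticDataError("firing_prob must be in [0, 1]")
            if o.firing_delay < 0:
                raise SyntheticDataError("firing_delay must be >= 0")
        if max(o.firing_prob for o in self.origins) < 1.0:
            raise SyntheticDataError(
                "viability requires at least one origin with firing_prob 1"
            )

    def with_firing_probs(self, probs) -> "ReplicationProgram":
        origins = tuple(
            replace(o, firing_prob=float(p))
            for o, p in zip(self.origins, probs)
        )
        return ReplicationProgram(self.replicon_id, self.replicon_length,
                                  origins, self.fork_speed, self.doubling_time)


def _replication_times(program: ReplicationProgram,
                       positions: np.ndarray) -> np.ndarray:
    """t[o, j] = minutes until a fork from origin o reaches probe j."""
    L = program.replicon_length
    t = np.empty((len(program.origins), len(positions)))
    for i, o in enumerate(program.origins):
        d = np.abs(positions - o.position)
        d = np.minimum(d, L - d)
        t[i] = o.firing_delay + d / program.fork_speed
    return t


def expected_ratio_profile(program: ReplicationProgram,
                           positions: np.ndarray) -> np.ndarray:
    """Closed-form expected exponential:stationary ratio per probe.

    Mixture over all origin-firing subsets S:
    ``E[copy] = sum_S P(S) * max(1, 2**(1 - t_S(x)/tau))`` with
    ``t_S(x) = min_{o in S} (s_o + d(x,o)/v)`` and 1 for the empty set.
    """
    positions = np.asarray(positions, dtype=float)
    t = _replication_times(program, positions)
    probs = np.array([o.firing_prob for o in program.origins])
    n = len(probs)
    tau = program.doubling_time
    out = np.zeros(len(positions))
    for mask in range(2 ** n):
        fired = [(mask >> i) & 1 for i in range(n)]
        w = np.prod([p if f else 1 - p for p, f in zip(probs, fired)])
        if w == 0:
            continue
        if mask == 0:
            out += w
            continue
        t_s = np.min(t[[i for i in range(n) if fired[i]]], axis=0)
        out += w * np.maximum(1.0, 2.0 ** (1.0 - t_s / tau))
    return out


def _lognormal_noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_marker_frequency(
    program: ReplicationProgram,
    design: ArrayDesign,
    n_cells: int = 10000,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-channel signal table over the array design.

    Returns a tidy frame with columns replicon_id, position, exp_signal,
    stat_signal, replicate.  Each replicate resamples both the cell
    population and the multiplicative lognormal measurement noise.
    """
    if n_cells < 1:
        raise SyntheticDataError("n_cells must be >= 1")
    probs = np.array([o.firing_prob for o in program.origins])
    if np.all(probs == 0):
        raise SyntheticDataError("all firing probabilities are zero")
    positions = design.positions(program.replicon_id)
    if positions.size == 0:
        raise SyntheticDataError(
            f"no probes on replicon {program.replicon_id!r}"
        )
    rng = np.random.default_rng(seed)
    tau = program.doubling_time
    t = _replication_times(program, positions.astype(float))
    n_origins = len(program.origins)

    frames = []
    for rep in range(1, n_replicates + 1):
        u = rng.random(n_cells)
        ages = -tau * np.log2(1.0 - u / 2.0)  # inverse CDF of the age density
        fired = rng.random((n_cells, n_origins)) < probs
        masks = fired @ (1 << np.arange(n_origins))
        mean_copy = np.zeros(len(positions))
        for mask in np.unique(masks):
            sel = masks == mask
            count = int(sel.sum())
            if mask == 0:
                mean_copy += count / n_cells  # unreplicated cells: copy 1
                continue
            idx = [i for i in range(n_origins) if (mask >> i) & 1]
            t_s = np.min(t[idx], axis=0)
            a_sorted = np.sort(ages[sel])
            n_ge = count - np.searchsorted(a_sorted, t_s, side="left")
            mean_copy += (count + n_ge) / n_cells  # count*(1) + n_ge extra copy
        exp_sig = mean_copy * _lognormal_noise(rng, len(positions), noise_cv)
        stat_sig = _lognormal_noise(rng, len(positions), noise_cv)
        frames.append(pd.DataFrame({
            "replicon_id": program.replicon_id,
            "position": positions,
            "exp_signal": exp_sig,
            "stat_signal": stat_sig,
            "replicate": rep,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Packaged fixture configs
# ---------------------------------------------------------------------------

PACKAGED_CONFIGS = (
    "hhis_oriC1_mimic",
    "hhis_oriC2_mimic",
    "hla_oriC2_mimic",
)


def load_mimic_config(name_or_path) -> dict:
    """Load a packaged mimic config by name, or any YAML file by path."""
    name = str(name_or_path)
    if name in PACKAGED_CONFIGS:
        ref = importlib.resources.files("oriscope") / "data" / f"{name}.yaml"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(name_or_path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


def build_from_config(name_or_path, seed: int | None = None):
    """Build a mimic genome from a config; returns (assembly, truth, config)."""
    cfg = load_mimic_config(name_or_path)
    origin_cfg = dict(cfg["origin"])
    spec = OriginArchitectureSpec(**origin_cfg)
    use_seed = cfg["seed"] if seed is None else seed
    assembly, gt = build_genome(
        [spec],
        [int(cfg["replicon_length"])],
        gc_background=float(cfg.get("gc_background", 0.6)),
        seed=int(use_seed),
        placements=[(0, int(cfg["origin_position"]))],
        skew_amp=float(cfg.get("skew_amp", 0.0)),
    )
    return assembly, gt, cfg
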