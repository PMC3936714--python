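# Methods

## Population model behind the marker-frequency simulator

The simulator draws cells from the steady-state age distribution of an
asynchronous exponentially growing culture, truncated to one doubling time:
`f(a) = (2 ln2/τ)·2^(−a/τ)` on `[0, τ)`. Division-time variance and
B/D-period structure are deliberately omitted; the minimal steady-state
model is sufficient to produce the tent-shaped log-ratio profiles that MFA
measures.

Each origin *o* fires independently with probability `p_o` at time `s_o`
(default 0). Bidirectional forks move at a constant speed `v` (bp/min) and
annihilate pairwise; with equal speeds this makes the replication time of a
locus simply `t(x) = min_o (s_o + d(x, o)/v)` over the *realized* firing
set, where `d` is circular distance. Non-fired origins are replicated
passively by incoming forks; a cell in which no origin fired contributes
copy number 1 everywhere. Copy number at `x` is 2 if `t(x) ≤ a`, else 1.

For a single origin with `p = 1` and `s = 0` this yields the closed form
`E[copy](x) = 2^(1 − t(x)/τ)` for `t ≤ τ` (and 1 beyond); for several
origins the expectation is the mixture over firing subsets `S`:
`E[copy] = Σ_S P(S)·max(1, 2^(1 − t_S(x)/τ))`. The simulator is checked
against this closed form, and the origin-usage fitter uses it as its
forward model.

Measurement noise is multiplicative lognormal per probe per channel
(mean 1, CV `noise_cv`, default 0.1), independent across replicates; both
the cell population and the noise are resampled per replicate. Lognormal
noise keeps signals positive and is scale-free, matching how two-channel
array intensities behave after normalization.

### Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `doubling_time` τ | min | 120 | haloarchaeal lab growth scale |
| `fork_speed` v | bp/min | 300–500 | chosen per experiment so `t_ter/τ` falls in 0.5–1; the demo uses 500 so a lone origin finishes the 120-kb mimic within one cycle (deletion analogs must be viable) |
| `noise_cv` | fraction | 0.1 | typical two-channel array ratio scatter |
| `n_replicates` | – | 3 | three biological replicates, as in the assay the simulator emulates |
| probe density | /kb | 1 (≥2 for MFA tests) | one probe per kb minimum, plus one probe per gene midpoint; 60-mers |

## MFA processing

Per replicate, both channels are divided by the replicate's
stationary-channel median (the upstream normalization pipeline of real
two-channel data is platform-specific; median-of-stationary is a robust,
scale-free stand-in), the per-probe ratio is exponential/stationary, and
replicate ratios are averaged. Smoothing is a centered circular moving
average on log2 ratios; profiles are treated as circular everywhere
(replicons are circular). Peak calling rotates the profile so its global
minimum sits at the seam, finds local maxima with prominence ≥ 0.1 log2,
and keeps them greedily by decreasing prominence subject to a 50-kb
minimum separation — values that separate two chromosomal-scale origin
peaks while rejecting noise bumps at the simulated CV. Plateau apexes take
the lowest coordinate.

Smoothing bandwidth is an analysis choice: ~10 kb (21 probes at 2
probes/kb) for noisy profiles, matching common MFA practice; window 5 or
none for noiseless checks. The usage fitter always works on the
*unsmoothed* profile because smoothing flattens peak apexes and biases
firing-probability estimates downward.

A reference peak is scored **lost** in a mutant when the mutant's height
over the peak — its log2 ratio at the reference apex minus the larger of
its log2 ratios at the reference peak's two prominence bases — is both
below half the reference height and below the prominence threshold. The
apex-minus-bases form matters: after an origin deletion the profile slopes
monotonically through the old peak's span, and a naive max-minus-min over
the span would mistake that slope for a retained peak.

Origin-usage fitting is an exhaustive grid search (`p` in steps of 0.05
per origin, `t_ter/τ` in 0.2–2.0 steps of 0.1) over the closed-form
mixture with `s_o = 0`, minimizing squared log2 error. Synchronous
potential firing at birth is a simplification that keeps the model
identifiable at desk scale; with it, recovery on simulated data is exact
at moderate noise (see the parameter-recovery tests).

## Sequence scanning

ORB hits are counted by per-position mismatches against an IUPAC consensus
on both strands (minus strand via the reverse-complement pattern), with a
wrap window of consensus length − 1 on circular replicons. `N` in the
subject never matches. Overlapping same-strand hits collapse to the
lowest-mismatch hit (ties leftmost). The packaged 20-nt default consensus
follows the classic archaeal ORB motif; the figure-level consensus of any
particular genome should be supplied via config, and the synthetic
genomes are always built from the same consensus the scanner uses. The
default `max_mismatch = 3` tolerates titration-cluster ORBs planted with
up to 2 substitutions while random 20-mer hits at ≤ 3 mismatches occur at
~3·10⁻⁸ per position per strand — effectively zero on desk-scale genomes.

The halophile-specific G-string is measured on the hit's strand-aware 3′
flank as a run of ≥ 6 consecutive G (appearing as a C-run left of a
minus-strand hit); it is treated as part of the ORB element.

AT-rich cores are maximal merged runs of 100-bp windows (step 10,
circular) whose AT fraction exceeds the replicon background by 0.20. The
offset is ~4 binomial standard deviations for a 100-bp window: measured
empirically before freezing, a +0.10 offset yields dozens of false windows
per 10 kb and +0.15 still 1–2 false regions per 20 kb, while +0.20 leaves
uniform background essentially clean and still sits far below the planted
cores (0.85 AT against ~0.40 background).

Inverted ORB pairs face inward (plus-strand hit upstream of minus-strand
hit, G-strings pointing into the gap), require an AT-rich region inside
the 20–500-bp inner gap, and are formed greedily by smallest gap. The
enhancer search looks for the longest *perfect* inverted repeat with arms
≥ 8 bp and G-rich-strand G fraction ≥ 0.8 inside the inter-ORB interval
*excluding* the G-string extensions — the two inward-facing G-strings are
themselves a perfect G-rich inverted repeat, so including them would make
an enhancer call tautological and immune to enhancer-arm mutations. Ties
resolve to the leftmost left arm, then the smallest loop.

Titration clusters group leftover ORB hits (outside any origin candidate)
whose consecutive gaps stay below `max_span/cluster_min` (default
1000/3 bp); the gap rule, rather than a fixed window, accommodates both
the dense 11-elements-in-722-bp architecture and sparser 3-element
clusters. Candidates are classified `ori_cdc6` when the nearest annotated
initiator gene lies within 2 kb edge-to-edge (circular), else `orphan`.

## Nucleotide disparity

Windowed skews are `(G−C)/(G+C)` and `(A−T)/(A+T)` per circular window
(0 where the denominator is 0). The cumulative track is the per-base
(G−C) running sum from coordinate 0 sampled at step boundaries, so its
final value equals the replicon's total G−C. On a circle the anchor is
arbitrary: only the extrema positions are meaningful, and they mark the
replichore switch points (origin and terminus under leading-strand G
excess). The synthetic generator can plant such strand asymmetry
(`skew_amp`), flipping at the first origin and its antipode.

## Genetic logic and titration model

The knockout, ARS and compatibility predictors encode experimentally
grounded rules over a declarative replication map (origins with cognate
initiators, activity flags, optional titration regions, initiators
essential outside replication). The titration-region lethality rule
(region deleted while its regulated origin locus is intact → not
obtainable) is a stated rule — an over-initiation proxy — not a derived
consequence of the titration model, because the mechanism is a hypothesis;
likewise the integration rule (titration-controlled origin on a plasmid
integrates when the host retains that origin locus) is hypothesis-derived
and labeled as such. Origin activity flags (dormant minichromosomal
origins, the indispensable megaplasmid origin) are data, not inference.

The equilibrium titration model treats all binding sites as identical and
independent with single occupancy: `T = F + (k + n_c)·F/(K_d + F)` is
solved for free initiator `F` by bisection on `[0, T]` to relative
tolerance 1e−10, and initiation requires all `k` origin sites occupied
simultaneously, `(F/(K_d+F))^k`. Defaults `T = 20·K_d`, `k = 2`. This is
the minimal model that yields the observed qualitative dose response
(efficiency strictly decreasing in competitor sites, increasing in total
initiator); it makes no kinetic or cooperative claims.

## What the synthetic data does and does not emulate

The generator reproduces the *architecture* of the origins (element order,
orientations, G-strings, enhancer arms, cluster density) and the
*population statistics* of marker frequency, on 40–120-kb replicons —
roughly 1/25 of the real chromosome scale, sized so the whole suite runs
in seconds. It does not emulate dye bias or spatial array artifacts,
replication–transcription conflicts, cell-cycle period structure, or the
sequence composition of real haloarchaeal genomes beyond a uniform 60 %
GC background (with optional strand asymmetry). Passing tests therefore
demonstrate the correctness of the algorithms on data satisfying the
stated models, not performance on real arrays or real genome sequence;
the scanner in particular assumes the supplied consensus matches the
genome's ORB dialect.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 is converted at the
  boundary; BED/bedGraph outputs are 0-based half-open. Spans that cross
  the circular seam are represented with end > replicon length (or start
  unrolled negative around a peak apex) and documented per field.
* Peak spans are unrolled around the apex so `span[0] ≤ position ≤
  span[1]` always holds.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic stage takes an explicit seed and fixed seeds reproduce
  byte-identical outputs (TSV floats are formatted with `%.6g`).
* Degenerate inputs fail loudly: empty consensus, windows larger than the
  replicon, all-silent replication programs, non-positive signal tables,
  mismatched probe grids, unknown genotype element ids.
* The site-mutation helpers implement the four G-rich site mutants as
  base swaps (G↔A, C↔T), which preserves length and purine/pyrimidine
  class while destroying G-richness.
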