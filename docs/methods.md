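# Methods

## The compartment model

Syncytial tissue is modelled as a graph of **well-mixed compartments**.  Each
node carries a volume (µm³), a nucleus count, and one concentration per
fluorescent species (a.u.); each undirected edge is an exchange bridge (ring
canal or fusion pore) with a rate *k* (s⁻¹) and an open/closed state.  For
species *s* on an open edge (a, b) the flux is *k·(C_b − C_a)*, applied
symmetrically to both nodes.  Volumes do not enter the kinetics: these
assays constrain no volumetric rate law, and the equal-volume convention
keeps the system linear and exactly checkable against closed forms.  The conservation guarantee (total volume-weighted amount constant
without sinks) therefore holds as stated for equal volumes, which all
shipped fixtures use.

Photomanipulation protocols schedule `pre → event → post` acquisition frames
at a fixed frame interval.  During event frames, **bleaching** removes the
bleached species in the target node at rate β (a bleach ROI smaller than its
compartment is the same as whole-compartment bleaching at
β·ROI-volume/compartment-volume, because intra-compartment mixing is assumed
fast relative to bleaching); **conversion** transfers `kaede_native` to
`kaede_converted` in the target node at rate γ.  **Imaging decay** is a
discrete per-acquisition multiplier (1 − α) per channel, not a continuous
rate, because it models the photobleaching incurred by each acquisition
itself.  Acquisition order per frame: record, apply decay, integrate one
frame interval.

**Integration.**  The scheme is explicit fixed-step RK4 (default step:
frame interval / 100).  Because bleaching, conversion and exchange are all
linear, the RK4 update over one sub-step is a constant matrix
(I + A + A²/2 + A³/6 + A⁴/24 with A = M·dt), and the per-frame propagator is
that matrix raised to the number of sub-steps — identical to the RK4
iterates in exact arithmetic and fast enough that a 10⁻⁶-relative
verification against the analytic two-compartment solution over a 4 × 4
(k, β) ∈ {0, 0.01, 0.1, 1}² s⁻¹ grid up to t = 300 s runs in well under a
second (at solver_dt = 5 ms; the analytic reference is an
eigen-decomposition of the 2 × 2 generator).  Stiff regimes are out of
scope; determinism is required, so no adaptive stepping.

**Rendering.**  Pixel value = gain · C_node(t) + background (+ Gaussian
and/or Poisson noise, seeded).  Values are clipped at zero after noise, so
fixtures carry enough background offset that clipping is negligible.
Coordinates are 0-based, frame ranges half-open.  All randomness flows from
a single integer seed; there is no global random state.

**Fixtures.**  `two_open`, `two_closed`, `chain3` and `fused_units` render
documented graphs at gain 100, background 10, Gaussian SD 2 (2% of signal),
pixel size 0.5 µm, frame interval 2 s, per-frame decay 0.001, bleach rate
0.5 s⁻¹ and bridge rate 0.05 s⁻¹.  Compartments are rendered as abutting
rectangular tiles with no background margin, so randomly placed null squares
sample exactly the decay-plus-noise population that an unbleached zone
experiences.  `fused_units` encodes the five-zone configuration produced by
partial fusion: a green-only zone in continuity with two fused subzones
(H_GFP, L_GFP) that are separated from each other by a barrier, one red zone
connected to L_GFP, and one untouched red neighbour.

## FLIP statistics

%FL = 1 − I_MEAN(Tend)/I_MEAN(Tstart).  **Tstart** defaults to the mean of
the pre-bleach frames (robust to single-frame noise) and **Tend** to the
final frame.  %FL is invariant to a global gain but *not* to an additive
offset; background subtraction is the caller's responsibility.

The **Monte-Carlo null** samples %FL (same Tstart/Tend convention) over
n = 10,000 squares of 10 × 10 µm placed uniformly at random, fully inside
the field, in the channel the caller names (in practice the unbleached
fluorophore).  The µm→pixel conversion rounds the square side to the nearest
integer ≥ 1.  Squares may overlap any region, including the bleach ROI —
an optional exclusion mask restricts them.  The threshold is the empirical
quantile at the confidence level, by the nearest-rank method, so by
construction the fraction of null samples at or below it equals the
confidence up to ties; the default level is 0.95, exposed as a parameter.
Significance is a *strict* inequality: a %FL exactly at the threshold is
still attributable to chance.  Across several movies of one fluorophore the
largest (most stringent) threshold is kept.  Box sums over summed-area
tables make the 10,000-square null essentially free (milliseconds on a
512 × 512 field).

Connected-nuclei counting sums the nuclei of every zone with a significant
call plus the bleached zone itself.  Photoconversion propagation calls a
distal zone "reached" when its mean converted-channel intensity at the
evaluation frame exceeds the background mean + 3 SD, with background
statistics taken from the same trace over the pre-conversion frames; the
summary is the percentage of adjacent clones reached.

## Compartment-map inference

Evidence records (one bleached zone, one observed zone, one significance
call) reduce to pairwise relations: significant ⇒ *connected*;
non-significant in a zone sharing a border with the bleached zone ⇒
*barrier* (absence of loss in a distant zone is weak evidence and stays
*untested*); a pair with both kinds of evidence is *dynamic* — read as
temporal remodelling of connectivity rather than measurement error, so
dynamic pairs contribute to neither merging nor separation.  Adjacency is
supplied by the caller (or taken as "all pairs" when omitted).

Zones merge by union-find over connected edges only; barrier pairs landing
inside a merged block are **violations** (again: remodelling).  The
**minimum compartment count** is the smallest number of blocks over all set
partitions such that no barrier pair shares a block and every block of more
than one zone is internally connected through connected evidence.  Merging
across a merely-untested pair is not allowed — a compartment is only as
large as the evidence for it — which is why the five-zone worked example
yields three compartments, not two.  The search is exhaustive
(Bell-number enumeration) and exact up to 10 zones; beyond that it is
refused and a lower bound (merged blocks + violations) is reported in the
error.  Only binary relations are inferred; exchange-rate magnitudes are
not estimated from %FL kinetics.

The simulated bleach survey (`run_bleach_survey`) bleaches each zone in turn
(β = 1 s⁻¹ for 150 frames at 2 s, per-frame decay 5 × 10⁻⁴), computes each
movie's null from the unbleached channel and measures every other zone in
the bleached channel.  These protocol values were chosen so that, noise-free,
loss at the far end of an eight-compartment chain (bridge rate 0.1 s⁻¹)
still clears the decay-driven threshold by a comfortable margin.

## Clonal dynamics

Discrete-time simulation at 1 h resolution over a horizon in hours ALH
(after larval hatching).  Founders start mononucleated with one copy of the
labelling transgene (heterozygous single insertion).  Within its window,
**endoreplication** doubles a nucleus's copies; **acytokinetic mitosis**
duplicates a nucleus within its unit — every copy is replicated and each
daughter receives one replica, so copy number and colours are conserved
through division, as they are in polyploid mitosis (replication precedes
partition).  **Fusion** merges two adjacent units (adjacency is a fixed
random geometric graph over founder positions, radius set for ≈ 4 expected
neighbours) and is logged with per-partner copy snapshots.  A per-nucleus
event with continuous rate *r* fires per step with probability e^r − 1
(capped at 1), making the expected per-step multiplication factor exactly
e^r, so a mitosis-only window of width *w* gives an expected unit size of
e^(r·w) — the property the branching-process test checks.

**Label induction** at time *t*: every transgene copy alive at *t*
independently recombines with probability = efficiency and, if it does,
draws one of four colours uniformly; later replicas inherit the colour of
the copy they came from.  Copy lineage is tracked explicitly, so induction
is applied retroactively to a finished simulation and several induction
times can be compared on the *same* event realisation (the baseline for
case classification is induction at t = 0 on the same seed).

**Clones** are maximal groups of labelled nuclei within one unit that share
an identical colour combination — the observable in tissue is colour plus
contiguity, and units are spatially separate territories.  The simulator
also knows ground-truth founder lineage and reports it per clone.  Nuclei
with no recombined copy are invisible and tallied separately.  Adjacent
same-combination clones in different units are not merged (rare with four
colours; a known idealisation).  Single-coloured clones at late induction
can arise through two routes — nuclei that never endoreplicated, or
multi-copy nuclei whose copies all drew the same colour — and the statistics
report both counts rather than asserting one.

**Case classification** against the t = 0 baseline: multicoloured-clone
fraction ≥ 0.2 distinguishes cases {2, 4} from {1, 3}; clone number > 1.2 ×
baseline distinguishes {3, 4} from {1, 2}.  Both thresholds are parameters
with these documented defaults (the source assays state only qualitative
directions).  Case 3 (mitosis before endoreplication) is implemented for
completeness even though the canonical schedule never produces it.  The
**canonical schedule** is 16 founders, endoreplication in [16, 48) h at
0.05 h⁻¹ per nucleus, mitosis in [48, 80) h at 0.04 h⁻¹, horizon 96 h —
endoreplication preceding mitosis at the population level, with rates set so
that by 48 h most nuclei carry multiple copies and final unit sizes are a
few nuclei.  Fusion defaults to off in clone-dynamics work (cases are a
proliferation-timing readout); overlap counting enables it explicitly.

**Fusion-overlap counting** (membrane labelling): a logged fusion is
detectable iff the two partners carried different colour combinations at
fusion time (from the logged copy snapshots); same-colour fusions are
flagged undetectable.  `events_per_clone` divides logged fusion events by
the total clone count and is invariant under colour relabelling.

## Niche quantification

`sample_cubes` places n (default 6) non-overlapping cubes of 150 × 150 px
footprint by seeded rejection sampling, honouring an optional exclusion
mask; the z extent "down to the anatomical boundary" is an explicit
`z_limit` parameter.  Membrane segmentation is plain 1-D k-means on the
intensity values (the hierarchical variant in the original toolbox is used
only as an intensity threshold, which plain k-means reproduces): Lloyd
iterations from two deterministic initialisations (mid-quantile centres and
centres spread evenly over the value range), keeping the lower-SSE solution;
membrane = the highest-mean cluster (k = 4 may keep the top two,
configurable), k kept constant across conditions.  A constant block returns
an empty mask with a warning.  On two-mode blocks this matches the
exhaustive 2-class within-variance minimiser, and the threshold scales with
intensity gain, making the membrane/NSC ratio gain-invariant.  An NSC
belongs to the cube containing its label centroid; manual correction of NSC
counts has no algorithmic rule, so counts are inputs.  The per-brain value
is the mean over cubes of membrane pixels / NSC count; zero-NSC cubes are an
error unless the caller opts to skip them.  Ensheathing: individually
ensheathed = total − Σ(sizes of chambers housing ≥ 2 NSCs), reported as a
percentage together with the multi-chamber size distribution.  Cross-
condition hypothesis testing is out of scope; the module emits tidy tables.

## What the synthetic data does and does not emulate

The generator reproduces the features the statistics depend on: well-mixed
compartments with exchange, targeted continuous bleaching and pulsed
conversion, per-acquisition decay, additive Gaussian (optionally Poisson)
noise, compartment label geometry, and clonal populations with
endoreplication, acytokinetic mitosis, fusion and four-colour single-copy
induction.  It does **not** simulate spatially resolved intra-compartment
diffusion, 3-D optics or PSF blur, tissue drift or z-shifts, membrane
morphology, NSC-chamber geometry, or nutrition-dependent triggering of
proliferation.  Passing tests therefore demonstrate the correctness and
calibration of the statistics under the stated model — threshold coverage,
false-positive control, connectivity recovery, case logic — not robustness
to optical artefacts, which on real data are handled by the usual upstream
corrections (registration, background subtraction) the interfaces leave to
the caller (a single integer-pixel ROI shift per frame range is supported in
lieu of drift registration).

Bleach-laser effective rates and imaging-decay magnitudes are not published
for these assays; fixture values above are documented package defaults, not
measured ones.

## Problem sizes and determinism

Default analyses run at the sizes stated here: 10,000-square nulls on
512 × 512 (or smaller) single-plane movies, 50-graph connectivity sweeps
with ≤ 8 compartments, 24 photoconversion trials, 100-seed case-logic
sweeps, 10,000-draw colour combinatorics.  Every stochastic routine takes an
explicit integer seed and is bit-reproducible; the CLI writes a manifest
(inputs, seeds, parameters, version) sufficient to re-run any stage
identically.
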