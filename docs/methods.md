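# Methods

This note documents the models, conventions and numerical choices behind
`pollinet`, in enough detail to reproduce every number the package
computes. Matrices are oriented plants-in-rows (P rows), pollinators-in-
columns (A columns) throughout; `F` is the grand total of interactions,
`I` the number of non-zero cells, `r_i`/`c_j` the marginal totals.

## Interaction calling from read counts

A link is called when a plant taxon's read count in one insect's pollen
load is **strictly greater** than the threshold (default 1,000 reads); the
boundary case `count == threshold` is not a link. When several markers
are genotyped (e.g. a chloroplast and a nuclear marker), a link is called
if *either* marker clears the threshold — counts are never summed across
markers, since marker-specific amplification biases would make the sum
meaningless. Before thresholding, wind-pollinated taxa (airborne
contamination, not visitation) and taxa resolved above genus are removed;
genus-level taxa are kept as genus nodes. Insects with no super-threshold
plant are excluded from the sequence-based network. These filters commute
with thresholding, and raising the threshold can only remove links
(monotonicity) — both properties are tested.

The threshold rationale is empirical: grasses dominate airborne pollen,
so the grass read distribution across insects estimates the background
contamination level that insect-pollinated taxa could also reach. The
`contamination_profile` function reports the fraction of insects with
zero, <100 and >threshold grass reads, and two removal measures:
`reads_removed` (share of grass read *volume* in sub-threshold cells) and
`insects_cleared` (share of insects left with no super-threshold grass
signal). The two differ strongly whenever a few insects carry very large
grass loads (occasional genuine grass foraging): volume then concentrates
in a heavy tail that thresholding does not remove, while nearly all
insects are cleared. Removal percentages quoted as `100 − %insects above
threshold` correspond to `insects_cleared`.

## Aggregation levels

Species-level cells count the *individuals* of an insect species linked
to a plant taxon, so the species matrix is a count (interaction
frequency) matrix even though the individual matrix is binary; totals are
conserved by aggregation. Group level additionally collapses plants to
four floral-morphology groups ordered by reward accessibility
(zygomorphic, tubular, ligulate, open actinomorphic) and insects to nine
functional groups. Per-species individual networks are built for every
insect species with at least `min_individuals` (default 10) captured
individuals, restricted to the plants that species contacts; at the
default study scale this selects on the order of eleven species.

## Index conventions

**Nestedness temperature.** The binary matrix is packed by descending
marginal totals (ties broken by label), and cell centers are mapped to
the unit square with the generalist–generalist corner at the origin. The
isocline of perfect nestedness for fill φ is the p-norm curve
`x^p + y^p = 1` whose enclosed area `Γ(1+1/p)²/Γ(1+2/p)` equals φ (p
solved by Brent's method). Presences outside the isocline and absences
inside it are *unexpected*; each contributes `(d/D)²`, where `d` is the
distance from the cell to the isocline along the diagonal direction
`(1,1)` through the cell (vectorized bisection) and `D` the length of
that diagonal inside the square. `T = 100 · mean(u) / 0.04145`, clipped
to `[0,100]`; `0.04145` is the classic normalization making a maximally
disordered matrix approach `T = 100`. Degenerate inputs (single
row/column, empty or full fill) return `T = 0` by convention. The
original temperature calculator is under-specified and re-packs rows and
columns heuristically; this implementation deliberately uses the single
marginal-sort packing above and is validated by limit behaviour
(staircase matrices attain the exhaustive minimum of their margin class;
a fine-grained checkerboard sits near the top of its class, though coarse
anti-nested blocks can run slightly hotter under this packing), not by
value-matching any particular legacy program.

**Barber modularity.** `Q = (1/F) Σ_ij (a_ij − k_i d_j / F) δ(g_i, g_j)`
on the weighted matrix. Maximization alternates label propagation (rows,
then columns, adopt the module maximizing their contribution to Q, ties
to the lowest label) with greedy agglomerative merging of module pairs
with positive gain, restarted from 20 random column labelings;
deterministic under the seed. The reported Q is re-derived from the
returned partition, which is also exposed per node.

**H₂′.** `H₂` is the Shannon entropy of the cell frequencies.
`H₂′ = (H₂max − H₂)/(H₂max − H₂min)` with integer-feasible extremes under
the observed margins: `H₂max` by largest-remainder rounding of the
independence matrix `r_i c_j / F` (the continuous entropy maximum) with
margin repair, `H₂min` by greedy concentration (repeatedly make the
largest feasible allocation). On small matrices (≤100 cells, F ≤ 64) both
are refined by hill-climbing over margin-preserving 2×2 cycle moves, and
the minimum additionally tries every first allocation; exhaustive
enumeration on all matrices up to 4×4 with F ≤ 8 confirms the heuristic
extremes are feasible and H₂′ tracks the exhaustively standardized value
to within 0.1. H₂ is clipped into `[H₂min, H₂max]` before standardizing;
`H₂′ = 0` when the margins leave no freedom.

**d′.** For a species with interaction proportions `p` and partner
availability `q_j = c_j / F`, the raw specialization is
`d = Σ p_j ln(p_j/q_j)`, standardized as `d′ = d / ln(F/f)` where `f` is
the species' own total — the analytic maximum, attained when all
interactions fall on a partner used by nobody else (then `q = f/F`). The
analytic minimum 0 (profile equal to availability) is used rather than a
discrete-feasibility minimum; integer constraints can make exactly 0
unattainable, so small positive d′ values on near-independent data are
expected.

**Evenness.** `E₂ = H₂ / ln(A·P)` — the all-cells denominator, so `E₂ = 1`
only for the full uniform matrix and a single non-zero cell gives 0.

**Degree distributions and f–s regression.** The cumulative distribution
`P(k ≥ s)` over the distinct observed degrees is fitted by nonlinear
least squares to `exp(−s/γ)`, `s^(−γ)` and `s^(−γ)·exp(−s/k_x)`; models
are ranked by Gaussian AIC (`n·ln(RSS/n) + 2k`) and at least five
distinct degrees are required. The f–s relation is ordinary least
squares of `log₁₀(links per species)` on `log₁₀(marginal total)` — the
log–log scale is what makes sub-unit slopes meaningful on count data
spanning orders of magnitude.

## Null models

Null networks conserve both margins exactly, so they contain common and
rare species exactly like the data. Sampling pairs the multiset of row
tokens with a uniformly shuffled multiset of column tokens, which
realizes the same conditional (multiple hypergeometric) distribution as
Patefield's sequential algorithm; a 2×2 check against the exact
hypergeometric law and per-replicate margin assertions guard this. The
95% interval is the empirical 2.5–97.5 percentile band over 100
replicates by default (a normal-approximation band is available);
an index is flagged when the observed value falls strictly outside.
Replicates on which an index fails are excluded with a warning. On data
generated from the independence model the pooled flag rate stays near
the nominal 5% (calibration test).

## Rarefaction comparison

Both species networks are restricted to the species present in both;
species emptied by the restriction are dropped from both sides,
iterating to a fixed point. The metabarcoding matrix is then downsampled
to the visit network's interaction total by a multinomial draw with cell
probabilities `a_ij/F` (grand total exact by construction); replicates
may contain empty rows/columns, which are dropped before indices are
computed, so network dimensions are re-estimated per replicate. The
empirical p-value uses the add-one estimator
`p = (1 + #{replicates on the smaller side of the observed value})/(n+1)`
— the smaller one-sided tail, stored with its direction — and Bonferroni
correction multiplies by the number of indices in the comparison table
(including the two f–s slopes). Networks that do not differ share a
letter in the rendered table.

Two structural caveats, both visible in the tests: (1) the smaller-tail
estimator lives on `(0, 0.5]`, so calibration is checked on `2p`;
(2) the *unresampled* original matrix is always slightly smoother than
any multinomial resample of itself, so entropy-type indices (evenness,
H₂′) carry a small conservative bias when the two networks are literally
identical — under realistic conditions, where the visit network is
itself a sample, p-values are approximately uniform (tested by
Kolmogorov–Smirnov sanity bound).

## Synthetic data generator

The generator emulates a subalpine-heathland pollination survey and its
paired metabarcoding assay; defaults are the study conditions used
throughout the tests and the acceptance script.

* **Community.** 90 insect-pollinated plant taxa (half growing off-site,
  reachable by foraging insects but invisible to the survey; off-site
  taxa may only be resolvable to genus, and a tenth remain above genus
  and are discarded during network building), 110 insect species in nine
  functional groups, 402 captured individuals in four merged
  communities. Plant and insect abundances are lognormal (σ = 2.5 and
  1.2) — few abundant, many rare.
* **Preferences.** Each insect group distributes its visit propensity
  across the four morphology groups (bees ≈ 0.7 on zygomorphic flowers,
  hoverflies ≈ 0.85 on open/ligulate flowers, empidids split); within a
  morphology group, plants receive propensity in proportion to
  abundance.
* **Visits.** One recorded visit per captured individual, drawn from its
  preference vector restricted to on-site plants (capture-on-flower
  design); multi-observation surveys are out of scope.
* **Pollen loads.** Each insect's latent foraging history is its capture
  visit plus a Poisson(7) number of further visits drawn from the full
  preference vector — pollen accumulates over a foraging bout, which is
  what makes the metabarcoding network roughly four times richer in
  species-level links than the visit network at the default settings.
  Each distinct visited plant yields `threshold + ⌈Lognormal(ln 3500,
  1.5)⌉` reads with probability 0.9, calibrated so that doubling the
  threshold to 2,000 removes about a fifth of the links; with
  probability 0.1 (carryover) only a sub-threshold geometric trace
  (mean 150) remains. Only the side of the threshold matters downstream,
  so the exact laws are convenience choices.
* **Contamination.** 35% of insects carry no grass reads; the rest draw
  a total grass load from Lognormal(5.157, 1.889) capped at 26,952,
  placed on a single grass taxon — parameters chosen so that overall
  ~60% of insects have <100 grass reads and ~11.5% exceed 1,000.
* **Reproducibility.** All stages draw from independent substreams of a
  single seed; the capture stream is shared between the visit and pollen
  simulators so the recorded visit is the first entry of the foraging
  history. With contamination disabled and single-visit histories the
  thresholded count matrix equals the visit matrix exactly, and the
  whole pipeline reduces to identity (tested).

What the generator does *not* emulate: read-level artifacts (PCR error,
chimeras, taxon misassignment — the generator produces the
post-bioinformatics count table directly), temporal turnover, repeated
observation of individuals, and the full singleton-richness of real
visit surveys (synthetic visit networks have fewer single-partner insect
species than typical field data, because captured individuals concentrate
in moderately abundant species). Passing tests therefore demonstrate the
correctness and calibration of the *methods*, not ecological realism of
any particular index value; only the arithmetic indices of the published
networks (connectance, density, linkage, extreme specialization) are
reproduced exactly, from their published dimensions and single-partner
counts.

## Problem sizes and determinism

Default replicate counts are 100 null networks and 1,000 rarefied
replicates; the full demonstration pipeline (402 individuals) runs in
tens of seconds on one CPU. Modularity uses 20 restarts everywhere.
Every public entry point is deterministic under its seed; pipeline
reruns with the same config produce byte-identical tables.
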