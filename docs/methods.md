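# Methods

This note documents the model, the numerical choices, and what the
synthetic data do and do not establish. Units throughout: stocks in
mmol C m⁻², flows in mmol C m⁻² d⁻¹, isotope signatures in ‰ vs VPDB.

## The food-web model

A site is described by compartments, directed flows, a site environment
and a physiological rule set (`ventlim.model`). Internal compartments
(detritus Det, dissolved organic carbon DOC, heterotrophic bacteria Bac,
chemosynthetic bacteria ChBac, macrofaunal guilds MacES/MacDF/MacSF/MacPS,
megafaunal guilds MegDF/MegSF) are mass-balanced at steady state; external
compartments (water-column detritus Det_w, buried detritus Det_s,
water-column DOC_w, dissolved inorganic carbon DIC, mobile external
predators) are unbounded sources and sinks. Steady state (dC/dt = 0) is
assumed throughout: stocks act as constraints on rates, never as state
variables, and no transient dynamics are modelled.

For a faunal compartment c we operationalise the physiological quantities
in flow terms as

- ingestion I = all inflows except DIC fixation,
- egesta + mortality Fe = the single flow c→Det (the detritus pool is
  defined to include faecal material and dead tissue, so one flow carries
  both),
- respiration R = c→DIC,
- secondary production P = flows to consumers plus the flow to external
  predation,

with assimilation A = I − Fe and, by mass balance, I = Fe + R + P. The
rate windows are linear in these sums: A ∈ [AE_lo, AE_hi]·I,
Fe ∈ [0.25, 0.80]·I, P ∈ [NGE_lo, NGE_hi]·A, P ∈ [g_lo, g_hi]·Tlim·B,
R ≥ m·Tlim·B and R ∈ [0.5, 1.5]·B·r·Tlim, where B is biomass,
Tlim = Q10^((T−20)/10) the temperature factor (Q10 = 2 by default;
`tlim_mode="rounded"` reproduces coarse one-decimal constants such as 0.2
at −1 °C), m the maintenance coefficient (0.01 d⁻¹ macrofauna, 0.001 d⁻¹
megafauna) and r the biomass-specific respiration rate. r defaults to
0.01 d⁻¹ for both classes; it is a genuinely uncertain constant,
configurable per class in the model file (`macrofauna.bsr`). Heterotrophic
bacteria carry no biomass-dependent bounds (bacterial biomass is a poor
proxy for activity); they are constrained by growth efficiency
P_b = U − R ∈ [0.05, 0.45]·U on uptake U and by viral lysis returning
[0.30, 0.80]·P_b to detritus. Chemoautotrophs (ChBac, and the
symbiont-bearing MacES, which has no feeding organs and therefore no
ingestion-based rows) are constrained by fixation efficiency
(U − R) ∈ [0.10, 0.50]·U on DIC uptake U.

Site-level rows: total respiration Σ(x→DIC) inside the SCOC range;
Det_w→Det inside the POC-flux range; DOC→DOC_w ≤ 0.1 × total respiration;
burial Det→Det_s ∈ [0.01, 0.03] × gross organic-matter input, where gross
input = POC deposition + gross suspension uptake + gross DIC fixation
(this base quantity reproduces burial at the percent level of gross
inputs, the conventional accounting).

Isotope diet constraints are linear mixing on flow-weighted source
signatures: for consumer j with sources i,
|Σᵢ fᵢⱼ (δᵢ + Δ − δⱼ)| ≤ k·sdⱼ·Σᵢ fᵢⱼ, with a single trophic
discrimination Δ = 1.0 ‰ for carbon and k = 2 consumer SDs, both
configurable. No functional form stronger than linear mixing is imposed;
consumers or sources without data simply contribute no rows.

Every compiled row carries a provenance tag (mass_balance:…, scoc, poc,
burial, doc_efflux, physiology:rule:compartment, isotope:consumer,
nonnegativity:flow, custom:i); temperature-sensitive rows are additionally
marked `[Tlim]`. Tags drive infeasibility certificates and let tests
verify that, e.g., changing only the temperature changes only `[Tlim]`
rows.

## Site topologies

When no explicit flow list is given, edges are generated from a fixed
recipe over the standard compartment ids (see `ventlim.model`). The three
shipped site webs are this recipe restricted to the guilds present plus a
small set of site-specific diet edits, chosen so that the webs carry 31
(BOV), 38 (HR1) and 37 (HR2) flows and 9/10/9 balanced compartments —
the sizes of the webs this package is built to emulate — while staying
consistent with the qualitative diet differences between an off-vent site
and two vents of increasing activity:

- BOV (off-vent, −1 °C): no chemosynthetic bacterial mat. Four further
  edges are absent: MacSF→MacPS (predator diets carry no suspension-fed
  carbon off-vent), MacDF→Predation (external predators take epibenthic
  rather than infaunal prey), MacES→Det (the sparse siboglinid population
  sheds negligible detritus) and DOC→Bac.
- HR1 (low-activity vent, 24 °C): the full web minus MacSF→MacPS.
- HR2 (high-activity vent, 48 °C): no symbiont-bearing macrofauna; mat
  carbon additionally reaches predators and megafaunal deposit feeders
  (ChBac→MacPS, ChBac→MegDF).

These per-site lists are a reconstruction, not measured topology. A
structural constraint discovered while building them: a faunal guild that
is present must keep at least one production outflow and its →Det flow —
otherwise the efficiency rows force it inactive while positive biomass
forces respiration, and the model compiles to an infeasible system. Any
topology edit must respect this.

The real stocks and isotope values behind these sites are unpublished, so
the fixtures carry SYNTHETIC placeholder stocks (generated as below and
flagged in file headers and CLI output); their environments (depths
1150/1174/1054 m, temperatures −1/24/48 °C, SCOC ranges [0.81, 2.86] and
[1.62, 2.86] mmol C m⁻² d⁻¹, POC range [0.70, 27.17], substrate
concentrations) are the published site descriptions.

## Solving and sampling

Feasibility is a phase-1 HiGHS linear program; infeasibility certificates
come from a deletion filter that leaves an irreducible set of conflicting
rows, reported by provenance. The parsimonious (minimum-Euclidean-norm)
solution is computed exactly by eliminating the equalities with an
orthonormal null-space basis and solving the remaining least-distance
problem via the Lawson–Hanson LDP→NNLS reduction; it serves as a sanity
check and reference point only — the analysis output is always the
ensemble. Per-flow attainable ranges are two LPs per flow; unbounded
coordinates are flagged, not raised, except when sampling is requested
(sampling an unbounded polytope is refused, naming the unbounded flows).

Sampling uses a mirror (reflective) random walk in the null space: a
Gaussian step is reflected specularly off each violated half-space until
the end point is interior, which leaves the uniform law on the polytope
invariant. Vent-web polytopes are severely anisotropic — per-flow ranges
span more than two orders of magnitude — and an isotropic walker either
creeps or reflects hundreds of times per step. The sampler therefore runs
a fixed ladder of pilot chains (3 000, 5 000, 8 000 steps), re-estimating
the polytope covariance after each, and executes the main chain in the
whitened (Cholesky) frame; the frame is fixed before any retained sample
is drawn, so uniform invariance is untouched. `jump_length` is the
proposal SD in whitened units; the default 0.3·√12 ≈ 1.04 is 0.3 of the
mean whitened axis width (a uniform axis of width W has SD W/√12).
Ensemble means are insensitive to this choice over at least a tenfold
range. The chain starts at the max-slack interior point (the parsimonious
point can lie on the boundary, which breaks reflections), discards a
burn-in of 1 000 steps by default (`--burn-in 0` reproduces a
no-discard protocol), and retains every subsequent iterate. All
randomness flows from one integer seed; the reflective kernel is compiled
(numba) with every random number pre-drawn from that seeded generator, so
ensembles are bit-reproducible. Every retained sample is verified against
the full system at 1e-8 — flows are O(0.01–10), so this tolerance is
~1e-9 of scale — and a violation raises instead of returning a corrupt
ensemble.

Production ensembles use 100 000 iterations. The convergence diagnostic
follows the run-length-ladder protocol (default 300 / 3 000 / 30 000 /
200 000): all runs share one seed and start point, so shorter runs are
exact prefixes of the longest; per tracked flow (default: five
non-constant flows spanning the magnitude range) the relative deviation of
prefix mean and SD from the longest run is reported, and the minimum
iterations is the smallest run length with every deviation within 2 %.
Flows pinned to constants by the equalities count as converged
immediately, avoiding 0/0.

## Ensemble reductions

Summaries use the sample SD (n − 1): ensembles are samples of the solution
space. CoV = SD/|mean|; a zero-mean flow has its CoV flagged undefined
rather than infinite. The fraction-of-solutions comparison pairs the two
ensembles exhaustively when |A|·|B| ≤ 10⁷ (computed by sorting, so it is
exact) and by seeded Monte-Carlo pairing beyond that; ties count as "not
greater", and the significance verdicts switch strictly above 0.95 and
0.98. Cross-pairing (rather than index-pairing) is used because the
ensembles are unordered samples.

Budget accounting: gross chemosynthesis = Σ DIC→fixers; net
chemosynthesis subtracts the fixers' respiration; gross/net suspension
feeding likewise over suspension feeders; net total = POC deposition +
net suspension + net chemosynthesis. Egesta are not subtracted from "net"
routes — they remain in-system as detritus and are tracked as detritus
production. Percentage input shares are computed per solution against net
total input, then averaged. Whole-system conservation (gross inputs −
respiration − burial − DOC efflux − external predation = 0) holds to
machine precision for every mass-balanced solution and is asserted at
1e-6.

Diet composition is the per-solution share of each feeding inflow in
total intake, averaged over solutions; solutions with zero intake are
counted and excluded rather than divided by. Symbiont fixation is not
feeding, so MacES has no diet.

## Network indices

The flow-matrix bridge places internal→internal flows in a square matrix
T and keeps imports (from Det_w and DIC), exports (to Det_s, DOC_w,
Predation) and respiration (to DIC) as separate vectors. Indices:

- TST = Σᵢ input throughflow (internal inputs + imports). On balanced
  matrices input and output throughflows coincide; throughout, the input
  convention is used (it also matches the worked cycling example below).
- FCI: with output fractions Gᵢⱼ = Tᵢⱼ/Tᵢ and N = (I − G)⁻¹, the cycled
  throughflow is Tc = Σᵢ ((nᵢᵢ−1)/nᵢᵢ)·Tᵢ; FCI = Tc/TST. The corrected
  variant cFCI = Tc/(TST − Tc) removes the cycled fraction from the
  denominator. Which convention a given reference value uses is often
  ambiguous, so both are always emitted. A fully cyclic component makes
  I − G singular and is reported as such.
- AMI in bits (log₂) over the extended matrix (an import row; export and
  respiration columns), with 0·log 0 = 0. Bits are the scale on which
  ~10-compartment webs land near 2.
- Compartmentalisation: mean Jaccard overlap of undirected interaction
  neighbourhoods over compartment pairs, neighbourhoods including the
  focal compartment — a complete graph scores 1, interacting dyads score
  within-pair 1, an edgeless graph 0.

Ensemble indices are computed per solution and then averaged (mean ± SD);
computing them on the mean flow network instead is possible via the
single-solution API but is not the default, since the per-solution route
is what gives an SD.

## Synthetic sites and what they show

`generate_site(template, seed)` is truth-first: (1) build the template
topology; (2) draw one ground-truth flow vector uniformly from a
*generation polytope* — mass balance, nonnegativity, all biomass-free
physiology rows, the template's SCOC/POC priors, small activity floors
(faunal respiration ≥ 0.001, bacterial ≥ 0.01 mmol C m⁻² d⁻¹, keeping
every guild alive), and per-guild rows bounding production against
respiration exactly so that a biomass consistent with the growth,
maintenance and respiration windows exists; (3) draw each guild's biomass
uniformly from the interior of the window its truth rates admit; (4) set
basal δ¹³C to −25 ‰ (photosynthetic) and −35 ‰ (chemosynthetic) — round
conventional values for the two organic-matter classes — and each
consumer's signature to its truth-weighted diet mixture + Δ with SD 1 ‰;
(5) emit SCOC and POC ranges as ±20 % intervals around the truth. The
construction guarantees (and asserts) that the truth satisfies the
compiled system strictly, with no rejection loops. The fixture variant
keeps the published field ranges instead of the ±20 % intervals.

`recovery_test` compiles, samples, and checks per-flow central 95 %
intervals against the truth. Across 20 seeds per template at 20 000
iterations, mean coverage is ≈ 96 % (≥ 90 % is the design requirement).

What this does and does not establish: the generator emulates the
*structure* of real site data (stocks consistent with rate windows,
signatures consistent with linear mixing, ranges that bracket the truth).
Real data differ in ways the generator does not imitate — field SCOC and
POC ranges are not centred on the truth, isotope signatures include
unmodelled fractionation and within-compartment variance, detritus is a
mixture whose signature is not −25 ‰, and stocks carry sampling error
that can make the compiled system infeasible or exclude the truth
(`recovery_test` demonstrates the latter with a shifted-SCOC dataset).
Passing recovery therefore validates the machinery — compilation,
sampling, interval construction — not the field accuracy of any
particular published budget. For the same reason the placeholder-stock
fixtures cannot numerically reproduce published budget tables or index
values; only orderings and magnitudes can be explored under plausible
stocks.

## Problem sizes and defaults

Default production runs use 100 000 iterations (seconds on one CPU for a
~40-flow web). Tests and the acceptance script use 5 000–100 000
iterations, 50 000-sample toy-polytope checks, 20 synthetic sites per
template at 20 000 iterations, and a convergence ladder capped at
100 000; these sizes give Monte-Carlo error well inside the asserted
tolerances. Numerical tolerances: constraint satisfaction 1e-8; budget
conservation 1e-6; index closed forms 1e-12.

## Known limitations

- No transient dynamics, no nitrogen/sulphur budgets, no topology
  inference; meiofauna are not a compartment, so bacterial/faunal
  respiration absorbs their share.
- The per-site flow lists are reconstructions (above); users with an
  authoritative topology should supply an explicit `## FLOWS` section.
- Uniform sampling is over the polytope in flow coordinates; no prior
  other than uniform is supported.
- The default edge recipe is keyed to the standard compartment ids;
  non-standard webs must pass explicit flow lists.
- Substrate concentrations (H₂S, CH₄) are carried as metadata only and do
  not constrain flows.
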