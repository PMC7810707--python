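# Methods

This note documents the models, algorithms, parameters and numerical
choices behind contextflux, and what the synthetic-data tests do and do
not establish about real data.

## Network model

A metabolic network is a list of metabolites, each assigned to exactly one
of eight sub-cellular compartments (`c` cytosol, `e` extracellular, `g`
golgi, `l` lysosome, `m` mitochondria, `n` nucleus, `r` endoplasmic
reticulum, `p` peroxisome; any other code is an error), and a list of
reactions with stoichiometry, flux bounds and a boolean GPR rule over the
gene universe.  Reversibility is encoded solely by a negative lower bound.
Reaction and metabolite *order* is part of the model: it fixes the rows
and columns of the stoichiometric matrix S and the LP column order, which
the extraction step deliberately permutes (see GIMME below).

The native store is a canonical JSON dialect (fixed key order, 2-space
indent), so write→read is the identity on every field and read→write is
byte-identity.  SBML Level 3 with the FBC package is an import/export
compatibility path: stoichiometry, bounds, compartments, GPRs and the
objective survive the round trip; the `is_exchange` flag maps to the
conventional `EX_` id prefix and the free-text `subsystem` label is not
carried.

Empty GPRs (exchanges, demands, spontaneous reactions) evaluate *present*
everywhere, so expression data can never switch off a reaction no gene
encodes.

The null-space dimension |reactions| − rank(S) counts the independent
steady-state flux degrees of freedom; rank uses the standard SVD tolerance
max(dim) · ε · σ_max (numpy's default).

## Expression thresholds

Presence calls are a hard intensity cutoff, default 11, boundary
inclusive (intensity ≥ 11 ⇒ present).  DE calls use linear fold-change
thresholds — up if fold > 1.75, down if fold < 0.55, both strict — plus
p ≤ 0.05 and FDR q < 0.1.  The near-equivalent log2 ±0.8 convention
(2^0.8 ≈ 1.74) is available through the `call_de` arguments; the linear
values are the default because they are the ones usually quoted alongside
published gene counts.  Fold-change distributions across toxins are
compared with the tie-corrected Kruskal–Wallis H test on the pooled linear
fold changes of each toxin's DE genes (up and down together — pooling
direction is a configuration choice), followed by Dunn's pairwise z tests
with Bonferroni adjustment (adjusted p = min(1, raw p × number of pairs);
the rank variance uses the standard tie term Σ(t³−t)/(12(N−1))).

## GIMME extraction

Given presence calls, GIMME solves

    min Σ_i w_i |v_i|   s.t.   S·v = 0,  lb ≤ v ≤ ub,  v_biomass ≥ f · z*

with binary penalties (w_i = 1 iff reaction i's GPR evaluates absent;
present and non-gene-associated reactions are free), f = 0.5 and z* the
parent FBA optimum.  Genes missing from the presence mapping are treated
as absent — real expression tables never cover a genome-scale model's full
gene universe.  Reversible reactions are split (v = v⁺ − v⁻) for the
absolute-value objective and re-merged on output.  The retained set is
{present-GPR reactions} ∪ {empty-GPR reactions} ∪ {absent reactions with
|v*| > 10⁻⁹ at the optimum}; the inconsistency score is the objective
value, zero exactly when the floor is attainable through present reactions
alone.  An unattainable floor raises a dedicated error, distinct from LP
failure.

The penalty LP is typically degenerate: alternate optima route the
required flux through different absent reactions.  The consensus procedure
exploits this deliberately: k = 3 extractions run on seeded random
permutations of the reaction columns (different column orders make the
solver land on different optimal vertices), and only reactions retained in
*all* k runs enter the consensus model.  An intersection can lose the
objective floor (e.g. two symmetric alternate paths, each dropped in some
iteration); such a consensus is flagged `floor_verified = False` and
warned about, never silently used.

Demand reactions model production capability: a protein demand consumes
free cytosolic amino acids with residue-count stoichiometry (no
polymerisation cost — the composition is the specification), an ATP
maintenance demand and a reduced-glutathione sink follow the standard
sink forms.  A demand that must stay active during extraction carries a
small positive lower bound (default 10⁻⁶ flux units), reset to 0 for all
subsequent simulations so the sampled polytope includes the zero-demand
state.  "Rich media" opens every exchange reaction's lower bound to
−1000 flux units (per-exchange overrides supported); identical media are
applied to every condition so sampled fluxes are directly comparable.

## ACHR sampling

The flux polytope is parametrised in an orthonormal basis N of null(S):
points are v = N·α, so every emitted sample satisfies S·v = 0 to machine
precision by construction and only the box bounds constrain the step.
Warm-up points are the 2·|reactions| flux-variability vertices
(deduplicated); projecting them into α-coordinates also scrubs the LP
solver's ~10⁻⁹ residuals.  Each step picks a random point from the pool
(warm-up ∪ previously accepted), takes the direction from the running
centre through it (the artificial centring), computes the feasible chord
[t_lo, t_hi] from the bounds, and moves a uniform distance along it.  The
chord is clamped to contain 0 to absorb round-off; degenerate directions
(norm < 10⁻¹²) are resampled with bounded retries, and a fully determined
polytope (null space of dimension 0, or all bounds tight) yields the
single feasible point repeated.  Defaults: 5000 points per model, burn-in
0, thinning 1, all configurable; two runs with the same seed are
bit-identical.

ACHR chains are autocorrelated; on a 1-D polytope the full-chord step
makes consecutive points independent (each new point is uniform on the
whole interval), but in higher dimensions per-coordinate marginals at
thinning 1 sit near the edge of iid-based test bands.  The uniformity
property test therefore uses thinning 2, where the iid Kolmogorov–Smirnov
band is applicable.

Samples from the k iteration models of one condition are merged by
concatenating rows over the intersection of their reaction sets (3 × 5000
= 15 000 points at the defaults); values are not rescaled because the
media are identical across models.  A numerical cutoff then zeroes every
entry with |v| strictly below 10⁻⁷ (the boundary value is kept; the
inequality direction is a documented choice).

## Co-sets

Pearson correlations are computed over the sampled points for all
reaction pairs with nonzero variance (constant reactions — σ ≤ 10⁻¹² —
are excluded and listed).  Co-sets are the connected components of the
graph with edges |r| ≥ 0.975, i.e. single-linkage grouping; exact cliques
(complete linkage) are NP-hard at scale, and for perfectly coupled sets
the two coincide.  The 0.975 default follows the correlation-coefficient
convention (R² > 0.95 ≈ |r| > 0.975); a single threshold knob covers both
readings.  Anticorrelated pairs group together by default (|r|); a signed
mode keeps them apart.  Components of size ≥ 2 are co-sets (singletons are
reported separately, and both totals appear in the manifest since
published co-set counts do not always state whether singletons are
included); the "large" filter keeps co-sets with ≥ 6 reactions.

Each co-set's representative is the member with the largest mean |flux| in
the control condition that exists in every condition.  Its per-condition
activity value is the mean |flux| over sampled points, expressed as a
percentage of the sum across conditions (rows sum to 100 where defined;
all-zero rows are flagged undefined, missing representatives contribute 0
and are flagged).  Percentage profiles are clustered agglomeratively
(Euclidean distance, average linkage) with rows pre-sorted by co-set id so
the dendrogram is deterministic.

## Differential flux

Each reaction shared by a treated and an untreated sample matrix is
tested with Welch's unequal-variance t-test by default; an index-paired
mode (`paired-by-index`) is available since merged matrices have equal
row counts, but independently sampled chains carry no natural pairing, so
unpaired is the default.  Significance requires all of: raw p below
α / (number of reactions actually tested) — the Bonferroni denominator
counts only shared, testable reactions and is recorded in the output —
a fold ratio ≥ 2 between the absolute means (one mean at 0 against an
active mean counts as infinite fold and passes; both ≈ 0 count as fold 1),
and both |means| < 1000 flux units (screening out numerically extreme
near-bound fluxes).  Swapping the two conditions inverts fold ratios but
preserves the significant set.  Per-toxin significant sets are intersected
with the same Venn partitioning used for DE genes.

## Synthetic data: what it emulates, and what it does not

`make_toy_network` builds chains of unimolecular conversions threaded
through compartments, with an uptake exchange at the head and a sink (or
the biomass reaction, for the first chain) at the tail.  Each chain is a
planted fully-coupled set and contributes one flux degree of freedom; each
parallel-path bypass adds one degree of freedom and un-couples the
bypassed step.  The planted null-space dimension, coupled sets,
compartment totals and FBA optimum ship as ground truth.

`make_expression` draws log-normal intensities (median 100 for expressed
genes, 3 for silenced ones, σ = 0.5) and clips them to the correct side of
the presence cutoff, so presence calls are deterministic while intensities
vary with the seed.

`make_de_tables` assigns genes to configured up/down Venn occupancy
strata exactly, then draws fold changes just beyond the thresholds:
up-folds 1.75·e^|N(δ_t, 0.4)|, down-folds 0.55·e^−|N(δ_max−δ_t, 0.4)|,
with per-toxin location shifts δ = (0.6, 0.15, 0.15) by default.  A larger
δ_t moves the toxin's whole fold distribution up in rank — up-genes
further above threshold *and* down-genes less extreme — so the rank
effects add; defined the other way (both magnitudes growing) they cancel
and the Kruskal–Wallis test loses its power.  At the defaults the KW test
rejects in ≈100 % of replicates.  Note that exact stratum counts make the
up:down composition of each group fixed rather than binomial; under an
equal-shift null this stratification makes KW *conservative* (rejections
below α), so the α-calibration of the test itself is demonstrated on
single-direction tables, where values are iid and exchangeable.  p and q
values are generated consistently with membership (members pass both
filters, non-members sit inside the fold window) — the tables are
fixtures for the thresholding machinery, not a hierarchical inferential
model.

These generators emulate the *decision structure* of a real study —
presence thresholds, Venn strata, planted coupling, silenced paths — not
its biology: no probe-level noise, no correlated co-expression, no
genome-scale degeneracy, unimolecular stoichiometry only.  Passing tests
establish that the pipeline's logic is correct on networks where the
answer is provable, not that any particular biological conclusion is
reproduced at genome scale, where published co-set and differential-flux
counts additionally depend on the reconstruction used, the transcriptome
and LP-solver degeneracy behaviour.

## Problem sizes and defaults used in shipped checks

The shipped test-suite and acceptance-script runs use toy networks of 6–16
reactions, 5000 sampled points for sampling/co-set checks, 1000 points per
group over 20 repetitions for differential-flux error control, 1000
replicates for KW calibration, and a 4-condition synthetic study at 150–500
points per iteration model for end-to-end determinism; the published-scale
DE replay uses a 6000-gene universe.  All are package choices balancing
statistical resolution against quick, deterministic runs on one CPU.

## Known limitations

- The LP backend is scipy's HiGHS; any solver meeting a 10⁻⁶ steady-state
  and 10⁻⁹ bound tolerance is acceptable, but alternate-optimum selection
  (which the consensus procedure exploits) is solver-dependent by design.
- ACHR is a single chain per model; no OptGP-style parallel chains, no
  formal convergence diagnostics beyond the shipped statistical checks.
- Single-linkage co-sets can chain through borderline correlations; a
  clique-based mode is not provided.
- Organelle profiles are descriptive counts, not enrichment statistics.
- The compartment mapping of external reconstructions must already use the
  8 single-letter codes; no automatic relabelling is attempted.
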