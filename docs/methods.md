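# Methods

`commix` studies how pairwise interactions between bacterial isolates depend
on community context. Because real measurements of this kind require a large
wet-lab experiment, the package pairs the analysis pipeline with a synthetic
experiment generator whose ground truth is known, so every inference step can
be validated against the world that produced the data.

## Experimental design model

A catalog of isolates (default 56, over 21 genera) is randomly partitioned
into `n_pools` disjoint pools of equal size (default 7 × 8). All 2^n − 1
nonempty pool combinations define the first-phase communities (127 for seven
pools). Communities are inoculated at a fixed total titer (default 1 × 10^6
cells) with every member receiving an equal share, and passaged by diluting
1:100 into fresh medium every 24 h for 6 cycles.

Second-phase communities are **nested single-dropout decompositions**: given
a community, a focal isolate, and a putative excluder, the decomposition
emits, for each background set `B` (grown one isolate at a time in a seeded
random order), the designs `B∪{focal}`, `B∪{focal, excluder}`, and
`B∪{excluder}`. The returned list is ordered as a chain in which consecutive
designs differ by exactly one isolate, and may be truncated
(`max_communities`) because real decompositions are non-exhaustive. The
original experiment selected ten community pairs by an unstated
"compositional diversity" criterion; rather than guess that rule, selection
here is explicit and seeded, and the reduced study decomposes around several
focal/excluder pairs of one community.

## Community dynamics

Within a growth cycle, densities follow the generalized Lotka–Volterra ODE

    dN_i/dt = N_i (r_i + Σ_j a_ij N_j),   a_ii < 0,

integrated with LSODA (relative tolerance 1e−8; the analytic Jacobian is
supplied). The underlying experiment specifies no dynamic model; GLV is the
minimal model with explicit pairwise per-capita interactions, which is what
makes ground-truth recovery tests possible. Serial passage multiplies the
end-of-cycle state by the dilution factor and integrates again. Densities
below an extinction floor (default 1e−3 cells/µL, i.e. less than one cell in
the 6 µL transferred at 1:100 from 600 µL) are set to zero; the floor is
absorbing, so an excluded lineage cannot re-invade. Dynamics are fully
deterministic — all stochasticity lives in parameter sampling and in the
observation models.

### Ground-truth prior

`sample_glv_parameters` draws, per isolate: growth rate r ~ N(0.5, 0.1) 1/h
(doubling time ≈ 1.4 h; r·24 h ≫ ln 100, so cultures regrow fully between
passages), carrying capacity K lognormal with median 1e5 CFU/µL (σ_log 0.3,
a typical batch-culture density), and a_ii = −r/K. Off-diagonal magnitudes
are half-normal with scale `interaction_scale · |a_ii|` (default 0.5:
interspecific effects weaker than self-limitation on average); the sign is
negative with probability `negative_fraction` (default 0.67, matching the
observed predominance of negative interactions in leaf-microbiome synthetic
communities); same-genus pairs receive an additional negative shift (default
0.5 scale units), encoding stronger resource overlap between congeners.
Positive coefficients are capped at `positive_cap·√(a_ii a_jj)` (default
0.5) so no mutualistic pair satisfies a_ij·a_ji ≥ a_ii·a_jj, the condition
under which the two-species equilibrium diverges; without the cap a few
percent of draws produce runaway mutualism, which the integrator reports as
an error rather than silently absorbing.

## Observation models

**Sequencing** is modeled at the count level: `depth` reads (default 50 000)
are multinomial over the true final relative abundances. Groups of isolates
with unresolvable reads ("ambiguity sets" — by default, congeneric isolates)
lose a binomial fraction (default 0.2) of their reads to a shared *tossed*
pool, reproducing the information loss of ambiguous read mapping.

**Total density** is observed by dilution plating: expected colonies are
`true_total × dilution × plated_volume` over a serial-dilution triplicate
(dilutions 3e−5, 1e−6, 3e−6, three plates each, 100 µL per plate); counts
are Poisson with a lognormal plating-efficiency multiplier (mean 1, CV
default 0.1), and the density estimate is the mean back-calculated CFU/µL
over the nine plates (an unbiased estimator). With CV = 0 the counts are the
rounded expectations — a fully deterministic observation.

A separate **noise-off path** (`observe_exact` / `profile_from_exact`)
reports exact relative abundances and exact totals. It exists so recovery
invariants can be checked at floating tolerance: reconstructed densities of
detected members equal the simulated truth to relative 1e−6. On this path
the total is discounted by the mass of sub-threshold members (which the
exact observation can separate); with a real plate count that mass is not
separable and the full estimate is used, exactly as in the lab workflow.

## Abundance reconstruction

1. *Reallocation*: each ambiguity set's tossed reads are redistributed over
   its members proportionally to their unambiguous counts. Integer counts
   use largest-remainder rounding so totals are conserved exactly (a
   fractional mode is available). A set with no unambiguous reads splits its
   pool equally, with a logged warning — a case the original workflow never
   defines.
2. *Detection*: isolates with strictly less than 1% of total mapped reads
   are treated as absent; an isolate at exactly 1% is kept ("less than" is
   the stated boundary). Remaining abundances are renormalized. The
   threshold is applied per replicate, after reallocation; a flag could
   reverse the order, but reallocation only moves reads within sets, so the
   ordering matters only for isolates near the boundary inside a set.
3. *Absolute conversion*: `absolute_i = relative_i × total_estimate`.
4. *Aggregation* (optional, default in the pipeline): a member is detected
   in a design's aggregate if detected in a strict majority of replicates;
   densities are means over replicates with zeros for non-detection. The
   original report does not state its aggregation rule, so both
   community-level ("aggregate") and replicate-level ("per_replicate")
   analyses are supported; richness–density statistics use replicate-level
   profiles.

## Interaction measurement

Contexts are paired on **observed** (post-threshold) membership: two
profiles form a context pair when their detected sets differ by exactly one
isolate — the interactor (a flag switches to inoculated membership). For
every focal isolate detected in the without-context, with densities n⁻
(without) and n⁺ (with interactor at density N_I):

* population-level effect: n⁺/n⁻, presented as (ratio − 1), and as
  ln(ratio) for distributional work (the log symmetrizes ratios);
* per-capita effect: (n⁺ − n⁻)/N_I.

The identity (ratio − 1) = per-capita × N_I / n⁻ links the two, and both
share the sign of n⁺ − n⁻. Records with n⁻ = 0 or N_I = 0 are skipped with
a logged reason (the ratio is undefined); records where the focal disappears
in the with-context are retained flagged as exclusions, with pop_ratio 0 and
undefined log, and drop out of log-based analyses.

**Pruning**: per measure independently, records outside ±1 sample SD
(n−1 denominator; the original does not specify) of the measure's mean are
removed — population pruning operates on ln(ratio) by default (configurable
to ratio − 1), per-capita pruning on the raw value. Independent per-measure
pruning is why the two measures carry different n. If the SD is zero no
outlier is definable and everything is kept.

## Cross-context statistics

* **Paired shifts**: records with the same (focal, interactor) whose
  backgrounds are nested and differ by `delta` isolates (default 1) are
  paired low→high; one low record may pair with several high records.
  Medians of the shift and of the |value| shift are tested with two-sided
  Wilcoxon signed-rank tests (exact null for n ≤ 25 without ties, normal
  approximation otherwise), overall and stratified by the sign of the
  low-context value. Fewer than 6 pairs triggers a small-sample warning.
* **Group comparisons**: two-sided Wilcoxon rank-sum tests of |value|
  between negative and positive records, and of raw values between
  same-genus and cross-genus (focal, interactor) pairs.
* **Richness–density**: Pearson correlations of final richness with total
  community density and with individual member density; pairwise t-tests of
  individual density between richness groups with Holm correction; Pearson
  correlation of richness context with |total density change| per
  interaction, dropping contexts with fewer than 3 observations.
* **Regressions** (ordinary least squares via statsmodels; the bespoke
  content is record construction and model specification, not the solver):
  within contexts, focal change (n⁺ − n⁻, an absolute density difference)
  on total density change, on richness context as a factor, and on their
  interaction; across paired contexts, the high-context focal change on the
  high-context total change, the context pair as a factor, the low-context
  focal change ("interaction effect", always taken bottom-up from the lower
  richness context), and total change + interaction effect jointly.
  Factor levels with fewer than 3 records are dropped with a warning, and
  categorical fits are skipped when fewer than two levels remain.

## Pipeline and provenance

Stages (design → simulate → abundance → interactions → stats) communicate
only through TSV tables with commented provenance headers (config hash,
master seed, package version); rereading and rewriting any table is
byte-identical. One master seed drives everything; child seeds are derived
per (design, replicate, observation) via a CRC-keyed `SeedSequence`, so any
single community is re-simulable in isolation. External relative-abundance
and CFU tables can replace the simulator via `import_external`, with schema
violations reported by row number.

## Problem sizes and scenario defaults

The bundled scenarios are sized to make their properties measurable while
keeping any run interactive:

* *Reduced noisy study*: 8 isolates over 4 genera, three nested
  decompositions, triplicate observation — roughly 160–180 profiles and
  600–1000 interaction records per seed, comparable to the 388-record
  full-scale study.
* *Attenuation scenario*: 6 isolates under all-negative competition at
  0.2–1 × 0.4 of self-limitation — the regime where total density saturates
  with richness, individual densities fall, and population effects shrink;
  evaluated over 20 independent worlds.
* *Sign recovery*: two-member communities with the focal-directed
  coefficient at 0.3–0.7 of self-limitation and a weak back-effect (so the
  interactor persists and the interaction remains measurable), 50 draws.
* *Pipeline smoke*: 5 pools of 2 isolates → 31 communities, duplicate.

## What the generator does and does not emulate

It emulates: equal-titer combinatorial inoculation, batch growth with
pairwise density-dependent interactions, serial dilution with extinction,
multinomial sequencing sampling with ambiguous-mapping loss, and plate-count
noise. It does not emulate: higher-order interactions (the GLV ground truth
is strictly pairwise, so measured context dependence arises from density
mediation, not interaction modification), resource-explicit or
pH/habitat-modification mechanisms, contamination, read-level artifacts, or
plating-viability differences between isolates. Passing tests therefore
demonstrate that the pipeline recovers what this model family generates —
they cannot certify behavior on mechanisms outside it, and in particular a
real community could display per-capita attenuation (true higher-order
effects) that this generator produces only as density-mediated attenuation
of population effects.

## Numerical choices

* ODE: LSODA, rtol 1e−8, atol = 1e−3 × extinction floor, analytic Jacobian;
  non-finite end states raise instead of propagating.
* Detection boundary: strictly-less-than 1% (an isolate at exactly 1% is
  kept).
* Largest-remainder rounding for integer read reallocation; ties broken by
  fractional part, then input order (stable sort).
* Degenerate reallocation (no unambiguous reads in a set): equal split with
  a warning.
* Wilcoxon: exact null for n ≤ 25 without ties or zeros; identical paired
  samples return p = 1 by convention.
* Pearson correlation of a constant series is reported as r = 0, p = 1
  rather than undefined.
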