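# Methods

This note documents the models and procedures implemented in toxpipe, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical choices made where the design was genuinely open.

## Study structure and preprocessing

The unit of analysis is the *exposure condition*: one (chemical, dose level,
duration, test system) cell with ≥2 treated replicates and a matched control
group.  Control pairing is always explicit in the sample metadata
(`control_group` column); a control group may serve several conditions (the
shared-control pattern of large toxicogenomics repositories), and pairing is
never inferred from names.

Input matrices are assumed already normalized (log₂ intensities).
Preprocessing applies two filters before any statistics:

- **Annotation filter** — genes with no external annotation are dropped.
- **Variance filter** — genes whose population variance across all samples
  falls below a quantile of the variance distribution are dropped.  The
  quantile defaults to 0.25; this is a stand-in convention, since "low
  variance" filtering thresholds vary across studies, and it is
  config-exposed (`prep.variance_quantile`).

An optional minimum-expression floor (drop genes whose maximum value is
below a cutoff) stands in for probe-level presence/absence filtering, which
needs raw array data; it is off by default.

Group means are arithmetic means of log₂ intensities; fold changes are
treatment mean minus control mean (already in log₂ space).  For reporting,
fold changes are discretized at ±0.6: strictly above 0.6 is up, strictly
below −0.6 is down, the closed band is unchanged.

## Rank-product differential expression

For a condition with n_t treatment and n_c control replicates, all
k = n_t·n_c pairwise replicate fold changes are formed (the standard
two-class rank-product construction).  Within each comparison, genes are
ranked with average ranks for ties (rank 1 = most extreme in the tested
direction), and RP(g) is the geometric mean of the k ranks, computed in the
log domain.

**pfp estimation.**  Each permutation reassigns every comparison column's
rank multiset to genes uniformly at random — equivalent to shuffling gene
labels within the column, and exactly the null the tests' enumeration
oracle integrates over.  With E(g) the average number of permuted rank
products at or below RP(g) per permutation, pfp(g) = E(g) / rank-position(g)
is step-down monotonized (cumulative maximum along increasing RP) so the
DEG set is nested in the cutoff, then clipped to [0, 1].  Defaults: 1000
permutations, cutoff 0.05 (strict inequality), both config-exposed; the
seed is mandatory.  A gene significant in both directions (possible only
under pathological ties) keeps the direction with the smaller RP, with a
warning.

The permutation count is the main accuracy dial: at 1000 permutations with
2000 genes the pfp at the 0.05 boundary is stable to well under the cutoff
granularity, and the null false-call rate in simulations sits far below the
nominal level (the rank-product pfp is conservative on pure noise).

## Pathway over-representation

The universe is the post-filter gene set of the test system (not the whole
genome), matching the matrices the DEGs were called on.  For each gene set:
p = P(X ≥ n_hit) with population = universe size, successes = set members in
the universe, draws = DEG count (scipy's hypergeometric survival function).
p-values are Benjamini–Hochberg adjusted across the sets tested for one
condition (config-exposed; BH is the default of the widely used enrichment
tooling this mirrors).  A result is *reported* when adjusted p < 0.05 and
more than two DEGs map to the set.  The chemical–pathway network links a
chemical to a pathway if the pathway is reported in any of its conditions;
pathways linked to exactly one chemical carry a `unique` flag.

## MIE activation scoring

MIEs are transcription factors; their targets come from a TRRUST-like
(tf, target, mode) table.  Per chemical, the DEG set is the union over all
its conditions and both directions — the table counts *differentially
expressed* targets, not mode-consistent ones, so the regulation mode column
is retained but unused in scoring.  n_de = |union ∩ mapped targets|, where
mapped targets are the TF's targets present in the analyzable universe.
Only MIEs with strictly more than 10 mapped targets are tabulated.
Percentages display as integers rounded half-away-from-zero; the >20% flag
uses the unrounded percentage.

## TIMBR metabolite prediction

Given per-condition DEG log₂FC values:

1. **GPR mapping** — each reaction's Δ is its GPR tree evaluated on signed
   fold changes: AND → min (a complex is limited by its most depleted
   subunit), OR → max (isozymes dominated by the most induced member);
   genes without a fold change contribute 0, empty GPRs give Δ = 0.  By
   default only DEGs enter (non-DEG genes are 0); a full-matrix mode can be
   had by passing all fold changes.
2. **Weights** — w_treatment = baseline·2^(−scale·Δ) and
   w_control = baseline·2^(+scale·Δ), so up-regulated reactions are cheap
   under treatment and costly under control, with w_t·w_c = baseline²
   always.  scale = 0.5 and baseline = 1 by default.  *This transform is
   the single most consequential free choice in the module*: the method
   family only requires that expression shifts map monotonically to
   relative weights, and the exponential form was chosen for its symmetry
   (product invariance) and scale interpretability; both knobs are
   config-exposed (`timbr.weight_scale`, `timbr.baseline_weight`).
3. **Capability** — v_max per metabolite is the plain FBA maximum of its
   secretion exchange flux (weights play no role); it is computed once per
   (model, bounds) and shared by the control and treatment solves, since
   production capability is weight-independent.
4. **Demand** — X = min Σ w·|v| subject to S·v = 0, bounds, and exchange
   flux ≥ opt_fraction·v_max.  opt_fraction defaults to 0.9 (a stand-in;
   config-exposed).  The absolute value is linearized by splitting every
   reaction into nonnegative forward/backward parts carrying the same
   weight; the LPs are solved with HiGHS via scipy.  Degenerate optima are
   acceptable — only X is contract-bearing.  Exchange bounds are fixed
   beforehand from a named uptake/secretion profile in the config (the
   stand-in for measured medium uptake rates).
5. **Scores** — X_raw = (X_control − X_treatment)/(X_control + X_treatment)
   (0 when both demands are 0, logged); z-transform across the condition's
   exchangeable metabolites with the population standard deviation; calls
   use strict cutoffs ±0.1 (a z of exactly 0.1 is unchanged).  If all raw
   scores coincide (σ = 0) every call is unchanged.

Demands are computed only for metabolites flagged exchangeable that have a
secretion exchange; an optional metabolite subset list restricts scoring
(e.g. to lipid-related metabolites) after the model is loaded.

## Parallelogram analysis

Per test system, an item is *frequent* when it appears in at least 5% of
the system's conditions — inclusive: 1 of 20 conditions is frequent — with
each system's own condition count as the denominator.  Human gene sets are
translated to rat IDs through the ortholog table before set comparison;
one-to-many orthologs expand to all images by default (a drop-ambiguous
mode exists).  Pathway IDs and metabolite IDs are shared across systems and
need no translation.  The three-way overlap reports all seven exclusive
Venn regions and the triple-intersection member list.

Metabolite × condition score matrices are clustered on each axis
independently with agglomerative hierarchical clustering (Ward linkage,
Euclidean distance — chosen for determinism, config-exposed), cut to k = 3
flat clusters per axis by default, and each condition cluster is summarized
by its rounded dose-level percentages.

## Synthetic data: what it emulates, and what it does not

The generator draws per-gene baselines once per study (gene-specific
platform intensity shared across conditions), plants a dose-dependent
fraction of DEGs per condition (2%/5%/10% at low/medium/high by default —
dose raises the *number* of DEGs, not their effect sizes, reflecting the
dose-response structure of multi-dose exposure studies; both behaviours are
configurable), and adds i.i.d. Gaussian replicate noise (sd 0.3 log₂ units
by default around an effect size of 1.5).  Planted shift magnitudes are
drawn around the nominal effect size (normal with sd = effect_size/3,
folded at zero) with equiprobable sign, so the nominal effect is the
typical planted effect — keeping rank ties rare without seeding the truth
table with sub-noise "DEGs" that no method could recover.  Conserved-signal
genes are planted up-regulated in every condition of every system.

The toy metabolic model is a linear backbone from a single uptake nutrient
through internal metabolites, with branches to each secreted exchangeable
metabolite and a few reversible shortcuts; every internal reaction carries
a GPR over 1–3 genes.  The uptake nutrient itself is flagged
non-exchangeable: under mass balance the sole imported species can never be
net-exported, so it is a boundary input, not a scorable product.  Defaults:
lb/ub = −1000/1000 for reversible reactions, 0/1000 irreversible, uptake
lb = −10.

What the generator does **not** emulate: probe-level array artifacts, batch
effects or outlier arrays, correlated gene–gene noise, realistic pathway
topology (gene sets are random draws), and genome-scale network complexity
(the toy model has tens of reactions, not thousands).  Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the assumed noise model — not robustness to the
systematic artifacts of real array data, which upstream normalization and
quality control must handle.

## Numerical and edge-case conventions

- Exchange reactions carry coefficient −1 for their metabolite: positive
  flux secretes, negative imports.
- LP bounds are non-strict (strict inequalities are meaningless in linear
  programming).
- Hierarchical clustering and all generators are deterministic given input
  order and seed; every source of randomness in the pipeline takes a seed
  from the config.
- Average ranks for ties everywhere ranks are used; a fully tied comparison
  column contributes (G+1)/2 to every gene's rank product.
- Zero-variance z-transforms, empty DEG sets, unmapped MIEs, unproducible
  metabolites (v_max = 0), and 0/0 production scores all degrade to the
  neutral outcome (unchanged / p = 1 / empty set) with a structured log
  line rather than an error.
- Pipeline problem sizes in the shipped configuration (2000 genes, two
  chemicals, three doses, three replicates, 1000 permutations, a ~15-
  reaction model) were chosen so a full three-system run completes in
  about a minute on one core while leaving every statistical property
  measurable; all sizes scale up through the config.

## Known limitations

- The rank-product pfp is Monte-Carlo: near-boundary genes can flip calls
  across seeds at low permutation counts; 1000 permutations is a floor, not
  a recommendation, for publication-grade runs.
- The TIMBR weight transform and optimal fraction are conventions of this
  implementation (the algorithm family leaves them to the modeler); results
  should be reported alongside these settings.
- BH adjustment treats each condition's pathway family independently; no
  cross-condition multiplicity control is attempted.
- Ortholog expansion can inflate rat-side set sizes when many-to-many
  mappings are dense; the drop-ambiguous mode trades recall for precision.
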