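# Methods

## Scope and model of the problem

The package treats off-target discovery as a chain of inferences: a
metabolome-wide perturbation profile says *what* is disrupted; a classifier
trained on reference antibiotics says *which mechanism class* the profile
resembles; constraint-based modelling says *which specific lesion* is
consistent with how nutrient supplements rescue growth; pocket similarity
says *which enzyme* the compound could plausibly bind; assay fits quantify
the confirmation experiments. Every stage is usable on real tabular inputs
(TSV intensity tables, the community JSON schema for stoichiometric models,
fingerprint tables), but the package ships a synthetic generator for each
input so the whole chain is testable against known ground truth.

## Differential abundance (metabstats)

Effect size is log2((mean(treated)+pc)/(mean(control)+pc)) with arithmetic
means over replicates and pseudocount pc (default 0, erroring on zero
denominators; half the minimum positive intensity is the recommended
nonzero choice). Base 2 is a convention choice and configurable.

Significance uses the one-sided Mann-Whitney test. For pooled sample size
≤ 12 the p-value is exact: all C(n+m, n) assignments of the pooled values
are enumerated, which is also exact under ties. Larger samples use the
tie-corrected normal approximation with continuity correction. With n = 3
vs 3 the smallest attainable one-sided p is 1/20 = 0.05; any smaller
printed value implies pooling across conditions or replicate structure not
modelled here. The test direction is chosen per metabolite from the
observed median difference and recorded.

## Mechanism classification (mechml)

Profiles are log2 fold-change vectors per (drug, time), filtered to
metabolites with annotation score > 50, zero-time profiles dropped,
replicates averaged per drug. The classifier is an L2-regularized
multinomial logistic regression (C = 1.0, tol = 1e-6, max 1000 iterations —
pinned rather than "default" for reproducibility), on features z-scored
using training-fold statistics. Evaluation is leave-one-out; classes with a
single member are flagged untrainable rather than silently skipped.

The "residual signature" removes a class signature from a profile by
orthogonal projection r = x − (⟨x,w⟩/⟨w,w⟩)·w onto the complement of the
class weight direction; the alternative (coefficient-wise subtraction) was
rejected because it is scale-dependent in the weights. The 2-D embedding
defaults to UMAP (2 components, 14 neighbors, random_state 42) but the
contract is only on the interface — two deterministic components — and a
PCA backend is available (the pipeline uses PCA for speed). DBSCAN
eps/min_samples default to 0.5/5 and are exposed; cluster counts are
data-dependent, not an invariant.

## Constraint-based rescue analysis (fbarescue)

FBA maximizes biomass flux subject to S·v = 0 and bounds, solved by HiGHS
(feasibility 1e-9, optimality 1e-8). Reference fluxes for fractional caps
come from a parsimonious step (fix μ*, minimize Σ|v| via a split-variable
LP), because the plain optimum is degenerate and "90% of optimal flux" is
otherwise ill-defined. Exchange fluxes are negative for uptake.

Lesion kinds:

* **pathway_fraction** — each target's |flux| capped at fraction × its pFBA
  reference (a zero-reference target is capped at zero, by design);
* **cofactor_drain** — an added charged→discharged reaction with an
  *enforced minimum* flux, modelling cofactor sequestration; the default
  drain magnitude in the pipeline is 50% of the baseline charging flux,
  large enough to bind without being lethal, and exposed in config;
* **knockout** — bounds (0, 0).

Supplements open the metabolite's exchange to uptake ≤ 0.1 mmol/gDW/hr
(configurable). Growth benefit is Δμ = μ(lesion+supplement) − μ(lesion);
as a pure bound relaxation it is never negative. A supplement with no
exchange contributes Δμ = 0 (no uptake route) rather than erroring, so
topology edits propagate cleanly into benefit vectors.

Expression shutoffs close reactions whose AND/OR gene rule is false given
an unexpressed-gene set; the default scope is a k-step neighborhood around
the supplemented metabolites because genome-scale global shutoffs tend to
be lethal in silico. Spontaneous (uncatalyzed) reactions carry a model flag
and are closable in one call.

Scenario ranking correlates each lesion's benefit vector with the
experimental rescue growth rates (Pearson); undefined correlations
(zero-variance or infeasible-lesion vectors) rank last; ties break by
scenario name. The null model enumerates (or samples, seeded) single-
reaction knockouts. Where a pathway has several constrained-reaction
variants their mean benefit is used — an interpretation choice, documented
here.

## The toy folate network (synthio)

~30 metabolites / ~40 reactions, unit biomass stoichiometry (only relative
growth changes matter). Glucose uptake is bounded at 10 mmol/gDW/hr; the
baseline optimum is μ* = 20/13 ≈ 1.538 in the model's arbitrary units. The
folate cofactor cycles between thf and mlthf: charged by SHMT
(ser + thf → gly + mlthf), discharged by thymidylate synthase (TMDS) and
AICAR transformylase (AICART), so folate limitation throttles both
nucleotide branches at once. Deliberate topology choices:

* thymidine salvage produces dTMP downstream of TMDS; uridine enters at UMP
  upstream of it;
* IMP→AMP is irreversible and the AMP→IMP deaminase is gene-gated by a
  cryptic gene (unexpressed by default), so AMP cannot reach the guanine
  branch; AMP's own entry is a spontaneous transport step. Before
  expression corrections AMP therefore looks as good as IMP; after closing
  unexpressed genes and spontaneous reactions its benefit is exactly zero —
  the behaviour that motivates the shutoff step;
* the citrate importer is gene-gated off, removing a spurious carbon-source
  rescue;
* serine synthesis is capacity-limited (7 mmol/gDW/hr) so a folate-cofactor
  drain is serine-limited and serine supplementation, but not glycine,
  relieves it; a folate-independent glycine route exists so glycine supply
  is not artificially welded to SHMT byproduct flux.

What the generator does *not* emulate: genome-scale redundancy (isozymes,
alternative carbon routing), realistic biomass composition, and
condition-specific expression — so passing tests show the *method*
discriminates lesions correctly on a network where ground truth is known,
not that any particular genome-scale model would.

## Metabolomics generator

Each sample is baseline × 2^(class effect) × exp(N(0, σ)) — multiplicative
log-normal noise, the standard assumption for MS intensities (the true
LC-MS noise law is not characterized; this is an assumption, stated here).
Defaults: 3 replicates, harvest points at 0, 0.5, 4 and 12 h (the zero-time
harvest carries no effect and exists to exercise the exclusion rule),
σ = 0.2 on the natural-log scale, class effects ±3 log2 units on 8
metabolites per class with one shared metabolite between consecutive
classes, and 30% of metabolites assigned annotation scores ≤ 50 to
exercise confidence filtering.

## Assays

Growth: OD(t) = K/(1 + exp(−r(t − t_mid))), sampled every 30 min over 15 h.
Lag is reported by the tangent-intercept construction (the inflection
tangent crosses the baseline at t_mid − 2/r); a threshold-crossing
alternative (5% of K) is available — the definition matters and neither is
canonical. Flat curves return r = 0 with lag flagged undefined.

Dose-response: the kinase assay couples *residual ATP* to luminescence, so
inhibition raises the signal. Percent activity rescales a signal between
the zero-inhibitor (full reaction, floor) and no-reaction (ceiling)
references; it is invariant to affine re-gaining of the luminometer and is
deliberately not clipped to [0, 100] (clipping biases the fit). A 4PL with
asymptotes bounded to [−10, 110]% is fitted on percent activity and the
IC50 is reported as the 50%-crossing of the fitted curve; with noise-free
unit-hill data this recovers the generating midpoint to machine precision.
Ki = IC50/(1 + [S]/Km) (competitive inhibition). For the worked example
with IC50 = 39.23 µM and [S] = 18 µM, Km = 1.7854 µM gives Ki = 3.54 µM;
that Km is obtained by inverting the relation, since only (IC50, Ki, [S])
triples are typically reported.

Cell lengths are log-normal with specified medians, truncated below 0.5 µm
(imaging resolution floor), n = 300 per group by default; comparison is
the shared one-sided Mann-Whitney test with a 10/25/75/90-percentile
boxplot summary.

## Pipeline and problem sizes

`run_pipeline` funnels all randomness through per-stage seeds derived from
one config seed and stamps a config hash into the report, so identical
configs give byte-identical report bodies. The combined candidate ranking
is a rank-sum of the pocket-similarity rank and a pathway-evidence rank
(1 if the candidate sits in the pathway implicated by the rescue stage,
else 2) — a deliberately simple, pluggable rule; the underlying evidence
columns are all exported for any other weighting.

Default analysis sizes (toy model ~40 reactions; panels of 5 classes × 3
usable time points × 3 replicates over 40 metabolites; 30-sample random
knockout nulls; 100-seed recovery simulations) keep a full test run and
pipeline execution in the minutes range on a single CPU while leaving every
statistical check well-powered at its stated tolerance.

## Known limitations

* Exact Mann-Whitney enumeration is O(C(n+m, n)) and capped at pooled size
  12; beyond that the normal approximation's accuracy (≲0.02 absolute at
  n = m = 6) is the operative guarantee.
* The LP-based benefit is a steady-state quantity; kinetic effects (lag
  prolongation by partially rescuing supplements) are visible only through
  the growth-fit stage, not the FBA stage.
* Pocket fingerprints are opaque bit sets; the package deliberately does no
  cleft detection or structural alignment, and whole-structure alignment
  p-values are consumed, never computed.
* The mechanism classifier assumes the query compound's class is among the
  training classes; a genuinely novel mechanism shows up only as a diffuse
  probability vector and a large residual signature.
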