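# Methods

## Scope and model

`fluxtarget` operates on genome-scale constraint-based metabolic models:
a stoichiometric matrix S over metabolites × reactions, flux bounds in
mmol/gDW/hr, boolean gene–protein–reaction (GPR) rules, and a biomass
pseudo-reaction as the growth objective. Steady-state flux vectors satisfy
S·v = 0 within bounds. Exchange reactions are written `met_e ⇌ ∅` with
negative flux denoting uptake; reversibility is encoded purely by a
negative lower bound. The model JSON dialect is the community exchange
format, so files interoperate with cobrapy in both directions (SBML L3/FBC
is supported through a cobrapy conversion).

## Omics discretization and integration

Gene activity is binary. Per dataset, a gene is **active** iff it is
expressed in *strictly more than* half of the samples in which its probe
was detected; genes never detected are *undetermined*, not inactive —
absence of evidence is treated as missing data. When several datasets cover
one cell type they are first discretized independently and then combined by
the same strict majority over datasets, which prevents large datasets from
dominating the consensus.

Integration across omics layers assigns tiers:

| tier | rule |
| --- | --- |
| high | active in transcriptomics **and** proteomics |
| moderate_transcriptomic | active only in transcriptomics, sample support ≥ 0.90 |
| moderate_proteomic | active only in proteomics, abundance quantile ≥ 0.75 |
| none | everything else (inactive) |

The 50% rule is strict (`>`) while the 90% and top-quartile rules are
inclusive (`≥`): "more than half" versus "at least". Proteomic abundance
quantiles are computed within each sample (run scales differ) and averaged
across samples.

## Context-specific extraction (GIMME)

Given a media-constrained template and reaction activity labels (a reaction
is active iff its GPR evaluates true over the active gene set; empty-GPR
reactions are `no_gene` and never pruned), extraction solves the linear
program

minimize Σ_inactive penalty·|v_r|  subject to  S·v = 0, bounds, v_objective ≥ f·z*

with reversible fluxes split into nonnegative forward/reverse parts and z*
the template's FBA optimum. Under binary activity the classic GIMME penalty
`threshold − expression` collapses to a flat penalty (default 1) on
inactive-reaction flux. Kept reactions are: all active, all `no_gene`, and
any inactive reaction carrying |flux| > tol in the minimizing solution
(metabolically required despite missing expression evidence). The kept GPRs
are retained complete, so an unexpressed isozyme remains deletable later.

The objective fraction *f* defaults to 0.9; it is a config knob
(`gimme_fraction`) since common practice varies between 0.5 and 0.9 and the
appropriate value depends on how literally the context data should be
allowed to throttle growth.

Hygiene runs in the order media → GIMME → dead-end removal → blocked-
reaction removal. Dead-end metabolites (no possible producer or no possible
consumer, given bounds) are removed iteratively with their incident
reactions; the fixpoint is scan-order independent. A final sweep removes
all reactions whose flux range at objective fraction 0 is within ±tol of
zero, which also guarantees no dead-end survives. The built model is then
leak-tested: with every exchange closed, a temporary drain per metabolite
must carry no flux; any leak indicates stoichiometric mass creation.

## Knockouts and flux-change classification

Deleting gene g closes exactly the reactions whose GPR becomes false with g
removed from the model's gene set. Knockouts disabling nothing (isozyme-
backed targets) are *silent*; they are recorded but excluded from scoring —
only genes whose deletion blocks at least one reaction are effective
targets. Perturbed fluxes come from MoMA: minimize ‖v − v_wt‖² (quadratic,
default, solved with OSQP at eps 1e-10 with polishing) or Σ|v − v_wt|
(linear variant via deviation splitting), subject to the perturbed
constraints; v_wt is one fixed FBA solution per model, cached and reused
for every knockout so all flux ratios share the same reference.

Flux changes are classified on magnitudes m = |v|: with wild-type magnitude
above abs_tol (1e-6), the ratio m_ko/m_wt calls **down** below 1 − rel_tol,
**up** above 1 + rel_tol (rel_tol default 0.05), otherwise **unchanged**;
a numerically zero wild-type flux calls **up** iff the knockout flux
exceeds abs_tol, with the ratio reported as NaN. Magnitudes rather than
signed values are compared because for a reversible reaction the sign is
direction, not activity; a flux that merely reverses sign at equal
magnitude is logged as a sign flip but classified unchanged. A signed mode
is available behind a flag.

Essentiality uses growth-ratio cutoffs: essential < 0.01 of wild-type
growth, reduced < 0.5, else nonessential; precision–recall curves rank
genes by ascending growth ratio and integrate precision over recall by the
trapezoid rule, anchored at recall 0.

## Scoring, ranking, selection

DEG tables are filtered at adjusted p < 0.05 and two-fold change; when
fewer than `min_metabolic_degs` (default 10) metabolic DEGs survive, the
threshold falls back to 1.5-fold (both knobs in config; the cutoff actually
used is recorded). For one knockout, the up-group is the set of *distinct*
reactions whose GPR contains at least one upregulated DEG (union
semantics — a reaction regulated by several same-direction DEGs counts
once; a reaction carrying both an up- and a down-DEG contributes to both
groups), partitioned by flux-change class into UpDec/UpInc/UpUnc, and
likewise for the down-group. The perturbation effect score is

PES = (UpDec − UpInc)/(UpDec + UpInc + UpUnc) + (DownInc − DownDec)/(DownInc + DownDec + DownUnc),

with a zero-denominator term contributing 0, which keeps the score total
and bounded in [−2, 2]; the maximum 2 is attained exactly when both
numerator counts are positive and all opposing/unchanged counts vanish.

Per model and disease, PES values are ranked (rank 1 = highest; ties
averaged), ranks standardized to Z-scores with the sample (n−1) standard
deviation (population mode behind `zscore_ddof=0`), and Z-scores summed
across cell-type models. The aggregate is re-standardized before applying
the −1 cutoff, so selection reads "at least one standard deviation better
than the mean aggregated score"; a raw-sum mode is available
(`restandardize_aggregate: false`) since the cutoff's reference scale is a
genuine modelling choice. Genes lacking a score in any model (e.g. pruned
from that cell type) are excluded from aggregation with a warning.

Pathway enrichment is a one-sided Fisher exact test (hypergeometric upper
tail) per pathway against a user-supplied background, Benjamini–Hochberg
corrected; significance requires p < 0.05 and FDR < 5%; fold enrichment is
(k/n)/(K/N).

## Validation procedures

Nutrient sweeps report, at each uptake grid point, the mean ± sd of FBA
growth over a local window of n equally spaced uptake values (default n =
5, step 0.1, i.e. 3.0 → {3.2, 3.1, 3.0, 2.9, 2.8}); a window of 1 is
pointwise FBA. Conditional-dependency surfaces flag whether nutrient B
moves growth only below a threshold availability of nutrient A.
Forced-flux responses raise a reaction's lower bound stepwise and record an
observed flux. Behavior suites compare qualitative outcomes (zero /
decreased / increased / unchanged / nonzero, using the same rel_tol
conventions) against literature expectations and report agree / partial /
disagree, where adjacent outcomes (e.g. expected decreased, observed
unchanged) count as partial.

## Synthetic data: what it emulates, and what it does not

The toy template (~27 reactions, ~22 metabolites, ~25 genes) mirrors the
central carbon metabolism relevant to T-cell activation: a glucose →
glycolysis chain with an energy token, a pyruvate node branching to lactate
secretion and a capacity-limited TCA-like cycle, glutamine anaplerosis
(deliberately lossy and uptake-capped, so the pyruvate-carboxylase route is
strictly required at optimum — this pins the optimal flux pattern and
avoids degenerate alternate optima on the reactions the benchmarks assert
about), a fatty-acid uptake/oxidation branch used by the naive profile
versus de novo lipogenesis in the effector profile, an essential amino-acid
uptake, and a five-precursor biomass reaction. The naive medium carries
fatty acids; the effector medium does not. A separate pyruvate-branch
fixture with a pinned glucose feed gives the mass-balance-forced
dehydrogenase/lactate tradeoff.

Omics samples are Bernoulli draws from per-gene activity probabilities
(0.95 active / 0.05 inactive) with symmetric flip noise (default 0.03) and
detection dropout (default 0.1); proteomic abundances are log-normal with a
higher location for active genes so active genes concentrate in the top
quartile. Disease DEG tables are *planted*: the generator runs the real
knockout/classification machinery on the template, draws upregulated DEGs
from genes all of whose reactions decrease under the planted knockout,
downregulated DEGs from genes all of whose reactions increase, and decoys
(half the table) from genes with unchanged reactions — so the planted
target provably reverses the signature, and the truth stays valid as solver
details evolve. Drug annotations cover 80% of genes (plus withdrawn
entries, which exercise the load-time filter), and the planted target is
always annotated; the essentiality reference is exhaustive single-gene FBA
deletion.

Passing the planted-recovery benchmark (top rank in 20/20 seeded
scenarios) shows the pipeline's bookkeeping and scoring are correct under
known ground truth. It does **not** show that the approach recovers targets
in real data: the toy network has no alternate pathways at genome scale, no
probe-mapping noise, no batch structure across datasets, and its DEG tables
are constructed to be reversible by a single gene. Model sizes, gene
counts, and target lists from real CD4+ T-cell studies are outside what
these synthetic conditions can reproduce.

## Numerical choices

- Zero-flux tolerance tol = 1e-6 everywhere (typical LP feasibility
  tolerance), configurable.
- LPs run on scipy's HiGHS (deterministic); the MoMA QP on OSQP with
  eps_abs = eps_rel = 1e-10 and solution polishing, clipped back into
  bounds post-hoc to absorb first-order solver slack.
- FBA returns one optimal vertex without uniqueness guarantees; everything
  downstream therefore references a single cached wild-type solution, and
  knockout fluxes always come from MoMA rather than re-optimization.
- Blocked-reaction detection uses objective fraction 0, so "blocked" means
  infeasible under any objective.
- Rank ties are averaged; an all-tied rank vector yields all-zero Z-scores
  with a warning rather than an error.
- Default problem sizes (toy template, 12 omics samples, 20 recovery
  seeds) keep the full test suite and the acceptance script in the
  seconds-to-minutes range on a single CPU.

## Known limitations

- The GIMME implementation assumes binary activity; graded expression
  penalties would need the threshold-minus-expression weighting.
- MoMA reference fluxes inherit any alternate-optimum arbitrariness of the
  wild-type FBA vertex; on degenerate networks the flux-change classes of
  individual reactions can depend on the solver's vertex choice (the
  synthetic template is constructed to avoid this on the assessed
  reactions).
- The leak test closes *all* boundary reactions, including demand-style
  single-metabolite reactions, so intentional maintenance drains are not
  probed for leaks.
- Directionality curation is not inferred; a config table
  (`directionality_overrides`) applies user-supplied bound overrides before
  extraction.
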