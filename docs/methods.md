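# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## The cohort model

Every analysis consumes a `Cohort`: row-aligned patient tables of binary
symptom indicators (default: the canonical 69 four-diagnostic symptoms),
numeric biomarkers (default: a 90-item clinical panel spanning blood and
urine routine, biochemistry, coagulation, thyroid function, cardiac
markers, ECG and echocardiography), and binary syndrome labels.

The synthetic generator draws, per patient:

* **Latent syndrome statuses** — independent Bernoulli draws per syndrome.
  Default prevalences follow the reference cohort's label counts:
  qi deficiency 225/411 ≈ 0.547 and phlegm-blood stasis 69/411 ≈ 0.168.
  An optional Gaussian-copula equicorrelation (`syndrome_correlation`,
  default 0) couples the latent statuses; the default is independence
  because the two syndromes are analysed as separate binary endpoints.
* **Symptoms** — a symptom mapped to a syndrome fires with probability
  `symptom_lift_rate` (default 0.60) when that syndrome is present and
  `symptom_base_rate` (default 0.10) otherwise. The default map assigns the
  published core-symptom groups: 11 qi-deficiency symptoms lift the qi
  label, and the phlegm-turbid (4) plus blood-stasis (6) groups both lift
  the composite phlegm-blood-stasis label, since that composite is the
  excessive core syndrome the identification modes target. The 0.10/0.60
  rates are a deliberate strong-signal regime: common enough that a
  411-patient cohort keeps all 69 columns non-constant, separated enough
  that mapped pairs dominate the mutual-information ranking.
* **Biomarkers** — `Normal(baseline + Σ active-syndrome shifts, sd)`. All
  90 defaults are standardized (baseline 0, sd 1), mirroring the
  data-standardization step a multi-centre cohort requires before
  modelling; the 8 qi-mode parameters (X TAL, RDW-CV, K, TSH, MONO,
  hs-CRP, LDL, A peak) carry a +1 sd qi shift and the 6 phlegm-mode
  parameters (hs-CRP, TBIL, GGT, PLT, FBG, P-R interval) a +1 sd phlegm
  shift — hs-CRP belongs to both panels and shifts under either. One
  standard deviation makes parameter-recovery simulations meaningful
  without being trivial.
* **Missingness** — off by default; an optional missing-at-random rate
  blanks biomarker cells, because real clinical tables have gaps.

What the generator does **not** emulate: inter-biomarker covariance beyond
the shared syndrome shifts, non-Gaussian biomarker distributions (skewed
inflammatory markers, count-like urine fields), symptom co-occurrence
beyond what the latent syndromes induce, site effects, and longitudinal
structure. Tests passing on this generator therefore demonstrate that the
algorithms recover planted structure of this simple kind — not that the
clinical effect sizes or the published tree shapes would re-emerge from
real data.

Identical configuration and seed give byte-identical cohorts; the CSV
format (`patient_id`, `sym_*`, `bio_*`, `lab_*`) round-trips losslessly
(floats are parsed with round-trip precision on read).

## Symptom association network

Association between two binary symptom vectors is their empirical mutual
information in bits; terms with an empty joint cell contribute zero, so the
statistic is always finite and nonnegative. MI was chosen as the
association screen because the reference analysis used a mutual-information
association model whose internal distance component is not published;
plain pairwise MI reproduces its observable output — a ranked pair list —
without guessing unpublished machinery.

Two selection modes (exactly one active):

* **Edge budget** (default m = 120, the published network size): the m
  highest-MI pairs, ties at the boundary broken lexicographically by pair
  name so rebuilds are deterministic.
* **Permutation gate**: pairs with permutation p below `alpha_perm`. Since
  the MI of a 2×2 table is a function of the 1–1 cell given fixed margins,
  the label-shuffling null is sampled exactly as hypergeometric draws of
  that cell — orders of magnitude faster than physically permuting columns
  and identical in distribution. p-values use the add-one convention
  `(1 + #{null ≥ observed}) / (n_perm + 1)`.

Constant symptom columns are dropped with a warning rather than raised:
small synthetic cohorts produce them routinely and they carry no
information. Pajek I/O uses the plain `.net` dialect — `*Vertices n`,
1-based `i "label"` lines (labels are quoted because symptom names contain
spaces), `*Edges`, `i j` lines — and round-trips node order and edge sets.

## Degree and k-core analysis

Degree is the number of incident edges. A node's core value is the largest
k such that it survives in the k-core, the maximal subgraph with minimum
internal degree ≥ k. The implementation peels: repeatedly remove a
minimum-degree node, assigning it the running maximum of removal degrees,
with bucketed degrees for O(V+E) behaviour. The naive fixpoint oracle
(for each k, delete nodes of degree < k until stable) is retained in the
test suite and must agree on every random graph tried; `networkx`'s core
numbers serve as a second independent check.

The published 69-node property table ships as a fixture. Its edge list was
never published, so the table cannot be regenerated — it is treated as
ground truth for consistency checks only: 69 rows, degree sum 240 (twice
the published 120 edges, by the handshake lemma), maximum degree 11,
exactly 31 nodes of core value 3, and core ≤ degree everywhere. One
discrepancy is documented rather than resolved: the reference prose lists
10 symptoms with degree above six, but the table implies 12 (sore waist
and knee, 9; irritable tantrum, 8). The package reports what the table
implies.

Core-syndrome labelling groups nodes with core ≥ k (default 3) by a
symptom→syndrome map. Only the published partial assignment (qi
deficiency, phlegm turbid, blood stasis — 21 of the 31 central symptoms)
ships as the default; the remaining central nodes are reported as
"unassigned" rather than guessed.

## CHAID

The learner follows Kass's original scheme with Pearson's statistic only.

* **Binning.** Continuous predictors are discretized once, globally, into
  at most `max_bins` (default 10) equal-frequency bins; duplicate quantile
  edges collapse, a constant column becomes a single bin. Ten ordinal bins
  is the common default of CHAID implementations. Missing values form
  their own category: an ordinary category for nominal predictors, a
  floating category for ordinal ones (free to merge with any group, in
  Kass's sense).
* **Merging.** At a node, for one predictor: repeatedly test every
  eligible group pair (all pairs if nominal, adjacent if ordinal, floating
  missing against every group) on its 2×k subtable; merge the pair with
  the largest p while that p exceeds `alpha_merge`; stop otherwise. Pairs
  indistinguishable through the response (an empty group, or fewer than two
  nonzero response columns) count as p = 1. Merged compound categories are
  never re-split — the optional refinement is omitted for determinism.
* **Adjustment.** The final grouping's full-table χ² p-value is multiplied
  by the Kass multiplier B for reducing c observed categories to r groups:
  the Stirling number of the second kind S(c, r) for nominal scales
  (computed by the alternating-sum formula), C(c−1, r−1) for ordinal.
  `p_adj = min(1, B·p)` ≥ p always.
* **Splitting.** A node with at least `parent_min` cases, depth below
  `max_depth` and an impure target evaluates every predictor; candidates
  whose grouping would create a child below `child_min` are discarded; the
  smallest `p_adj` wins (ties: smaller raw p, then predictor name) and the
  node splits iff `p_adj ≤ alpha_split`. Defaults mirror the reference
  settings — parent 50, child 25, depth 3, α = 0.05 for both merge and
  split (the reference states a single α; 0.05 is the conventional level).
  The reduced-predictor external-validation regime (parent 2, child 1) is
  expressible through the same configuration.
* **Prediction.** Cases are routed by their binned category; unseen
  categories at a node follow the largest child (logged); leaves emit
  their majority class and class proportions. A constant training target
  yields a flagged root-only tree rather than an exception.

Fitting is deterministic and invariant to row order: all decisions are
functions of category counts, and all ties break by fixed lexicographic
rules. Trees serialize to versioned JSON and a plain-text rendering.

The exact published trees cannot be reproduced — the underlying patient
data is unavailable — so the test suite checks structure-level properties
instead: node-count partitions, size minimums, p-adjustment inequalities,
growth monotonicity in α and in the size limits, null behaviour on pure
noise, and root-split recovery of the truly shifted biomarkers on
synthetic cohorts. The recovery simulation fits depth-1 trees: the root
decision is identical at any depth and only the root variable is scored.

## Validation

Stratified k-fold assignment (default 10 folds) shuffles each class with
the configured seed and deals fold slots round-robin, carrying the slot
offset across classes; fold sizes and per-class counts are balanced within
one by construction, and classes rarer than the fold count still receive
an assignment (folds whose training complement loses a class are skipped
with a warning and reported). The pooled out-of-fold confusion matrix is
the headline cross-validation result; resubstitution metrics from the
full-data tree are also reported, because SPSS-style cross-validation
tables can reflect either reading and the reference does not say which.
Percentages are displayed rounded half-up to one decimal, matching the
printed convention (Python's bankers' rounding would disagree on .x5
boundaries).

The four published confusion matrices (internal 411-patient and external
212-patient runs, two syndromes each) ship as a JSON fixture together with
their printed percentages; `reproduce_paper_tables` recomputes all twelve
percentages and both correct-prediction counts from the raw counts and
flags any mismatch. One documented inconsistency in the source: the
external-validation cohort is described once as 212 patients and once as
211; the table counts sum to 212 per row, so 212 is used.

## Numerical and design conventions

* Chi-square tail probabilities come from `scipy` (`chdtrc` on the hot
  merge path — identical values, no distribution-object overhead).
* All simulations derive their randomness from explicit integer seeds;
  the pipeline spawns per-stage seeds (below 2³¹) from one master seed via
  `numpy.random.SeedSequence`, so arms rerun independently yet
  reproducibly. Reports embed a configuration digest that excludes the
  output directory and log level.
* Simulation sizes in the acceptance script (50 recovery seeds, 100 null
  replicates at n = 300 with 5 predictors, 20 random graphs at n = 30)
  were chosen as the smallest runs whose Monte-Carlo error is comfortably
  inside the margins being checked.

## Known limitations

* The MI screen is pairwise and unconditional; it cannot distinguish
  direct association from association induced by a shared syndrome.
* CHAID here offers no exhaustive-split variant, no surrogate splits and
  no pruning; likelihood-ratio χ² is deliberately not offered.
* The generator's strong-signal defaults make recovery tests easy relative
  to clinical reality; effect sizes in real cohorts are smaller and
  correlated.
* Published-table fixtures validate arithmetic consistency, not the
  original computation: the raw cohort, the 120-edge list and the fitted
  trees are unpublished and cannot be re-derived.
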