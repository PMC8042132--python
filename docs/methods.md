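# Methods

## Model and procedure

`guiltnet` chains two independent evidence streams into a per-gene function
prediction.

**Co-expression front end.** Samples (columns) of a gene × sample matrix
are quantile-normalized: the reference vector is the per-rank mean of the
sorted sample vectors, each sample's values are replaced by the reference
value at their rank, and ties within a sample receive the mean of the
reference values at the tied ranks. Gene–gene similarity is the sample
Pearson coefficient over all samples pooled. Each gene's KNN set is its
*K* = 40 most positively correlated partners — signed *r*, not |*r*|, since
"most correlated" in this setting means co-regulated, not anti-regulated
(an `absolute=True` switch exists). Exact ties are broken by ascending
gene id so results are platform-independent. Genes with zero variance get
*r* = 0 against everything (and are reported), keeping the matrix total and
the KNN step deterministic.

**Literature network.** Text is tokenized by splitting on non-alphanumeric
characters except internal hyphens; thesaurus surface forms are matched as
token subsequences, case-insensitively, longest match first, so "integrin
alpha 9" suppresses the inner "integrin". Each recognized term counts once
per document. The network's edge weight is the number of documents
mentioning both endpoints; no weight threshold is applied at build time.
A surface form claimed by two term ids is a hard input error rather than
first-wins, because silent mis-attribution would corrupt every downstream
count.

**Commonality scoring.** For query *Q* over gene universe of size *N*, a
concept with gene degree *d_c* gets expected sharing |Q|·d_c/N — the mean
of the hypergeometric distribution of overlaps under uniform query draws,
which the test suite pins by exhaustive subset enumeration. Obs/Exp is the
ratio of observed to expected sharing and Score = shared · Obs/Exp. Edge
weights are ignored at scoring time (a connection either exists or not);
`min_weight` optionally raises the bar for what counts as a connection.
Concepts need `shared_rels >= 2` by default: a single link carries no
enrichment information. Only non-gene concepts are scored; gene-type terms
define the universe. The query gene itself is excluded from its own KNN
query set. Curation of the output (e.g. keeping only disease/phenotype
concepts) is a filter (`concept_types`), not a computation.

**Association screen.** Pearson *r* with two-sided *p* from the *t*
transform at *n*−2 degrees of freedom, pairwise deletion for missing trait
values, per-pair *n* reported. Significance at raw *p* < 0.05 with no
multiple-testing correction — deliberately, because that is the screening
convention of strain-panel databases; the FDR-controlled stage is ORA.
Zero-variance inputs are errors, not silent *r* = 0: a degenerate trait must
surface. |*r*| within 1e-14 of 1 is treated as exact linear dependence
(*p* = 0) to absorb float rounding.

**ORA.** Hypergeometric upper tail via `scipy.stats.hypergeom`, BH step-up
via `statsmodels`; both are cross-checked in the tests against exhaustive
enumeration and a hand-rolled reference step-up, keeping implementation and
oracle separate. Sets are intersected with the universe before testing; the
minimum-overlap filter (default 5) runs *before* BH, so the adjustment's
*m* counts only tested sets — this matches common web-tool behavior and
does change adjusted values, which is why the ordering is fixed and tested.
The universe is an explicit argument everywhere (no hidden default
platform), since analyses legitimately differ on it.

**Profiling.** The "modified Z-score" is the Iglewicz–Hoaglin form
0.6745·(x − median)/MAD. Summarization order is mean-over-samples first,
then z across genes. MAD = 0 raises an error that names the explicit
fallback (0.7979·(x − median)/meanAD, enabled only by flag) rather than
switching silently, because the two scales are not interchangeable.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage can be validated against planted truth.

* *Expression*: gene *g* in module *m* is √ρ·f_m + √(1−ρ)·ε_g with f_m, ε_g
  standard normal per sample, so any two module genes have population
  correlation exactly ρ and E[sample r] ≈ ρ. Defaults for the end-to-end
  scenario: three 12-gene modules, ρ = 0.85, 120 genes × 120 samples —
  large enough that a K=10 KNN set is dominated by module-mates, small
  enough to run in seconds. No probe-level effects, batch structure, or
  heteroskedasticity are simulated, so passing tests demonstrate recovery
  under clean factor structure, not robustness to array artifacts.
* *Corpus*: signal documents pair a module's genes with its linked
  concepts; background documents draw terms uniformly. Documents are
  space-separated surface forms plus filler tokens — term recognition is
  exercised (synonyms, case, token boundaries) but no real scientific
  language, so the matcher's behavior on prose punctuation/abbreviation
  ambiguity is out of scope. Defaults: 800 documents, 60% signal, 5
  mentions per document.
* *Traits*: trait = Σβ·x_g + N(0, σ²) per strain; the acceptance analyses
  use a 38-strain panel, the scale of a BXD-type recombinant-inbred set.
  All effects on one trait must share σ (one noise term per trait).
* *Gene sets*: planted sets contain a full module padded to size with
  random genes; decoys are uniform draws. `enriched_sets` carries
  (set name, module id) pairs so the generator knows which module each
  planted set contains.

All generators take one explicit integer seed and are byte-reproducible;
the pipeline derives per-stage seeds from one global seed by a fixed
schedule (expression: s, corpus: s+1, traits: s+2, gene sets: s+3).

## Numerical and design choices

* Quantile-normalization tie rule: mean of the reference values at the tied
  ranks (not interpolation at the mean rank), applied per tie group.
* Correlations are clipped to [−1, 1]; |r| = 1 short-circuits to p = 0.
* Commonality sort: Score desc, then shared_rels desc, then concept id asc —
  fully deterministic.
* ORA sort: adjusted p asc, then enrichment ratio desc.
* Monotone-transform invariance: warping one sample monotonically before
  quantile normalization preserves every sample's rank structure (Spearman
  ρ = 1 column-wise against the unwarped normalization) but *not* the
  Pearson correlations exactly, because the reference distribution itself
  shifts; the tests assert the rank-structure form, which is the version
  that actually holds.
* Permutation oracle for the analytic Pearson p: compared at n = 25 with
  10⁴ shuffles, where Monte-Carlo noise dominates the (small, discrete)
  difference between the permutation null and the t null; a 2-standard-error
  band covers ~95% per case, so the check tolerates 2 excursions in 20
  cases. At smaller n the permutation/t discrepancy itself exceeds the
  Monte-Carlo band and the comparison would test the wrong thing.
* Calibration problem sizes (1000 null replicates, 500 power replicates,
  200 ORA replicates × 200 decoys, the 120-gene scenario) were chosen so
  each Monte-Carlo estimate has standard error well inside its acceptance
  band while the whole suite runs in seconds.

## Known limitations

* Co-occurrence is counted at document level with unit weight; sentence-level
  or graded weighting is a config hook, not implemented.
* No p-value accompanies Obs/Exp — the score is a ranking device, not a
  calibrated test; the ORA stage is where significance is controlled.
* The screen's raw p < 0.05 threshold admits ~5% of null pairs by design;
  downstream interpretation must account for that.
* The pipeline operates on supplied or synthetic corpora and matrices; no
  repository clients (GEO/GTEx/PubMed) are included, and literature-scale
  corpora are out of scope.
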