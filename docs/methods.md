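# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of `catgut`.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

All abundance tables are features × samples, tied to one annotation
level (phylum … species; KEGG ortholog group (KO), pathway, pathway
group). Proportions live in [0, 1] internally; percentages appear only
in report helpers (half-up rounding, 1 decimal in percent space).
Relative abundance uses the per-sample total of annotated reads as the
denominator, so column sums may fall below 1 when an explicit
denominator is supplied (the unannotated fraction is simply absent).

Level aggregation sums children into parents. The KO → pathway step is
many-to-many: by default each KO's value is added **in full** to every
pathway containing it (the KEGG convention), so pathway columns of a
proportions table can sum to more than 1 — the very over-counting that
motivates the parsimony step. A `weight="split"` mode divides by the
multiplicity and conserves mass instead.

## Synthetic cohort

The generator emulates the study design the analysis assumes:

- 30 kittens (16 M, 14 F) from 17 litters, assigned to groups F-EN 7,
  F-CN 7, M-EN 8, M-CN 8 such that no group holds two littermates
  (13 litters of two, 4 singletons; greedy assignment to the groups
  with most unfilled slots, which is always feasible at these sizes).
- Sampling ages 18, 30, 42 weeks; one early-neutered female is
  withdrawn after her first sample, giving 88 samples.
- Per-sample annotated-read totals are drawn uniformly from
  23,000–91,000 at desk scale. This preserves the relative spread of
  the study's read depths (23–91 million) at one-thousandth scale; a
  `--full-scale` flag restores the original range for cluster runs.

Genus counts follow a Dirichlet-multinomial: per sample, a composition
is drawn from Dirichlet(θ · m) and counts from
Multinomial(denominator, composition), so column sums equal the design
denominators exactly. The mean vector m is the age-specific calibrated
composition (below) after three modifications on the logit scale:

1. **Injected effects** (age / sex / neuter log-odds-ratios): each
   shifted feature takes exactly expit(logit(p) + β) and only the
   unshifted remainder renormalises, so the realised log-OR of the
   focal feature equals the injected β. Default: all zero, matching a
   cohort with no true gender or neuter effect.
2. **Kitten random intercept**: a per-kitten, per-genus N(0, 0.3)
   logit shift, constant over ages, inducing within-kitten correlation.
   The study does not state the within-kitten correlation; sd 0.3 is
   an explicit assumption of this package. Because the shift passes
   through a nonlinearity and a renormalisation, realised sample means
   of dominant genera sit slightly below their calibration targets.
3. θ defaults to 50, chosen to reproduce qualitatively high
   inter-individual variability; for rare genera (mean ≪ 1/θ) the
   resulting per-sample proportions are strongly right-skewed, as real
   rare-taxon abundances are.

**Calibration.** The per-age genus means reproduce the published
average composition of the kitten faecal microbiome: the 34 most
abundant genera take their printed percentages; within each of the
five major phyla, the gap between the printed phylum mean and the
displayed-genus sum is spread over a log-series tail of "hidden"
genera of that phylum; mass outside the five phyla goes to an
"Other"-phylum log-series tail. 100 genera in total at desk scale
(the study identified 605); columns renormalise to exactly 1.

KO counts redistribute each sample's genus composition through fixed
genus-specific KO profiles (sparse gamma weights, density 0.15, every
KO reachable) and a second multinomial draw; 400 KOs at desk scale
(7,277 in the study). Each genus carries a private pool of gene
identifiers (Poisson mean 40 + 5); a sample's gene set is the union of
the pools of the genera present, so gene richness grows with genus
richness by construction.

The synthetic KO→pathway hierarchy assigns each KO to
1 + Poisson(0.5) distinct pathways (mean multiplicity 1.5); every
pathway receives at least one KO.

All randomness flows from one root seed; each stage uses
`seed + offset` with fixed documented offsets, so stages are
individually reproducible and identical (spec, seed) pairs give
bit-identical outputs.

**What the generator does not emulate:** sequencing error, annotation
noise and read-level quality filtering (these happen upstream of the
count tables); antibiotic perturbation of individual kittens; genuinely
phylogenetically structured KO sharing between genera. Passing tests
therefore demonstrate correctness of the statistical machinery under a
plausible compositional model, not robustness to annotation artefacts.

## Diversity and trend testing

Shannon H′ uses the natural log, computed on per-sample proportions;
zero entries contribute nothing and an all-zero sample is an error.

Rarefaction subsamples reads without replacement (multivariate
hypergeometric) at the 13-depth schedule 10k, 20k, 50k, 100k, 250k,
500k, 1m, 2m, 4m, 6m, 8m, 10m, 20m reads, rescaled per sample by
(sample total / 2 × 10⁷) so desk-scale runs keep the full
13 × 10 × 88 = 11,440-point grid shape; the deepest subsample equals
the sample's read total. Replicate means agree with the closed form
E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)), which the test suite uses as an
independent oracle.

Trend tests fit a linear mixed model (kitten random intercept, ML) with
categorical age, sex, neuter group and all interactions as candidates.
Backward elimination removes the highest-order term with the largest
likelihood-ratio p ≥ 0.05, never removing a main effect while a
retained interaction contains it, refitting after each drop. Pairwise
age comparisons use LS-mean contrasts from the final model with a
studentized-range (Tukey HSD) reference, k = number of ages,
df = n − rank − 1. A constant response returns a trivial report rather
than a degenerate fit; aliased designs raise an error naming the term.

Note an inherent property of stepwise selection: a truly null covariate
appears in the final model with probability roughly the union of the
per-term test sizes (measured ≈ 25–40 % here across its four candidate
terms), even though each individual test is close to its nominal 5 %.
Conclusions about *age* are therefore drawn from the age contrasts, not
from covariate retention.

The rarefaction trend report averages replicates at each sample's
deepest depth and reuses the same machinery; the original
depth-within-age-within-kitten nesting with depth-variability weights
is deliberately approximated by the kitten-level random intercept, and
the report says so.

## Ordination

Raw JSD (natural log, range [0, ln 2], 0·ln 0 ≡ 0, no pseudocounts) is
the between-sample distance, matching the cited workflow; its square
root is metric but the raw divergence is not, so the double-centred
matrix can have negative eigenvalues. These are reported alongside the
positive spectrum — no Cailliez/Lingoes correction — and variance
shares are computed over positive eigenvalues only. Coordinates are
eigenvectors scaled by √λ for positive λ. The implementation is plain
classical scaling and is cross-checked against scikit-bio's PCoA in the
tests. Pathway-weighted scatter plots rescale point areas linearly into
a stated range; zero abundance maps to the minimum size, never to
omission.

## Association chain

Per feature, the response is the per-sample proportion
count/denominator with the denominator as binomial weight, fitted by
GEE (logit link, kitten clusters, exchangeable working correlation by
default, independence as an option). Candidate fixed effects and the
elimination rule match the mixed-model procedure above, with Wald tests
in place of LRTs.

**Small-sample inference.** With 30 clusters the textbook sandwich
covariance with a χ² reference is badly anti-conservative (measured
≈ 2 % tail probability at p = 0.005 under the generator's null).
`catgut` therefore uses the Mancl–DeRouen bias-corrected sandwich —
each cluster's residual inflated by (I − H_k)⁻¹ — with F references for
joint tests and t references for contrasts, denominator df =
n_clusters − n_params − 1. Age effects are summarised by **marginal
(LS-mean) contrasts**, which coincide with coefficient contrasts when
no age interaction is retained and remain calibrated when a chance
interaction survives elimination (testing the raw age main effect in
such a model is a selection-biased subgroup test). Under these choices
the family-wise error of the full filter → GEE → Sidak chain on null
cohorts is controlled (≈ 2–5 % measured at desk scale; the acceptance
suite asserts ≤ 7.5 % over 200 replicates).

Features with > 75 % zero counts are removed before fitting (strictly
greater: a feature at exactly 75 % is kept), and the Sidak critical
value 1 − 0.95^(1/m) always uses the post-filter m. Features absent
from an entire age are flagged `quasi_separated` but still fitted; an
optional 0.5-count continuity adjustment is off by default.
Non-convergence yields a flagged NA result, never an exception.

Direction classes: `pairwise-18` (default for taxa) calls a feature
"up" when the 18→30 and 18→42 odds ratios are both > 1 and both
individually significant at the family threshold; `monotone` (default
for KOs feeding enrichment) requires OR(18→30) > 1 and OR(30→42) > 1
regardless of per-contrast significance. Significant features matching
neither pattern are "mixed", and up + down + mixed = significant is
asserted whenever families are summarised.

## Parsimony and enrichment

Parsimony pathway inference solves minimum set cover over the pathways
containing at least one observed KO: exactly by integer programming
(HiGHS) up to 25 candidate pathways, greedy
(largest-uncovered-first, ties by pathway id; classical
ln(max size) + 1 bound) above, with a flag to force either. The ILP
objective carries an id-ordered perturbation (summing to < 1) so ties
break lexicographically and results are deterministic. Pathways with
no observed KO are "removed" without being candidates. Pooled KO sets
are the default unit; per-sample application is available by calling
the function per sample column.

The enrichment p-value is the plain fraction of permutations with
count ≥ observed — the percentage-of-subsets definition — with the
(k+1)/(n+1) estimator available behind a flag. With 1,000 permutations
the only achievable p below a Sidak cutoff of ~3 × 10⁻⁴ is exactly 0;
the run report surfaces this granularity rather than hiding it. One
shared permutation stream scores all pathways per direction; the two
directions use seeds derived from the root seed. The exact
hypergeometric tail is computed alongside every permutation p as a
cross-check (they must agree within Monte-Carlo tolerance since the
permutation scheme *is* sampling without replacement). Mixed-direction
KOs are excluded from the directional subsets but kept in the universe
(the analysed set) by default; `universe_mode="directional"` restricts
the universe to up + down KOs instead.

## Problem sizes and determinism

Desk-scale defaults: 100 genera, 400 KOs, 60 pathways, 23k–91k reads
per sample. Simulation studies in the test suite use further reduced
cohorts (10 genera, flat age means unless an effect is injected) with
200 replicates for parameter recovery and null calibration. The full
default pipeline completes in a few minutes on one CPU. Every stage
output carries a header comment with the producing stage and the
config hash (paths excluded from the hash), and identical
(config, seed) runs produce byte-identical stage outputs.

## Known limitations

- Proportions of annotated reads are compositional: injecting a
  positive effect on one feature necessarily depresses the others, and
  a large significant fraction of features is expected when a dominant
  genus shifts. No log-ratio transform is applied, by design (the
  analysed quantity is the annotated-read proportion itself).
- The GEE models each feature univariately; cross-feature dependence
  enters only through the Sidak bound's conservativeness.
- Backward elimination is a selection procedure; retained-covariate
  lists should not be read as significance statements (see above).
- Raw JSD ordination is non-metric; axis variance shares are relative
  to the positive spectrum only.
- The rarefaction mixed model approximates the depth-nesting structure
  (documented in its report).
- Annotation-level effects (database coverage, LCA resolution, QC
  cutoffs) are upstream of this package and not modelled.
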