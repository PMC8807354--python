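# Methods

## Complementarity screen

The screen treats "complementarity" as duplex formation: a match of length
*L* between UCR *u* and hairpin *h* means `u[i..i+L-1] ==
revcomp(h[j..j+L-1])`.  An `identity` mode (plain substring equality) is
retained because seed-and-extend screens of this kind are sometimes run on
pre-complemented databases; the two modes are interconvertible and both are
exposed on the CLI.  Matching is exact: G:U wobble pairs are not counted
(the flag is reserved but unimplemented), and `N` matches nothing,
including itself.

The matcher scans each diagonal of the comparison matrix once, so every
reported segment is maximal (extendable in neither direction) and each
(i, j) pair appears once; two distinct maximal segments may overlap and are
both reported.  This is equivalent to seed-and-extend with exhaustive
seeds, and is checked in the tests against a brute-force oracle that
enumerates start pairs and extends them independently.  Reports are sorted
by descending length with lexicographic tie-breaks, making output
byte-deterministic.

Mature-arm exclusion is a post-filter on whole matches: any match sharing
at least one hairpin position with a mature interval is dropped; adjacency
is not overlap.  For exact matches this is order-independent versus masking
the sequence before the search, and easier to audit.  Cluster grouping
merges matches that share (UCR, cluster, matched subsequence); a hairpin
with a blank cluster id forms a singleton cluster named after itself.

Seed-site scanning uses the standard site taxonomy: the 6mer core is the
reverse complement of miRNA nucleotides 2–7, extended to 7mer-m8 (match at
position 8), 7mer-A1 (A opposite position 1) or 8mer (both).  Scanning the
6mer core rather than the 7mer is what makes the 6mer and 7mer-A1 classes
reachable at all; constructions with a full nt 2–8 complement plus t1-A are
classified 8mer, as expected.

## Editing quantification

Clones enter as base-called FASTA sequences (chromatogram parsing is
upstream of this pipeline).  Anchoring is ungapped at the
minimum-Hamming-distance offset because the amplicons are short and
primer-defined; a clone whose best placement exceeds 10 % mismatches is
rejected and logged — this also removes indel-bearing clones, a
conservative choice consistent with clone counting.  The editing frequency
denominator is the number of accepted clones covering the position, which
equals the total clone count when clones are full-length (the protocol's
setting, 75–100 clones per cDNA).

The stem-loop coordinate of reference position *p* is
`p − stemloop_start + 1`, so the stem-loop 5′ end is +1; non-positive
values flag upstream positions.  Site calling lists adenosines with at
least `min_count` (default 1) A→G clones; statistical claims are made only
through the two-condition contrast.

The Fisher exact p is two-sided by the sum-of-smaller-or-equal-probability
convention over the fixed-margin hypergeometric family (the convention of
`scipy.stats.fisher_exact`, verified in the tests against a full
enumeration oracle on every small-margin table).  The chi-squared statistic
is Pearson's without continuity correction; a table with an all-zero
edited (or unedited) column is reported as statistic 0, p 1 rather than an
error, since the exact test already covers that case.

## Comparative Ct

Technical replicates are averaged on the Ct scale before any delta is
formed (a decision, not an inference from the source protocol; averaging
after ΔCt differs only through replicate pairing, which the data model does
not track).  Multi-reference normalization subtracts the arithmetic mean of
the reference Cts, i.e. divides by the geometric mean of reference
expressions.  Amplification efficiency is fixed at 2; no efficiency
correction or outlier rejection is attempted.  Fold changes are invariant
to adding a constant to every Ct, and fraction percentages always sum
to 100 — both asserted as properties.

## Survival analysis

Dichotomization is strict: hypermethylated iff β > 0.33, asserted at the
boundary.  Percentages are rounded half-up to one decimal (409/503 →
81.3).  Kaplan–Meier estimation and the log-rank test are delegated to
lifelines behind this module's interface; the toy-data tests re-derive the
product-limit and O−E/V arithmetic by hand.

The Cox fit is implemented in-package because the required combination —
Breslow tie handling with Wald standard errors — is not available in the
installed survival libraries (lifelines fits Efron only; scikit-survival
exposes no inference).  Newton–Raphson starts at β = 0 with step-halving;
convergence when max|score| < 1e-9 or the relative log-likelihood change
< 1e-12, at most 50 iterations.  Efron tie handling is available via
`ties="efron"` and is cross-checked against lifelines; on tie-free data the
two conventions coincide and both are compared against a dense grid search
of the partial likelihood.  A coefficient diverging past |β| > 20 is
reported as monotone likelihood (complete separation); a singular
information matrix raises with diagnostics.  CIs are `exp(β ± 1.96·SE)`
(95 % Wald).

Multivariate covariate coding: methylation hyper = 1, IDH1 MUT = 1, age in
years (continuous), sex M = 1.  The source analysis does not state its
codings; these are documented so signs are interpretable either way.
Survival times are used in days as supplied.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised.

*Sequences.*  One 322-nt UCR (the length of the ultraconserved region used
in the in-vitro assays) against 85-nt hairpins with miRBase-style 5p/3p
mature intervals.  The default plant list mirrors the published screen
outcome: a 13-nt top hit, a 12-nt site shared by all four hairpins of a
four-member cluster placed at the stem base just outside the 3p arm, two
further 12-nt singletons, and a 10-nt sub-threshold plant.  Planted
segments are made maximal by construction (flanking bases are forced away
from the complementary base), and rejection sampling regenerates the random
background until the screen recovers exactly the qualifying plants; the
attempt cap errors out rather than biasing silently.  `mutate_plant`
substitutes k planted nucleotides (the mut12/mut5-style substrates);
`compensate_hairpin` rewrites the hairpin segment to pair the mutated UCR.

*Clones.*  Clone counts default to the protocol's 75–100 range; each clone
is edited independently at each site with its probability, then uniform
per-base error (default 0.001, a Sanger-scale figure) is applied.  The
truth table stores per-clone edits, so tabulation can be tested as an
exact recount.

*Cohorts.*  Group sizes and prevalences default to the study cohort: 503
LGG / 134 GBM with hypermethylation prevalence 0.813 / 0.216; in
deterministic mode the hypermethylated count is exactly round(prev·n)
half-up (409 and 29), so printed percentages are matched exactly.
β-values come from a two-component scaled-Beta mixture strictly separated
at 0.33.  Survival is exponential with hazard
`baseline · hr_meth^hyper · hr_idh1^mut`; the default planted methylation
HR is 0.135 (the published LGG univariate value).  Values the source
analysis does not state were chosen once as field-realistic for TCGA
gliomas and not revisited: IDH1 mutation fractions 0.80 (LGG) / 0.10
(GBM), baseline hazards ln2/1500 d⁻¹ (LGG) and ln2/400 d⁻¹ (GBM), target
censoring fractions 0.60 / 0.20, age ~ N(43, 12²) / N(60, 12²) clipped to
[18, 90], male fraction 0.55.  Censoring is independent uniform on
[0, T_max] with T_max solved by bisection from
E[(1 − e^{−hT})/(hT)] = target fraction.

What the generators do **not** emulate: linkage between methylation and
IDH1 status (they are independent by default, so marginal and conditional
hazard ratios coincide when only one effect is planted — real cohorts
confound them), non-exponential baseline hazards, methylation-array probe
noise, within-run clone dependence, and genomic sequence composition.
Passing tests therefore demonstrate correctness of the estimators under
their stated models, not robustness to those real-data features.

## Recomputation script

`scripts/acceptance.py` reruns every stage from scratch.  Hazard-ratio
recoveries are averaged over 200 cohort replicates on the log scale
(geometric mean of per-replicate estimates), since the Cox coefficient is
the natural parameter and an arithmetic mean of ratios is upward-biased by
Jensen's inequality.  The univariate recomputation plants methylation as
the only hazard modifier: with an additional independent planted covariate
the marginal (univariate) hazard ratio is attenuated toward 1 relative to
the conditional one — a well-known property of proportional-hazards
models — so isolating the effect is what makes the planted value the
correct target.  The multivariate recomputation plants HR 0.486 for
methylation alongside an IDH1 effect and fits the full four-covariate
model.  Problem sizes (200 replicates of n = 503/134 cohorts, 50 clone-set
replicates of 100 clones) keep the full run in the tens of seconds while
holding Monte-Carlo error on each reported value well below the effect
sizes of interest.

## Known limitations

- The screen is exact-match only: no mismatches, gaps, wobbles or
  thermodynamic scoring; it ranks by length, not binding energy.
- Editing anchoring is ungapped; clones with true indels are excluded
  rather than realigned.
- The Cox implementation handles ties by Breslow/Efron only (no exact
  method) and fits fixed effects only.
- The overall hypermethylation percentage implied by the integer cohort
  margins (438/637 = 68.76 %) differs in the second decimal from the
  published 68.75 % figure, which is not attainable with any integer count
  over 637 cases; the per-group counts and percentages are matched exactly.
- Reproduction of the published survival effect sizes on the real TCGA
  cohort requires external clinical data (see
  `analysis/06_tcga_validation.py`); in-repo validation is via planted
  synthetic cohorts.
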