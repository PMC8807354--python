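# tucrmir

Analysis pipeline for an RNA–RNA regulatory axis in glioma: a transcribed
ultraconserved region (T-UCR, `uc.160+`) that base-pairs with the
pri-miRNAs of the *miR-376* cluster, enhances their processing and A-to-I
editing, and whose promoter CpG-island hypermethylation stratifies glioma
survival.  The package is aimed at computational biologists who want each
stage of that analysis as tested, reusable code: exact-complementarity
screening between sequence databases, clone-based editing quantification,
comparative-Ct expression arithmetic, and methylation-stratified survival
modeling — plus synthetic-data generators so the whole pipeline runs and is
testable without any external downloads.

## What it computes

**Complementarity screen** (`tucrmir.seqmatch`).  For a T-UCR sequence *u*
and hairpin *h*, the screen reports every maximal segment pair
(*i*, *j*, *L*) with *L* ≥ `min_len` (default 11) such that

    u[i .. i+L-1] = revcomp(h[j .. j+L-1]),

i.e. the two subsequences can form a perfect Watson–Crick duplex; G:U
wobbles and `N` never count.  Matches overlapping annotated mature-arm
intervals are excluded (the biogenesis-relevant signal lies in the lower
stem and flanks), and identical matches shared by hairpins of one miRNA
cluster are grouped.  A seed-site scanner classifies canonical 8mer /
7mer-m8 / 7mer-A1 / 6mer target sites for unedited and edited mature
miRNAs (seed = nucleotides 2–8 from the miRNA 5′ end).

**Editing quantification** (`tucrmir.editing`).  Sequenced cDNA clones are
anchored ungapped on the pri-miRNA reference (≤ 10 % mismatches, else
rejected); the editing frequency at an adenosine is

    f = (# clones with A→G) / (# usable clones covering the position),

reported in stem-loop coordinates where the 5′ end of the annotated
stem-loop is +1.  Condition contrasts use the two-sided Fisher exact test
and Pearson's chi-squared on the 2×2 edited/unedited table.

**Comparative Ct** (`tucrmir.qpcr`).  Fold change = 2^−ΔΔCt with ΔCt taken
against the mean of the endogenous-control Cts; nuclear/cytoplasmic splits
use 2^−Ct abundances normalized to 100 %.

**Clinical survival** (`tucrmir.survival`).  A case is hypermethylated
when its island β-value > 0.33 (strict).  Prevalence, LGG-vs-GBM Fisher
enrichment, Kaplan–Meier curves with log-rank tests (via lifelines), and a
Cox proportional-hazards fit written in-package: Newton–Raphson on the
partial likelihood with Breslow tie handling (Efron behind a flag), Wald
95 % CIs `exp(β ± 1.96·SE)`, monotone-likelihood detection.

**Synthetic data** (`tucrmir.simulate`).  Sequence databases with planted
reverse-complement segments (guarded against accidental matches), clone
sets with per-site Bernoulli editing plus sequencing error, and glioma-like
cohorts (503 LGG / 134 GBM, prevalence 0.813 / 0.216, exponential survival
with planted hazard ratios, uniform censoring calibrated to a target
fraction).  Every generator emits a truth table and is byte-deterministic
under a fixed seed.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_complementarity_screen.py
python analysis/05_clinical_survival.py
```

prints (abridged):

```
top hit: 13 nt with hp-1289 (clu-1289)
shared cluster site: 12 nt across 4 hairpins
mut12: 0 matches >= 11 nt remain; mut5+compensation restores [12]
...
ALL: 438/637 hypermethylated (68.8%)
LGG: 409/503 hypermethylated (81.3%)
GBM: 29/134 hypermethylated (21.6%)
LGG-vs-GBM enrichment Fisher p = 7.83e-38
LGG univariate HR = 0.129 (95% CI 0.096-0.175)
```

The screen's top hit is the planted 13-nt segment; the 12-nt site is
recovered on all four hairpins of the planted cluster and is destroyed by
mutating its 12 complementary nucleotides (mut12) but restored when 5
mutations are matched by compensatory hairpin substitutions.  On the
cohort, the strict β > 0.33 rule yields 409/503 hypermethylated LGG cases
(81.3 %) and 29/134 GBM cases (21.6 %), a strongly LGG-enriched pattern,
and hypermethylation is protective in LGG (hazard ratio well below 1, CI
excluding 1).  `analysis/03_…` and `04_…` run the editing contrast and the
comparative-Ct quantification; `analysis/06_tcga_validation.py` re-runs
the survival pipeline on a user-supplied real TCGA clinical table.

The same stages are scriptable through a single CLI
(`tucrmir match|editing|quant|clinical|simulate`, see `tucrmir --help`);
every report carries a commented run manifest (command, config hash, input
checksums, seed, version).

## Layout

- `src/tucrmir/` — library: `io`, `seqmatch`, `editing`, `qpcr`,
  `survival`, `simulate`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
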