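# siderosig

Statistical pipeline for low-risk myelodysplastic-syndrome (MDS) cohort
studies centred on ring sideroblasts: permutation differential expression,
consensus gene-signature selection across random subsamples, gene-list
overlap and enrichment statistics, and a targeted-capture variant triage
cascade with codon-level annotation and two-SNP haplotype association.

## The problem

Refractory anemia with ring sideroblasts (RARS) is a low-risk MDS subtype
marked by mitochondrial iron (ferritin) accumulation in erythroid
precursors and recurrent *SF3B1* spliceosome mutations.  Studies of this
disease typically combine (i) bone-marrow expression profiling of RARS
vs other low-risk MDS (RCUD) vs healthy controls, (ii) signature
selection between spliceosome-mutated and unmutated patients, (iii)
validation of gene lists against independent cohorts, and (iv) targeted
capture sequencing of iron/mitochondrial genes to triage candidate
variants.  `siderosig` packages that statistical machinery as reusable,
tested code, together with a synthetic cohort generator so every stage
can be validated against known ground truth without patient data.

## What it computes

**SAM-style permutation differential expression.**  Per gene,
`d = r / (s + s0)`: the two-class form uses `r = x̄₂ − x̄₁` over a Welch
(unequal-variance) standard error; the multiclass form is an F-like
between/within ratio.  The fudge factor `s0` is chosen by the classic
percentile search minimising the coefficient of variation of the median
absolute `d` across scale bins.  The null is built by relabelling samples
(100 cycles by default), p-values pool the permuted `|d|` across genes,
and q-values are the median permuted false-positive count at each gene's
`|d|` divided by its rank, made monotone.  Fold changes are reported on
the linear scale as `R fold = 2^(x̄_case − x̄_ref)`.

**Moderated t.**  An empirical-Bayes t with shrunken variance
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` on `d₀ + d_g` degrees of freedom;
`(d₀, s₀²)` are fitted by closed-form moment matching on `log s²`.
Benjamini–Hochberg q-values.

**Consensus signatures.**  Repeated balanced subsampling (`k` vs `k`
samples per contrast, moderated t inside, q-cutoff per contrast), with
per-gene significance-frequency counting and top-N extraction.  Presets
`mut200` (7 v 7 × 10000, q<0.01, top 200) and `rs75` (4 v 4 × 7425,
FDR<0.10, top 75, ≥10 contrasts).  A permutation global-association test
(`Q = Σ_g (Σ_s x̃_gs ỹ_s)²`) checks that the signature predicts the
classes.

**Overlap and enrichment.**  2×2 overlap tables over an explicit gene
universe; odds ratios with Woolf CIs and the Haldane–Anscombe zero-cell
correction; exact Fisher tests (integer arithmetic up to total 2000,
log-space beyond); the classical 2×2 chi-square; and hypergeometric
over-representation against GMT gene-set collections, with optional
EASE-style conservative p-values.

**Variant triage.**  Known-SNP removal (by position+allele key or ID),
coding/non-coding classification against CDS transcript models,
strand-aware codon-level amino-acid-change annotation (synonymous /
missense / nonsense / start-loss), stage-by-stage cascade accounting,
plus two-SNP haplotype classification (variant allele at both linked
sites = variant haplotype) and case/control carrier-frequency
comparison.

## Worked example

Simulate the default study design (30 RARS vs 31 controls, 2000 genes,
100 genes planted 2 log2 units up in RARS, residual SD 0.7) and run the
SAM screen:

```python
from siderosig import (CohortDesign, SamConfig,
                       generate_expression_cohort, sam_analyze)

design = CohortDesign(group_sizes={"RARS": 30, "CTRL": 31}, n_genes=2000,
                      n_planted=100, effect_log2=2.0, noise_sd=0.7,
                      seed=1, planted_group="RARS")
cohort, truth = generate_expression_cohort(design)
res = sam_analyze(cohort, SamConfig(n_permutations=100, fdr_cutoff=0.05,
                                    contrast=("CTRL", "RARS"), seed=1))
```

This prints (via the snippet in `scripts/acceptance.py`-style reporting):

```
genes called at FDR<0.05: 106
planted genes recovered: 100 / 100
  gene  statistic  rfold     p  q
G00640       6.18  5.429 5e-06  0
G00319      6.179  5.844 5e-06  0
G01375      5.803  5.634 5e-06  0
```

All 100 planted genes are recovered at FDR<0.05 (the 6 extra calls are
within the permutation FDR's tolerance); `rfold ≈ 4–6` reflects the
planted 2-log2 shift plus sampling noise.  The same cohort can be pushed
through the consensus selector, the global test, enrichment and the
variant cascade — see the CLI:

```bash
siderosig simulate --seed 1 --outdir sim
siderosig de-sam --expr sim/expression.tsv --pheno sim/phenotype.tsv \
    --contrast CTRL,RARS --out de.tsv
siderosig signature --expr sim/expression.tsv --pheno sim/phenotype.tsv \
    --by mutation --preset mut200 --outdir sig
siderosig overlap --list-a up_a.txt --list-b up_b.txt --universe all.txt
```

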