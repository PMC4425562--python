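# Methods

This note documents the statistical procedures implemented in
`siderosig`, the parameter choices that matter, what the synthetic
generator does and does not emulate, and the design decisions taken
where the conventions of the field leave room.

## SAM-style permutation differential expression

For gene *g* the two-class statistic is

    d_g = (x̄₂ − x̄₁) / (se_g + s0),   se_g = sqrt(s₁²/n₁ + s₂²/n₂)

with per-group sample variances (Welch, unequal variances — we never
pool across groups in the two-class denominator).  The multiclass
statistic generalises the numerator to
`r = sqrt((Σ_k 1/n_k) · Σ_k n_k (x̄_k − x̄)²)` — which reduces exactly to
`|x̄₂ − x̄₁|` for two groups — over the matching pooled within-group scale
`s = sqrt((Σ_k 1/n_k)/(N − K) · WSS)`, giving a non-negative F-like
ratio with the fudge in the denominator.

**Fudge factor.**  Candidates are the 0th, 5th, …, 100th percentiles of
the per-gene scale `s`.  For each candidate, genes are split into
`min(100, G/10)` quantile bins of `s`; the bin-wise spread of `d` is the
median absolute deviation scaled by 1/0.64, and the candidate minimising
the coefficient of variation of these spreads wins.  Ties break toward
the smallest percentile, which makes the constant-`s` case deterministic.
If every `s` is zero the search is undefined; a nominal positive fudge is
returned with a warning (only the overall scale of `d` is affected).

**Permutation null.**  The sample labels are permuted `n_permutations`
times (default 100) with the `s0` fixed from the observed data.  When
the requested count meets or exceeds the number of distinct relabelings,
all of them are enumerated instead (with a warning), which makes small
fixtures exactly reproducible against brute-force enumeration.  Per-gene
p-values pool permuted `|d|` across genes:
`p_g = max(#{|d_perm| ≥ |d_g|}, 1) / (B·G)` — the floor keeps p strictly
positive; counting is inclusive at ties.  q-values follow the
median-false-positive convention: for each permutation the number of
permuted `|d|` at or above `|d_g|` is counted, the median across
permutations is divided by the observed rank of `|d_g|`, and the result
is made monotone (a larger `|d|` never receives a larger q) and capped at
1.  No π₀ estimate is applied (π̂₀ = 1, conservative).  Calls are made at
q below the configured FDR (default 0.05).

## Moderated t

For a two-group contrast with pooled residual variance `s²_g` on
`d_g = n₁+n₂−2` degrees of freedom, the hierarchical model
`s²_g ~ s₀²·F(d_g, d₀)` implies known digamma/trigamma offsets for the
mean and variance of `log s²_g`.  Matching the empirical moments gives
closed-form estimates: solve `ψ′(d₀/2) = Var(e) − mean(ψ′(d_g/2))` with
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` (Newton iteration on the
trigamma inverse), then `s₀² = exp(ē + ψ(d₀/2) − log(d₀/2))`.  When the
empirical spread does not exceed the sampling noise the fit returns
`d₀ = ∞` and the shrunken variances collapse to `s₀²` (normal reference
distribution).  The moderated statistic is
`t̃ = (x̄₂−x̄₁)/sqrt(s̃²(1/n₁+1/n₂))` on `d₀+d_g` df with
`s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g)`; a forced `d₀ = 0` recovers the
ordinary pooled t exactly, which the tests use as a limit oracle.
Multiple testing is Benjamini–Hochberg (delegated to statsmodels).

## Consensus-signature selection

Each contrast draws `k` samples per class without replacement, runs the
moderated t on the 2k-column subset and flags genes with BH q below the
cutoff; flags are accumulated over `n_contrasts` iterations.  Distinct
contrasts may repeat subsets — at 10000 contrasts of 7-of-13 draws the
subset space is necessarily revisited — and no duplicate detection is
attempted.  The procedure is iterated subsampling implemented
iteratively.  The top-N list is ordered by selection frequency, with
ties broken by mean `|t̃|` across contrasts and then lexicographic gene
ID, so results are fully deterministic given the seed.  The optional
minimum-contrast filter (preset `rs75` sets 10) drops genes below the
threshold before ranking; the `mut200` preset applies none.  If fewer
genes than N were ever significant and no filter is set, the shorter
list is returned with a warning.

The global-association check row-standardises the signature submatrix
(zero-variance rows become zero, so an all-constant matrix yields Q = 0
and p = 1), centres the binary labels and computes
`Q = Σ_g (Σ_s x̃_gs ỹ_s)²`; the p-value is the add-one permutation tail
over label permutations (default 9999).  Only the permutation p-value is
offered; no asymptotic approximation.

## Overlap, odds ratios, enrichment

Overlap tables live over an explicit universe; the default background
for enrichment is the measured gene universe (the expression matrix),
not the genome, because contingency enrichment is background-sensitive.
The odds ratio applies the Haldane–Anscombe +0.5 to all cells only when
some cell is zero, and its CI is the Woolf log-scale interval.  Fisher
p-values use exact integer hypergeometric weights for totals up to 2000
(so the enumeration-oracle tests compare at 1e-12) and log-space weights
with a 1e-7 relative tie tolerance beyond; the chi-square is the
classical `n(ad−bc)²/∏margins` form, with Yates available but off by
default.  For the haplotype carrier comparison both the uncorrected
chi-square and the one-sided Fisher are reported, since borderline
contingency p-values depend on that choice (on counts 12/100 vs 5/100
they are 0.076 and 0.063 respectively).  EASE-mode enrichment decrements
the overlap by one (floored at zero) before taking the upper tail.

## Variant triage and haplotypes

Coordinates are 1-based inclusive; only single-nucleotide substitutions
are accepted (every variant the pipeline targets is one), and indels
raise immediately.  Known-SNP matching succeeds on either the
(chrom, pos, alt) key or the ID, because catalog builds drift.  The
cascade is strictly three-way: known SNP → non-coding → synonymous;
splice-region or UTR subcategories are not modelled.  Annotation maps
the genomic position to the spliced CDS offset; on minus-strand models
the offset counts from the rightmost CDS base and both alleles are
complemented before codon mutation and translation (standard nuclear
code, via Biopython).  Consequences: synonymous (amino acid unchanged),
nonsense (new stop), start-loss (codon 1 M lost), missense (the rest —
including stop-loss, which the three-way cascade has no separate bin
for).  Haplotype classification requires the variant allele at both
linked sites; discordant samples are "other" and count as non-carriers
in the case/control table, and heterozygous carriers count as carriers.

## Synthetic cohorts

The generator emulates the study designs the pipeline targets, not the
biology.  Expression: per-gene baseline means Normal(7, 1.5) on the log2
scale (the rough range of an RMA-normalised array), i.i.d. Normal
residuals with SD 0.7 by default, and planted genes shifted up by a
fixed log2 effect (default 2.0) in one group.  Optionally the per-gene
variances are drawn from a scaled inverse-chi-square (d₀ = 4,
s₀² = 0.25) so the moderated-t hierarchy holds exactly and its
hyperparameters are recoverable.  Default group sizes are 30/39/31
(RARS/RCUD/controls) with mutation splits of 22 vs 13 and 13 vs 6.
Variants: one forward-strand transcript model per pseudo-chromosome
(60–200 codons, 1–3 exons; reverse strand is exercised by dedicated unit
fixtures), Poisson(1367) variants per sample over 6 samples, 56% known
SNPs, 15% coding (85% of novel variants non-coding) and 6.3%
amino-acid-changing overall (≈42% of coding), matching the discard
proportions a capture screen of this type reports.  Haplotype cohorts
default to 100 cases at 12% carrier frequency vs 100 controls at 5%.

What this does **not** capture: probe-level artifacts, batch effects,
correlated genes, library/coverage structure in the variant calls, or
linkage beyond the two modelled sites.  Passing tests therefore
demonstrate the statistics are implemented correctly and calibrated
under their own model assumptions — not that the pipeline's operating
characteristics transfer unchanged to real cohorts.

## Numerical choices and problem sizes

Seeds are explicit arguments everywhere; there is no hidden global
random state, and every seeded stage reruns byte-identically.
Permutation counting is inclusive at ties.  The test suite and the
acceptance script run the selector at 1000 contrasts (rather than the
full 10000-contrast preset) and calibration checks at 2000 genes over
10–20 replicate cohorts — sizes chosen so the whole validation completes
in well under a minute while leaving the binomial/KS margins wide; the
full presets are available unchanged through the API and CLI.

## Known limitations

- The SAM q-value is the median-false-positive form with π̂₀ = 1, not the
  original Δ-table sweep; only calls at a fixed FDR are contractually
  comparable.
- The multiclass SAM denominator pools within-group variances (the
  unequal-variance convention applies to the two-class form only).
- The moderated-t fit assumes equal residual df across genes (true for
  complete matrices, which is all the readers produce).
- Enrichment knows nothing about category databases; collections are
  supplied as GMT.
- VCF support is the GT-only substitution subset the pipeline needs, not
  the full specification.
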