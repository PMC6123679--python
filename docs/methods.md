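# Methods

This note documents the models, estimators and design choices behind each
pipeline stage, what the synthetic-data generators emulate (and what they do
not), and the numerical conventions that matter when reproducing results.

## Synthetic data: the study conditions

All validation rests on simulated inputs with known ground truth, generated
by `sbevol.simulate` from a single `SimConfig`.  Defaults mirror a
two-sex gonad RNA-seq design at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes in the expression study |
| `n_samples_per_group` | 4 | biological replicates per sex (4 vs 4) |
| `library_size` | 5e6 | expected reads per sample |
| `dispersion` | 0.1 | NB dispersion φ; var = μ + φμ² (φ=0 ⇒ Poisson) |
| `frac_female_biased`, `frac_male_biased` | 0.1, 0.1 | true biased fractions |
| `effect_log2fc` | 3 | true |log2FC| of biased genes |
| `n_tissues` | 9 | tissue-panel contexts |
| `n_chromosomes` | 24 | chromosomes for gene placement |
| `branch_lengths` | (0.05, 0.05, 0.1) | expected substitutions/codon on the focal, sister and outgroup branches |
| `kappa` | 2.0 | transition/transversion rate ratio of the codon model |
| `n_codons` | 300 | codons per simulated gene |
| `mk_*` | see below | MK count model |
| `n_species`, `conservation_prob` | 6, 0.8 | conservation simulation |

Counts are gamma-Poisson (negative binomial) with a log-normal baseline
abundance profile (σ = 1.5 on the natural-log scale).  The sex effect is
split symmetrically — half up in one sex, half down in the other on the
log2 scale — so library composition stays balanced and TMM tests are not
confounded.  Labels are assigned deterministically, so configured class
proportions hold exactly.

The tissue panel draws genes from three archetypes (single-tissue, uniform,
graded in log2 steps), rotated across tissues.  Because cpm is a
compositional measure, the generator computes each gene's *expected
realized* floored log2-cpm profile analytically (designed value divided by
the per-tissue designed total) and records the closed-form τ of that
profile as ground truth.  Tissues designed silent yield τ = 1 for the
single-tissue archetype exactly; the uniform archetype's true τ deviates
from 0 only through per-tissue composition differences (< 0.03 at the
defaults).

The codon simulator is a Goldman–Yang-style continuous-time chain over the
61 sense codons: single-base neighbor rates κ^(transition) · ω^(non-synonymous),
stop targets rejected, uniform codon frequencies, simulated by the embedded
jump chain so every substitution event is recorded.  Branch lengths are
normalized so that one time unit is one expected substitution per codon
under the gene's own ω.  The ancestral sequence sits at the focal/sister
split; the outgroup branch spans root to outgroup.  There are no indels,
no rate variation among sites, and no alignment error — which is exactly
why masking (below) can only remove genuine signal in simulation.

MK count tables are Poisson: Pn ~ Pois(Lₙθ_P), Ps ~ Pois(Lₛθ_P),
Dn ~ Pois(Lₙθ_D), Ds ~ Pois(Lₛθ_D) with Lₙ = 250, Lₛ = 100 sites,
θ_P = 0.05 and θ_D = 0.1 per site.  Equal per-site rates make E[DoS] = 0
exactly (binomial conditioning).  The deleterious regime doubles only the
Pn rate; the positive regime only the Dn rate.

What the generators do **not** emulate: read-level noise and mapping error,
isoform structure, GC or length biases, linked selection, demography, and
correlated expression between genes.  Passing tests therefore demonstrate
the correctness and calibration of the estimators under the stated model,
not robustness to every artifact of real data.

## Differential expression and gene classes

The test is an exact conditional binomial test on group-summed counts: for
each gene with total t across both groups, the group-1 total is
Binomial(t, π) under the null, with π the group-1 share of the summed
effective library sizes (library size × TMM factor).  The two-sided p
doubles the smaller tail, capped at 1.  This replaces an NB exact test with
moderated dispersion; the design is validated by error control rather than
by equality with any particular implementation: under the null study
conditions (φ = 0.1, 4 vs 4) the |log2FC| > 1 gate keeps the sex-biased
false-call fraction well under 2%, and power at true |log2FC| = 3 is ~100%.
log2FC uses group means of counts rescaled to a common effective library
size with a prior count of 0.5 (no infinities on zeros); positive log2FC
means female-biased.

TMM follows the reference formulation: M- and A-values against a reference
sample (auto-selected by upper-quartile closeness), 30%/5% two-sided rank
trimming, inverse-asymptotic-variance weighting, geometric-mean rescaling.
The implementation agrees with edgeR's `calcNormFactors` to ~1e-8 on a
fixed fixture.  The cpm filter retains a gene iff cpm >= 0.5 in at least
⌈n/2⌉ samples ("below threshold in more than half" excludes; exactly half
retains).  FDR is Benjamini–Hochberg.  Thresholds: strict > 1 for the bias
gate, inclusive >= 3 for strong bias.

## Expression indices

τ is computed on per-tissue means of TMM-normalized log2 cpm with negative
values floored at 0 (log2 cpm of rare genes is negative; τ assumes
non-negative components).  CVE uses the sample (n−1) standard deviation of
normalized cpm.  π defaults to the mean |log2FC| over the three
control-vs-stress contrasts; a `de_count` variant (number of significant
contrasts) is available behind a switch.  Extreme-π sets use type-7
(linear-interpolation) quantiles at 10%/90% with ties kept inclusively.

## Lineage-specific dN/dS

The estimator is a counting scheme chosen to be fully oracle-verifiable:

1. **Clean**: every codon column containing a gap or N anywhere is removed
   whole; alignments under 100 bp are flagged and later excluded.
2. **Mask**: each non-focal sequence is scanned against the focal in
   5-codon windows; >= 4 codons with a non-synonymous difference mask the
   window (set to N) in that sequence.  Windows are judged on the unmasked
   input and masks applied afterwards.  Sequences with < 75 bp unmasked are
   flagged.  In simulation (no misalignment) masking removes genuine
   divergent windows; the effect on pooled ω is ~2% at the default branch
   lengths and grows with divergence (~30% by 0.4 substitutions/codon of
   focal+sister separation) — a property of the masking parameters, not of
   the estimator.
3. **Assign**: per variable codon column, focal ≠ sister with
   sister = outgroup is a focal-branch change; focal = sister ≠ outgroup is
   outgroup-side (ignored); every other pattern (all distinct, or
   focal = outgroup ≠ sister) is ambiguous, skipped and counted.  Skipping
   is direction-neutral, so ω is unaffected while dN and dS are mildly
   conservative.  Multi-step codon changes are averaged over minimal
   stop-free mutational pathways with equal weights.
4. **Sites**: mutational-opportunity counting per focal codon position,
   transitions weighted by κ (default 2.0, matching a transition-biased
   mutation process; κ = 1 reduces to the classic equal-rate count).  With
   κ-blind sites on transition-biased data, ω is systematically
   underestimated because transitions are enriched for synonymous changes —
   the κ-aware count removes that bias.  Stops are excluded per position
   and fractions renormalized, so N + S equals 3 × codons exactly.
5. **Correct**: dX = −(3/4)·ln(1 − 4pX/3) per class (Jukes–Cantor);
   non-positive correction arguments set a saturation flag.
6. **Filter**: exclude dS > 2, N·dN < 1, S·dS < 1, short or
   saturation-flagged genes.

**Class-level ω.** Per-gene ω is a ratio of small counts (a 300-codon gene
at 0.05 substitutions/codon carries ~5 synonymous events); the arithmetic
mean of such ratios is biased upward by E[1/sd] inflation (~+25% at these
sizes) regardless of estimator quality.  The class mean is therefore
estimated by pooling counts across genes — (Σnd/ΣN)/(Σsd/ΣS) — which
recovers ω = 1 within a few percent across all divergences tried, and the
per-gene median is reported alongside (medians are also the per-class
summary used for group comparisons).

## Selection statistics

DoS and NI_TG are computed exactly as defined above; genes with
Ps + Ds = 0 are skipped in NI_TG and missing values propagate.  When
divergence counts come from the rate stage, pathway-averaged (fractional)
nd/sd are rounded half-to-even to integers.  Polymorphism tabulation
classifies ref/alt codon pairs by the genetic code and drops stop
gain/loss variants.  Group NI_TG ships with a seeded nonparametric
bootstrap CI (1000 gene resamples).

## Clustering tests

The Markov odds score conditions on the first label: the ML first-order
chain's transition likelihood is compared with a Bernoulli(p = k/n)
likelihood over positions 2..n.  Because the null is one particular
transition matrix (equal rows), the ML chain's likelihood can never be
lower, so the score is >= 0 and equals 0 exactly when transition
frequencies match the marginal.  Significance comes from within-chromosome
label permutation with the add-one estimator (1 + #{>= observed})/(B + 1);
ties count toward the permutation tail, keeping the test conservative.
Measured type-I error at α = 0.05 is ~0.04–0.05 and power against blocks of
10 among 500 genes is ~1.  The adjacency Fisher test cross-tabulates
consecutive label pairs (contiguity); the enrichment Fisher test
cross-tabulates membership × chromosome (abundance).  Both are reported
because "clustering" admits either reading; adjacency is the default.

## Group comparisons

Wilcoxon rank-sum is exact (full enumeration, via the standard
distribution) when the combined sample is <= 20 without ties, otherwise the
normal approximation with tie and continuity corrections; the two agree to
< 0.01 at 10 + 10.  Bonferroni multiplies by the family size — all pairs
tested for a metric in one run.  Missing values are dropped pairwise with
per-group n reported.  The χ² helper is Pearson's with 1 df and no
continuity correction by default; Fisher's odds ratio uses the Haldane
half-count correction only when a zero cell is present (and only for the
reported ratio, never for p).

## End-to-end validation scenario

The female-selection study (`workflow.female_selection_config`) sets
|log2FC| = 4 so biased genes are unambiguously strong, and
ω = 0.6 for female-biased vs 0.2 elsewhere, over 600 genes.  The expected
outcome — and the one observed — is a Bonferroni-significant Fem-FC3 vs UB
ω contrast with no *elevation* of Male-FC3 (a significant contrast with a
lower male median is not an elevation; the check is directional).  Because
the male contrast is a true null tested at a fixed level, a few percent of
random seeds will show a spurious male elevation; this is inherent to the
criterion, not to the pipeline.

## Problem sizes and runtime

Validation sizes were chosen so each property is measured with comfortable
Monte-Carlo margins while the whole suite stays interactive: 20 × 2000
genes for null FDR control, 300 genes × 300 codons per ω value for
recovery, 5000 genes (and 20 seeds) for neutral MK calibration, 200
replicates for the deleterious regime, 1000 null and 200 blocked
simulations (400 permutations each) for clustering calibration, and a
600-gene end-to-end study.  `scripts/acceptance.py` completes in roughly
15 s on one CPU; the pytest suite in ~40 s.

## Known limitations

- The DE test has no dispersion moderation; it is calibrated for the
  two-group balanced designs it targets, relying on the fold-change gate
  for biological-significance filtering.
- The ω estimator is a parsimony/counting method: it assumes low divergence
  (multiple hits handled only through pathway averaging and Jukes–Cantor),
  a known κ, uniform codon frequencies, and no selection on codon usage.
- NI_TG and DoS assume silent-site neutrality and unique-site SNP counts
  (no frequency weighting).
- The Markov odds score is first-order and per-chromosome; long-range or
  higher-order spatial structure is outside its alternative.
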