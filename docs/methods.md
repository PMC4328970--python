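# Methods

This note records the statistical models behind `coexdiv`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Exact two-library tag test

For one gene with `x` tags in a library of `N1` total tags and `y` tags in
a library of `N2`, the null probability of `y` given `x` is

    p(y | x) = ((x+y)! / (x! y!)) · (N2/N1)^y / (1 + N2/N1)^(x+y+1),

which is the negative-binomial pmf NB(y; x+1, N1/(N1+N2)) — the posterior
predictive of a Poisson rate under a flat prior, the standard exact
statistic for comparing two DGE tag libraries. The two-sided p-value is
the minimum-likelihood tail: the sum of all density terms no larger than
the observed one. Because the density is unimodal, the retained terms are
the complement of a contiguous interval around the mode, whose edges are
found by bisection on the log-pmf; the implementation is O(log support)
per gene and fully vectorized across genes.

The tail is inherently asymmetric in which library it conditions on. The
package evaluates it conditioning on each library in turn and averages
the two tails, which makes the p-value symmetric under swapping
(x, N1) ↔ (y, N2) by construction. Under an equal-rate null the test is
slightly conservative (empirical rejection ≈ 0.8% at the 0.9% threshold),
as expected for a discrete exact test.

DEG calling combines three gates per stage pair: |log₂ ratio| > 0.5 on
TPM with a 1-TPM pseudocount (the pseudocount handles zeros), p < 0.009,
and Benjamini–Hochberg FDR < 0.02 computed per comparison family (one BH
correction across genes within each stage pair). A gene is a temporal DEG
if any pairwise stage comparison within the period passes all gates; the
union over all pairs (not only consecutive stages) is the most inclusive
reading of "temporally differentially expressed" and is configurable.
Replicate libraries of a stage are pooled before testing, since the test
is defined for one library per side.

## Network construction and module detection

Expression enters the network as log₂(TPM + 1) — the log stabilizes the
variance of tag counts; the choice is configurable. Pearson correlation
is computed across samples; constant genes are excluded with a warning.
The unsigned adjacency is a_ij = |cor_ij|^β with β = 10 for all analyses,
and the unsigned topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    k_i = Σ_{u≠i} a_iu,

with unit diagonal. Genes are clustered by average-linkage (UPGMA)
hierarchical clustering of the dissimilarity 1 − TOM (delegated to
scipy's linkage; heights verified against a naive O(n³) UPGMA in the test
suite). Modules come from a static cut of the dendrogram at height
0.995; clusters smaller than 30 genes are left unassigned. Surviving
modules are named by decreasing size along the conventional color
sequence (turquoise, blue, brown, …). Dynamic tree cutting — an adaptive
alternative that the field also uses — is intentionally not implemented;
the static cut with these constants is the primary path.

The module eigengene is the first right-singular vector of the module's
per-gene standardized expression (zero mean, unit variance across
samples); `variance_explained` is s₁²/Σs². The sign is fixed so the
eigengene correlates positively with the module's mean standardized
profile, with ties broken toward the first gene. Eigengene–indicator
association uses the Kruskal–Wallis rank test with tie correction and the
χ² approximation for the p-value (exact enumeration is unnecessary at the
screening sample sizes involved; all-identical inputs return H = 0,
p = 1 by convention).

## Module preservation and hubs

Two module assignments are compared over all module pairs. Overlap
fractions use the full module sizes on each side — matching how the
worked percentages 47% (1021/2183) and 72% (1021/1417) are formed — and
significance is the hypergeometric upper tail P(X ≥ overlap) with the
union of both networks' assigned module genes as the universe. The union
(rather than the intersection of the two gene sets) matters when the
networks were built on different DEG lists: restricting to the
intersection can make the universe collapse onto the overlap itself and
void the test. A pair is preserved when max(fraction_A, fraction_B) > 0.5
and p < 0.001; the max-fraction reading is deliberate, since a pair with
fractions 47%/72% counts as preserved. Qualifying pairs are matched
one-to-one greedily by ascending p so each module joins at most one
preserved pair; modules in no preserved pair are condition-specific.

Module backbones are the top 300 intra-module edges by TOM weight (ties
broken lexicographically by gene pair); hub genes have backbone degree
≥ 15. Backbone weight uses TOM rather than raw adjacency because TOM is
the network's similarity measure throughout.

## Ka/Ks estimation (NG86)

SNPs with overall alternate-allele frequency below 5% are removed
(alleles are counted over diploid genotypes, missing genotypes excluded
from the denominator; exactly 5% is retained). Per-group consensus
sequences substitute the majority allele at each surviving SNP, with
ties at 50% keeping the reference for determinism. The default contrast
is the domestic-group consensus against the wild-group consensus.

The estimator is Nei–Gojobori (1986) counting: each codon position
contributes the fraction of its three single-base changes that are
synonymous (changes to stop codons count as nonsynonymous, so every
codon's S + N = 3); site counts are averaged over both sequences.
Substitutions in codons differing at multiple positions are averaged
over all mutational orderings with equal weight, excluding orderings
that pass through a stop codon (if all do, all are used). The
proportions pN = Nd/N and pS = Sd/S receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p); a proportion ≥ 3/4 leaves the correction
undefined and flags the record instead of producing a number. The
implementation agrees with Biopython's independent NG86 routine to
nine decimals on random alignments, and with a hand-counted codon panel
exactly.

Category bins: "Conserved" (identical sequences, no SNP observed), "0"
(ω = 0 with observed SNPs), "0–0.1", "0.1–1", ">1", and the sentinel
"99" for Ks = 0 with Ka > 0, mimicking the convention of ML estimators
that report ω = 99 when synonymous changes are absent. The legend-style
open intervals leave ω = 0.1 and ω = 1 formally unassigned; the bins are
implemented right-closed (0 < ω ≤ 0.1 and 0.1 < ω ≤ 1). Sentinel genes
are excluded from any ">0.1" aggregate and from positive-selection calls,
because ω = 99 is not a reliable estimate.

## Synthetic-data generator

The generator emulates a two-condition, five-stage developmental DGE
experiment: prenatal stages named for days post-coitus (35–91), tag
libraries of 3.5 million tags, and gene modules planted as blocks that
are either shared between conditions or specific to one. Defaults use
two replicate libraries per stage (10 samples per condition); the
emulated study design — a single library per stage — is available as
`n_replicates_per_stage=1`, but see Limitations.

Module structure: all genes of a module follow one latent per-sample
trajectory (a stage-level component plus a replicate-level component,
mixed by `stage_share`), and each gene adds independent noise. The
latent share is set from the target within-module correlation after
correcting for the attenuation that counting noise adds on the observed
scale, so the realized Pearson correlation of the generated data matches
the configured target (verified by Monte Carlo: mean within-module |r|
within 0.1 of the 0.8 target). Latent trajectories of distinct modules
within a condition are drawn mutually orthogonal across samples, so the
planted between-module correlation is exactly zero rather than zero only
in expectation. Background genes are flat in expectation and carry only
counting noise — like real non-differentially-expressed genes, they are
removed by the DEG filter before network construction; genes of a module
specific to the other condition behave as background.

Counts are negative-binomial around TPM-scaled means (size parameter
`dispersion`, default 300 — about 30-fold the Poisson variance at these
counts; Poisson is the dispersion → ∞ limit). Expression levels are
scaled against the baseline composition with a lognormal mean
correction, so a module's swing does not compositionally distort the
expected counts of unrelated genes; realized library totals therefore
fluctuate mildly around the nominal depth, as real sequencing depth
does. Module genes receive mid-range baselines (2⁵–2⁷·⁵ TPM) so the
swinging module mass stays a small fraction of the library; background
baselines span 2⁵–2¹⁰ TPM, the range reliably quantified at this depth.

The coding-sequence generator plants exact numbers of synonymous and
nonsynonymous single-base changes (one per codon, verified against the
genetic code; no stop codons anywhere). The SNP generator plants
per-group allele frequencies from a Beta spectrum and draws diploid
genotypes binomially; alleles that would create an in-frame stop are
never planted.

What passing tests on these data do **not** show about real data: the
generator has no tag-to-gene mapping ambiguity, no sequencing error, no
linkage disequilibrium between SNPs, no correlated background structure,
and modules are disjoint blocks with a single latent dimension each —
real coexpression is messier on every count.

## Numerical choices

- Tag-test tie tolerance: density terms within a 10⁻¹² relative band of
  the observed term count as ties and enter the tail.
- TOM entries are clipped to [0, 1] against rounding; isolated vertices
  (zero connectivity) get TOM 0 off-diagonal.
- UPGMA tie-breaking follows scipy's deterministic ordering.
- Static-cut clusters are ordered by size with cluster id as the
  deterministic tie-break before color naming.
- The backbone sorts by (−weight, gene_i, gene_j), so ties are stable.
- Consensus ties (exactly 50% alternate) keep the reference allele.
- Seeds are explicit arguments everywhere; no global RNG state is used.

## Limitations

With five samples per network — the emulated study's literal design —
the sampling noise of Pearson correlation is so large (E|r_null|^β stays
comparable to module adjacencies at β = 10) that the fixed 0.995 cut
merges everything into one cluster; the method as parameterized needs on
the order of ten samples per network before planted modules separate
reliably. This is a genuine resolution limit of the static-cut variant
at small sample sizes, and likely the reason adaptive (dynamic) cutting
exists; recovery results reported by the acceptance script therefore use
10 samples per condition. The preservation test is membership-based
only; permutation-based preservation statistics (Z-summary and
relatives) are out of scope, as are SNP calling from alignments,
codon-model maximum-likelihood ω, GO enrichment, and all figure
rendering.
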