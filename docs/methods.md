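# Methods

## Substitution model

Codon evolution is modelled as a continuous-time reversible Markov chain on
the 61 sense codons of the universal nuclear code (stop codons are never
valid states; any codon containing a gap, N, IUPAC ambiguity or stop is
treated as missing for that taxon, since a partially observed codon cannot
be scored under a whole-codon model). Instantaneous rates follow the
GY94 parameterization: zero for multi-nucleotide changes, and otherwise
proportional to the target codon's equilibrium frequency π_j, multiplied by
κ for transitions and ω for nonsynonymous changes. Codon frequencies are
F3x4 — products of position-specific nucleotide frequencies renormalized
over sense codons — estimated from the alignment with a 0.5 pseudocount per
nucleotide per position so that short alignments cannot assign zero
frequency to an observed state (a zero-frequency observed state is still a
hard error).

**Normalization.** The generator is divided by its mean rate *at ω = 1*
(same κ, π). Branch lengths are therefore expected substitutions per codon
site under neutrality, and changing the site ω rescales only the
nonsynonymous flow while the synonymous rate per branch stays fixed. This
is what anchors each site test to the gene's local synonymous substitution
rate: a site can only look constrained relative to how fast the gene is
evolving synonymously.

Transition probabilities are computed by eigendecomposition of the
reversibility-symmetrized generator (D^{1/2} Q D^{-1/2} with D = diag(π) is
symmetric), which is faster and more stable than a generic matrix
exponential and exact for reversible Q; zero-length branches use the
identity exactly. Likelihoods use Felsenstein pruning with per-site
rescaling; taxa that are missing, excluded, or absent from the alignment
enter with all-ones partials (marginalized). Log-likelihoods are floored at
−745 (the log of the smallest positive double) so impossible configurations
on degenerate trees remain finite.

## Gene-level fit

Per gene, (κ, ω_g, ρ) are estimated by maximizing the pruning likelihood
over all codon columns, where ρ is a scalar multiplier on the fixed species
tree's branch lengths. Requirements: at least 3 informative non-query taxa
and at least 10 codon columns. The optimization is L-BFGS-B on
(log κ, log ω, log ρ) with bounds κ ∈ [0.01, 100], ω ∈ [1e-4, 10],
ρ ∈ [1e-6, 100], started from (2, 0.5, 1). The surface is well conditioned
in log space, so random restarts are used only if the first fit fails to
converge (two, seeded), followed by a derivative-free Nelder-Mead polish —
line searches on finite-difference gradients occasionally stall within
rounding error of the optimum. A fit that still fails raises an error
carrying the best parameters found.

**Masking.** The query species (the crop whose SNPs are being tested) is
excluded from the F3x4 counts, the gene fit, and every site likelihood.
This reduces reference bias: including the query would let its own allele
pull the test toward tolerating it. The masking property is asserted in the
test suite (mutating the query sequence leaves masked results bit-identical
while unmasked likelihoods move).

## The site test and call rule

At each queried codon, lnL₀ fixes the site ω at 1 and lnL₁ maximizes it
over [1e-4, 10] (bounded Brent on log ω; the batched runner first scans a
shared 25-point log-grid vectorized across sites, then refines within the
bracketing cells — identical to the per-site path to optimizer tolerance,
which is verified in the tests). D = 2(lnL₁ − lnL₀) is clipped at zero and
referred to the two-sided χ²(1) upper tail; a ½χ²₀ + ½χ²₁ boundary-mixture
reference is available behind a flag. Codons with fewer than 10 informative
non-query species are reported as untested.

A deleterious call additionally requires ω̂ < 1 (constraint, not
acceleration), p below α/n with n the number of codons actually tested in
the run (α = 0.05), and allele novelty: the reference or alternate base
absent from every other species at that alignment column. Novelty with zero
informative comparative states is vacuously true but logged; such columns
are normally already untested under the 10-species rule.

### Calibration caveat

The χ²(1) reference is an asymptotic approximation, and its accuracy
depends on how much substitution history a column carries. On simulated
neutral data with 20 taxa and **total** tree length 2 (about two
substitution events per codon column), the realized null rejection rate at
p < 0.05 is ≈ 0.02–0.03 rather than 0.05: near-invariant columns produce a
lump of D values in [2.7, 3.8], just below the 3.84 critical value, for any
tree shape (random-join, star, balanced all behave the same). With total
length ≥ 5 the same code calibrates within three binomial standard errors
of nominal (measured 0.054–0.058 at n = 1000). The likelihood itself is
pinned to |ΔlnL| < 1e−12 against an independent brute-force enumeration
oracle, so this is a property of the χ² approximation in low-information
regimes, not of the implementation. Consequence for practice: tests on
shallow phylogenies are conservative at nominal α, and at stringent
Bonferroni thresholds have essentially no power — deep, many-species
alignments are a prerequisite for the method, which is why the simulated
validation fixtures use a 30-taxon tree of total length 18.

## Effect classification

Each biallelic SNP is classified per overlapping transcript by substituting
the alternate base into the reference codon (complemented for minus-strand
genes): synonymous, missense, nonsense (gain of stop), stop_loss (loss of a
terminal stop), or noncoding when the position falls in a transcript's
footprint outside its CDS. stop_loss is kept as its own class rather than
folded into nonsynonymous so loss-of-stop events remain visible; summary
tables may merge it. A per-SNP summary class uses the precedence
nonsense > stop_loss > missense > synonymous > noncoding, while the full
per-transcript annotation is always retained (a SNP may be intronic in one
transcript and exonic in another). Variants in flagged transcripts (CDS
length not a multiple of 3 after GFF3 phase adjustment, or an internal
stop) are classified "unknown" and excluded from codon-level summaries.
SNPs in start codons are classified by their codon change like any other.
Grantham distances are recomputed from the composition/polarity/volume
formula with the published weights and the scale fixed by mean distance
= 100 over the 190 amino-acid pairs.

## Polarization and spectra

The ancestral base at a coding SNP is the strict-majority state (> 50% of
informative taxa) among a configured outgroup clade — the species most
closely related to the query — at the SNP's alignment column; ties and
data-free columns are unknown, and such variants are excluded with a reason
code rather than dropped. A weighted-by-proximity vote would be a
reasonable alternative; unweighted majority is used because the outgroup
clades in practice are small (2–3 species). Noncoding SNPs are not
polarized (outside CDS the cross-species alignments are unreliable).
Heterozygous genotypes contribute one derived allele, so N diploids give
unfolded spectra over 1..2N−1 derived copies; half-calls and missing
genotypes shrink a variant's called-allele total. The spectra conserve
counts exactly: every polarized segregating variant of a class appears in
exactly one bin, and the exclusion ledger balances the input count.

## Consensus and downstream summaries

The final deleterious set is the triple intersection — nonsynonymous, and
called deleterious by the LRT and both external method tables. Variants
missing any method's verdict form a separate "untestable" stratum rather
than counting as tolerated, and both denominators (all nonsynonymous;
per-method testable) are reported for proportion tables, since published
per-method proportions are ambiguous between the two. Recombination
analysis computes cM/Mb per between-marker interval, excludes negative or
> 20 cM/Mb intervals as marker-placement artifacts, assigns each
nonsynonymous SNP to exactly one half-open interval [start, end), and
relates rate to deleterious proportion by interval-level Pearson
correlation and SNP-level logistic regression (IRLS via statsmodels, Wald
p for the slope); SNPs outside the map are logged, never silently dropped.

## Simulator

The simulator evolves codon alignments under exactly the engine's model:
root codons drawn from π (or fixed to a given CDS for gene fixtures), then
per-branch sampling from exp(ρtQ(ω_site)). All randomness flows from one
seed, with per-gene streams split from it so results are invariant to gene
order; identical seeds give byte-identical output. The toy genome bundle
plants SNPs of every effect class on both strands, including a
dual-transcript gene (exonic in one isoform, intronic in the other), a
phase-0 multi-exon gene, and an intergenic site, with a truth table of
intended classes. What the simulator does **not** emulate: alignment error,
indels and frameshifts, rate variation beyond per-site ω, paralogous
homolog hits, genotype-calling error, and linkage between sites — so green
tests demonstrate correctness of the machinery under the model, not
robustness to real-data artifacts.

## Problem sizes used in validation

Simulation checks use 20-taxon trees with 400–2000 codon columns for
calibration/power/recovery (50 replicates for parameter recovery, with
tolerance κ̂ ∈ [1.6, 2.4], ω̂_g ∈ [0.4, 0.6] at true (2.0, 0.5)), 100 random
parameterizations on ≤ 4-taxon trees for the enumeration oracle, and a
30-taxon, total-length-18 tree for the end-to-end fixture. These sizes give
each stochastic check a comfortable margin while keeping a full validation
run to a couple of minutes on one CPU.

## Known limitations

* Branch lengths are never re-estimated per site; ρ rescales the fixed
  topology globally per gene.
* The χ²(1) reference is conservative on shallow trees (see above).
* No rate variation across sites beyond the tested site's own ω; no
  multi-nucleotide codon changes.
* Ancestral inference is majority vote, not marginal likelihood
  reconstruction.
* The external predictors are consumed as verdict tables; their internal
  scores are not modelled.
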