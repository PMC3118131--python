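# Methods

This note documents the statistical model behind `hapcore`, the numerical
choices in its implementation, what the synthetic data generator does and
does not emulate, and the design decisions taken where more than one
reasonable construction exists.

## Family likelihood and explanation sets

The data unit is a nuclear family with unphased multilocus genotypes for
father, mother, and `n_i` children, ascertained through an affected
proband (children are reordered so the first child is the first affected
one; relative order of the rest is preserved, ties broken by file order).
An *explanation* is an ordered quadruple `(j, k, u, v)` of haplotype
indices — father's transmitted and non-transmitted, mother's transmitted
and non-transmitted — such that `(j, k)` is compatible with the father's
genotype, `(u, v)` with the mother's, and the merged pair `(j, u)` exactly
reproduces the proband's genotype at observed markers.  Each remaining
child contributes the factor `s(j,k,u,v; g) ∈ {0..4}`, the number of the
four gamete combinations compatible with that child's genotype;
explanations whose `s`-product vanishes are dropped.  Missing markers act
as wildcards (both alleles of a marker are missing together).

The proband-conditional family likelihood under the alternative is

    L_i = Σ_{(j,k,u,v)} γ_{j,Tr} γ_{u,Tr} γ_{k,NTr} γ_{v,NTr} · Π_{l'≥2} s(·; g_l'),

and the null restricts `Tr = NTr`.  The raw `s` counts are used rather
than `s/4`: the omitted `4^(n_i−1)` factor is constant within a family and
cancels in every likelihood ratio.  Summing the ordered quadruples against
the proband constraint is algebraically identical to the unordered,
proband-free explanation set with the proband folded into the `s` product,
so one enumeration serves both the null (pooled) and alternative fits, and
pooled estimates do not depend on which child is the proband.  Families
without an affected child cannot define a transmission contrast; they are
excluded from testing (logged) but still inform pooled frequency
estimates through their unconditional explanation sets.

## EM estimation

The E-step weights each explanation by its posterior probability under
current frequencies; the M-step sets each haplotype frequency to its
expected slot count divided by the number of slots — `4n` pooled, or `2n`
separately for the transmitted slots `(j, u)` and non-transmitted slots
`(k, v)`.  Numerical choices:

* convergence when the log-likelihood changes by less than 1e-8, capped at
  1000 iterations (non-convergence is flagged, never silently accepted);
* per-haplotype scores floored at 1e-12 inside likelihoods;
* after the pooled fit, haplotypes below 1e-6 are pruned and the vector
  renormalized; the explanation rows are re-filtered to the surviving
  space (with a guard that restores haplotypes rather than ever emptying
  a family's explanation set);
* pooled fits start from uniform frequencies (deterministic);
* alternative (Tr/NTr) fits start from the corresponding null optimum.
  Because each EM update is monotone, this start guarantees
  `ℓ̂₁ ≥ ℓ̂₀` and hence a nonnegative LRT statistic by construction, and
  it is deterministic.  Residual float noise below 1e-6 is clamped to
  zero; anything larger raises an optimization-failure error.

Candidate haplotypes are reconstructed from the data: per family, parental
diplotypes are enumerated from the genotypes, pre-filtered by a necessary
per-child gamete condition, and jointly filtered so that every child is
compatible with at least one gamete combination; the union over families,
with uniform initial frequencies, is the EM's candidate table.  Caps on
enumeration sizes (100,000 retained explanations per family; larger
transient grids chunked) turn pathological inputs into clear errors that
suggest marker windowing.

## Evolution-guided clustering and the core-coded likelihood

Frequency is used as a proxy for haplotype age.  The *core* `H⁽⁰⁾` is the
smallest descending-frequency prefix of the estimated haplotypes whose
cumulative frequency reaches the mass threshold (default 0.9; ties at the
boundary are broken lexicographically so the selection is deterministic).
Each non-core haplotype joins layer `H⁽ᵐ⁾` at its minimum Hamming distance
m from the core.  The allocation matrix `B⁽ᵐ⁾` gives, for each haplotype
in layer m, a probability row over the previous level: its one-step
mutation ancestors, weighted proportionally to the ancestor's frequency
(older ≈ more frequent).  Two degenerate situations arise in finite
samples and are handled explicitly:

* a haplotype with no distance-1 ancestor in the previous level falls back
  to the minimal-distance ancestors, again frequency-weighted (logged);
* an entirely empty intermediate layer is dropped, so the allocation chain
  always links consecutive non-empty levels.

Per-site mutation-rate weighting is deliberately omitted: all sites are
treated as equal-rate, single-step mutations.  The products
`Γᵐ = B⁽ᵐ⁾ ⋯ B⁽¹⁾` are row-stochastic, so the revised core frequencies
`π̃⁽⁰⁾ = π⁽⁰⁾ + Σₘ (Γᵐ)ᵀ π⁽ᵐ⁾` conserve total mass exactly.

In the core-coded likelihood every haplotype's score is a fixed linear
form in the c core parameters: a core haplotype scores its own entry and a
layer-m haplotype scores `Γᵐ[row]·γ`.  The Γ coefficients are frozen from
the pooled fit — clustering precedes testing — and the recode is applied
as stated even though the scores over all haplotypes then sum to slightly
more than one (the rare rows reuse core mass); the maximization is over
the core simplex either way.  Because the scores are linear with
nonnegative coefficients, the recoded model is a latent-ancestry mixture
and the same EM machinery applies (expected core counts through the
posterior `A[h,c]γ_c / (Aγ)[h]`), preserving monotone ascent.  A
softmax-parameterized L-BFGS refinement backs up the core-coded EM if it
hits the iteration cap, and is accepted only when it improves the
likelihood.  The same recoding mechanism expresses the grouped comparator
(rare haplotypes mapped to one indicator column) and the identity recode
reproduces the full-haplotype test, which is also the mass-1.0 limit of
the clustered test.

Degrees of freedom: the alternative carries `2(c−1)` free parameters and
the null `c−1`, so LRT-C refers `2(ℓ̂₁−ℓ̂₀)` to `χ²(c−1)`; the full test
uses `h−1` with h the number of haplotypes with positive pooled estimate,
and LRT-G uses the number of kept (non-rare, default cutoff 0.05 of pooled
frequency) haplotypes.  Degenerate one-parameter spaces return statistic
0 with df clamped to 1 and a warning.  The clustering is re-estimated on
every dataset (every simulation replicate), since the core set is itself
a function of the data.

## Disease-model simulator

Penetrances derive from genotype relative risks (1, r, 2r−1) additive,
(1, r, r) dominant, (1, 1, r) recessive, anchored to prevalence K via
`K = (1−p)² f0 + 2p(1−p) f1 + p² f2`; models with `f2 > 1` are rejected.
The liability-allele frequency among cases is
`P(A|D) = [f2 p² + f1 p(1−p)]/K`, which the sampler reproduces by
construction: the proband's ordered haplotype pair is drawn from
`P(j,u | affected) ∝ π_j π_u f_{a(j)+a(u)}` (ascertainment by conditional
sampling rather than population rejection sampling — distributionally
identical for the proband and far cheaper), the parents' non-transmitted
haplotypes independently from the pool, and each extra sibling receives
one paternal and one maternal haplotype uniformly at random with affection
drawn from its own penetrance.  Sibling affections are not used for
ascertainment.  Parents carry unknown affection status.  Sibship sizes are
1 + Poisson(2) by default and, in replicated studies, are drawn from a
dedicated seed so each family keeps its size across replicates; passing no
sibship seed redraws them.  All haplotypes are collapsed to unphased
genotypes before analysis.

### The fixture pool

The benchmark pool emulates the structure of a tag-SNP haplotype block:
13 markers, 15 haplotypes, the 10 most frequent holding exactly 90% of the
mass.  Cores arise by sequential single-site mutations from a random root
with geometric-decay frequencies (ratio 0.86, giving a frequency range of
roughly 0.02–0.16, matching the block the method was benchmarked on);
non-core haplotypes are single-site mutants of random cores sharing the
remaining 10% equally, so the layering depth is exactly one.  Structural
mutations avoid the liability marker, and liability-allele carriage is
assigned clade-wise (a core together with its mutants), which preserves
every distance-1 link; an exact target allele frequency is achieved by
splitting at most one rare haplotype's mass into an additional
liability-site mutant of a core (at most 16 haplotypes, logged), and
arrangements for which no clade subset comes close enough are re-drawn.
The generator does **not** emulate linkage-disequilibrium decay within the
block, recombination, genotyping error, or missingness; passing tests
therefore demonstrate correctness of the estimation and testing machinery
under clean block structure, not robustness to those artifacts (missing
data is handled on input but never injected).

## Study drivers and problem sizes

Type-I error, power, and core-identification studies simulate replicate
datasets (replicate r seeded with `seed + r`), run the tests or the
pooled-EM/core-selection front end, and aggregate rejection rates with
binomial standard errors; replicates that raise an optimization failure
are excluded and counted.  The package's standard study sizes are
N = 200 families with 400 replicates for null calibration and 200
replicates for power and core-identification runs — large enough that the
binomial standard error of a 5% rate is about 1.1 percentage points —
with replicate counts exposed as parameters throughout.

## Known limitations

* Haplotypes are transmitted intact: no recombination within the block
  and no de novo mutation in transmission.
* The χ² reference for all three tests is asymptotic; no permutation
  p-values are provided.
* No standard errors for frequency estimates (no Louis information).
* Core selection by cumulative mass is a rule of thumb; entropy-based
  selection criteria are out of scope.
* Extended pedigrees are split into independent nuclear units; the
  likelihood treats them as independent.
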