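# hapcore

Evolution-guided haplotype clustering and likelihood-ratio association
tests for nuclear-family SNP data.

## The problem

Haplotype-based association studies of a block of linked SNPs face two
coupled difficulties: the haplotype space is large (so tests burn many
degrees of freedom, much of it on rare haplotypes), and phase is ambiguous
when only unphased genotypes are observed.  Family data help with both —
parental genotypes constrain phase, and transmitted versus non-transmitted
parental haplotypes give an association contrast that is immune to
population stratification — but a naive haplotype-level test still
dissipates power across rare categories.

`hapcore` implements a family-based testing pipeline for geneticists
running candidate-region or simulation studies:

1. **Phase handling.** For each nuclear family with genotypes `G_i` and an
   affected proband, enumerate every explanation quadruple `(j, k, u, v)` —
   father's transmitted/untransmitted and mother's
   transmitted/untransmitted haplotypes — compatible with all genotypes,
   weighting each by the transmission-count product
   `s(j,k,u,v; g_child) ∈ {0..4}` over the remaining siblings.
2. **EM frequency estimation.** Maximize
   `L = Π_i Σ_{(j,k,u,v)∈E_i} π_j π_k π_u π_v · s` over the haplotype
   frequency simplex, with posterior explanation weights in the E-step and
   expected slot counts (4 per family) in the M-step.
3. **Evolutionary clustering.** Take the leading haplotypes reaching 90%
   cumulative estimated frequency as the *core* `H⁽⁰⁾` (frequency proxies
   age); layer the remainder by minimum Hamming distance m into `H⁽ᵐ⁾`;
   link adjacent layers with row-stochastic allocation matrices `B⁽ᵐ⁾`
   (one-step ancestors, frequency-weighted); form `Γᵐ = B⁽ᵐ⁾⋯B⁽¹⁾` so each
   rare haplotype has a probability row over the cores.  Core frequencies
   are revised as `π̃⁽⁰⁾ = π⁽⁰⁾ + Σₘ (Γᵐ)ᵀ π⁽ᵐ⁾` and every rare frequency
   is recoded as the linear form `Γᵐ[i]·γ` in the c core parameters.
4. **Testing (LRT-C).** Refit the family likelihood with transmitted slots
   scored by `γ·Tr` and non-transmitted by `γ·NTr`, both living on the
   c-dimensional core simplex; the statistic `2(ℓ̂₁ − ℓ̂₀) ~ χ²(c−1)`.
   Comparators: the full-haplotype LRT (df = h−1) and LRT-G, which lumps
   all rare haplotypes into one group.

A disease-model simulator (additive / dominant / recessive penetrances
anchored to a prevalence K, proband-first ascertainment, Poisson sibships)
and Monte-Carlo study drivers for type-I error, power, and core-recovery
rates are included, together with a generator for the benchmark haplotype
pool: 13 tag SNPs, 15 haplotypes, the top 10 carrying 90% of the mass.

## Worked example

```python
import numpy as np
from hapcore import (DiseaseModel, SimConfig, allele_freq_in_cases,
                     make_fixture_pool, run_tests, simulate_dataset)

pool = make_fixture_pool(target_p=0.25, seed=7)     # 15 haplotypes, 10 cores
model = DiseaseModel.from_mode("additive", 3.0, 0.25, 0.01)
print("penetrances:", (model.f0, model.f1, model.f2))
print("P(A|D) =", round(allele_freq_in_cases(model), 4))

fams, truth = simulate_dataset(
    SimConfig(n_families=200, pools=pool, model=model, seed=1, sibship_seed=1)
)
res = run_tests(fams)
for m in ("lrtc", "lrtg", "full"):
    r = res[m]
    print(f"{r.method:9s} stat={r.statistic:7.2f}  df={r.df:2d}  p={r.p_value:.3g}")
```

prints

```
penetrances: (0.005, 0.015, 0.025)
P(A|D) = 0.4375
LRT-C     stat=  24.08  df=10  p=0.00739
LRT-G     stat=  17.97  df= 8  p=0.0215
LRT-full  stat=  25.10  df=14  p=0.0336
```

The additive r=3 model at K=1% gives penetrances (0.005, 0.015, 0.025);
the liability allele rises from 25% in the population to 43.75% among
cases.  On this dataset all three tests reject at the 5% level, but the
clustered test spends only 10 degrees of freedom against the full test's
14 and returns the smallest p-value — the dimension reduction is where its
power advantage comes from.

A thin CLI wraps the same pipeline: `hapcore simulate`, `hapcore test
--ped file.ped --method lrtc`, and study drivers `hapcore type1 | power |
cores` (see `hapcore --help`).

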