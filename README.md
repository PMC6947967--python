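# gbsim

Simulation pipeline for studying **genotyping-by-sequencing (GBS) data
quality and genomic prediction** in a selected livestock population:
forward-in-time breeding simulation, a Poisson read-depth GBS error model
with heterozygote undercalling, Bayesian genotype correction to expected
dosages, marker quality control, and SNP-BLUP genomic prediction.

It is aimed at quantitative geneticists who want to ask: *given GBS data
at mean depth x, edited at a given MAF threshold, how many genotypes are
missing or wrong, and what does that do to the reliability of genomic
prediction?*

## The model

**Population.** A historical population (2000 individuals for 1000
generations, then a decline to 400 over 200 generations) establishes
mutation–drift equilibrium and LD; 40 males + 200 females found an
expanded generation (litter size 5); 100 sires + 500 dams then breed ten
recent generations of 2500, with 80%/40% sire/dam replacement by highest
EBV (animal-model BLUP, Henderson's mixed-model equations with
A⁻¹ from pedigree rules). The genome is 5 × 100 cM with an evenly spaced
bi-allelic marker grid (1 cM = 1 Mb), 100 QTL per chromosome with
gamma(0.4) effects scaled so var(TBV) = h²σ²ₚ = 0.3, and recurrent
mutation at 2.5 × 10⁻⁵ in the historical phases only.

**GBS.** Read counts are n ~ Poisson(x) per individual × locus
(x ∈ {2, 4, 5, 10}); zero reads ⇒ missing. A true heterozygote covered by
n reads shows a single allele with probability 2(½)ⁿ and is miscalled
homozygous. Called homozygotes are corrected to posterior-mean dosages

    Gc_aa = 2pq(½)ⁿ / (q² + 2pq(½)ⁿ),
    Gc_AA = (2p² + 2pq(½)ⁿ) / (p² + 2pq(½)ⁿ),     Gc_Aa = 1,

with p estimated from the calls as p̂ = (P(GBS_AA) − P(GBS_aa) + 1)/2.

**Prediction.** SNP-BLUP, y = 1μ + Mg + e with g ~ N(0, Iσ²_g), solved as
a ridge system with λ = σ²ₑ/σ²_g derived from h²; equivalent to GBLUP with
the marker kinship McMc′/Σ2pq. Training on 7500 animals from generations
6–9, testing on 2500 from generation 10; reliability = r²(GEBV, TBV).

## Worked example

```python
import numpy as np
from gbsim import GenomeSpec, PopulationDesign, QCConfig, gbs, qc
from gbsim.scenarios import simulate_population, replicate_rng

spec, design = GenomeSpec(), PopulationDesign()
rng = replicate_rng(2, 0)
pop = simulate_population(spec, design, rng, scale=0.2)   # desk-scale history
rows = np.sort(rng.choice(pop.n_genotyped, 10_000, replace=False))
truth = pop.genotypes[rows]

depths = gbs.simulate_depths(*truth.shape, 2, rng)        # mean depth 2
calls = gbs.call_genotypes(truth, depths, rng)
kept = qc.apply_qc(calls, QCConfig(maf_threshold=0.01)).kept_loci
acc = gbs.accuracy_summary(calls[:, kept], truth[:, kept])
print(f"kept {len(kept)} SNPs | missing {acc.missing_rate:.1%} "
      f"incorrect {acc.incorrect_rate:.1%} correct {acc.correct_rate:.3f} "
      f"r {acc.correlation:.3f}")
```

prints (one replicate, seed shown above):

```
kept 7313 SNPs | missing 13.5% incorrect 14.7% correct 0.718 r 0.873
```

i.e. at mean depth 2, 13.5% of genotypes are missing (the Poisson zero
class e⁻²), ~15% of all entries are heterozygotes miscalled homozygous,
so only ~72% of entries are non-missing and correct, and the pooled
correlation between (mean-imputed) calls and true genotypes is 0.87. At
depth 10 the same pipeline yields a correlation of 0.997 and a correct
rate of 0.996.

A `gbsim` command-line tool exposes the same pipeline
(`simulate`, `gbs`, `qc`, `predict`, `run-study`, `report`); try
`gbsim run-study --seed 1 --replicates 2 --scale 0.1 --out study/`.

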