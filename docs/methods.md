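# Methods

## Scope and shape

`gbsim` implements a five-stage pipeline: forward population simulation
(`popsim`, `pedigree`), GBS data generation and correction (`gbs`),
marker editing (`qc`), SNP-BLUP prediction (`gblup`, a
scikit-learn-compatible estimator), and study orchestration
(`scenarios`, plus a thin `click` CLI). External haplotype imputers are
out of scope; `bridge` only shuttles VCFs to and from a user-supplied
command.

## Population model

* **Historical phases.** Founder allele frequencies are i.i.d.
  Uniform(0,1) per locus; 1000 generations at N = 2000 (equal sexes,
  random union of gametes), then a linear decline to N = 400 over 200
  generations. Recurrent mutation flips alleles at 2.5 × 10⁻⁵ per locus
  per transmitted gamete, historical phases only. The uniform start
  combined with drift keeps the segregating-site frequency spectrum
  near-uniform (the quasi-stationary shape under pure drift), while
  mutation adds a rare-variant excess; both matter for every
  depth-dependent error statistic, because the population mean of 2pq
  sets the heterozygote exposure.
* **Meiosis.** Haldane model: crossover counts Poisson in map length, no
  interference. For a fixed set of tracked loci this is sampled exactly
  as independent Bernoulli phase switches between adjacent loci with
  r = (1 − e⁻²ᵈ)/2, plus a fair-coin phase at each chromosome start. The
  switch field is sampled sparsely (per-interval binomial counts
  scattered over gametes), which makes desk-scale history runs cheap.
* **Selection phases.** 40♂ + 200♀ sampled from the last historical
  generation; one expanded generation (200 litters of 5); 100 sires +
  500 dams selected on EBV; ten recent generations of 2500 offspring with
  80%/40% sire/dam replacement by highest EBV after each generation (ties
  broken by EBV then animal id; survivors are the best current parents).
  EBVs come from the animal-model MME with λ = (1 − h²)/h², A⁻¹ built by
  Henderson's rules with Meuwissen–Luo-style Mendelian-sampling
  variances (inbreeding computed for parents via a generation-vectorised
  path-coefficient walk, memoised per full-sib litter), solved by
  Jacobi-preconditioned conjugate gradients to 10⁻⁸ relative residual.
* **Trait.** 500 QTL at random grid positions; |effect| ~ Gamma(0.4, 1)
  with random sign, rescaled exactly so var(TBV) = h²σ²ₚ = 0.3 in the
  expanded cohort; phenotype = TBV + N(0, 0.7). No polygenic residual.

## Tracked loci and the GBS panel

The 5 × 10⁶ marker grid is never materialised. GBS placement positions
are drawn first (inter-locus gaps from the published ten-bin distance
table, mean 62.015 kb; positions snapped to the 100 bp grid), and the
simulator tracks a cluster of backup grid loci around each placement
(offsets 0, ±1, ±2.5, ±5, ±10, ±30 kb) plus the QTL. GBS loci are SNPs:
after the expanded generation, each placement identifies its nearest
loci segregating in that cohort (its SNP-discovery proxy); after
breeding, each placement greedily takes its nearest candidate that is
still polymorphic in the genotyped cohort and not claimed by a
neighbouring placement. The cluster spans the distance over which
fixation is locally correlated, so this reproduces dense-grid snapping
behaviour at a tiny fraction of the memory; placements with no
segregating locus within 50 kb are dropped (<1%).

## GBS error model, correction, and metrics

Read depths are i.i.d. Poisson(x). Calls: missing at n = 0; true
homozygotes called truthfully (no sequencing error); a true heterozygote
is called aa if u ≤ (½)ⁿ, AA if (½)ⁿ < u < 2(½)ⁿ (u ~ U(0,1)), else Aa.
Corrected dosages follow the posterior-mean formulas with p estimated
from the calls (the difference P(GBS_AA) − P(GBS_aa) is immune to the
symmetric het-miscall inflation, so p̂ is unbiased). Degenerate p̂ ∈ {0,1}
collapses the dosage to 0 or 2 exactly. Rounding ties go away from 1,
which is equivalent to "toward the originally called homozygote" because
aa-called dosages lie in [0,1] and AA-called in [1,2].

Accuracy metrics pool all individual × locus entries: missing rate,
incorrect rate (non-missing, ≠ truth after rounding), correct rate
(their complement — the three partition the entries exactly), and the
pooled Pearson correlation with missing entries replaced by locus means
(`missing_policy="drop"` is available). Error and accuracy metrics are
reported on the MAF ≥ 0.01-edited panel: the printed benchmark rates
satisfy correct = 1 − missing − incorrect exactly at that editing level,
so the incorrect/missing/correct figures all refer to one panel.
Metrics are computed over a genotyped cohort of 10,000 individuals (the
imputation-cohort size of the study design), subsampled from the 25,000
recent-generation animals.

## Marker editing

Call-rate filtering (default: loci with ≥ 0.8 non-missing; the
`individuals` and `both` axes are selectable) followed by MAF editing at
one of {none, 0.001, 0.01, 0.03}, computed by allele counting on
non-missing calls. Monomorphic-in-calls loci are always removed, also
under "no MAF limit": zero-variance columns carry no information and
break correlation metrics. Filters are idempotent and composable; masks
record their provenance.

## SNP-BLUP

Training-mean-centred dosages; μ̂ = training phenotype mean;
σ²_g = h²σ²ₚ / Σ2p̂q̂ (p̂ from training column means), σ²ₑ = (1 − h²)σ²ₚ,
λ = σ²ₑ/σ²_g; solved by Cholesky on the primal normal equations when
loci ≤ records, otherwise through the dual (records × records) system.
The posterior mean under fixed variances coincides with the Gibbs
sampler mean a Bayesian implementation would give, so a sampler is not
included. GEBVs are invariant between the primal and dual routes and
equal GBLUP with kinship McMc′/Σ2p̂q̂ (asserted in the test-suite against
a dense-inverse oracle). Mean-imputed entries equal their locus mean and
are inert after centring. Dosage inputs enter M unrounded.

## Desk-scale execution

The full design (1200 historical generations) is expensive, so scaled
runs shrink the historical phases only, by `scale` (tests and the
acceptance script use 0.2): generations and sizes scale jointly
(preserving Σ 1/2N, with the phase-2 generation count solved so its
drift integral matches the full design and its end size stays 400), the
mutation rate scales as μ/scale (preserving 4Nμ), and historical map
distances scale as d/scale (preserving 4Nc, hence LD). This is the
standard diffusion rescaling; the bottleneck, expansion, selection and
prediction phases always run at full size, because their drift and
selection response are part of what is measured. Prediction benchmarks
in the test-suite use the full 7500/2500 train/test split on 3
replicates.

## What the generator does and does not emulate

Simulated data have exact Poisson depths, no sequencing error, no
restriction-site dropout structure, HWE-consistent priors, and a
frequency spectrum produced by uniform-start drift plus recurrent
mutation. Passing tests therefore validate the error model, the
correction algebra, the editing logic and the prediction machinery —
not robustness to real-GBS artefacts (allelic bias, index hopping,
batch-dependent depth). Two emergent quantities are known to sit below
the published benchmark levels: mean short-range LD (r² ≈ 0.17–0.18 at
< 50 kb in generation 10, versus 0.259) and, in proportion, prediction
reliabilities; and the segregating-site spectrum carries somewhat more
ultra-rare mass than the published kept-SNP counts imply (e.g. ~3% of
panel loci below MAF 0.001 versus ~1.6%). Both trace to the
frequency-spectrum details of the original data generator, which the
design tables do not fully pin down; the incorrect-rate benchmarks sit
at the lower edge of their tolerance for the same reason.

## Numerical choices

* RNG: a single master seed; every replicate draws from
  `SeedSequence(master, spawn_key=(replicate,))`; reruns are bit-identical.
* CG tolerances: 10⁻⁸ (pedigree BLUP default); SNP-BLUP solved direct.
* Selection tie-breaks: stable sort by (−EBV, id).
* Sexes are assigned exactly half male per cohort (the design's 50%
  male-progeny proportion, made deterministic).
* Genotype containers: NumPy `.npz` plus 4-column pedigree TSV; VCF
  import/export (GT and DS) via pysam for external-imputer round trips.
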