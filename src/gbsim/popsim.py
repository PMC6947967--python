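"""Forward-in-time diploid population simulation.

Simulates the three-stage breeding design: (1) a long random-mating
historical phase under recurrent mutation and drift (constant size, then a
gradual bottleneck) that establishes mutation--drift equilibrium and LD;
(2) a single expanded generation bred from a small founder sample of the
last historical generation; (3) ten recent generations under truncation
selection on pedigree-BLUP EBVs with partial sire/dam replacement.

Genomes are tracked at an explicit subset of the dense marker grid (the
full grid is never materialised).  Meiosis follows the Haldane model:
crossover counts are Poisson in map length with no interference, which for
a fixed set of tracked loci is equivalent to independent Bernoulli phase
switches between adjacent loci with probability given by Haldane's map
function r = (1 - exp(-2d)) / 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .config import GenomeSpec, PopulationDesign
from .pedigree import Pedigree, pedigree_blup

MALE, FEMALE = 0, 1

__all__ = [
    "TrackedLoci", "HaploidGenomes", "QTLModel", "TraitRecords",
    "RecentPopulation", "init_founders", "sample_gametes", "run_historical",
    "assign_qtl_effects", "expand_and_breed_recent", "mean_ld_r2", "ld_decay",
    "MALE", "FEMALE",
]


# ---------------------------------------------------------------------------
# loci and genomes


@dataclass(frozen=True)
class TrackedLoci:
    """Sorted bi-allelic loci on the marker grid, a thin subset of the genome.

    ``chrom`` / ``pos_bp`` are parallel arrays sorted by (chromosome,
    position); ``is_qtl`` flags the causal subset.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    is_qtl: np.ndarray

    def __post_init__(self):
        if not (len(self.chrom) == len(self.pos_bp) == len(self.is_qtl)):
            raise ValueError("locus arrays must have equal length")
        key = self.chrom.astype(np.int64) * (self.pos_bp.max() + 1 if len(self.pos_bp) else 1) + self.pos_bp
        if np.any(np.diff(key) <= 0):
            raise ValueError("loci must be strictly increasing within chromosome order")

    def __len__(self) -> int:
        return len(self.pos_bp)

    def chrom_slices(self) -> list[slice]:
        out = []
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out

    def subset(self, idx: np.ndarray) -> "TrackedLoci":
        idx = np.asarray(idx)
        return TrackedLoci(self.chrom[idx], self.pos_bp[idx], self.is_qtl[idx])


def switch_probabilities(loci: TrackedLoci, spec: GenomeSpec,
                         map_scale: float = 1.0) -> np.ndarray:
    """Per-locus phase-switch probability for gamete sampling.

    Interior loci: Haldane recombination fraction to the previous locus.
    First locus of each chromosome: 0.5 (independent fair starting phase).
    ``map_scale`` inflates map distances; a scaled-down historical phase
    uses 1/scale so that the population-scaled recombination rate 4*N*c
    (which shapes LD) is preserved, mirroring the mutation-rate scaling.
    """
    d_bp = np.diff(loci.pos_bp, prepend=loci.pos_bp[:1])
    d_morgan = map_scale * d_bp / (spec.bp_per_cm * 100.0)
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    new_chrom = np.r_[True, np.diff(loci.chrom) != 0]
    r[new_chrom] = 0.5
    return r.astype(np.float32)


class HaploidGenomes:
    """Per-individual haplotype pairs over the tracked loci.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with alleles in
    {0, 1}; allele 1 is the "A" allele whose count defines the genotype
    code (aa=0, Aa=1, AA=2).
    """

    def __init__(self, loci: TrackedLoci, haplotypes: np.ndarray):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if haplotypes.shape[2] != len(loci):
            raise ValueError("haplotype columns must match tracked loci")
        if haplotypes.size and haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        self.loci = loci
        self.haplotypes = haplotypes

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Genotype codes (count of allele 1), shape (n, n_loci), uint8."""
        return self.haplotypes.sum(axis=1, dtype=np.uint8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def subset_loci(self, idx: np.ndarray) -> "HaploidGenomes":
        return HaploidGenomes(self.loci.subset(idx), self.haplotypes[:, :, idx])

    def subset_individuals(self, idx: np.ndarray) -> "HaploidGenomes":
        return HaploidGenomes(self.loci, self.haplotypes[idx])


def uniform_tracked_loci(spec: GenomeSpec, n_tracked: int, rng: np.random.Generator,
                         n_qtl: int = 0) -> TrackedLoci:
    """A uniformly random subset of the marker grid (plus optional QTL flags),
    for stand-alone use of the simulator without a GBS panel."""
    per_chrom = spec.n_marker_loci_per_chrom
    if n_tracked > per_chrom * spec.n_chromosomes:
        raise ValueError("n_tracked exceeds the marker grid")
    chroms, positions = [], []
    base = np.ones(spec.n_chromosomes, dtype=int) * (n_tracked // spec.n_chromosomes)
    base[: n_tracked % spec.n_chromosomes] += 1
    for c in range(spec.n_chromosomes):
        gi = np.sort(rng.choice(per_chrom, size=base[c], replace=False))
        chroms.append(np.full(base[c], c, dtype=np.int16))
        positions.append((gi.astype(np.int64) + 1) * spec.grid_spacing_bp)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    is_qtl = np.zeros(len(pos), dtype=bool)
    if n_qtl:
        is_qtl[rng.choice(len(pos), size=n_qtl, replace=False)] = True
    return TrackedLoci(chrom, pos, is_qtl)


def init_founders(spec: GenomeSpec, loci: TrackedLoci, n_individuals: int,
                  rng: np.random.Generator) -> HaploidGenomes:
    """First historical generation: each locus gets a founder frequency
    p0 ~ Uniform(0, 1); haplotype alleles are independent Bernoulli(p0)."""
    if len(loci) > spec.n_marker_loci_per_chrom * spec.n_chromosomes:
        raise ValueError("tracked loci exceed the marker grid")
    p0 = rng.random(len(loci))
    haps = (rng.random((n_individuals, 2, len(loci))) < p0).astype(np.uint8)
    return HaploidGenomes(loci, haps)


# ---------------------------------------------------------------------------
# meiosis


def sample_gametes(genomes: HaploidGenomes, parent_idx: np.ndarray,
                   switch_prob: np.ndarray, rng: np.random.Generator,
                   mutation_rate: float = 0.0, chunk: int = 512) -> np.ndarray:
    """Sample one recombinant gamete per entry of ``parent_idx``.

    Phase along each chromosome is a Bernoulli switch chain with the
    Haldane probabilities from :func:`switch_probabilities`; mutation flips
    alleles of the transmitted gamete at ``mutation_rate`` per locus.
    Returns a (len(parent_idx), n_loci) uint8 array.
    """
    parent_idx = np.asarray(parent_idx)
    n_g, n_l = len(parent_idx), genomes.n_loci
    out = np.empty((n_g, n_l), dtype=np.uint8)
    for start in range(0, n_g, chunk):
        sl = slice(start, min(start + chunk, n_g))
        g = sl.stop - sl.start
        switch = _sparse_bernoulli_field(g, switch_prob, rng)
        phase = np.bitwise_xor.accumulate(switch, axis=1)
        ph = genomes.haplotypes[parent_idx[sl]]
        h0, h1 = ph[:, 0, :], ph[:, 1, :]
        # select h0 where phase 0, h1 where phase 1, without a fancy gather
        out[sl] = h0 ^ ((h0 ^ h1) & phase)
    if mutation_rate > 0.0:
        n_flip = rng.binomial(n_g * n_l, mutation_rate)
        if n_flip:
            flat = np.unique(rng.integers(0, n_g * n_l, size=n_flip))
            out.reshape(-1)[flat] ^= 1
    return out


def _sparse_bernoulli_field(n_rows: int, p: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Exact i.i.d. Bernoulli(p_j) field over (n_rows, len(p)) cells,
    sampled sparsely: per column j the number of successes is
    Binomial(n_rows, p_j); successes are assigned to distinct random rows.
    Most switch probabilities are tiny, so the field is extremely sparse."""
    n_l = len(p)
    counts = rng.binomial(n_rows, p)
    field = np.zeros((n_rows, n_l), dtype=np.uint8)
    singles = np.flatnonzero(counts == 1)
    if len(singles):
        field[rng.integers(0, n_rows, size=len(singles)), singles] = 1
    for j in np.flatnonzero(counts > 1):
        rows = rng.choice(n_rows, size=counts[j], replace=False)
        field[rows, j] = 1
    return field


def _breed(genomes: HaploidGenomes, sires: np.ndarray, dams: np.ndarray,
           switch_prob: np.ndarray, rng: np.random.Generator,
           mutation_rate: float = 0.0) -> HaploidGenomes:
    """Random union of gametes: one paternal + one maternal gamete per child."""
    pat = sample_gametes(genomes, sires, switch_prob, rng, mutation_rate)
    mat = sample_gametes(genomes, dams, switch_prob, rng, mutation_rate)
    return HaploidGenomes(genomes.loci, np.stack([pat, mat], axis=1))


def _half_sexes(n: int) -> np.ndarray:
    sex = np.zeros(n, dtype=np.int8)
    sex[n // 2:] = FEMALE
    return sex


# ---------------------------------------------------------------------------
# historical phases


def historical_schedule(design: PopulationDesign) -> list[int]:
    """Per-generation population sizes: constant phase 1, then a linear
    decline to the phase-2 end size (sizes rounded to even for equal sexes)."""
    sizes = [design.hist_phase1_size] * design.hist_phase1_generations
    decline = np.linspace(design.hist_phase1_size, design.hist_phase2_end_size,
                          design.hist_phase2_generations + 1)[1:]
    sizes += [_even(s) for s in decline]
    return sizes


def _even(x: float) -> int:
    n = int(round(x))
    return n if n % 2 == 0 else n + 1


def run_historical(spec: GenomeSpec, design: PopulationDesign,
                   genomes: HaploidGenomes, rng: np.random.Generator,
                   mutation: bool = True,
                   schedule: Optional[Sequence[int]] = None,
                   map_scale: float = 1.0) -> HaploidGenomes:
    """Random-mating historical phases with recurrent mutation.

    Each generation, every offspring draws a random sire from the male half
    and a random dam from the female half of the previous generation.
    Returns the final historical generation (with sexes split evenly: the
    first half of rows are male).
    """
    sizes = list(schedule) if schedule is not None else historical_schedule(design)
    if not sizes:
        return genomes
    mu = spec.marker_mutation_rate if mutation else 0.0
    sw = switch_probabilities(genomes.loci, spec, map_scale=map_scale)
    sex = _half_sexes(genomes.n_individuals)
    for n_next in sizes:
        if min(np.sum(sex == MALE), np.sum(sex == FEMALE)) < 1 or n_next < 4:
            raise ValueError("population too small to continue (need >= 2 per sex)")
        males = np.flatnonzero(sex == MALE)
        females = np.flatnonzero(sex == FEMALE)
        sires = males[rng.integers(0, len(males), size=n_next)]
        dams = females[rng.integers(0, len(females), size=n_next)]
        genomes = _breed(genomes, sires, dams, sw, rng, mu)
        sex = _half_sexes(n_next)
    return genomes


# ---------------------------------------------------------------------------
# QTL model and trait


@dataclass
class QTLModel:
    """Additive QTL effects, rescaled so the true-breeding-value variance in
    the scaling cohort equals the QTL heritability times the phenotypic
    variance."""

    qtl_idx: np.ndarray          # indices into the tracked loci
    effects: np.ndarray          # allele-substitution effect of allele 1, post-scaling
    target_variance: float

    def tbv(self, qtl_dosages: np.ndarray) -> np.ndarray:
        """TBV = sum_j effect_j * allele count_j over the QTL columns."""
        return qtl_dosages.astype(np.float64) @ self.effects


def assign_qtl_effects(spec: GenomeSpec, genomes: HaploidGenomes,
                       rng: np.random.Generator,
                       target_variance: Optional[float] = None,
                       heritability: float = 0.3,
                       phenotypic_variance: float = 1.0) -> QTLModel:
    """Sample |effect| ~ Gamma(shape, 1) with random sign for each QTL locus
    and rescale so var(TBV) hits the target in the supplied (scaling) cohort."""
    if target_variance is None:
        target_variance = heritability * phenotypic_variance
    qtl_idx = np.flatnonzero(genomes.loci.is_qtl)
    if len(qtl_idx) == 0:
        raise ValueError("no QTL flagged among tracked loci")
    mag = rng.gamma(spec.qtl_gamma_shape, 1.0, size=len(qtl_idx))
    sign = rng.integers(0, 2, size=len(qtl_idx)) * 2 - 1
    eff = mag * sign
    dos = genomes.dosages()[:, qtl_idx].astype(np.float64)
    if not np.any(dos.var(axis=0) > 0):
        raise ValueError("all QTL are fixed in the scaling cohort (zero genetic variance)")
    raw = dos @ eff
    v = raw.var()
    if v <= 1e-12:
        raise ValueError("zero genetic variance in the scaling cohort")
    eff = eff * np.sqrt(target_variance / v)
    return QTLModel(qtl_idx=qtl_idx, effects=eff, target_variance=target_variance)


@dataclass
class TraitRecords:
    """True breeding values and phenotypes for a cohort of animals."""

    tbv: np.ndarray
    phenotype: np.ndarray
    residual_variance: float


def make_phenotypes(tbv: np.ndarray, residual_variance: float,
                    rng: np.random.Generator) -> np.ndarray:
    return tbv + rng.normal(0.0, np.sqrt(residual_variance), size=len(tbv))


# ---------------------------------------------------------------------------
# expansion and recent generations


@dataclass
class RecentPopulation:
    """Output of the expansion + selection phases.

    ``genotypes`` holds genotype codes of the genotyped cohort (all
    recent-generation animals) at the recorded loci; trait and pedigree
    arrays cover every animal entered into the pedigree (historical-sample
    founders have generation -1 and no phenotype).
    """

    pedigree: Pedigree
    tbv: np.ndarray
    phenotype: np.ndarray
    residual_variance: float
    genotyped_ids: np.ndarray
    genotypes: np.ndarray             # (n_genotyped, n_recorded_loci) uint8
    recorded_loci: TrackedLoci
    qtl: QTLModel
    final_genomes: HaploidGenomes     # last recent generation, recorded loci

    @property
    def genotyped_generations(self) -> np.ndarray:
        return self.pedigree.generation[self.genotyped_ids]

    def traits(self) -> TraitRecords:
        """Trait records of the genotyped cohort."""
        return TraitRecords(tbv=self.tbv[self.genotyped_ids],
                            phenotype=self.phenotype[self.genotyped_ids],
                            residual_variance=self.residual_variance)


def _select_parents(ebv: np.ndarray, current: np.ndarray, candidates: np.ndarray,
                    n_total: int, replacement: float) -> np.ndarray:
    """Replace the stated fraction of the parent set with the highest-EBV
    candidates; survivors are the highest-EBV current parents.  Ties break
    by animal id (stable)."""
    n_new = int(round(n_total * replacement))
    n_keep = n_total - n_new
    if len(candidates) < n_new:
        raise ValueError("not enough replacement candidates")
    def top(ids: np.ndarray, k: int) -> np.ndarray:
        order = np.lexsort((ids, -ebv[ids]))
        return ids[order[:k]]
    return np.concatenate([top(current, n_keep), top(candidates, n_new)])


def expand_and_breed_recent(
    spec: GenomeSpec,
    design: PopulationDesign,
    genomes_hist: HaploidGenomes,
    rng: np.random.Generator,
    panel_hook: Optional[Callable[[HaploidGenomes], np.ndarray]] = None,
    blup_tol: float = 1e-8,
) -> RecentPopulation:
    """Sample bottleneck founders, breed the expanded generation, assign and
    scale QTL effects on it, then run the recent generations under EBV-based
    truncation selection with partial sire/dam replacement.

    ``panel_hook``, if given, is called with the expanded-generation genomes
    and must return the indices of loci to record for the genotyped cohort
    (QTL loci are always retained for TBV computation).  Mutation is off in
    the expanded and recent generations.
    """
    sw = switch_probabilities(genomes_hist.loci, spec)
    n_hist = genomes_hist.n_individuals
    sex_hist = _half_sexes(n_hist)
    males = np.flatnonzero(sex_hist == MALE)
    females = np.flatnonzero(sex_hist == FEMALE)
    if len(males) < design.founder_males or len(females) < design.founder_females:
        raise ValueError("last historical generation too small for the founder sample")
    f_m = rng.choice(males, size=design.founder_males, replace=False)
    f_f = rng.choice(females, size=design.founder_females, replace=False)
    founder_rows = np.concatenate([f_m, f_f])
    founder_sex = np.r_[np.zeros(len(f_m), np.int8), np.ones(len(f_f), np.int8)]

    ped = Pedigree()
    founder_ids = ped.add(np.full(len(founder_rows), -1), np.full(len(founder_rows), -1),
                          founder_sex, generation=-1)
    genomes = genomes_hist.subset_individuals(founder_rows)
    row_of = {int(i): k for k, i in enumerate(founder_ids)}
    id_sex = dict(zip(founder_ids.tolist(), founder_sex.tolist()))

    sire_ids = founder_ids[founder_sex == MALE]
    dam_ids = founder_ids[founder_sex == FEMALE]

    def breed_cohort(sire_pool: np.ndarray, dam_pool: np.ndarray, gen_label: int,
                     genomes_parents: HaploidGenomes, sw_local: np.ndarray,
                     parent_row: dict) -> tuple[np.ndarray, HaploidGenomes, np.ndarray]:
        n_off = len(dam_pool) * design.litter_size
        dam_of = np.repeat(dam_pool, design.litter_size)
        sire_of = sire_pool[rng.integers(0, len(sire_pool), size=n_off)]
        off = _breed(genomes_parents,
                     np.array([parent_row[int(s)] for s in sire_of]),
                     np.array([parent_row[int(d)] for d in dam_of]),
                     sw_local, rng, 0.0)
        sex = _half_sexes(n_off)
        ids = ped.add(sire_of, dam_of, sex, generation=gen_label)
        return ids, off, sex

    # --- expanded generation(s)
    exp_ids = exp_sex = None
    for _ in range(design.expand_generations):
        exp_ids, genomes, exp_sex = breed_cohort(sire_ids, dam_ids, 0, genomes, sw, row_of)
        row_of = {int(i): k for k, i in enumerate(exp_ids)}
        sire_ids = exp_ids[exp_sex == MALE]
        dam_ids = exp_ids[exp_sex == FEMALE]
        id_sex.update(zip(exp_ids.tolist(), exp_sex.tolist()))

    # --- QTL effects scaled on the expanded cohort; phenotype it
    qtl = assign_qtl_effects(spec, genomes, rng,
                             heritability=design.heritability,
                             phenotypic_variance=design.phenotypic_variance)
    n_total_guess = ped.n_animals + design.recent_generations * design.recent_dams * design.litter_size
    tbv = np.full(n_total_guess, np.nan)
    phen = np.full(n_total_guess, np.nan)
    qtl_dos = genomes.dosages()[:, qtl.qtl_idx]
    tbv[exp_ids] = qtl.tbv(qtl_dos)
    phen[exp_ids] = make_phenotypes(tbv[exp_ids], design.residual_variance, rng)

    # --- panel: restrict the tracked loci for the recent phase
    if panel_hook is not None:
        record_idx = np.asarray(panel_hook(genomes))
    else:
        record_idx = np.arange(genomes.n_loci)
    record_idx = np.unique(np.concatenate([record_idx, qtl.qtl_idx]))
    remap = -np.ones(genomes.n_loci, dtype=np.int64)
    remap[record_idx] = np.arange(len(record_idx))
    genomes = genomes.subset_loci(record_idx)
    sw = switch_probabilities(genomes.loci, spec)
    qtl = QTLModel(qtl_idx=remap[qtl.qtl_idx], effects=qtl.effects,
                   target_variance=qtl.target_variance)

    # --- select recent founders on EBV among the expanded cohort
    def solve_ebv() -> np.ndarray:
        sol = pedigree_blup(ped, phen[:ped.n_animals], design.heritability, tol=blup_tol)
        return sol.ebv

    ebv = solve_ebv()
    exp_males = exp_ids[exp_sex == MALE]
    exp_females = exp_ids[exp_sex == FEMALE]
    if len(exp_males) < design.recent_sires or len(exp_females) < design.recent_dams:
        raise ValueError("expanded generation too small for the recent parent sets")
    sires = _select_parents(ebv, exp_males[:0], exp_males, design.recent_sires, 1.0)
    dams = _select_parents(ebv, exp_females[:0], exp_females, design.recent_dams, 1.0)

    genotyped_ids: list[np.ndarray] = []
    genotype_blocks: list[np.ndarray] = []
    live_row = {int(i): k for k, i in enumerate(exp_ids)}
    live_genomes = genomes

    for gen in range(1, design.recent_generations + 1):
        parent_ids = np.unique(np.concatenate([sires, dams]))
        parent_rows = np.array([live_row[int(i)] for i in parent_ids])
        parents_g = live_genomes.subset_individuals(parent_rows)
        prow = {int(i): k for k, i in enumerate(parent_ids)}
        ids, off_genomes, sex = breed_cohort(sires, dams, gen, parents_g, sw, prow)
        if ids.max() >= len(tbv):  # grow trait arrays if needed
            extra = np.full(ids.max() + 1 - len(tbv), np.nan)
            tbv = np.concatenate([tbv, extra])
            phen = np.concatenate([phen, extra.copy()])
        dos = off_genomes.dosages()
        tbv[ids] = qtl.tbv(dos[:, qtl.qtl_idx])
        phen[ids] = make_phenotypes(tbv[ids], design.residual_variance, rng)
        id_sex.update(zip(ids.tolist(), sex.tolist()))
        genotyped_ids.append(ids)
        genotype_blocks.append(dos)

        # keep parents + offspring available for the next selection round
        live_genomes = HaploidGenomes(
            genomes.loci,
            np.concatenate([parents_g.haplotypes, off_genomes.haplotypes], axis=0))
        live_row = {int(i): k for k, i in enumerate(np.concatenate([parent_ids, ids]))}

        if gen < design.recent_generations:
            ebv = solve_ebv()
            sires = _select_parents(ebv, sires, ids[sex == MALE],
                                    design.recent_sires, design.sire_replacement)
            dams = _select_parents(ebv, dams, ids[sex == FEMALE],
                                   design.recent_dams, design.dam_replacement)

    gids = np.concatenate(genotyped_ids)
    gmat = np.concatenate(genotype_blocks, axis=0)
    n = ped.n_animals
    last_ids = genotyped_ids[-1]
    final = HaploidGenomes(genomes.loci,
                           live_genomes.haplotypes[[live_row[int(i)] for i in last_ids]])
    return RecentPopulation(
        pedigree=ped, tbv=tbv[:n], phenotype=phen[:n],
        residual_variance=design.residual_variance,
        genotyped_ids=gids, genotypes=gmat, recorded_loci=genomes.loci,
        qtl=qtl, final_genomes=final)


# ---------------------------------------------------------------------------
# LD summaries


def mean_ld_r2(genotypes: np.ndarray, chrom: np.ndarray, pos_bp: np.ndarray,
               max_distance_bp: int = 50_000) -> tuple[float, int]:
    """Unweighted mean squared correlation of genotype dosages over all
    same-chromosome marker pairs closer than ``max_distance_bp``; pairs with
    a monomorphic member are skipped.  Returns (mean r^2, number of pairs)."""
    total, count = _ld_accumulate(genotypes, chrom, pos_bp, [0, max_distance_bp])
    if count[0] == 0:
        raise ValueError("no qualifying marker pairs")
    return float(total[0] / count[0]), int(count[0])


def ld_decay(genotypes: np.ndarray, chrom: np.ndarray, pos_bp: np.ndarray,
             bin_edges_bp: Sequence[int]) -> "pd.DataFrame":
    """Mean r^2 per distance bin (edges in bp)."""
    import pandas as pd
    total, count = _ld_accumulate(genotypes, chrom, pos_bp, list(bin_edges_bp))
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"bin_low_bp": bin_edges_bp[:-1], "bin_high_bp": bin_edges_bp[1:],
                         "mean_r2": mean, "n_pairs": count})


def _ld_accumulate(genotypes, chrom, pos_bp, edges):
    X = np.asarray(genotypes, dtype=np.float64)
    if X.shape[1] != len(pos_bp):
        raise ValueError("genotype columns must match positions")
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    nbin = len(edges) - 1
    total = np.zeros(nbin)
    count = np.zeros(nbin, dtype=np.int64)
    max_d = edges[-1]
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        p = pos_bp[cols]
        k = 1
        while k < len(cols):
            d = p[k:] - p[:-k]
            if d.min() >= max_d:
                break
            a, b = cols[:-k], cols[k:]
            ok = (d < max_d) & poly[a] & poly[b]
            if ok.any():
                ai, bi = a[ok], b[ok]
                r = (Xc[:, ai] * Xc[:, bi]).mean(axis=0) / (sd[ai] * sd[bi])
                bidx = np.searchsorted(edges, d[ok], side="right") - 1
                np.add.at(total, bidx, r * r)
                np.add.at(count, bidx, 1)
            k += 1
    return total, count
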