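"""Study orchestration: one replicate = population simulation -> GBS ->
QC -> prediction over the full (depth x MAF x variant) grid, plus
aggregation over replicates.

All data-set variants within a replicate share the same simulated
population, read depths and random genotype calls, so comparisons between
variants are paired.  Variants computed internally:

* ``GBS``       raw calls; missing mean-imputed before prediction
* ``Gc``        calls corrected to expected dosage (GBS-estimated allele
                frequencies); missing mean-imputed before prediction
* ``GcRounded`` the corrected dosages rounded back to genotype codes
* ``GBSr``      true genotypes at the GBS loci (benchmark)
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import gbs, popsim, qc
from .config import GenomeSpec, PopulationDesign, QCConfig, ScenarioConfig
from .gblup import SNPBLUP, evaluate, make_split

__all__ = ["SimulatedStudyPopulation", "simulate_population", "run_replicate",
           "aggregate", "replicate_rng"]

#: cluster of backup grid offsets tracked around every intended GBS
#: position, spanning the local scale over which fixation is correlated,
#: so that snapping to a segregating locus emulates the full dense grid.
CLUSTER_OFFSETS_BP = (0, -1000, 1000, -2500, 2500, -5000, 5000,
                      -10000, 10000, -30000, 30000)


@dataclass
class SimulatedStudyPopulation:
    """A simulated population with its finalized GBS panel.

    ``genotypes`` holds true genotype codes of the genotyped cohort (all
    recent-generation animals, rows aligned with ``genotyped_ids``) at the
    panel loci; ``phenotype`` covers every pedigree animal.
    """

    pedigree: "object"
    phenotype: np.ndarray
    genotyped_ids: np.ndarray
    panel_chrom: np.ndarray
    panel_pos: np.ndarray
    genotypes: np.ndarray
    generations: np.ndarray
    tbv: np.ndarray
    spec: GenomeSpec
    design: PopulationDesign
    scale: float
    n_intended: int

    @property
    def n_genotyped(self) -> int:
        return self.genotypes.shape[0]


def _build_tracked_loci(spec: GenomeSpec, intended_chrom, intended_pos,
                        rng: np.random.Generator) -> popsim.TrackedLoci:
    """Tracked = GBS placement clusters + random QTL positions."""
    sp_bp = spec.grid_spacing_bp
    max_grid = spec.chrom_length_bp // sp_bp
    chroms, poss = [], []
    for c in range(spec.n_chromosomes):
        base = intended_pos[intended_chrom == c]
        cand = (base[None, :] + np.asarray(CLUSTER_OFFSETS_BP)[:, None]).ravel()
        cand = np.clip(np.round(cand / sp_bp), 1, max_grid).astype(np.int64) * sp_bp
        cand = np.unique(cand)
        # QTL at random grid positions not colliding with candidates
        qtl = set()
        while len(qtl) < spec.n_qtl_per_chrom:
            draw = (rng.integers(1, max_grid + 1,
                                 size=spec.n_qtl_per_chrom - len(qtl))) * sp_bp
            qtl.update(int(x) for x in draw if x not in set(cand.tolist()))
        qtl = np.array(sorted(qtl), dtype=np.int64)
        allpos = np.concatenate([cand, qtl])
        flags = np.r_[np.zeros(len(cand), bool), np.ones(len(qtl), bool)]
        order = np.argsort(allpos, kind="stable")
        chroms.append(np.full(len(allpos), c, dtype=np.int16))
        poss.append((allpos[order], flags[order]))
    chrom = np.concatenate(chroms)
    pos = np.concatenate([p for p, _ in poss])
    is_qtl = np.concatenate([f for _, f in poss])
    return popsim.TrackedLoci(chrom, pos, is_qtl)


def simulate_population(spec: GenomeSpec, design: PopulationDesign,
                        rng: np.random.Generator, scale: float = 1.0,
                        distance_fractions=gbs.DEFAULT_DISTANCE_FRACTIONS,
                        ) -> SimulatedStudyPopulation:
    """Run the full forward simulation and finalize the GBS panel.

    ``scale`` < 1 shrinks the historical phases and breeding-design sizes
    (drift- and mutation-drift-preserving; see PopulationDesign.scaled and
    GenomeSpec.with_mutation_scaled).
    """
    d = design.scaled(scale)
    s = spec.with_mutation_scaled(scale) if scale != 1.0 else spec
    ic, ip = gbs.sample_gbs_positions(spec, rng, distance_fractions)
    loci = _build_tracked_loci(spec, ic, ip, rng)
    founders = popsim.init_founders(s, loci, d.hist_phase1_size, rng)
    hist = popsim.run_historical(s, d, founders, rng, mutation=True,
                                 map_scale=1.0 / scale)

    holder: dict = {}

    def panel_hook(genomes_expanded: popsim.HaploidGenomes) -> np.ndarray:
        # GBS loci are SNPs: each placement keeps its nearest loci
        # segregating in the expanded (SNP-discovery) cohort; the final
        # choice, after breeding, prefers the nearest one still polymorphic
        # in the genotyped cohort.
        freq = genomes_expanded.allele_frequencies()
        seg = (freq > 0) & (freq < 1) & ~genomes_expanded.loci.is_qtl
        cand = gbs.nearest_segregating_candidates(
            ic, ip, genomes_expanded.loci.chrom, genomes_expanded.loci.pos_bp,
            seg, k=3)
        holder["cand"] = cand
        return np.unique(cand[cand >= 0])

    pop = popsim.expand_and_breed_recent(s, d, hist, rng, panel_hook=panel_hook)
    cand = holder["cand"]
    # translate original tracked-locus indices to recorded-matrix columns
    key = loci.chrom.astype(np.int64) * (10 ** 10) + loci.pos_bp
    rec_key = pop.recorded_loci.chrom.astype(np.int64) * (10 ** 10) + pop.recorded_loci.pos_bp
    cand_cols = np.where(cand >= 0,
                         np.searchsorted(rec_key, key[np.clip(cand, 0, None)]), -1)
    counts = pop.genotypes.sum(axis=0, dtype=np.int64)
    poly = (counts > 0) & (counts < 2 * pop.genotypes.shape[0])
    # greedy assignment: each placement takes its nearest polymorphic
    # candidate not already claimed (on the dense real grid, neighbouring
    # placements essentially never need to share a locus)
    used = np.zeros(len(poly), dtype=bool)
    chosen = []
    for r in range(cand_cols.shape[0]):
        fallback = -1
        for col in cand_cols[r]:
            if col < 0 or not poly[col]:
                continue
            if not used[col]:
                used[col] = True
                chosen.append(col)
                fallback = -2
                break
            if fallback == -1:
                fallback = col
        # all polymorphic candidates taken: the placement collapses onto an
        # already-chosen locus (drop it, as deduplication would)
    cols = np.unique(np.asarray(chosen, dtype=np.int64))
    if len(cols) == 0:
        raise ValueError("empty GBS panel after polymorphism screening")
    genotypes = pop.genotypes[:, cols]
    gens = pop.genotyped_generations
    return SimulatedStudyPopulation(
        pedigree=pop.pedigree, phenotype=pop.phenotype,
        genotyped_ids=pop.genotyped_ids,
        panel_chrom=pop.recorded_loci.chrom[cols],
        panel_pos=pop.recorded_loci.pos_bp[cols],
        genotypes=genotypes, generations=gens,
        tbv=pop.tbv[pop.genotyped_ids], spec=spec, design=d, scale=scale,
        n_intended=len(ip))


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic per-replicate stream: (master_seed, replicate_index)
    fully determines every draw."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,)))


def _mean_impute_rows(data: np.ndarray, rows: np.ndarray,
                      col_means: np.ndarray) -> np.ndarray:
    """Mean-imputed float64 matrix for a row subset, with locus means taken
    from the whole cohort (missing = -1 for int input, NaN for float)."""
    x = np.asarray(data[rows], dtype=np.float64)
    if np.issubdtype(np.asarray(data).dtype, np.floating):
        miss = np.isnan(x)
    else:
        miss = data[rows] == gbs.MISSING
    x[miss] = np.broadcast_to(col_means, x.shape)[miss]
    return x


def _call_col_means(calls: np.ndarray) -> np.ndarray:
    ok = calls != gbs.MISSING
    cnt = ok.sum(axis=0)
    if np.any(cnt == 0):
        raise ValueError("locus with all calls missing")
    return np.where(ok, calls, 0).sum(axis=0) / cnt


def run_replicate(spec: GenomeSpec, design: PopulationDesign,
                  config: ScenarioConfig, replicate_index: int,
                  metric_cohort_size: int = 10_000) -> pd.DataFrame:
    """Execute the full grid for one replicate; returns one row per
    (depth, maf, variant) cell.

    Accuracy metrics are computed over a genotyped cohort of up to
    ``metric_cohort_size`` individuals (the imputation-cohort size of the
    study design); prediction uses the train/test split.
    """
    rng = replicate_rng(config.master_seed, replicate_index)
    pop = simulate_population(spec, design, rng, scale=config.scale_factor)
    n_g = pop.n_genotyped
    if n_g > metric_cohort_size:
        mrows = np.sort(rng.choice(n_g, size=metric_cohort_size, replace=False))
    else:
        mrows = np.arange(n_g)
    truth = pop.genotypes[mrows]
    rows = []
    split = None
    if config.predict:
        split = make_split(pop.generations, rng,
                           train_size=config.train_size,
                           test_size=config.test_size)
        train_y = pop.phenotype[pop.genotyped_ids[split.training_ids]]
        test_tbv = pop.tbv[split.test_ids]

    for depth in config.depths:
        # one draw of reads and calls for the whole genotyped cohort, so the
        # metric cohort and the train/test split see the same GBS data
        depths_all = gbs.simulate_depths(n_g, pop.genotypes.shape[1], depth, rng)
        calls_all = gbs.call_genotypes(pop.genotypes, depths_all, rng)
        if config.mask_reads_upto:
            calls_all = gbs.mask_low_reads(calls_all, depths_all, config.mask_reads_upto)
        depths_m, calls_m = depths_all[mrows], calls_all[mrows]
        if config.predict:
            pred_rows = np.concatenate([split.training_ids, split.test_ids])
            depths_p, calls_p = depths_all[pred_rows], calls_all[pred_rows]
            truth_p = pop.genotypes[pred_rows]
        del depths_all, calls_all
        for maf in config.maf_criteria:
            mask = qc.apply_qc(calls_m, QCConfig(maf_threshold=maf))
            kl = mask.kept_loci
            c_k, d_k, t_k = calls_m[:, kl], depths_m[:, kl], truth[:, kl]
            variant_data = {}
            p_hat = None
            if any(v.startswith("Gc") for v in config.variants):
                p_hat = gbs.estimate_freq_from_gbs(c_k)
                gc_m = gbs.corrected_dosage_matrix(c_k, d_k, p_hat)
            for variant in config.variants:
                if variant == "GBS":
                    data = c_k
                elif variant == "Gc":
                    data = gc_m
                elif variant == "GcRounded":
                    data = gbs.round_dosages(gc_m)
                elif variant == "GBSr":
                    data = t_k.astype(np.int8)
                else:
                    raise ValueError(f"unknown variant {variant!r}")
                try:
                    acc = gbs.accuracy_summary(data, t_k)
                    acc_fields = dataclasses.asdict(acc)
                except ValueError:
                    acc_fields = dict(missing_rate=np.nan, incorrect_rate=np.nan,
                                      correct_rate=np.nan, correlation=np.nan,
                                      n_entries=t_k.size)
                row = dict(replicate=replicate_index, depth=depth,
                           maf="none" if maf is None else maf, variant=variant,
                           n_loci_kept=len(kl), **acc_fields)
                if config.predict:
                    n_tr = len(split.training_ids)
                    cp_k = calls_p[:, kl]
                    if variant == "GBSr":
                        M = truth_p[:, kl].astype(np.float64)
                    elif variant == "GBS":
                        M = _mean_impute_rows(cp_k, np.arange(len(pred_rows)),
                                              _call_col_means(c_k))
                    else:
                        gc_p = gbs.corrected_dosage_matrix(
                            cp_k, depths_p[:, kl], p_hat)
                        if variant == "GcRounded":
                            gc_p = gbs.round_dosages(gc_p).astype(np.float64)
                            gc_p[gc_p < 0] = np.nan
                            ref = gbs.round_dosages(gc_m).astype(np.float64)
                            ref[ref < 0] = np.nan
                        else:
                            ref = gc_m
                        cnt = np.isfinite(ref).sum(axis=0)
                        means = np.nansum(ref, axis=0) / cnt
                        M = np.where(np.isnan(gc_p),
                                     np.broadcast_to(means, gc_p.shape),
                                     gc_p).astype(np.float64)
                    model = SNPBLUP(h2=design.heritability,
                                    var_p=design.phenotypic_variance)
                    model.fit(M[:n_tr], train_y)
                    gebv = model.gebv(M[n_tr:])
                    metrics = evaluate(gebv, test_tbv)
                    row.update(reliability=metrics.reliability,
                               slope_b=metrics.slope_b)
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean, SD and SE per grid cell over replicates (identical grids only)."""
    if not replicates:
        raise ValueError("no replicates to aggregate")
    keys = ["depth", "maf", "variant"]
    grids = [tuple(map(tuple, r[keys].drop_duplicates().values)) for r in replicates]
    if len(set(grids)) != 1:
        raise ValueError("replicates cover different grids")
    df = pd.concat(replicates, ignore_index=True)
    metrics = [c for c in df.columns
               if c not in keys + ["replicate"] and np.issubdtype(df[c].dtype, np.number)]
    n = df.groupby(keys, sort=False)["replicate"].nunique().rename("n_replicates")
    agg = df.groupby(keys, sort=False)[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    out = agg.join(n).reset_index()
    for m in metrics:
        sd = out[f"{m}_std"].fillna(0.0)
        out[f"{m}_std"] = sd
        out[f"{m}_se"] = sd / np.sqrt(out["n_replicates"])
    return out
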