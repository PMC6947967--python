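"""Genotyping-by-sequencing data generation, correction and accuracy metrics.

Read depth per individual x locus is Poisson with the scenario mean; zero
reads means a missing genotype.  With no sequencing error, called
homozygotes equal the truth; a true heterozygote covered by n reads shows
only one allele with probability 2 * (1/2)^n and is then miscalled
homozygous (aa or AA with equal probability (1/2)^n each).

Called homozygotes are corrected to their posterior-expected dosage
("genotype correction", Gc) under Hardy-Weinberg priors with the
locus allele frequency p:

    Gc_aa = 2pq (1/2)^n / (q^2 + 2pq (1/2)^n)
    Gc_AA = (2p^2 + 2pq (1/2)^n) / (p^2 + 2pq (1/2)^n)
    Gc_Aa = 1

Genotype codes throughout: aa=0, Aa=1, AA=2; missing is -1 in integer
call matrices and NaN in dosage matrices.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import GenomeSpec

MISSING = -1

#: Inter-locus distance distribution of GBS SNPs (bp -> probability).
DEFAULT_DISTANCE_FRACTIONS: Tuple[Tuple[int, float], ...] = (
    (500, 0.13), (2500, 0.08), (7500, 0.08), (15_000, 0.12), (25_000, 0.09),
    (35_000, 0.06), (45_000, 0.05), (75_000, 0.16), (125_000, 0.07), (200_000, 0.16),
)

__all__ = [
    "MISSING", "DEFAULT_DISTANCE_FRACTIONS", "GBSPanel", "AccuracySummary",
    "mean_gap_bp", "sample_gbs_positions", "snap_to_segregating",
    "simulate_depths", "call_genotypes", "mask_low_reads", "correct_genotypes",
    "round_dosages", "estimate_freq_from_gbs", "accuracy_summary",
]


@dataclass(frozen=True)
class GBSPanel:
    """GBS locus coordinates plus their column indices into a genotype
    matrix over tracked loci."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    locus_idx: np.ndarray

    def __post_init__(self):
        if not (len(self.chrom) == len(self.pos_bp) == len(self.locus_idx)):
            raise ValueError("panel arrays must be parallel")

    def __len__(self) -> int:
        return len(self.pos_bp)


def _validate_fractions(fractions) -> tuple[np.ndarray, np.ndarray]:
    dist = np.array([d for d, _ in fractions], dtype=np.int64)
    prob = np.array([p for _, p in fractions], dtype=np.float64)
    if np.any(prob < 0) or not np.isclose(prob.sum(), 1.0, atol=1e-9):
        raise ValueError("distance fractions must be non-negative and sum to 1")
    return dist, prob


def mean_gap_bp(fractions=DEFAULT_DISTANCE_FRACTIONS) -> float:
    dist, prob = _validate_fractions(fractions)
    return float((dist * prob).sum())


def sample_gbs_positions(spec: GenomeSpec, rng: np.random.Generator,
                         fractions=DEFAULT_DISTANCE_FRACTIONS
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw intended GBS locus positions along each chromosome.

    The first locus sits at a random offset within a first drawn gap; each
    subsequent locus adds an independent gap from the fraction table.
    Positions are snapped to the evenly spaced marker grid.  Returns
    (chrom, pos_bp) arrays.
    """
    dist, prob = _validate_fractions(fractions)
    L = spec.chrom_length_bp
    if L < dist.min():
        raise ValueError("chromosome shorter than the smallest gap")
    chroms, positions = [], []
    sp_bp = spec.grid_spacing_bp
    for c in range(spec.n_chromosomes):
        pos = rng.uniform(0.0, float(rng.choice(dist, p=prob)))
        out = []
        while pos < L:
            snapped = int(np.clip(round(pos / sp_bp), 1, L // sp_bp)) * sp_bp
            out.append(snapped)
            pos += float(rng.choice(dist, p=prob))
        if not out:
            raise ValueError("no GBS loci placed on chromosome %d" % c)
        out = np.unique(np.asarray(out, dtype=np.int64))
        chroms.append(np.full(len(out), c, dtype=np.int16))
        positions.append(out)
    return np.concatenate(chroms), np.concatenate(positions)


def nearest_segregating_candidates(intended_chrom: np.ndarray,
                                   intended_pos: np.ndarray,
                                   loci_chrom: np.ndarray, loci_pos: np.ndarray,
                                   segregating: np.ndarray, k: int = 2,
                                   max_snap_bp: int = 50_000) -> np.ndarray:
    """For each intended GBS position, the ``k`` nearest segregating tracked
    loci on the same chromosome within ``max_snap_bp``, ordered by distance
    (ties toward the left).  Returns an (n_intended, k) array of locus
    indices, -1-padded where fewer candidates exist."""
    n = len(intended_pos)
    out = np.full((n, k), -1, dtype=np.int64)
    for c in np.unique(intended_chrom):
        sel = np.flatnonzero(intended_chrom == c)
        want = intended_pos[sel]
        cand = np.flatnonzero((loci_chrom == c) & segregating)
        if len(cand) == 0:
            continue
        cpos = loci_pos[cand]
        j = np.searchsorted(cpos, want)
        # window of 2k neighbours around the insertion point
        offs = np.arange(-k, k)
        idx = np.clip(j[:, None] + offs[None, :], 0, len(cpos) - 1)
        dist = np.abs(cpos[idx] - want[:, None]).astype(np.float64)
        dist[dist > max_snap_bp] = np.inf
        # de-duplicate clipped repeats within each row
        for r in range(len(want)):
            _, first = np.unique(idx[r], return_index=True)
            dup = np.ones(2 * k, dtype=bool)
            dup[first] = False
            dist[r, dup] = np.inf
        order = np.argsort(dist, axis=1, kind="stable")[:, :k]
        picked = np.take_along_axis(idx, order, axis=1)
        d_sorted = np.take_along_axis(dist, order, axis=1)
        picked = np.where(np.isinf(d_sorted), -1, cand[picked])
        out[sel] = picked
    return out


def snap_to_segregating(intended_chrom: np.ndarray, intended_pos: np.ndarray,
                        loci_chrom: np.ndarray, loci_pos: np.ndarray,
                        segregating: np.ndarray,
                        max_snap_bp: int = 50_000) -> GBSPanel:
    """Map each intended GBS position to the nearest segregating tracked
    marker locus on the same chromosome (within ``max_snap_bp``); intended
    positions with no nearby segregating locus are dropped, and duplicate
    hits are collapsed."""
    chosen = []
    for c in np.unique(intended_chrom):
        cand = np.flatnonzero((loci_chrom == c) & segregating)
        if len(cand) == 0:
            continue
        cpos = loci_pos[cand]
        want = intended_pos[intended_chrom == c]
        j = np.searchsorted(cpos, want)
        left = np.clip(j - 1, 0, len(cpos) - 1)
        right = np.clip(j, 0, len(cpos) - 1)
        d_left = np.abs(cpos[left] - want)
        d_right = np.abs(cpos[right] - want)
        pick = np.where(d_right < d_left, right, left)
        dist = np.minimum(d_left, d_right)
        pick = pick[dist <= max_snap_bp]
        chosen.append(cand[pick])
    if not chosen:
        raise ValueError("empty GBS panel: no segregating loci near intended positions")
    idx = np.unique(np.concatenate(chosen))
    return GBSPanel(chrom=loci_chrom[idx], pos_bp=loci_pos[idx], locus_idx=idx)


# ---------------------------------------------------------------------------
# reads and calling


def simulate_depths(n_individuals: int, n_loci: int, mean_depth: float,
                    rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Poisson(mean_depth) read counts, (n_individuals, n_loci) int16."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    return rng.poisson(mean_depth, size=(n_individuals, n_loci)).astype(np.int16)


def _het_call(u: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Calling rule for true heterozygotes with n >= 1 reads and uniform
    draw u: aa if u <= (1/2)^n, AA if (1/2)^n < u < 2(1/2)^n, else Aa."""
    thr = np.power(0.5, n.astype(np.float64))
    return np.where(u <= thr, 0, np.where(u < 2.0 * thr, 2, 1)).astype(np.int8)


def call_genotypes(true_genotypes: np.ndarray, depths: np.ndarray,
                   rng: np.random.Generator, chunk_loci: int = 2048) -> np.ndarray:
    """GBS genotype calls: missing at zero reads, homozygotes called
    truthfully, heterozygotes subject to the one-allele-only miscall rule."""
    truth = np.asarray(true_genotypes)
    depths = np.asarray(depths)
    if truth.shape != depths.shape:
        raise ValueError("genotype and depth matrices must have equal shape")
    if depths.min() < 0:
        raise ValueError("negative read counts")
    calls = truth.astype(np.int8)
    calls[depths == 0] = MISSING
    for j0 in range(0, truth.shape[-1], chunk_loci):
        sl = (..., slice(j0, min(j0 + chunk_loci, truth.shape[-1])))
        het = (truth[sl] == 1) & (depths[sl] > 0)
        if het.any():
            u = rng.random(int(het.sum()))
            block = calls[sl]
            block[het] = _het_call(u, depths[sl][het])
            calls[sl] = block
    return calls


def mask_low_reads(calls: np.ndarray, depths: np.ndarray,
                   max_masked_reads: int) -> np.ndarray:
    """Set entries with 1 <= reads <= max_masked_reads to missing."""
    if max_masked_reads < 0:
        raise ValueError("max_masked_reads must be >= 0")
    out = calls.copy()
    if max_masked_reads >= 1:
        out[(depths >= 1) & (depths <= max_masked_reads)] = MISSING
    return out


# ---------------------------------------------------------------------------
# genotype correction


def correct_genotypes(calls: np.ndarray, depths: np.ndarray,
                      p: np.ndarray) -> np.ndarray:
    """Bayesian correction of called homozygotes to expected dosage.

    ``p`` is the per-locus frequency of allele A.  Heterozygote calls stay
    exactly 1, missing stays missing (NaN).  Degenerate frequencies
    collapse the dosage: p = 0 -> 0, p = 1 -> 2.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    calls = np.asarray(calls)
    q = 1.0 - p
    t = np.power(0.5, np.asarray(depths, dtype=np.float64))
    het_mass = 2.0 * p * q * t
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_aa = het_mass / (q * q + het_mass)
        gc_AA = (2.0 * p * p + het_mass) / (p * p + het_mass)
    # degenerate frequencies: no heterozygote prior mass, dosage collapses
    gc_aa = np.where(p == 0, 0.0, np.where(p == 1, 2.0, gc_aa))
    gc_AA = np.where(p == 1, 2.0, np.where(p == 0, 0.0, gc_AA))
    out = np.full(calls.shape, np.nan)
    out[calls == 1] = 1.0
    aa = calls == 0
    AA = calls == 2
    out[aa] = np.broadcast_to(gc_aa, calls.shape)[aa]
    out[AA] = np.broadcast_to(gc_AA, calls.shape)[AA]
    return out


def corrected_dosage_matrix(calls: np.ndarray, depths: np.ndarray,
                            p: np.ndarray, dtype=np.float32,
                            chunk_loci: int = 1024) -> np.ndarray:
    """Genotype correction over a large matrix, built block-wise to keep
    the temporaries small; see :func:`correct_genotypes`."""
    out = np.empty(calls.shape, dtype=dtype)
    for j0 in range(0, calls.shape[1], chunk_loci):
        sl = slice(j0, min(j0 + chunk_loci, calls.shape[1]))
        out[:, sl] = correct_genotypes(calls[:, sl], depths[:, sl], p[sl])
    return out


def round_dosages(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to genotype codes; NaN stays missing (-1).

    Ties round away from 1 (0.5 -> 0, 1.5 -> 2); because corrected aa
    dosages lie in [0, 1] and AA dosages in [1, 2], this resolves ties
    toward the originally called homozygote.
    """
    d = np.asarray(dosages, dtype=np.float64)
    finite = np.isfinite(d)
    if np.any((d[finite] < -1e-9) | (d[finite] > 2 + 1e-9)):
        raise ValueError("dosages out of [0, 2]")
    out = np.full(d.shape, MISSING, dtype=np.int8)
    out[finite] = (d[finite] > 0.5).astype(np.int8) + (d[finite] >= 1.5).astype(np.int8)
    return out


def estimate_freq_from_gbs(calls: np.ndarray,
                           on_all_missing: str = "error") -> np.ndarray:
    """Allele-A frequency per locus from called genotypes:
    p = (P(GBS_AA) - P(GBS_aa) + 1) / 2 among non-missing calls, clamped to
    [0, 1].  The heterozygote-miscall inflation of both homozygote classes
    cancels in the difference, so the estimator is unbiased."""
    calls = np.asarray(calls)
    non_missing = (calls != MISSING).sum(axis=0)
    if np.any(non_missing == 0):
        if on_all_missing == "error":
            raise ValueError("locus with all calls missing")
        if on_all_missing != "nan":
            raise ValueError("on_all_missing must be 'error' or 'nan'")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_AA = (calls == 2).sum(axis=0) / non_missing
        p_aa = (calls == 0).sum(axis=0) / non_missing
        p = (p_AA - p_aa + 1.0) / 2.0
    p = np.clip(p, 0.0, 1.0)
    p[non_missing == 0] = np.nan
    return p


# ---------------------------------------------------------------------------
# accuracy metrics


@dataclass(frozen=True)
class AccuracySummary:
    """Entry-pooled accuracy of a genotype matrix against the truth.

    Rates partition all individual x locus entries: missing, non-missing
    and wrong (after rounding dosages), non-missing and correct.  The
    correlation pools all entries, with missing entries replaced by the
    locus mean of non-missing values (mirroring the mean imputation used
    before prediction) or dropped, per ``missing_policy``.
    """

    missing_rate: float
    incorrect_rate: float
    correct_rate: float
    correlation: float
    n_entries: int


def _as_float_with_nan(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    out = data.astype(np.float64)
    out[data == MISSING] = np.nan
    return out


def accuracy_summary(data: np.ndarray, true_genotypes: np.ndarray,
                     missing_policy: str = "mean",
                     chunk_loci: int = 1024) -> AccuracySummary:
    """Missing/incorrect/correct rates and pooled Pearson correlation of a
    called or dosage matrix versus the true genotype codes.

    Processes locus blocks and pools sufficient statistics, so large
    cohorts never materialise extra full-size float copies.
    """
    if missing_policy not in ("mean", "drop"):
        raise ValueError("missing_policy must be 'mean' or 'drop'")
    data = np.asarray(data)
    truth_all = np.asarray(true_genotypes)
    if data.shape != truth_all.shape:
        raise ValueError("shape mismatch between data and truth")
    n = data.size
    n_miss = n_wrong = n_correct = 0
    n_used = 0
    s_x = s_t = s_xx = s_tt = s_xt = 0.0
    for j0 in range(0, data.shape[1], chunk_loci):
        sl = slice(j0, min(j0 + chunk_loci, data.shape[1]))
        x = _as_float_with_nan(data[:, sl])
        truth = truth_all[:, sl].astype(np.float64)
        miss = np.isnan(x)
        rounded = round_dosages(np.where(miss, np.nan, x))
        wrong = (~miss) & (rounded != truth)
        correct = (~miss) & (rounded == truth)
        n_miss += int(miss.sum())
        n_wrong += int(wrong.sum())
        n_correct += int(correct.sum())
        if missing_policy == "mean":
            cnt = (~miss).sum(axis=0)
            if np.any(cnt == 0):
                raise ValueError("locus with all entries missing")
            col_mean = np.where(miss, 0.0, x).sum(axis=0) / cnt
            xf = np.where(miss, np.broadcast_to(col_mean, x.shape), x).ravel()
            tf = truth.ravel()
        else:
            xf = x[~miss]
            tf = truth[~miss]
        n_used += xf.size
        s_x += float(xf.sum()); s_t += float(tf.sum())
        s_xx += float(xf @ xf); s_tt += float(tf @ tf); s_xt += float(xf @ tf)
    var_x = s_xx - s_x * s_x / n_used
    var_t = s_tt - s_t * s_t / n_used
    if var_x <= 0 or var_t <= 0:
        raise ValueError("zero variance: correlation undefined")
    corr = (s_xt - s_x * s_t / n_used) / np.sqrt(var_x * var_t)
    return AccuracySummary(
        missing_rate=n_miss / n,
        incorrect_rate=n_wrong / n,
        correct_rate=n_correct / n,
        correlation=float(corr),
        n_entries=int(n),
    )
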