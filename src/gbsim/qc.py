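"""Marker editing: call-rate and MAF filters, mean imputation, panel masks.

Filters operate on called genotype matrices (missing = -1) and return
index masks so the same edit can be applied to every derived data set
(raw calls, corrected dosages, true genotypes) of the paired design.
Monomorphic loci are always removed, including under "no MAF limit":
zero-variance columns carry no information for prediction and break
correlation metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import QCConfig
from .gbs import MISSING

__all__ = ["PanelMask", "call_rate_filter", "maf_filter", "allele_counting_maf",
           "mean_impute", "apply_qc"]


@dataclass(frozen=True)
class PanelMask:
    """Ordered kept-index sets with filter provenance."""

    kept_loci: np.ndarray
    kept_individuals: np.ndarray
    provenance: tuple = ()

    def compose(self, other: "PanelMask") -> "PanelMask":
        """Apply ``other`` (expressed in this mask's coordinates) after this."""
        return PanelMask(
            kept_loci=self.kept_loci[other.kept_loci],
            kept_individuals=self.kept_individuals[other.kept_individuals],
            provenance=self.provenance + other.provenance,
        )


def call_rate_filter(calls: np.ndarray, config: Optional[QCConfig] = None) -> PanelMask:
    """Drop loci (and/or individuals, per the configured axis) whose
    non-missing fraction falls below the call-rate threshold."""
    config = config or QCConfig()
    calls = np.asarray(calls)
    n_ind, n_loc = calls.shape
    ok = calls != MISSING
    kept_loci = np.arange(n_loc)
    kept_ind = np.arange(n_ind)
    thr = config.call_rate_threshold
    if config.call_rate_axis in ("loci", "both"):
        kept_loci = np.flatnonzero(ok.mean(axis=0) >= thr)
    if config.call_rate_axis in ("individuals", "both"):
        kept_ind = np.flatnonzero(ok.mean(axis=1) >= thr)
    if len(kept_loci) == 0 or len(kept_ind) == 0:
        raise ValueError("call-rate filter removed everything")
    return PanelMask(kept_loci, kept_ind,
                     (("call_rate", thr, config.call_rate_axis),))


def allele_counting_maf(calls: np.ndarray) -> np.ndarray:
    """MAF per locus by allele counting over non-missing called genotypes."""
    calls = np.asarray(calls)
    non_missing = (calls != MISSING).sum(axis=0)
    counts = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / (2.0 * non_missing)
    p = np.where(non_missing == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def maf_filter(calls: np.ndarray, threshold: Optional[float]) -> PanelMask:
    """Drop loci below the MAF threshold (computed on called genotypes).

    ``threshold`` None means "no MAF limit": only monomorphic loci (MAF = 0
    in the called data) are removed.
    """
    maf = allele_counting_maf(calls)
    thr = 0.0 if threshold is None else float(threshold)
    with np.errstate(invalid="ignore"):
        keep = (maf > 0.0) & (maf >= thr)
    kept = np.flatnonzero(keep)
    n_ind = np.asarray(calls).shape[0]
    return PanelMask(kept, np.arange(n_ind), (("maf", threshold),))


def apply_qc(calls: np.ndarray, config: QCConfig) -> PanelMask:
    """Fixed filter order: call rate first, then MAF."""
    m1 = call_rate_filter(calls, config)
    sub = np.asarray(calls)[np.ix_(m1.kept_individuals, m1.kept_loci)]
    m2 = maf_filter(sub, config.maf_threshold)
    return m1.compose(m2)


def mean_impute(calls: np.ndarray) -> np.ndarray:
    """Replace missing entries by the locus mean of non-missing calls,
    yielding a dosage matrix; non-missing entries are unchanged.  Accepts
    integer call matrices (missing = -1) or dosage matrices (missing = NaN).
    """
    x = np.asarray(calls, dtype=np.float64)
    if not np.issubdtype(np.asarray(calls).dtype, np.floating):
        x = np.where(np.asarray(calls) == MISSING, np.nan, x)
    miss = np.isnan(x)
    cnt = (~miss).sum(axis=0)
    if np.any(cnt == 0):
        raise ValueError("locus with all entries missing cannot be mean-imputed")
    col_mean = np.where(miss, 0.0, x).sum(axis=0) / cnt
    return np.where(miss, np.broadcast_to(col_mean, x.shape), x)
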