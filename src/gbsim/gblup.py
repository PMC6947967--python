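"""SNP-BLUP genomic prediction.

Fits y = 1*mu + M*g + e with g ~ N(0, I*sigma_g^2), e ~ N(0, I*sigma_e^2).
With variance components fixed, the posterior mean of g solves the ridge
system [Mc' Mc + lambda I] g = Mc' (y - mu), lambda = sigma_e^2/sigma_g^2,
where Mc is the training-mean-centred genotype matrix.  By default the
marker variance is derived from the trait heritability:
sigma_g^2 = h2 * var_p / sum_j 2 p_j (1 - p_j), sigma_e^2 = (1 - h2) * var_p.

``SNPBLUP`` is a scikit-learn-compatible estimator (fit/predict,
get_params/set_params); GEBVs equal GBLUP breeding values with the
marker-derived kinship Mc Mc' / sum 2pq, which the test-suite uses as an
independent oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["SNPBLUP", "PredictionMetrics", "TrainTestSplit", "make_split", "evaluate"]


class SNPBLUP(RegressorMixin, BaseEstimator):
    """Ridge-type SNP-BLUP with heritability-derived shrinkage.

    Parameters
    ----------
    h2, var_p:
        Trait heritability and phenotypic variance used to fix the variance
        components when ``lam`` is not given.
    lam:
        Explicit shrinkage ratio sigma_e^2 / sigma_g^2; overrides h2/var_p.
    solver:
        "auto" picks the primal normal equations when loci <= records and
        the dual (records x records) form otherwise.
    """

    def __init__(self, h2: float = 0.3, var_p: float = 1.0,
                 lam: Optional[float] = None, solver: str = "auto"):
        self.h2 = h2
        self.var_p = var_p
        self.lam = lam
        self.solver = solver

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_records, n_loci) matching y")
        if not np.isfinite(X).all():
            raise ValueError("genotype matrix contains non-finite entries "
                             "(impute missing genotypes first)")
        if not np.isfinite(y).all():
            raise ValueError("phenotypes must be finite")
        n, m = X.shape
        self.column_means_ = X.mean(axis=0)
        Xc = X - self.column_means_
        self.mu_ = float(y.mean())
        yc = y - self.mu_
        p_hat = self.column_means_ / 2.0
        self.sum_2pq_ = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
        if self.lam is not None:
            lam = float(self.lam)
            self.sigma_g2_ = np.nan
            self.sigma_e2_ = np.nan
        else:
            if not 0.0 < self.h2 < 1.0:
                raise ValueError("h2 must lie in (0, 1)")
            if self.sum_2pq_ <= 0:
                raise ValueError("all loci monomorphic: marker variance undefined")
            self.sigma_g2_ = self.h2 * self.var_p / self.sum_2pq_
            self.sigma_e2_ = (1.0 - self.h2) * self.var_p
            lam = self.sigma_e2_ / self.sigma_g2_
        if lam <= 0:
            raise ValueError("shrinkage ratio must be positive")
        self.lambda_ = lam
        solver = self.solver
        if solver == "auto":
            solver = "primal" if m <= n else "dual"
        if solver == "primal":
            lhs = Xc.T @ Xc
            lhs[np.diag_indices(m)] += lam
            self.coef_ = sla.cho_solve(sla.cho_factor(lhs, overwrite_a=True),
                                       Xc.T @ yc)
        elif solver == "dual":
            K = Xc @ Xc.T
            K[np.diag_indices(n)] += lam
            alpha = sla.cho_solve(sla.cho_factor(K, overwrite_a=True), yc)
            self.coef_ = Xc.T @ alpha
        else:
            raise ValueError("solver must be 'auto', 'primal' or 'dual'")
        self.n_features_in_ = m
        return self

    def gebv(self, X) -> np.ndarray:
        """Genomic breeding values (M - training means) @ g."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("locus mismatch with the fitted model")
        return (X - self.column_means_) @ self.coef_

    def predict(self, X) -> np.ndarray:
        return self.mu_ + self.gebv(X)


@dataclass(frozen=True)
class PredictionMetrics:
    """Reliability = r^2(GEBV, TBV); slope of the TBV-on-GEBV regression."""

    reliability: float
    slope_b: float
    n: int


def evaluate(gebv: np.ndarray, tbv: np.ndarray) -> PredictionMetrics:
    gebv = np.asarray(gebv, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if gebv.shape != tbv.shape:
        raise ValueError("GEBV and TBV must cover the same individuals")
    if gebv.std() == 0 or tbv.std() == 0:
        raise ValueError("zero variance: metrics undefined")
    r = float(np.corrcoef(gebv, tbv)[0, 1])
    slope = float(np.cov(tbv, gebv)[0, 1] / gebv.var(ddof=1))
    return PredictionMetrics(reliability=r * r, slope_b=slope, n=len(gebv))


@dataclass(frozen=True)
class TrainTestSplit:
    training_ids: np.ndarray
    test_ids: np.ndarray


def make_split(generations: np.ndarray, rng: np.random.Generator,
               train_size: int = 7500, test_size: int = 2500,
               train_generations: Tuple[int, int] = (6, 9),
               test_generation: int = 10,
               ids: Optional[np.ndarray] = None) -> TrainTestSplit:
    """Training set sampled from recent generations 6-9, test set from
    generation 10; uniform subsampling without replacement when the
    candidate pools exceed the target sizes."""
    generations = np.asarray(generations)
    ids = np.arange(len(generations)) if ids is None else np.asarray(ids)
    lo, hi = train_generations
    train_pool = ids[(generations >= lo) & (generations <= hi)]
    test_pool = ids[generations == test_generation]
    if len(train_pool) < train_size or len(test_pool) < test_size:
        raise ValueError("candidate pools smaller than the requested split")
    train = train_pool if len(train_pool) == train_size else np.sort(
        rng.choice(train_pool, size=train_size, replace=False))
    test = test_pool if len(test_pool) == test_size else np.sort(
        rng.choice(test_pool, size=test_size, replace=False))
    return TrainTestSplit(training_ids=train, test_ids=test)
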