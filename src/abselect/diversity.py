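"""Diversity-accumulation curves and the power-law read-depth model.

Diversity D (unique ROI values, or clusters after re-clustering a subsample)
is measured on seeded random subsamples of the read pool, and the number of
reads needed to reach a diversity target is modelled as

    reads = C * D**k

fit by nonlinear least squares with reads as the response, initialised from
the log-log linear regression.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin


def accumulation_curve(
    read_values: Sequence[str],
    depths: Sequence[int],
    replicates: int = 5,
    seed: int = 0,
    diversity_fn: Callable[[Sequence[str]], int] | None = None,
) -> pd.DataFrame:
    """Diversity at seeded random subsamples of the per-read ROI values.

    For each replicate one permutation of the reads is drawn and every depth
    is a prefix of it, so diversity is non-decreasing in depth within a
    replicate and the whole curve is reproducible for a fixed seed.
    ``diversity_fn`` maps a subsample to a diversity (default: number of
    distinct values; pass a clustering counter for cluster-unit curves).

    Returns a frame with columns reads, replicate, diversity.
    """
    values = np.asarray(read_values, dtype=object)
    n = len(values)
    depths = sorted(int(d) for d in depths)
    if not depths or depths[0] < 1:
        raise ValueError("depths must be positive")
    if depths[-1] > n:
        raise ValueError(f"depth {depths[-1]} exceeds the {n} available reads")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if diversity_fn is None:
        diversity_fn = lambda sub: len(set(sub))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        perm = values[rng.permutation(n)]
        for depth in depths:
            rows.append((depth, rep, int(diversity_fn(perm[:depth]))))
    return pd.DataFrame(rows, columns=["reads", "replicate", "diversity"])


def default_depth_grid(n_reads: int, n_depths: int = 10, lo: int = 100) -> list[int]:
    """Log-spaced depth grid from ``lo`` to the dataset size."""
    lo = min(lo, n_reads)
    grid = np.unique(np.round(np.geomspace(lo, n_reads, n_depths)).astype(int))
    return grid.tolist()


def _power(D, C, k):
    return C * np.power(D, k)


class PowerLawModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of reads = C * D**k.

    Attributes (after fit): ``C_``, ``k_``, ``converged_`` (False when the
    nonlinear fit failed and the log-log estimate was kept), ``residuals_``
    (reads-scale), ``n_points_``.
    """

    def fit(self, X, y):
        """Fit with diversity as X (1-d) and sampled read numbers as y."""
        D = np.asarray(X, dtype=float).ravel()
        reads = np.asarray(y, dtype=float).ravel()
        if D.shape != reads.shape:
            raise ValueError("diversity and reads must align")
        if np.unique(D).size < 3:
            raise ValueError("need at least 3 distinct diversity values")
        if np.any(D <= 0) or np.any(reads <= 0):
            raise ValueError("diversity and reads must be positive")
        # log-log linear regression initialisation
        slope, intercept = np.polyfit(np.log(D), np.log(reads), 1)
        C0, k0 = float(np.exp(intercept)), float(slope)
        try:
            (C, k), _ = curve_fit(
                _power, D, reads, p0=(C0, k0), maxfev=10000,
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            )
            self.converged_ = True
        except RuntimeError:
            C, k = max(C0, 1e-12), max(k0, 1e-12)
            self.converged_ = False
        self.C_, self.k_ = float(C), float(k)
        self.residuals_ = reads - _power(D, self.C_, self.k_)
        self.n_points_ = int(D.size)
        return self

    def predict(self, X) -> np.ndarray:
        D = np.asarray(X, dtype=float).ravel()
        return _power(D, self.C_, self.k_)

    def reads_required(self, target_diversity: int) -> int:
        """Predicted read number for a diversity target, rounded up."""
        if target_diversity < 1:
            raise ValueError("target diversity must be >= 1")
        return int(np.ceil(_power(float(target_diversity), self.C_, self.k_)))


def fit_power(points: pd.DataFrame) -> PowerLawModel:
    """Fit the power model to an accumulation-curve frame (reads, diversity)."""
    return PowerLawModel().fit(points["diversity"].to_numpy(),
                               points["reads"].to_numpy())


def reads_required(fit: PowerLawModel, target_diversity: int) -> int:
    return fit.reads_required(target_diversity)
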