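"""Cross-task prediction of stimulation-specific deltas.

Per-subject taVNS-minus-sham differences (deltas) of spectra or pupil
series from one task are averaged within significant clusters and used as
subject-level predictors of the other task's delta profile, tested
point-by-point under CBPT.  With one delta value per subject and point,
the per-point model reduces to a regression across subjects (the random
intercept is absorbed by the residual); the permutation shuffles the
predictor assignment across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cbpt import Cluster, PermScheme, form_clusters, max_cluster_mass, cluster_p

__all__ = ["DeltaSeries", "compute_deltas", "cluster_average_delta",
           "predict_across"]


@dataclass
class DeltaSeries:
    """Per-subject taVNS-minus-sham values over one axis."""

    axis: np.ndarray                 # time (s) or frequency (Hz)
    delta: pd.DataFrame              # subjects x points
    source: str = ""

    def __post_init__(self) -> None:
        if self.delta.shape[1] != self.axis.size:
            raise ValueError("delta width must match axis length")


def compute_deltas(values: Dict[int, Dict[int, np.ndarray]], axis: np.ndarray,
                   source: str = "") -> DeltaSeries:
    """Pointwise per-subject subtraction, taVNS (1) minus sham (0).

    ``values[subject][stimulation]`` is that subject-condition's series.
    Subjects missing one condition are excluded (logged in ``source``
    consumers via the resulting index).
    """
    rows = {}
    for subj, conds in values.items():
        if 0 in conds and 1 in conds:
            rows[subj] = np.asarray(conds[1], dtype=float) - np.asarray(conds[0], dtype=float)
    if not rows:
        raise ValueError("no subject has both stimulation conditions")
    delta = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return DeltaSeries(axis=np.asarray(axis, dtype=float), delta=delta,
                       source=source)


def cluster_average_delta(delta: DeltaSeries, cluster: Cluster) -> pd.Series:
    """Mean delta over the cluster's points, one scalar per subject."""
    idx = cluster.indices
    if idx.size == 0:
        raise ValueError("empty cluster")
    if idx.max() >= delta.delta.shape[1]:
        raise ValueError("cluster extent outside delta axis")
    return delta.delta.iloc[:, idx].mean(axis=1)


def _ols_t(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """t statistics of all non-intercept coefficients, y ~ [1, X]."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    dof = n - A.shape[1]
    if dof <= 0:
        return np.full(A.shape[1] - 1, np.nan), np.full(A.shape[1] - 1, np.nan)
    s2 = np.sum((y - fitted) ** 2) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    return coef[1:] / se[1:], coef[1:]


def predict_across(outcome: DeltaSeries, predictors: pd.DataFrame,
                   scheme: PermScheme = PermScheme(),
                   test_col: Optional[str] = None) -> List[Cluster]:
    """Does a cluster-averaged delta predict another task's delta profile?

    ``predictors`` holds one row per subject (index-aligned with the
    outcome deltas) and one column per cluster-averaged predictor
    (e.g. ``fm_plrt``).  The tested predictor (default: first column) is
    assessed by its per-point t statistic; remaining columns enter as
    covariates.  CBPT permutes the tested predictor's subject assignment;
    significant clusters report the average beta inside them.
    """
    common = outcome.delta.index.intersection(predictors.index)
    if len(common) < 5:
        raise ValueError("need at least 5 subjects shared by outcome and predictors")
    Y = outcome.delta.loc[common].to_numpy()
    P = predictors.loc[common].to_numpy(dtype=float)
    cols = list(predictors.columns)
    j = 0 if test_col is None else cols.index(test_col)
    n, m = Y.shape
    dof = n - P.shape[1] - 1
    thr = float(stats.t.ppf(1 - scheme.threshold_alpha / 2, dof))

    def tmap(pred: np.ndarray) -> tuple:
        ts = np.empty(m)
        betas = np.empty(m)
        for k in range(m):
            t, b = _ols_t(Y[:, k], pred)
            ts[k] = t[j]
            betas[k] = b[j]
        return ts, betas

    tobs, betas = tmap(P)
    clusters = form_clusters(tobs, thr, signed=True)
    for c in clusters:
        c.beta_avg = float(np.mean(betas[c.indices]))
    rng = np.random.default_rng(scheme.seed)
    null = np.empty(scheme.n_perm)
    for b_i in range(scheme.n_perm):
        Pp = P.copy()
        Pp[:, j] = P[rng.permutation(n), j]
        ts, _ = tmap(Pp)
        null[b_i] = max_cluster_mass(ts, thr)
    return cluster_p(clusters, null)
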