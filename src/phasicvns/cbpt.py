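"""Cluster-based permutation testing (CBPT).

Per-point statistics (paired t, mixed-model likelihood-ratio chi-square,
or a continuous predictor's t) are thresholded at an uncorrected per-point
alpha; contiguous suprathreshold points form clusters whose masses (summed
statistics) are compared against the distribution of the largest cluster
mass under random within-subject permutation of condition labels.  The
permutation p value is floored at 1/n_perm.  Signed statistics form
positive and negative clusters separately; the null uses the maximum
absolute cluster mass (two-sided family-wise control).

Cluster effect sizes follow the paired Cohen's d convention: ``d_avg`` is
the d of per-subject values averaged across the cluster, ``d_max`` the
largest per-point d inside it (no ordering between the two is implied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import mixed_models as mm

__all__ = ["PermScheme", "Cluster", "paired_t", "form_clusters",
           "max_cluster_mass", "sign_flip_null", "cluster_p",
           "cluster_effect_sizes", "cbpt_paired", "pointwise_lmm_chisq",
           "cbpt_lmm", "tfr_cbpt"]


@dataclass(frozen=True)
class PermScheme:
    n_perm: int = 10000
    seed: int = 0
    threshold_alpha: float = 0.05
    tail: str = "two"                # for t statistics

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0.0 < self.threshold_alpha < 0.5:
            raise ValueError("threshold_alpha must lie in (0, 0.5)")


@dataclass
class Cluster:
    indices: np.ndarray              # flat indices into the statistic array
    mass: float
    direction: int                   # +1 / -1 (0 for unsigned statistics)
    p: float = np.nan
    d_avg: float = np.nan
    d_max: float = np.nan
    d_max_loc: Optional[int] = None
    beta_avg: float = np.nan

    @property
    def extent(self) -> Tuple[int, int]:
        return int(self.indices.min()), int(self.indices.max())

    def to_dict(self) -> dict:
        return {"start": int(self.indices.min()), "end": int(self.indices.max()),
                "n_points": int(self.indices.size), "mass": self.mass,
                "direction": self.direction, "p": self.p,
                "d_avg": self.d_avg, "d_max": self.d_max,
                "d_max_loc": self.d_max_loc, "beta_avg": self.beta_avg}


def paired_t(delta: np.ndarray) -> np.ndarray:
    """Per-point one-sample t of subject-wise condition differences."""
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    m = delta.mean(axis=0)
    sd = delta.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (sd / np.sqrt(n))


def _runs(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return zip(idx[::2], idx[1::2])


def form_clusters(stat: np.ndarray, threshold: float,
                  signed: bool = True) -> List[Cluster]:
    """Maximal contiguous suprathreshold runs of a 1-D statistic series.

    For signed statistics, positive (stat > threshold) and negative
    (stat < -threshold) clusters are formed separately.  NaN points
    (non-converged fits) are subthreshold.  ``threshold`` is on the
    statistic's own scale.
    """
    stat = np.asarray(stat, dtype=float)
    out: List[Cluster] = []
    with np.errstate(invalid="ignore"):
        masks = [(stat > threshold, 1)]
        if signed:
            masks.append((stat < -threshold, -1))
    for mask, sign in masks:
        mask = mask & np.isfinite(stat)
        for a, b in _runs(mask):
            idx = np.arange(a, b)
            out.append(Cluster(indices=idx, mass=float(stat[a:b].sum()),
                               direction=sign))
    out.sort(key=lambda c: c.indices.min())
    return out


def max_cluster_mass(stat: np.ndarray, threshold: float, signed: bool = True) -> float:
    """Largest absolute cluster mass (0.0 when no point is suprathreshold)."""
    clusters = form_clusters(stat, threshold, signed)
    return max((abs(c.mass) for c in clusters), default=0.0)


def _sign_matrix(n_subjects: int, scheme: PermScheme):
    """Sign-flip matrix; exhaustive enumeration when 2^n <= n_perm."""
    n_distinct = 2 ** n_subjects
    if n_distinct <= scheme.n_perm:
        warnings.warn(f"only {n_distinct} distinct sign flips; enumerating "
                      "exhaustively")
        bits = ((np.arange(n_distinct)[:, None] >> np.arange(n_subjects)) & 1)
        return 1.0 - 2.0 * bits, True
    rng = np.random.default_rng(scheme.seed)
    return rng.choice([-1.0, 1.0], size=(scheme.n_perm, n_subjects)), False


def sign_flip_null(delta: np.ndarray, scheme: PermScheme,
                   threshold: Optional[float] = None) -> np.ndarray:
    """Max-cluster-mass null for a paired design via within-subject label flips.

    ``delta`` is (n_subjects, n_points).  Flipping a subject's condition
    labels negates its difference, so the null is generated by random sign
    flips.  Returns one max cluster mass per permutation; seeded.
    """
    delta = np.asarray(delta, dtype=float)
    n, m = delta.shape
    if threshold is None:
        threshold = float(stats.t.ppf(1 - scheme.threshold_alpha / 2, n - 1))
    S, _ = _sign_matrix(n, scheme)
    M = S @ delta / n
    ss = (delta ** 2).sum(axis=0)
    var = (ss - n * M ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = M / np.sqrt(var / n)
    return np.array([max_cluster_mass(T[i], threshold) for i in range(T.shape[0])])


def cluster_p(clusters: Sequence[Cluster], null: np.ndarray) -> List[Cluster]:
    """Attach permutation p values: count(null >= |mass|)/n, floored at 1/n.

    Ties count toward the null (conservative).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    for c in clusters:
        count = int(np.sum(null >= abs(c.mass)))
        c.p = max(count / null.size, 1.0 / null.size)
    return list(clusters)


def _paired_d(a_minus_b: np.ndarray) -> float:
    sd = a_minus_b.std(ddof=1)
    return float(a_minus_b.mean() / sd) if sd > 0 else 0.0


def cluster_effect_sizes(cluster: Cluster, cond_a: np.ndarray,
                         cond_b: np.ndarray) -> Cluster:
    """Paired Cohen's d of cluster-averaged values and max per-point d.

    ``cond_a`` / ``cond_b`` are (n_subjects, n_points) per-subject values
    of the two conditions over the full axis.
    """
    if cond_a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    idx = cluster.indices
    diff = cond_a[:, idx] - cond_b[:, idx]
    cluster.d_avg = _paired_d(diff.mean(axis=1))
    per_point = np.array([_paired_d(diff[:, j]) for j in range(idx.size)])
    j = int(np.argmax(np.abs(per_point)))
    cluster.d_max = float(per_point[j])
    cluster.d_max_loc = int(idx[j])
    return cluster


def cbpt_paired(cond_a: np.ndarray, cond_b: np.ndarray,
                scheme: PermScheme = PermScheme()) -> List[Cluster]:
    """Full 1-D CBPT for a paired two-condition design.

    ``cond_a``/``cond_b``: (n_subjects, n_points) per-subject values
    (trial-averaged).  Per-point paired t, two-sided cluster forming at
    ``threshold_alpha``, sign-flip max-mass null, effect sizes attached.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    delta = cond_a - cond_b
    n = delta.shape[0]
    thr = float(stats.t.ppf(1 - scheme.threshold_alpha / 2, n - 1))
    tobs = paired_t(delta)
    clusters = form_clusters(tobs, thr, signed=True)
    null = sign_flip_null(delta, scheme, thr)
    clusters = cluster_p(clusters, null)
    for c in clusters:
        cluster_effect_sizes(c, cond_a, cond_b)
    return clusters


# ---------------------------------------------------------------------------
# mixed-model per-point statistics


def pointwise_lmm_chisq(data: pd.DataFrame, outcome: str, term: str,
                        formula_rhs: str, groups: str = "subject",
                        re_formula: Optional[str] = None,
                        point_col: str = "point",
                        max_nonconverged: float = 0.2) -> np.ndarray:
    """LRT chi-square for ``term`` from an LMM fitted at each point.

    ``data`` is long-format with a ``point_col`` index.  Non-converged
    points carry NaN (treated as subthreshold by the clustering); more
    than ``max_nonconverged`` of them aborts with a diagnostic.
    """
    points = np.sort(data[point_col].unique())
    full_formula = f"{outcome} ~ {formula_rhs}"
    out = np.full(points.size, np.nan)
    n_bad = 0
    for i, pt in enumerate(points):
        sub = data[data[point_col] == pt]
        try:
            full = mm.fit_mixed(sub, full_formula, groups, re_formula,
                                "gaussian", reml=False)
            red = mm.fit_mixed(sub, mm._drop_term(full_formula, term), groups,
                               re_formula, "gaussian", reml=False)
            if not (full.converged and red.converged):
                n_bad += 1
                continue
            out[i], _, _ = mm.lrt(full, red)
        except Exception:
            n_bad += 1
    if n_bad > max_nonconverged * points.size:
        raise RuntimeError(
            f"{n_bad}/{points.size} per-point fits failed to converge")
    return out


def cbpt_lmm(data: pd.DataFrame, outcome: str, term: str, formula_rhs: str,
             scheme: PermScheme, groups: str = "subject",
             re_formula: Optional[str] = None, point_col: str = "point",
             unit_col: str = "trial",
             df_term: int = 1) -> Tuple[List[Cluster], np.ndarray]:
    """CBPT with a mixed-model LRT chi-square as the per-point statistic.

    The permutation shuffles only the tested predictor's labels within
    subject, at the level of ``unit_col`` (a trial or condition identifier,
    applied consistently across points); covariates stay fixed.  The
    cluster-forming threshold is the chi-square ``1 - threshold_alpha``
    quantile at the term's df; the statistic is one-sided so clusters are
    unsigned.  Computationally heavy; intended for modest grids and
    permutation counts.
    """
    data = data.reset_index(drop=True)
    thr = float(stats.chi2.ppf(1 - scheme.threshold_alpha, df_term))
    obs = pointwise_lmm_chisq(data, outcome, term, formula_rhs, groups,
                              re_formula, point_col)
    clusters = form_clusters(obs, thr, signed=False)
    rng = np.random.default_rng(scheme.seed)
    null = np.empty(scheme.n_perm)
    base_col = term.split(":")[0]
    for b in range(scheme.n_perm):
        perm = data.copy()
        perm[base_col] = _permute_within(perm, base_col, groups, unit_col, rng)
        st = pointwise_lmm_chisq(perm, outcome, term, formula_rhs, groups,
                                 re_formula, point_col)
        null[b] = max_cluster_mass(st, thr, signed=False)
    return cluster_p(clusters, null), obs


def _permute_within(data: pd.DataFrame, col: str, groups: str,
                    unit_col: str, rng) -> np.ndarray:
    """Shuffle a unit-level label within subject, consistently across points."""
    out = data[col].to_numpy().copy()
    for _, sub in data.groupby(groups):
        units = sub[[unit_col, col]].drop_duplicates(unit_col)
        labels = units[col].to_numpy()
        mapping = dict(zip(units[unit_col].to_numpy(),
                           labels[rng.permutation(labels.size)]))
        pos = sub.index.to_numpy()
        out[pos] = sub[unit_col].map(mapping).to_numpy()
    return out


# ---------------------------------------------------------------------------
# 3-D (sensor x frequency x time) clustering for TFR maps


def _grid_adjacency(shape: Tuple[int, int], mask_flat: np.ndarray,
                    sensor_adj: np.ndarray, n_sensors: int) -> sparse.coo_matrix:
    """Adjacency among suprathreshold cells: 8-neighborhood in the
    frequency-time plane within sensor, identical cells across neighboring
    sensors."""
    nf, nt = shape
    n_cells = n_sensors * nf * nt
    rows, cols = [], []
    idx3 = np.flatnonzero(mask_flat)
    mask = mask_flat.reshape(n_sensors, nf, nt)
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for s in range(n_sensors):
        base = s * nf * nt
        for df_, dt_ in shifts:
            f0 = slice(max(df_, 0), nf + min(df_, 0))
            f1 = slice(max(-df_, 0), nf + min(-df_, 0))
            t0 = slice(max(dt_, 0), nt + min(dt_, 0))
            t1 = slice(max(-dt_, 0), nt + min(-dt_, 0))
            both = mask[s, f0, t0] & mask[s, f1, t1]
            fi, ti = np.nonzero(both)
            a = base + (fi + max(df_, 0)) * nt + (ti + max(dt_, 0))
            b = base + (fi + max(-df_, 0)) * nt + (ti + max(-dt_, 0))
            rows.append(a); cols.append(b)
    si, sj = np.nonzero(np.triu(sensor_adj, 1))
    for a_s, b_s in zip(si, sj):
        both = mask[a_s].ravel() & mask[b_s].ravel()
        cells = np.flatnonzero(both)
        rows.append(a_s * nf * nt + cells)
        cols.append(b_s * nf * nt + cells)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=np.int8)
    # self-links keep isolated suprathreshold cells in the component list
    rows = np.concatenate([rows, idx3])
    cols = np.concatenate([cols, idx3])
    data = np.ones(rows.size, dtype=np.int8)
    return sparse.coo_matrix((data, (rows, cols)), shape=(n_cells, n_cells))


def _clusters_3d(tmap: np.ndarray, threshold: float,
                 sensor_adj: np.ndarray) -> List[Cluster]:
    n_sensors, nf, nt = tmap.shape
    out: List[Cluster] = []
    for sign in (1, -1):
        mask = (sign * tmap > threshold) & np.isfinite(tmap)
        flat = mask.ravel()
        if not flat.any():
            continue
        adj = _grid_adjacency((nf, nt), flat, sensor_adj, n_sensors)
        n_comp, labels = sparse.csgraph.connected_components(adj.tocsr(),
                                                             directed=False)
        tflat = tmap.ravel()
        for comp in np.unique(labels[flat]):
            idx = np.flatnonzero((labels == comp) & flat)
            out.append(Cluster(indices=idx, mass=float(tflat[idx].sum()),
                               direction=sign))
    return out


def tfr_cbpt(tfr_a: np.ndarray, tfr_b: np.ndarray, sensor_adj: np.ndarray,
             scheme: PermScheme = PermScheme(),
             times: Optional[np.ndarray] = None,
             window_s: Tuple[float, float] = (0.6, 5.0)) -> List[Cluster]:
    """Paired-t CBPT on (n_subjects, n_sensors, n_freqs, n_times) TFR maps.

    The analysis window excludes the stimulation period (interpolated data);
    clusters are 3-D connected components under 8-neighborhood in the
    frequency-time plane plus declared sensor neighbors.  The null flips
    condition labels within subject.
    """
    tfr_a = np.asarray(tfr_a, dtype=float)
    tfr_b = np.asarray(tfr_b, dtype=float)
    if times is not None:
        sel = (times >= window_s[0]) & (times <= window_s[1])
        if not sel.any():
            raise ValueError("analysis window outside TFR support")
        tfr_a = tfr_a[..., sel]
        tfr_b = tfr_b[..., sel]
    delta = tfr_a - tfr_b
    n = delta.shape[0]
    thr = float(stats.t.ppf(1 - scheme.threshold_alpha / 2, n - 1))
    tobs = paired_t(delta.reshape(n, -1)).reshape(delta.shape[1:])
    clusters = _clusters_3d(tobs, thr, sensor_adj)
    S, _ = _sign_matrix(n, scheme)
    null = np.empty(S.shape[0])
    flat = delta.reshape(n, -1)
    ss = (flat ** 2).sum(axis=0)
    for i in range(S.shape[0]):
        M = S[i] @ flat / n
        var = (ss - n * M ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (M / np.sqrt(var / n)).reshape(delta.shape[1:])
        cl = _clusters_3d(T, thr, sensor_adj)
        null[i] = max((abs(c.mass) for c in cl), default=0.0)
    return cluster_p(clusters, null)
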