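"""Morphospace dispersion: PCA, disparity, hull volume, evenness, nulls.

Disparity is the mean squared distance from a reference mean (n in the
denominator, matching the Procrustes-variance convention); hull volume and
functional evenness operate on the leading PCA axes.  Significance comes
from label permutations, robustness from within-group bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PCAResult",
    "run_pca",
    "group_disparity",
    "hull_volume",
    "functional_evenness",
    "permutation_pvalues",
    "bootstrap_dispersion",
    "cell_summaries",
]

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    def cumulative_variance(self, n_axes: int) -> float:
        return float(self.variance_explained[:n_axes].sum())


def run_pca(residual_traits: pd.DataFrame) -> PCAResult:
    """Covariance-matrix PCA on centered (not rescaled) residual traits.

    Axes are ordered by variance; each axis is signed so its largest-
    magnitude loading is positive.  Rank-deficient input yields fewer axes
    with a warning.
    """
    X = residual_traits.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 species")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals.max(), 0.0) * 1e-12
    keep = evals > tol
    if keep.sum() < min(n - 1, p):
        warnings.warn(f"rank-deficient traits: keeping {int(keep.sum())} axes")
    evals, evecs = np.maximum(evals[keep], 0.0), evecs[:, keep]
    # sign convention: largest-|loading| entry positive per axis
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    axes = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    scores = pd.DataFrame(Xc @ evecs, index=residual_traits.index, columns=axes)
    loadings = pd.DataFrame(evecs, index=residual_traits.columns, columns=axes)
    return PCAResult(scores=scores, loadings=loadings,
                     variance_explained=evals / evals.sum())


# ------------------------------------------------------------------ metrics
def group_disparity(values, groups=None, center="overall"):
    """Per-group multivariate variance: mean squared distance from a mean.

    ``center='overall'`` (default) measures deviations from the grand mean
    of all species; ``'group'`` uses each group's own mean.  Denominator is
    the group size n (not n-1).  Returns a dict (or a float if ``groups``
    is None, i.e. one group).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    grand = X.mean(axis=0)
    if groups is None:
        return float(np.mean(np.sum((X - grand) ** 2, axis=1)))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sub = X[groups == g]
        if len(sub) == 0:
            warnings.warn(f"empty group {g!r}: disparity undefined")
            continue
        ref = grand if center == "overall" else sub.mean(axis=0)
        out[g] = float(np.mean(np.sum((sub - ref) ** 2, axis=1)))
    return out


def hull_volume(points) -> float:
    """Convex-hull volume of a point cloud (d-dimensional).

    Degenerate (affinely dependent) sets return 0 with a warning; fewer
    points than d+1 is an error.
    """
    X = np.asarray(points, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more than {d} points in {d}-D, got {n}")
    try:
        return float(ConvexHull(X).volume)
    except QhullError:
        warnings.warn("degenerate point set: hull volume 0")
        return 0.0


def _mst_edge_lengths(X: np.ndarray) -> np.ndarray:
    D = squareform(pdist(X))
    mst = minimum_spanning_tree(D)
    return np.asarray(mst[mst.nonzero()]).ravel()


def functional_evenness(points) -> float:
    """MST-based functional evenness (FEve) with equal weights, in [0, 1].

    FEve = [sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)] / [1 - 1/(S-1)], where
    PEW_l are the normalized MST edge lengths.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    S = len(X)
    if S < 3:
        raise ValueError("FEve needs at least 3 points")
    ew = _mst_edge_lengths(X)
    total = ew.sum()
    if total <= 0:
        return 1.0  # all points identical: perfectly even by convention
    pew = ew / total
    thr = 1.0 / (S - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


_METRICS = {
    "disparity": lambda X: group_disparity(X),
    "volume": hull_volume,
    "evenness": functional_evenness,
}


def _metric_fn(metric):
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


def _group_metric(fn, X, groups, labels, metric_name, center="overall"):
    if metric_name == "disparity":
        return group_disparity(X, groups, center=center)
    return {g: fn(X[groups == g]) for g in labels}


# ------------------------------------------------------------------- nulls
def permutation_pvalues(metric, values, groups, n_perm=1000, seed=None,
                        center="overall"):
    """Pairwise permutation p-values for between-group metric differences.

    Group labels are permuted (sizes preserved); p is the fraction of
    permutations whose permuted absolute difference strictly exceeds the
    empirical absolute difference (no +1 correction, so p may be 0 and is
    then best reported as < 1/n_perm).  Permutations for which the metric
    is undefined in some group are redrawn (count logged).
    """
    fn = _metric_fn(metric)
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    emp = _group_metric(fn, X, groups, labels, name, center)
    pairs = list(combinations(labels, 2))
    emp_diff = {pr: abs(emp[pr[0]] - emp[pr[1]]) for pr in pairs}
    exceed = {pr: 0 for pr in pairs}
    n_resampled = 0
    done = 0
    while done < n_perm:
        perm = rng.permutation(groups)
        try:
            vals = _group_metric(fn, X, perm, labels, name, center)
        except (ValueError, QhullError):
            n_resampled += 1
            if n_resampled > 100 * n_perm:
                raise RuntimeError("metric undefined for nearly all permutations")
            continue
        for pr in pairs:
            if abs(vals[pr[0]] - vals[pr[1]]) > emp_diff[pr]:
                exceed[pr] += 1
        done += 1
    if n_resampled:
        logger.info("%d degenerate permutations redrawn", n_resampled)
    rows = [
        {"group_a": a, "group_b": b, "empirical_diff": emp_diff[(a, b)],
         "p_value": exceed[(a, b)] / n_perm}
        for a, b in pairs
    ]
    return pd.DataFrame(rows)


def bootstrap_dispersion(metric, values, groups, n_boot=1000, seed=None,
                         center="overall"):
    """Within-group bootstrap distributions of a dispersion metric.

    Species are resampled with replacement inside each group; the metric is
    recomputed per replicate.  Returns {group: ndarray of n_boot values}.
    """
    fn = _metric_fn(metric)
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    grand = X.mean(axis=0)
    out = {}
    for g in pd.unique(groups):
        sub = X[groups == g]
        n_g = len(sub)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            while True:
                samp = sub[rng.integers(n_g, size=n_g)]
                try:
                    if name == "disparity":
                        ref = grand if center == "overall" else samp.mean(axis=0)
                        reps[r] = float(np.mean(np.sum((samp - ref) ** 2, axis=1)))
                    else:
                        reps[r] = fn(samp)
                except (ValueError, QhullError):
                    continue
                break
        out[g] = reps
    return out


# ---------------------------------------------------------- cell assemblages
def cell_summaries(occurrence: pd.DataFrame, values: pd.DataFrame,
                   tip_rates=None, center="cell") -> pd.DataFrame:
    """Per-cell assemblage disparity and mean tip rate.

    ``occurrence`` has columns cell, species; ``values`` is species-indexed
    (trait matrix).  Cells with < 2 member species get NA disparity; mean
    rate is defined from 1 member.  Occurrence species missing from
    ``values`` are dropped with a logged count.
    """
    occ = occurrence[["cell", "species"]].drop_duplicates()
    known = occ["species"].isin(values.index)
    dropped = int((~known).sum())
    if dropped:
        logger.info("%d occurrence rows dropped (species not in trait data)", dropped)
    occ = occ[known]
    X = values.to_numpy(dtype=float)
    grand = X.mean(axis=0)
    idx = {sp: i for i, sp in enumerate(values.index)}
    rows = []
    for cell, sub in occ.groupby("cell", sort=True):
        members = np.array([idx[s] for s in sub["species"]])
        pts = X[members]
        if len(members) >= 2:
            ref = pts.mean(axis=0) if center == "cell" else grand
            disp = float(np.mean(np.sum((pts - ref) ** 2, axis=1)))
        else:
            disp = np.nan
        rec = {"cell": cell, "n_species": len(members), "disparity": disp}
        if tip_rates is not None:
            rates = tip_rates.reindex(sub["species"]).dropna()
            rec["mean_tip_rate"] = float(rates.mean()) if len(rates) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
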