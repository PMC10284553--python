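"""Diversity, dispersion and indicator statistics for article groups.

The analysis treats each lexicon feature as a "species" and each article as
a "site", then borrows community-ecology machinery:

* per-article feature richness and the first-order Hill number
  (exponential Shannon entropy of mention proportions), compared between
  groups by one-way ANOVA;
* multivariate homogeneity of group dispersions (PERMDISP) on the
  Bray-Curtis dissimilarity of relative feature frequencies — each
  article's distance to its group's spatial median in a principal
  coordinates embedding, with the standard correction for negative
  eigenvalues (imaginary axes);
* indicator-feature analysis (IndVal): specificity × fidelity, with a
  group-label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .features import RelFreqMatrix

__all__ = [
    "DiversityProfile",
    "DispersionResult",
    "IndvalResult",
    "diversity_profile",
    "anova_compare",
    "bray_curtis",
    "dispersion_test",
    "indval",
    "geometric_median",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DiversityProfile:
    """Per-article richness and effective feature number (Hill q=1)."""

    table: pd.DataFrame  # columns: group, richness, hill1

    def group_means(self) -> pd.DataFrame:
        return self.table.groupby("group")[["richness", "hill1"]].agg(["mean", "std"])


@dataclass(frozen=True)
class DispersionResult:
    """PERMDISP output: distances to group spatial medians and the ANOVA."""

    distances: pd.Series
    groups: pd.Series
    group_stats: pd.DataFrame  # mean, sd per group
    F: float
    df1: int
    df2: int
    p: float
    coordinates: pd.DataFrame | None = None


@dataclass(frozen=True)
class IndvalResult:
    """Per-feature indicator statistics.

    Columns: ``group`` (best group), ``A`` (specificity), ``B`` (fidelity),
    ``stat`` (= max_g A_g B_g), ``p`` (permutation, add-one convention),
    ``present`` (False for features absent everywhere, whose statistics are
    undefined and reported as NaN).
    """

    table: pd.DataFrame
    n_perm: int
    mode: str


def diversity_profile(rf: RelFreqMatrix) -> DiversityProfile:
    """Richness and first-order Hill number for every article.

    Richness counts features with nonzero relative frequency.  The Hill
    number is ``exp(-sum p_f ln p_f)`` where ``p_f`` are the article's
    feature mentions normalized to proportions; it equals richness exactly
    when nonzero proportions are uniform and is otherwise smaller.
    """
    X = rf.values.to_numpy(dtype=float)
    rowsum = X.sum(axis=1)
    if (rowsum <= 0).any():
        bad = list(rf.values.index[rowsum <= 0])
        raise ValueError(f"all-zero rows {bad}; apply drop_featureless first")
    P = X / rowsum[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    hill1 = np.exp(-plogp.sum(axis=1))
    richness = (X > 0).sum(axis=1)
    table = pd.DataFrame(
        {"group": rf.groups, "richness": richness, "hill1": hill1},
        index=rf.values.index,
    )
    return DiversityProfile(table=table)


def anova_compare(values, groups) -> dict:
    """One-way ANOVA of a per-article quantity across groups.

    Returns ``{"F", "df1", "df2", "p"}``.  Every group must have at least
    two members.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    samples = [values[groups == g] for g in labels]
    F, p = stats.f_oneway(*samples)
    return {
        "F": float(F),
        "df1": int(len(labels) - 1),
        "df2": int(len(values) - len(labels)),
        "p": float(p),
    }


def bray_curtis(rf: RelFreqMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, d(x,y) = sum|x-y| / sum(x+y).

    Accepts a :class:`RelFreqMatrix` or a raw nonnegative matrix; all rows
    must have a positive sum.  Returns a symmetric matrix with zero
    diagonal and values in [0, 1].
    """
    if isinstance(rf, RelFreqMatrix):
        X = rf.values.to_numpy(dtype=float)
    else:
        X = np.asarray(rf, dtype=float)
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero rows")
    return squareform(pdist(X, metric="braycurtis"))


def geometric_median(points: np.ndarray, tol: float = 1e-14, max_iter: int = 2000) -> np.ndarray:
    """Spatial (geometric) median by iteratively reweighted least squares.

    Weiszfeld iteration with the Vardi-Zhang adjustment when the iterate
    lands on a data point.  ``points`` is (n, d); returns the point
    minimizing the sum of Euclidean distances.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-D")
    n, d = pts.shape
    if n == 1 or d == 0:
        return pts.mean(axis=0)
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        dists = np.linalg.norm(pts - y, axis=1)
        at_point = dists < _EPS
        if at_point.any():
            # Vardi-Zhang: treat the coincident point separately
            mask = ~at_point
            if not mask.any():
                return y
            w = 1.0 / dists[mask]
            T = (pts[mask] * w[:, None]).sum(axis=0) / w.sum()
            R = ((pts[mask] - y) * w[:, None]).sum(axis=0)
            r_norm = np.linalg.norm(R)
            eta = at_point.sum()
            if r_norm <= eta:
                return y
            step = min(1.0, eta / r_norm)
            y_new = (1 - step) * T + step * y
        else:
            w = 1.0 / dists
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol * (1.0 + np.linalg.norm(y)):
            return y_new
        y = y_new
    return y


def _pcoa(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix.

    Returns (real_coords, imag_coords): axes for positive and negative
    eigenvalues of the Gower-centered matrix, scaled by sqrt(|eigenvalue|).
    """
    n = d.shape[0]
    A = -0.5 * d.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def dispersion_test(d: np.ndarray | pd.DataFrame, groups) -> DispersionResult:
    """PERMDISP: distances to group spatial medians, compared by ANOVA.

    The dissimilarity matrix is embedded by principal coordinates analysis
    keeping both real axes (positive eigenvalues) and imaginary axes
    (negative eigenvalues, present for semi-metric dissimilarities such as
    Bray-Curtis).  Each group's spatial median is the geometric median,
    computed separately in the real and imaginary subspaces; member
    distances combine the two parts as ``d_i^2 = d_real^2 - d_imag^2``,
    floored at 0.  Group dispersions are compared with a one-way ANOVA on
    those distances.
    """
    if isinstance(d, pd.DataFrame):
        index = d.index
        d = d.to_numpy(dtype=float)
    else:
        d = np.asarray(d, dtype=float)
        index = pd.RangeIndex(d.shape[0])
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if np.allclose(d, 0.0):
        raise ValueError("zero dispersion: all points identical")
    groups = pd.Series(np.asarray(groups), index=index, name="group")

    real, imag = _pcoa(d)
    n = d.shape[0]
    dist = np.zeros(n)
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        med_r = geometric_median(real[mask]) if real.shape[1] else np.zeros(0)
        med_i = geometric_median(imag[mask]) if imag.shape[1] else np.zeros(0)
        dr2 = ((real[mask] - med_r) ** 2).sum(axis=1) if real.shape[1] else 0.0
        di2 = ((imag[mask] - med_i) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        dist[mask] = np.sqrt(np.maximum(dr2 - di2, 0.0))

    anova = anova_compare(dist, groups.to_numpy())
    distances = pd.Series(dist, index=index, name="dist_to_median")
    group_stats = (
        pd.DataFrame({"group": groups, "dist": dist})
        .groupby("group")["dist"]
        .agg(mean="mean", sd="std")
    )
    coords = pd.DataFrame(
        np.hstack([real, imag]),
        index=index,
        columns=[f"PCoA{i + 1}" for i in range(real.shape[1])]
        + [f"iPCoA{i + 1}" for i in range(imag.shape[1])],
    )
    return DispersionResult(
        distances=distances,
        groups=groups,
        group_stats=group_stats,
        F=anova["F"],
        df1=anova["df1"],
        df2=anova["df2"],
        p=anova["p"],
        coordinates=coords,
    )


def _indval_stats(X: np.ndarray, occ: np.ndarray, codes: np.ndarray, n_groups: int):
    """IndVal components for one labeling.

    Returns (stat per feature, specificity matrix, fidelity matrix), with
    groups on axis 0 and features on axis 1.
    """
    means = np.empty((n_groups, X.shape[1]))
    fidelity = np.empty((n_groups, X.shape[1]))
    for g in range(n_groups):
        mask = codes == g
        means[g] = X[mask].mean(axis=0)
        fidelity[g] = occ[mask].mean(axis=0)
    denom = means.sum(axis=0)
    safe = np.where(denom > 0, denom, 1.0)
    spec = means / safe
    stat = (spec * fidelity).max(axis=0)
    absent = denom <= 0
    spec[:, absent] = np.nan
    stat[absent] = np.nan
    return stat, spec, fidelity


def indval(
    rf_or_presence,
    groups,
    mode: str = "abundance",
    n_perm: int = 999,
    seed: int | None = 0,
) -> IndvalResult:
    """Indicator-feature analysis with a group-label permutation test.

    For each feature and group g, specificity ``A_g`` is the group's mean
    abundance divided by the sum of all groups' mean abundances, and
    fidelity ``B_g`` is the fraction of the group's articles containing the
    feature; the indicator value is ``max_g A_g * B_g``.  In
    ``mode="presence"`` the occurrence indicator replaces abundance, so the
    statistic reflects where a feature occurs rather than how intensely it
    is used.  Significance comes from ``n_perm`` seeded permutations of the
    group labels with the add-one convention
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``.

    Features absent everywhere have an undefined statistic and are flagged
    with ``present=False``.
    """
    if mode not in ("abundance", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if isinstance(rf_or_presence, RelFreqMatrix):
        values = rf_or_presence.values
        groups = rf_or_presence.groups if groups is None else groups
    elif isinstance(rf_or_presence, pd.DataFrame):
        values = rf_or_presence
    else:
        values = pd.DataFrame(np.asarray(rf_or_presence, dtype=float))
    X = values.to_numpy(dtype=float)
    occ = (X > 0).astype(float)
    if mode == "presence":
        X = occ
    labels_arr = np.asarray(groups)
    uniq, codes = np.unique(labels_arr, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    n_groups = len(uniq)

    obs_stat, spec, fid = _indval_stats(X, occ, codes, n_groups)
    present = X.sum(axis=0) > 0
    best = np.zeros(X.shape[1], dtype=int)
    ok = present
    best[ok] = np.nanargmax((spec * fid)[:, ok], axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        perm_stat, _, _ = _indval_stats(X, occ, perm, n_groups)
        exceed += (np.nan_to_num(perm_stat, nan=-1.0)
                   >= np.nan_to_num(obs_stat, nan=np.inf))
    p = (1.0 + exceed) / (n_perm + 1.0)

    table = pd.DataFrame(
        {
            "group": [uniq[b] if pr else None for b, pr in zip(best, present)],
            "A": [spec[b, j] if present[j] else np.nan for j, b in enumerate(best)],
            "B": [fid[b, j] if present[j] else np.nan for j, b in enumerate(best)],
            "stat": np.where(present, obs_stat, np.nan),
            "p": np.where(present, p, np.nan),
            "present": present,
        },
        index=values.columns,
    )
    return IndvalResult(table=table, n_perm=n_perm, mode=mode)
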