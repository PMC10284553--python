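"""Standalone complexity metrics.

A small catalogue of information-theoretic and statistical measures often
used to quantify complexity features of ecological data: Shannon entropy,
mean information gain and fluctuation complexity of symbol sequences, SVD
entropy of a matrix, mutual information of a two-way table, and the
coefficient of variation of a series.

All logarithms are natural by default (``base="e"``); pass ``base=2`` for
bits where the function accepts it.  Block statistics use overlapping
windows and plug-in (maximum-likelihood) frequencies without bias
correction.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

__all__ = [
    "shannon_entropy",
    "mean_information_gain",
    "fluctuation_complexity",
    "fluctuation_complexity_probs",
    "svd_entropy",
    "mutual_information",
    "coefficient_of_variation",
]


def _log(x: np.ndarray, base) -> np.ndarray:
    out = np.log(x)
    if base == 2:
        out = out / np.log(2.0)
    elif base not in ("e", np.e):
        raise ValueError("base must be 'e' or 2")
    return out


def shannon_entropy(p: Sequence[float], base="e") -> float:
    """Entropy -sum p_i log p_i of a probability vector, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    return float(-(nz * _log(nz, base)).sum())


def _block_entropy(s: list, L: int) -> float:
    """Plug-in entropy of overlapping length-L blocks (cyclic).

    Blocks wrap around the end of the sequence so every block length sees
    the same number of windows; this makes strictly periodic sequences
    yield exactly zero information gain instead of a boundary artifact.
    """
    n = len(s)
    ext = s + s[: L - 1]
    counts = Counter(tuple(ext[i:i + L]) for i in range(n))
    freqs = np.array(list(counts.values()), dtype=float) / n
    return float(-(freqs * np.log(freqs)).sum())


def mean_information_gain(s: Sequence, L: int = 1) -> float:
    """Entropy gained by extending block length from L to L+1.

    ``H_s(L+1) - H_s(L)`` over empirical overlapping-block frequencies: the
    average information obtained by observing one more step of the
    sequence.  Zero for constant and strictly periodic-with-period-dividing
    structure sequences; approaches the per-symbol entropy for i.i.d. data.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    s = list(s)
    if len(s) < L + 1:
        raise ValueError(f"sequence of length {len(s)} too short for L={L}")
    return _block_entropy(s, L + 1) - _block_entropy(s, L)


def fluctuation_complexity(s: Sequence) -> float:
    """Degree of structure of a sequence: sum_ij P_ij (log(P_i / P_j))^2.

    ``P_ij`` are empirical frequencies of successive symbol pairs and
    ``P_i`` the marginal symbol frequencies.  Vanishes both for constant
    sequences and when all states are equally probable (the log ratio is
    zero everywhere); large when transitions connect states of very
    different probability.
    """
    s = list(s)
    if len(set(s)) <= 1:
        return 0.0
    if len(s) < 3:
        raise ValueError("need at least 2 observed transitions")
    n = len(s)
    marg = Counter(s)
    p = {k: v / n for k, v in marg.items()}
    pairs = Counter(zip(s[:-1], s[1:]))
    total = n - 1
    out = 0.0
    for (i, j), c in pairs.items():
        out += (c / total) * np.log(p[i] / p[j]) ** 2
    return float(out)


def fluctuation_complexity_probs(marginal: Sequence[float], pair: np.ndarray) -> float:
    """Fluctuation complexity from explicit marginal and pair probabilities.

    ``sum_ij pair[i, j] (log(marginal[i] / marginal[j]))^2`` — the exact
    population form of :func:`fluctuation_complexity`, useful when the
    symbol process is known analytically.
    """
    p = np.asarray(marginal, dtype=float)
    pij = np.asarray(pair, dtype=float)
    if pij.shape != (p.size, p.size):
        raise ValueError("pair table shape must match marginal length")
    with np.errstate(divide="ignore"):
        ratio = np.log(np.where(p > 0, p, 1.0))
    logratio = ratio[:, None] - ratio[None, :]
    return float((pij * logratio**2).sum())


def svd_entropy(m: np.ndarray) -> float:
    """Normalized entropy of a matrix's singular-value spectrum, in [0, 1].

    With ``s_i = sigma_i / sum(sigma)`` over the k nonzero singular values,
    ``J = -(1/ln k) sum s_i ln s_i``; by convention J = 0 for a rank-1
    matrix.  J = 1 means all singular values are equal (the data cannot be
    compressed); small J means a few directions explain the matrix.
    Invariant to orthogonal rotations.
    """
    m = np.asarray(m, dtype=float)
    sigma = np.linalg.svd(m, compute_uv=False)
    tol = max(m.shape) * np.finfo(float).eps * (sigma[0] if sigma.size else 0.0)
    sigma = sigma[sigma > tol]
    if sigma.size == 0:
        raise ValueError("zero matrix has no nonzero singular values")
    k = sigma.size
    if k == 1:
        return 0.0
    s = sigma / sigma.sum()
    return float(-(s * np.log(s)).sum() / np.log(k))


def mutual_information(joint: np.ndarray, base="e") -> float:
    """Mutual information I(X;Y) = H(X) + H(Y) - H(X,Y) of a count table."""
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2:
        raise ValueError("joint must be a 2-way table")
    if (joint < 0).any():
        raise ValueError("counts must be nonnegative")
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty table")
    pxy = joint / total
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _h(p):
        nz = p[p > 0]
        return float(-(nz * _log(nz, base)).sum())

    return max(0.0, _h(px) + _h(py) - _h(pxy.ravel()))


def coefficient_of_variation(x: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean of a series."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    mean = x.mean()
    if abs(mean) < 1e-300:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)
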