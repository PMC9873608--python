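"""Inter-sample distances between frequency profiles.

Three measures, all operating on aligned feature vectors:

* Euclidean (EU): ``d = sqrt(sum (q_i - p_i)^2)``.
* Endres-Schindelin (ES): ``d = sqrt(KL(p, m) + KL(q, m))`` with
  ``m = (p + q)/2`` — the metric square root of twice the Jensen-Shannon
  divergence, natural logarithm throughout, so ``d <= sqrt(2 ln 2)``.
* Bray-Curtis (BC): ``d = 1 - 2 C_pq / (S_p + S_q)`` where ``C_pq`` is the
  sum of element-wise minima.

ES requires probability vectors.  synCUF profiles sum to one *per family*
(about 20 overall), so they are renormalized to a single distribution over
the 61 codons before ES; EU and BC are applied to synCUFs as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import FrequencyProfile, profiles_to_frame

DISTANCE_METHODS = ("EU", "ES", "BC")


def _aligned(p: FrequencyProfile, q: FrequencyProfile) -> tuple[np.ndarray, np.ndarray]:
    if p.kind != q.kind or p.k != q.k:
        raise ValueError(f"profile kinds differ: {p.kind}/{p.k} vs {q.kind}/{q.k}")
    if p.values.index.equals(q.values.index):
        return p.array(), q.array()
    union = p.values.index.union(q.values.index)
    return (p.values.reindex(union, fill_value=0.0).to_numpy(),
            q.values.reindex(union, fill_value=0.0).to_numpy())


def euclidean(p: FrequencyProfile, q: FrequencyProfile) -> float:
    """L2 distance between two same-kind profiles."""
    a, b = _aligned(p, q)
    return float(np.sqrt(((a - b) ** 2).sum()))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    # natural log; 0*log0 := 0.  q_i > 0 wherever p_i > 0 for mixture args.
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def endres_schindelin(p: FrequencyProfile, q: FrequencyProfile) -> float:
    """ES distance; inputs are renormalized to sum to 1 first."""
    a, b = _aligned(p, q)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative entries in frequency profile")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    a, b = a / sa, b / sb
    m = 0.5 * (a + b)
    val = _kl(a, m) + _kl(b, m)
    return float(np.sqrt(max(val, 0.0)))


def bray_curtis(p: FrequencyProfile, q: FrequencyProfile) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 C_pq / (S_p + S_q)`` in [0, 1]."""
    a, b = _aligned(p, q)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative entries in frequency profile")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    c = np.minimum(a, b).sum()
    return float(1.0 - 2.0 * c / denom)


_PAIRWISE = {"EU": euclidean, "ES": endres_schindelin, "BC": bray_curtis}


@dataclass
class DistanceMatrix:
    """Symmetric inter-sample distance matrix with labels."""

    ids: list[str]
    data: np.ndarray
    method: str
    kind: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def get(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)],
                              self.method, self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def pair_series(self) -> pd.Series:
        """Condensed distances indexed by unordered (id_i, id_j) tuples."""
        n = len(self.ids)
        iu, ju = np.triu_indices(n, 1)
        index = pd.MultiIndex.from_arrays(
            [np.array(self.ids)[iu], np.array(self.ids)[ju]])
        return pd.Series(self.data[iu, ju], index=index)


def distance_matrix(profiles: list[FrequencyProfile], method: str,
                    ) -> DistanceMatrix:
    """All-pairs distances between same-kind profiles.

    EU and BC go through :func:`scipy.spatial.distance.pdist`; ES uses the
    package's own implementation (with per-vector renormalization).
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    frame = profiles_to_frame(profiles)
    x = frame.to_numpy()
    if method == "EU":
        cond = pdist(x, metric="euclidean")
    elif method == "BC":
        cond = pdist(x, metric="braycurtis")
    else:
        rows = x / x.sum(axis=1, keepdims=True)
        n = len(rows)
        cond = np.empty(n * (n - 1) // 2)
        pos = 0
        for i in range(n - 1):
            a = rows[i]
            b = rows[i + 1:]
            m = 0.5 * (a + b)
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = np.where(a > 0, a * np.log(a / m), 0.0).sum(axis=1)
                tb = np.where(b > 0, b * np.log(b / m), 0.0).sum(axis=1)
            cond[pos:pos + len(b)] = np.sqrt(np.maximum(ta + tb, 0.0))
            pos += len(b)
    return DistanceMatrix(list(frame.index), squareform(cond),
                          method, profiles[0].kind)


@dataclass
class WithinBetweenSplit:
    """Partition of all unordered sample pairs into within/between-group lists."""

    within: list[tuple[tuple[str, str], float]]
    between: list[tuple[tuple[str, str], float]]
    focal: str = "all"

    def within_values(self) -> np.ndarray:
        return np.array([d for _, d in self.within])

    def between_values(self) -> np.ndarray:
        return np.array([d for _, d in self.between])


def within_between_split(matrix: DistanceMatrix,
                         labels: dict[str, str],
                         focal: str | None = None) -> WithinBetweenSplit:
    """Split pairwise distances into within- and between-group sets.

    With ``focal`` given, only pairs touching the focal group count: within
    = both members focal, between = exactly one member focal.  Without it,
    every unordered pair lands in exactly one of the two lists.
    """
    missing = [s for s in matrix.ids if s not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    within, between = [], []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            la, lb = labels[a], labels[b]
            d = float(matrix.data[i, j])
            if focal is None:
                (within if la == lb else between).append(((a, b), d))
            else:
                n_focal = (la == focal) + (lb == focal)
                if n_focal == 2:
                    within.append(((a, b), d))
                elif n_focal == 1:
                    between.append(((a, b), d))
    if focal is not None and not within:
        warnings.warn(f"group {focal!r} has no within pair")
    return WithinBetweenSplit(within, between, focal or "all")
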