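"""Group-separation statistics on distance matrices.

* ANOSIM — Clarke's rank-based R with a seeded label-permutation P-value.
* Clustering Index (CI) — ratio of the mean within-group distance of a
  focal group to the mean distance between that group and all others, with
  a label-randomization significance test whose P-value is the fraction of
  randomized datasets with a *lower* CI than observed.
* Ordination (centered PCA) and a Mann-Whitney within-vs-between report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .distances import DistanceMatrix, WithinBetweenSplit
from .profiles import FrequencyProfile, profiles_to_frame


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnosimResult(R={self.R:.4f}, p={self.p:.4g}, n_perm={self.n_permutations})"


def _check_groups(ids: list[str], labels: dict[str, str]) -> np.ndarray:
    missing = [s for s in ids if s not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    lab = np.array([labels[s] for s in ids])
    if len(ids) < 3:
        raise ValueError("need at least 3 samples")
    names, counts = np.unique(lab, return_counts=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    small = names[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    return lab


def _anosim_r(ranks: np.ndarray, same: np.ndarray) -> float:
    # Clarke's R = (mean between rank - mean within rank) / (n(n-1)/4);
    # the denominator equals half the number of unordered pairs, which
    # pins R to [-1, 1] with 1 at complete separation.
    m = len(ranks)
    r_w = ranks[same].mean()
    r_b = ranks[~same].mean()
    return float((r_b - r_w) / (m / 2.0))


def anosim(matrix: DistanceMatrix, labels: dict[str, str],
           n_permutations: int = 10_000,
           seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on a labeled distance matrix.

    Distances are converted to midranks once; R is recomputed for
    ``n_permutations`` random relabelings that preserve group sizes.  The
    P-value uses the add-one estimator ``(1 + hits) / (1 + n)`` with hits
    counting permuted R >= observed R.
    """
    lab = _check_groups(matrix.ids, labels)
    n = len(matrix.ids)
    cond = matrix.condensed()
    ranks = rankdata(cond)  # midranks for ties
    iu, ju = np.triu_indices(n, 1)
    same = lab[iu] == lab[ju]
    r_obs = _anosim_r(ranks, same)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        r_perm = _anosim_r(ranks, perm[iu] == perm[ju])
        if r_perm >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    names, counts = np.unique(lab, return_counts=True)
    return AnosimResult(r_obs, p, n_permutations,
                        dict(zip(names.tolist(), counts.tolist())), seed)


def clustering_index(matrix: DistanceMatrix, labels: dict[str, str],
                     focal: str) -> float:
    """CI = mean(within-focal distances) / mean(focal-to-other distances).

    Values below 1 indicate that the focal group's samples sit closer to
    each other than to samples from other groups.
    """
    lab = np.array([labels.get(s) for s in matrix.ids], dtype=object)
    if any(v is None for v in lab):
        raise ValueError("every sample needs a label")
    return _ci_from_masks(matrix.data, lab == focal, focal)


def _ci_from_masks(data: np.ndarray, is_focal: np.ndarray, focal: str) -> float:
    n_f = int(is_focal.sum())
    if n_f < 2:
        raise ValueError(f"group {focal!r} needs >= 2 members (has {n_f})")
    if n_f == len(is_focal):
        raise ValueError(f"group {focal!r} needs at least one outside sample")
    within = data[np.ix_(is_focal, is_focal)]
    iu = np.triu_indices(n_f, 1)
    between = data[np.ix_(is_focal, ~is_focal)]
    return float(within[iu].mean() / between.mean())


@dataclass
class CIResult:
    ci: float
    p: float
    n_random: int
    focal: str
    seed: int | None = None


def ci_permutation_test(matrix: DistanceMatrix, labels: dict[str, str],
                        focal: str, n_random: int = 100,
                        seed: int | None = None) -> CIResult:
    """Label-randomization test for the Clustering Index.

    Random datasets reassign samples to groups keeping all group sizes
    fixed; the P-value is the fraction of random datasets whose CI is
    strictly lower than the observed one (granularity ``1/n_random``).
    Note the one-sidedness: an observed CI near or above 1 yields large
    P-values by construction.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    lab = np.array([labels[s] for s in matrix.ids], dtype=object)
    ci_real = _ci_from_masks(matrix.data, lab == focal, focal)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_random):
        perm = rng.permutation(lab)
        if _ci_from_masks(matrix.data, perm == focal, focal) < ci_real:
            hits += 1
    return CIResult(ci_real, hits / n_random, n_random, focal, seed)


@dataclass
class OrdinationSummary:
    """Centered principal components of a profile matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray          # samples x components
    variance_explained: np.ndarray   # fractions, non-increasing

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def ordination(profiles: list[FrequencyProfile] | pd.DataFrame) -> OrdinationSummary:
    """PCA on centered (not scaled) profiles, as R's ``prcomp`` default."""
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if len(frame) < 3:
        raise ValueError("need at least 3 samples")
    x = frame.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0.0):
        raise ValueError("profiles are constant across samples")
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > s[0] * 1e-12
    u, s = u[:, keep], s[keep]
    var = s ** 2
    return OrdinationSummary(list(frame.index), u * s, var / var.sum())


@dataclass
class WithinBetweenTest:
    u_statistic: float
    p_raw: float
    p_adjusted: float
    n_within: int
    n_between: int
    mean_within: float
    mean_between: float


def compare_within_between(split: WithinBetweenSplit,
                           n_groups_tested: int = 1) -> WithinBetweenTest:
    """Two-sided Mann-Whitney U on within vs between distances.

    ``n_groups_tested`` is the Bonferroni factor applied when the same
    comparison is run for several groups.
    """
    w, b = split.within_values(), split.between_values()
    if len(w) == 0 or len(b) == 0:
        raise ValueError("both within and between lists must be non-empty")
    u, p = mannwhitneyu(w, b, alternative="two-sided")
    return WithinBetweenTest(float(u), float(p), min(1.0, float(p) * n_groups_tested),
                             len(w), len(b), float(w.mean()), float(b.mean()))
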