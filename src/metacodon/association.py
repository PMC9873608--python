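"""Associations among pairwise-distance variables, and GC-binned ANOSIM.

The unit of observation here is an unordered *sample pair*: each column of
a :class:`DistanceVectorTable` holds one distance variable (codon EU/BC,
amino-acid distance, |delta GC|, k-mer distance, feature-matrix distance...)
evaluated on the same set of pairs.  Correlation, partial correlation and
regression among such columns quantify how much of the codon-usage
divergence between communities tracks each candidate driver.

Pairwise distances are not independent observations; P-values here carry
the same caveat as any distance-vector correlation and should be read as
descriptive.  A Mantel-style permutation P-value is available via
``spearman_mantel`` for the cautious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .distances import DistanceMatrix
from .groupstats import AnosimResult, anosim
from .profiles import FrequencyProfile, profiles_to_frame
from . import distances as _dist


def build_distance_table(columns: dict[str, DistanceMatrix | pd.Series]
                         ) -> pd.DataFrame:
    """Assemble named distance variables into one pairs x variables table.

    Accepts :class:`DistanceMatrix` objects and/or pair-indexed series (as
    produced by ``DistanceMatrix.pair_series``); all inputs must cover the
    identical pair set.
    """
    series = {}
    for name, obj in columns.items():
        s = obj.pair_series() if isinstance(obj, DistanceMatrix) else obj
        series[name] = s
    frame = pd.DataFrame(series)
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"pair sets are not aligned for columns {bad}")
    return frame


def gc_distance_column(gc_values: dict[str, float],
                       pairs: pd.MultiIndex) -> pd.Series:
    """|GC_a - GC_b| for each sample pair (the scalar-consistent GC distance)."""
    return pd.Series(
        [abs(gc_values[a] - gc_values[b]) for a, b in pairs], index=pairs)


def spearman(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray
             ) -> tuple[float, float]:
    """Spearman's rank correlation with two-sided P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_mantel(x: pd.Series, y: pd.Series, n_permutations: int = 999,
                    seed: int | None = None) -> tuple[float, float]:
    """Spearman rho with a permutation P-value (pair rows permuted jointly)."""
    rho, _ = spearman(x, y)
    rng = np.random.default_rng(seed)
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        r, _ = stats.spearmanr(xv, rng.permutation(yv))
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, (1 + hits) / (1 + n_permutations)


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=0)


def partial_correlation(table: pd.DataFrame, target: str, test: str,
                        controls: list[str]) -> tuple[float, float]:
    """Partial Spearman correlation between ``target`` and ``test``.

    All columns are rank-transformed; target and test are each regressed on
    the controls (with intercept) and the residuals are correlated.  The
    P-value uses the t approximation with ``df = n - len(controls) - 2``.
    With no controls this reduces exactly to :func:`spearman`.
    """
    if not controls:
        return spearman(table[target], table[test])
    cols = [target, test, *controls]
    x = table[cols].to_numpy(dtype=float)
    n = len(x)
    if n < len(controls) + 3:
        raise ValueError("too few rows for the requested controls")
    r = _rank(x)
    z = np.column_stack([np.ones(n), r[:, 2:]])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        cc = np.corrcoef(r[:, 2:], rowvar=False)
        pair = np.argwhere(np.triu(np.isclose(np.abs(cc), 1.0), 1))
        names = [(controls[i], controls[j]) for i, j in pair]
        raise ValueError(f"collinear controls: {names or controls}")
    beta, *_ = np.linalg.lstsq(z, r[:, :2], rcond=None)
    resid = r[:, :2] - z @ beta
    rho = float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])
    df = n - len(controls) - 2
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


@dataclass
class RegressionReport:
    """Standardized OLS fit of one distance variable on several others."""

    response: str
    beta: pd.Series       # standardized coefficients, no intercept
    p_values: pd.Series
    r_squared: float
    n: int


def fit_regression(table: pd.DataFrame, response: str,
                   predictors: list[str]) -> RegressionReport:
    """OLS on z-standardized columns; reports standardized beta, p and R^2."""
    if len(table) <= len(predictors) + 1:
        raise ValueError("not enough rows for the requested predictors")
    cols = [response, *predictors]
    x = table[cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant columns: {bad}")
    z = (x - x.mean(axis=0)) / sd
    design = sm.add_constant(z[:, 1:])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix (collinear predictors)")
    fit = sm.OLS(z[:, 0], design).fit()
    return RegressionReport(
        response,
        pd.Series(fit.params[1:], index=predictors),
        pd.Series(fit.pvalues[1:], index=predictors),
        float(fit.rsquared),
        len(table),
    )


@dataclass
class GCBinResult:
    """ANOSIM within one GC bin (or the reason it was skipped)."""

    bin_label: str
    gc_low: float
    gc_high: float
    sample_ids: list[str]
    result: AnosimResult | None
    skipped_reason: str | None = None


def gc_binned_anosim(profiles: list[FrequencyProfile],
                     labels: dict[str, str],
                     gc_values: dict[str, float],
                     binning: str = "quantile",
                     n_bins: int = 4,
                     method: str = "EU",
                     n_permutations: int = 10_000,
                     seed: int | None = None) -> list[GCBinResult]:
    """Run ANOSIM separately inside GC-content bins.

    Bins are formed by sample GC quantiles (balanced occupancy, the
    default) or by equal-width intervals; a bin is skipped unless it holds
    at least two groups of at least two samples.  A biome signal that
    persists within narrow GC bins cannot be a pure GC artifact.
    """
    ids = [p.sample_id for p in profiles]
    missing = [s for s in ids if s not in gc_values]
    if missing:
        raise ValueError(f"samples without GC value: {missing}")
    gc = np.array([gc_values[s] for s in ids])
    if binning == "quantile":
        edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    elif binning == "width":
        edges = np.linspace(gc.min(), gc.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    edges[-1] = np.nextafter(edges[-1], np.inf)
    assignment = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, n_bins - 1)

    full = _dist.distance_matrix(profiles, method)
    out: list[GCBinResult] = []
    rng = np.random.default_rng(seed)
    for b in range(n_bins):
        members = [s for s, a in zip(ids, assignment) if a == b]
        label = f"bin{b + 1}"
        lo, hi = float(edges[b]), float(min(edges[b + 1], gc.max()))
        if len(members) < 4:
            out.append(GCBinResult(label, lo, hi, members, None,
                                   "fewer than 4 samples"))
            continue
        sub_labels = {s: labels[s] for s in members}
        counts = pd.Series(list(sub_labels.values())).value_counts()
        if (counts >= 2).sum() < 2:
            out.append(GCBinResult(label, lo, hi, members, None,
                                   "fewer than 2 groups with >= 2 samples"))
            continue
        keep = [s for s in members if counts[sub_labels[s]] >= 2]
        sub = full.subset(keep)
        res = anosim(sub, sub_labels, n_permutations,
                     seed=int(rng.integers(2 ** 31)))
        out.append(GCBinResult(label, lo, hi, keep, res))
    return out
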