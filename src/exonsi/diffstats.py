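"""Moderated t-statistic with background variance s0 and randomization FDR.

The per-exon statistic is the SAM-style moderated d:

    d = (mean1 - mean2) / (s + s0)
    s = sqrt[(1/n1 + 1/n2) * (SS1 + SS2) / (n1 + n2 - 2)]

where SS is the within-group sum of squared deviations and s0 (default
0.1) is a background variance constant that stabilises low-variance
features.  Significance is calibrated against a randomization null:
either exhaustive/sampled label permutations (for a 3-vs-3 design all
C(6,3) = 20 assignments are enumerated) or a Gaussian redraw of each
exon's values from its pooled mean and standard deviation.  The q-value
of an exon is the SAM false-discovery estimate — median across
randomizations of the null exceedance count of |d|, divided by the
observed exceedance count — clipped to [0, 1] and monotonized so q never
increases with |d|; the null-proportion factor pi0 is fixed at 1
(conservative).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_S0 = 0.1
DEFAULT_Q_MAX = 0.05
MAX_EXHAUSTIVE = 10_000


def moderated_d(group1, group2, s0: float = DEFAULT_S0):
    """Moderated difference statistic for one feature or a stack of features.

    ``group1``/``group2`` are 1-D (single feature) or 2-D
    (features x replicates) arrays; returns a scalar or a 1-D array.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs >= 2 replicate values")
    if s0 < 0:
        raise ParameterError("s0 must be >= 0")
    ss1 = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    d = (g1.mean(axis=1) - g2.mean(axis=1)) / (s + s0)
    if np.isscalar(group1[0]) or np.asarray(group1).ndim == 1:
        return float(d[0])
    return d


def _group_indices(labels: list[str]) -> tuple[np.ndarray, np.ndarray, str, str]:
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    names = list(seen)
    if len(names) != 2:
        raise ParameterError(f"need exactly two condition labels, got {names}")
    labels_arr = np.asarray(labels)
    idx1 = np.flatnonzero(labels_arr == names[0])
    idx2 = np.flatnonzero(labels_arr == names[1])
    return idx1, idx2, names[0], names[1]


def permutation_null(values, labels: list[str],
                     scheme: str = "label-permutation",
                     s0: float = DEFAULT_S0, seed: int | None = None,
                     n_perm: int = 20,
                     max_exhaustive: int = MAX_EXHAUSTIVE) -> np.ndarray:
    """Null ensemble of moderated d values, one column per randomization.

    ``label-permutation`` reassigns the condition labels over the sample
    columns; all assignments are enumerated when their number is at most
    ``max_exhaustive`` (20 for a 3-vs-3 design, identity included),
    otherwise ``n_perm`` assignments are sampled with ``seed``.
    ``gaussian`` redraws each exon's values from one Gaussian with that
    exon's pooled mean and pooled SD, ``n_perm`` times.
    """
    mat = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    idx1, idx2, _, _ = _group_indices(labels)
    n_total = mat.shape[1]
    if len(idx1) + len(idx2) != n_total:
        raise ParameterError("labels must cover every sample column")

    if scheme == "label-permutation":
        n_all = comb(n_total, len(idx1))
        if n_all <= max_exhaustive:
            assignments = list(combinations(range(n_total), len(idx1)))
        else:
            rng = np.random.default_rng(seed)
            assignments = [tuple(rng.choice(n_total, size=len(idx1),
                                            replace=False))
                           for _ in range(n_perm)]
        null = np.empty((mat.shape[0], len(assignments)))
        all_cols = set(range(n_total))
        for b, g1_cols in enumerate(assignments):
            g2_cols = sorted(all_cols - set(g1_cols))
            null[:, b] = moderated_d(mat[:, list(g1_cols)], mat[:, g2_cols], s0)
        return null
    if scheme == "gaussian":
        rng = np.random.default_rng(seed)
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        null = np.empty((mat.shape[0], n_perm))
        for b in range(n_perm):
            redraw = mean + sd * rng.standard_normal(mat.shape)
            null[:, b] = moderated_d(redraw[:, idx1], redraw[:, idx2], s0)
        return null
    raise ParameterError(f"unknown randomization scheme {scheme!r}")


def compute_q(observed_d, null_d) -> np.ndarray:
    """SAM q-values from an observed vector and a null ensemble.

    For each exon, the numerator is the median across randomizations of
    the per-randomization count of null |d*| at or above the exon's |d|;
    the denominator is the count of observed |d| at or above it (always
    at least 1, the exon itself).  Ratios are clipped to [0, 1] and then
    monotonized: each exon receives the smallest estimate attained at any
    threshold it passes, so q is non-increasing in |d|.
    """
    d = np.asarray(observed_d, dtype=float)
    null = np.asarray(null_d, dtype=float)
    if d.size == 0 or null.size == 0:
        raise ParameterError("observed and null ensembles must be non-empty")
    abs_d = np.abs(d)
    sorted_obs = np.sort(abs_d)
    # observed exceedances: #\{j : |d_j| >= |d_i|\}, self included
    n_obs = d.size - np.searchsorted(sorted_obs, abs_d, side="left")
    # null exceedances per randomization column, then the median
    null_counts = np.empty((d.size, null.shape[1]))
    for b in range(null.shape[1]):
        col = np.sort(np.abs(null[:, b]))
        null_counts[:, b] = col.size - np.searchsorted(col, abs_d, side="left")
    med_null = np.median(null_counts, axis=1)
    # pi0 = 1; each randomization has as many features as observed
    q_raw = np.clip(med_null / n_obs, 0.0, 1.0)
    # step-up monotonization: an exon's q is the smallest estimate over all
    # thresholds it passes, i.e. over exons with smaller or equal |d|
    order = np.argsort(abs_d, kind="stable")
    q = np.empty_like(q_raw)
    q[order] = np.minimum.accumulate(q_raw[order])
    return q


def exon_differential(si: pd.DataFrame, labels: list[str],
                      s0: float = DEFAULT_S0,
                      scheme: str = "label-permutation",
                      seed: int | None = None, n_perm: int = 20,
                      log2fc: pd.Series | None = None) -> pd.DataFrame:
    """Moderated d and randomization q for every row of an SI table.

    ``labels`` gives the condition of each SI column; d is oriented as
    first-labelled condition minus second.  Returns a DataFrame indexed
    like ``si`` with columns ``d``, ``q`` and, when ``log2fc`` is given,
    the fold change used downstream for direction calls.
    """
    idx1, idx2, c1, c2 = _group_indices(labels)
    mat = si.to_numpy(dtype=float)
    d = moderated_d(mat[:, idx1], mat[:, idx2], s0)
    null = permutation_null(si, labels, scheme=scheme, s0=s0, seed=seed,
                            n_perm=n_perm)
    q = compute_q(d, null)
    result = pd.DataFrame({"d": d, "q": q}, index=si.index)
    result.attrs["s0"] = s0
    result.attrs["conditions"] = (c1, c2)
    if log2fc is not None:
        result["log2fc"] = log2fc.reindex(si.index)
    return result


def call_significant(result: pd.DataFrame, q_max: float = DEFAULT_Q_MAX
                     ) -> tuple[set[str], set[str]]:
    """Partition significant exons into up/down sets by fold-change sign.

    Direction uses ``log2fc`` when present (positive = up), else the sign
    of d.  Exons with a zero direction score land in neither set.
    """
    sig = result[result["q"] < q_max]
    score = sig["log2fc"] if "log2fc" in sig.columns else sig["d"]
    up = set(sig.index[score > 0])
    down = set(sig.index[score < 0])
    return up, down
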