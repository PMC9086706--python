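"""Maximal information coefficient (MIC) and the nonlinearity rule.

MIC scans all grid resolutions (i columns x j rows) with i*j <= B(n) =
n^0.6 (each axis capped at 15).  For a given (i, j) one axis is
mass-equipartitioned and the other is partitioned optimally by dynamic
programming; both orientations are tried.  The optimized quantity is
the mutual information of the induced discrete distribution,

    I = H(rows) - sum_cols (m_col/n) H(rows | col),

which is additive over columns, so the column optimum is exact for the
given row partition.  The characteristic-matrix entry is I normalized
by log2(min(i, j)); MIC is its maximum.

A correlation is flagged nonlinear when MIC - r^2 >= 0.1, with r the
Pearson correlation of the same pairs.

Following the reference grid-search procedure, runs of equal-x points
("clumps") are never split, and when the number of clumps exceeds both
64 and 15*i they are merged by mass equipartition into at most 15*i
superclumps before the dynamic programme; for n <= 60 the search is
therefore exhaustive over all tie-respecting cut positions.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy import stats as sstats

_EXACT_CLUMP_LIMIT = 64
_SUPERCLUMP_FACTOR = 15


class MICError(ValueError):
    pass


@dataclass(frozen=True)
class MICResult:
    mic: float
    pearson_r: float
    r2: float
    nonlinear: bool
    n: int
    best_grid: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "mic": self.mic,
            "pearson_r": self.pearson_r,
            "r2": self.r2,
            "nonlinear": self.nonlinear,
            "n": self.n,
            "best_grid": list(self.best_grid),
        }


def _seg_cost(cum: np.ndarray, a: int, b: int, n: float) -> float:
    """(mass/n) * H2(rows within clumps (a, b]) in bits."""
    cnt = cum[b] - cum[a]
    mass = cnt.sum()
    if mass <= 0:
        return 0.0
    nz = cnt[cnt > 0]
    return float((mass * math.log2(mass) - (nz * np.log2(nz)).sum()) / n)


def _dp_best_costs_py(cum: np.ndarray, n: float, max_cols: int) -> np.ndarray:
    """min over partitions into exactly l columns (l = 1..max_cols) of the
    summed column cost; vectorised fallback used when numba is absent."""
    m = cum.shape[0] - 1
    max_cols = min(max_cols, m)
    # segment cost matrix S[a, b] for a < b
    counts = cum[None, :, :] - cum[:, None, :]  # (m+1, m+1, j)
    mass = counts.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        plog = np.where(counts > 0, counts * np.log2(np.maximum(counts, 1)), 0.0).sum(axis=2)
        mlog = np.where(mass > 0, mass * np.log2(np.maximum(mass, 1)), 0.0)
    seg = (mlog - plog) / n
    big = np.inf
    f_prev = np.full(m + 1, big)
    f_prev[1:] = seg[0, 1:]
    best = np.full(max_cols + 1, big)
    best[1] = f_prev[m]
    for l in range(2, max_cols + 1):
        f_cur = np.full(m + 1, big)
        for t in range(l, m + 1):
            f_cur[t] = np.min(f_prev[l - 1 : t] + seg[l - 1 : t, t])
        f_prev = f_cur
        best[l] = f_prev[m]
    return best[1:]


try:  # numba gives a large constant-factor speedup on identical arithmetic
    from numba import njit

    @njit(cache=True)
    def _dp_best_costs_nb(cum, n, max_cols):  # pragma: no cover - numba path
        m = cum.shape[0] - 1
        j = cum.shape[1]
        if max_cols > m:
            max_cols = m
        big = 1e300
        seg = np.empty((m + 1, m + 1))
        for a in range(m + 1):
            for b in range(a + 1, m + 1):
                mass = 0.0
                acc = 0.0
                for r in range(j):
                    c = cum[b, r] - cum[a, r]
                    if c > 0:
                        mass += c
                        acc += c * math.log2(c)
                seg[a, b] = (mass * math.log2(mass) - acc) / n if mass > 0 else 0.0
        f_prev = np.full(m + 1, big)
        for t in range(1, m + 1):
            f_prev[t] = seg[0, t]
        best = np.full(max_cols, big)
        best[0] = f_prev[m]
        for l in range(2, max_cols + 1):
            f_cur = np.full(m + 1, big)
            for t in range(l, m + 1):
                mn = big
                for tp in range(l - 1, t):
                    v = f_prev[tp] + seg[tp, t]
                    if v < mn:
                        mn = v
                f_cur[t] = mn
            f_prev = f_cur
            best[l - 1] = f_prev[m]
        return best

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dp_best_costs(cum: np.ndarray, n: float, max_cols: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _dp_best_costs_nb(cum.astype(np.float64), float(n), int(max_cols))
    return _dp_best_costs_py(cum.astype(np.float64), float(n), int(max_cols))


def equipartition_labels(values: np.ndarray, k: int) -> np.ndarray:
    """Mass-equipartition into at most k row bins; ties never split."""
    v = np.asarray(values)
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    labels_sorted = np.zeros(n, dtype=np.int64)
    start = 0
    for r in range(k):
        end = int(round((r + 1) * n / k))
        end = max(end, start + 1)
        end = min(end, n)
        while 0 < end < n and vs[end] == vs[end - 1]:
            end += 1
        labels_sorted[start:end] = r
        start = end
        if start >= n:
            break
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels


def _clump_cumulative(x: np.ndarray, row_labels: np.ndarray, n_rows: int, max_cols: int):
    """Cumulative clump-by-row counts along sorted x, with superclump merging."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    rows = row_labels[order]
    # clump boundaries: positions where x changes
    change = np.empty(len(xs), dtype=bool)
    change[0] = True
    change[1:] = xs[1:] != xs[:-1]
    clump_id = np.cumsum(change) - 1
    m = int(clump_id[-1]) + 1
    counts = np.zeros((m, n_rows), dtype=np.float64)
    np.add.at(counts, (clump_id, rows), 1.0)
    limit = _SUPERCLUMP_FACTOR * max_cols
    if m > _EXACT_CLUMP_LIMIT and m > limit:
        # merge clumps into at most `limit` superclumps by mass equipartition
        mass = counts.sum(axis=1)
        cummass = np.cumsum(mass)
        n = cummass[-1]
        targets = np.arange(1, limit) * n / limit
        cut_idx = np.unique(np.searchsorted(cummass, targets, side="left"))
        groups = np.zeros(m, dtype=np.int64)
        prev = 0
        for g, ci in enumerate(cut_idx):
            groups[prev : ci + 1] = g
            prev = ci + 1
        groups[prev:] = len(cut_idx)
        merged = np.zeros((groups[-1] + 1, n_rows))
        np.add.at(merged, groups, counts)
        counts = merged
        m = counts.shape[0]
    cum = np.zeros((m + 1, n_rows))
    np.cumsum(counts, axis=0, out=cum[1:])
    return cum


def optimized_mi(x: np.ndarray, y: np.ndarray, n_cols: int, n_rows: int) -> float:
    """Max mutual information (bits) over <= n_cols x-partitions given a
    mass-equipartition of y into n_rows rows."""
    n = len(x)
    rows = equipartition_labels(y, n_rows)
    cum = _clump_cumulative(x, rows, n_rows, n_cols)
    row_tot = cum[-1]
    p = row_tot[row_tot > 0] / n
    h_rows = float(-(p * np.log2(p)).sum())
    best_costs = _dp_best_costs(cum, float(n), n_cols)
    return h_rows - float(np.min(best_costs))


def mic(x, y, alpha: float = 0.6, max_grid: int = 15) -> MICResult:
    """MIC, Pearson r and the MIC - r^2 >= 0.1 nonlinearity flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MICError("x and y must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 25:
        raise MICError(f"need >= 25 paired finite observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MICError("MIC undefined for a constant variable")
    b = max(4.0, n**alpha)
    best = 0.0
    best_grid = (2, 2)
    for i in range(2, max_grid + 1):
        if 2 * i > b:
            break
        for j in range(2, max_grid + 1):
            if i * j > b:
                break
            norm = math.log2(min(i, j))
            val = max(optimized_mi(x, y, i, j), optimized_mi(y, x, j, i)) / norm
            if val > best:
                best = val
                best_grid = (i, j)
    r = float(sstats.pearsonr(x, y).statistic)
    r2 = r * r
    return MICResult(
        mic=float(min(best, 1.0)),
        pearson_r=r,
        r2=r2,
        nonlinear=bool(best - r2 >= 0.1),
        n=n,
        best_grid=best_grid,
    )
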