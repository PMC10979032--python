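"""Affinity transform and the regression evaluation suite.

Reported metrics: MSE, RMSE, Pearson r, Spearman ρ (mid-ranks for ties),
concordance index (CI, ties in the prediction count 0.5) and the coefficient
of determination r². The CI ships in two forms that must agree: an O(n²)
pair-enumeration reference and an O(n log n) Fenwick-tree fast path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats


def kd_to_pkd(kd):
    """pKd = -log10(Kd / 1e9) for a dissociation constant given in nM."""
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be strictly positive")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


@dataclass
class MetricReport:
    mse: float
    rmse: float
    pearson: float
    spearman: float
    ci: float
    r2: float
    n: int
    undefined: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)

    def to_json(self, **kw):
        return json.dumps(self.to_dict(), **kw)


def regression_metrics(y, yhat):
    """MSE, RMSE, Pearson, Spearman, CI and r² for one prediction set.

    Correlation fields are NaN (and listed in ``undefined``) when either
    vector is constant; the CI is NaN when the true values admit no strictly
    ordered pair.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least two observations")
    mse = float(np.mean((y - yhat) ** 2))
    rmse = float(np.sqrt(mse))
    undefined = []
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        pearson = spearman = float("nan")
        undefined += ["pearson", "spearman"]
    else:
        pearson = float(stats.pearsonr(y, yhat).statistic)
        spearman = float(stats.spearmanr(y, yhat).statistic)
    if np.ptp(y) == 0:
        r2 = float("nan")
        undefined.append("r2")
        ci = float("nan")
        undefined.append("ci")
    else:
        r2 = float(1.0 - np.sum((yhat - y) ** 2) / np.sum((np.mean(y) - y) ** 2))
        ci = concordance_index(y, yhat)
    return MetricReport(mse=mse, rmse=rmse, pearson=pearson, spearman=spearman,
                        ci=ci, r2=r2, n=n, undefined=undefined)


def concordance_index_slow(y, yhat):
    """O(n²) reference CI: all pairs with strictly ordered true values;
    a correctly ordered prediction counts 1, a tie 0.5."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    num = 0.0
    z = 0
    n = len(y)
    for i in range(n):
        for j in range(n):
            if y[i] > y[j]:
                z += 1
                d = yhat[i] - yhat[j]
                num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    if z == 0:
        return float("nan")
    return num / z


class _Fenwick:
    def __init__(self, n):
        self.t = np.zeros(n + 1)

    def add(self, i, v=1.0):
        i += 1
        while i < len(self.t):
            self.t[i] += v
            i += i & (-i)

    def prefix(self, i):
        """Sum of entries with index < i."""
        s = 0.0
        while i > 0:
            s += self.t[i]
            i -= i & (-i)
        return s


def concordance_index(y, yhat):
    """Fast CI via a Fenwick tree over compressed prediction ranks.

    Processes observations in ascending true order, one tie-group at a time;
    for each element, earlier elements with smaller prediction are
    concordant and equal predictions count half.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    ranks = stats.rankdata(yhat, method="dense").astype(int) - 1
    n_ranks = ranks.max() + 1
    order = np.argsort(y, kind="stable")
    tree = _Fenwick(n_ranks)
    num = 0.0
    z = 0
    seen = 0
    i = 0
    while i < n:
        j = i
        while j < n and y[order[j]] == y[order[i]]:
            j += 1
        group = order[i:j]
        for idx in group:
            r = ranks[idx]
            below = tree.prefix(r)          # strictly smaller predictions
            equal = tree.prefix(r + 1) - below
            num += below + 0.5 * equal
            z += seen
        for idx in group:
            tree.add(ranks[idx])
        seen += len(group)
        i = j
    if z == 0:
        return float("nan")
    return num / z
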