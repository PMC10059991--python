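"""Quade test and post-hoc procedures for comparing algorithms across problems.

The Quade test is a nonparametric analogue of a two-way ANOVA for n
problems x k algorithms result tables.  Unlike the Friedman test it does
not treat all problems as equally informative: each problem (block) is
weighted by the rank of its within-problem score range, so problems on
which the algorithms differ a lot count more.

Procedure (higher scores = better by default):

1. rank algorithms within each problem, rank 1 for the best score
   (midranks on ties);
2. rank the problems by their score range R_i = max - min (midranks);
   call these weights Q_i;
3. form S_ij = Q_i * (r_ij - (k+1)/2) and the statistic
   F = (n-1) * B / (A - B), with A = sum S_ij^2 and
   B = (1/n) * sum_j (sum_i S_ij)^2, which is F-distributed with
   (k-1, (n-1)(k-1)) degrees of freedom under the null;
4. weighted average ranks T_j = sum_i Q_i r_ij / (n(n+1)/2) feed the
   pairwise post-hoc z statistics
   z = (T_a - T_b) / sqrt(k(k+1)(2n+1)(k-1) / (18 n (n+1))).

Five p-value adjustments against a control are provided: Bonferroni-Dunn,
Holm, Hochberg, Finner and Li.  For k = 2 (a single comparison) all five
coincide with the raw two-sided normal p-value.

No Quade implementation exists in scipy or statsmodels, so the procedure
is implemented here; it cross-checks against R's ``stats::quade.test``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ResultMatrix:
    """n problems (rows, e.g. subjects) x k algorithms (columns) score table."""

    scores: np.ndarray
    problems: list[str]
    algorithms: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n, k = self.scores.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 problems and 2 algorithms")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("result matrix contains missing or non-finite cells")
        if len(self.problems) != n or len(self.algorithms) != k:
            raise ValueError("label lengths do not match the score table")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResultMatrix":
        return cls(frame.to_numpy(dtype=float),
                   [str(i) for i in frame.index],
                   [str(c) for c in frame.columns])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.problems, columns=self.algorithms)


@dataclass
class QuadeResult:
    matrix: ResultMatrix
    within_ranks: np.ndarray      # r_ij, rank 1 = best
    block_weights: np.ndarray     # Q_i, rank of the problem's score range
    average_ranks: np.ndarray     # T_j per algorithm (lower = better)
    statistic: float
    df: tuple[int, int]
    p_value: float

    def ranks_by_algorithm(self) -> dict[str, float]:
        return dict(zip(self.matrix.algorithms, self.average_ranks))


@dataclass
class PosthocResult:
    control: str
    comparisons: list[str]
    z: np.ndarray
    p_raw: np.ndarray
    adjusted: dict[str, np.ndarray] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        data = {"z": self.z, "p": self.p_raw}
        data.update(self.adjusted)
        return pd.DataFrame(data, index=self.comparisons)


def quade_test(matrix: ResultMatrix, higher_is_better: bool = True) -> QuadeResult:
    """Run the Quade test on a complete n x k result table.

    Raises ``ValueError`` when every block is fully tied (A = B = 0),
    where the statistic is undefined.
    """
    X = matrix.scores
    n, k = X.shape
    direction = -1.0 if higher_is_better else 1.0
    r = np.apply_along_axis(sps.rankdata, 1, direction * X)
    ranges = X.max(axis=1) - X.min(axis=1)
    Q = sps.rankdata(ranges)
    S = Q[:, None] * (r - (k + 1) / 2.0)
    A = float((S ** 2).sum())
    B = float((S.sum(axis=0) ** 2).sum() / n)
    if A == B:
        raise ValueError("Quade statistic undefined: all blocks are tied (A == B)")
    stat = (n - 1) * B / (A - B)
    df = (k - 1, (n - 1) * (k - 1))
    p = float(sps.f.sf(stat, *df))
    T = (Q[:, None] * r).sum(axis=0) / (n * (n + 1) / 2.0)
    return QuadeResult(matrix, r, Q, T, float(stat), df, p)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    """Adjusted p-values for m comparisons ordered arbitrarily."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ps = p[order]
    adj = np.empty(m)
    if method == "bonferroni-dunn":
        adj = np.minimum(m * ps, 1.0)
    elif method == "holm":
        # step-down: running max of (m - i) * p_(i)
        adj = np.minimum(np.maximum.accumulate((m - np.arange(m)) * ps), 1.0)
    elif method == "hochberg":
        # step-up: running min (from the largest p) of (m - i) * p_(i)
        adj = np.minimum.accumulate(((m - np.arange(m)) * ps)[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
    elif method == "finner":
        adj = 1.0 - (1.0 - ps) ** (m / np.arange(1, m + 1))
        adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    elif method == "li":
        adj = ps / (ps + 1.0 - ps[-1])
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    out = np.empty(m)
    out[order] = adj
    return out


POSTHOC_METHODS = ("bonferroni-dunn", "holm", "hochberg", "finner", "li")


def quade_posthoc(result: QuadeResult, control: str) -> PosthocResult:
    """Pairwise comparisons of every algorithm against a control.

    z statistics use the Quade weighted average ranks with
    SE = sqrt(k(k+1)(2n+1)(k-1) / (18 n (n+1))); two-sided normal
    p-values are adjusted by all five supported procedures.
    """
    algos = result.matrix.algorithms
    if control not in algos:
        raise KeyError(f"unknown control algorithm {control!r}")
    n, k = result.matrix.scores.shape
    se = np.sqrt(k * (k + 1) * (2 * n + 1) * (k - 1) / (18.0 * n * (n + 1)))
    ci = algos.index(control)
    others = [j for j in range(k) if j != ci]
    T = result.average_ranks
    z = np.array([(T[j] - T[ci]) / se for j in others])
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    labels = [f"{control} vs. {algos[j]}" for j in others]
    adjusted = {m: _adjust(p_raw, m) for m in POSTHOC_METHODS}
    return PosthocResult(control, labels, z, p_raw, adjusted)


def decide(result: PosthocResult, alpha: float = 0.05,
           method: str = "holm") -> dict[str, bool]:
    """Reject/retain per comparison: reject iff adjusted p < alpha (strict)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    adj = result.adjusted[method]
    return {lab: bool(p < alpha) for lab, p in zip(result.comparisons, adj)}
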