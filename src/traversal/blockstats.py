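"""Mack-Skillings test for replicated complete block designs.

The design here is targets (blocks) x protocols (treatments) x replicate
runs, with the same number c of replicates in every cell.  Observations
are ranked within each block (mid-ranks for ties), treatment rank sums are
accumulated across blocks, and the omnibus statistic is the quadratic form

    MS = (S - E)' V^- (S - E)

where V is the exact permutation covariance of the rank-sum vector given
the realized ranks (so ties are handled automatically) and V^- is a
pseudoinverse.  Without ties this reduces to the familiar closed form with
chi-square (k - 1) asymptotics.  A within-block permutation p-value and an
exact enumeration for small designs are provided alongside the asymptotic
one; post-hoc pairwise comparisons use a large-sample Tukey-type rule that
controls the experimentwise error rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, studentized_range

from .errors import DesignError, ValidationError

#: switch from exact enumeration to the asymptotic p-value when the total
#: number of within-block assignments exceeds this
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class BlockDesignTable:
    """Complete replicated block design: (n_blocks, k_treatments, c_replicates)."""

    values: np.ndarray
    blocks: tuple[str, ...]
    treatments: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise DesignError("values must be (n_blocks, k_treatments, c_replicates)")
        if not np.all(np.isfinite(v)):
            raise DesignError("incomplete design: missing or non-finite observations")
        n, k, c = v.shape
        if k < 2 or n < 1 or c < 1:
            raise DesignError("need k >= 2 treatments, n >= 1 blocks, c >= 1 replicates")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        if len(self.blocks) != n or len(self.treatments) != k:
            raise DesignError("block/treatment labels do not match the table shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        block_col: str = "block",
        treatment_col: str = "treatment",
        value_col: str = "value",
    ) -> "BlockDesignTable":
        """Build a table from a long-format frame, checking completeness."""
        blocks = sorted(df[block_col].unique().tolist())
        treatments = sorted(df[treatment_col].unique().tolist())
        sizes = df.groupby([block_col, treatment_col]).size()
        c_values = set(sizes.tolist())
        if len(sizes) != len(blocks) * len(treatments) or len(c_values) != 1:
            raise DesignError("incomplete design: unequal or missing cells")
        c = c_values.pop()
        values = np.empty((len(blocks), len(treatments), c))
        for bi, b in enumerate(blocks):
            for tj, t in enumerate(treatments):
                cell = df[(df[block_col] == b) & (df[treatment_col] == t)][value_col]
                values[bi, tj] = cell.to_numpy()
        return cls(values, tuple(map(str, blocks)), tuple(map(str, treatments)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None


def _rank_sums(block: np.ndarray) -> tuple[np.ndarray, float]:
    """Within-block mid-rank sums per treatment and the rank population variance."""
    k, c = block.shape
    ranks = rankdata(block.ravel()).reshape(k, c)
    return ranks.sum(axis=1), float(np.var(ranks))


def _moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-sum vector S, its permutation-null mean E, and covariance V."""
    n, k, c = values.shape
    N = k * c
    S = np.zeros(k)
    V = np.zeros((k, k))
    base = N * np.eye(k) - c * np.ones((k, k))
    for i in range(n):
        r, var = _rank_sums(values[i])
        S += r
        # drawing c of the N realized ranks without replacement per treatment
        if N > 1:
            V += (c * var / (N - 1)) * base
    E = np.full(k, n * c * (N + 1) / 2.0)
    return S, E, V


def _statistic_from(S: np.ndarray, E: np.ndarray, V: np.ndarray) -> float:
    x = S - E
    if np.allclose(V, 0.0):
        return 0.0
    return float(x @ np.linalg.pinv(V) @ x)


def mack_skillings(tbl: BlockDesignTable, method: str = "auto") -> TestResult:
    """Omnibus Mack-Skillings test of treatment effects.

    ``method`` is ``"asymptotic"`` (chi-square, k - 1 df), ``"exact"``
    (full within-block enumeration) or ``"auto"``, which uses the exact
    enumeration when it needs at most ``EXACT_ENUMERATION_LIMIT``
    assignments and the asymptotic tail otherwise.  All observations tied
    gives statistic 0 and p = 1.
    """
    n, k, c = tbl.shape
    S, E, V = _moments(tbl.values)
    stat = _statistic_from(S, E, V)
    if np.allclose(V, 0.0):
        return TestResult(0.0, k - 1, 1.0, "degenerate (all tied)")
    if method not in ("auto", "asymptotic", "exact"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        per_block = math.factorial(k * c) // math.factorial(c) ** k
        method = "exact" if per_block**n <= EXACT_ENUMERATION_LIMIT else "asymptotic"
    if method == "exact":
        p = exact_pvalue(tbl)
        return TestResult(stat, k - 1, p, "exact enumeration")
    p = float(chi2.sf(stat, k - 1))
    return TestResult(stat, k - 1, p, "asymptotic chi-square")


def _block_assignment_sums(block: np.ndarray) -> np.ndarray:
    """Rank-sum vectors of every distinct assignment of one block's ranks."""
    k, c = block.shape
    ranks = rankdata(block.ravel())
    N = k * c
    out = []

    def rec(remaining: tuple[int, ...], acc: list[float]) -> None:
        if len(acc) == k - 1:
            out.append(acc + [ranks[list(remaining)].sum()])
            return
        for combo in itertools.combinations(remaining, c):
            rest = tuple(x for x in remaining if x not in combo)
            rec(rest, acc + [ranks[list(combo)].sum()])

    rec(tuple(range(N)), [])
    return np.asarray(out)


def exact_pvalue(tbl: BlockDesignTable) -> float:
    """Exact permutation p-value by full within-block enumeration."""
    n, k, c = tbl.shape
    _, E, V = _moments(tbl.values)
    obs = _statistic_from(*_moments(tbl.values))
    per_block = [_block_assignment_sums(tbl.values[i]) for i in range(n)]
    total = 1
    for pb in per_block:
        total *= len(pb)
    if total > EXACT_ENUMERATION_LIMIT:
        raise ValidationError(
            f"{total} assignments exceed the exact-enumeration limit"
        )
    Vinv = np.linalg.pinv(V)
    sums = per_block[0]
    for pb in per_block[1:]:
        sums = (sums[:, None, :] + pb[None, :, :]).reshape(-1, k)
    x = sums - E
    stats = np.einsum("ij,jk,ik->i", x, Vinv, x)
    return float(np.mean(stats >= obs - 1e-9))


def permutation_pvalue(
    tbl: BlockDesignTable, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo within-block permutation p-value and its standard error.

    Ranks are invariant under within-block permutation, so only the
    treatment assignment is reshuffled; the covariance V is likewise
    permutation-invariant, making the statistic cheap to vectorize.
    """
    n, k, c = tbl.shape
    N = k * c
    S, E, V = _moments(tbl.values)
    obs = _statistic_from(S, E, V)
    Vinv = np.linalg.pinv(V)
    rng = np.random.default_rng(seed)
    sums = np.zeros((n_perm, k))
    for i in range(n):
        ranks = rankdata(tbl.values[i].ravel())
        perm = np.argsort(rng.random((n_perm, N)), axis=1)
        permuted = ranks[perm].reshape(n_perm, k, c)
        sums += permuted.sum(axis=2)
    x = sums - E
    stats = np.einsum("ij,jk,ik->i", x, Vinv, x)
    p = float(np.mean(stats >= obs - 1e-9))
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_perm) / n_perm))
    return p, se


def posthoc_pairs(tbl: BlockDesignTable, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs comparisons controlling the experimentwise error at alpha.

    A pair (u, v) is declared different when |S_u - S_v| exceeds
    q_{alpha, k, inf} * sqrt(Var(S_u - S_v) / 2), the large-sample
    Tukey-type critical value on the tie-corrected rank-sum scale.  For
    k = 2 this is algebraically the omnibus test at the same alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    n, k, c = tbl.shape
    S, E, V = _moments(tbl.values)
    q = float(studentized_range.ppf(1.0 - alpha, k, np.inf))
    rows = []
    for u in range(k):
        for v in range(u + 1, k):
            diff = S[u] - S[v]
            var_d = V[u, u] + V[v, v] - 2 * V[u, v]
            crit = q * math.sqrt(max(var_d, 0.0) / 2.0)
            rows.append(
                {
                    "treatment_a": tbl.treatments[u],
                    "treatment_b": tbl.treatments[v],
                    "rank_sum_diff": diff,
                    "critical": crit,
                    "significant": bool(abs(diff) >= crit) if crit > 0 else False,
                }
            )
    return pd.DataFrame(rows)
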