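"""One-shot trust game and dictator game: payoffs and behavioral statistics.

In the one-shot trust game (TG) both players are endowed with 10 points
(1 point = 3 CNY).  The trustor transfers X in 0..10; the transfer is
tripled; the trustee returns Y in 0..3X.  Final payoffs: trustor
``10 - X + Y``, trustee ``10 + 3X - Y``.  X is the trust-propensity measure.
The programmed trustee returns a uniform integer between 40% and 60% of the
tripled transfer.  In the one-shot dictator game (DG) the dictator splits an
endowment of 20; the allocation X in 0..20 is the social-preference measure.

The statistics layer covers the comparisons used with these scores: a
weighted meta-analytic mean transfer, a one-sample Wilcoxon signed-rank test
against a benchmark proportion (the scores are discrete and non-normal), and
an FDR-corrected Spearman correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .statistical_inference import fdr_adjust


@dataclass(frozen=True)
class GameRule:
    """Parameterization of the TG/DG pair.

    ``return_fraction_range`` bounds the programmed trustee return as a
    fraction of the tripled transfer; returns are whole points (rounded
    half-even at the bounds, matching the games' one-point increments).
    """

    trustor_endowment: int = 10
    trustee_endowment: int = 10
    multiplier: int = 3
    dictator_endowment: int = 20
    point_value: float = 3.0  # CNY per point
    return_fraction_range: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self) -> None:
        lo, hi = self.return_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("return fractions must satisfy 0 <= lo <= hi <= 1")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")

    def return_bounds(self, X: int) -> tuple[int, int]:
        """Integer bounds of the programmed return for transfer ``X``."""
        lo, hi = self.return_fraction_range
        tripled = self.multiplier * X
        return int(round(lo * tripled)), int(round(hi * tripled))


@dataclass(frozen=True)
class GameOutcome:
    X: int
    Y: int
    trustor_points: int
    trustee_points: int
    trustor_cny: float
    trustee_cny: float


def tg_payoff(X: int, Y: int, rule: GameRule = GameRule()) -> GameOutcome:
    """Final TG payoffs for transfer ``X`` and return ``Y``.

    Trustor: ``E - X + Y``; trustee: ``E' + mX - Y`` (endowments E, E' and
    multiplier m from the rule).  The point totals always satisfy
    ``trustor + trustee = E + E' + (m - 1) X``.
    """
    X, Y = int(X), int(Y)
    if not 0 <= X <= rule.trustor_endowment:
        raise ValueError(f"transfer X={X} outside 0..{rule.trustor_endowment}")
    if not 0 <= Y <= rule.multiplier * X:
        raise ValueError(f"return Y={Y} outside 0..{rule.multiplier * X}")
    trustor = rule.trustor_endowment - X + Y
    trustee = rule.trustee_endowment + rule.multiplier * X - Y
    return GameOutcome(X=X, Y=Y, trustor_points=trustor, trustee_points=trustee,
                       trustor_cny=trustor * rule.point_value,
                       trustee_cny=trustee * rule.point_value)


def trustee_return(X: int, rule: GameRule = GameRule(),
                   rng: np.random.Generator | None = None) -> int:
    """Programmed return: uniform integer in the rule's fraction bounds."""
    if not 0 <= X <= rule.trustor_endowment:
        raise ValueError(f"transfer X={X} outside 0..{rule.trustor_endowment}")
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = rule.return_bounds(int(X))
    return int(rng.integers(lo, hi + 1))


def payment_bounds(rule: GameRule = GameRule()) -> tuple[float, float]:
    """Exact (min, max) trustor payment in CNY under the programmed return.

    Computed by exhaustive enumeration of every feasible transfer and every
    integer return the algorithm can produce.
    """
    payments = [
        tg_payoff(X, Y, rule).trustor_cny
        for X in range(rule.trustor_endowment + 1)
        for Y in range(*(b + o for b, o in zip(rule.return_bounds(X), (0, 1))))
    ]
    return min(payments), max(payments)


def dg_payoff(X: int, rule: GameRule = GameRule()) -> tuple[int, int]:
    """DG payoffs ``(dictator, receiver)`` for allocation ``X``."""
    X = int(X)
    if not 0 <= X <= rule.dictator_endowment:
        raise ValueError(f"allocation X={X} outside 0..{rule.dictator_endowment}")
    return rule.dictator_endowment - X, X


# ---------------------------------------------------------------------------
# Behavioral statistics
# ---------------------------------------------------------------------------

def weighted_mean_transfer(studies: list[tuple[float, int]]) -> float:
    """Subject-weighted mean transfer proportion across studies.

    ``studies`` is a list of (proportion_sent, n_subjects); the result is
    ``sum(p_i n_i) / sum(n_i)``.
    """
    if not studies:
        raise ValueError("empty study list")
    num = den = 0.0
    for p, n in studies:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
        if n < 1:
            raise ValueError("study must have n >= 1 subjects")
        num += p * n
        den += n
    return num / den


def wilcoxon_vs_benchmark(
    sample: np.ndarray, benchmark: float, method: str = "approx"
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of ``sample`` against a benchmark.

    Zero differences are dropped; ties get average ranks.  ``method="approx"``
    returns the tie-corrected normal z (positive when the sample tends above
    the benchmark) with its two-tailed p.  ``method="exact"`` enumerates all
    sign assignments (n <= 20 after dropping zeros) for the exact two-tailed
    p alongside the same z.
    """
    d = np.asarray(sample, dtype=float) - float(benchmark)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean_w) / np.sqrt(var_w)
    if method == "approx":
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        stat_obs = abs(w_pos - mean_w)
        hits = total = 0
        for signs in range(1 << n):
            w = sum(ranks[j] for j in range(n) if signs >> j & 1)
            total += 1
            if abs(w - mean_w) >= stat_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError("method must be 'approx' or 'exact'")
    return float(z), float(p)


def correlation_screen(
    table: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Spearman correlations over variable pairs with BH-FDR q-values.

    ``pairs`` defaults to all unordered column pairs.  Missing data are
    dropped pairwise; a pair with a constant variable (or fewer than 4
    complete cases) is flagged and excluded from the correction.
    """
    if pairs is None:
        pairs = list(combinations(table.columns, 2))
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if len(sub) < 4 or np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"var1": a, "var2": b, "n": len(sub),
                         "rho": np.nan, "p": np.nan, "flag": "degenerate"})
            continue
        res = stats.spearmanr(x, y)
        rows.append({"var1": a, "var2": b, "n": len(sub),
                     "rho": float(res.statistic), "p": float(res.pvalue), "flag": ""})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["flag"] == ""
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    return out
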