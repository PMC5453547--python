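"""Inferential statistics used by the audit.

Three planned tests: an unequal-variance (Welch) t-test for group
contrasts, Spearman rank correlation for genus size vs sharing incidence,
and a Pearson chi-square homogeneity test across families.  Statistics are
computed from their closed forms; p-values come from scipy distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    groups: dict[str, dict[str, float]] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "groups": self.groups,
            "warnings": list(self.warnings),
        }


def subsample_to_min_n(x: Sequence[float], y: Sequence[float], seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomly subsample the larger group down to the smaller group's n."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    if len(x) > n:
        x = rng.choice(x, size=n, replace=False)
    if len(y) > n:
        y = rng.choice(y, size=n, replace=False)
    return x, y


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, v in (("x", x), ("y", y)):
        if len(v) < 2:
            raise ValueError(f"group {name} needs n >= 2")
        if np.var(v, ddof=1) == 0.0:
            raise ValueError(f"group {name} has zero variance")
    vx = np.var(x, ddof=1) / len(x)
    vy = np.var(y, ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        groups={
            "x": {"n": len(x), "mean": float(x.mean())},
            "y": {"n": len(y), "mean": float(y.mean())},
        },
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-rank ties; p via t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(
        statistic=rho,
        df=float(n - 2),
        p_value=p,
        groups={"pairs": {"n": n, "mean": float("nan")}},
    )


def chi_square_homogeneity(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square for an r x 2 count table against homogeneity.

    df = r - 1.  A warning is attached when more than 20% of expected
    counts fall below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise ValueError("table must be r x 2 with r >= 2")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ValueError("zero row or column total")
    expected = np.outer(row_tot, col_tot) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[0] - 1
    p = float(sps.chi2.sf(x2, df))
    warnings: tuple[str, ...] = ()
    frac_small = float((expected < 5).mean())
    if frac_small > 0.2:
        warnings = (
            f"{frac_small:.0%} of expected counts are below 5; "
            "chi-square approximation may be poor",
        )
    return TestResult(statistic=x2, df=float(df), p_value=p, warnings=warnings)
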