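"""Small-sample association statistics for trait / movement-metric tables.

With five or six individuals, parametric p-values are fragile; this module
implements the screen used on such data: Pearson product-moment correlation
with the two-tailed t-transform p-value, Spearman rank correlation where a
Shapiro-Wilk test rejects normality, and an exhaustive permutation check
that reports the fraction of all n! pairings whose correlation meets or
exceeds the observed one.  Multiple-testing-adjusted significance is
reported alongside raw p-values, never silently filtered.
"""

from __future__ import annotations

import itertools
import logging
import math
import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TraitTable",
    "CorrelationResult",
    "pearson_r",
    "r_to_p",
    "spearman_r",
    "choose_method",
    "permutation_ratio",
    "trait_correlation_screen",
]

log = logging.getLogger(__name__)

#: Fig-style flags for the exhaustive permutation ratio.
POSITIVE_FLAG = 0.025
NEGATIVE_FLAG = 0.975


@dataclass
class TraitTable:
    """Individuals x variables table with named subsets.

    ``data`` is indexed by individual id; ``subsets`` maps a subset name
    (e.g. a single-breed subgroup) to the list of individual ids it contains.
    """

    data: pd.DataFrame
    subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated variable names: {dup}")

    def subset(self, name: str | None) -> pd.DataFrame:
        if name is None:
            return self.data
        return self.data.loc[self.subsets[name]]


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance variable")
    return float(np.corrcoef(x, y)[0, 1])


def r_to_p(r: float, n: int) -> float:
    """Two-tailed p for a correlation via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) >= 1:
        warnings.warn("|r| = 1: p below machine precision")
        return sys.float_info.min
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def spearman_r(x, y) -> tuple[float, float]:
    """Rank correlation with mid-ranks; p via the t approximation.

    At n of 5-6 the t approximation is only indicative; use
    :func:`permutation_ratio` for an exact check.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n >= 4 for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("all-tied variable")
    rho = pearson_r(stats.rankdata(x), stats.rankdata(y))
    return rho, r_to_p(rho, len(x))


def choose_method(x, y, alpha: float = 0.05) -> str:
    """'spearman' if a Shapiro-Wilk test rejects normality of either variable."""
    for v in (x, y):
        v = np.asarray(v, float)
        if np.ptp(v) > 0 and stats.shapiro(v).pvalue < alpha:
            return "spearman"
    return "pearson"


def _perm_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of y against every permutation of x's pairing (all n!)."""
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return (yc[perms] @ xc) / denom


def permutation_ratio(x, y, monte_carlo: bool = False, n_mc: int = 100_000,
                      seed: int = 0) -> float:
    """Fraction of pairings whose correlation >= the observed correlation.

    All n! pairings of ``y`` against the fixed ``x`` are enumerated (n <= 8);
    the identity pairing is included, so the ratio is at least 1/n!.  A
    ratio below 0.025 flags a positive association, above 0.975 a negative
    one.  For n > 8 pass ``monte_carlo=True`` to sample pairings instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance variable")
    r_obs = pearson_r(x, y)
    if n > 8:
        if not monte_carlo:
            raise ValueError("n > 8: exhaustive enumeration infeasible; "
                             "pass monte_carlo=True to sample pairings")
        rng = np.random.default_rng(seed)
        xc, yc = x - x.mean(), y - y.mean()
        denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        hits = sum(
            (yc[rng.permutation(n)] @ xc) / denom >= r_obs for _ in range(n_mc))
        return (hits + 1) / (n_mc + 1)
    r_all = _perm_correlations(x, y)
    return float(np.mean(r_all >= r_obs - 1e-12))


@dataclass(frozen=True)
class CorrelationResult:
    var_a: str
    var_b: str
    n: int
    method: str
    r: float
    p: float
    perm_ratio: float

    @property
    def perm_flag(self) -> str:
        if self.perm_ratio < POSITIVE_FLAG:
            return "positive"
        if self.perm_ratio > NEGATIVE_FLAG:
            return "negative"
        return "none"


def trait_correlation_screen(table: TraitTable, subset: str | None = None,
                             alpha: float = 0.05,
                             max_exhaustive: int = 8) -> pd.DataFrame:
    """All-pairs correlation screen over a trait/metric table.

    Every unordered variable pair gets a method choice (Shapiro-Wilk gate),
    coefficient, two-tailed p, and the exhaustive Pearson permutation ratio.
    Bonferroni and Benjamini-Hochberg adjusted significance are annotated
    next to the raw p-values.  Constant variables are skipped with a log
    entry.  With k usable variables the screen has k(k-1)/2 rows.
    """
    df = table.subset(subset).apply(pd.to_numeric, errors="coerce")
    df = df.dropna(axis=1, how="any")
    if len(df) < 4:
        raise ValueError("subset must contain at least 4 individuals")
    usable = []
    for c in df.columns:
        if np.ptp(df[c].to_numpy(float)) == 0:
            log.info("skipping constant variable %r", c)
        else:
            usable.append(c)
    n = len(df)
    results = []
    for ai, a in enumerate(usable):
        for b in usable[ai + 1:]:
            x = df[a].to_numpy(float)
            y = df[b].to_numpy(float)
            method = choose_method(x, y, alpha)
            if method == "pearson":
                r = pearson_r(x, y)
                p = r_to_p(r, n)
            else:
                r, p = spearman_r(x, y)
            ratio = permutation_ratio(x, y, monte_carlo=n > max_exhaustive)
            results.append(CorrelationResult(a, b, n, method, r, p, ratio))
    out = pd.DataFrame([vars(r) | {"perm_flag": r.perm_flag} for r in results])
    if len(out):
        out["significant_raw"] = out["p"] < alpha
        out["significant_bonferroni"] = multipletests(
            out["p"], alpha=alpha, method="bonferroni")[0]
        out["significant_bh"] = multipletests(
            out["p"], alpha=alpha, method="fdr_bh")[0]
    return out
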