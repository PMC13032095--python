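"""Statistical battery, implemented from first principles.

Spearman rank correlation, Benjamini-Hochberg FDR, the paired t test, the
Wilcoxon rank-sum test (normal approximation with tie correction plus exact
enumeration for small samples), and one-way repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction are all computed directly from
their definitions; scipy supplies only distribution tail functions (and the
Shapiro-Wilk routine, used as a normality gate).  Reference implementations
in scipy/statsmodels/pingouin serve as independent oracles in the test
suite, never as the computation itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exceptions import ConfigurationError
from .synthetic_cohort import DOMAINS, FACETS, PROTOTYPES

__all__ = [
    "midrank", "spearman", "bh_fdr", "paired_t", "wilcoxon_rank_sum",
    "rm_anova_gg", "shapiro_wilk", "correlation_battery",
    "CorrelationRecord", "RMANOVAResult",
]


@dataclass(frozen=True)
class CorrelationRecord:
    """One (predictor, index) cell of a correlation battery."""

    predictor: str
    index: str
    family: str
    n: int
    rho: float
    p: float
    q: float


@dataclass(frozen=True)
class RMANOVAResult:
    """One-way within-subject ANOVA with Greenhouse-Geisser correction."""

    F: float
    eps_gg: float
    df1: float
    df2: float
    p: float
    n: int
    k: int


def midrank(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average (mid-ranks)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sx = x[order]
    i = 0
    while i < n:
        j = i
        while j < n and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average of ranks i+1 .. j
        i = j
    return ranks


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with mid-ranks and a Student-t two-sided p value.

    Pairs with a missing value in either vector are deleted before ranking
    (pairwise deletion).  A constant vector yields the undefined-correlation
    marker (NaN, NaN).  |rho| = 1 returns p = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("spearman: input vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ConfigurationError(f"spearman: need n >= 3 complete pairs, got {n}")
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    q_(i) = min_{j >= i} m * p_(j) / j on the sorted scale, mapped back to
    the input order and capped at 1.  Missing entries (NaN) are excluded
    from m and returned as NaN; callers report the exclusion count.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ConfigurationError("bh_fdr: p values must lie in [0, 1]")
    m = pv.size
    q = np.full(p.shape, np.nan)
    if m:
        order = np.argsort(pv, kind="mergesort")
        sorted_q = pv[order] * m / np.arange(1, m + 1)
        sorted_q = np.minimum.accumulate(sorted_q[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(sorted_q, 1.0)
        q[valid] = qs
    return q


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.

    Zero-variance differences take a dedicated branch: all-zero differences
    give t = 0, p = 1; a nonzero constant difference gives the infinite-t
    marker with p = 0, each with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("paired_t: input vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = (x - y)[keep]
    n = d.size
    if n < 2:
        raise ConfigurationError(f"paired_t: need n >= 2 complete pairs, got {n}")
    df = n - 1
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            warnings.warn("paired_t: zero-variance, zero-mean differences; t = 0")
            return 0.0, df, 1.0
        warnings.warn("paired_t: zero-variance nonzero differences; |t| = inf")
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided permutation p for the rank-sum statistic, full enumeration."""
    total = 0
    extreme = 0
    mu = n_a * (len(ranks) + 1) / 2.0
    dev = abs(w_obs - mu)
    for combo in combinations(range(len(ranks)), n_a):
        w = float(sum(ranks[i] for i in combo))
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12) -> dict:
    """Wilcoxon rank-sum test of two independent samples.

    Returns the rank sum of the first group, a z statistic from the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction, the corresponding two-sided p, and -- when the combined
    sample size does not exceed ``exact_max_n`` -- the exact two-sided p by
    full enumeration of rank assignments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ConfigurationError("wilcoxon_rank_sum: both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n = n_a + n_b
    ranks = midrank(pooled)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        dev = w - mu
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / math.sqrt(var) if dev != 0 else 0.0
        p = 2.0 * _sps.norm.sf(abs(z))
    out = {"w": w, "z": float(z), "p": float(min(p, 1.0)), "n_a": n_a, "n_b": n_b,
           "p_exact": None}
    if n <= exact_max_n:
        out["p_exact"] = _exact_rank_sum_p(ranks, n_a, w)
    return out


def rm_anova_gg(data) -> RMANOVAResult:
    """One-way within-subject ANOVA with Greenhouse-Geisser correction.

    ``data`` is an n x k matrix (subjects x conditions); rows containing
    missing values are removed (listwise deletion, reflected in ``n``).
    F = MS_condition / MS_error after removing the subject effect.  The
    Greenhouse-Geisser epsilon is (sum lambda)^2 / ((k-1) sum lambda^2)
    where lambda are the eigenvalues of the covariance of k-1 orthonormal
    contrast scores; the corrected degrees of freedom are eps*(k-1) and
    eps*(k-1)(n-1).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError("rm_anova_gg: data must be a 2-D matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2:
        raise ConfigurationError(f"rm_anova_gg: need k >= 2 conditions, got {k}")
    if n < k:
        raise ConfigurationError(f"rm_anova_gg: need n >= k complete rows, got {n}")
    grand = x.mean()
    row_means = x.mean(axis=1, keepdims=True)
    col_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means - col_means + grand
    ss_err = float((resid**2).sum())
    df1_raw, df2_raw = k - 1, (k - 1) * (n - 1)
    if ss_err == 0:
        raise ConfigurationError("rm_anova_gg: zero error variance")
    f_stat = (ss_cond / df1_raw) / (ss_err / df2_raw)
    # orthonormal contrasts via QR of the centering complement
    helmert = np.eye(k)[:, 1:] - 1.0 / k
    q, _ = np.linalg.qr(helmert)
    scores = x @ q  # n x (k-1)
    v = np.cov(scores, rowvar=False, ddof=1)
    v = np.atleast_2d(v)
    lam = np.linalg.eigvalsh(v)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float((lam**2).sum())
    if denom == 0:
        raise ConfigurationError(
            "rm_anova_gg: singular contrast covariance (no within-subject variance)"
        )
    eps = float(lam.sum()) ** 2 / denom
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    df1, df2 = eps * df1_raw, eps * df2_raw
    p = float(_sps.f.sf(f_stat, df1, df2))
    return RMANOVAResult(F=float(f_stat), eps_gg=eps, df1=df1, df2=df2, p=p, n=n, k=k)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (gate for choosing rank-based statistics).

    Delegates to the established routine after contract checks: 3 <= n <=
    5000 and non-degenerate data.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= x.size <= 5000:
        raise ConfigurationError(f"shapiro_wilk: n = {x.size} outside [3, 5000]")
    if np.all(x == x[0]):
        raise ConfigurationError("shapiro_wilk: constant vector (zero variance)")
    w, p = _sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Correlation battery
# ---------------------------------------------------------------------------

NEO_PREDICTORS = tuple(FACETS) + tuple(DOMAINS)       # 35 predictors
ATTACHMENT_PREDICTORS = tuple(PROTOTYPES)             # 4 predictors


def correlation_battery(
    traits: pd.DataFrame,
    indexes: pd.DataFrame,
    index_cols: list[str],
    fdr_level: float = 0.05,
    trend_level: float = 0.10,
) -> pd.DataFrame:
    """Spearman screen of every predictor against every index, FDR per family.

    Families mirror the per-figure reporting structure: one BH family per
    (index x instrument) battery -- the 35 NEO predictors (30 facets + 5
    domains) form one family per index, the 4 attachment prototypes another.
    Pairwise deletion is used per cell, so n may drift across cells.
    Undefined correlations (constant predictor) stay as missing markers and
    are excluded from the family size, with the count reported in
    ``n_undefined`` attached as DataFrame attrs.
    """
    df = traits.merge(indexes, on="participant_id", how="inner")
    records = []
    n_undefined = 0
    for index_col in index_cols:
        for instrument, predictors in (
            ("neo", NEO_PREDICTORS),
            ("attachment", ATTACHMENT_PREDICTORS),
        ):
            family = f"{index_col}|{instrument}"
            rows = []
            for pred in predictors:
                if pred not in df.columns:
                    continue
                x = df[pred].to_numpy(dtype=float)
                y = df[index_col].to_numpy(dtype=float)
                n = int((~(np.isnan(x) | np.isnan(y))).sum())
                rho, p = spearman(x, y)
                if np.isnan(rho):
                    n_undefined += 1
                rows.append(
                    {"predictor": pred, "index": index_col, "family": family,
                     "instrument": instrument, "n": n, "rho": rho, "p": p}
                )
            qs = bh_fdr([r["p"] for r in rows])
            for r, q in zip(rows, qs):
                r["q"] = float(q) if not np.isnan(q) else float("nan")
                if np.isnan(q):
                    r["significance"] = "undefined"
                elif q < fdr_level:
                    r["significance"] = "significant"
                elif q < trend_level:
                    r["significance"] = "trend"
                else:
                    r["significance"] = "ns"
            records.extend(rows)
    out = pd.DataFrame.from_records(records)
    out.attrs["n_undefined"] = n_undefined
    out.attrs["fdr_level"] = fdr_level
    return out


def attachment_domain_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman matrix of attachment prototypes x personality domains.

    All 20 cells form a single BH family (one figure, one family).
    """
    rows = []
    for proto in PROTOTYPES:
        for dom in DOMAINS:
            x = traits[proto].to_numpy(dtype=float)
            y = traits[dom].to_numpy(dtype=float)
            rho, p = spearman(x, y)
            n = int((~(np.isnan(x) | np.isnan(y))).sum())
            rows.append({"prototype": proto, "domain": dom, "n": n, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
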