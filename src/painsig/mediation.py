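"""Baron-Kenny causal-steps mediation with Sobel validation.

For a candidate chain X -> M -> Y the procedure fits three least-squares
regressions on the same complete-case sample:

    step 1:  Y ~ X        (total effect c)
    step 2:  M ~ X        (path a)
    steps 3-4:  Y ~ X + M (paths b and c')

and classifies the model at level alpha: "full" mediation when c, a, b are
significant and c' is not; "partial" when all four are; "none" when a or b
fails; "no-total-effect" when c fails (the remaining paths are still
reported).  The indirect effect is validated with the classic first-order
Sobel statistic z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2).

Because the three fits share one sample, the ordinary-least-squares identity
c = c' + a*b holds exactly and is asserted on every fitted model.
Variables are z-standardized before fitting so coefficients are comparable
across models; unstandardized coefficients are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .exceptions import CollinearityError, ConfigurationError

__all__ = ["ols", "sobel", "baron_kenny", "bootstrap_indirect", "MediationModel", "PathEstimate"]


@dataclass(frozen=True)
class PathEstimate:
    coef: float
    se: float
    t: float
    p: float

    def significant(self, alpha: float) -> bool:
        return self.p < alpha


@dataclass
class MediationModel:
    """Fitted causal-steps model (standardized scale, unstandardized alongside)."""

    x_label: str
    m_label: str
    y_label: str
    n: int
    c_total: PathEstimate
    a: PathEstimate
    b: PathEstimate
    c_prime: PathEstimate
    sobel_z: float
    sobel_p: float
    classification: str
    alpha: float
    unstandardized: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def path(p: PathEstimate) -> dict:
            return {"coef": p.coef, "se": p.se, "t": p.t, "p": p.p}

        return {
            "x": self.x_label, "m": self.m_label, "y": self.y_label, "n": self.n,
            "c_total": path(self.c_total), "a": path(self.a), "b": path(self.b),
            "c_prime": path(self.c_prime),
            "sobel_z": self.sobel_z, "sobel_p": self.sobel_p,
            "classification": self.classification, "alpha": self.alpha,
            "unstandardized": self.unstandardized,
        }


def ols(y, predictors) -> list[PathEstimate]:
    """Least-squares fit of y on one or two predictors (intercept included).

    Returns one :class:`PathEstimate` per predictor (intercept omitted).
    Standard errors use the unbiased residual variance; p values come from
    the Student t distribution with n - p - 1 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.asarray(v, dtype=float) for v in (
        predictors if isinstance(predictors, (list, tuple)) else [predictors]
    )]
    n = y.size
    if any(c.size != n for c in cols):
        raise ConfigurationError("ols: predictor length mismatch")
    if n <= len(cols) + 1:
        raise ConfigurationError(f"ols: n = {n} too small for {len(cols)} predictors")
    X = np.column_stack([np.ones(n), *cols])
    # collinearity check: centered predictor block must be well conditioned
    centered = np.column_stack(cols) - np.mean(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1] or np.linalg.cond(centered) > 1e8:
        raise CollinearityError("ols: collinear predictors")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    out = []
    for j in range(1, X.shape[1]):
        if se[j] == 0:
            t = math.inf if beta[j] != 0 else 0.0
            p = 0.0 if beta[j] != 0 else 1.0
        else:
            t = beta[j] / se[j]
            p = 2.0 * float(_sps.t.sf(abs(t), dof))
        out.append(PathEstimate(coef=float(beta[j]), se=float(se[j]),
                                t=float(t), p=min(float(p), 1.0)))
    return out


def sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """First-order Sobel test of the indirect effect a*b.

    z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2), two-sided normal p.  a*b = 0
    with a defined denominator gives z = 0, p = 1; a zero denominator yields
    the undefined marker (NaN, NaN).
    """
    if se_a < 0 or se_b < 0:
        raise ConfigurationError("sobel: standard errors must be >= 0")
    denom = math.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    if denom == 0:
        if a * b == 0:
            return 0.0, 1.0
        return float("nan"), float("nan")
    z = a * b / denom
    p = 2.0 * float(_sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("mediation: constant variable")
    return (v - v.mean()) / sd


def baron_kenny(
    x, m, y,
    alpha: float = 0.05,
    x_label: str = "X", m_label: str = "M", y_label: str = "Y",
) -> MediationModel:
    """Fit the causal-steps mediation model X -> M -> Y.

    Complete cases only, the same case set across all three regressions.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[keep], m[keep], y[keep]
    n = x.size
    if n < 10:
        raise ConfigurationError(f"baron_kenny: need >= 10 complete cases, got {n}")
    # unstandardized fits (reported alongside)
    cu = ols(y, [x])[0]
    au = ols(m, [x])[0]
    cpu, bu = ols(y, [x, m])
    # standardized fits (classification scale)
    xs, ms, ys = _standardize(x), _standardize(m), _standardize(y)
    c_total = ols(ys, [xs])[0]
    a = ols(ms, [xs])[0]
    c_prime, b = ols(ys, [xs, ms])
    # exact least-squares decomposition of the total effect
    assert abs(c_total.coef - (c_prime.coef + a.coef * b.coef)) < 1e-10
    z, p = sobel(a.coef, a.se, b.coef, b.se)
    if not (a.significant(alpha) and b.significant(alpha)):
        cls = "none"
    elif not c_total.significant(alpha):
        cls = "no-total-effect"
    elif c_prime.significant(alpha):
        cls = "partial"
    else:
        cls = "full"
    return MediationModel(
        x_label=x_label, m_label=m_label, y_label=y_label, n=n,
        c_total=c_total, a=a, b=b, c_prime=c_prime,
        sobel_z=z, sobel_p=p, classification=cls, alpha=alpha,
        unstandardized={
            "c_total": cu.coef, "a": au.coef, "b": bu.coef, "c_prime": cpu.coef,
        },
    )


def bootstrap_indirect(
    x, m, y, n_boot: int = 2000, seed: int = 0, ci: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the indirect effect a*b.

    Optional diagnostic beyond the classic Sobel validation; standardized
    scale, complete cases.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[keep], m[keep], y[keep]
    rng = np.random.default_rng(seed)
    n = x.size
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xs, ms, ys = _standardize(x[idx]), _standardize(m[idx]), _standardize(y[idx])
        a = ols(ms, [xs])[0].coef
        b = ols(ys, [xs, ms])[1].coef
        vals[i] = a * b
    lo = (1 - ci) / 2
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo))
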