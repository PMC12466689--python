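"""Statistical estimators for antimicrobial-use surveillance.

Three estimators carry the analysis:

* :func:`wilson_interval` — the Wilson score interval for a binomial
  proportion, used for every reported percentage.
* :func:`pooled_prevalence` — a common-effect (fixed-effect) inverse-variance
  meta-analysis of per-practice treatment prevalences, which adjusts the
  overall prevalence for the practice effect.
* :class:`AgeSplineModel` — a logistic regression of treatment status on a
  natural cubic spline of horse age (3 degrees of freedom by default),
  capturing the U-shaped age dependence of treatment probability.

All percentages destined for reports are rounded half-up to one decimal via
:func:`round_pct`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit


__all__ = [
    "PrevalenceEstimate",
    "MetaPrevalence",
    "AgeSplineModel",
    "AgeSplineResults",
    "SeparationError",
    "natural_spline_basis",
    "wilson_interval",
    "pooled_prevalence",
    "yearly_trend",
    "round_pct",
]


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round a percentage half-up to ``ndigits`` decimals (report parity)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceEstimate:
    """A binomial proportion k/n with its Wilson score interval."""

    k: int
    n: int
    point: float
    lower: float
    upper: float
    ci_level: float = 0.95
    z: float = 1.959963984540054

    @property
    def point_pct(self) -> float:
        return round_pct(100.0 * self.point)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return round_pct(100.0 * self.lower), round_pct(100.0 * self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci_pct
        return f"{self.point_pct}% (95% CI {lo}-{hi}%)"


def wilson_interval(k, n, ci_level: float = 0.95):
    """Wilson score confidence interval for a binomial proportion.

    With ``p = k/n`` and ``z`` the standard-normal quantile for ``ci_level``::

        (p + z^2/2n  +/-  z * sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n)

    clamped to [0, 1].  Scalars return a :class:`PrevalenceEstimate`;
    array input returns ``(lower, upper)`` arrays (vectorised, used by the
    coverage simulation).
    """
    z = float(sps.norm.ppf(0.5 + ci_level / 2.0))
    k_arr = np.asarray(k, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("require 0 <= k <= n")
    p = k_arr / n_arr
    denom = 1.0 + z * z / n_arr
    centre = p + z * z / (2.0 * n_arr)
    half = z * np.sqrt(p * (1.0 - p) / n_arr + z * z / (4.0 * n_arr * n_arr))
    lower = np.clip((centre - half) / denom, 0.0, 1.0)
    upper = np.clip((centre + half) / denom, 0.0, 1.0)
    # at the boundaries the score bound is exact; remove fp residue
    lower = np.where(k_arr == 0, 0.0, lower)
    upper = np.where(k_arr == n_arr, 1.0, upper)
    if np.isscalar(k) or np.ndim(k) == 0:
        return PrevalenceEstimate(
            k=int(k), n=int(n), point=float(p),
            lower=float(lower), upper=float(upper),
            ci_level=ci_level, z=z,
        )
    return lower, upper


# ---------------------------------------------------------------------------
# Common-effect inverse-variance meta-analysis of proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaPrevalence:
    """Pooled prevalence across practices (common-effect meta-analysis).

    Per-practice proportions are pooled on the ``transform`` scale with
    weights equal to the inverse within-practice variance; the pooled CI is
    back-transformed.  ``table`` holds per-practice estimates and normalised
    weights (forest-plot data).
    """

    point: float
    lower: float
    upper: float
    transform: str
    ci_level: float
    table: pd.DataFrame = field(repr=False)

    @property
    def point_pct(self) -> float:
        return round_pct(100.0 * self.point)


def pooled_prevalence(counts, transform: str = "logit",
                      ci_level: float = 0.95) -> MetaPrevalence:
    """Pool per-practice proportions with a common-effect meta-analysis.

    Parameters
    ----------
    counts
        Sequence of ``(k_i, n_i)`` pairs, one per practice.
    transform
        ``"logit"`` (default): theta_i = logit(p_i), within-practice variance
        ``1/k_i + 1/(n_i - k_i)``; zero or full cells get a 0.5 continuity
        correction (0.5 added to both cells).  ``"raw"``: theta_i = p_i,
        variance ``p_i (1 - p_i) / n_i`` with the same continuity rule.
    """
    if transform not in ("logit", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    ks = np.array([c[0] for c in counts], dtype=float)
    ns = np.array([c[1] for c in counts], dtype=float)
    if len(ks) == 0 or np.any(ns < 1):
        raise ValueError("need >=1 practice with n_i >= 1")
    # continuity correction for boundary cells
    boundary = (ks == 0) | (ks == ns)
    kc = np.where(boundary, ks + 0.5, ks)
    nc = np.where(boundary, ns + 1.0, ns)
    p = kc / nc
    if transform == "logit":
        theta = logit(p)
        var = 1.0 / kc + 1.0 / (nc - kc)
    else:
        theta = p
        var = p * (1.0 - p) / nc
        if np.any(var <= 0):
            raise ValueError("degenerate within-practice variance on raw scale")
    w = 1.0 / var
    wsum = w.sum()
    pooled = float((w * theta).sum() / wsum)
    se = math.sqrt(1.0 / wsum)
    z = float(sps.norm.ppf(0.5 + ci_level / 2.0))
    lo, hi = pooled - z * se, pooled + z * se
    if transform == "logit":
        point, lower, upper = expit(pooled), expit(lo), expit(hi)
    else:
        point = pooled
        lower, upper = max(lo, 0.0), min(hi, 1.0)
    table = pd.DataFrame({
        "k": ks.astype(int), "n": ns.astype(int),
        "estimate": ks / ns, "theta": theta, "variance": var,
        "weight": w / wsum,
    })
    return MetaPrevalence(point=float(point), lower=float(lower),
                          upper=float(upper), transform=transform,
                          ci_level=ci_level, table=table)


# ---------------------------------------------------------------------------
# Natural cubic spline logistic regression of treatment on age
# ---------------------------------------------------------------------------

class SeparationError(ValueError):
    """Raised when the logistic fit is degenerate (one outcome class only,
    or perfect separation)."""


def _spline_knots(x: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Interior knots at quantiles, boundary knots at the data range."""
    if df < 2:
        raise ValueError("natural spline needs df >= 2")
    n_interior = df - 1
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, probs)
    boundary = np.array([x.min(), x.max()], dtype=float)
    return np.asarray(interior, dtype=float), boundary


def natural_spline_basis(x, knots=None, boundary_knots=None, df: int = 3):
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    The basis spans the space of cubic splines on the given knots that are
    linear beyond the boundary knots (second and third derivatives vanish
    there).  Construction: with sorted knots ``xi_1 < ... < xi_K`` (boundary
    knots included) and truncated cubics ``t_k(x) = max(x - xi_k, 0)^3``,

        d_k(x) = (t_k(x) - t_K(x)) / (xi_K - xi_k)
        basis  = [x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}]

    which yields ``K - 1`` columns; interior knots are chosen so that
    ``K - 1 == df``.
    """
    x = np.asarray(x, dtype=float)
    if knots is None or boundary_knots is None:
        interior, boundary = _spline_knots(x, df)
        if knots is not None:
            interior = np.asarray(knots, dtype=float)
        if boundary_knots is not None:
            boundary = np.asarray(boundary_knots, dtype=float)
    else:
        interior = np.asarray(knots, dtype=float)
        boundary = np.asarray(boundary_knots, dtype=float)
    xi = np.sort(np.concatenate([interior, boundary]))
    if len(np.unique(xi)) != len(xi):
        raise ValueError("duplicate spline knots")
    K = len(xi)

    def d(k: int) -> np.ndarray:
        tk = np.maximum(x - xi[k], 0.0) ** 3
        tK = np.maximum(x - xi[K - 1], 0.0) ** 3
        return (tk - tK) / (xi[K - 1] - xi[k])

    dlast = d(K - 2)
    cols = [x] + [d(k) - dlast for k in range(K - 2)]
    return np.column_stack(cols), xi


@dataclass
class AgeSplineResults:
    """Fitted treatment-probability-over-age curve with pointwise CI.

    ``curve`` has columns ``age``, ``probability``, ``lower``, ``upper``;
    ``minimum_age`` is the grid age with the lowest fitted probability.
    """

    params: np.ndarray
    cov_params: np.ndarray
    knots: np.ndarray
    df: int
    ci_level: float
    curve: pd.DataFrame
    n_obs: int
    n_treated: int
    converged: bool
    deviance: float
    _model: "AgeSplineModel"

    @property
    def minimum_age(self) -> float:
        i = int(np.argmin(self.curve["probability"].to_numpy()))
        return float(self.curve["age"].iloc[i])

    def predict(self, ages) -> pd.DataFrame:
        return self._model._predict(self, np.asarray(ages, dtype=float))

    def summary(self) -> str:
        lines = [
            "Treatment probability over age — natural-spline logistic fit",
            f"  n = {self.n_obs} consultations, {self.n_treated} treated",
            f"  spline df = {self.df}, knots at "
            + ", ".join(f"{k:.2f}" for k in self.knots),
            f"  converged: {self.converged}, deviance = {self.deviance:.1f}",
            f"  fitted minimum at age {self.minimum_age:.1f} y",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - thin plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c["age"], 100 * c["probability"], color="C0")
        ax.fill_between(c["age"], 100 * c["lower"], 100 * c["upper"],
                        alpha=0.25, color="C0")
        ax.set_xlabel("age [years]")
        ax.set_ylabel("% consultations with antibiotic treatment")
        return ax


class AgeSplineModel:
    """Logistic regression of treatment status on a natural spline of age.

    Ages must be pre-filtered to the plausible range (0-40 years for
    horses); the model places ``df - 1`` interior knots at age quantiles and
    boundary knots at the observed range, then fits by maximum likelihood
    (IRLS, via a binomial GLM).  Pointwise confidence bands come from the
    delta method on the linear predictor.
    """

    def __init__(self, ages, treated, df: int = 3):
        self.ages = np.asarray(ages, dtype=float)
        self.treated = np.asarray(treated).astype(float)
        if self.ages.shape != self.treated.shape:
            raise ValueError("ages and treated must have equal length")
        if self.ages.size < df + 2:
            raise ValueError("too few observations for the requested df")
        self.df = int(df)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, age_col: str = "age_years",
                       treated_col: str = "treated", df: int = 3,
                       age_range: tuple[float, float] = (0.0, 40.0)):
        d = data[[age_col, treated_col]].dropna()
        d = d[(d[age_col] >= age_range[0]) & (d[age_col] <= age_range[1])]
        return cls(d[age_col].to_numpy(), d[treated_col].to_numpy(), df=df)

    def fit(self, ci_level: float = 0.95, grid_points: int = 201,
            maxiter: int = 25, tol: float = 1e-8) -> AgeSplineResults:
        import statsmodels.api as sm

        y = self.treated
        if y.min() == y.max():
            raise SeparationError(
                "all outcomes identical: logistic fit is degenerate")
        X, xi = natural_spline_basis(self.ages, df=self.df)
        self._knots = xi
        Xc = sm.add_constant(X, prepend=True)
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(
                maxiter=maxiter, tol=tol)
        except Exception as exc:  # statsmodels PerfectSeparation etc.
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise SeparationError("non-finite coefficients (separation?)")
        out = AgeSplineResults(
            params=np.asarray(res.params), cov_params=np.asarray(res.cov_params()),
            knots=xi, df=self.df, ci_level=ci_level,
            curve=pd.DataFrame(), n_obs=len(y), n_treated=int(y.sum()),
            converged=bool(res.converged), deviance=float(res.deviance),
            _model=self,
        )
        grid = np.linspace(self.ages.min(), self.ages.max(), grid_points)
        out.curve = self._predict(out, grid)
        return out

    def _predict(self, res: AgeSplineResults, ages: np.ndarray) -> pd.DataFrame:
        import statsmodels.api as sm

        interior, boundary = res.knots[1:-1], res.knots[[0, -1]]
        X, _ = natural_spline_basis(ages, knots=interior,
                                    boundary_knots=boundary)
        Xc = sm.add_constant(X, prepend=True, has_constant="add")
        eta = Xc @ res.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xc, res.cov_params, Xc))
        z = float(sps.norm.ppf(0.5 + res.ci_level / 2.0))
        return pd.DataFrame({
            "age": ages,
            "probability": expit(eta),
            "lower": expit(eta - z * se),
            "upper": expit(eta + z * se),
        })


def fit_age_spline(ages, treated, df: int = 3,
                   ci_level: float = 0.95) -> AgeSplineResults:
    """Convenience wrapper: ``AgeSplineModel(ages, treated, df).fit()``."""
    return AgeSplineModel(ages, treated, df=df).fit(ci_level=ci_level)


# ---------------------------------------------------------------------------
# Yearly trend
# ---------------------------------------------------------------------------

def yearly_trend(consultations: pd.DataFrame,
                 treated_col: str = "treated",
                 restrict_to_practices_present_all_years: bool = True,
                 years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-year treated share with Wilson CIs.

    When the restriction flag is set, only practices with at least one
    consultation in every calendar year of the range contribute (so the
    series is not distorted by practices joining or leaving).
    """
    d = consultations.copy()
    d["year"] = pd.to_datetime(d["date"]).dt.year
    if years is None:
        years = (int(d["year"].min()), int(d["year"].max()))
    year_range = list(range(years[0], years[1] + 1))
    d = d[d["year"].isin(year_range)]
    if restrict_to_practices_present_all_years:
        per = d.groupby("practice_id")["year"].nunique()
        keep = per[per == len(year_range)].index
        d = d[d["practice_id"].isin(keep)]
    rows = []
    for yr in year_range:
        sub = d[d["year"] == yr]
        n = len(sub)
        k = int(sub[treated_col].sum()) if n else 0
        if n:
            est = wilson_interval(k, n)
            rows.append({"year": yr, "k": k, "n": n, "pct": est.point_pct,
                         "lower_pct": est.ci_pct[0], "upper_pct": est.ci_pct[1]})
        else:
            rows.append({"year": yr, "k": 0, "n": 0, "pct": np.nan,
                         "lower_pct": np.nan, "upper_pct": np.nan})
    return pd.DataFrame(rows)
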