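"""Allometric power-law scaling and nonparametric group comparisons.

A physiological quantity Y (elemental content, phytodetritus intake) is
modelled against individual size X as Y = a * X**b. Fitting is ordinary
least squares on (ln X, ln Y); the back-transformed intercept gives the
scaling coefficient a and the slope the scaling exponent b. b ~ 1 means the
quantity rises in proportion to size (isometry); b < 1 means the
weight-specific quantity declines with size (hypoallometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, SingularFitError

ScalingRegime = Literal["isometric", "hypoallometric", "hyperallometric"]


class PowerLawScaling:
    """Power-law regressor Y = a * X**b fitted by log-log least squares.

    scikit-learn style estimator: ``fit(X, y)`` then ``predict(X)``; fitted
    attributes carry a trailing underscore.

    Parameters
    ----------
    ci_level : float, default 0.95
        Two-sided confidence level for the exponent interval (t-based).

    Attributes
    ----------
    a_ : float
        Scaling coefficient, exp(log-intercept).
    b_ : float
        Scaling exponent (log-log slope).
    se_b_ : float
        Standard error of ``b_``.
    ci_b_ : tuple of float
        Confidence interval for ``b_``.
    r_squared_ : float
    n_ : int
    equation_ : str
        Back-transformed equation, e.g. ``"Y = 0.288 * X^0.90"``.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def get_params(self, deep: bool = True) -> dict:
        return {"ci_level": self.ci_level}

    def set_params(self, **params) -> "PowerLawScaling":
        for key, value in params.items():
            if key != "ci_level":
                raise ValueError(f"unknown parameter {key!r}")
            self.ci_level = value
        return self

    def fit(self, X, y, sample_weight=None) -> "PowerLawScaling":
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != yv.shape:
            raise InvalidInputError("X and y must have the same length")
        if len(x) < 3:
            raise InvalidInputError(f"need at least 3 points, got {len(x)}")
        if np.any(x <= 0) or np.any(yv <= 0):
            raise InvalidInputError("power-law fit requires strictly positive X and Y")
        if np.ptp(np.log(x)) < 1e-12:
            raise SingularFitError("predictor is constant; exponent unidentifiable")

        design = sm.add_constant(np.log(x))
        if sample_weight is None:
            model = sm.OLS(np.log(yv), design)
        else:
            model = sm.WLS(np.log(yv), design, weights=np.asarray(sample_weight, dtype=float))
        res = model.fit()

        self.log_intercept_ = float(res.params[0])
        self.a_ = float(math.exp(res.params[0]))
        self.b_ = float(res.params[1])
        self.se_b_ = float(res.bse[1])
        alpha = 1.0 - self.ci_level
        ci = res.conf_int(alpha=alpha)
        self.ci_b_ = (float(ci[1][0]), float(ci[1][1]))
        self.r_squared_ = float(res.rsquared)
        self.n_ = int(len(x))
        self.equation_ = f"Y = {self.a_:.4g} * X^{self.b_:.3g}"
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "a_"):
            raise RuntimeError("PowerLawScaling must be fitted before predict")
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.any(x <= 0):
            raise InvalidInputError("predict requires strictly positive X")
        return self.a_ * x ** self.b_

    def score(self, X, y) -> float:
        """R^2 on the log-log scale (the scale the model is fitted on)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.log(np.asarray(y, dtype=float).reshape(-1))
        pred = np.log(self.predict(x))
        ss_res = float(np.sum((yv - pred) ** 2))
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass(frozen=True)
class ScalingFit:
    """Result of one power-law scaling fit."""

    response: str
    predictor: str
    a: float
    b: float
    se_b: float
    ci_b: tuple[float, float]
    n: int
    r_squared: float
    equation: str

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_b"] = list(self.ci_b)
        return d


def fit_power_law(x: Sequence[float], y: Sequence[float], *, response: str = "Y",
                  predictor: str = "X", ci_level: float = 0.95,
                  sample_weight: Sequence[float] | None = None) -> ScalingFit:
    """Fit Y = a * X**b by log-log least squares; see :class:`PowerLawScaling`."""
    est = PowerLawScaling(ci_level=ci_level).fit(x, y, sample_weight=sample_weight)
    return ScalingFit(response=response, predictor=predictor, a=est.a_, b=est.b_,
                      se_b=est.se_b_, ci_b=est.ci_b_, n=est.n_,
                      r_squared=est.r_squared_, equation=est.equation_)


def classify_scaling(fit: ScalingFit) -> ScalingRegime:
    """Classify a scaling exponent by where 1 falls relative to its CI."""
    lo, hi = fit.ci_b
    if hi < 1.0:
        return "hypoallometric"
    if lo > 1.0:
        return "hyperallometric"
    return "isometric"


#: The standard scaling-fit set: (response, predictor) column pairs of the
#: per-individual capsule table, in the order they are reported.
STANDARD_FIT_PAIRS = (
    ("toc_per_ind", "dw_per_ind"),
    ("tn_per_ind", "dw_per_ind"),
    ("pc_per_ind", "dw_per_ind"),
    ("pn_per_ind", "dw_per_ind"),
    ("pc_per_ind", "toc_per_ind"),
    ("pn_per_ind", "tn_per_ind"),
)


def standard_fits(per_individual, ci_level: float = 0.95) -> dict[str, ScalingFit]:
    """Fit the standard set of size-scaling relations on a capsule table.

    Parameters
    ----------
    per_individual : DataFrame
        Output of :func:`foramtracer.prep.per_individual_table`.

    Returns
    -------
    dict
        Keyed ``"<response>~<predictor>"`` (e.g. ``"toc_per_ind~dw_per_ind"``).
    """
    fits = {}
    for response, predictor in STANDARD_FIT_PAIRS:
        fits[f"{response}~{predictor}"] = fit_power_law(
            per_individual[predictor], per_individual[response],
            response=response, predictor=predictor, ci_level=ci_level)
    return fits


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups."""

    variable: str
    group1: str
    group2: str
    U_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "normal"


def _u_statistic(ranks: np.ndarray, idx1: Sequence[int], n1: int, n2: int) -> float:
    r1 = float(np.sum(ranks[list(idx1)]))
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact permutation p-value of the two-sided U test over a tied multiset.

    Counts, over all C(n1+n2, n1) equally likely group assignments, those
    whose U deviates from the null mean n1*n2/2 at least as much as observed.
    The count is computed with a subset-sum generating function over the
    doubled midranks (integers even under ties), so the cost is polynomial
    rather than combinatorial.
    """
    n = len(ranks)
    n2 = n - n1
    doubled = np.rint(2.0 * ranks).astype(np.int64)  # midranks are k or k + 1/2
    total_sum = int(doubled.sum())
    # dp[k, s] = number of k-subsets of the ranks seen so far with doubled-sum s
    dp = np.zeros((n1 + 1, total_sum + 1))
    dp[0, 0] = 1.0
    for r in doubled:
        for k in range(min(n1, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total_sum + 1 - r]
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    sums = np.nonzero(dp[n1] > 0)[0]
    u_values = sums / 2.0 - n1 * (n1 + 1) / 2.0
    hits = dp[n1, sums[np.abs(u_values - mu) >= dev_obs - 1e-9]].sum()
    return float(hits / dp[n1].sum())


def mann_whitney(group1: Sequence[float], group2: Sequence[float], *,
                 variable: str = "value", label1: str = "group1",
                 label2: str = "group2", exact_limit: int = 400) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    For small problems (n1*n2 <= ``exact_limit``) the p-value is exact: the
    permutation distribution of U over all C(n1+n2, n1) relabellings of the
    observed (possibly tied) pooled values is computed by a subset-sum
    recursion, and the two-sided p is the probability of a deviation of U
    from its mean n1*n2/2 at least as large as observed. Larger problems use
    the normal approximation with midranks and the standard tie correction.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 == 0 or n2 == 0:
        raise InvalidInputError("both groups must be non-empty")

    pooled = np.concatenate([x1, x2])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, range(n1), n1, n2)
    mu = n1 * n2 / 2.0

    if n1 * n2 <= exact_limit:
        p = _exact_two_sided_p(ranks, n1, u_obs)
        method = "exact"
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:  # all values identical
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)  # continuity corrected
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        method = "normal"

    return GroupComparison(variable=variable, group1=label1, group2=label2,
                           U_statistic=float(u_obs), p_value=float(p),
                           n1=n1, n2=n2, method=method)
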