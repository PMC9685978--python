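"""Univariable two-sample MR estimators.

All estimators consume a univariable :class:`~mrscreen.instruments.HarmonisedSet`
(per-SNP exposure effects ``bx`` with SE ``sx``, outcome effects ``by`` with
SE ``sy``) and return an :class:`MRResults` carrying the causal-effect
estimate on the log-odds-per-SD scale, its standard error, normal-theory 95%
confidence bounds, a two-sided p-value and the instrument count.

Estimators
----------
- Wald ratio: ``theta = by / bx`` for a single instrument, first-order
  delta-method SE ``sy / |bx|``.
- IVW: fixed-effect inverse-variance-weighted meta-analysis of the per-SNP
  Wald ratios, each weighted by the inverse variance of the SNP-outcome
  association; algebraically a weighted regression of ``by`` on ``bx``
  through the origin with weights ``sy^-2``.
- MR-Egger: weighted regression ``by = alpha + theta * bx`` after orienting
  all SNPs to ``bx >= 0``; the intercept absorbs directional pleiotropy
  under the InSIDE assumption.  SEs carry a multiplicative random-effects
  inflation ``max(1, sqrt(RSS_w / (J - 2)))`` and p-values use a t(J-2)
  reference.
- Weighted median: the 50% point of the weight-ordered per-SNP ratio
  estimates; consistent when at least half the weight comes from valid
  instruments.  Its SE comes from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .instruments import HarmonisedSet
from .summstats import MIN_PVALUE, ValidationError

Z95 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    pass


@dataclass
class MRResults:
    """A causal-effect estimate from one MR method.

    ``theta`` is on the log-odds-per-SD scale; ``odds_ratio()`` transforms
    the point estimate and CI to the OR scale used for reporting.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise EstimationError("standard error must be positive")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise EstimationError("confidence interval must bracket the estimate")

    def odds_ratio(self) -> dict:
        """OR per SD with 95% CI, exp-transformed from the log-odds triple."""
        return {
            "or": float(np.exp(self.theta)),
            "ci_low": float(np.exp(self.ci_low)),
            "ci_high": float(np.exp(self.ci_high)),
        }

    def to_frame(self) -> pd.DataFrame:
        orr = self.odds_ratio()
        row = {
            "method": self.method,
            "n_snp": self.n_snp,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": orr["or"],
            "or_ci_low": orr["ci_low"],
            "or_ci_high": orr["ci_high"],
            "egger_intercept": self.intercept,
            "egger_intercept_p": self.intercept_p,
        }
        return pd.DataFrame([row])

    def summary(self) -> str:
        orr = self.odds_ratio()
        lines = [
            f"{self.method} MR estimate ({self.n_snp} SNPs)",
            f"  theta  = {self.theta: .4f}  (SE {self.se:.4f})",
            f"  95% CI = [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            f"  OR/SD  = {orr['or']:.2f}  ({orr['ci_low']:.2f}, {orr['ci_high']:.2f})",
            f"  p      = {self.pvalue:.3g}",
        ]
        if self.intercept is not None:
            lines.append(
                f"  intercept = {self.intercept: .5f} (SE {self.intercept_se:.5f}, "
                f"p = {self.intercept_p:.3g})"
            )
        return "\n".join(lines)


def _normal_result(method: str, theta: float, se: float, n_snp: int, **kw) -> MRResults:
    z = theta / se
    p = float(np.clip(2 * stats.norm.sf(abs(z)), MIN_PVALUE, 1.0))
    return MRResults(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pvalue=p,
        n_snp=n_snp,
        **kw,
    )


def _univariable_arrays(hset: HarmonisedSet) -> tuple[np.ndarray, ...]:
    if hset.n_exposure != 1:
        raise EstimationError("univariable estimator given a multi-exposure set")
    return hset.bx.ravel(), hset.sx.ravel(), hset.by.ravel(), hset.sy.ravel()


# --------------------------------------------------------------------- #


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRResults:
    """Single-instrument causal estimate ``by / bx``.

    The first-order (delta-method) standard error ``sy / |bx|`` ignores the
    uncertainty in ``bx``, consistent with the fixed-effect IVW weighting
    and appropriate for strong instruments.
    """
    if bx == 0:
        raise EstimationError("null_instrument: bx must be nonzero")
    theta = by / bx
    se = sy / abs(bx)
    return _normal_result("wald", theta, se, n_snp=1)


class IVW:
    """Fixed-effect inverse-variance-weighted MR model.

    ``IVW(hset).fit()`` returns the IVW estimate; a single-SNP set reduces
    exactly to the Wald ratio.  With ``random_effects=True`` the SE is
    inflated by ``max(1, sqrt(RSS_w/(J-1)))`` (multiplicative random
    effects) as a sensitivity variant.
    """

    def __init__(self, hset: HarmonisedSet):
        self.hset = hset
        self.bx, self.sx, self.by, self.sy = _univariable_arrays(hset)

    def fit(self, random_effects: bool = False) -> MRResults:
        bx, by, sy = self.bx, self.by, self.sy
        j = len(bx)
        if j == 0:
            raise EstimationError("no instruments")
        if j == 1:
            res = wald_ratio(bx[0], self.sx[0], by[0], sy[0])
            return replace(res, method="ivw", meta={"reduced_to": "wald"})
        w = sy**-2
        sxx = float(np.sum(w * bx * bx))
        theta = float(np.sum(w * bx * by)) / sxx
        se = sxx**-0.5
        if random_effects:
            rss = float(np.sum(w * (by - theta * bx) ** 2))
            se *= max(1.0, np.sqrt(rss / (j - 1)))
        return _normal_result("ivw", theta, se, n_snp=j)


def ivw(hset: HarmonisedSet, random_effects: bool = False) -> MRResults:
    return IVW(hset).fit(random_effects=random_effects)


class MREgger:
    """MR-Egger regression with a pleiotropy intercept.

    Each SNP is oriented so its exposure effect is non-negative (flipping
    ``bx`` and ``by`` jointly leaves the ratio unchanged), then ``by`` is
    regressed on ``bx`` with an intercept and weights ``sy^-2``.  The slope
    estimates the causal effect under InSIDE; a nonzero intercept indicates
    directional pleiotropy.
    """

    def __init__(self, hset: HarmonisedSet):
        self.hset = hset
        self.bx, self.sx, self.by, self.sy = _univariable_arrays(hset)

    def fit(self) -> MRResults:
        bx, by, sy = self.bx.copy(), self.by.copy(), self.sy
        j = len(bx)
        if j < 3:
            raise EstimationError("insufficient_instruments: MR-Egger needs >= 3 SNPs")
        flip = bx < 0
        bx[flip] *= -1
        by[flip] *= -1
        w = sy**-2
        x = np.column_stack([np.ones(j), bx])
        xtw = x.T * w
        xtwx = xtw @ x
        coef = np.linalg.solve(xtwx, xtw @ by)
        resid = by - x @ coef
        rss = float(np.sum(w * resid**2))
        # multiplicative random-effects inflation, floored at 1
        phi = max(1.0, rss / (j - 2))
        cov = np.linalg.inv(xtwx) * phi
        alpha, theta = coef
        se_a, se_t = np.sqrt(np.diag(cov))
        tdist = stats.t(df=j - 2)
        p_t = float(np.clip(2 * tdist.sf(abs(theta / se_t)), MIN_PVALUE, 1.0))
        p_a = float(np.clip(2 * tdist.sf(abs(alpha / se_a)), MIN_PVALUE, 1.0))
        tcrit = tdist.ppf(0.975)
        return MRResults(
            method="egger",
            theta=float(theta),
            se=float(se_t),
            ci_low=float(theta - tcrit * se_t),
            ci_high=float(theta + tcrit * se_t),
            pvalue=p_t,
            n_snp=j,
            intercept=float(alpha),
            intercept_se=float(se_a),
            intercept_p=p_a,
            meta={"rss_w": rss, "inflation": float(np.sqrt(phi))},
        )


def egger(hset: HarmonisedSet) -> MRResults:
    return MREgger(hset).fit()


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    """50% point of ratio estimates under cumulative-midpoint weighting.

    Weights are normalised to sum to one; with sorted ratios the breakpoint
    of ratio j sits at the midpoint of its weight mass,
    ``s_j = sum_{i<j} w_i + w_j / 2``, and the estimate interpolates theta
    against s at 0.5.
    """
    order = np.argsort(theta_j, kind="mergesort")
    th = theta_j[order]
    wn = w[order] / w.sum()
    s = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, s, th))


class WeightedMedian:
    """Weighted-median MR model with a parametric-bootstrap SE."""

    def __init__(self, hset: HarmonisedSet):
        self.hset = hset
        self.bx, self.sx, self.by, self.sy = _univariable_arrays(hset)

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> MRResults:
        bx, sx, by, sy = self.bx, self.sx, self.by, self.sy
        j = len(bx)
        if j < 3:
            raise EstimationError(
                "insufficient_instruments: weighted median needs >= 3 SNPs"
            )
        if seed is None:
            raise EstimationError("weighted median requires an explicit bootstrap seed")
        theta_j = by / bx
        w = bx**2 / sy**2
        theta = _weighted_median_point(theta_j, w)

        rng = np.random.default_rng(seed)
        bx_star = rng.normal(bx, sx, size=(n_boot, j))
        by_star = rng.normal(by, sy, size=(n_boot, j))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            tb = by_star[b] / bx_star[b]
            wb = bx_star[b] ** 2 / sy**2
            boots[b] = _weighted_median_point(tb, wb)
        se = float(boots.std(ddof=1))
        res = _normal_result("weighted_median", theta, se, n_snp=j)
        res.meta.update({"n_boot": n_boot, "seed": seed})
        return res


def weighted_median(hset: HarmonisedSet, n_boot: int = 1000, seed: int | None = None) -> MRResults:
    return WeightedMedian(hset).fit(n_boot=n_boot, seed=seed)


# --------------------------------------------------------------------- #


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR q-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
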