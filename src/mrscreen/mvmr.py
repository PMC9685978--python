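"""Multivariable IVW regression: direct effects adjusted for co-exposures.

Multivariable MR regresses the per-SNP outcome effects on the K-column
matrix of per-SNP exposure effects with no intercept and inverse-variance
weights ``sy^-2``.  Each coefficient estimates the direct effect of its
exposure on the outcome conditional on the other modelled exposures, under
the assumption that pleiotropic pathways operate through the modelled set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import Z95, EstimationError, MRResults, _normal_result
from .instruments import HarmonisedSet, instrument_union  # noqa: F401  (re-export)


@dataclass
class MVMRResults:
    """Per-exposure direct-effect estimates from one multivariable fit."""

    exposures: list[str]
    estimates: list[MRResults]
    conditional_f: dict[str, float]

    def summary(self) -> str:
        lines = [f"Multivariable IVW ({self.estimates[0].n_snp} SNPs)"]
        for name, est in zip(self.exposures, self.estimates):
            orr = est.odds_ratio()
            lines.append(
                f"  {name:24s} theta = {est.theta: .4f} (SE {est.se:.4f}) "
                f"OR {orr['or']:.2f} ({orr['ci_low']:.2f}, {orr['ci_high']:.2f}) "
                f"p = {est.pvalue:.3g}  cond. F = {self.conditional_f[name]:.1f}"
            )
        return "\n".join(lines)


class MultivariableIVW:
    """Multivariable IVW model over a K-exposure harmonised set."""

    def __init__(self, hset: HarmonisedSet):
        self.hset = hset
        self.X = hset.bx_matrix()
        self.y = hset.by.ravel()
        self.sy = hset.sy.ravel()

    def fit(self, random_effects: bool = False) -> MVMRResults:
        X, y, sy = self.X, self.y, self.sy
        j, k = X.shape
        if j <= k:
            raise EstimationError(
                f"insufficient_instruments: {j} SNPs for {k} exposures"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.nan_to_num(np.corrcoef(X, rowvar=False), nan=1.0)
            pair = "unknown"
            if k >= 2:
                off = np.abs(corr - np.eye(k))
                i1, i2 = np.unravel_index(np.argmax(off), off.shape)
                pair = (
                    f"{self.hset.exposure_names[i1]} / {self.hset.exposure_names[i2]}"
                )
            raise EstimationError(
                f"collinear_exposures: design matrix rank {rank} < {k} "
                f"(most collinear pair: {pair})"
            )
        w = sy**-2
        xtw = X.T * w
        xtwx = xtw @ X
        theta = np.linalg.solve(xtwx, xtw @ y)
        cov = np.linalg.inv(xtwx)
        if random_effects:
            rss = float(np.sum(w * (y - X @ theta) ** 2))
            cov = cov * max(1.0, rss / (j - k))
        se = np.sqrt(np.diag(cov))

        estimates = [
            _normal_result("mvmr", float(t), float(s), n_snp=j)
            for t, s in zip(theta, se)
        ]
        return MVMRResults(
            exposures=list(self.hset.exposure_names),
            estimates=estimates,
            conditional_f=self._conditional_f(),
        )

    def _conditional_f(self) -> dict[str, float]:
        """Weak-instrument diagnostic: the F statistic of regressing each
        exposure column on the other columns (with intercept).  A large F
        means the column is largely explained by co-exposures, i.e. weak
        conditional instrument strength.  For K = 1 the mean per-SNP F of
        the single exposure is reported instead.
        """
        X = self.X
        j, k = X.shape
        out: dict[str, float] = {}
        if k == 1:
            f = (X[:, 0] / self.hset.sx.ravel()) ** 2
            return {self.hset.exposure_names[0]: float(f.mean())}
        for i, name in enumerate(self.hset.exposure_names):
            target = X[:, i]
            others = np.column_stack([np.ones(j), np.delete(X, i, axis=1)])
            coef, *_ = np.linalg.lstsq(others, target, rcond=None)
            resid = target - others @ coef
            rss = float(resid @ resid)
            tss = float(np.sum((target - target.mean()) ** 2))
            p = others.shape[1] - 1
            dof = j - p - 1
            if tss <= 0 or dof <= 0:
                out[name] = float("nan")
                continue
            r2 = max(0.0, 1 - rss / tss)
            out[name] = (
                float("inf") if r2 >= 1 else float((r2 / p) / ((1 - r2) / dof))
            )
        return out


def mvmr_ivw(hset: HarmonisedSet, random_effects: bool = False) -> MVMRResults:
    return MultivariableIVW(hset).fit(random_effects=random_effects)
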