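"""Bayesian model averaging over exposure subsets (MR-BMA style ranking).

Given a K-exposure harmonised set, every non-empty subset S of exposures is
a candidate multivariable model.  On the whitened scale (each SNP's effects
divided by the SNP-outcome SE) the model is

    y~ = X~_S theta_S + eps,   eps ~ N(0, I),   theta_S ~ N(0, sigma^2 I)

whose marginal likelihood is available in closed form:
y~ ~ N(0, sigma^2 X~_S X~_S' + I).  Each model gets a prior
p^|S| (1-p)^(K-|S|) from an independent-inclusion prior with probability p,
and a posterior probability (PP) proportional to prior x evidence.

Per-exposure summaries:

- MIP (marginal inclusion probability): summed PP of all models containing
  the exposure — the posterior probability the exposure is a causal
  determinant of the outcome.
- MACE (model-averaged causal effect): PP-weighted posterior-mean direct
  effect, counting 0 when the exposure is absent from a model.  It
  understates the causal effect and is read for direction and relative
  size, not magnitude.

Empirical p-values come from permuting the whitened outcome vector against
the exposure matrix and re-running the whole averaging; BH FDR is applied
across exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimationError, bh_adjust
from .instruments import HarmonisedSet

#: exhaustive enumeration bound; 2^20 - 1 models is already ~1e6
MAX_EXHAUSTIVE_K = 20


def enumerate_models(k: int) -> list[tuple[int, ...]]:
    """All non-empty subsets of ``range(k)``, ordered by size then
    lexicographically; exactly ``2^k - 1`` models."""
    if not (1 <= k <= MAX_EXHAUSTIVE_K):
        raise EstimationError(
            f"exhaustive enumeration supports 1 <= K <= {MAX_EXHAUSTIVE_K}; "
            "larger exposure sets need a stochastic model search (not implemented)"
        )
    out: list[tuple[int, ...]] = []
    for size in range(1, k + 1):
        out.extend(combinations(range(k), size))
    return out


def model_evidence(
    X: np.ndarray, y: np.ndarray, members: tuple[int, ...], sigma: float
) -> tuple[float, np.ndarray]:
    """Log marginal likelihood and posterior-mean effects for one subset.

    ``X`` and ``y`` are already whitened (unit residual variance).  Uses the
    matrix determinant lemma and Woodbury identity so the cost is in the
    subset size, not the SNP count.
    """
    Xs = X[:, list(members)]
    j, m = Xs.shape
    if j <= m:
        raise EstimationError("insufficient_instruments: need n_snp > |members|")
    gram = Xs.T @ Xs
    a = np.eye(m) + sigma**2 * gram  # |I_J + s^2 Xs Xs'| = |I_m + s^2 Xs'Xs|
    sign, logdet = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"singular evidence covariance (cond={np.linalg.cond(a):.3g})"
        )
    xty = Xs.T @ y
    try:
        ainv_xty = np.linalg.solve(a, xty)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular evidence covariance (cond={np.linalg.cond(a):.3g})"
        ) from exc
    # y' (s^2 Xs Xs' + I)^-1 y via Woodbury
    quad = y @ y - sigma**2 * (xty @ ainv_xty)
    log_evidence = -0.5 * (j * np.log(2 * np.pi) + logdet + quad)
    # posterior mean (sigma^-2 I + Xs'Xs)^-1 Xs'y
    post_prec = np.eye(m) / sigma**2 + gram
    theta = np.linalg.solve(post_prec, xty)
    return float(log_evidence), theta


@dataclass
class BMAResults:
    """Exposure ranking from Bayesian model averaging."""

    exposures: list[str]
    mip: np.ndarray
    mace: np.ndarray
    empirical_p: np.ndarray | None
    fdr_q: np.ndarray | None
    prior_p: float
    sigma: float
    models: pd.DataFrame  # members, size, log_evidence, posterior_prob
    n_perm: int
    seed: int | None

    def ranking(self) -> pd.DataFrame:
        """Table-shaped ranking: rank, exposure, MIP, MACE, p, FDR q."""
        df = pd.DataFrame(
            {
                "exposure": self.exposures,
                "mip": self.mip,
                "mace": self.mace,
                "pvalue": self.empirical_p if self.empirical_p is not None else np.nan,
                "fdr_q": self.fdr_q if self.fdr_q is not None else np.nan,
            }
        ).sort_values("mip", ascending=False, kind="mergesort")
        df.insert(0, "rank", range(1, len(df) + 1))
        return df.reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"MR-BMA ranking (prior inclusion p = {self.prior_p}, "
            f"sigma = {self.sigma}, {len(self.models)} candidate models)"
        ]
        for row in self.ranking().itertuples(index=False):
            p_txt = "" if np.isnan(row.pvalue) else f"  p = {row.pvalue:.4g}  q = {row.fdr_q:.4g}"
            lines.append(
                f"  {row.rank}. {row.exposure:24s} MIP = {row.mip:.3f}  "
                f"MACE = {row.mace: .3f}{p_txt}"
            )
        return "\n".join(lines)


class MRBMA:
    """Bayesian model-averaging model over a K-exposure harmonised set.

    Parameters
    ----------
    hset
        Harmonised set with K >= 2 exposures and n_snp > K.
    prior_p
        Prior inclusion probability per exposure (default 0.5; 0.25 / 0.75
        as sensitivity values).
    sigma
        Prior SD of causal effects on the whitened scale (default 0.25).
    """

    def __init__(self, hset: HarmonisedSet, prior_p: float = 0.5, sigma: float = 0.25):
        if not (0 < prior_p < 1):
            raise ValueError("prior_p must be in (0, 1)")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.hset = hset
        self.prior_p = float(prior_p)
        self.sigma = float(sigma)
        sy = hset.sy.ravel()
        self.X = hset.bx_matrix() / sy[:, None]
        self.y = hset.by.ravel() / sy
        self.k = self.X.shape[1]
        if hset.n_snp <= self.k:
            raise EstimationError("insufficient_instruments: need n_snp > K")

    # ------------------------------------------------------------------ #

    def _average(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Posterior-probability-weighted summaries for one outcome vector."""
        models = enumerate_models(self.k)
        log_post = np.empty(len(models))
        thetas: list[np.ndarray] = []
        for i, members in enumerate(models):
            log_ev, theta = model_evidence(self.X, y, members, self.sigma)
            log_prior = len(members) * np.log(self.prior_p) + (
                self.k - len(members)
            ) * np.log(1 - self.prior_p)
            log_post[i] = log_ev + log_prior
            thetas.append(theta)
        log_post -= log_post.max()
        pp = np.exp(log_post)
        pp /= pp.sum()

        mip = np.zeros(self.k)
        mace = np.zeros(self.k)
        for p, members, theta in zip(pp, models, thetas):
            for pos, exp_idx in enumerate(members):
                mip[exp_idx] += p
                mace[exp_idx] += p * theta[pos]
        table = pd.DataFrame(
            {
                "members": [
                    ",".join(self.hset.exposure_names[i] for i in m) for m in models
                ],
                "size": [len(m) for m in models],
                "posterior_prob": pp,
            }
        )
        return mip, mace, table

    def fit(self, n_perm: int = 0, seed: int | None = None) -> BMAResults:
        """Compute the ranking; with ``n_perm > 0`` also permutation
        p-values (requires a seed)."""
        mip, mace, table = self._average(self.y)
        empirical_p = fdr_q = None
        if n_perm:
            if seed is None:
                raise EstimationError("permutation p-values require a seed")
            rng = np.random.default_rng(seed)
            exceed = np.zeros(self.k)
            for _ in range(n_perm):
                y_perm = self.y[rng.permutation(len(self.y))]
                mip_perm, _, _ = self._average(y_perm)
                exceed += mip_perm >= mip
            empirical_p = (1 + exceed) / (n_perm + 1)
            fdr_q = bh_adjust(empirical_p)
        table = table.sort_values(
            "posterior_prob", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
        return BMAResults(
            exposures=list(self.hset.exposure_names),
            mip=mip,
            mace=mace,
            empirical_p=empirical_p,
            fdr_q=fdr_q,
            prior_p=self.prior_p,
            sigma=self.sigma,
            models=table,
            n_perm=n_perm,
            seed=seed,
        )


def bma_rank(
    hset: HarmonisedSet,
    prior_p: float = 0.5,
    sigma: float = 0.25,
    n_perm: int = 0,
    seed: int | None = None,
) -> BMAResults:
    return MRBMA(hset, prior_p=prior_p, sigma=sigma).fit(n_perm=n_perm, seed=seed)


def prior_sensitivity(
    hset: HarmonisedSet,
    priors: tuple[float, ...] = (0.25, 0.5, 0.75),
    sigma: float = 0.25,
    n_perm: int = 0,
    seed: int | None = None,
) -> dict:
    """Run the averaging at several inclusion priors and summarise rank
    concordance (Kendall tau of the MIP orderings between prior pairs)."""
    results = {p: bma_rank(hset, p, sigma, n_perm, seed) for p in priors}
    taus = {}
    plist = sorted(results)
    for a, b in combinations(plist, 2):
        tau, _ = stats.kendalltau(results[a].mip, results[b].mip)
        taus[(a, b)] = float(tau)
    return {"results": results, "kendall_tau": taus}
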