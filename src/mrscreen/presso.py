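"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test asks whether the per-SNP residuals around a leave-one-out
IVW fit are larger than expected from the reported standard errors alone;
the per-SNP test localises the excess to individual variants; the
outlier-corrected estimate reruns IVW without the flagged variants; and the
distortion test asks whether removing them moved the estimate more than
removing a random subset of the same size would.

All empirical p-values use the (1 + count) / (n + 1) estimator so they are
never exactly zero, and every simulation is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimationError, MRResults, ivw
from .instruments import HarmonisedSet


@dataclass
class PRESSOResults:
    """Output of the MR-PRESSO battery for one exposure-outcome pair."""

    global_rss: float
    global_p: float
    outlier_ids: list[str]
    per_snp_p: dict[str, float]
    raw_estimate: MRResults
    corrected_estimate: MRResults
    distortion_p: float | None
    n_sim: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"MR-PRESSO ({self.raw_estimate.n_snp} SNPs, {self.n_sim} simulations)",
            f"  global RSS = {self.global_rss:.3f}, global p = {self.global_p:.4g}",
            f"  outliers   = {self.outlier_ids or 'none'}",
        ]
        if self.distortion_p is not None:
            lines.append(f"  distortion p = {self.distortion_p:.4g}")
        return "\n".join(lines)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over the left-out index."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def _weighted_rss_and_resid2(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, np.ndarray]:
    w = sy**-2
    theta_loo = _loo_slopes(bx, by, w)
    resid2 = w * (by - theta_loo * bx) ** 2
    return float(resid2.sum()), resid2


class MRPRESSO:
    """MR-PRESSO model for a univariable harmonised set.

    Parameters
    ----------
    hset
        Univariable harmonised set with at least 4 instruments.
    n_sim
        Number of simulated datasets for the empirical null (default 1000).
    outlier_threshold
        Bonferroni-adjusted per-SNP significance cutoff for flagging an
        outlier (default 0.05).
    """

    def __init__(
        self,
        hset: HarmonisedSet,
        n_sim: int = 1000,
        outlier_threshold: float = 0.05,
    ):
        if hset.n_exposure != 1:
            raise EstimationError("MR-PRESSO expects a univariable set")
        if hset.n_snp < 4:
            raise EstimationError("insufficient_instruments: MR-PRESSO needs >= 4 SNPs")
        self.hset = hset
        self.n_sim = int(n_sim)
        self.outlier_threshold = float(outlier_threshold)

    def fit(self, seed: int) -> PRESSOResults:
        h = self.hset
        # work in variant_id order so results are invariant to input order
        order = np.argsort(h.variant_ids.astype(str), kind="mergesort")
        h = h.subset(order)
        bx, sx = h.bx.ravel(), h.sx.ravel()
        by, sy = h.by.ravel(), h.sy.ravel()
        j = len(bx)
        n_sim = self.n_sim
        rng = np.random.default_rng(seed)

        w = sy**-2
        theta_loo = _loo_slopes(bx, by, w)
        obs_rss, obs_resid2 = _weighted_rss_and_resid2(bx, by, sy)

        # simulate under the per-SNP leave-one-out fitted model
        bx_star = rng.normal(bx, sx, size=(n_sim, j))
        by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
        w_mat = np.broadcast_to(w, (n_sim, j))
        s_xy = np.sum(w_mat * bx_star * by_star, axis=1, keepdims=True)
        s_xx = np.sum(w_mat * bx_star * bx_star, axis=1, keepdims=True)
        theta_loo_star = (s_xy - w_mat * bx_star * by_star) / (
            s_xx - w_mat * bx_star * bx_star
        )
        resid2_star = w_mat * (by_star - theta_loo_star * bx_star) ** 2
        rss_star = resid2_star.sum(axis=1)

        global_p = (1 + int(np.sum(rss_star >= obs_rss))) / (n_sim + 1)

        # per-SNP: compare each observed squared residual against that
        # SNP's simulated distribution, Bonferroni-multiplied by J
        exceed = np.sum(resid2_star >= obs_resid2[None, :], axis=0)
        p_snp_raw = (1 + exceed) / (n_sim + 1)
        p_snp = np.minimum(1.0, p_snp_raw * j)
        flagged = p_snp < self.outlier_threshold
        outlier_ids = [str(v) for v in h.variant_ids[flagged]]
        per_snp_p = {str(v): float(p) for v, p in zip(h.variant_ids, p_snp)}

        raw = ivw(h)
        if flagged.all():
            raise EstimationError("degenerate_outlier_set: every SNP flagged as outlier")
        corrected = ivw(h.subset(~flagged))
        corrected.method = "presso_corrected"
        raw.method = "presso_raw"

        distortion_p: float | None = None
        if flagged.any():
            k = j - int(flagged.sum())
            obs_shift = abs(corrected.theta - raw.theta)
            n_d = min(n_sim, 1000)
            # random size-k subsets via the argsort trick, IVW slopes vectorised
            sel = np.argsort(rng.random((n_d, j)), axis=1) < k
            wsel = sel * w
            theta_sub = np.sum(wsel * bx * by, axis=1) / np.sum(
                wsel * bx * bx, axis=1
            )
            shifts = np.abs(theta_sub - raw.theta)
            distortion_p = (1 + int(np.sum(shifts >= obs_shift))) / (n_d + 1)

        return PRESSOResults(
            global_rss=obs_rss,
            global_p=global_p,
            outlier_ids=outlier_ids,
            per_snp_p=per_snp_p,
            raw_estimate=raw,
            corrected_estimate=corrected,
            distortion_p=distortion_p,
            n_sim=n_sim,
            seed=seed,
        )


def presso(
    hset: HarmonisedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_threshold: float = 0.05,
) -> PRESSOResults:
    if seed is None:
        raise EstimationError("MR-PRESSO requires an explicit seed")
    return MRPRESSO(hset, n_sim=n_sim, outlier_threshold=outlier_threshold).fit(seed)
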