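"""Built-in calibration and power studies on synthetic panels.

Each study simulates summary-statistics panels with known ground truth and
measures an operating characteristic of an estimator: confidence-interval
coverage, test size, bias under invalid instruments, outlier-detection
power, or ranking recovery.  They are the package's standing evidence that
the estimators behave as advertised under their own assumptions; the
docs discuss what they do and do not show about real GWAS data.

All studies derive per-replicate seeds from a base seed, so a run is fully
reproducible and two runs with different base seeds give independent
Monte-Carlo estimates.
"""

from __future__ import annotations

import numpy as np

from .bma import bma_rank
from .estimators import egger, ivw, weighted_median
from .instruments import HarmonisedSet
from .pipeline import ScreenConfig, run_screen
from .presso import presso
from .simulate import TruthManifest, harmonised_from_simulation, simulate


def _hset(seed: int, **kwargs) -> HarmonisedSet:
    exposures, outcome, _ = simulate(TruthManifest(seed=seed, **kwargs))
    return harmonised_from_simulation(exposures, outcome)


def ivw_null_coverage(seed: int = 0, n_rep: int = 1000, J: int = 50) -> float:
    """Fraction of null-effect replicates whose IVW 95% CI covers zero.

    With no causal effect and no pleiotropy this estimates the CI's actual
    coverage; a calibrated interval sits near 0.95.
    """
    covered = 0
    for r in range(n_rep):
        res = ivw(_hset(seed + r, J=J, theta_true=[0.0]))
        covered += res.ci_low <= 0.0 <= res.ci_high
    return covered / n_rep


def egger_intercept_type1(
    seed: int = 0,
    n_rep: int = 1000,
    J: int = 50,
    pleio_sd: float = 0.004,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the Egger intercept test under balanced pleiotropy.

    Balanced pleiotropy has a zero-mean direct effect, so the intercept's
    null holds and the rejection rate estimates the test's size.
    """
    rejected = 0
    for r in range(n_rep):
        h = _hset(
            seed + r,
            J=J,
            theta_true=[0.1],
            pleiotropy_mode="balanced",
            pleio_sd=pleio_sd,
        )
        rejected += egger(h).intercept_p < alpha
    return rejected / n_rep


def median_vs_ivw_bias(
    seed: int = 0,
    n_rep: int = 200,
    J: int = 50,
    theta: float = 0.1,
    invalid_fraction: float = 0.3,
    pleio_mu: float = 0.004,
    n_boot: int = 50,
) -> dict[str, float]:
    """Mean bias of IVW vs the weighted median with a minority of
    directionally pleiotropic instruments (effect alleles oriented
    exposure-increasing, so the pleiotropy does not cancel)."""
    bias_ivw = np.empty(n_rep)
    bias_wm = np.empty(n_rep)
    for r in range(n_rep):
        h = _hset(
            seed + r,
            J=J,
            theta_true=[theta],
            orient_bx=True,
            pleiotropy_mode="directional",
            pleio_mu=pleio_mu,
            pleio_sd=pleio_mu / 4,
            pleio_fraction=invalid_fraction,
        )
        bias_ivw[r] = ivw(h).theta - theta
        bias_wm[r] = weighted_median(h, n_boot=n_boot, seed=seed + r).theta - theta
    return {
        "bias_ivw": float(bias_ivw.mean()),
        "bias_weighted_median": float(bias_wm.mean()),
    }


def presso_outlier_power(
    seed: int = 0,
    n_rep: int = 200,
    J: int = 30,
    n_sim: int = 1000,
    outlier_scale: float = 10.0,
) -> float:
    """Fraction of replicates in which the single injected outlier SNP is
    flagged by the per-SNP outlier test."""
    outlier = f"rs{100000 + J // 4}"
    found = 0
    for r in range(n_rep):
        h = _hset(
            seed + r,
            J=J,
            theta_true=[0.1],
            outlier_ids=[outlier],
            outlier_scale=outlier_scale,
        )
        res = presso(h, n_sim=n_sim, seed=seed + r)
        found += outlier in res.outlier_ids
    return found / n_rep


def bma_top1_recovery(
    seed: int = 0,
    n_rep: int = 200,
    K: int = 4,
    J: int = 100,
    theta: float = 0.15,
    rho: float = 0.3,
) -> float:
    """Fraction of replicates in which the single true causal exposure
    attains the top marginal inclusion probability among K correlated
    exposures."""
    R = (np.full((K, K), rho) + (1 - rho) * np.eye(K)).tolist()
    theta_true = [theta] + [0.0] * (K - 1)
    top = 0
    for r in range(n_rep):
        h = _hset(seed + r, K=K, J=J, theta_true=theta_true, exposure_corr=R)
        res = bma_rank(h)
        top += int(np.argmax(res.mip) == 0)
    return top / n_rep


def screen_fdr_recovery(
    seed: int = 0,
    n_rep: int = 100,
    n_exposures: int = 10,
    J_per_exposure: int = 20,
    theta: float = 0.15,
) -> float:
    """Fraction of end-to-end screens in which exactly the one causal
    exposure (out of ``n_exposures``) is FDR-significant."""
    from .pipeline import EstimatorSettings

    K = n_exposures
    theta_true = [theta] + [0.0] * (K - 1)
    exact = 0
    for r in range(n_rep):
        exposures, outcome, _ = simulate(
            TruthManifest(K=K, J=J_per_exposure * K, theta_true=theta_true, seed=seed + r)
        )
        cfg = ScreenConfig(
            estimators=EstimatorSettings(n_boot=0, n_sim=0, seed=seed + r)
        )
        # primary-only screen: skip the robust-estimator battery for speed
        report = _primary_only_screen(exposures, [outcome], cfg)
        hits = report.estimates[
            (report.estimates["method"].isin(["ivw", "wald"]))
            & (report.estimates["fdr_q"] < 0.05)
        ]["exposure"].tolist()
        exact += hits == ["exposure_0"]
    return exact / n_rep


def _primary_only_screen(exposures, outcomes, cfg) -> "ScreenReport":
    """IVW/Wald-only variant of run_screen used by the recovery study."""
    from .estimators import bh_adjust, wald_ratio
    from .instruments import harmonise, select_instruments
    from .pipeline import ScreenReport

    import pandas as pd

    rows = []
    for outcome in outcomes:
        outcome_rows = []
        for exposure in exposures:
            iv = select_instruments(exposure, None, cfg.clump_config())
            if len(iv) == 0:
                continue
            h = harmonise(iv, outcome, cfg.palindrome_policy)
            res = (
                wald_ratio(h.bx[0], h.sx[0], h.by[0], h.sy[0])
                if h.n_snp == 1
                else ivw(h)
            )
            row = res.to_frame().iloc[0].to_dict()
            row.update({"exposure": exposure.trait_name, "outcome": outcome.trait_name})
            outcome_rows.append(row)
        qs = bh_adjust([r["pvalue"] for r in outcome_rows])
        for r, q in zip(outcome_rows, qs):
            r["fdr_q"] = float(q)
        rows.extend(outcome_rows)
    est = pd.DataFrame(rows)
    return ScreenReport(estimates=est, skips=pd.DataFrame())
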