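"""Seeded generator of GWAS summary statistics with known ground truth.

The generator emulates the structure of a two-sample MR screen on
biobank-scale data: exposures are measured on a standardised
(inverse-rank-normalised) scale from a large quantitative-trait GWAS, the
outcome is a case-control log-odds GWAS, and instruments are strong,
LD-free SNPs.

Data-generating model, per SNP j and exposure k:

- SNP j is assigned a primary exposure a_j; it draws a scalar effect
  g_j ~ N(0, 1) and its true exposure-effect vector is
  ``beta_X[j, :] = tau * g_j * R[:, a_j]`` where R is the K x K exposure
  correlation — with R = I a SNP instruments only its assigned exposure,
  while correlated exposures (e.g. lipids) share attenuated effects.
- The true outcome effect is ``beta_Y[j] = sum_k theta_k beta_X[j, k] +
  alpha_j`` with the pleiotropy term alpha_j drawn per mode:
  ``none`` (0), ``balanced`` (N(0, psi^2)), ``directional`` (N(mu, psi^2)),
  or ``inside_violating`` (c * beta_X[j, 0] + N(0, psi^2), which couples
  pleiotropy to instrument strength and breaks InSIDE).
- SNPs listed in ``outlier_ids`` have their true outcome effect multiplied
  by ``outlier_scale``; they are guaranteed at least reference instrument
  strength (assigned |g| >= 1) so the distortion has a nonzero fitted value
  to inflate.
- Observed effects add sampling noise: ``b = beta + N(0, se^2)`` with
  ``se_x = 1 / sqrt(n_x)`` and ``se_y = 1 / sqrt(n_y)``, the standardised /
  balanced-case-control approximations for the declared GWAS sample sizes.

All draws come from one ``numpy`` Generator seeded from the manifest, in a
fixed order (exposure effects, pleiotropy, exposure noise, outcome noise),
so a manifest replays byte-identically.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .summstats import AssociationTable, recompute_pvalues

#: biobank-scale female quantitative-trait GWAS
DEFAULT_N_EXPOSURE = 194_174
#: breast-cancer consortium case-control GWAS (cases + controls)
DEFAULT_N_OUTCOME = 228_951


class TruthManifest(BaseModel):
    """Ground-truth settings for one simulated summary-statistics panel."""

    K: int = Field(1, ge=1, description="number of exposures")
    J: int = Field(50, ge=3, description="number of variants")
    theta_true: list[float] = Field(
        default_factory=lambda: [0.0], description="causal effects, log-odds per SD"
    )
    assignment: Optional[list[int]] = Field(
        None, description="per-SNP primary exposure index; default round-robin"
    )
    tau: float = Field(0.02, gt=0, description="SD of true SNP-exposure effects")
    exposure_corr: Optional[list[list[float]]] = Field(
        None, description="K x K correlation of exposure effects; default identity"
    )
    pleiotropy_mode: Literal["none", "balanced", "directional", "inside_violating"] = (
        "none"
    )
    pleio_mu: float = Field(0.0, description="mean of directional pleiotropy")
    pleio_sd: float = Field(0.0, ge=0, description="SD of pleiotropy effects")
    pleio_fraction: float = Field(
        1.0, ge=0, le=1, description="fraction of SNPs (the last ones) that are pleiotropic"
    )
    orient_bx: bool = Field(
        False,
        description="orient assigned effects positive (effect allele = exposure-raising)",
    )
    inside_c: float = Field(
        0.5, description="coupling of pleiotropy to bx under inside_violating"
    )
    outlier_ids: list[str] = Field(default_factory=list)
    outlier_scale: float = Field(10.0, description="multiplier on outlier beta_Y")
    palindromic_fraction: float = Field(0.0, ge=0, le=1)
    n_x: int = Field(DEFAULT_N_EXPOSURE, gt=1)
    n_y: int = Field(DEFAULT_N_OUTCOME, gt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TruthManifest":
        if len(self.theta_true) != self.K:
            raise ValueError("theta_true must have K entries")
        if self.J < self.K + 2:
            raise ValueError("J must be at least K + 2")
        if self.assignment is not None:
            if len(self.assignment) != self.J:
                raise ValueError("assignment must have J entries")
            if any(not (0 <= a < self.K) for a in self.assignment):
                raise ValueError("assignment indices must lie in [0, K)")
        if self.exposure_corr is not None:
            r = np.asarray(self.exposure_corr, dtype=float)
            if r.shape != (self.K, self.K):
                raise ValueError("exposure_corr must be K x K")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("exposure_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("exposure_corr must be positive semi-definite")
        return self

    def corr_matrix(self) -> np.ndarray:
        if self.exposure_corr is None:
            return np.eye(self.K)
        return np.asarray(self.exposure_corr, dtype=float)

    def assignment_vector(self) -> np.ndarray:
        if self.assignment is not None:
            return np.asarray(self.assignment, dtype=int)
        return np.arange(self.J) % self.K


def _variant_frame(
    manifest: TruthManifest, beta: np.ndarray, se: float, n: int, palindromic: np.ndarray
) -> pd.DataFrame:
    j = manifest.J
    ids = [f"rs{100000 + i}" for i in range(j)]
    eff = np.full(j, "A", dtype=object)
    oth = np.where(palindromic, "T", "G").astype(object)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": [str(1 + i % 22) for i in range(j)],
            "pos": (1 + np.arange(j)) * 2_000_000,  # > 10 Mb window apart per chrom
            "effect_allele": eff,
            "other_allele": oth,
            "eaf": np.full(j, 0.3),
            "beta": beta,
            "se": np.full(j, se),
            "pvalue": recompute_pvalues(beta, np.full(j, se)),
            "n": n,
        }
    )


def simulate(
    manifest: TruthManifest,
) -> tuple[list[AssociationTable], AssociationTable, TruthManifest]:
    """Generate K exposure tables and one outcome table from a manifest."""
    rng = np.random.default_rng(manifest.seed)
    J, K = manifest.J, manifest.K
    R = manifest.corr_matrix()
    assign = manifest.assignment_vector()
    theta = np.asarray(manifest.theta_true, dtype=float)

    # true per-SNP exposure effects: assigned scalar propagated through R
    g = rng.normal(size=J)
    if manifest.orient_bx:
        g = np.abs(g)
    ids = np.array([f"rs{100000 + i}" for i in range(J)])
    if manifest.outlier_ids:
        # outlier SNPs get at least reference instrument strength (|g| >= 1,
        # i.e. exposure effect >= tau): a multiplicative distortion of a
        # near-zero fitted value would be no outlier at all
        is_out = np.isin(ids, manifest.outlier_ids)
        g = np.where(is_out & (np.abs(g) < 1), np.where(g < 0, -1.0, 1.0), g)
    beta_x = manifest.tau * g[:, None] * R[:, assign].T  # (J, K)

    # pleiotropy; with pleio_fraction < 1 only the trailing SNPs are invalid
    mode = manifest.pleiotropy_mode
    if mode == "none":
        alpha = np.zeros(J)
    elif mode == "balanced":
        alpha = rng.normal(0.0, manifest.pleio_sd, size=J)
    elif mode == "directional":
        alpha = rng.normal(manifest.pleio_mu, manifest.pleio_sd, size=J)
    else:  # inside_violating
        alpha = manifest.inside_c * beta_x[:, 0] + rng.normal(
            0.0, manifest.pleio_sd, size=J
        )
    n_invalid = int(round(manifest.pleio_fraction * J))
    if n_invalid < J:
        alpha[: J - n_invalid] = 0.0
    beta_y = beta_x @ theta + alpha

    if manifest.outlier_ids:
        beta_y = np.where(
            np.isin(ids, manifest.outlier_ids),
            beta_y * manifest.outlier_scale,
            beta_y,
        )

    se_x = 1.0 / np.sqrt(manifest.n_x)
    se_y = 1.0 / np.sqrt(manifest.n_y)
    bx_obs = beta_x + rng.normal(0.0, se_x, size=(J, K))
    by_obs = beta_y + rng.normal(0.0, se_y, size=J)

    n_pal = int(round(manifest.palindromic_fraction * J))
    palindromic = np.zeros(J, dtype=bool)
    palindromic[:n_pal] = True

    exposures = []
    for k in range(K):
        df = _variant_frame(manifest, bx_obs[:, k], se_x, manifest.n_x, palindromic)
        exposures.append(
            AssociationTable(
                trait_name=f"exposure_{k}",
                trait_type="exposure",
                data=df,
                scale_note="inverse-rank normalised (simulated)",
            )
        )
    out_df = _variant_frame(manifest, by_obs, se_y, manifest.n_y, palindromic)
    outcome = AssociationTable(
        trait_name="outcome",
        trait_type="outcome",
        data=out_df,
        scale_note="log-odds (simulated)",
    )
    return exposures, outcome, manifest


def harmonised_from_simulation(
    exposures: list[AssociationTable], outcome: AssociationTable
) -> "HarmonisedSet":
    """Assemble a HarmonisedSet directly from a simulated panel.

    Simulated tables share variant ids, order and allele coding by
    construction, so no allele alignment is needed; this is the fast path
    for repeated simulation studies.
    """
    from .instruments import HarmonisedSet

    bx = np.column_stack([t.data["beta"].to_numpy(float) for t in exposures])
    sx = np.column_stack([t.data["se"].to_numpy(float) for t in exposures])
    if bx.shape[1] == 1:
        bx, sx = bx.ravel(), sx.ravel()
    return HarmonisedSet(
        exposure_names=[t.trait_name for t in exposures],
        outcome_name=outcome.trait_name,
        variant_ids=exposures[0].data["variant_id"].to_numpy(object),
        bx=bx,
        sx=sx,
        by=outcome.data["beta"].to_numpy(float),
        sy=outcome.data["se"].to_numpy(float),
    )


# --------------------------------------------------------------------- #

# Fixed 5-SNP univariable panel with hand-checkable effects.  All exposure
# p-values are far below 5e-8 and alleles are concordant, so selection and
# harmonisation pass every variant through.
_FIXTURE_BX = [0.030, 0.045, -0.025, 0.060, 0.038]
_FIXTURE_SX = [0.0023, 0.0023, 0.0023, 0.0023, 0.0023]
_FIXTURE_BY = [0.0031, 0.0047, -0.0024, 0.0058, 0.0042]
_FIXTURE_SY = [0.0021, 0.0021, 0.0021, 0.0021, 0.0021]


def fixture_small() -> tuple[AssociationTable, AssociationTable]:
    """A constant 5-SNP, 1-exposure dataset for smoke tests and examples."""
    j = 5
    base = {
        "variant_id": [f"rs{i + 1}" for i in range(j)],
        "chrom": ["1", "2", "3", "4", "5"],
        "pos": [1_000_000 * (i + 1) for i in range(j)],
        "effect_allele": ["A"] * j,
        "other_allele": ["G"] * j,
        "eaf": [0.25, 0.4, 0.3, 0.2, 0.35],
        "n": [DEFAULT_N_EXPOSURE] * j,
    }
    exp = AssociationTable(
        trait_name="fixture_exposure",
        trait_type="exposure",
        data=pd.DataFrame(
            base
            | {
                "beta": _FIXTURE_BX,
                "se": _FIXTURE_SX,
                "pvalue": recompute_pvalues(_FIXTURE_BX, _FIXTURE_SX),
            }
        ),
        scale_note="inverse-rank normalised (fixture)",
    )
    out = AssociationTable(
        trait_name="fixture_outcome",
        trait_type="outcome",
        data=pd.DataFrame(
            base
            | {
                "beta": _FIXTURE_BY,
                "se": _FIXTURE_SY,
                "pvalue": recompute_pvalues(_FIXTURE_BY, _FIXTURE_SY),
                "n": [DEFAULT_N_OUTCOME] * j,
            }
        ),
        scale_note="log-odds (fixture)",
    )
    return exp, out
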