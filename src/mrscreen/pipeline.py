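"""End-to-end screen: univariable battery, FDR, sensitivity, ranking, reports.

``run_screen`` runs every exposure against every outcome: instrument
selection, harmonisation, then IVW (Wald ratio when a single instrument
survives), MR-Egger, weighted median and MR-PRESSO where the instrument
count permits.  BH FDR is applied across exposures within each outcome on
the primary (IVW/Wald) p-values.  ``run_ranking`` feeds the nominally
significant exposures into the Bayesian model averaging, and
``run_bidirectional`` swaps exposure and outcome roles to probe reverse
causation.  All estimates are computed on the log-odds scale and
exp-transformed to odds ratios only in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import bma, estimators, mvmr, presso
from .instruments import (
    ClumpConfig,
    HarmonisedSet,
    R2Source,
    f_statistics,
    harmonise,
    harmonise_multi,
    instrument_union,
    select_instruments,
)
from .summstats import AssociationTable, read_association_table

logger = logging.getLogger(__name__)


class SourceSpec(BaseModel):
    """One summary-statistics file and how to read it."""

    path: str
    trait_name: str
    column_map: dict[str, str] = Field(default_factory=dict)
    scale_note: str = ""


class EstimatorSettings(BaseModel):
    n_boot: int = 1000
    n_sim: int = 1000
    n_perm: int = 100
    sigma: float = 0.25
    priors: list[float] = Field(default_factory=lambda: [0.25, 0.5, 0.75])
    seed: int = 1
    random_effects: bool = False
    outlier_threshold: float = 0.05


class ScreenConfig(BaseModel):
    """Validated YAML/JSON configuration for a full screen."""

    exposures: list[SourceSpec] = Field(default_factory=list)
    outcomes: list[SourceSpec] = Field(default_factory=list)
    clump: dict = Field(default_factory=dict)
    estimators: EstimatorSettings = Field(default_factory=EstimatorSettings)
    nominal_alpha: float = 0.05
    fdr_alpha: float = 0.05
    mvmr_presets: dict[str, list[str]] = Field(default_factory=dict)
    bidirectional_pairs: list[tuple[str, str]] = Field(default_factory=list)
    output_dir: str = "mrscreen_output"
    palindrome_policy: str = "infer_by_frequency"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def clump_config(self) -> ClumpConfig:
        return ClumpConfig(**self.clump)

    def fingerprint(self) -> str:
        """Hash of the configuration (seeds included) that determines every
        stochastic output of the run."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    """Tidy results of a screen: one row per exposure x outcome x method."""

    estimates: pd.DataFrame
    skips: pd.DataFrame
    rankings: dict = field(default_factory=dict)
    fingerprint: str = ""

    def significant(self, outcome: str, alpha: float = 0.05) -> list[str]:
        """Exposures nominally significant for an outcome by the primary
        (IVW or Wald) estimate."""
        df = self.estimates
        mask = (
            (df["outcome"] == outcome)
            & df["method"].isin(["ivw", "wald"])
            & (df["pvalue"] < alpha)
        )
        return df.loc[mask, "exposure"].tolist()


def _load_tables(specs: Sequence[SourceSpec], trait_type: str) -> list[AssociationTable]:
    return [
        read_association_table(
            s.path,
            column_map=s.column_map,
            trait_name=s.trait_name,
            trait_type=trait_type,
            scale_note=s.scale_note,
        )
        for s in specs
    ]


def _battery(
    hset: HarmonisedSet, settings: EstimatorSettings, seed: int
) -> tuple[list[estimators.MRResults], list[dict]]:
    """Run every applicable univariable estimator on one harmonised set."""
    results: list[estimators.MRResults] = []
    skips: list[dict] = []
    j = hset.n_snp
    if j == 1:
        results.append(
            estimators.wald_ratio(
                hset.bx.ravel()[0], hset.sx.ravel()[0], hset.by.ravel()[0], hset.sy.ravel()[0]
            )
        )
        for method, need in (("egger", 3), ("weighted_median", 3), ("presso", 4)):
            skips.append({"method": method, "reason": f"needs >= {need} SNPs, have 1"})
        return results, skips

    results.append(estimators.ivw(hset, random_effects=settings.random_effects))
    if j >= 3:
        results.append(estimators.egger(hset))
        results.append(
            estimators.weighted_median(hset, n_boot=settings.n_boot, seed=seed)
        )
    else:
        skips.append({"method": "egger", "reason": f"needs >= 3 SNPs, have {j}"})
        skips.append({"method": "weighted_median", "reason": f"needs >= 3 SNPs, have {j}"})
    if j >= 4:
        pres = presso.presso(
            hset,
            n_sim=settings.n_sim,
            seed=seed,
            outlier_threshold=settings.outlier_threshold,
        )
        results.append(pres.raw_estimate)
        results.append(pres.corrected_estimate)
    else:
        skips.append({"method": "presso", "reason": f"needs >= 4 SNPs, have {j}"})
    return results, skips


def run_screen(
    exposures: Sequence[AssociationTable],
    outcomes: Sequence[AssociationTable],
    config: ScreenConfig | None = None,
    r2_source: R2Source | None = None,
) -> ScreenReport:
    """Univariable screen of every exposure against every outcome."""
    config = config or ScreenConfig()
    settings = config.estimators
    clump_cfg = config.clump_config()
    rows: list[dict] = []
    skip_rows: list[dict] = []

    for oi, outcome in enumerate(outcomes):
        outcome_rows: list[dict] = []
        for ei, exposure in enumerate(exposures):
            pair_seed = settings.seed + 1000 * oi + ei
            iv = select_instruments(exposure, r2_source, clump_cfg)
            if len(iv) == 0:
                skip_rows.append(
                    {
                        "exposure": exposure.trait_name,
                        "outcome": outcome.trait_name,
                        "method": "all",
                        "reason": "no_instruments",
                    }
                )
                continue
            try:
                hset = harmonise(iv, outcome, config.palindrome_policy)
            except Exception as exc:  # no shared variants etc.
                skip_rows.append(
                    {
                        "exposure": exposure.trait_name,
                        "outcome": outcome.trait_name,
                        "method": "all",
                        "reason": str(exc),
                    }
                )
                continue
            fstats = f_statistics(hset)
            results, skips = _battery(hset, settings, pair_seed)
            for res in results:
                row = res.to_frame().iloc[0].to_dict()
                row.update(
                    {
                        "exposure": exposure.trait_name,
                        "outcome": outcome.trait_name,
                        "f_min": fstats["min"],
                        "f_mean": fstats["mean"],
                        "f_max": fstats["max"],
                    }
                )
                outcome_rows.append(row)
            for s in skips:
                skip_rows.append(
                    {
                        "exposure": exposure.trait_name,
                        "outcome": outcome.trait_name,
                        **s,
                    }
                )

        # FDR across exposures within this outcome, over primary p-values
        primary = [
            r for r in outcome_rows if r["method"] in ("ivw", "wald")
        ]
        if primary:
            qs = estimators.bh_adjust([r["pvalue"] for r in primary])
            for r, q in zip(primary, qs):
                r["fdr_q"] = float(q)
        rows.extend(outcome_rows)

    est = pd.DataFrame(rows)
    if len(est):
        est["nominal_significant"] = est["pvalue"] < config.nominal_alpha
        est["fdr_significant"] = est.get("fdr_q", pd.Series(dtype=float)) < config.fdr_alpha
        # surface IVW-null-but-robust-method-significant discordance
        est["discordant"] = False
        for (exp_name, out_name), grp in est.groupby(["exposure", "outcome"]):
            prim = grp[grp["method"].isin(["ivw", "wald"])]
            others = grp[~grp["method"].isin(["ivw", "wald"])]
            if len(prim) and not prim.iloc[0]["nominal_significant"]:
                if (others["pvalue"] < config.nominal_alpha).any():
                    est.loc[prim.index, "discordant"] = True
    skips = pd.DataFrame(skip_rows, columns=["exposure", "outcome", "method", "reason"])
    return ScreenReport(estimates=est, skips=skips, fingerprint=config.fingerprint())


def run_screen_from_config(config: ScreenConfig, r2_source: R2Source | None = None) -> ScreenReport:
    exposures = _load_tables(config.exposures, "exposure")
    outcomes = _load_tables(config.outcomes, "outcome")
    return run_screen(exposures, outcomes, config, r2_source)


def run_bidirectional(
    forward_exposure: AssociationTable,
    forward_outcome: AssociationTable,
    config: ScreenConfig | None = None,
    r2_source: R2Source | None = None,
) -> dict[str, ScreenReport]:
    """Run the univariable battery in both causal directions.

    The reverse run treats the outcome GWAS as the exposure (its
    genome-wide-significant variants become the instruments) and the
    original exposure as the outcome; the report schema is identical.
    """
    config = config or ScreenConfig()
    forward = run_screen([forward_exposure], [forward_outcome], config, r2_source)
    rev_exp = AssociationTable(
        trait_name=forward_outcome.trait_name,
        trait_type="exposure",
        data=forward_outcome.data,
        scale_note=forward_outcome.scale_note,
    )
    rev_out = AssociationTable(
        trait_name=forward_exposure.trait_name,
        trait_type="outcome",
        data=forward_exposure.data,
        scale_note=forward_exposure.scale_note,
    )
    reverse = run_screen([rev_exp], [rev_out], config, r2_source)
    return {"forward": forward, "reverse": reverse}


def run_mvmr_preset(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    config: ScreenConfig | None = None,
    r2_source: R2Source | None = None,
) -> mvmr.MVMRResults:
    """Multivariable model on the pooled, re-clumped instrument union."""
    config = config or ScreenConfig()
    union = instrument_union(exposures, config.clump_config(), r2_source)
    hset = harmonise_multi(exposures, outcome, union, config.palindrome_policy)
    return mvmr.mvmr_ivw(hset, random_effects=config.estimators.random_effects)


def run_ranking(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    significant: Sequence[str],
    config: ScreenConfig | None = None,
    r2_source: R2Source | None = None,
) -> dict:
    """Bayesian model-averaging ranking of the significant exposures.

    Builds the union instrument set across the named exposures, assembles
    the K-exposure harmonised set, and runs the averaging at each
    configured inclusion prior.
    """
    config = config or ScreenConfig()
    chosen = [t for t in exposures if t.trait_name in set(significant)]
    if len(chosen) < 2:
        return {"skipped": "fewer than 2 significant exposures"}
    union = instrument_union(chosen, config.clump_config(), r2_source)
    hset = harmonise_multi(chosen, outcome, union, config.palindrome_policy)
    s = config.estimators
    return bma.prior_sensitivity(
        hset,
        priors=tuple(s.priors),
        sigma=s.sigma,
        n_perm=s.n_perm,
        seed=s.seed,
    )


# --------------------------------------------------------------------- #


def render_report(report: ScreenReport, out_dir: str | Path) -> list[Path]:
    """Write deterministic TSV/markdown files for a completed screen.

    Emits a tidy estimates TSV, a skip-log TSV, a per-outcome markdown
    forest table sorted by primary p-value, and (when rankings are present)
    a Table-1-shaped ranking TSV per prior plus a model-ranking TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    est_path = out_dir / "estimates.tsv"
    cols = [
        "exposure", "outcome", "method", "n_snp", "theta", "se", "ci_low",
        "ci_high", "pvalue", "fdr_q", "or", "or_ci_low", "or_ci_high",
        "egger_intercept", "egger_intercept_p", "nominal_significant",
        "fdr_significant", "discordant", "f_min", "f_mean", "f_max",
    ]
    est = report.estimates.reindex(columns=cols)
    est.to_csv(est_path, sep="\t", index=False, float_format="%.6g")
    written.append(est_path)

    skip_path = out_dir / "skips.tsv"
    report.skips.to_csv(skip_path, sep="\t", index=False)
    written.append(skip_path)

    if len(est):
        for outcome, grp in est.groupby("outcome", sort=True):
            prim = grp[grp["method"].isin(["ivw", "wald"])].sort_values(
                "pvalue", kind="mergesort"
            )
            lines = [
                f"# MR screen: {outcome}",
                "",
                "| Exposure | Method | N SNPs | OR (95% CI) | p | FDR q |",
                "|---|---|---|---|---|---|",
            ]
            for _, r in prim.iterrows():
                flag = "**" if r["fdr_significant"] else (
                    "*" if r["nominal_significant"] else ""
                )
                q = "" if pd.isna(r["fdr_q"]) else f"{r['fdr_q']:.3g}"
                lines.append(
                    f"| {r['exposure']}{flag} | {r['method']} | {int(r['n_snp'])} | "
                    f"{r['or']:.2f} ({r['or_ci_low']:.2f}, {r['or_ci_high']:.2f}) | "
                    f"{r['pvalue']:.3g} | {q} |"
                )
            md_path = out_dir / f"forest_{outcome}.md"
            md_path.write_text("\n".join(lines) + "\n")
            written.append(md_path)

    for prior, res in report.rankings.items():
        rank_path = out_dir / f"ranking_prior_{prior}.tsv"
        res.ranking().to_csv(rank_path, sep="\t", index=False, float_format="%.6g")
        written.append(rank_path)
        models_path = out_dir / f"models_prior_{prior}.tsv"
        res.models.to_csv(models_path, sep="\t", index=False, float_format="%.6g")
        written.append(models_path)

    return written
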