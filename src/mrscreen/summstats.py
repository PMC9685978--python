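"""GWAS summary-statistics tables: data model, readers/writers, validation.

A summary-statistics table holds one row per variant with the fields a
two-sample MR analysis needs: identifier, location, allele coding, the
per-allele effect estimate (beta) with its standard error, the association
p-value, the effect-allele frequency and the sample size.  Exposure betas
are interpreted on a standardised (inverse-rank-normalised) scale; binary
outcome betas on the log-odds scale.  The ``scale_note`` attribute records
which.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for association tables
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: columns a column_map must cover when reading a file
MANDATORY = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

#: sentinel written for missing numeric fields
MISSING_TOKEN = "NA"

#: smallest p-value stored; keeps -log10(p) finite downstream
MIN_PVALUE = np.finfo(float).tiny


class SummStatsError(ValueError):
    """Base error for summary-statistics format/validation problems."""


class FormatError(SummStatsError):
    """A file is missing a mandatory column or is otherwise unreadable."""


class ValidationError(SummStatsError):
    """Row contents violate a table invariant (duplicates, se <= 0, ...)."""


def _normal_two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal tail probability of a z-score, floored at MIN_PVALUE."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, MIN_PVALUE, 1.0)


@dataclass
class AssociationTable:
    """A validated per-variant association table for one trait.

    Parameters
    ----------
    trait_name
        Label of the trait (e.g. ``"testosterone"``).
    trait_type
        ``"exposure"`` or ``"outcome"``; exposures are assumed to be on a
        standardised scale, outcomes on log-odds.
    data
        DataFrame with the canonical :data:`COLUMNS`.  Missing optional
        fields (``chrom``, ``pos``, ``eaf``, ``n``) may be NaN.
    scale_note
        Free-text record of the effect scale.
    """

    trait_name: str
    trait_type: str
    data: pd.DataFrame
    scale_note: str = ""
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "outcome"):
            raise ValidationError(
                f"trait_type must be 'exposure' or 'outcome', got {self.trait_type!r}"
            )
        df = self.data.reindex(columns=COLUMNS).copy()
        for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("variant_id", "chrom", "effect_allele", "other_allele"):
            df[col] = df[col].astype("string")
        df = df.reset_index(drop=True)
        self.data = df
        self._validate()

    # ------------------------------------------------------------------ #

    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            logger.warning("association table %r is empty", self.trait_name)
            return
        dup = df["variant_id"][df["variant_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(
                f"duplicate variant_id in {self.trait_name!r}: {sorted(dup)}"
            )
        bad_se = df["se"].notna() & (df["se"] <= 0)
        if bad_se.any():
            raise ValidationError(
                f"se <= 0 for variants {df.loc[bad_se, 'variant_id'].tolist()}"
            )
        same = df["effect_allele"] == df["other_allele"]
        if same.fillna(False).any():
            raise ValidationError(
                "effect_allele equals other_allele for "
                f"{df.loc[same.fillna(False), 'variant_id'].tolist()}"
            )
        bad_p = df["pvalue"].notna() & ~(
            (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        )
        if bad_p.any():
            raise ValidationError(
                f"pvalue outside (0, 1] for {df.loc[bad_p, 'variant_id'].tolist()}"
            )

    # ------------------------------------------------------------------ #

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> pd.Series:
        return self.data["variant_id"]

    def subset(self, mask) -> "AssociationTable":
        """Row-subset preserving order and metadata."""
        return AssociationTable(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            data=self.data.loc[mask].reset_index(drop=True),
            scale_note=self.scale_note,
        )


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "",
    trait_type: str = "exposure",
    scale_note: str = "",
    sep: str | None = None,
) -> AssociationTable:
    """Read a delimited summary-statistics file into an :class:`AssociationTable`.

    ``column_map`` maps canonical field names to the file's headers, e.g.
    ``{"variant_id": "SNP", "beta": "Beta.OBC", "se": "SE.OBC", ...}`` for a
    supplementary-table export with per-outcome columns.  Identity mapping is
    assumed for fields not listed.  Rows with missing beta or se are dropped
    (counted on the returned table); a missing p-value column is recomputed
    as the two-sided normal tail probability of beta/se.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=[MISSING_TOKEN, ""])
    column_map = dict(column_map or {})
    rename = {}
    for canonical in COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
    missing = [c for c in MANDATORY if column_map.get(c, c) not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) "
            + ", ".join(f"{c} (looked for {column_map.get(c, c)!r})" for c in missing)
        )
    df = raw.rename(columns=rename).reindex(columns=COLUMNS)
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    usable = df["beta"].notna() & df["se"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d row(s) with missing beta or se", path, n_dropped
        )
    df = df.loc[usable].reset_index(drop=True)

    need_p = df["pvalue"].isna()
    if need_p.any():
        z = df.loc[need_p, "beta"] / df.loc[need_p, "se"]
        df.loc[need_p, "pvalue"] = _normal_two_sided_p(z.to_numpy(float))
    df["pvalue"] = df["pvalue"].clip(lower=MIN_PVALUE)

    table = AssociationTable(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        data=df,
        scale_note=scale_note,
    )
    table.n_dropped = n_dropped
    return table


def write_association_table(table: AssociationTable, path: str | Path, sep: str = "\t") -> None:
    """Write a table so that ``read_association_table`` round-trips it."""
    path = Path(path)
    out = table.data.reindex(columns=COLUMNS).copy()
    # format positions/sample sizes without a trailing .0 where integral
    for col in ("pos", "n"):
        vals = out[col]
        out[col] = [
            MISSING_TOKEN
            if pd.isna(v)
            else (str(int(v)) if float(v).is_integer() else repr(float(v)))
            for v in vals
        ]
    for col in ("eaf", "beta", "se", "pvalue"):
        out[col] = [MISSING_TOKEN if pd.isna(v) else repr(float(v)) for v in out[col]]
    out.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)


def recompute_pvalues(beta: Sequence[float], se: Sequence[float]) -> np.ndarray:
    """Two-sided normal p-values from effect estimates and standard errors."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be strictly positive")
    return _normal_two_sided_p(beta / se)
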