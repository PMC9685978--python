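"""Instrument selection, LD clumping, harmonisation, instrument strength.

The instrument-preparation step turns raw exposure and outcome summary
statistics into the aligned per-SNP effect arrays the MR estimators consume:

1. keep genome-wide-significant variants (``p < 5e-8`` by default);
2. greedily prune variants in linkage disequilibrium, keeping the lowest
   p-value within each window (``r^2 < 0.001`` within 10,000 kb by default);
3. intersect with the outcome table and align effect alleles, flipping the
   outcome beta where the allele coding is reversed and resolving or
   dropping palindromic (A/T, C/G) variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .summstats import AssociationTable, ValidationError

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: effect-allele-frequency window inside which a palindromic variant's
#: strand cannot be inferred from frequency
PALINDROME_AMBIGUITY_WINDOW = (0.42, 0.58)


class HarmonisationError(ValueError):
    pass


class ClumpError(ValueError):
    pass


@dataclass(frozen=True)
class ClumpConfig:
    """Significance and LD-pruning thresholds for instrument selection."""

    p_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_max <= 1):
            raise ValueError("r2_max must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


# --------------------------------------------------------------------- #
# r^2 sources

R2Source = Callable[[str, str], float]


class FileR2Source:
    """Pairwise r^2 lookup backed by a 3-column (id1, id2, r2) table.

    Pairs absent from the table are treated as unlinked (r^2 = 0) only when
    queried across chromosomes; within a clumping window the caller treats a
    lookup failure as an error, so the table must cover in-window pairs.
    """

    def __init__(self, path: str | Path, sep: str = "\t"):
        df = pd.read_csv(path, sep=sep, header=0, dtype={0: str, 1: str})
        df.columns = ["id1", "id2", "r2"]
        self._r2: dict[tuple[str, str], float] = {}
        for id1, id2, r2 in df.itertuples(index=False):
            r2 = float(r2)
            if not (0 <= r2 <= 1):
                raise ValueError(f"r2 out of [0,1] for pair ({id1}, {id2}): {r2}")
            self._r2[(id1, id2)] = r2
            self._r2[(id2, id1)] = r2

    def __call__(self, id1: str, id2: str) -> float:
        try:
            return self._r2[(id1, id2)]
        except KeyError:
            raise KeyError(f"no r2 entry for pair ({id1}, {id2})") from None


# --------------------------------------------------------------------- #


def filter_significant(table: AssociationTable, p_threshold: float = 5e-8) -> AssociationTable:
    """Retain rows with ``pvalue < p_threshold`` (strict), preserving order."""
    mask = table.data["pvalue"] < p_threshold
    return table.subset(mask.to_numpy())


def greedy_clump(
    table: AssociationTable,
    r2_source: R2Source | None,
    config: ClumpConfig = ClumpConfig(),
) -> AssociationTable:
    """Greedy LD pruning: repeatedly accept the most significant remaining
    variant and discard every unaccepted variant within ``window_kb`` on the
    same chromosome with ``r^2 >= r2_max`` against it.

    With no ``r2_source`` (the LD-free synthetic path) variants are assumed
    independent and only exact same-position duplicates are pruned.
    Ties on p-value break by ascending (chrom, pos, variant_id) so output is
    deterministic.  Accepted variants are returned in genomic order.
    """
    df = table.data
    if len(df) == 0:
        return table
    order = df.assign(_row=np.arange(len(df))).sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    )
    pos = df["pos"].to_numpy(float)
    chrom = df["chrom"].to_numpy(object)
    vid = df["variant_id"].to_numpy(object)
    window_bp = config.window_kb * 1000.0

    alive = np.ones(len(df), dtype=bool)
    accepted: list[int] = []
    for i in order["_row"]:
        if not alive[i]:
            continue
        accepted.append(i)
        alive[i] = False
        if np.isnan(pos[i]):
            continue
        in_window = (
            alive
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.flatnonzero(in_window):
            if r2_source is None:
                # LD-free panel: only same-position duplicates are linked
                r2 = 1.0 if pos[j] == pos[i] else 0.0
            else:
                try:
                    r2 = r2_source(vid[i], vid[j])
                except KeyError as exc:
                    raise ClumpError(
                        f"r2 lookup failed within clumping window for pair "
                        f"({vid[i]}, {vid[j]})"
                    ) from exc
            if r2 >= config.r2_max:
                alive[j] = False

    keep = np.zeros(len(df), dtype=bool)
    keep[accepted] = True
    out = table.subset(keep)
    # genomic order
    out.data = (
        out.data.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def select_instruments(
    table: AssociationTable,
    r2_source: R2Source | None = None,
    config: ClumpConfig = ClumpConfig(),
) -> AssociationTable:
    """Significance filter followed by greedy clumping."""
    return greedy_clump(filter_significant(table, config.p_threshold), r2_source, config)


def instrument_union(
    tables: Sequence[AssociationTable],
    config: ClumpConfig = ClumpConfig(),
    r2_source: R2Source | None = None,
) -> list[str]:
    """Pooled instrument list for multivariable MR.

    Pools every variant reaching ``p_threshold`` in *any* exposure table,
    ranks the pooled set by each variant's minimum p-value across exposures,
    and greedy-clumps it.  Returns the retained variant ids in genomic order.
    """
    if len(tables) < 2:
        raise ValueError("instrument_union requires at least two exposure tables")
    frames = []
    for t in tables:
        sig = filter_significant(t, config.p_threshold)
        frames.append(sig.data[["variant_id", "chrom", "pos", "pvalue"]])
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) == 0:
        raise ClumpError("no variant reaches the significance threshold in any exposure")
    pooled = (
        pooled.sort_values("pvalue", kind="mergesort")
        .groupby("variant_id", as_index=False, sort=False)
        .first()
    )
    # dummy allele columns so AssociationTable validates; only id/pos/p matter
    pooled = pooled.assign(effect_allele="A", other_allele="G", beta=0.0, se=1.0)
    pooled_table = AssociationTable(
        trait_name="pooled", trait_type="exposure", data=pooled
    )
    clumped = greedy_clump(pooled_table, r2_source, config)
    return clumped.data["variant_id"].tolist()


# --------------------------------------------------------------------- #
# Harmonisation


@dataclass
class HarmonisedSet:
    """Aligned per-SNP exposure and outcome effects for one analysis.

    ``bx``/``sx`` have shape (J,) for a univariable set or (J, K) for a
    K-exposure set; ``by``/``sy`` have shape (J,).  ``drop_log`` records
    every variant excluded during harmonisation with its reason.
    """

    exposure_names: list[str]
    outcome_name: str
    variant_ids: np.ndarray
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    drop_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        for name in ("bx", "sx", "by", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        j = len(self.variant_ids)
        if self.bx.shape[0] != j or self.by.shape[0] != j:
            raise ValueError("bx/by SNP dimension does not match variant_ids")
        if self.bx.shape != self.sx.shape or self.by.shape != self.sy.shape:
            raise ValueError("effect and SE arrays must share a shape")
        if j and (np.any(self.sx <= 0) or np.any(self.sy <= 0)):
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposure(self) -> int:
        return 1 if self.bx.ndim == 1 else self.bx.shape[1]

    def bx_matrix(self) -> np.ndarray:
        """bx as a (J, K) matrix regardless of storage shape."""
        return self.bx[:, None] if self.bx.ndim == 1 else self.bx

    def subset(self, mask: np.ndarray) -> "HarmonisedSet":
        mask = np.asarray(mask)
        return HarmonisedSet(
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
            variant_ids=self.variant_ids[mask],
            bx=self.bx[mask],
            sx=self.sx[mask],
            by=self.by[mask],
            sy=self.sy[mask],
            drop_log=list(self.drop_log),
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _complement_pair(a1: str, a2: str) -> tuple[str, str] | None:
    try:
        return COMPLEMENT[a1], COMPLEMENT[a2]
    except KeyError:
        return None  # indel or non-ACGT allele; no strand flip possible


def harmonise(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_policy: str = "infer_by_frequency",
    ambiguity_window: tuple[float, float] = PALINDROME_AMBIGUITY_WINDOW,
) -> HarmonisedSet:
    """Align outcome effect alleles to the exposure coding.

    For each shared variant: if the outcome's (effect, other) alleles match
    the exposure's directly the outcome beta is kept; if they are swapped the
    beta sign is flipped and the frequency complemented; if they match only
    after complementing both strands the same logic applies on the flipped
    coding; otherwise the variant is dropped with reason ``allele_mismatch``.

    Palindromic variants (A/T or C/G) are handled per ``palindrome_policy``:

    - ``"infer_by_frequency"`` (default): aligned via effect-allele
      frequency when both frequencies fall outside ``ambiguity_window``,
      else dropped with reason ``palindromic_ambiguous``;
    - ``"drop"``: always dropped (reason ``palindromic``);
    - ``"keep"``: treated like any other variant (assumes same strand).
    """
    if palindrome_policy not in ("infer_by_frequency", "drop", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    exp = exposure.data.set_index("variant_id")
    out = outcome.data.set_index("variant_id")
    shared = [v for v in exposure.data["variant_id"] if v in out.index]
    if not shared:
        raise HarmonisationError("no_shared_variants")

    lo, hi = ambiguity_window
    keep_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    drop_log: list[dict] = []

    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        palindromic = _is_palindromic(ea_e, oa_e)

        if palindromic and palindrome_policy == "drop":
            drop_log.append({"variant_id": vid, "reason": "palindromic"})
            continue
        if palindromic and palindrome_policy == "infer_by_frequency":
            eaf_e, eaf_o = e["eaf"], o["eaf"]
            if (
                pd.isna(eaf_e)
                or pd.isna(eaf_o)
                or (lo <= float(eaf_e) <= hi)
                or (lo <= float(eaf_o) <= hi)
            ):
                drop_log.append(
                    {"variant_id": vid, "reason": "palindromic_ambiguous"}
                )
                continue
            # align by frequency: same minor/major orientation => same coding
            flip = (float(eaf_e) < 0.5) != (float(eaf_o) < 0.5)
            beta_o = -float(o["beta"]) if flip else float(o["beta"])
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                beta_o = float(o["beta"])
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o = -float(o["beta"])
            else:
                comp = _complement_pair(ea_o, oa_o)
                if comp is not None and comp == (ea_e, oa_e):
                    beta_o = float(o["beta"])
                elif comp is not None and comp == (oa_e, ea_e):
                    beta_o = -float(o["beta"])
                else:
                    drop_log.append({"variant_id": vid, "reason": "allele_mismatch"})
                    continue

        keep_ids.append(vid)
        bx.append(float(e["beta"]))
        sx.append(float(e["se"]))
        by.append(beta_o)
        sy.append(float(o["se"]))

    if not keep_ids:
        raise HarmonisationError(
            "no_shared_variants: all shared variants dropped during harmonisation"
        )
    return HarmonisedSet(
        exposure_names=[exposure.trait_name],
        outcome_name=outcome.trait_name,
        variant_ids=np.array(keep_ids, dtype=object),
        bx=np.array(bx),
        sx=np.array(sx),
        by=np.array(by),
        sy=np.array(sy),
        drop_log=drop_log,
    )


def harmonise_multi(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    variant_ids: Sequence[str],
    palindrome_policy: str = "infer_by_frequency",
) -> HarmonisedSet:
    """Build a K-exposure harmonised set on a fixed instrument list.

    Each exposure is harmonised against the outcome on the given variants;
    only variants present (and harmonisable) in every exposure are kept, so
    the SNP set is identical across exposure columns.
    """
    per_exp: list[HarmonisedSet] = []
    wanted = set(variant_ids)
    for t in exposures:
        sub = t.subset(t.data["variant_id"].isin(wanted).to_numpy())
        per_exp.append(harmonise(sub, outcome, palindrome_policy))
    common = set(per_exp[0].variant_ids.tolist())
    for h in per_exp[1:]:
        common &= set(h.variant_ids.tolist())
    if not common:
        raise HarmonisationError("no_shared_variants")
    ordered = [v for v in variant_ids if v in common]
    idx0 = {v: i for i, v in enumerate(per_exp[0].variant_ids)}
    bx = np.column_stack(
        [
            h.bx[[{v: i for i, v in enumerate(h.variant_ids)}[v] for v in ordered]]
            for h in per_exp
        ]
    )
    sx = np.column_stack(
        [
            h.sx[[{v: i for i, v in enumerate(h.variant_ids)}[v] for v in ordered]]
            for h in per_exp
        ]
    )
    rows0 = [idx0[v] for v in ordered]
    drop_log = [d for h in per_exp for d in h.drop_log]
    return HarmonisedSet(
        exposure_names=[t.trait_name for t in exposures],
        outcome_name=outcome.trait_name,
        variant_ids=np.array(ordered, dtype=object),
        bx=bx,
        sx=sx,
        by=per_exp[0].by[rows0],
        sy=per_exp[0].sy[rows0],
        drop_log=drop_log,
    )


# --------------------------------------------------------------------- #


def f_statistics(hset: HarmonisedSet) -> dict:
    """Per-SNP instrument-strength F statistics, ``F_j = (bx_j / sx_j)^2``.

    Returns the per-SNP values plus min/mean/max and the count of weak
    instruments (``F <= 10``).  Univariable sets only.
    """
    if hset.n_exposure != 1:
        raise ValueError("f_statistics expects a univariable harmonised set")
    bx = hset.bx.ravel()
    sx = hset.sx.ravel()
    if np.any(sx == 0):
        raise ValidationError("sx must be nonzero")
    f = (bx / sx) ** 2
    return {
        "per_snp": f,
        "min": float(f.min()),
        "mean": float(f.mean()),
        "max": float(f.max()),
        "n_weak": int((f <= 10).sum()),
    }
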