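import numpy as np
import pandas as pd
import pytest

from mrscreen import (
    AssociationTable,
    HarmonisedSet,
    TruthManifest,
    fixture_small,
    harmonised_from_simulation,
    simulate,
)


@pytest.fixture
def fixture_pair():
    """The constant 5-SNP exposure/outcome panel."""
    return fixture_small()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_table(
    variant_ids,
    beta,
    se,
    pvalue=None,
    chrom=None,
    pos=None,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    trait_name="trait",
    trait_type="exposure",
):
    """Build a small AssociationTable from arrays, broadcasting scalars."""
    j = len(variant_ids)

    def bc(v):
        return [v] * j if np.isscalar(v) or isinstance(v, str) else list(v)

    from scipy import stats

    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pvalue is None:
        with np.errstate(divide="ignore"):
            pvalue = np.clip(
                2 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0
            )
    df = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": bc(chrom if chrom is not None else "1"),
            "pos": bc(pos) if pos is not None else list(1000 * (1 + np.arange(j))),
            "effect_allele": bc(effect_allele),
            "other_allele": bc(other_allele),
            "eaf": bc(eaf),
            "beta": beta,
            "se": se,
            "pvalue": np.asarray(pvalue, float),
            "n": 10000,
        }
    )
    return AssociationTable(trait_name=trait_name, trait_type=trait_type, data=df)


def make_hset(bx, sx, by, sy, exposure_names=None, ids=None):
    bx = np.asarray(bx, float)
    j = bx.shape[0]
    names = exposure_names or (
        ["x"] if bx.ndim == 1 else [f"x{k}" for k in range(bx.shape[1])]
    )
    return HarmonisedSet(
        exposure_names=names,
        outcome_name="y",
        variant_ids=np.array(ids if ids is not None else [f"rs{i}" for i in range(j)]),
        bx=bx,
        sx=np.asarray(sx, float),
        by=np.asarray(by, float),
        sy=np.asarray(sy, float),
    )


def sim_hset(seed, **kwargs):
    """Simulate a panel and assemble its harmonised set (fast path)."""
    manifest = TruthManifest(seed=seed, **kwargs)
    exposures, outcome, _ = simulate(manifest)
    return harmonised_from_simulation(exposures, outcome)
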