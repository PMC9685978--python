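"""Instrument selection, clumping, harmonisation, F statistics."""

import numpy as np
import pytest

from mrscreen import (
    ClumpConfig,
    f_statistics,
    filter_significant,
    greedy_clump,
    harmonise,
)
from mrscreen.instruments import ClumpError, HarmonisationError

from conftest import make_hset, make_table


class TestFilterSignificant:
    def test_strict_inequality_at_threshold(self):
        table = make_table(
            ["rs1", "rs2", "rs3"],
            beta=[0.1] * 3,
            se=[0.01] * 3,
            pvalue=[4.9e-8, 5e-8, 1e-3],
        )
        kept = filter_significant(table, 5e-8)
        assert kept.data["variant_id"].tolist() == ["rs1"]

    def test_threshold_one_keeps_everything(self):
        table = make_table(["rs1", "rs2"], beta=[0.1, 0.2], se=[0.1, 0.1])
        assert len(filter_significant(table, 1 - 1e-12)) == 2

    def test_count_matches_linear_scan_oracle(self, rng):
        n = 1000
        pvals = 10 ** rng.uniform(-12, 0, size=n)
        table = make_table(
            [f"rs{i}" for i in range(n)], beta=[0.1] * n, se=[0.1] * n, pvalue=pvals
        )
        kept = filter_significant(table, 1e-6)
        assert len(kept) == sum(1 for p in pvals if p < 1e-6)


class _DictR2:
    def __init__(self, pairs):
        self.pairs = {}
        for (a, b), r in pairs.items():
            self.pairs[(a, b)] = r
            self.pairs[(b, a)] = r

    def __call__(self, a, b):
        return self.pairs.get((a, b), 0.0)


def _brute_force_clump(table, r2, config):
    """Independent greedy oracle: literal restatement of the procedure on
    python lists, no vectorisation."""
    rows = table.data.to_dict("records")
    remaining = sorted(
        range(len(rows)),
        key=lambda i: (
            rows[i]["pvalue"],
            rows[i]["chrom"],
            rows[i]["pos"],
            rows[i]["variant_id"],
        ),
    )
    removed = set()
    accepted = []
    for i in remaining:
        if i in removed:
            continue
        accepted.append(i)
        for j in remaining:
            if j == i or j in removed or j in accepted:
                continue
            same_chrom = rows[j]["chrom"] == rows[i]["chrom"]
            close = abs(rows[j]["pos"] - rows[i]["pos"]) <= config.window_kb * 1000
            if same_chrom and close:
                if r2(rows[i]["variant_id"], rows[j]["variant_id"]) >= config.r2_max:
                    removed.add(j)
    return sorted(rows[i]["variant_id"] for i in accepted)


class TestGreedyClump:
    def test_independent_snps_all_retained(self):
        table = make_table(
            ["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.01] * 3, pos=[100, 200, 300]
        )
        out = greedy_clump(table, _DictR2({}), ClumpConfig(r2_max=0.001))
        assert len(out) == 3

    def test_best_pvalue_dominates_linked_neighbour(self):
        table = make_table(
            ["rs1", "rs2"],
            beta=[0.1, 0.1],
            se=[0.01, 0.01],
            pvalue=[1e-20, 1e-9],
            pos=[1000, 6000],
        )
        r2 = _DictR2({("rs1", "rs2"): 0.9})
        out = greedy_clump(table, r2, ClumpConfig(r2_max=0.001))
        assert out.data["variant_id"].tolist() == ["rs1"]

    def test_boundary_r2_equal_to_threshold_is_discarded(self):
        table = make_table(
            ["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
            pvalue=[1e-20, 1e-9], pos=[1000, 2000],
        )
        r2 = _DictR2({("rs1", "rs2"): 0.001})
        out = greedy_clump(table, r2, ClumpConfig(r2_max=0.001))
        assert len(out) == 1

    def test_chained_ld_matches_brute_force_oracle(self, rng):
        n = 10
        pvals = 10 ** rng.uniform(-30, -8, size=n)
        table = make_table(
            [f"rs{i}" for i in range(n)],
            beta=[0.1] * n,
            se=[0.01] * n,
            pvalue=pvals,
            pos=list(range(1000, 1000 + n * 3000, 3000)),
        )
        # chain: each consecutive pair linked, some skips
        pairs = {(f"rs{i}", f"rs{i+1}"): 0.8 for i in range(n - 1)}
        pairs[("rs0", "rs5")] = 0.6
        r2 = _DictR2(pairs)
        cfg = ClumpConfig(r2_max=0.5)
        out = greedy_clump(table, r2, cfg)
        assert sorted(out.data["variant_id"]) == _brute_force_clump(table, r2, cfg)

    def test_retained_set_is_independent_post_hoc(self, rng):
        n = 20
        pvals = 10 ** rng.uniform(-30, -8, size=n)
        ids = [f"rs{i}" for i in range(n)]
        table = make_table(
            ids, beta=[0.1] * n, se=[0.01] * n, pvalue=pvals,
            pos=list(range(0, n * 2000, 2000)),
        )
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    pairs[(ids[i], ids[j])] = rng.random()
        r2 = _DictR2(pairs)
        cfg = ClumpConfig(r2_max=0.2)
        out = greedy_clump(table, r2, cfg)
        kept = out.data["variant_id"].tolist()
        pos = dict(zip(table.data["variant_id"], table.data["pos"]))
        for a in kept:
            for b in kept:
                if a < b and abs(pos[a] - pos[b]) <= cfg.window_kb * 1000:
                    assert r2(a, b) < cfg.r2_max

    def test_lookup_failure_in_window_raises(self):
        class Failing:
            def __call__(self, a, b):
                raise KeyError((a, b))

        table = make_table(
            ["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01], pos=[1000, 2000]
        )
        with pytest.raises(ClumpError, match="rs"):
            greedy_clump(table, Failing(), ClumpConfig())

    def test_no_r2_source_dedups_same_position_only(self):
        table = make_table(
            ["rs1", "rs2", "rs3"],
            beta=[0.1] * 3,
            se=[0.01] * 3,
            pvalue=[1e-20, 1e-9, 1e-10],
            pos=[1000, 1000, 2000],
        )
        out = greedy_clump(table, None, ClumpConfig())
        assert out.data["variant_id"].tolist() == ["rs1", "rs3"]


class TestHarmonise:
    def test_same_alleles_keep_outcome_beta(self):
        exp = make_table(["rs1"], beta=[0.1], se=[0.01])
        out = make_table(["rs1"], beta=[0.2], se=[0.02], trait_type="outcome")
        h = harmonise(exp, out)
        assert h.by[0] == pytest.approx(0.2)
        assert h.drop_log == []

    def test_swapped_alleles_flip_sign(self):
        exp = make_table(["rs1"], beta=[0.1], se=[0.01], effect_allele="A", other_allele="G")
        out = make_table(
            ["rs1"], beta=[0.2], se=[0.02], effect_allele="G", other_allele="A",
            trait_type="outcome",
        )
        h = harmonise(exp, out)
        assert h.by[0] == pytest.approx(-0.2)

    def test_complement_strand_resolved_before_mismatch(self):
        # outcome coded on the other strand: A/G -> T/C
        exp = make_table(["rs1"], beta=[0.1], se=[0.01], effect_allele="A", other_allele="G")
        out = make_table(
            ["rs1"], beta=[0.2], se=[0.02], effect_allele="T", other_allele="C",
            trait_type="outcome",
        )
        h = harmonise(exp, out)
        assert h.by[0] == pytest.approx(0.2)

    def test_unresolvable_alleles_dropped_with_reason(self):
        exp = make_table(
            ["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
            effect_allele="A", other_allele="G",
        )
        out = make_table(
            ["rs1", "rs2"], beta=[0.2, 0.2], se=[0.02, 0.02],
            effect_allele=["A", "A"], other_allele=["G", "C"], trait_type="outcome",
        )
        h = harmonise(exp, out)
        assert h.variant_ids.tolist() == ["rs1"]
        assert h.drop_log == [{"variant_id": "rs2", "reason": "allele_mismatch"}]

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = make_table(
            ["rs1"], beta=[0.1], se=[0.01], effect_allele="A", other_allele="T", eaf=0.3
        )
        out = make_table(
            ["rs1"], beta=[0.2], se=[0.02], effect_allele="A", other_allele="T",
            eaf=0.50, trait_type="outcome",
        )
        with pytest.raises(HarmonisationError):
            harmonise(exp, out)  # only variant dropped -> empty set

    def test_palindromic_aligned_by_frequency_outside_window(self):
        exp = make_table(
            ["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
            effect_allele="A", other_allele="T", eaf=0.2,
        )
        out = make_table(
            ["rs1", "rs2"], beta=[0.2, 0.2], se=[0.02, 0.02],
            effect_allele="A", other_allele="T", eaf=[0.2, 0.8], trait_type="outcome",
        )
        h = harmonise(exp, out)
        # rs1: same orientation; rs2: opposite frequency -> flipped
        assert h.by.tolist() == pytest.approx([0.2, -0.2])

    def test_drop_policy_removes_all_palindromes(self):
        exp = make_table(
            ["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
            effect_allele=["A", "C"], other_allele=["T", "G"], eaf=0.2,
        )
        out = make_table(
            ["rs1", "rs2"], beta=[0.2, 0.2], se=[0.02, 0.02],
            effect_allele=["A", "C"], other_allele=["T", "G"], eaf=0.2,
            trait_type="outcome",
        )
        with pytest.raises(HarmonisationError):
            harmonise(exp, out, palindrome_policy="drop")

    def test_involution_pre_swapped_outcome_gives_identical_by(self):
        exp = make_table(["rs1", "rs2"], beta=[0.1, -0.2], se=[0.01, 0.01])
        out = make_table(
            ["rs1", "rs2"], beta=[0.2, 0.3], se=[0.02, 0.02], trait_type="outcome"
        )
        h1 = harmonise(exp, out)
        swapped = out.data.copy()
        swapped[["effect_allele", "other_allele"]] = swapped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        swapped["beta"] = -swapped["beta"]
        swapped["eaf"] = 1 - swapped["eaf"]
        out2 = make_table(["rs1"], beta=[0.1], se=[0.1], trait_type="outcome")
        out2.data = swapped
        h2 = harmonise(exp, out2)
        np.testing.assert_allclose(h1.by, h2.by)

    def test_drop_plus_retained_equals_intersection(self):
        exp = make_table(
            ["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.01] * 3,
            effect_allele="A", other_allele="G",
        )
        out = make_table(
            ["rs2", "rs3", "rs4"], beta=[0.2] * 3, se=[0.02] * 3,
            effect_allele="A", other_allele=["G", "C", "G"], trait_type="outcome",
        )  # rs3 coded A/C: unresolvable against A/G -> allele_mismatch
        h = harmonise(exp, out)
        assert len(h.drop_log) + h.n_snp == 2  # intersection is {rs2, rs3}

    def test_no_shared_variants_raises(self):
        exp = make_table(["rs1"], beta=[0.1], se=[0.01])
        out = make_table(["rs9"], beta=[0.2], se=[0.02], trait_type="outcome")
        with pytest.raises(HarmonisationError, match="no_shared_variants"):
            harmonise(exp, out)


class TestFStatistics:
    def test_unit_ratio_gives_f_one(self):
        h = make_hset([0.01], [0.01], [0.0], [0.01])
        assert f_statistics(h)["per_snp"][0] == pytest.approx(1.0)

    def test_hand_computed_f(self):
        h = make_hset([0.03], [0.005], [0.0], [0.01])
        assert f_statistics(h)["per_snp"][0] == pytest.approx(36.0)

    def test_summary_consistent_with_per_snp(self, rng):
        bx = rng.normal(0, 0.05, 20)
        sx = rng.uniform(0.001, 0.01, 20)
        h = make_hset(bx, sx, np.zeros(20), np.full(20, 0.01))
        f = f_statistics(h)
        assert f["min"] == pytest.approx(f["per_snp"].min())
        assert f["max"] == pytest.approx(f["per_snp"].max())
        assert f["n_weak"] == int((f["per_snp"] <= 10).sum())
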