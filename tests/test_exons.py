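"""Exon CV ranking, GO enrichment and poly(A) scanning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from segnorm import exons, synthetic


def _table(rows, samples):
    return pd.DataFrame(
        rows, columns=["gene_id", "exon_index", "exon_length"] + samples
    )


class TestComputeTpm:
    def test_single_exon_gets_the_whole_million(self):
        tab = _table([["g1", 1, 150, 10, 7]], ["a", "b"])
        tpm = exons.compute_tpm(tab)
        assert np.allclose(tpm.to_numpy(), 1e6)

    def test_length_normalization_closed_form(self):
        tab = _table([["g1", 1, 100, 50], ["g1", 2, 200, 50]], ["a"])
        tpm = exons.compute_tpm(tab)["a"].to_numpy()
        assert tpm[0] == pytest.approx(2e6 / 3)
        assert tpm[1] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_one_million_on_generated_data(self):
        tab, _ = synthetic.gen_exon_counts(n_genes=30, n_samples=5, seed=3)
        tpm = exons.compute_tpm(tab)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_all_zero_sample_is_named(self):
        tab = _table([["g1", 1, 100, 5, 0]], ["good", "dead"])
        with pytest.raises(ValueError, match="dead"):
            exons.compute_tpm(tab)


class TestEnumerateCombos:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 3), (3, 7), (5, 15)])
    def test_combination_counts(self, k, expected):
        tab = _table([["g", i + 1, 100, 1] for i in range(k)], ["a"])
        assert len(exons.enumerate_combos(tab)) == expected

    def test_five_exons_enumerated_by_hand(self):
        tab = _table([["g", i, 100, 1] for i in range(1, 6)], ["a"])
        combos = {(c.scheme, c.members) for c in exons.enumerate_combos(tab)}
        singles = {("single", (i,)) for i in range(1, 6)}
        adjacent = {("pair_adjacent", (i, i + 1)) for i in range(1, 5)}
        skips = {("pair_skip", (i, i + 2)) for i in range(1, 4)}
        trios = {("trio", (i, i + 1, i + 2)) for i in range(1, 4)}
        assert combos == singles | adjacent | skips | trios


def _tpm_from(expr_by_gene, samples):
    rows = []
    idx = []
    for (gene, exon), values in expr_by_gene.items():
        rows.append(values)
        idx.append((gene, exon))
    df = pd.DataFrame(rows, columns=samples)
    df.index = pd.MultiIndex.from_tuples(idx, names=["gene_id", "exon_index"])
    return df


class TestRankByCv:
    def test_constant_expression_has_zero_cv_and_rank_one(self):
        tpm = _tpm_from({("g1", 1): [5, 5, 5, 5], ("g2", 1): [1, 2, 3, 4]},
                        ["a", "b", "c", "d"])
        ranked = exons.rank_by_cv(tpm)
        assert ranked.iloc[0]["gene_id"] == "g1"
        assert ranked.iloc[0]["cv"] == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        tpm = _tpm_from({("g1", 1): [1, 2, 3]}, ["a", "b", "c"])
        ranked = exons.rank_by_cv(tpm)
        assert ranked.iloc[0]["cv"] == pytest.approx(0.5)

    def test_cv_ceiling_drops_unstable_combos(self):
        tpm = _tpm_from({("g1", 1): [1, 1, 1], ("g2", 1): [0.01, 0.02, 8]},
                        ["a", "b", "c"])
        ranked = exons.rank_by_cv(tpm, cv_max=1.0)
        assert set(ranked["gene_id"]) == {"g1"}

    def test_needs_three_samples(self):
        tpm = _tpm_from({("g1", 1): [1, 2]}, ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            exons.rank_by_cv(tpm)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cv_is_scale_invariant(self, scale):
        tpm = _tpm_from(
            {("g1", 1): [1.0, 2.0, 3.5], ("g2", 1): [4.0, 4.5, 5.0]},
            ["a", "b", "c"],
        )
        base = exons.rank_by_cv(tpm, cv_max=np.inf)
        scaled = exons.rank_by_cv(tpm * scale, cv_max=np.inf)
        assert np.allclose(base["cv"], scaled["cv"], rtol=1e-9)

    def test_proportional_extra_exon_leaves_cv_unchanged(self):
        # a pair whose second exon is a scalar multiple of the first has the
        # same relative profile, hence the same CV as the single exon
        single = _tpm_from({("g1", 1): [2.0, 3.0, 4.0]}, ["a", "b", "c"])
        pair = _tpm_from(
            {("g1", 1): [2.0, 3.0, 4.0], ("g1", 2): [1.0, 1.5, 2.0]},
            ["a", "b", "c"],
        )
        cv_single = exons.rank_by_cv(single).iloc[0]["cv"]
        ranked = exons.rank_by_cv(pair)
        cv_pair = ranked[ranked["scheme"] == "pair_adjacent"].iloc[0]["cv"]
        assert cv_pair == pytest.approx(cv_single, rel=1e-12)

    def test_splice_perturbed_exon_loses_to_constitutive_pairs(self):
        tab, truth = synthetic.gen_exon_counts(
            n_genes=40, n_samples=10, stable_fraction=1.0, cv_low=0.15,
            cv_high=0.8, splice_perturb_rate=1.0, seed=5,
        )
        tpm = exons.compute_tpm(tab)
        ranked = exons.rank_by_cv(tpm, cv_max=np.inf)
        ranked = ranked.reset_index().rename(columns={"index": "rank_pos"})
        pert_ranks, pair_ranks = [], []
        for gene, exon in truth.perturbed_exons.items():
            sub = ranked[ranked["gene_id"] == gene]
            single = sub[(sub["scheme"] == "single") & (sub["members"] == str(exon))]
            pairs = sub[
                (sub["scheme"] == "pair_adjacent")
                & (~sub["members"].str.contains(rf"\b{exon}\b"))
            ]
            if len(single) and len(pairs):
                pert_ranks.append(single["rank_pos"].iloc[0])
                pair_ranks.append(pairs["rank_pos"].min())
        assert np.median(pair_ranks) < np.median(pert_ranks)


class TestTopListsAndSelection:
    def _ranked(self):
        rows = [
            {"gene_id": f"g{i}", "scheme": "pair_adjacent" if i < 3 else "single",
             "members": "1", "mean_tpm": 10.0, "mean_log2_tpm": 3.3,
             "cv": 0.01 * (i + 1)}
            for i in range(10)
        ]
        return pd.DataFrame(rows)

    def test_neighbour_fraction_counted(self):
        res = exons.top_list_composition(self._ranked(), 10)
        assert res["neighbour_count"] == 3
        assert res["neighbour_fraction"] == pytest.approx(0.3)

    def test_all_singles_give_zero(self):
        tab = self._ranked()
        tab["scheme"] = "single"
        assert exons.top_list_composition(tab, 10)["neighbour_fraction"] == 0.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            exons.top_list_composition(self._ranked(), 0)

    def test_best_combo_per_gene_kept(self):
        tab = pd.DataFrame(
            [
                {"gene_id": "g1", "scheme": "single", "members": "1",
                 "mean_tpm": 1.0, "mean_log2_tpm": 0.0, "cv": 0.1},
                {"gene_id": "g1", "scheme": "single", "members": "2",
                 "mean_tpm": 1.0, "mean_log2_tpm": 0.0, "cv": 0.3},
                {"gene_id": "g2", "scheme": "single", "members": "1",
                 "mean_tpm": 1.0, "mean_log2_tpm": 0.0, "cv": 0.2},
            ]
        ).sort_values("cv").reset_index(drop=True)
        top = exons.select_top_genes(tab, n_genes=2)
        assert list(top["gene_id"]) == ["g1", "g2"]
        assert top.iloc[0]["cv"] == pytest.approx(0.1)

    def test_short_gene_list_warns_and_returns_all(self):
        tab = pd.DataFrame(
            [{"gene_id": f"g{i}", "scheme": "single", "members": "1",
              "mean_tpm": 1.0, "mean_log2_tpm": 0.0, "cv": 0.1 * (i + 1)}
             for i in range(3)]
        )
        with pytest.warns(UserWarning, match="3 distinct genes"):
            top = exons.select_top_genes(tab, n_genes=5)
        assert len(top) == 3

    def test_known_lowest_cv_genes_recovered_exactly(self, rng):
        genes = [f"g{i:03d}" for i in range(120)]
        cvs = rng.permutation(np.linspace(0.01, 0.9, 120))
        tab = pd.DataFrame(
            [{"gene_id": g, "scheme": "single", "members": "1",
              "mean_tpm": 1.0, "mean_log2_tpm": 0.0, "cv": c}
             for g, c in zip(genes, cvs)]
        ).sort_values("cv").reset_index(drop=True)
        expected = set(tab.head(100)["gene_id"])
        top = exons.select_top_genes(tab, n_genes=100)
        assert set(top["gene_id"]) == expected


class TestGoEnrichment:
    def test_ubiquitous_term_is_uninformative(self):
        bg = {f"g{i}" for i in range(20)}
        ann = pd.DataFrame({"gene_id": sorted(bg), "term_id": "GO:1"})
        res = exons.go_enrichment(["g0", "g1"], ann, bg, fdr_cutoff=1.1)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_fisher_matches_exact_hypergeometric_oracle(self, rng):
        # oracle: exact rational-arithmetic summation of hypergeometric
        # probabilities not exceeding the observed table's probability
        from fractions import Fraction

        for _ in range(60):
            n_bg = int(rng.integers(10, 50))
            n_list = int(rng.integers(2, n_bg - 1))
            n_term = int(rng.integers(1, n_bg))
            a_max = min(n_list, n_term)
            a = int(rng.integers(max(0, n_list + n_term - n_bg), a_max + 1))

            def pmf_num(x):
                return math.comb(n_term, x) * math.comb(n_bg - n_term, n_list - x)

            obs = pmf_num(a)
            total = sum(
                pmf_num(x)
                for x in range(max(0, n_list + n_term - n_bg), a_max + 1)
                if pmf_num(x) <= obs
            )
            oracle = float(Fraction(total, math.comb(n_bg, n_list)))

            bg = [f"g{i}" for i in range(n_bg)]
            gene_list = bg[:n_list]
            term_genes = gene_list[:a] + bg[n_list : n_list + (n_term - a)]
            ann = pd.DataFrame({"gene_id": term_genes, "term_id": "GO:X"})
            res = exons.go_enrichment(gene_list, ann, bg, fdr_cutoff=1.1)
            assert res.iloc[0]["p"] == pytest.approx(oracle, abs=1e-12)

    def test_list_must_be_subset_of_background(self):
        with pytest.raises(ValueError):
            exons.go_enrichment(["x"], pd.DataFrame({"gene_id": [], "term_id": []}),
                                {"a"})

    def test_empty_annotation_yields_empty_result(self):
        res = exons.go_enrichment(
            ["a"], pd.DataFrame({"gene_id": [], "term_id": []}), {"a", "b"}
        )
        assert res.empty


class TestPolyaScan:
    def test_motif_free_sequence(self):
        assert exons.scan_polya_signals("CCCGGG" * 10) == []

    def test_canonical_hit_by_inspection(self):
        assert exons.scan_polya_signals("GGAAUAAAGG") == [("AAUAAA", 3, "canonical")]

    def test_t_read_as_u_and_labels(self):
        hits = exons.scan_polya_signals("AATAAAGATTAAA")
        assert ("AAUAAA", 1, "canonical") in hits
        assert ("AUUAAA", 8, "non-canonical") in hits

    def test_matches_bruteforce_scan_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 1000))
        brute = []
        for motif, label in exons.POLYA_MOTIFS.items():
            for i in range(len(seq) - 5):
                if seq[i : i + 6] == motif:
                    brute.append((motif, i + 1, label))
        assert sorted(exons.scan_polya_signals(seq)) == sorted(brute)

    def test_ambiguous_bases_listed(self):
        with pytest.raises(ValueError, match=r"\[3\]"):
            exons.scan_polya_signals("AANAAA")
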