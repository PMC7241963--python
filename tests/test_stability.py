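"""The four reference-gene stability algorithms against brute-force oracles."""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from segnorm import stability


def _brute_m_values(quantities: pd.DataFrame) -> dict:
    """Independent geNorm M: plain loops, statistics.stdev on log2 ratios."""
    genes = list(quantities.columns)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            ratios = [
                math.log2(quantities.loc[s, g] / quantities.loc[s, h])
                for s in quantities.index
            ]
            sds.append(statistics.stdev(ratios))
        out[g] = sum(sds) / len(sds)
    return out


class TestCqToQuantity:
    def _summary(self, cq_by_gene):
        rows = []
        for gene, values in cq_by_gene.items():
            for i, cq in enumerate(values):
                rows.append({"sample": f"s{i}", "assay": gene, "consensus_cq": cq})
        return pd.DataFrame(rows)

    def test_constant_cq_gives_unit_quantities(self):
        q = stability.cq_to_quantity(self._summary({"A": [25.0, 25.0, 25.0]}))
        assert np.allclose(q.to_numpy(), 1.0)

    def test_one_cycle_above_minimum_halves_quantity(self):
        q = stability.cq_to_quantity(self._summary({"A": [25.0, 26.0]}))
        assert q["A"].tolist() == pytest.approx([1.0, 0.5])

    def test_missing_cell_listed(self):
        df = self._summary({"A": [25.0, 26.0]})
        df = pd.concat(
            [df, pd.DataFrame([{"sample": "s0", "assay": "B", "consensus_cq": 24.0}])]
        )
        with pytest.raises(ValueError, match=r"\(s1, B\)"):
            stability.cq_to_quantity(df)


class TestGenorm:
    def test_proportional_pair_is_most_stable(self, rng):
        base = rng.lognormal(0, 0.5, 8)
        q = pd.DataFrame(
            {"A": base, "B": 3.0 * base, "C": base * rng.lognormal(0, 0.7, 8)}
        )
        res = stability.genorm(q)
        assert res.exclusion_order[0] == "C"
        assert res.m_values["A"] == pytest.approx(res.m_values["B"], rel=1e-12)
        assert res.m_values["C"] > res.m_values["A"]

    def test_m_values_match_bruteforce_oracle(self, toy_quantities):
        oracle = _brute_m_values(toy_quantities)
        m = stability.genorm_m_values(toy_quantities)
        for gene, val in oracle.items():
            assert m[gene] == pytest.approx(val, abs=1e-10)

    def test_stepwise_exclusion_matches_bruteforce_at_every_step(self, rng):
        # recompute the whole stepwise procedure independently
        for seed in range(10):
            g = np.random.default_rng(seed)
            n_genes = int(g.integers(4, 7))
            n_samples = int(g.integers(5, 9))
            q = pd.DataFrame(
                g.lognormal(0, 0.5, (n_samples, n_genes)),
                columns=[f"g{j}" for j in range(n_genes)],
            )
            res = stability.genorm(q)
            remaining = list(q.columns)
            for step, excluded in enumerate(res.exclusion_order[:-1]):
                oracle = _brute_m_values(q[remaining])
                worst_m = max(oracle.values())
                ties = sorted(g_ for g_, v in oracle.items()
                              if abs(v - worst_m) < 1e-12)
                assert excluded == ties[-1]
                remaining.remove(excluded)
            assert set(res.exclusion_order[-1]) == set(remaining)

    def test_m_invariant_to_per_gene_rescaling(self, toy_quantities):
        scaled = toy_quantities.copy()
        scaled["A"] *= 37.0
        scaled["C"] *= 0.003
        m0 = stability.genorm_m_values(toy_quantities)
        m1 = stability.genorm_m_values(scaled)
        assert np.allclose(m0.to_numpy(), m1.to_numpy(), atol=1e-12)

    def test_v_series_and_optimal_n(self, rng):
        base = rng.lognormal(0, 0.5, 10)
        noise = {f"g{j}": base * rng.lognormal(0, 0.05, 10) for j in range(4)}
        q = pd.DataFrame(noise)
        res = stability.genorm(q, cutoff=0.15)
        assert res.optimal_n == 2
        # V_2/3 oracle: SD over samples of log2(NF2/NF3) on the stability order
        order = [g for grp in ([list(res.exclusion_order[-1])]
                               + [[g] for g in reversed(res.exclusion_order[:-1])])
                 for g in sorted(grp)]
        logq = np.log2(q[order].to_numpy())
        v23 = np.std(logq[:, :2].mean(axis=1) - logq[:, :3].mean(axis=1), ddof=1)
        assert res.v_series[2] == pytest.approx(v23, abs=1e-12)

    def test_degenerate_matrix_rejected(self):
        q = pd.DataFrame({"A": [1.0, 1.0, 0.0], "B": [1, 1, 1], "C": [1, 2, 3]})
        with pytest.raises(ValueError):
            stability.genorm(q)


class TestNormfinder:
    def test_gene_tracking_the_sample_mean_has_zero_stability(self, rng):
        common = rng.lognormal(0, 0.5, 6)
        q = pd.DataFrame({"A": common, "B": common, "C": common})
        res = stability.normfinder(q)
        assert np.allclose(res["score"], 0.0, atol=1e-12)

    def test_matches_explicit_residual_sd_oracle(self, toy_quantities):
        x = np.log2(toy_quantities.to_numpy())
        resid = x - x.mean(axis=1, keepdims=True)
        oracle = {
            g: statistics.stdev(resid[:, j])
            for j, g in enumerate(toy_quantities.columns)
        }
        res = stability.normfinder(toy_quantities).set_index("gene")
        for g, v in oracle.items():
            assert res.loc[g, "score"] == pytest.approx(v, abs=1e-10)

    def test_designed_low_variance_gene_ranks_first(self):
        hits = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            common = g.lognormal(0, 0.4, 10)
            q = pd.DataFrame(
                {"quiet": common * g.lognormal(0, 0.05, 10)}
                | {f"mid{j}": common * g.lognormal(0, 0.35, 10) for j in range(5)}
            )
            res = stability.normfinder(q)
            hits += res.iloc[0]["gene"] == "quiet"
        assert hits >= 28

    def test_group_of_one_rejected(self, toy_quantities):
        groups = pd.Series(["x", "y", "y", "y", "y", "y"],
                           index=toy_quantities.index)
        with pytest.raises(ValueError, match="at least 2"):
            stability.normfinder(toy_quantities, groups)

    def test_grouped_mode_penalizes_group_shifted_gene(self, rng):
        common = rng.lognormal(0, 0.3, 8)
        q = pd.DataFrame(
            {
                "flat": common * rng.lognormal(0, 0.05, 8),
                "shifty": common * np.r_[np.full(4, 4.0), np.full(4, 0.25)]
                * rng.lognormal(0, 0.05, 8),
                "mid": common * rng.lognormal(0, 0.2, 8),
            },
            index=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=q.index)
        res = stability.normfinder(q, groups).set_index("gene")
        assert res.loc["shifty", "score"] > res.loc["flat", "score"]


class TestBestkeeper:
    def test_constant_gene_ranks_first(self, toy_cq):
        cq = toy_cq.copy()
        cq["X"] = 25.0
        res = stability.bestkeeper(cq)
        assert res.iloc[0]["gene"] == "X"
        assert res.iloc[0]["score"] == 0.0

    def test_gene_identical_to_index_has_unit_correlation(self):
        # two identical genes: each equals the geometric-mean index
        cq = pd.DataFrame({"A": [24.0, 25.0, 26.0], "B": [24.0, 25.0, 26.0]})
        res = stability.bestkeeper(cq).set_index("gene")
        assert res.loc["A", "r_vs_index"] == pytest.approx(1.0)

    def test_toy_matrix_matches_spreadsheet_style_oracle(self, toy_cq):
        res = stability.bestkeeper(toy_cq).set_index("gene")
        index = [
            math.exp(sum(math.log(v) for v in row) / len(row))
            for row in toy_cq.to_numpy()
        ]
        for gene in toy_cq.columns:
            col = toy_cq[gene].tolist()
            sd = statistics.stdev(col)
            cv = 100.0 * sd / statistics.mean(col)
            r = np.corrcoef(col, index)[0, 1]
            assert res.loc[gene, "score"] == pytest.approx(sd, abs=1e-10)
            assert res.loc[gene, "cv_pct"] == pytest.approx(cv, abs=1e-10)
            assert res.loc[gene, "r_vs_index"] == pytest.approx(r, abs=1e-10)

    def test_high_sd_flagged_inconsistent(self, toy_cq):
        cq = toy_cq.copy()
        cq["X"] = cq["X"] * 0 + np.linspace(20, 30, len(cq))
        res = stability.bestkeeper(cq).set_index("gene")
        assert bool(res.loc["X", "inconsistent"])


class TestComparativeDcq:
    def test_constant_offset_pair_scores_zero_between_them(self):
        cq = pd.DataFrame(
            {"A": [24.0, 25.0, 26.0], "B": [26.0, 27.0, 28.0],
             "C": [24.0, 26.5, 25.0]}
        )
        res = stability.comparative_dcq(cq).set_index("gene")
        # A and B tie: their mutual dCq SD is 0, both pair with C equally
        assert res.loc["A", "score"] == pytest.approx(res.loc["B", "score"])

    def test_matches_bruteforce_pairwise_sd_table(self, toy_cq):
        res = stability.comparative_dcq(toy_cq).set_index("gene")
        genes = list(toy_cq.columns)
        for g in genes:
            sds = [
                statistics.stdev((toy_cq[g] - toy_cq[h]).tolist())
                for h in genes if h != g
            ]
            assert res.loc[g, "score"] == pytest.approx(
                sum(sds) / len(sds), abs=1e-10
            )

    def test_invariant_to_additive_cq_shift(self, toy_cq):
        shifted = toy_cq.copy()
        shifted["Y"] = shifted["Y"] + 7.5
        r0 = stability.comparative_dcq(toy_cq).set_index("gene")["score"]
        r1 = stability.comparative_dcq(shifted).set_index("gene")["score"]
        assert np.allclose(r0.to_numpy(), r1.reindex(r0.index).to_numpy(), atol=1e-12)


class TestComposeNf:
    def test_single_gene_nf_is_that_gene(self, toy_quantities):
        nf = stability.compose_nf(toy_quantities, ["A"])
        assert np.allclose(nf.to_numpy(), toy_quantities["A"].to_numpy())

    def test_geometric_mean_of_two(self):
        q = pd.DataFrame({"A": [1.0, 9.0], "B": [4.0, 1.0]})
        nf = stability.compose_nf(q, ["A", "B"])
        assert nf.tolist() == pytest.approx([2.0, 3.0])

    def test_empty_set_rejected(self, toy_quantities):
        with pytest.raises(ValueError):
            stability.compose_nf(toy_quantities, [])
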