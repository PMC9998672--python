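"""Correlation screening, sign partitioning and network export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import networkx as nx
from rhizometab import (
    SimConfig,
    build_network,
    correlate_all,
    generate_index_table,
    generate_metabolome,
    impute,
    make_sample_meta,
    partition_significant,
)
from rhizometab.screen import read_sif, write_sif
from rhizometab.soil_indices import permutation_pvalue


def records_from(index_table, matrix, **kw):
    return correlate_all(index_table, matrix, **kw)


class TestCorrelateAll:
    def test_metabolite_equal_to_ph_column(self, small_dataset):
        idx = small_dataset["indexes"]
        m = pd.DataFrame(
            {s: [np.expm1(v)] for s, v in idx["ph"].items()}, index=["echo"]
        ).astype(float)
        rec = correlate_all(idx, m)  # log1p(expm1(ph)) == ph exactly
        row = rec[(rec["index_name"] == "ph") & (rec["metabolite_id"] == "echo")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 0.05
        assert row["significant"] and row["sign"] == "+"

    def test_negated_relationship(self, small_dataset):
        idx = small_dataset["indexes"]
        m = pd.DataFrame({s: [np.expm1(10.0 - v)] for s, v in idx["ph"].items()}, index=["anti"]).astype(float)
        rec = correlate_all(idx, m)
        row = rec[(rec["index_name"] == "ph") & (rec["metabolite_id"] == "anti")].iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        assert row["sign"] == "-"

    def test_matches_scipy_pearsonr_per_pair(self, small_dataset):
        idx, matrix = small_dataset["indexes"], impute(small_dataset["matrix"])
        rec = correlate_all(idx, matrix)
        sub = rec.sample(25, random_state=0)
        for row in sub.itertuples(index=False):
            x = idx.loc[matrix.columns, row.index_name].to_numpy()
            y = np.log1p(matrix.loc[row.metabolite_id].to_numpy())
            r, p = stats.pearsonr(x, y)
            assert row.r == pytest.approx(r, rel=1e-9)
            assert row.p == pytest.approx(p, rel=1e-6)

    def test_analytic_p_agrees_with_permutation_oracle(self, small_dataset):
        # at n=9 the discrete permutation null deviates from the continuous
        # t null by a few hundredths per pair; agreement is asserted on the
        # mean over pairs plus a loose per-pair bound
        idx, matrix = small_dataset["indexes"], impute(small_dataset["matrix"])
        rec = correlate_all(idx, matrix)
        rng = np.random.default_rng(7)
        sub = rec.sample(50, random_state=1)
        diffs = []
        for row in sub.itertuples(index=False):
            x = idx.loc[matrix.columns, row.index_name].to_numpy()
            y = np.log1p(matrix.loc[row.metabolite_id].to_numpy())
            p_perm = permutation_pvalue(x, y, n_perm=10_000, rng=rng)
            diffs.append(abs(row.p - p_perm))
        assert np.mean(diffs) <= 0.01
        assert max(diffs) <= 0.05

    def test_null_pvalues_uniform_by_ks(self):
        # pool null p-values over several seeds; KS against Uniform(0,1)
        ps = []
        for seed in range(4):
            cfg = SimConfig(seed=200 + seed, n_metabolites=300, n_pos=0, n_neg=0, missing_rate=0.0)
            matrix, _, _ = generate_metabolome(cfg)
            rec = correlate_all(generate_index_table(cfg), matrix)
            ps.append(rec["p"].to_numpy())
        ps = np.concatenate(ps)
        assert len(ps) >= 10_000
        # correlated tests inflate KS slightly; check gross uniformity
        stat = stats.kstest(ps, "uniform").statistic
        assert stat < 0.05

    def test_constant_rows_skipped_with_reason(self, small_dataset):
        idx = small_dataset["indexes"]
        m = pd.DataFrame(
            {s: [5.0, v] for s, v in zip(small_dataset["matrix"].columns, range(9))},
            index=["const", "vary"],
        )
        rec = correlate_all(idx, m)
        assert "const" not in set(rec["metabolite_id"])
        assert any(mid == "const" and why == "constant" for _, mid, why in rec.attrs["skipped"])

    def test_pairwise_complete_on_missing_cells(self, small_dataset):
        idx = small_dataset["indexes"]
        m = small_dataset["matrix"].iloc[:30]  # has NaN cells at 10% rate
        rec = correlate_all(idx, m)
        assert (rec["n"] <= 9).all() and (rec["n"] >= 3).all()
        some = rec[rec["n"] < 9]
        assert len(some) > 0
        row = some.iloc[0]
        y = m.loc[row["metabolite_id"]]
        mask = y.notna()
        r, p = stats.pearsonr(idx.loc[m.columns, row["index_name"]][mask.to_numpy()], np.log1p(y[mask]))
        assert row["r"] == pytest.approx(r, rel=1e-9)

    def test_sample_mismatch_raises(self, small_dataset):
        m = small_dataset["matrix"].rename(columns={"P1_1": "stranger"})
        with pytest.raises(ValueError, match="absent"):
            correlate_all(small_dataset["indexes"], m)

    def test_deterministic_ordering(self, small_dataset):
        idx, matrix = small_dataset["indexes"], impute(small_dataset["matrix"])
        rec = correlate_all(idx, matrix)
        grp = rec.groupby("index_name", sort=False)["metabolite_id"].apply(list)
        for ids in grp:
            assert ids == sorted(ids)

    def test_bh_correction_weakly_increases_pvalues(self, small_dataset):
        idx, matrix = small_dataset["indexes"], impute(small_dataset["matrix"])
        raw = correlate_all(idx, matrix, correction="none")
        bh = correlate_all(idx, matrix, correction="bh")
        assert (bh["p_adj"].to_numpy() >= bh["p"].to_numpy() - 1e-12).all()
        assert bh["significant"].sum() <= raw["significant"].sum()


class TestPartition:
    def test_planted_55_166_recovered_exactly(self, planted_dataset):
        d = planted_dataset
        rec = correlate_all(d["indexes"], d["matrix"])
        res = partition_significant(rec)
        assert len(res.positive_set) == 55
        assert len(res.negative_set) == 166
        assert res.n_significant == 221
        assert res.positive_set == d["truth"].planted_positive
        assert res.negative_set == d["truth"].planted_negative

    def test_sign_coherence_ph_vs_fungi_on_noiseless_data(self, planted_dataset):
        # a metabolite rising with pH must fall with fungi, and vice versa
        rec = correlate_all(planted_dataset["indexes"], planted_dataset["matrix"])
        wide = rec.pivot(index="metabolite_id", columns="index_name", values="r")
        assert (np.sign(wide["ph"]) == -np.sign(wide["fungi"])).all()

    def test_no_significant_records_gives_empty_sets(self, small_dataset):
        rec = correlate_all(small_dataset["indexes"], impute(small_dataset["matrix"]), alpha=1e-12)
        res = partition_significant(rec)
        assert not res.positive_set and not res.negative_set and not res.conflicted_set

    def test_tied_votes_go_to_conflicted(self):
        rec = pd.DataFrame(
            {
                "index_name": ["ph", "bacteria"],
                "metabolite_id": ["m1", "m1"],
                "n": [9, 9],
                "r": [0.9, -0.9],
                "p": [0.01, 0.01],
                "p_adj": [0.01, 0.01],
                "significant": [True, True],
                "sign": ["+", "-"],
            }
        )
        rec.attrs["alpha"] = 0.05
        res = partition_significant(rec)
        assert res.conflicted_set == {"m1"}

    def test_fungi_sign_inverted_before_voting(self):
        rec = pd.DataFrame(
            {
                "index_name": ["fungi"],
                "metabolite_id": ["m1"],
                "n": [9],
                "r": [-0.95],
                "p": [0.001],
                "p_adj": [0.001],
                "significant": [True],
                "sign": ["-"],
            }
        )
        rec.attrs["alpha"] = 0.05
        res = partition_significant(rec)
        # negative with fungi = positive association with the pH gradient
        assert res.positive_set == {"m1"}

    def test_require_all_is_more_selective(self, small_dataset):
        rec = correlate_all(small_dataset["indexes"], impute(small_dataset["matrix"]))
        any_res = partition_significant(rec, require="any")
        all_res = partition_significant(rec, require="all")
        assert all_res.n_significant <= any_res.n_significant

    def test_partition_sets_disjoint(self, small_dataset):
        rec = correlate_all(small_dataset["indexes"], impute(small_dataset["matrix"]))
        res = partition_significant(rec)
        assert not res.positive_set & res.negative_set
        assert not res.positive_set & res.conflicted_set
        assert not res.negative_set & res.conflicted_set


class TestNetwork:
    def test_complete_bipartite_toy(self):
        rec = pd.DataFrame(
            {
                "index_name": ["ph", "ph", "ph", "mbc", "mbc", "mbc"],
                "metabolite_id": ["a", "b", "c"] * 2,
                "n": [9] * 6,
                "r": [0.9] * 6,
                "p": [0.01] * 6,
                "p_adj": [0.01] * 6,
                "significant": [True] * 6,
                "sign": ["+"] * 6,
            }
        )
        rec.attrs["alpha"] = 0.05
        res = partition_significant(rec)
        g = build_network(res)
        assert g.number_of_edges() == 6
        kinds = nx.get_node_attributes(g, "kind")
        assert sum(v == "index" for v in kinds.values()) == 2
        assert sum(v == "metabolite" for v in kinds.values()) == 3

    def test_planted_scenario_node_and_edge_counts(self, planted_dataset):
        d = planted_dataset
        rec = correlate_all(d["indexes"], d["matrix"])
        res = partition_significant(rec)
        g = build_network(res, d["annotations"])
        met_nodes = [n for n, k in g.nodes(data="kind") if k == "metabolite"]
        assert len(met_nodes) == 221
        n_sig_partitioned = int(
            (rec["significant"] & rec["metabolite_id"].isin(res.positive_set | res.negative_set)).sum()
        )
        assert g.number_of_edges() == n_sig_partitioned

    def test_graphml_and_sif_round_trip(self, planted_dataset, tmp_path):
        d = planted_dataset
        rec = correlate_all(d["indexes"], d["matrix"])
        res = partition_significant(rec)
        gml, sif = tmp_path / "net.graphml", tmp_path / "net.sif"
        g = build_network(res, d["annotations"], graphml_path=gml, sif_path=sif)
        g2 = nx.read_graphml(gml)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in g2.edges}
        edges = read_sif(sif)
        assert len(edges) == g.number_of_edges()
        expected = {
            (u, "pos" if d_["sign"] == "+" else "neg", v) for u, v, d_ in g.edges(data=True)
        }
        assert edges == expected

    def test_empty_screen_valid_files(self, tmp_path):
        rec = pd.DataFrame(
            columns=["index_name", "metabolite_id", "n", "r", "p", "p_adj", "significant", "sign"]
        )
        rec.attrs["alpha"] = 0.05
        res = partition_significant(rec)
        g = build_network(res, sif_path=tmp_path / "e.sif", graphml_path=tmp_path / "e.graphml")
        assert g.number_of_edges() == 0
        assert read_sif(tmp_path / "e.sif") == set()
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
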