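"""Tests of the co-expression screen: Pearson p-values, the hard double
threshold, bipartite networks with K-scores, TR and merged screens, and
genome-adjacency reporting."""
import numpy as np
import pandas as pd
import pytest

from phx import (
    PlantedPair,
    generate_expression,
    merged_network,
    pearson_with_p,
    screen_pairs,
    stage_network,
    tr_screen,
)
from phx.coexnet import (
    adjacency_cluster_report,
    build_network,
    k_scores,
    write_edge_list,
    write_node_attributes,
)
from phx.ingest import normalize_to_reference
from phx.syndata import orf_id


class TestPearsonWithP:
    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        r, p = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0) and p == 0.0

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.9, 5.0])
        r, p = pearson_with_p(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_pearsonr(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for n in (3, 5, 9, 15):
            x, y = rng.normal(size=(2, n))
            r, p = pearson_with_p(x, y)
            r2, p2 = stats.pearsonr(x, y)
            assert r == pytest.approx(r2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(400):
            x, y = rng.normal(size=(2, 20))
            ps.append(pearson_with_p(x, y)[1])
        ps = np.asarray(ps)
        assert 0.35 < (ps < 0.5).mean() < 0.65
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson_with_p([1, 2], [3, 4])


def _screen_matrix(seed=0, n_phage=6, n_host=8, n_times=4, reps=3):
    """Random single-condition matrix for screen oracle tests."""
    from phx.containers import ExpressionMatrix

    rng = np.random.default_rng(seed)
    times = [0] + [5 * (i + 1) for i in range(n_times)]
    cols = [f"t{t}_r{r}" for t in times for r in range(1, reps + 1)]
    samples = pd.DataFrame(
        {
            "time_min": [t for t in times for _ in range(reps)],
            "replicate": [r for _ in times for r in range(1, reps + 1)],
            "condition": "infected",
        },
        index=pd.Index(cols, name="sample_id"),
    )
    phage = [f"ORF{i:02d}" for i in range(1, n_phage + 1)]
    host = [f"PA{i:04d}" for i in range(1, n_host + 1)]
    vals = pd.DataFrame(
        np.exp(rng.normal(5, 1, (n_phage + n_host, len(cols)))),
        index=phage + host, columns=cols,
    )
    feats = pd.DataFrame(
        {"organism": ["phage"] * n_phage + ["host"] * n_host}, index=phage + host
    )
    return ExpressionMatrix(vals, samples, feats)


class TestScreenPairs:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_all_pairs_oracle(self, seed):
        """The vectorized screen equals a naive all-pairs loop on random
        instances (relaxed thresholds so edges actually survive)."""
        from scipy import stats

        m = _screen_matrix(seed=seed, n_phage=12, n_host=20)
        times = [5, 10, 15, 20]
        edges = screen_pairs(m, times, cor_min=0.3, alpha=0.4)
        cols = m.sample_ids(times=times)
        logv = np.log2(m.values[cols])
        expected = set()
        for ph in m.phage_ids:
            for h in m.host_ids:
                r, p = stats.pearsonr(logv.loc[ph], logv.loc[h])
                if p < 0.4 and abs(r) > 0.3:
                    expected.add((ph, h, round(r, 9)))
        got = {(e.phage, e.host, round(e.cor, 9)) for e in edges.itertuples()}
        assert got == expected

    def test_threshold_monotonicity(self):
        m = _screen_matrix(seed=3, n_phage=10, n_host=15)
        times = [5, 10, 15, 20]
        base = screen_pairs(m, times, cor_min=0.2, alpha=0.5)
        tighter_cor = screen_pairs(m, times, cor_min=0.4, alpha=0.5)
        tighter_p = screen_pairs(m, times, cor_min=0.2, alpha=0.2)
        base_set = {(e.phage, e.host) for e in base.itertuples()}
        assert {(e.phage, e.host) for e in tighter_cor.itertuples()} <= base_set
        assert {(e.phage, e.host) for e in tighter_p.itertuples()} <= base_set

    def test_window_too_small_names_minimum(self):
        m = _screen_matrix(reps=1, n_times=2)
        with pytest.raises(ValueError, match="at least 3"):
            screen_pairs(m, [5], level="replicate")

    def test_sign_matches_correlation(self):
        m = _screen_matrix(seed=4)
        edges = screen_pairs(m, [5, 10, 15, 20], cor_min=0.1, alpha=0.9)
        assert (
            np.sign(edges["cor"]) == edges["sign"].map({"+": 1, "-": -1})
        ).all()

    def test_mean_level_uses_timepoint_means(self):
        m = _screen_matrix(seed=5, n_times=5)
        edges = screen_pairs(m, [5, 10, 15, 20, 25], level="mean",
                             cor_min=0.2, alpha=0.9)
        assert (edges["n"] == 5).all() if len(edges) else True


class TestNetworks:
    def _edges(self, pairs, sign="+"):
        return pd.DataFrame(
            [
                {"phage": p, "host": h, "cor": 0.995 if sign == "+" else -0.995,
                 "p": 1e-6, "sign": sign, "stage": "early", "n": 6}
                for p, h in pairs
            ]
        )

    def test_star_gives_k_score_five(self):
        edges = self._edges([("ORF60", f"PA{i:04d}") for i in range(1, 6)])
        net = stage_network(edges, "early")
        assert net.nodes["ORF60"]["k_score"] == 5
        assert all(net.nodes[f"PA{i:04d}"]["k_score"] == 1 for i in range(1, 6))

    def test_single_edge_both_endpoints_k1(self):
        net = stage_network(self._edges([("ORF01", "PA0001")]), "early")
        assert k_scores(net) == {"ORF01": 1, "PA0001": 1}

    def test_negative_only_edges_give_empty_network(self):
        net = stage_network(self._edges([("ORF01", "PA0001")], sign="-"), "early")
        assert net.number_of_nodes() == 0

    def test_k_score_conservation_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = {
                (f"ORF{rng.integers(1, 15):02d}", f"PA{rng.integers(1, 30):04d}")
                for _ in range(rng.integers(1, 40))
            }
            net = build_network(self._edges(sorted(pairs)), positive_only=True)
            assert sum(k_scores(net).values()) == 2 * net.number_of_edges()

    def test_bipartite_between_organisms(self, mirror_normalized):
        res = merged_network(mirror_normalized)
        organisms = {
            n: d["organism"] for n, d in res.network.nodes(data=True)
        }
        for u, v in res.network.edges:
            assert organisms[u] != organisms[v]

    def test_export_tables(self, tmp_path):
        edges = self._edges([("ORF01", "PA0001"), ("ORF01", "PA0002")])
        net = stage_network(edges, "early")
        write_edge_list(edges, tmp_path / "edges.tsv")
        write_node_attributes(net, tmp_path / "nodes.tsv")
        back = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        assert set(back["id"]) == {"ORF01", "PA0001", "PA0002"}
        assert back.set_index("id").loc["ORF01", "k_score"] == 2


class TestTRScreen:
    def test_empty_tr_list_rejected(self, mirror_normalized):
        with pytest.raises(ValueError, match="regulator"):
            tr_screen(mirror_normalized, tr_genes=[])

    def test_single_planted_positive_pair(self, small_config_factory):
        pairs = [PlantedPair(orf_id(6), "PA0030", +1, 0.9975, "middle")]
        cfg = small_config_factory(
            seed=4, tr_pairs=pairs, tr_genes=("PA0030", "PA0031", "PA0032")
        )
        m = normalize_to_reference(generate_expression(cfg, "infected"), "16S")
        res = tr_screen(m)
        assert res.n_positive == 1 and res.n_negative == 0
        assert res.positive.iloc[0]["host"] == "PA0030"

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_pairs_recovered_with_sign(self, seed, small_config_factory):
        pairs = [
            PlantedPair(orf_id(5), "PA0040", -1, 0.9975, "middle"),
            PlantedPair(orf_id(7), "PA0041", +1, 0.9975, "middle"),
        ]
        cfg = small_config_factory(
            seed=seed, tr_pairs=pairs,
            tr_genes=tuple([p.host for p in pairs] + ["PA0050", "PA0051"]),
        )
        m = normalize_to_reference(generate_expression(cfg, "infected"), "16S")
        res = tr_screen(m)
        assert {(e.phage, e.host) for e in res.negative.itertuples()} == {
            (orf_id(5), "PA0040")
        }
        assert {(e.phage, e.host) for e in res.positive.itertuples()} == {
            (orf_id(7), "PA0041")
        }

    @pytest.mark.parametrize("seed", range(50))
    def test_null_data_yields_no_pairs(self, seed, small_config_factory):
        """Without planted pairs the hard thresholds are essentially
        unreachable at n=9 (50 seeds)."""
        cfg = small_config_factory(
            seed=seed, host_gene_count=60,
            tr_genes=tuple(f"PA{i:04d}" for i in range(1, 41)),
        )
        m = normalize_to_reference(generate_expression(cfg, "infected"), "16S")
        res = tr_screen(m)
        assert res.n_negative == 0 and res.n_positive == 0


class TestMergedNetwork:
    def test_missing_time_point_is_hard_error(self, small_config_factory):
        m = generate_expression(small_config_factory(), "infected")
        sub_cols = m.sample_ids(times=[0, 5, 10, 20, 30])
        from phx.containers import ExpressionMatrix

        sub = ExpressionMatrix(
            m.values[sub_cols], m.samples.loc[sub_cols], m.features
        )
        with pytest.raises(ValueError, match="missing"):
            merged_network(sub)

    def test_function_target_counts(self, small_config_factory):
        from phx import generate_annotations

        pairs = [
            PlantedPair(orf_id(9), f"PA{i:04d}", +1, 0.9975, "merged")
            for i in range(1, 4)
        ]
        cfg = small_config_factory(seed=6, merged_pairs=pairs)
        m = normalize_to_reference(generate_expression(cfg, "infected"), "16S")
        spike = {"F_T": {"PA0001", "PA0002", "PA0003"}}
        amap = generate_annotations(cfg, terms_per_gene=0, n_terms=3, spike=spike)
        res = merged_network(m, annotation_map=amap)
        assert res.function_targets.loc[orf_id(9), "F_T"] == 3

    def test_empty_network_empty_table(self, small_config_factory):
        cfg = small_config_factory(seed=8, host_gene_count=30)
        m = normalize_to_reference(generate_expression(cfg, "infected"), "16S")
        res = merged_network(m)
        assert res.network.number_of_nodes() == 0
        assert res.function_targets.empty


class TestAdjacencyReport:
    def _net(self, components):
        import networkx as nx

        G = nx.Graph()
        for i, orfs in enumerate(components):
            for o in orfs:
                G.add_node(o, organism="phage")
                G.add_edge(o, f"PA{i:04d}")
                G.nodes[f"PA{i:04d}"]["organism"] = "host"
        return G

    def test_contiguous_component(self):
        rep = adjacency_cluster_report(self._net([["ORF64", "ORF65"]]))
        assert rep.table.iloc[0]["contiguous"]
        assert rep.contiguity_fraction == 1.0

    def test_non_contiguous_component(self):
        rep = adjacency_cluster_report(self._net([["ORF60", "ORF70"]]))
        assert not rep.table.iloc[0]["contiguous"]

    def test_singleton_contiguous_by_convention(self):
        rep = adjacency_cluster_report(self._net([["ORF07"]]))
        assert rep.table.iloc[0]["contiguous"]

    def test_mixed_components_fraction(self):
        rep = adjacency_cluster_report(
            self._net([["ORF64", "ORF65"], ["ORF60", "ORF70"]])
        )
        assert rep.contiguity_fraction == 0.5
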