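import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from estuarch.netinfer import (
    AssociationNetwork,
    NetworkConfig,
    classify_roles,
    clr_transform,
    detect_modules,
    infer_direct_network,
    summarize_cross_domain,
    zi_pi,
)
from estuarch.synthdata import (
    PlantedGraphSpec,
    random_planted_graph_spec,
    simulate_graph_counts,
)
from estuarch.tables import FeatureTable, TaxonomyMap


class TestClr:
    def test_uniform_sample_is_zero(self):
        tab = FeatureTable(pd.DataFrame([[5, 5, 5]], index=["s"], columns=list("abc")))
        out = clr_transform(tab, pseudocount=1.0)
        assert np.allclose(out.values, 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        tab = FeatureTable(
            pd.DataFrame(rng.integers(0, 100, (5, 20)),
                         index=[f"s{i}" for i in range(5)])
        )
        out = clr_transform(tab)
        assert np.abs(out.values.sum(axis=1)).max() < 1e-9

    def test_geometric_mean_hand_value(self):
        # counts (1,3,9): gmean 3, clr = (-log3, 0, log3); tiny pseudocount
        tab = FeatureTable(pd.DataFrame([[1, 3, 9]], index=["s"], columns=list("abc")))
        out = clr_transform(tab, pseudocount=1e-9)
        assert np.allclose(out.values[0], [-np.log(3), 0.0, np.log(3)], atol=1e-6)

    def test_pseudocount_validated(self):
        tab = FeatureTable(pd.DataFrame([[1, 2]], index=["s"]))
        with pytest.raises(ValueError):
            clr_transform(tab, pseudocount=0.0)


def _graph(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, weight=1.0, abs_weight=1.0, sign="+")
    return AssociationNetwork(graph=g, config=NetworkConfig())


class TestInference:
    def test_planted_chain_has_no_skip_edge(self):
        # A-B-C embedded in a background of independent taxa
        edges = (("ZOTU1", "ZOTU2", 1, 0.45), ("ZOTU2", "ZOTU3", 1, 0.45))
        spec = PlantedGraphSpec(25, edges, (), 500, 50_000, seed=101)
        tab, _ = simulate_graph_counts(spec)
        net = infer_direct_network(tab, None, NetworkConfig(), seed=0)
        got = set(net.edges)
        assert ("ZOTU1", "ZOTU2") in got
        assert ("ZOTU2", "ZOTU3") in got
        assert ("ZOTU1", "ZOTU3") not in got

    def test_env_confounded_pair_resolved(self):
        spec = PlantedGraphSpec(
            20, (), (("temperature", "ZOTU1", 1.0), ("temperature", "ZOTU2", 1.0)),
            300, 50_000, seed=5,
        )
        tab, env = simulate_graph_counts(spec)
        net = infer_direct_network(
            tab, env, NetworkConfig(env_names=("temperature",)), seed=0
        )
        got = set(net.edges)
        assert ("ZOTU1", "ZOTU2") not in got
        assert ("ZOTU1", "temperature") in got
        assert ("ZOTU2", "temperature") in got

    def test_planted_benchmark_precision_recall(self):
        spec = random_planted_graph_spec(seed=3)
        tab, _ = simulate_graph_counts(spec)
        net = infer_direct_network(tab, None, NetworkConfig(), seed=0)
        got = set(net.edges)
        truth = {tuple(sorted((a, b))) for a, b, _, _ in spec.edges}
        tp = len(got & truth)
        assert tp / len(got) >= 0.8   # precision
        assert tp / len(truth) >= 0.8  # recall

    def test_invariant_to_sample_and_feature_order(self):
        spec = random_planted_graph_spec(n_taxa=20, n_edges=10, n_samples=150, seed=6)
        tab, _ = simulate_graph_counts(spec)
        net1 = infer_direct_network(tab, None, NetworkConfig(), seed=0)
        shuffled = FeatureTable(
            tab.data.sample(frac=1, axis=0, random_state=3).sample(
                frac=1, axis=1, random_state=4
            )
        )
        net2 = infer_direct_network(shuffled, None, NetworkConfig(), seed=1)
        assert set(net1.edges) == set(net2.edges)

    def test_missing_env_rejected(self):
        spec = random_planted_graph_spec(n_taxa=10, n_edges=4, n_samples=60, seed=7)
        tab, _ = simulate_graph_counts(spec)
        env = pd.DataFrame({"temperature": [np.nan] + [1.0] * 59}, index=tab.sample_ids)
        with pytest.raises(ValueError, match="missing"):
            infer_direct_network(tab, env, NetworkConfig(env_names=("temperature",)))

    def test_too_few_samples_rejected(self):
        spec = random_planted_graph_spec(n_taxa=10, n_edges=4, n_samples=5, seed=8)
        tab, _ = simulate_graph_counts(spec)
        with pytest.raises(ValueError, match="n_obs_min"):
            infer_direct_network(tab, None, NetworkConfig(n_obs_min=10))


class TestModules:
    def test_two_cliques_two_modules(self):
        clique1 = list(itertools.combinations(["a", "b", "c", "d"], 2))
        clique2 = list(itertools.combinations(["w", "x", "y", "z"], 2))
        net = _graph(clique1 + clique2 + [("d", "w")])
        modules = detect_modules(net)
        assert modules["a"] == modules["b"] == modules["c"] == modules["d"]
        assert modules["w"] == modules["x"] == modules["y"] == modules["z"]
        assert modules["a"] != modules["w"]

    def test_isolated_nodes_are_singletons(self):
        net = _graph([("a", "b")], nodes=["a", "b", "lonely"])
        modules = detect_modules(net)
        assert modules["lonely"] not in (modules["a"], modules["b"])

    def test_partition_beats_singletons(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(15, 0.3, seed=10)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
            g[u][v]["abs_weight"] = 1.0
            g[u][v]["sign"] = "+"
        net = AssociationNetwork(graph=g, config=NetworkConfig())
        modules = detect_modules(net)
        comms = {}
        for n, m in modules.items():
            comms.setdefault(m, set()).add(n)
        q = nx.community.modularity(g, comms.values(), weight="abs_weight")
        q_singleton = nx.community.modularity(g, [{n} for n in g.nodes], weight="abs_weight")
        assert q >= q_singleton


class TestZiPi:
    @staticmethod
    def _fixture():
        # 7-node, two-module graph with an inter-module connector
        edges = [
            ("a", "b"), ("a", "c"), ("b", "c"),        # module 0 triangle
            ("d", "e"), ("d", "f"), ("e", "f"), ("f", "g"),  # module 1
            ("c", "d"),                                  # bridge
        ]
        net = _graph(edges)
        modules = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1, "g": 1}
        return net, modules

    def test_matches_brute_force_formula(self):
        net, modules = self._fixture()
        df = zi_pi(net, modules)
        g = net.graph
        # independent brute-force recomputation
        for node in g.nodes:
            k = g.degree(node)
            per_mod = {}
            for nb in g.neighbors(node):
                per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
            pi = 1 - sum((c / k) ** 2 for c in per_mod.values()) if k else 0.0
            assert df.loc[node, "Pi"] == pytest.approx(pi)
        for mod in set(modules.values()):
            members = [n for n in g.nodes if modules[n] == mod]
            within = np.array(
                [sum(1 for nb in g.neighbors(n) if modules[nb] == mod) for n in members],
                dtype=float,
            )
            sd = within.std()
            for n, w in zip(members, within):
                expect = 0.0 if sd == 0 else (w - within.mean()) / sd
                assert df.loc[n, "Zi"] == pytest.approx(expect)

    def test_single_module_pi_zero(self):
        net = _graph([("a", "b"), ("b", "c")])
        df = zi_pi(net, {"a": 0, "b": 0, "c": 0})
        assert (df["Pi"] == 0.0).all()

    def test_even_split_pi_half(self):
        net = _graph([("hub", "a"), ("hub", "b"), ("hub", "c"), ("hub", "d")])
        modules = {"hub": 0, "a": 0, "b": 0, "c": 1, "d": 1}
        df = zi_pi(net, modules)
        assert df.loc["hub", "Pi"] == pytest.approx(0.5)

    def test_zi_standardized_within_module(self):
        net, modules = self._fixture()
        df = zi_pi(net, modules)
        for mod in set(modules.values()):
            sub = df[df["module"] == mod]["Zi"]
            if sub.std(ddof=0) > 0:
                assert sub.mean() == pytest.approx(0.0, abs=1e-12)
                assert sub.std(ddof=0) == pytest.approx(1.0)

    def test_missing_module_raises(self):
        net = _graph([("a", "b")])
        with pytest.raises(KeyError):
            zi_pi(net, {"a": 0})


class TestRoles:
    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (2.5, 0.62, "peripheral"),   # both boundaries inclusive
            (3.0, 0.7, "network_hub"),
            (0.0, 0.0, "peripheral"),
            (2.5001, 0.62, "module_hub"),
            (2.5, 0.6201, "connector"),
            (-1.0, 0.9, "connector"),
        ],
    )
    def test_threshold_classification(self, zi, pi, expected):
        df = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
        assert classify_roles(df).loc["n"] == expected

    def test_roles_partition_nodes(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"Zi": rng.normal(2.5, 1, 50), "Pi": rng.uniform(0, 1, 50)})
        roles = classify_roles(df)
        assert roles.isin(["peripheral", "connector", "module_hub", "network_hub"]).all()
        assert len(roles) == 50


class TestCrossDomainSummary:
    @staticmethod
    def _setup():
        tax_rows = {
            "A1": ("Archaea", "p", "c", "o", "f", "Nitrosopumilus"),
            "A2": ("Archaea", "p", "c", "o", "f", "Poseidonia"),
            "B1": ("Bacteria", "p", "c", "o", "f", "gB1"),
            "B2": ("Bacteria", "p", "c", "o", "f", "gB2"),
            "P1": ("Bacteria", "Cyanobacteria", "c", "Chloroplast", "f", "gP"),
        }
        tax = TaxonomyMap(
            pd.DataFrame.from_dict(tax_rows, orient="index",
                                   columns=list(TaxonomyMap.RANKS))
        )
        g = nx.Graph()
        for n in tax_rows:
            domain = ("archaea" if n.startswith("A")
                      else "phytoplankton" if n.startswith("P") else "bacteria")
            g.add_node(n, kind="taxon", domain=domain, mean_rel_abundance=0.01)
        g.add_node("temperature", kind="env", domain="")
        def e(u, v, w):
            g.add_edge(u, v, weight=w, abs_weight=abs(w), sign="+" if w >= 0 else "-")
        e("A1", "A2", 0.5)    # archaea-archaea +
        e("A1", "B1", 0.4)    # archaea-bacteria +
        e("A1", "B2", -0.4)   # archaea-bacteria -
        e("A2", "P1", 0.3)    # archaea-phytoplankton +
        e("B1", "B2", 0.2)    # other
        e("A1", "temperature", 0.6)  # taxon-env
        return AssociationNetwork(graph=g, config=NetworkConfig()), tax

    def test_edge_class_counts_match_enumeration(self):
        net, tax = self._setup()
        out = summarize_cross_domain(net, tax)["edge_classes"].set_index("edge_class")
        assert out.loc["archaea-archaea", "n_edges"] == 1
        assert out.loc["archaea-bacteria", "n_edges"] == 2
        assert out.loc["archaea-phytoplankton", "n_edges"] == 1
        assert out.loc["taxon-env", "n_edges"] == 1
        assert out.loc["other", "n_edges"] == 1
        assert out.loc["archaea-bacteria", "pct_positive"] == pytest.approx(50.0)
        assert out.loc["all", "n_edges"] == 6

    def test_genus_degrees(self):
        net, tax = self._setup()
        genera = summarize_cross_domain(net, tax)["archaeal_genera"].set_index("genus")
        # A1: degree 4 (A2, B1, B2, temperature), cross-domain = 2 bacteria
        assert genera.loc["Nitrosopumilus", "degree"] == 4
        assert genera.loc["Nitrosopumilus", "cross_domain_degree"] == 2
        assert genera.loc["Poseidonia", "cross_domain_degree"] == 1

    def test_no_archaea_all_zero(self):
        net, tax = self._setup()
        for n in ["A1", "A2"]:
            net.graph.remove_node(n)
        out = summarize_cross_domain(net, tax)["edge_classes"].set_index("edge_class")
        assert out.loc["archaea-archaea", "n_edges"] == 0
        assert out.loc["archaea-bacteria", "n_edges"] == 0

    def test_all_positive_percent(self):
        net, tax = self._setup()
        for _, _, attrs in net.graph.edges(data=True):
            attrs["weight"] = abs(attrs["weight"])
            attrs["sign"] = "+"
        out = summarize_cross_domain(net, tax)["edge_classes"]
        assert (out.dropna(subset=["pct_positive"])["pct_positive"] == 100.0).all()
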