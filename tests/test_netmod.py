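"""Greedy dense-module search: score mapping, per-step oracle, merging."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflammage import netmod


def test_p_to_z_reference_values():
    g, _ = netmod.p_to_z(0.5)
    assert g == 0.0  # median of the null scores zero
    g, _ = netmod.p_to_z(0.05)
    assert g == pytest.approx(1.6449, abs=1e-4)
    g, _ = netmod.p_to_z(2.8e-6)
    assert g == pytest.approx(4.54, abs=0.005)
    g, _ = netmod.p_to_z(0.9)
    assert g == 0.0  # truncated below at zero


def test_p_to_z_sign_and_floor():
    _, z = netmod.p_to_z(0.05, beta_sign=-1.0)
    assert z == pytest.approx(-stats.norm.isf(0.025), abs=1e-10)
    with pytest.warns(RuntimeWarning, match="floor"):
        g, _ = netmod.p_to_z(0.0)
    assert g == pytest.approx(stats.norm.isf(1e-30), rel=1e-6)
    with pytest.raises(ValueError):
        netmod.p_to_z(1.5)


def _graph(edges, scores):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(scores)
    for n, s in scores.items():
        g.nodes[n]["g"] = s
    return g


def test_isolated_seed_module():
    g = _graph([], {"A": 3.0})
    mod = netmod.grow_module(g, "A")
    assert mod.members == ("A",) and mod.z_m == 3.0


def test_low_scoring_neighbor_rejected():
    g = _graph([("A", "B")], {"A": 3.0, "B": 0.0})
    mod = netmod.grow_module(g, "A")
    # Z' = 3/sqrt(2) = 2.121 < 3: stay at the seed
    assert mod.members == ("A",)
    assert mod.z_m == pytest.approx(3.0)


def test_high_scoring_neighbor_accepted():
    g = _graph([("A", "B")], {"A": 3.0, "B": 2.0})
    mod = netmod.grow_module(g, "A")
    assert mod.members == ("A", "B")
    assert mod.z_m == pytest.approx(5.0 / np.sqrt(2))


def test_missing_seed_errors():
    with pytest.raises(KeyError):
        netmod.grow_module(_graph([], {"A": 1.0}), "ZZ")


def _verify_greedy_trace(graph, mod):
    """Step-by-step recomputation: each addition is the max-Z' candidate and
    strictly increases the module score."""
    members = [mod.seed]
    total = graph.nodes[mod.seed].get("g", 0.0)
    z = total
    for gene, z_after in mod.trace[1:]:
        cands = {
            n
            for m in members
            for n in graph.neighbors(m)
            if n not in members
        }
        assert gene in cands
        best_z = max(
            (total + graph.nodes[c].get("g", 0.0)) / np.sqrt(len(members) + 1)
            for c in cands
        )
        z_new = (total + graph.nodes[gene].get("g", 0.0)) / np.sqrt(len(members) + 1)
        assert z_new == pytest.approx(best_z, abs=1e-12)
        assert z_new > z
        members.append(gene)
        total += graph.nodes[gene].get("g", 0.0)
        z = z_new
    assert tuple(members) == mod.members
    # Z_m recomputes from members exactly
    assert mod.z_m == pytest.approx(
        sum(graph.nodes[m].get("g", 0.0) for m in mod.members) / np.sqrt(len(mod.members)),
        abs=1e-12,
    )


@pytest.mark.parametrize("seed", range(100))
def test_greedy_oracle_on_random_small_graphs(seed):
    """Random graphs with <= 8 nodes: every greedy step is verified maximal
    and score-increasing by exhaustive candidate enumeration."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
    for node in g.nodes:
        g.nodes[node]["g"] = float(np.round(rng.uniform(0, 4), 3))
    seed_node = f"N{rng.integers(n)}"
    mod = netmod.grow_module(g, seed_node)
    assert mod.z_m >= g.nodes[seed_node]["g"] - 1e-12
    _verify_greedy_trace(g, mod)
    # trace scores strictly increasing
    zs = [z for _, z in mod.trace]
    assert all(b > a for a, b in zip(zs, zs[1:]))
    # connectivity of the module
    assert nx.is_connected(g.subgraph(mod.members))


def test_score_network_unscored_nodes_get_zero():
    g = nx.Graph([("A", "B"), ("B", "C")])
    results = pd.DataFrame({"gene": ["A", "B"], "beta": [1.0, -2.0],
                            "p": [1e-4, 0.03]})
    scored = netmod.score_network(g, results)
    assert scored.nodes["C"]["g"] == 0.0 and not scored.nodes["C"]["scored"]
    assert scored.nodes["A"]["g"] > scored.nodes["B"]["g"] > 0
    assert scored.nodes["B"]["z"] < 0  # sign follows beta


def test_moderate_connector_recruited_when_bridging():
    """A modestly scored hub joins once the module is strong enough, opening
    the path to further strong genes; a zero-score hub never can, because
    (T+0)/sqrt(k+1) < T/sqrt(k) always under strict improvement."""
    g = _graph(
        [("S", "A"), ("A", "HUB"), ("HUB", "X")],
        {"S": 4.0, "A": 4.0, "HUB": 2.0, "X": 4.0},
    )
    mod = netmod.grow_module(g, "S")
    assert mod.members == ("S", "A", "HUB", "X")
    zero_hub = _graph([("S", "HUB"), ("HUB", "X")], {"S": 4.0, "HUB": 0.0, "X": 4.0})
    assert netmod.grow_module(zero_hub, "S").members == ("S",)


def test_build_subnetwork_merging_and_determinism():
    rng = np.random.default_rng(7)
    g = nx.gnp_random_graph(40, 0.12, seed=3)
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(40)})
    results = pd.DataFrame(
        {"gene": [f"N{i:02d}" for i in range(40)],
         "beta": rng.normal(size=40),
         "p": rng.uniform(1e-8, 1, 40)}
    )
    sub1, mods1 = netmod.build_subnetwork(g, results, n_seeds=5)
    sub2, mods2 = netmod.build_subnetwork(g, results, n_seeds=5)
    assert set(sub1.nodes) == set(sub2.nodes)
    assert [m.members for m in mods1] == [m.members for m in mods2]
    union = set().union(*[set(m.members) for m in mods1])
    assert set(sub1.nodes) == union
    # induced edges only: every original edge within the union is present
    for a, b in itertools.combinations(sorted(union), 2):
        assert sub1.has_edge(a, b) == g.has_edge(a, b)


def test_all_zero_scores_no_growth():
    g = nx.path_graph(5)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(5)})
    results = pd.DataFrame({"gene": [f"N{i}" for i in range(5)],
                            "beta": [1.0] * 5, "p": [0.99] * 5})
    sub, mods = netmod.build_subnetwork(g, results, n_seeds=3)
    assert all(m.k == 1 for m in mods)
    assert sub.number_of_edges() <= 2  # only seed nodes, induced edges


def test_fewer_seeds_than_requested_warns():
    g = nx.Graph([("A", "B")])
    results = pd.DataFrame({"gene": ["A", "B"], "beta": [1, 1],
                            "p": [0.001, 0.002]})
    with pytest.warns(RuntimeWarning, match="seeds"):
        sub, mods = netmod.build_subnetwork(g, results, n_seeds=10)
    assert len(mods) == 2


def test_planted_cluster_recovered(small_data, small_config):
    """The planted high-score cluster is mostly recovered in the union."""
    from inflammage import assoc

    truth = small_data["truth"]
    cohort = small_data["cohort"]
    results, _ = assoc.run_scan(
        small_data["expression"], truth.delta, cohort, ["age", "sex"]
    )
    sub, _ = netmod.build_subnetwork(small_data["network"], results, n_seeds=25)
    cluster = set(sorted(truth.true_gene_ids)[: small_config.planted_cluster_size])
    frac = len(cluster & set(sub.nodes)) / len(cluster)
    assert frac >= 0.8
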