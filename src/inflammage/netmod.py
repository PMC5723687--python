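"""Greedy dense-module search on a PPI network.

Each gene carries an unsigned node score g = Phi^-1(1 - p) (truncated at 0
for p > 0.5); a module's score is Z_m = (sum of member scores) / sqrt(k).
Starting from each of the top seed genes, the search repeatedly adds the
single neighboring gene that most increases Z_m, stopping when no addition
strictly increases it; the modules grown from all seeds are merged and the
subgraph induced on their union is the reported subnetwork.  Unscored
network nodes get g = 0 so they can still be recruited as connectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-30


def p_to_z(p: float, beta_sign: float = 1.0, p_floor: float = P_FLOOR) -> tuple[float, float]:
    """Map a two-sided p to (unsigned node score g, signed display z).

    g = Phi^-1(1 - p), truncated below at 0 (p > 0.5 scores 0); the signed z
    is sign(beta) * |Phi^-1(p/2)|, used only for display coloring.  p = 0 is
    capped at ``p_floor`` with a warning.
    """
    import warnings

    if p <= 0.0:
        warnings.warn(f"p=0 capped at floor {p_floor:g}", RuntimeWarning, stacklevel=2)
        p = p_floor
    if p > 1.0:
        raise ValueError("p must lie in (0, 1]")
    g = float(max(stats.norm.isf(p), 0.0))
    z_signed = float(np.sign(beta_sign) * abs(stats.norm.isf(p / 2.0)))
    return g, z_signed


@dataclass
class ModuleResult:
    seed: str
    members: tuple
    z_m: float
    trace: list = field(default_factory=list)  # (added gene, score after)

    @property
    def k(self) -> int:
        return len(self.members)


def module_score(graph: nx.Graph, members: Sequence[str]) -> float:
    """Z_m = sum of member node scores / sqrt(k)."""
    members = list(members)
    total = sum(graph.nodes[m].get("g", 0.0) for m in members)
    return total / np.sqrt(len(members))


def score_network(
    graph: nx.Graph,
    results: pd.DataFrame,
    p_floor: float = P_FLOOR,
) -> nx.Graph:
    """Attach node scores from a scan-results table (feature/gene, beta, p).

    Genes absent from the results get g = 0 and are flagged unscored; they
    remain eligible as connectors during module growth.
    """
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    key = "gene" if "gene" in results.columns else "feature"
    by_gene = results.drop_duplicates(subset=key, keep="first").set_index(key)
    for node in g.nodes:
        if node in by_gene.index:
            row = by_gene.loc[node]
            score, z_signed = p_to_z(float(row["p"]), float(np.sign(row["beta"])), p_floor)
            g.nodes[node].update(g=score, z=z_signed, p=float(row["p"]), scored=True)
        else:
            g.nodes[node].update(g=0.0, z=0.0, p=np.nan, scored=False)
    return g


def grow_module(graph: nx.Graph, seed: str) -> ModuleResult:
    """Greedy best-first expansion from a seed gene.

    At each step every node adjacent to the current module (and not in it)
    is a candidate; the one giving the largest Z' = (sum g + g_cand)/sqrt(k+1)
    is added iff Z' strictly exceeds the current score.  Ties break by higher
    candidate score, then lexicographic gene symbol.
    """
    if seed not in graph:
        raise KeyError(f"seed gene {seed!r} not in network")
    members = [seed]
    member_set = {seed}
    total = graph.nodes[seed].get("g", 0.0)
    z_m = total / 1.0
    trace = [(seed, z_m)]
    while True:
        candidates = set()
        for m in member_set:
            candidates.update(n for n in graph.neighbors(m) if n not in member_set)
        if not candidates:
            break
        k = len(members)
        best = None
        # sorted() + strict > keeps the lexicographically smallest symbol on ties
        for cand in sorted(candidates):
            gc = graph.nodes[cand].get("g", 0.0)
            z_new = (total + gc) / np.sqrt(k + 1)
            if best is None or (z_new, gc) > (best[0], best[1]):
                best = (z_new, gc, cand)
        z_new, gc, cand = best
        if z_new > z_m:
            members.append(cand)
            member_set.add(cand)
            total += gc
            z_m = z_new
            trace.append((cand, z_m))
        else:
            break
    return ModuleResult(seed=seed, members=tuple(members), z_m=float(z_m), trace=trace)


def build_subnetwork(
    graph: nx.Graph,
    results: pd.DataFrame,
    n_seeds: int = 25,
    p_floor: float = P_FLOOR,
) -> tuple[nx.Graph, list[ModuleResult]]:
    """Grow one module per top seed gene and merge them.

    Seeds are the ``n_seeds`` genes with the smallest scan p that exist in
    the network; if fewer are available the search proceeds with those and
    warns.  Returns the subgraph induced on the union of module members
    (node attributes g, z, p, degree) and the per-seed modules.
    """
    import warnings

    scored = score_network(graph, results, p_floor)
    key = "gene" if "gene" in results.columns else "feature"
    ranked = results.sort_values(["p", key], kind="stable")
    seeds = [g for g in ranked[key] if g in scored][:n_seeds]
    if len(seeds) < n_seeds:
        warnings.warn(
            f"only {len(seeds)} scored genes present in the network "
            f"(requested {n_seeds} seeds)",
            RuntimeWarning,
            stacklevel=2,
        )
    modules = [grow_module(scored, s) for s in seeds]
    union = sorted(set().union(*[set(m.members) for m in modules])) if modules else []
    sub = scored.subgraph(union).copy()
    for node in sub.nodes:
        sub.nodes[node]["degree"] = sub.degree(node)
    return sub, modules


def subnetwork_tables(sub: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node-attribute and edge-list tables for graph viewers."""
    nodes = pd.DataFrame(
        [
            {
                "gene": n,
                "g": sub.nodes[n].get("g", 0.0),
                "z_signed": sub.nodes[n].get("z", 0.0),
                "p": sub.nodes[n].get("p", np.nan),
                "degree": sub.degree(n),
            }
            for n in sorted(sub.nodes)
        ]
    )
    edges = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in sub.edges), columns=["gene_a", "gene_b"]
    )
    return nodes, edges
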