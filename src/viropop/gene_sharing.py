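"""Gene-sharing genus networks.

Each viral population carries a set of protein clusters (PCs).  For a pair
of populations sharing ``k`` of their ``n_a`` and ``n_b`` PCs out of
``N`` total, the edge weight is the improbability of that overlap under a
hypergeometric null:

    score = -log10 P[X >= k],  X ~ Hypergeom(N, n_a, n_b)

computed in log space via log-gamma.  Edges at or above a significance
threshold form an undirected network; connected components of size >= 2
passing a density check become genera, their well-connected members are
``clustered``, poorly connected or rejected-component nodes are
``outliers``, and isolated nodes are ``singletons`` — a deliberately
simplified analogue of vConTACT-style genus assignment (no ClusterONE/MCL).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ProteinClusterProfile",
    "GenusAssignment",
    "edge_significance",
    "build_network",
    "assign_genera",
]

DEFAULT_SIGNIFICANCE_THRESHOLD = 1.0  # P <= 0.1
DEFAULT_DENSITY_MIN = 0.5


@dataclass(frozen=True)
class ProteinClusterProfile:
    population_id: str
    pc_ids: frozenset[str]


@dataclass(frozen=True)
class GenusAssignment:
    population_id: str
    genus_id: str | None
    status: str  # clustered | outlier | singleton


def _log_comb(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def edge_significance(shared: int, n_a: int, n_b: int, n_total_pcs: int) -> float:
    """-log10 of the hypergeometric upper-tail probability of sharing at
    least ``shared`` PCs.

    ``P = sum_{k=shared}^{min(n_a, n_b)} C(n_a,k) C(N-n_a, n_b-k) / C(N, n_b)``
    evaluated with log-gamma and log-sum-exp, so extreme overlaps do not
    underflow.
    """
    if not (0 <= n_a <= n_total_pcs and 0 <= n_b <= n_total_pcs):
        raise ValueError("profile sizes must be within [0, n_total_pcs]")
    upper = min(n_a, n_b)
    if shared < 0 or shared > upper:
        raise ValueError(f"shared={shared} outside [0, min(n_a, n_b)={upper}]")
    if shared == 0:
        return 0.0
    k = np.arange(shared, upper + 1)
    # terms with n_b - k > N - n_a have zero probability
    valid = (n_b - k) <= (n_total_pcs - n_a)
    k = k[valid]
    if k.size == 0:
        raise ValueError("impossible margins: no feasible overlap values")
    log_terms = (
        _log_comb(n_a, k)
        + _log_comb(n_total_pcs - n_a, n_b - k)
        - _log_comb(n_total_pcs, n_b)
    )
    log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)  # clamp tiny positive rounding
    return -log_p / np.log(10.0)


def build_network(
    profiles: list[ProteinClusterProfile] | dict[str, set[str]],
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
) -> nx.Graph:
    """Build the thresholded gene-sharing graph over populations.

    The hypergeometric universe is the union of all PC ids across
    profiles.  Every population is a node; an edge is kept iff its score
    meets the threshold, with the score stored as the ``weight``
    attribute.
    """
    if isinstance(profiles, dict):
        profiles = [ProteinClusterProfile(p, frozenset(s)) for p, s in profiles.items()]
    graph = nx.Graph()
    for prof in profiles:
        graph.add_node(prof.population_id)
    n_total = len(set().union(*[set(p.pc_ids) for p in profiles])) if profiles else 0
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            shared = len(set(a.pc_ids) & set(b.pc_ids))
            if shared == 0:
                continue
            score = edge_significance(shared, len(a.pc_ids), len(b.pc_ids), n_total)
            if score >= significance_threshold:
                graph.add_edge(a.population_id, b.population_id, weight=score)
    return graph


def assign_genera(
    graph: nx.Graph,
    membership_min_edges: int = 1,
    density_min: float = DEFAULT_DENSITY_MIN,
) -> list[GenusAssignment]:
    """Label populations as clustered / outlier / singleton.

    Connected components of size >= 2 whose internal edge density is at
    least ``density_min`` become genera (ids ``g001``... in order of their
    lexicographically smallest member).  Within an accepted genus, nodes
    with at least ``membership_min_edges`` internal edges are
    ``clustered``; other nodes with edges — weakly attached members or
    members of rejected components — are ``outliers``; edgeless nodes are
    ``singletons``.  The three statuses partition the node set.
    """
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    assignments: list[GenusAssignment] = []
    genus_counter = 0
    for comp in components:
        if len(comp) == 1:
            node = comp[0]
            assignments.append(GenusAssignment(node, None, "singleton"))
            continue
        sub = graph.subgraph(comp)
        density = nx.density(sub)
        if density >= density_min:
            members = [n for n in comp if sub.degree(n) >= membership_min_edges]
            if len(members) >= 2:
                genus_counter += 1
                genus_id = f"g{genus_counter:03d}"
                for node in comp:
                    if node in members:
                        assignments.append(GenusAssignment(node, genus_id, "clustered"))
                    else:
                        assignments.append(GenusAssignment(node, None, "outlier"))
            else:
                # a genus needs at least two well-connected members
                for node in comp:
                    assignments.append(GenusAssignment(node, None, "outlier"))
        else:
            for node in comp:
                assignments.append(GenusAssignment(node, None, "outlier"))
    assignments.sort(key=lambda a: a.population_id)
    return assignments
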