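"""Molecular networking by modified-cosine spectral similarity.

Spectra become nodes; a pair of spectra is linked when their modified cosine
exceeds the threshold with at least the minimum number of matched peaks.
The modified cosine matches peak pairs either directly or after shifting one
spectrum by the precursor mass difference, so shared neutral losses count as
matches — the property that lets, e.g., two phosphatidylcholines differing
by one CH2 connect through their common head-group and chain ions.

Peak intensities are square-root transformed and L2-normalized before
scoring.  The one-to-one peak assignment is solved exactly (maximum-weight
bipartite matching over the candidate pairs) rather than greedily, so the
score is the true optimum over assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from lipidnet.msio import Spectrum

__all__ = ["NetworkParams", "MolecularNetwork", "modified_cosine",
           "build_network", "write_graphml", "read_graphml"]


@dataclass(frozen=True)
class NetworkParams:
    """Topology parameters of the molecular network.

    Defaults follow common feature-based molecular networking practice:
    cosine > 0.60, >= 6 matched peaks, 0.02 Da fragment and parent
    tolerances, mutual top-100 neighbor sparsification, and removal of
    components smaller than 2 nodes.
    """

    cos_threshold: float = 0.60
    min_matched_peaks: int = 6
    fragment_tol: float = 0.02
    precursor_tol: float = 0.02
    top_k: int = 100
    min_cluster_size: int = 2
    use_shift: bool = True  # neutral-loss (precursor-shifted) match channel

    def __post_init__(self) -> None:
        if not (0 < self.cos_threshold <= 1):
            raise ValueError("cos_threshold must be in (0, 1]")
        for name in ("min_matched_peaks", "fragment_tol", "precursor_tol",
                     "top_k", "min_cluster_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _weight_vector(spectrum: Spectrum) -> np.ndarray:
    w = np.sqrt(spectrum.intensity)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02,
                    use_shift: bool = True) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Peaks are weighted by sqrt(intensity) and L2-normalized per spectrum.
    Candidate peak pairs match directly (|dmz| <= fragment_tol) or after
    shifting spectrum b by the precursor mass difference; a one-to-one
    assignment maximizing the summed weight products is chosen.  Returns
    ``(cosine, n_matched)``; symmetric in its arguments and bounded [0, 1].
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified cosine is undefined for empty spectra")
    wa, wb = _weight_vector(a), _weight_vector(b)
    dmz = a.mz[:, None] - b.mz[None, :]
    candidate = np.abs(dmz) <= fragment_tol
    if use_shift:
        shift = a.precursor_mz - b.precursor_mz
        if abs(shift) > fragment_tol:
            candidate |= np.abs(dmz - shift) <= fragment_tol
    if not candidate.any():
        return 0.0, 0
    products = np.where(candidate, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(products, maximize=True)
    chosen = products[rows, cols]
    used = chosen > 0
    score = float(np.sum(chosen[used]))
    return min(score, 1.0), int(np.count_nonzero(used))


@dataclass
class MolecularNetwork:
    """A spectral similarity network with node metadata.

    Node attributes: precursor_mz, rt, annotation, node_class (``standard``,
    ``standard_and_sample`` or ``sample``).  Edge attributes: cosine,
    n_matched.
    """

    graph: nx.Graph
    params: NetworkParams

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_table(self):
        import pandas as pd
        rows = [
            {"source": u, "target": v, **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "cosine",
                                           "n_matched"])


def build_network(spectra: Sequence[Spectrum],
                  params: NetworkParams | None = None,
                  node_attrs: dict[str, dict] | None = None,
                  ) -> MolecularNetwork:
    """Build a molecular network from spectra.

    All usable spectrum pairs are scored; edges must pass the cosine
    threshold (strictly greater) and minimum matched peaks, then survive the
    mutual top-K rank filter (each endpoint must rank the other within its K
    best neighbors by cosine; ties broken by higher cosine then lower node
    id).  Components smaller than ``min_cluster_size`` are dropped.
    """
    params = params or NetworkParams()
    usable = [s for s in spectra if s.is_usable]
    if len(usable) < 2:
        raise ValueError("networking needs at least two non-empty spectra")
    ids = [s.id for s in usable]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")

    # all-pairs scoring
    edges: list[tuple[str, str, float, int]] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            cos, n = modified_cosine(usable[i], usable[j],
                                     fragment_tol=params.fragment_tol,
                                     use_shift=params.use_shift)
            if cos > params.cos_threshold and n >= params.min_matched_peaks:
                edges.append((ids[i], ids[j], cos, n))

    # mutual top-K sparsification
    neighbor_rank: dict[str, dict[str, int]] = {nid: {} for nid in ids}
    by_node: dict[str, list[tuple[float, str]]] = {nid: [] for nid in ids}
    for u, v, cos, _ in edges:
        by_node[u].append((cos, v))
        by_node[v].append((cos, u))
    for nid, neigh in by_node.items():
        neigh.sort(key=lambda t: (-t[0], t[1]))
        for rank, (_, other) in enumerate(neigh, start=1):
            neighbor_rank[nid][other] = rank

    graph = nx.Graph()
    for s in usable:
        graph.add_node(s.id, precursor_mz=float(s.precursor_mz),
                       rt=float(s.rt) if s.rt is not None else None)
    for u, v, cos, n in edges:
        if (neighbor_rank[u][v] <= params.top_k
                and neighbor_rank[v][u] <= params.top_k):
            graph.add_edge(u, v, cosine=cos, n_matched=n)

    if node_attrs:
        for nid, attrs in node_attrs.items():
            if nid in graph:
                graph.nodes[nid].update(attrs)

    # drop undersized components (singletons included)
    for component in list(nx.connected_components(graph)):
        if len(component) < params.min_cluster_size:
            graph.remove_nodes_from(component)
    return MolecularNetwork(graph=graph, params=params)


def write_graphml(network: MolecularNetwork, path: str | Path) -> None:
    """Write the network as GraphML (None attributes are dropped: GraphML
    has no null type)."""
    graph = network.graph.copy()
    for _, data in graph.nodes(data=True):
        for key in [k for k, v in data.items() if v is None]:
            del data[key]
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path,
                 params: NetworkParams | None = None) -> MolecularNetwork:
    return MolecularNetwork(graph=nx.read_graphml(str(path)),
                            params=params or NetworkParams())
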