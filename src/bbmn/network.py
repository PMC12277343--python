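"""Molecular networking: modified-cosine similarity and graph assembly.

Nodes are MS2 spectra; edges connect spectra whose modified-cosine
similarity clears a threshold.  The modified cosine aligns peak pairs
either directly or offset by the precursor mass difference, which keeps
structurally related compounds connected across single modifications
(hydroxylation, hydration, dimerization).  Standard molecular-networking
topology filters apply: minimum matched peaks, per-node top-k edge
retention, and a maximum component size enforced by pruning the weakest
edges.  Nodes carrying a diagnostic building-block ion are flagged so the
family of interest stands out in the exported graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .filtering import FilterHit
from .spectra import MsmsSpectrum

__all__ = [
    "SimilarityEdge",
    "MolecularNetwork",
    "ConsensusIon",
    "modified_cosine",
    "build_network",
    "flag_building_blocks",
    "consensus_diagnostic",
    "export_graphml",
    "export_tables",
]

#: Peaks closer than this to the precursor m/z are dropped before scoring
#: (residual precursor and near-precursor ions carry no structural
#: information and inflate self-similarity).
PRECURSOR_WINDOW = 17.0


class SimilarityEdge(NamedTuple):
    id_a: str
    id_b: str
    score: float
    matched_peaks: int
    precursor_delta: float


def _prepared_peaks(
    spec: MsmsSpectrum, precursor_window: Optional[float]
) -> list[tuple[float, float]]:
    """Square-root-scaled, unit-norm peak weights after precursor cleanup."""
    peaks = [
        p
        for p in spec.peaks
        if precursor_window is None or p.mz <= spec.precursor_mz - precursor_window
    ]
    weights = [(p.mz, p.intensity ** 0.5) for p in peaks if p.intensity > 0]
    norm = sum(w * w for _, w in weights) ** 0.5
    if norm == 0:
        return []
    return [(mz, w / norm) for mz, w in weights]


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol: float = 0.02,
    precursor_window: Optional[float] = PRECURSOR_WINDOW,
) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Intensities are square-root scaled and each spectrum normalized to
    unit Euclidean norm.  Peak pairs are candidates when their m/z values
    agree within ``frag_tol`` either directly or after shifting one
    spectrum by the precursor mass difference.  A one-to-one assignment is
    built greedily by descending weight product (ties: smaller m/z
    difference); the score is the sum of assigned products, in [0, 1].

    Returns ``(score, matched_peaks)``.  A spectrum left without usable
    peaks (all zero intensity, or everything inside the precursor window)
    scores 0 with 0 matches.
    """
    if frag_tol <= 0:
        raise ValueError(f"frag_tol must be positive, got {frag_tol}")
    wa = _prepared_peaks(a, precursor_window)
    wb = _prepared_peaks(b, precursor_window)
    if not wa or not wb:
        return 0.0, 0
    shift = b.precursor_mz - a.precursor_mz
    # candidate pairs: (i, j) with direct or precursor-shifted m/z match;
    # when both apply keep the smaller deviation
    candidates: dict[tuple[int, int], float] = {}
    for i, (mza, _) in enumerate(wa):
        for j, (mzb, _) in enumerate(wb):
            direct = abs(mza - mzb)
            shifted = abs(mza + shift - mzb)
            dev = min(direct, shifted)
            if dev <= frag_tol:
                candidates[(i, j)] = dev
    # greedy one-to-one assignment, symmetric under argument swap
    order = sorted(
        candidates.items(),
        key=lambda kv: (
            -(wa[kv[0][0]][1] * wb[kv[0][1]][1]),
            kv[1],
            min(wa[kv[0][0]][0], wb[kv[0][1]][0]),
            max(wa[kv[0][0]][0], wb[kv[0][1]][0]),
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for (i, j), _dev in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += wa[i][1] * wb[j][1]
        matched += 1
    return min(score, 1.0), matched


@dataclass
class MolecularNetwork:
    """A spectral similarity network.

    Thin wrapper around an undirected :class:`networkx.Graph` whose node
    attributes are ``precursor_mz``, ``retention_time``,
    ``building_block`` and ``component``, and whose edge attributes are
    ``score``, ``matched_peaks`` and ``precursor_delta``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[SimilarityEdge]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append(
                SimilarityEdge(a, b, data["score"], data["matched_peaks"], data["precursor_delta"])
            )
        return sorted(out)

    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=min)

    def relabel_components(self) -> None:
        """Assign deterministic component ids, ordered by each
        component's smallest member id."""
        for cid, comp in enumerate(self.components()):
            for node in comp:
                self.graph.nodes[node]["component"] = cid


def _edge_removal_key(graph: nx.Graph, edge: tuple[str, str]):
    data = graph.edges[edge]
    a, b = sorted(edge)
    return (data["score"], -data["precursor_delta"], a, b)


def build_network(
    spectra: Sequence[MsmsSpectrum],
    frag_tol: float = 0.02,
    score_threshold: float = 0.7,
    min_matched: int = 4,
    top_k: int = 10,
    max_component: int = 100,
    precursor_window: Optional[float] = PRECURSOR_WINDOW,
) -> MolecularNetwork:
    """Score all spectrum pairs and assemble the thresholded network.

    Edges require score >= ``score_threshold`` and at least
    ``min_matched`` matched peaks.  An edge then survives top-k filtering
    only if it ranks among the ``top_k`` best edges of both endpoints.
    Finally, any connected component larger than ``max_component`` is
    split by repeatedly deleting its weakest edge (lowest score; ties:
    larger precursor delta, then lexicographic ids).
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    if not (0 < score_threshold <= 1):
        raise ValueError(f"score_threshold must be in (0, 1], got {score_threshold}")
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique")

    g = nx.Graph()
    for s in sorted(spectra, key=lambda s: s.id):
        g.add_node(
            s.id,
            precursor_mz=s.precursor_mz,
            retention_time=s.retention_time if s.retention_time is not None else float("nan"),
            building_block=False,
            component=0,
        )
    by_id = {s.id: s for s in spectra}
    ordered = sorted(ids)
    for i, ida in enumerate(ordered):
        for idb in ordered[i + 1 :]:
            score, matched = modified_cosine(
                by_id[ida], by_id[idb], frag_tol, precursor_window
            )
            if score >= score_threshold and matched >= min_matched:
                g.add_edge(
                    ida,
                    idb,
                    score=score,
                    matched_peaks=matched,
                    precursor_delta=abs(by_id[ida].precursor_mz - by_id[idb].precursor_mz),
                )

    # top-k: an edge survives only if within the k best edges of BOTH ends
    keep = set()
    rank_key = lambda e, n: (
        -g.edges[e]["score"],
        g.edges[e]["precursor_delta"],
        tuple(sorted(e)),
    )
    top: dict[str, set] = {}
    for node in g.nodes:
        incident = sorted(g.edges(node), key=lambda e: rank_key(e, node))
        top[node] = {tuple(sorted(e)) for e in incident[:top_k]}
    for u, v in list(g.edges):
        e = tuple(sorted((u, v)))
        if e in top[u] and e in top[v]:
            keep.add(e)
    g.remove_edges_from([e for e in list(g.edges) if tuple(sorted(e)) not in keep])

    # component-size bound: prune weakest edges until every component fits
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = min(oversized, key=min)
        worst = min(g.subgraph(comp).edges, key=lambda e: _edge_removal_key(g, e))
        g.remove_edge(*worst)

    net = MolecularNetwork(g)
    net.relabel_components()
    return net


def flag_building_blocks(
    network: MolecularNetwork, hits: Iterable[FilterHit]
) -> MolecularNetwork:
    """Mark nodes appearing in the diagnostic-ion hits; clear all others.

    Idempotent.  Hit ids not present in the network raise ``KeyError``
    listing the offenders.
    """
    hit_ids = {h.spectrum_id for h in hits}
    unknown = sorted(hit_ids - set(network.graph.nodes))
    if unknown:
        raise KeyError(f"hit spectrum ids not in network: {', '.join(unknown)}")
    for node in network.graph.nodes:
        network.graph.nodes[node]["building_block"] = node in hit_ids
    return network


class ConsensusIon(NamedTuple):
    mz: float
    support: int
    total_intensity: float


def consensus_diagnostic(
    spectra: Sequence[MsmsSpectrum], mz_tol: float = 0.02
) -> list[ConsensusIon]:
    """Candidate diagnostic ions shared across a spectrum family.

    Product ions from all spectra are clustered by single linkage (peaks
    within ``mz_tol`` of a neighbour join the same cluster); each cluster
    reports its intensity-weighted mean m/z (4 decimals), the number of
    distinct supporting spectra, and total intensity.  Ranked by support
    descending, then total intensity descending — the top entry is the
    best candidate for a conserved building-block ion.
    """
    if len(spectra) < 2:
        raise ValueError("consensus needs at least two spectra")
    points = sorted(
        (p.mz, p.intensity, s.id) for s in spectra for p in s.peaks
    )
    clusters: list[list[tuple[float, float, str]]] = []
    for pt in points:
        if clusters and pt[0] - clusters[-1][-1][0] <= mz_tol:
            clusters[-1].append(pt)
        else:
            clusters.append([pt])
    out = []
    for cl in clusters:
        total = sum(i for _, i, _ in cl)
        mean = sum(mz * i for mz, i, _ in cl) / total if total > 0 else cl[0][0]
        out.append(ConsensusIon(round(mean, 4), len({sid for _, _, sid in cl}), total))
    return sorted(out, key=lambda c: (-c.support, -c.total_intensity, c.mz))


def export_graphml(network: MolecularNetwork, sink: Union[str, Path, IO[bytes]]) -> None:
    """Write the network as GraphML (Cytoscape/yEd-importable).

    Node and edge insertion order is id-sorted, so output is
    deterministic for a fixed network.
    """
    g = nx.Graph()
    for node in network.node_ids:
        g.add_node(node, **network.graph.nodes[node])
    for e in network.edges:
        g.add_edge(
            e.id_a,
            e.id_b,
            score=e.score,
            matched_peaks=e.matched_peaks,
            precursor_delta=e.precursor_delta,
        )
    nx.write_graphml(g, sink)


def export_tables(network: MolecularNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables mirroring the GraphML content."""
    nodes = pd.DataFrame(
        [
            {
                "spectrum_id": n,
                "precursor_mz": network.graph.nodes[n]["precursor_mz"],
                "retention_time": network.graph.nodes[n]["retention_time"],
                "building_block": network.graph.nodes[n]["building_block"],
                "component": network.graph.nodes[n]["component"],
            }
            for n in network.node_ids
        ],
        columns=["spectrum_id", "precursor_mz", "retention_time", "building_block", "component"],
    )
    edges = pd.DataFrame(
        [e._asdict() for e in network.edges],
        columns=["id_a", "id_b", "score", "matched_peaks", "precursor_delta"],
    )
    return nodes, edges
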