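"""Molecular-network construction and spectral-library dereplication.

Consensus parent-ion nodes are connected by modified-cosine edges: every
unordered node pair is scored, pairs passing the cosine and matched-peak
thresholds become candidate edges, and a candidate survives only if each
endpoint ranks in the other's top-K most similar neighbours (the mutual
top-K rule that keeps molecular families from collapsing into hairballs).
Nodes are also matched against an annotated spectral library — filtered
with the same peak filters as the input data — to dereplicate known
compounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .clustering import ConsensusNode
from .similarity import SimilarityParams, cosine
from .spectra_io import SampleRecord, Spectrum

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "LibraryHit",
    "MolecularNetwork",
    "score_all_pairs",
    "mutual_topk_filter",
    "library_search",
    "build_network",
    "export_network",
    "node_group_label",
]


@dataclass(frozen=True)
class NetworkParams:
    """Edge and library-match thresholds.

    min_cosine / min_matched_peaks : both must hold for a candidate edge
        (defaults 0.7 and 6, inclusive comparisons).
    top_k : mutual-rank cutoff; an edge survives only if each endpoint is
        within the other's top_k candidate neighbours by cosine (default 10).
    library_min_cosine / library_min_matched_peaks : thresholds for
        library hits (defaults 0.7 and 6).
    """

    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: int = 10
    library_min_cosine: float = 0.7
    library_min_matched_peaks: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.min_cosine <= 1 or not 0 <= self.library_min_cosine <= 1:
            raise ValueError("cosine thresholds must be in [0, 1]")
        if self.min_matched_peaks < 0 or self.library_min_matched_peaks < 0:
            raise ValueError("matched-peak floors must be non-negative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class NetworkEdge:
    """An undirected scored edge; node_a < node_b by construction."""

    node_a: int
    node_b: int
    cosine: float
    matched_peaks: int
    mass_diff: float


@dataclass(frozen=True)
class LibraryHit:
    node_id: int
    compound_name: str
    library_precursor_mz: float
    score: float
    matched_peaks: int
    is_best: bool = False


@dataclass
class MolecularNetwork:
    nodes: list[ConsensusNode]
    edges: list[NetworkEdge]
    library_hits: dict[int, list[LibraryHit]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def score_all_pairs(
    nodes: Sequence[ConsensusNode],
    np_: NetworkParams | None = None,
    sp: SimilarityParams | None = None,
) -> list[NetworkEdge]:
    """Score every unordered node pair; return candidates passing both thresholds."""
    np_ = np_ or NetworkParams()
    sp = sp or SimilarityParams(use_shift=True)
    spectra = [n.consensus_spectrum() for n in nodes]
    candidates: list[NetworkEdge] = []
    for i in range(len(nodes)):
        if spectra[i].is_empty:
            continue
        for j in range(i + 1, len(nodes)):
            if spectra[j].is_empty:
                continue
            res = cosine(spectra[i], spectra[j], sp)
            if res.score >= np_.min_cosine and res.matched_peaks >= np_.min_matched_peaks:
                a, b = nodes[i].node_id, nodes[j].node_id
                if a > b:
                    a, b = b, a
                candidates.append(
                    NetworkEdge(
                        node_a=a,
                        node_b=b,
                        cosine=res.score,
                        matched_peaks=res.matched_peaks,
                        mass_diff=abs(
                            nodes[i].precursor_mz - nodes[j].precursor_mz
                        ),
                    )
                )
    return candidates


def mutual_topk_filter(
    candidates: Sequence[NetworkEdge], np_: NetworkParams | None = None
) -> list[NetworkEdge]:
    """Keep edge (u, v) iff v is in u's top-K candidate neighbours AND vice versa.

    A neighbour v is within u's top-K iff fewer than K of u's candidate
    neighbours score strictly higher than cosine(u, v); ties at the K-th
    position are therefore all included.
    """
    np_ = np_ or NetworkParams()
    neigh: dict[int, list[float]] = {}
    for e in candidates:
        neigh.setdefault(e.node_a, []).append(e.cosine)
        neigh.setdefault(e.node_b, []).append(e.cosine)

    def in_topk(u: int, score: float) -> bool:
        higher = sum(1 for s in neigh[u] if s > score)
        return higher < np_.top_k

    return [
        e
        for e in candidates
        if in_topk(e.node_a, e.cosine) and in_topk(e.node_b, e.cosine)
    ]


def library_search(
    nodes: Sequence[ConsensusNode],
    library: Sequence[Spectrum],
    np_: NetworkParams | None = None,
    sp: SimilarityParams | None = None,
) -> dict[int, list[LibraryHit]]:
    """Match each node against an annotated spectral library.

    Library spectra must already be preprocessed with the same peak filters
    as the input data; their ``spectrum_id`` serves as the compound name.
    The shift-aware cosine is used so analogs of library compounds can
    still match. All passing hits are returned per node, sorted best
    first, with the best hit flagged.
    """
    np_ = np_ or NetworkParams()
    sp = sp or SimilarityParams(use_shift=True)
    hits: dict[int, list[LibraryHit]] = {}
    for node in nodes:
        ns = node.consensus_spectrum()
        if ns.is_empty:
            continue
        node_hits: list[LibraryHit] = []
        for entry in library:
            if entry.is_empty:
                continue
            res = cosine(ns, entry, sp)
            if (
                res.score >= np_.library_min_cosine
                and res.matched_peaks >= np_.library_min_matched_peaks
            ):
                node_hits.append(
                    LibraryHit(
                        node_id=node.node_id,
                        compound_name=entry.spectrum_id,
                        library_precursor_mz=entry.precursor_mz,
                        score=res.score,
                        matched_peaks=res.matched_peaks,
                    )
                )
        if node_hits:
            node_hits.sort(key=lambda h: (-h.score, -h.matched_peaks, h.compound_name))
            node_hits[0] = LibraryHit(
                node_id=node_hits[0].node_id,
                compound_name=node_hits[0].compound_name,
                library_precursor_mz=node_hits[0].library_precursor_mz,
                score=node_hits[0].score,
                matched_peaks=node_hits[0].matched_peaks,
                is_best=True,
            )
            hits[node.node_id] = node_hits
    return hits


def build_network(
    nodes: Sequence[ConsensusNode],
    np_: NetworkParams | None = None,
    sp: SimilarityParams | None = None,
    library: Sequence[Spectrum] | None = None,
) -> MolecularNetwork:
    """Score pairs, apply the mutual top-K rule, and optionally search a library."""
    np_ = np_ or NetworkParams()
    sp = sp or SimilarityParams(use_shift=True)
    candidates = score_all_pairs(nodes, np_, sp)
    edges = mutual_topk_filter(candidates, np_)
    hits = library_search(nodes, library, np_, sp) if library else {}
    return MolecularNetwork(nodes=list(nodes), edges=edges, library_hits=hits)


# ---------------------------------------------------------------------------
# Export


def node_group_label(
    node: ConsensusNode,
    meta: Mapping[str, SampleRecord],
    media_nodes: Iterable[int] = (),
) -> str:
    """Fig-2-style node label: a single group name, "both", or "media"."""
    if node.node_id in set(media_nodes):
        return "media"
    groups = {
        meta[sid].group
        for sid in node.sample_presence
        if sid in meta and not meta[sid].is_blank and meta[sid].group
    }
    if not groups:
        return "none"
    if len(groups) == 1:
        return next(iter(groups))
    return "both"


def export_network(
    net: MolecularNetwork,
    meta: Sequence[SampleRecord],
    outdir: str | Path,
    media_nodes: Iterable[int] | None = None,
) -> dict[str, Path]:
    """Write nodes.tsv, edges.tsv and a Cytoscape-importable network.graphml.

    The node table carries everything the attribution statistics need:
    precursor m/z, member and strain counts, per-sample presence, the
    group label (one group / "both" / "media") and the best library hit.
    """
    from .cohort_stats import flag_media_nodes  # local import: avoids cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_map = {r.sample_id: r for r in meta}
    if media_nodes is None:
        media_nodes = flag_media_nodes(net, meta)
    media_set = set(media_nodes)

    nodes_path = outdir / "nodes.tsv"
    with open(nodes_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "node_id",
                "precursor_mz",
                "n_members",
                "n_strains",
                "group_label",
                "samples",
                "library_hit",
                "library_score",
            ]
        )
        for node in net.nodes:
            best = next(
                (h for h in net.library_hits.get(node.node_id, []) if h.is_best), None
            )
            samples = ";".join(
                f"{sid}:{cnt}" for sid, cnt in sorted(node.sample_presence.items())
            )
            w.writerow(
                [
                    node.node_id,
                    f"{node.precursor_mz:.4f}",
                    node.n_members,
                    node.n_strains,
                    node_group_label(node, meta_map, media_set),
                    samples,
                    best.compound_name if best else "",
                    f"{best.score:.4f}" if best else "",
                ]
            )

    edges_path = outdir / "edges.tsv"
    with open(edges_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node_a", "node_b", "cosine", "matched_peaks", "mass_diff"])
        for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b)):
            w.writerow(
                [e.node_a, e.node_b, f"{e.cosine:.4f}", e.matched_peaks, f"{e.mass_diff:.4f}"]
            )

    graph = nx.Graph()
    for node in net.nodes:
        best = next(
            (h for h in net.library_hits.get(node.node_id, []) if h.is_best), None
        )
        graph.add_node(
            node.node_id,
            precursor_mz=float(node.precursor_mz),
            n_members=node.n_members,
            n_strains=node.n_strains,
            group_label=node_group_label(node, meta_map, media_set),
            library_hit=best.compound_name if best else "",
        )
    for e in net.edges:
        graph.add_edge(
            e.node_a,
            e.node_b,
            cosine=float(e.cosine),
            matched_peaks=e.matched_peaks,
            mass_diff=float(e.mass_diff),
        )
    graphml_path = outdir / "network.graphml"
    nx.write_graphml(graph, graphml_path)
    return {"nodes": nodes_path, "edges": edges_path, "graphml": graphml_path}
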