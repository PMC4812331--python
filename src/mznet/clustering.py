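"""Consensus clustering of replicate MS/MS scans into parent-ion nodes.

Repeated scans of the same parent ion — across technical replicates and
across samples — are near-identical spectra with near-identical precursor
masses. A greedy single-pass, precursor-sorted clusterer groups them: a
spectrum joins the first existing cluster whose consensus precursor lies
within the parent-mass tolerance AND whose consensus spectrum it matches
at or above the cosine threshold (plain cosine: replicates need no
precursor shift); otherwise it seeds a new cluster. Each cluster's
consensus spectrum — pooled peaks grouped at the fragment tolerance,
intensity-weighted mean m/z, summed intensity, re-window-filtered — is
one node of the molecular network.

This deterministic single pass replaces the multi-round heuristic of
large-scale cluster engines; it is oracle-testable and sufficient at the
cohort sizes this package targets.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .preprocess import FilterParams, window_filter
from .similarity import SimilarityParams, cosine
from .spectra_io import Peak, Spectrum

__all__ = ["ClusterParams", "ConsensusNode", "cluster_spectra", "build_consensus"]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering settings.

    parent_tol_da : precursor-mass tolerance for joining a cluster
        (default 2.0 Da).
    min_cluster_similarity : plain-cosine threshold against the cluster's
        consensus spectrum (default 0.7).
    min_cluster_size : clusters with fewer members are discarded after the
        pass (default 1, i.e. nothing is discarded).
    """

    parent_tol_da: float = 2.0
    min_cluster_similarity: float = 0.7
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.parent_tol_da <= 0:
            raise ValueError("parent_tol_da must be positive")
        if not 0 <= self.min_cluster_similarity <= 1:
            raise ValueError("min_cluster_similarity must be in [0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ConsensusNode:
    """A clustered parent ion: one node of the molecular network.

    precursor_mz is the intensity-weighted mean of member precursors
    (weighted by each member's total ion intensity). sample_presence maps
    sample_id to the number of member spectra from that sample;
    strain_presence is derived from sample metadata at attribution time
    and n_strains counts the distinct producing strains.
    """

    node_id: int
    precursor_mz: float
    peaks: tuple[Peak, ...]
    member_spectrum_ids: list[str] = field(default_factory=list)
    sample_presence: dict[str, int] = field(default_factory=dict)
    strain_presence: set[str] = field(default_factory=set)

    @property
    def n_members(self) -> int:
        return len(self.member_spectrum_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strain_presence)

    def consensus_spectrum(self) -> Spectrum:
        """The node's consensus peaks as a Spectrum (for similarity scoring)."""
        return Spectrum(
            spectrum_id=f"node:{self.node_id}",
            sample_id="",
            precursor_mz=self.precursor_mz,
            peaks=self.peaks,
        )


def build_consensus(
    members: list[Spectrum],
    sp: SimilarityParams | None = None,
    fp: FilterParams | None = None,
) -> tuple[Peak, ...]:
    """Merge member peak lists into one consensus peak list.

    Peaks pooled across members are grouped single-linkage at the fragment
    tolerance (adjacent pooled peaks closer than the tolerance belong to
    the same group); each group becomes one consensus peak with
    intensity-weighted mean m/z and summed intensity. The result is
    re-window-filtered so consensus spectra obey the same density cap as
    input spectra.
    """
    if not members:
        raise ValueError("build_consensus requires at least one member")
    sp = sp or SimilarityParams()
    fp = fp or FilterParams()
    if len(members) == 1:
        return members[0].peaks
    pooled = sorted(
        (pk for m in members for pk in m.peaks), key=lambda pk: pk.mz
    )
    groups: list[list[Peak]] = []
    for pk in pooled:
        if groups and pk.mz - groups[-1][-1].mz <= sp.fragment_tol_da:
            groups[-1].append(pk)
        else:
            groups.append([pk])
    consensus = []
    for grp in groups:
        total = sum(p.intensity for p in grp)
        if total > 0:
            mz = sum(p.mz * p.intensity for p in grp) / total
        else:
            mz = sum(p.mz for p in grp) / len(grp)
        consensus.append(Peak(mz, total))
    ref = members[0]
    filtered = window_filter(ref.with_peaks(consensus), fp)
    return filtered.peaks


def _consensus_precursor(members: list[Spectrum]) -> float:
    weights = [m.total_intensity() for m in members]
    total = sum(weights)
    if total == 0:
        return sum(m.precursor_mz for m in members) / len(members)
    return sum(m.precursor_mz * w for m, w in zip(members, weights)) / total


class _Cluster:
    __slots__ = ("members", "precursor", "peaks")

    def __init__(self, seed: Spectrum):
        self.members: list[Spectrum] = [seed]
        self.precursor = seed.precursor_mz
        self.peaks = seed.peaks

    def add(self, s: Spectrum, sp: SimilarityParams, fp: FilterParams) -> None:
        self.members.append(s)
        self.precursor = _consensus_precursor(self.members)
        self.peaks = build_consensus(self.members, sp, fp)

    def spectrum(self) -> Spectrum:
        return Spectrum(
            spectrum_id="consensus",
            sample_id="",
            precursor_mz=self.precursor,
            peaks=self.peaks,
        )


def cluster_spectra(
    spectra: list[Spectrum],
    cp: ClusterParams | None = None,
    sp: SimilarityParams | None = None,
    fp: FilterParams | None = None,
    sample_to_strain: dict[str, str] | None = None,
) -> list[ConsensusNode]:
    """Cluster spectra into consensus parent-ion nodes.

    Spectra are processed in ascending precursor order (ties broken by
    spectrum_id, fixing determinism); each spectrum joins the
    lowest-numbered qualifying cluster or seeds a new one. Every input
    spectrum belongs to exactly one cluster; clusters smaller than
    ``min_cluster_size`` are discarded at the end.

    ``sample_to_strain`` (sample_id -> strain_id) populates each node's
    strain_presence; samples absent from the map contribute no strain.
    """
    cp = cp or ClusterParams()
    sp = sp or SimilarityParams()
    cluster_sp = SimilarityParams(
        fragment_tol_da=sp.fragment_tol_da, use_shift=False, weighting=sp.weighting
    )
    fp = fp or FilterParams()
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.spectrum_id))

    clusters: list[_Cluster] = []
    # precursor-sorted index over clusters for the tolerance window scan
    sorted_prec: list[float] = []
    sorted_idx: list[int] = []

    def _reindex() -> None:
        order = sorted(range(len(clusters)), key=lambda k: clusters[k].precursor)
        sorted_prec[:] = [clusters[k].precursor for k in order]
        sorted_idx[:] = order

    stale = 0
    for s in ordered:
        lo = bisect_left(sorted_prec, s.precursor_mz - cp.parent_tol_da)
        hi = bisect_right(sorted_prec, s.precursor_mz + cp.parent_tol_da)
        best: int | None = None
        for k in sorted_idx[lo:hi]:
            cl = clusters[k]
            if abs(cl.precursor - s.precursor_mz) > cp.parent_tol_da:
                continue
            if s.is_empty or not cl.peaks:
                continue
            if cosine(s, cl.spectrum(), cluster_sp).score >= cp.min_cluster_similarity:
                if best is None or k < best:
                    best = k
        if best is None and s.is_empty:
            # empty spectra cannot match anything; each seeds its own cluster
            pass
        if best is not None:
            clusters[best].add(s, cluster_sp, fp)
            stale += 1
        else:
            clusters.append(_Cluster(s))
            stale += 1
        # consensus precursors drift as members join; refresh the index
        if stale >= 1:
            _reindex()
            stale = 0

    nodes: list[ConsensusNode] = []
    node_id = 0
    for cl in clusters:
        if len(cl.members) < cp.min_cluster_size:
            continue
        presence: dict[str, int] = {}
        strains: set[str] = set()
        for m in cl.members:
            presence[m.sample_id] = presence.get(m.sample_id, 0) + 1
            if sample_to_strain and m.sample_id in sample_to_strain:
                strains.add(sample_to_strain[m.sample_id])
        nodes.append(
            ConsensusNode(
                node_id=node_id,
                precursor_mz=cl.precursor,
                peaks=cl.peaks,
                member_spectrum_ids=[m.spectrum_id for m in cl.members],
                sample_presence=presence,
                strain_presence=strains,
            )
        )
        node_id += 1
    return nodes
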