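"""Attribution statistics over a molecular network.

Given a network of consensus parent ions and the sample metadata, this
module answers the comparative questions: which ions come from the growth
medium rather than the bacteria; how many ions are exclusive to each
isolation location versus shared; how strain-specific production is; how
parent-ion mass is distributed; how productive each genus is per strain;
how spectral diversity accumulates with sampling effort (rarefaction);
and what neutral losses explain observed fragment mass differences.

Conventions
-----------
* Media flagging is conservative: one member spectrum from a blank sample
  is enough to call a node a media component. Media nodes are excluded
  from group/strain/genus attribution but stay in every denominator.
* Percentages and per-strain averages are rounded half-up to one decimal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import ConsensusNode
from .network import MolecularNetwork
from .spectra_io import SampleRecord

__all__ = [
    "AttributionSummary",
    "StrainSpecificity",
    "MassBinSummary",
    "GenusSummary",
    "RarefactionCurve",
    "round_half_up",
    "percent",
    "flag_media_nodes",
    "attribute_groups",
    "strain_specificity",
    "mass_bins",
    "genus_stats",
    "rarefaction",
    "neutral_loss_annotate",
    "DEFAULT_MASS_BINS",
    "NEUTRAL_LOSSES",
]

DEFAULT_MASS_BINS: tuple[tuple[float, float], ...] = (
    (149.0, 300.0),
    (301.0, 500.0),
    (501.0, 1000.0),
    (1001.0, 2558.0),
)

#: Monoisotopic masses (Da) of common neutral losses; extensible by callers.
NEUTRAL_LOSSES: dict[str, float] = {
    "CO": 27.99491,
    "H2O": 18.01056,
    "CO2": 43.98983,
    "NH3": 17.02655,
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 64.25 -> 64.3 at 1 digit."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """count / total as a percentage, rounded half-up."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Attribution summaries


@dataclass(frozen=True)
class AttributionSummary:
    """Location attribution of the network's parent ions.

    Counts partition the nodes: media + sum(exclusive per group) + shared
    == total_nodes (nodes with no attributable group — e.g. produced only
    by samples missing from the metadata — are reported separately under
    ``unattributed`` and kept in the total). Fractions are percentages of
    total_nodes, media included in the denominator.
    """

    total_nodes: int
    media_nodes: int
    per_group_exclusive: dict[str, int]
    shared_all_groups: int
    unattributed: int = 0
    fractions: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        per_group_exclusive: Mapping[str, int],
        shared: int,
        media: int,
        total: int | None = None,
        unattributed: int = 0,
    ) -> "AttributionSummary":
        """Build a summary (and its percentage fractions) from raw counts."""
        exclusive = dict(per_group_exclusive)
        if total is None:
            total = media + sum(exclusive.values()) + shared + unattributed
        fractions = {g: percent(c, total) for g, c in exclusive.items()}
        fractions["shared"] = percent(shared, total)
        fractions["media"] = percent(media, total)
        fractions["exclusive_union"] = percent(sum(exclusive.values()), total)
        return cls(
            total_nodes=total,
            media_nodes=media,
            per_group_exclusive=exclusive,
            shared_all_groups=shared,
            unattributed=unattributed,
            fractions=fractions,
        )


@dataclass(frozen=True)
class StrainSpecificity:
    """Histogram of how many strains produce each non-media parent ion."""

    histogram: dict[int, int]
    fraction_single_strain: float


@dataclass(frozen=True)
class MassBinSummary:
    """Parent-ion counts per m/z bin: (low, high, count, percent)."""

    bins: tuple[tuple[float, float, int, float], ...]
    overflow: int = 0


@dataclass(frozen=True)
class GenusRow:
    genus: str
    strain_count: int
    node_count: int
    avg_per_strain: float


@dataclass(frozen=True)
class GenusSummary:
    per_genus: dict[str, GenusRow]
    cross_genus_count: int


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean (± sd) distinct clusters observed in the first k samples."""

    points: tuple[tuple[int, float, float], ...]
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# Node-level helpers


def _meta_map(meta: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in meta}


def flag_media_nodes(
    net: MolecularNetwork,
    meta: Sequence[SampleRecord],
    min_blank_members: int = 1,
) -> set[int]:
    """Node ids whose membership includes >= ``min_blank_members`` blank spectra.

    Any blank membership (the default) marks a node as a medium component:
    anything detectable in the uninoculated medium control is discounted
    from strain attribution, however many strains also show it.
    """
    blanks = {r.sample_id for r in meta if r.is_blank}
    flagged: set[int] = set()
    for node in net.nodes:
        blank_members = sum(
            cnt for sid, cnt in node.sample_presence.items() if sid in blanks
        )
        if blank_members >= min_blank_members:
            flagged.add(node.node_id)
    return flagged


def _node_groups(
    node: ConsensusNode, meta: Mapping[str, SampleRecord]
) -> set[str]:
    groups: set[str] = set()
    for sid in node.sample_presence:
        rec = meta.get(sid)
        if rec is None or rec.is_blank:
            continue
        if not rec.group:
            raise ValueError(
                f"strain {rec.strain_id!r} (sample {sid!r}) has no group label"
            )
        groups.add(rec.group)
    return groups


def attribute_groups(
    net: MolecularNetwork,
    meta: Sequence[SampleRecord],
    media_nodes: set[int] | None = None,
) -> AttributionSummary:
    """Classify every non-media node as group-exclusive or shared.

    A node's groups are those of its producing (non-blank) samples:
    exactly one group -> exclusive to it; two or more -> shared. Fractions
    are percentages of ALL nodes, media included in the denominator.
    """
    mm = _meta_map(meta)
    if media_nodes is None:
        media_nodes = flag_media_nodes(net, meta)
    all_groups = sorted({r.group for r in meta if not r.is_blank and r.group})
    exclusive: dict[str, int] = {g: 0 for g in all_groups}
    shared = 0
    unattributed = 0
    for node in net.nodes:
        if node.node_id in media_nodes:
            continue
        groups = _node_groups(node, mm)
        if not groups:
            unattributed += 1
        elif len(groups) == 1:
            exclusive[next(iter(groups))] += 1
        else:
            shared += 1
    return AttributionSummary.from_counts(
        per_group_exclusive=exclusive,
        shared=shared,
        media=len(media_nodes),
        total=len(net.nodes),
        unattributed=unattributed,
    )


def strain_specificity(
    net: MolecularNetwork,
    meta: Sequence[SampleRecord],
    media_nodes: set[int] | None = None,
) -> StrainSpecificity:
    """Histogram of producing-strain counts over non-media nodes.

    The single-strain fraction is reported as a percentage of all nodes in
    the network (media included in the denominator).
    """
    if media_nodes is None:
        media_nodes = flag_media_nodes(net, meta)
    hist: Counter[int] = Counter()
    for node in net.nodes:
        if node.node_id in media_nodes:
            continue
        hist[node.n_strains] += 1
    total = len(net.nodes)
    return StrainSpecificity(
        histogram=dict(sorted(hist.items())),
        fraction_single_strain=percent(hist.get(1, 0), total),
    )


def mass_bins(
    net: MolecularNetwork,
    edges: Sequence[tuple[float, float]] = DEFAULT_MASS_BINS,
) -> MassBinSummary:
    """Bin nodes by consensus precursor m/z.

    Upper edges are inclusive and each next bin starts above the previous
    upper edge, so with the default partition 300.0 falls in 149–300 and
    300.5 in 301–500. Nodes outside every bin go to an overflow count with
    a warning. Percentages use all nodes as the denominator.
    """
    uppers = [hi for _, hi in edges]
    low0 = edges[0][0]
    counts = [0] * len(edges)
    overflow = 0
    for node in net.nodes:
        mz = node.precursor_mz
        if mz < low0 or mz > uppers[-1]:
            overflow += 1
            continue
        placed = False
        prev_hi = None
        for b, (lo, hi) in enumerate(edges):
            lower_ok = mz >= lo if prev_hi is None else mz > prev_hi
            if lower_ok and mz <= hi:
                counts[b] += 1
                placed = True
                break
            prev_hi = hi
        if not placed:
            overflow += 1
    if overflow:
        warnings.warn(
            f"{overflow} node(s) fell outside the mass-bin partition", stacklevel=2
        )
    total = len(net.nodes)
    return MassBinSummary(
        bins=tuple(
            (lo, hi, counts[b], percent(counts[b], total))
            for b, (lo, hi) in enumerate(edges)
        ),
        overflow=overflow,
    )


def per_strain_average(node_count: int, strain_count: int) -> float:
    """Average parent ions per strain, half-up to 1 decimal."""
    if strain_count == 0:
        return 0.0
    return round_half_up(node_count / strain_count, 1)


def genus_stats(
    net: MolecularNetwork,
    meta: Sequence[SampleRecord],
    media_nodes: set[int] | None = None,
    cross_genus_min: int = 3,
) -> GenusSummary:
    """Per-genus parent-ion counts and per-strain averages.

    A node is attributed to a genus iff at least one producing strain
    belongs to it (so one node can count toward several genera).
    ``cross_genus_min`` sets how many distinct genera make a node
    boundary-crossing (default 3, i.e. strains of more than two genera).
    """
    mm = _meta_map(meta)
    if media_nodes is None:
        media_nodes = flag_media_nodes(net, meta)
    strains_per_genus: dict[str, set[str]] = {}
    for r in meta:
        if not r.is_blank:
            strains_per_genus.setdefault(r.genus, set()).add(r.strain_id)
    node_counts: Counter[str] = Counter()
    cross = 0
    for node in net.nodes:
        if node.node_id in media_nodes:
            continue
        genera = {
            mm[sid].genus
            for sid in node.sample_presence
            if sid in mm and not mm[sid].is_blank
        }
        for g in genera:
            node_counts[g] += 1
        if len(genera) >= cross_genus_min:
            cross += 1
    per_genus = {
        g: GenusRow(
            genus=g,
            strain_count=len(strains),
            node_count=node_counts.get(g, 0),
            avg_per_strain=per_strain_average(node_counts.get(g, 0), len(strains)),
        )
        for g, strains in sorted(strains_per_genus.items())
    }
    return GenusSummary(per_genus=per_genus, cross_genus_count=cross)


def rarefaction(
    sample_to_clusters: Mapping[str, Iterable[int]],
    n_permutations: int = 100,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction of spectral-cluster diversity over samples.

    For k = 1..n_samples, the mean (over ``n_permutations`` seeded random
    sample orderings) number of distinct clusters observed among the first
    k samples, with its standard deviation. The mean is non-decreasing in
    k by construction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    samples = sorted(sample_to_clusters)
    if not samples:
        raise ValueError("rarefaction requires at least one sample")
    sets = [frozenset(sample_to_clusters[s]) for s in samples]
    n = len(sets)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen: set[int] = set()
        for k, idx in enumerate(order):
            seen.update(sets[idx])
            counts[p, k] = len(seen)
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=0)
    points = tuple(
        (k + 1, float(means[k]), float(sds[k])) for k in range(n)
    )
    return RarefactionCurve(points=points, n_permutations=n_permutations, seed=seed)


def neutral_loss_annotate(
    fragment_pairs: Sequence[tuple[float, float]],
    tol_da: float = 0.005,
    losses: Mapping[str, float] = NEUTRAL_LOSSES,
) -> list[tuple[float, float, float, str]]:
    """Annotate fragment-pair mass differences with known neutral losses.

    Each (mz_high, mz_low) pair yields (mz_high, mz_low, delta, label)
    where label is the loss whose monoisotopic mass lies within ``tol_da``
    of the difference — the closest one if several qualify — or
    "unassigned".
    """
    out = []
    for mz_high, mz_low in fragment_pairs:
        delta = mz_high - mz_low
        best_name = "unassigned"
        best_err = None
        for name, mass in losses.items():
            err = abs(delta - mass)
            if err <= tol_da and (best_err is None or err < best_err):
                best_name = name
                best_err = err
        out.append((mz_high, mz_low, delta, best_name))
    return out


def sample_cluster_map(net: MolecularNetwork) -> dict[str, set[int]]:
    """sample_id -> set of node ids the sample's spectra contributed to."""
    out: dict[str, set[int]] = {}
    for node in net.nodes:
        for sid in node.sample_presence:
            out.setdefault(sid, set()).add(node.node_id)
    return out
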