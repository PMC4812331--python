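"""End-to-end pipeline: read -> filter -> cluster -> network -> stats -> export.

A run is fully described by a :class:`PipelineConfig`; identical config and
inputs produce identical outputs (all randomness is seeded, all tie-breaks
deterministic). Each run directory receives:

* ``nodes.tsv`` / ``edges.tsv`` / ``network.graphml`` — the molecular network;
* ``summary.json`` — every attribution statistic;
* ``rarefaction.tsv`` — the diversity curve;
* ``manifest.json`` — config, package version, seed and input inventory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import ClusterParams, cluster_spectra
from .cohort_stats import (
    DEFAULT_MASS_BINS,
    attribute_groups,
    flag_media_nodes,
    genus_stats,
    mass_bins,
    neutral_loss_annotate,
    rarefaction,
    sample_cluster_map,
    strain_specificity,
)
from .network import NetworkParams, build_network, export_network
from .preprocess import FilterParams, preprocess_spectrum
from .similarity import SimilarityParams
from .spectra_io import Spectrum, read_mgf, read_sample_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mznet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the offending record."""


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; defaults are the workflow's standard values
    (±17 Da precursor exclusion, top-6-per-±50-Da window filter, 2.0 Da
    parent tolerance, 0.5 Da fragment tolerance, cosine ≥ 0.7, ≥ 6 matched
    peaks, mutual top-10)."""

    input_dir: str = "."
    metadata: str = "samples.tsv"
    library: str | None = None
    outdir: str = "run"
    filters: FilterParams = field(default_factory=FilterParams)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    rarefaction_permutations: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, klass in (
            ("filters", FilterParams),
            ("similarity", SimilarityParams),
            ("clustering", ClusterParams),
            ("network", NetworkParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _read_inputs(config: PipelineConfig):
    input_dir = Path(config.input_dir)
    mgf_files = sorted(input_dir.glob("*.mgf"))
    if not mgf_files:
        raise PipelineError(f"read: no .mgf files found in {input_dir}")
    try:
        meta = read_sample_table(config.metadata)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"read: sample table {config.metadata}: {exc}") from exc
    known = {r.sample_id for r in meta}
    spectra: list[Spectrum] = []
    for f in mgf_files:
        batch = read_mgf(f)
        if batch and batch[0].sample_id not in known:
            log.warning("sample %s not in metadata; its spectra are unattributed", f.stem)
        spectra.extend(batch)
    return spectra, meta, mgf_files


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spectra, meta, mgf_files = _read_inputs(config)
    log.info("read %d spectra from %d files", len(spectra), len(mgf_files))

    try:
        filtered = [preprocess_spectrum(s, config.filters) for s in spectra]
    except ValueError as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    nonempty = [s for s in filtered if not s.is_empty]
    if len(nonempty) < len(filtered):
        log.info("dropped %d spectra emptied by filtering", len(filtered) - len(nonempty))

    sample_to_strain = {r.sample_id: r.strain_id for r in meta if not r.is_blank}
    nodes = cluster_spectra(
        nonempty, config.clustering, config.similarity, config.filters, sample_to_strain
    )
    log.info("clustered into %d consensus nodes", len(nodes))

    library = None
    if config.library:
        raw_lib = read_mgf(config.library, sample_id="library")
        library = [
            s
            for s in (preprocess_spectrum(e, config.filters) for e in raw_lib)
            if not s.is_empty
        ]
    net = build_network(nodes, config.network, config.similarity, library)
    log.info("network: %d nodes, %d edges, %d library hits",
             net.n_nodes, net.n_edges, len(net.library_hits))

    media = flag_media_nodes(net, meta)
    try:
        summary = attribute_groups(net, meta, media)
    except ValueError as exc:
        raise PipelineError(f"stats: {exc}") from exc
    spec = strain_specificity(net, meta, media)
    bins = mass_bins(net, DEFAULT_MASS_BINS)
    genus = genus_stats(net, meta, media)
    curve = rarefaction(
        sample_cluster_map(net), config.rarefaction_permutations, config.seed
    )

    export_network(net, meta, outdir, media)
    summary_payload = {
        "total_nodes": summary.total_nodes,
        "media_nodes": summary.media_nodes,
        "per_group_exclusive": summary.per_group_exclusive,
        "shared_all_groups": summary.shared_all_groups,
        "unattributed": summary.unattributed,
        "fractions": summary.fractions,
        "strain_specificity": {
            "histogram": {str(k): v for k, v in spec.histogram.items()},
            "fraction_single_strain": spec.fraction_single_strain,
        },
        "mass_bins": [
            {"low": lo, "high": hi, "count": c, "percent": p}
            for lo, hi, c, p in bins.bins
        ],
        "mass_bin_overflow": bins.overflow,
        "genus": {
            g: {
                "strain_count": row.strain_count,
                "node_count": row.node_count,
                "avg_per_strain": row.avg_per_strain,
            }
            for g, row in genus.per_genus.items()
        },
        "cross_genus_count": genus.cross_genus_count,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_payload, fh, indent=1, sort_keys=True)

    # neutral-loss reading of edge mass differences (e.g. CH2 homologs fall
    # outside the table and stay unassigned; CO/H2O/CO2/NH3 gaps are named)
    prec = {n.node_id: n.precursor_mz for n in net.nodes}
    pairs = [
        (max(prec[e.node_a], prec[e.node_b]), min(prec[e.node_a], prec[e.node_b]))
        for e in net.edges
    ]
    with open(outdir / "loss_annotations.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tmass_diff\tloss\n")
        for e, (_, _, delta, label) in zip(net.edges, neutral_loss_annotate(pairs, 0.01)):
            fh.write(f"{e.node_a}\t{e.node_b}\t{delta:.5f}\t{label}\n")

    with open(outdir / "rarefaction.tsv", "w") as fh:
        fh.write("k\tmean_clusters\tsd\n")
        for k, mean, sd in curve.points:
            fh.write(f"{k}\t{mean:.4f}\t{sd:.4f}\n")

    manifest = {
        "mznet_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": [f.name for f in mgf_files],
        "n_spectra": len(spectra),
        "n_spectra_after_filtering": len(nonempty),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
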