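"""Seeded synthetic MS/MS cohorts with known ground truth.

The generator emulates the structure of a multi-strain, two-location
bioprospecting cohort: strains from two isolation locations each produce
a mixture of compounds that are shared between locations, exclusive to
one location, or private to a single strain; medium components appear in
every extract including the uninoculated blanks; a fraction of compounds
carry a homolog (precursor shifted by a repeat mass, fragment ladder
partially shifted) so the shift-aware cosine has analog pairs to find.

Each compound is a precursor mass plus a random fragment ladder drawn
below the precursor; every producing sample emits a configurable number
of replicate spectra with Gaussian m/z jitter and low-intensity uniform
noise peaks. A registry records every compound's category and producing
samples and maps every emitted spectrum back to its compound, so cluster
purity and attribution recovery can be scored exactly.

Everything is driven by one integer seed; the same design and seed yield
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort_stats import percent
from .spectra_io import (
    Peak,
    SampleRecord,
    Spectrum,
    write_mgf,
    write_sample_table,
)

__all__ = [
    "SyntheticDesign",
    "CompoundRecord",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "evaluate_recovery",
]

_GENUS_CYCLE = ("Bacillus", "Bacillus", "Bacillus", "Streptomyces", "unknown")


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a synthetic cohort.

    Defaults describe a two-location, five-strains-per-location cohort
    with two medium blanks — roughly 230 designed compounds emitting about
    1,500 spectra — sized so a full pipeline run completes in well under a
    minute while exercising every attribution category.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {"Antarctica": 5, "Scotland": 5}
    )
    n_shared_compounds: int = 25
    n_group_exclusive: int = 50  # per group
    n_strain_exclusive: int = 10  # per strain
    n_media_compounds: int = 6
    fragments_per_compound: tuple[int, int] = (8, 20)
    precursor_range: tuple[float, float] = (150.0, 2600.0)
    family_fraction: float = 0.1
    homolog_repeat_mass: float = 14.0157
    replicates: int = 3
    mz_jitter_sd: float = 0.01
    noise_peaks: int = 3
    intensity_lognormal: tuple[float, float] = (2.0, 0.7)
    noise_intensity_lognormal: tuple[float, float] = (-1.5, 0.5)
    n_blanks: int = 2
    seed: int = 0

    def validate(self) -> None:
        n_strains = sum(self.groups.values())
        if n_strains == 0 and (
            self.n_strain_exclusive > 0
            or self.n_group_exclusive > 0
            or self.n_shared_compounds > 0
        ):
            raise ValueError("design has zero strains but nonzero strain compounds")
        if self.n_shared_compounds > 0 and len(self.groups) < 2:
            raise ValueError("shared compounds require at least two groups")
        lo, hi = self.fragments_per_compound
        if lo < 1 or hi < lo:
            raise ValueError("fragments_per_compound range invalid")
        if self.mz_jitter_sd < 0 or self.noise_peaks < 0 or self.replicates < 1:
            raise ValueError("jitter/noise/replicates must be non-negative (replicates >= 1)")
        if self.precursor_range[0] < 90:
            raise ValueError("precursor_range lower bound must leave room for a ladder")


@dataclass
class CompoundRecord:
    compound_id: str
    precursor_mz: float
    fragment_mz: list[float]
    fragment_intensity: list[float]
    producing_samples: list[str]
    category: str  # shared | group-exclusive:<g> | strain-exclusive:<s> | media | homolog-of:<id>

    def attribution_groups(self, sample_group: dict[str, str]) -> set[str]:
        return {
            sample_group[s] for s in self.producing_samples if sample_group.get(s)
        }


@dataclass
class GroundTruth:
    """Registry of designed compounds plus the spectrum -> compound map."""

    compounds: dict[str, CompoundRecord]
    spectrum_map: dict[str, str]
    #: per spectrum, designed peak m/z values inside the ±17 Da precursor window
    expected_excluded: dict[str, list[float]]
    design: SyntheticDesign

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.compounds.values():
            key = c.category.split(":", 1)[0]
            counts[key] = counts.get(key, 0) + 1
        return counts

    def designed_fractions(self, sample_group: dict[str, str]) -> dict[str, float]:
        """Designed media / per-group-exclusive / shared percentages of all compounds."""
        total = len(self.compounds)
        media = 0
        shared = 0
        exclusive: dict[str, int] = {}
        for c in self.compounds.values():
            if c.category == "media":
                media += 1
                continue
            groups = c.attribution_groups(sample_group)
            if len(groups) >= 2:
                shared += 1
            elif len(groups) == 1:
                g = next(iter(groups))
                exclusive[g] = exclusive.get(g, 0) + 1
        out = {f"exclusive_{g}": percent(c, total) for g, c in sorted(exclusive.items())}
        out["shared"] = percent(shared, total)
        out["media"] = percent(media, total)
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "design": asdict(self.design),
            "compounds": {
                cid: {
                    "precursor_mz": c.precursor_mz,
                    "fragment_mz": c.fragment_mz,
                    "fragment_intensity": c.fragment_intensity,
                    "producing_samples": c.producing_samples,
                    "category": c.category,
                }
                for cid, c in self.compounds.items()
            },
            "spectrum_map": self.spectrum_map,
            "expected_excluded": self.expected_excluded,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return path


@dataclass
class Cohort:
    spectra: list[Spectrum]
    samples: list[SampleRecord]
    truth: GroundTruth

    def spectra_by_sample(self) -> dict[str, list[Spectrum]]:
        out: dict[str, list[Spectrum]] = {r.sample_id: [] for r in self.samples}
        for s in self.spectra:
            out.setdefault(s.sample_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# Generation


def _make_samples(design: SyntheticDesign) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    for group in sorted(design.groups):
        n = design.groups[group]
        prefix = group[:2].upper()
        for i in range(n):
            sid = f"{prefix}{i + 1:02d}"
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    strain_id=sid,
                    group=group,
                    genus=_GENUS_CYCLE[i % len(_GENUS_CYCLE)],
                    is_blank=False,
                )
            )
    for b in range(design.n_blanks):
        samples.append(
            SampleRecord(
                sample_id=f"BLANK{b + 1}",
                strain_id=f"BLANK{b + 1}",
                group="",
                genus="unknown",
                is_blank=True,
            )
        )
    return samples


def _draw_compound(
    rng: np.random.Generator, design: SyntheticDesign
) -> tuple[float, list[float], list[float]]:
    lo, hi = design.precursor_range
    precursor = float(rng.uniform(lo, hi))
    n_frag = int(rng.integers(design.fragments_per_compound[0],
                              design.fragments_per_compound[1] + 1))
    # ladder strictly below the precursor-exclusion window, above the low-mass cutoff
    frag_mz = sorted(float(m) for m in rng.uniform(50.0, precursor - 20.0, n_frag))
    mu, sigma = design.intensity_lognormal
    frag_int = [float(v) for v in rng.lognormal(mu, sigma, n_frag)]
    return precursor, frag_mz, frag_int


def generate_cohort(design: SyntheticDesign | None = None) -> Cohort:
    """Generate spectra, metadata and ground truth for a designed cohort."""
    design = design or SyntheticDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    samples = _make_samples(design)
    strains = [r for r in samples if not r.is_blank]
    by_group: dict[str, list[SampleRecord]] = {}
    for r in strains:
        by_group.setdefault(r.group, []).append(r)
    all_sample_ids = [r.sample_id for r in samples]

    compounds: dict[str, CompoundRecord] = {}

    def register(cid: str, producers: list[str], category: str) -> CompoundRecord:
        precursor, fmz, fint = _draw_compound(rng, design)
        rec = CompoundRecord(cid, precursor, fmz, fint, list(producers), category)
        compounds[cid] = rec
        return rec

    for i in range(design.n_shared_compounds):
        producers: list[str] = []
        for g in sorted(by_group):
            members = by_group[g]
            k = int(rng.integers(1, min(3, len(members)) + 1))
            picked = rng.choice(len(members), size=k, replace=False)
            producers.extend(members[j].sample_id for j in sorted(picked))
        register(f"SH{i:03d}", producers, "shared")

    for g in sorted(by_group):
        members = by_group[g]
        for i in range(design.n_group_exclusive):
            k = int(rng.integers(1, min(3, len(members)) + 1))
            picked = rng.choice(len(members), size=k, replace=False)
            producers = [members[j].sample_id for j in sorted(picked)]
            register(f"GX-{g[:2].upper()}{i:03d}", producers, f"group-exclusive:{g}")

    for r in strains:
        for i in range(design.n_strain_exclusive):
            register(
                f"SX-{r.sample_id}-{i:02d}",
                [r.sample_id],
                f"strain-exclusive:{r.strain_id}",
            )

    for i in range(design.n_media_compounds):
        register(f"MED{i:03d}", list(all_sample_ids), "media")

    # homolog families: shift precursor by k repeat units; fragments above a
    # random core mass shift with it, fragments below are shared with the parent
    parent_ids = [cid for cid, c in compounds.items() if c.category != "media"]
    for cid in list(parent_ids):
        if rng.random() >= design.family_fraction:
            continue
        parent = compounds[cid]
        k = int(rng.integers(1, 4))
        shift = k * design.homolog_repeat_mass
        core = float(rng.uniform(min(parent.fragment_mz), max(parent.fragment_mz)))
        fmz = [m if m <= core else m + shift for m in parent.fragment_mz]
        order = np.argsort(fmz)
        hom = CompoundRecord(
            compound_id=f"{cid}-H{k}",
            precursor_mz=parent.precursor_mz + shift,
            fragment_mz=[float(fmz[j]) for j in order],
            fragment_intensity=[parent.fragment_intensity[j] for j in order],
            producing_samples=list(parent.producing_samples),
            category=f"homolog-of:{cid}",
        )
        compounds[hom.compound_id] = hom

    spectra: list[Spectrum] = []
    spectrum_map: dict[str, str] = {}
    expected_excluded: dict[str, list[float]] = {}
    nmu, nsigma = design.noise_intensity_lognormal
    for cid in sorted(compounds):
        c = compounds[cid]
        for sid in sorted(c.producing_samples):
            for rep in range(design.replicates):
                spec_id = f"{sid}|{cid}|{rep}"
                n = len(c.fragment_mz)
                mz = np.asarray(c.fragment_mz) + rng.normal(0, design.mz_jitter_sd, n) \
                    if design.mz_jitter_sd > 0 else np.asarray(c.fragment_mz, dtype=float)
                inten = np.asarray(c.fragment_intensity) * np.exp(
                    rng.normal(0, 0.1, n)
                )
                peaks = [Peak(float(m), float(v)) for m, v in zip(mz, inten) if m > 0]
                excluded: list[float] = []
                if design.noise_peaks > 0:
                    nmz = rng.uniform(50.0, c.precursor_mz + 10.0, design.noise_peaks)
                    nint = rng.lognormal(nmu, nsigma, design.noise_peaks)
                    for m, v in zip(nmz, nint):
                        peaks.append(Peak(float(m), float(v)))
                        if abs(float(m) - c.precursor_mz) <= 17.0:
                            excluded.append(float(m))
                prec = c.precursor_mz + (
                    float(rng.normal(0, design.mz_jitter_sd))
                    if design.mz_jitter_sd > 0
                    else 0.0
                )
                spectra.append(
                    Spectrum(
                        spectrum_id=spec_id,
                        sample_id=sid,
                        precursor_mz=prec,
                        peaks=tuple(peaks),
                        charge=1,
                    )
                )
                spectrum_map[spec_id] = cid
                if excluded:
                    expected_excluded[spec_id] = excluded

    truth = GroundTruth(
        compounds=compounds,
        spectrum_map=spectrum_map,
        expected_excluded=expected_excluded,
        design=design,
    )
    return Cohort(spectra=spectra, samples=samples, truth=truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write one MGF per sample, samples.tsv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, specs in sorted(cohort.spectra_by_sample().items()):
        paths[sid] = write_mgf(specs, outdir / f"{sid}.mgf")
    paths["samples"] = write_sample_table(cohort.samples, outdir / "samples.tsv")
    paths["truth"] = cohort.truth.to_json(outdir / "truth.json")
    return paths


# ---------------------------------------------------------------------------
# Recovery scoring


def evaluate_recovery(truth: GroundTruth, net, summary) -> dict:
    """Score a pipeline run against the generator's registry.

    Returns designed vs recovered attribution fractions (percent of all
    nodes/compounds) with absolute errors, plus cluster purity and
    completeness computed from the spectrum -> compound map:

    * purity — member-weighted mean over nodes of the largest single-compound
      share of the node's members (1.0 = every node is one compound);
    * completeness — spectrum-weighted mean over compounds of the largest
      share of the compound's spectra recovered in a single node.
    """
    samples = _make_samples(truth.design)
    sample_group = {r.sample_id: r.group for r in samples if not r.is_blank}
    designed = truth.designed_fractions(sample_group)

    recovered = {
        f"exclusive_{g}": summary.fractions.get(g, 0.0)
        for g in sorted(summary.per_group_exclusive)
    }
    recovered["shared"] = summary.fractions.get("shared", 0.0)
    recovered["media"] = summary.fractions.get("media", 0.0)

    errors = {
        k: abs(designed.get(k, 0.0) - recovered.get(k, 0.0))
        for k in set(designed) | set(recovered)
    }

    node_sizes = 0
    purity_hits = 0
    compound_best: dict[str, int] = {}
    compound_total: dict[str, int] = {}
    for cid in truth.spectrum_map.values():
        compound_total[cid] = compound_total.get(cid, 0) + 1
    for node in net.nodes:
        counts: dict[str, int] = {}
        for spec_id in node.member_spectrum_ids:
            cid = truth.spectrum_map.get(spec_id)
            if cid is None:
                continue
            counts[cid] = counts.get(cid, 0) + 1
        if not counts:
            continue
        node_sizes += sum(counts.values())
        purity_hits += max(counts.values())
        for cid, cnt in counts.items():
            compound_best[cid] = max(compound_best.get(cid, 0), cnt)
    purity = purity_hits / node_sizes if node_sizes else 0.0
    total_spectra = sum(compound_total.values())
    completeness = (
        sum(compound_best.get(cid, 0) for cid in compound_total) / total_spectra
        if total_spectra
        else 0.0
    )
    return {
        "designed": designed,
        "recovered": recovered,
        "abs_error_pp": errors,
        "max_abs_error_pp": max(errors.values()) if errors else 0.0,
        "purity": purity,
        "completeness": completeness,
        "node_count": len(net.nodes),
        "designed_compound_count": len(truth.compounds),
    }
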