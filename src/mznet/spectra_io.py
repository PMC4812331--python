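"""MS/MS spectrum data model and MGF / sample-metadata I/O.

The pipeline's unit of data is a single tandem-MS scan: a precursor m/z,
an optional charge, and a centroided peak list. Spectra are exchanged in
Mascot Generic Format (MGF), the minimal open peak-list format that
spectral libraries also ship as; parsing and serialisation are delegated
to :mod:`pyteomics.mgf`.

Sample metadata (which strain an injection came from, the strain's
isolation-location group and genus, and whether the sample is an
uninoculated medium blank) is a 5-column TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "Spectrum",
    "SampleRecord",
    "MGFError",
    "read_mgf",
    "write_mgf",
    "read_sample_table",
    "write_sample_table",
]

SAMPLE_TABLE_COLUMNS = ("sample_id", "strain_id", "group", "genus", "is_blank")


class MGFError(ValueError):
    """Raised when an MGF file cannot be parsed into spectra."""


@dataclass(frozen=True)
class Peak:
    """One centroided fragment peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A single MS/MS scan.

    Peaks are stored sorted strictly ascending in m/z; duplicate m/z values
    (within float equality) are merged by summing intensities at
    construction time, so the sorted-unique invariant always holds.

    A missing charge is interpreted downstream as z = 1, the dominant
    assumption for singly protonated [M + H]+ ions.
    """

    spectrum_id: str
    sample_id: str
    precursor_mz: float
    peaks: tuple[Peak, ...]
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.charge is not None and self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        object.__setattr__(self, "peaks", _canonical_peaks(self.peaks))

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def is_empty(self) -> bool:
        return not self.peaks

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def total_intensity(self) -> float:
        return float(sum(p.intensity for p in self.peaks))

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        """Return a copy carrying ``peaks``; precursor metadata unchanged."""
        return replace(self, peaks=tuple(peaks))


def _canonical_peaks(peaks: Sequence[Peak]) -> tuple[Peak, ...]:
    ordered = sorted(peaks, key=lambda p: p.mz)
    merged: list[Peak] = []
    for p in ordered:
        if merged and p.mz == merged[-1].mz:
            merged[-1] = Peak(p.mz, merged[-1].intensity + p.intensity)
        else:
            merged.append(p)
    return tuple(merged)


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one injected sample.

    ``group`` is the isolation-location label used for biogeographic
    attribution (e.g. "Scotland", "Antarctica"); blanks carry no group
    requirement. Unknown genus is recorded as the literal label "unknown"
    so taxonomically unidentified strains still form their own category.
    """

    sample_id: str
    strain_id: str
    group: str
    genus: str = "unknown"
    is_blank: bool = False


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str | Path, sample_id: str | None = None) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Parameters
    ----------
    path
        MGF file with BEGIN IONS / END IONS blocks, PEPMASS, optional
        CHARGE and TITLE lines.
    sample_id
        Sample the spectra belong to. Defaults to the file stem (one MGF
        file per sample); pass explicitly to override, e.g. when a
        TITLE-prefix convention maps one file to several samples.

    Spectrum ids come from TITLE when present, otherwise they are generated
    as ``"<filename>:<ordinal>"``. Peak lists come back sorted ascending in
    m/z. Spectra with zero peaks are retained (downstream filters may drop
    them). Malformed blocks raise :class:`MGFError` naming the file and the
    offending entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    default_sample = sample_id if sample_id is not None else path.stem
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for ordinal, entry in enumerate(reader, start=1):
                spectra.append(_entry_to_spectrum(entry, path, ordinal, default_sample))
    except MGFError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors on bad syntax
        raise MGFError(
            f"{path}: malformed MGF near block {len(spectra) + 1}: {exc}"
        ) from exc
    return spectra


def _entry_to_spectrum(
    entry: dict, path: Path, ordinal: int, sample_id: str
) -> Spectrum:
    params = entry.get("params", {})
    pepmass = params.get("pepmass")
    if pepmass is None or pepmass[0] is None:
        raise MGFError(f"{path}: block {ordinal} is missing PEPMASS")
    precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    title = params.get("title")
    spectrum_id = str(title) if title else f"{path.name}:{ordinal}"
    charge = None
    if params.get("charge"):
        charge = abs(int(params["charge"][0]))
    mz = np.asarray(entry.get("m/z array", []), dtype=float)
    inten = np.asarray(entry.get("intensity array", []), dtype=float)
    if mz.shape != inten.shape:
        raise MGFError(f"{path}: block {ordinal} has mismatched peak columns")
    peaks = tuple(Peak(float(m), float(i)) for m, i in zip(mz, inten))
    try:
        return Spectrum(
            spectrum_id=spectrum_id,
            sample_id=sample_id,
            precursor_mz=precursor,
            peaks=peaks,
            charge=charge,
        )
    except ValueError as exc:
        raise MGFError(f"{path}: block {ordinal} ({spectrum_id}): {exc}") from exc


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> Path:
    """Write spectra to ``path`` in MGF; round-trips through :func:`read_mgf`."""
    path = Path(path)
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id, "pepmass": (s.precursor_mz,)}
        if s.charge is not None:
            params["charge"] = [s.charge]
        entries.append(
            {
                "m/z array": s.mz_array(),
                "intensity array": s.intensity_array(),
                "params": params,
            }
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _mgf.write(entries, fh)
    return path


# ---------------------------------------------------------------------------
# Sample metadata


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the 5-column sample-metadata TSV.

    Required header columns: sample_id, strain_id, group, genus, is_blank.
    Duplicate sample_ids are an error; an empty genus becomes "unknown".
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row_no, row in enumerate(reader, start=2):
            sid = (row["sample_id"] or "").strip()
            if not sid:
                raise ValueError(f"{path}: line {row_no}: empty sample_id")
            if sid in seen:
                raise ValueError(f"{path}: line {row_no}: duplicate sample_id {sid!r}")
            seen.add(sid)
            flag_raw = (row["is_blank"] or "").strip().lower()
            if flag_raw in _TRUE:
                is_blank = True
            elif flag_raw in _FALSE:
                is_blank = False
            else:
                raise ValueError(
                    f"{path}: line {row_no}: unrecognised is_blank value {flag_raw!r}"
                )
            records.append(
                SampleRecord(
                    sample_id=sid,
                    strain_id=(row["strain_id"] or "").strip(),
                    group=(row["group"] or "").strip(),
                    genus=(row["genus"] or "").strip() or "unknown",
                    is_blank=is_blank,
                )
            )
    return records


def write_sample_table(records: Iterable[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SAMPLE_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.sample_id, r.strain_id, r.group, r.genus, str(r.is_blank).lower()]
            )
    return path
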