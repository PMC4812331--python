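"""Modified (precursor-shift-aware) cosine similarity between MS/MS spectra.

Spectra are compared as unit vectors of square-root-transformed peak
intensities. Two peaks may pair either directly (|Δm/z| ≤ fragment
tolerance) or, when shift-aware matching is on, after offsetting one
spectrum's fragments by the precursor-mass difference — this is what lets
structural analogs (homologs differing by a repeat unit, adducts, simple
modifications) score highly even though their fragment m/z values differ.

Candidate pairs are assigned one-to-one by an exact maximum-weight
matching (Hungarian algorithm), so the score — the sum of weight products
over assigned pairs — is the best achievable alignment of the two
spectra. It lies in [0, 1] with 1 meaning identical fragmentation, and it
is exactly symmetric in its arguments. A simple greedy assignment is
near-optimal but measurably suboptimal on conflicting candidate sets,
which is why the optimal matching is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra_io import Spectrum

__all__ = [
    "SimilarityParams",
    "SimilarityResult",
    "MatchedPair",
    "normalize_intensities",
    "cosine",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Spectral-matching settings.

    fragment_tol_da : fragment-ion match tolerance in Da (default 0.5).
    use_shift : allow peaks to match after shifting by the precursor-mass
        difference (modified cosine). On for network edges and library
        search; clustering of near-identical replicates uses the plain
        cosine.
    weighting : intensity transform before unit normalisation; "sqrt"
        (default) tempers the dominance of base peaks, "none" uses raw
        intensities.
    """

    fragment_tol_da: float = 0.5
    use_shift: bool = True
    weighting: Literal["sqrt", "none"] = "sqrt"

    def __post_init__(self) -> None:
        if self.fragment_tol_da <= 0:
            raise ValueError("fragment_tol_da must be positive")
        if self.weighting not in ("sqrt", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class MatchedPair:
    """One assigned peak pair: indices into the two peak lists."""

    index_a: int
    index_b: int
    shifted: bool


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    matched_peaks: int
    pairs: tuple[MatchedPair, ...]


def normalize_intensities(s: Spectrum, weighting: str = "sqrt") -> np.ndarray:
    """Return the spectrum's peak weights: transformed intensities at unit Euclidean norm."""
    if s.is_empty:
        raise ValueError("cannot normalize an empty spectrum")
    inten = s.intensity_array()
    if weighting == "sqrt":
        w = np.sqrt(inten)
    elif weighting == "none":
        w = inten.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return w / norm


def cosine(
    a: Spectrum, b: Spectrum, p: SimilarityParams | None = None
) -> SimilarityResult:
    """Modified cosine score between two spectra.

    Candidate pairs (i, j) satisfy |mz_a(i) - mz_b(j)| ≤ tol (direct) or,
    when ``use_shift``, |mz_a(i) - (mz_b(j) + Δ)| ≤ tol with
    Δ = precursor_mz(a) - precursor_mz(b) (shifted). A pair inside both
    windows counts once, as direct. Candidates are assigned one-to-one by
    a maximum-weight matching on the weight products; the score is the
    summed weight product of the assigned pairs.

    Empty spectra score 0 with no matches. The score is symmetric in its
    arguments and equals 1.0 for a spectrum against itself.
    """
    p = p or SimilarityParams()
    if a.is_empty or b.is_empty:
        return SimilarityResult(0.0, 0, ())
    wa = normalize_intensities(a, p.weighting)
    wb = normalize_intensities(b, p.weighting)
    mza = a.mz_array()
    mzb = b.mz_array()
    tol = p.fragment_tol_da

    diff = mza[:, None] - mzb[None, :]
    direct = np.abs(diff) <= tol
    if p.use_shift:
        delta = a.precursor_mz - b.precursor_mz
        shifted = np.abs(diff - delta) <= tol
    else:
        shifted = np.zeros_like(direct)
    # a pair matching both ways counts once, as direct
    shifted &= ~direct
    allowed = direct | shifted
    if not allowed.any():
        return SimilarityResult(0.0, 0, ())

    profit = np.where(allowed, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(profit, maximize=True)
    score = 0.0
    pairs: list[MatchedPair] = []
    for i, j in zip(rows, cols):
        if not allowed[i, j]:
            continue
        score += float(profit[i, j])
        pairs.append(MatchedPair(int(i), int(j), bool(shifted[i, j])))
    pairs.sort(key=lambda pr: (pr.index_a, pr.index_b))
    return SimilarityResult(min(score, 1.0), len(pairs), tuple(pairs))
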