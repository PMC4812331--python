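"""Spectral peak filters applied before any similarity computation.

Two filters, applied in this order to both query and library spectra:

1. precursor-window exclusion — drop every fragment peak within ±17 Da of
   the precursor m/z, removing the unfragmented precursor and its
   immediate neutral-loss satellites;
2. rank-in-window filter — keep a peak only if its intensity is among the
   top 6 within the ±50 Da window centred on that peak, a standard
   density-equalising noise filter for molecular networking.

Both are single-pass on the original intensities (ranks are not recomputed
as peaks are removed) and therefore idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectra_io import Spectrum

__all__ = ["FilterParams", "remove_precursor_window", "window_filter", "preprocess_spectrum"]


@dataclass(frozen=True)
class FilterParams:
    """Peak-filter settings.

    precursor_exclusion_da : half-width (Da) of the exclusion window around
        the precursor m/z (default 17.0).
    window_da : half-width (Da) of the sliding intensity-rank window
        (default 50.0).
    top_k_per_window : number of peaks retained per window (default 6).
    """

    precursor_exclusion_da: float = 17.0
    window_da: float = 50.0
    top_k_per_window: int = 6

    def __post_init__(self) -> None:
        if self.precursor_exclusion_da <= 0 or self.window_da <= 0:
            raise ValueError("filter window widths must be positive")
        if self.top_k_per_window < 1:
            raise ValueError("top_k_per_window must be >= 1")


def remove_precursor_window(s: Spectrum, p: FilterParams | None = None) -> Spectrum:
    """Drop all peaks within ±``precursor_exclusion_da`` of the precursor m/z.

    Retains exactly the peaks with ``|mz - precursor_mz| > precursor_exclusion_da``;
    an empty result is allowed. Precursor metadata is unchanged.
    """
    p = p or FilterParams()
    kept = [
        pk for pk in s.peaks if abs(pk.mz - s.precursor_mz) > p.precursor_exclusion_da
    ]
    return s.with_peaks(kept)


def window_filter(s: Spectrum, p: FilterParams | None = None) -> Spectrum:
    """Keep a peak iff it ranks in the top-k by intensity within ±``window_da`` of itself.

    The rank of a peak counts, among all input peaks within ±window_da of its
    own m/z (itself included), those with strictly greater intensity plus
    equally intense peaks at lower m/z — i.e. intensity ties are broken in
    favour of the lower-m/z peak. Ranking is computed once on the input
    spectrum, never iteratively, so the filter is idempotent and never
    removes a peak that is the intensity maximum of its own neighbourhood.
    """
    p = p or FilterParams()
    peaks = s.peaks
    n = len(peaks)
    if n <= p.top_k_per_window:
        return s
    kept = []
    # peaks are sorted by mz; the window is a contiguous run
    lo = 0
    hi = 0
    for i, pk in enumerate(peaks):
        while peaks[lo].mz < pk.mz - p.window_da:
            lo += 1
        if hi < lo:
            hi = lo
        while hi < n and peaks[hi].mz <= pk.mz + p.window_da:
            hi += 1
        rank = 0
        for j in range(lo, hi):
            q = peaks[j]
            if q.intensity > pk.intensity or (
                q.intensity == pk.intensity and q.mz < pk.mz
            ):
                rank += 1
        if rank < p.top_k_per_window:
            kept.append(pk)
    return s.with_peaks(kept)


def preprocess_spectrum(s: Spectrum, p: FilterParams | None = None) -> Spectrum:
    """Apply precursor-window exclusion then the rank-in-window filter."""
    p = p or FilterParams()
    return window_filter(remove_precursor_window(s, p), p)
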