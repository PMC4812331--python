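"""Independent brute-force oracles and random-instance generators.

Everything here is deliberately naive — per-peak scans, exhaustive
enumeration of assignments, double loops — and shares no code path with
the package implementations it checks.
"""

from __future__ import annotations

import numpy as np

from mznet import Peak, Spectrum


# ---------------------------------------------------------------------------
# random instances


def random_spectrum(
    rng: np.random.Generator,
    n_peaks: tuple[int, int] = (5, 40),
    precursor: tuple[float, float] = (200.0, 900.0),
    spectrum_id: str = "r",
) -> Spectrum:
    prec = float(rng.uniform(*precursor))
    n = int(rng.integers(n_peaks[0], n_peaks[1] + 1))
    mz = np.sort(rng.uniform(50.0, prec + 20.0, n))
    inten = rng.lognormal(1.0, 0.8, n)
    return Spectrum(
        spectrum_id=spectrum_id,
        sample_id="s",
        precursor_mz=prec,
        peaks=tuple(Peak(float(m), float(v)) for m, v in zip(mz, inten)),
    )


def random_spectrum_pair(
    rng: np.random.Generator, max_peaks: int = 6
) -> tuple[Spectrum, Spectrum]:
    """A pair with deliberate near-matches so candidate conflicts occur."""
    pa = float(rng.uniform(200, 500))
    pb = pa + float(rng.uniform(-30, 30))
    na = int(rng.integers(2, max_peaks + 1))
    nb = int(rng.integers(2, max_peaks + 1))
    mza = sorted(float(m) for m in rng.uniform(50, pa - 20, na))
    mzb = []
    for _ in range(nb):
        if rng.random() < 0.5:
            mzb.append(float(rng.choice(mza)) + float(rng.uniform(-0.8, 0.8)))
        else:
            mzb.append(float(rng.uniform(50, pb - 20)))
    a = Spectrum(
        "a", "s", pa, tuple(Peak(m, float(rng.lognormal(1, 0.5))) for m in mza)
    )
    b = Spectrum(
        "b",
        "s",
        pb,
        tuple(Peak(m, float(rng.lognormal(1, 0.5))) for m in sorted(mzb) if m > 0),
    )
    return a, b


# ---------------------------------------------------------------------------
# brute-force reimplementations


def bf_precursor_filter(s: Spectrum, half_width: float) -> list[Peak]:
    return [p for p in s.peaks if abs(p.mz - s.precursor_mz) > half_width]


def bf_window_filter(s: Spectrum, window: float, k: int) -> list[Peak]:
    kept = []
    for p in s.peaks:
        neigh = [q for q in s.peaks if abs(q.mz - p.mz) <= window]
        better = sum(
            1
            for q in neigh
            if q.intensity > p.intensity
            or (q.intensity == p.intensity and q.mz < p.mz)
        )
        if better < k:
            kept.append(p)
    return kept


def bf_modified_cosine(
    a: Spectrum, b: Spectrum, tol: float = 0.5, use_shift: bool = True,
    weighting: str = "sqrt",
) -> float:
    """Exhaustive search over all one-to-one candidate-pair subsets."""
    ia, ib = a.intensity_array(), b.intensity_array()
    wa = np.sqrt(ia) if weighting == "sqrt" else ia.astype(float)
    wb = np.sqrt(ib) if weighting == "sqrt" else ib.astype(float)
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    mza, mzb = a.mz_array(), b.mz_array()
    delta = a.precursor_mz - b.precursor_mz
    cand = [
        (i, j)
        for i in range(len(mza))
        for j in range(len(mzb))
        if abs(mza[i] - mzb[j]) <= tol
        or (use_shift and abs(mza[i] - mzb[j] - delta) <= tol)
    ]
    best = 0.0

    def recurse(idx: int, used_a: frozenset, used_b: frozenset, acc: float) -> None:
        nonlocal best
        best = max(best, acc)
        for t in range(idx, len(cand)):
            i, j = cand[t]
            if i in used_a or j in used_b:
                continue
            recurse(t + 1, used_a | {i}, used_b | {j}, acc + wa[i] * wb[j])

    recurse(0, frozenset(), frozenset(), 0.0)
    return min(best, 1.0)


def bf_mutual_topk(candidates, k: int):
    """Mutual top-K via explicit per-node sorted neighbour lists."""
    scores: dict[int, list[float]] = {}
    for e in candidates:
        scores.setdefault(e.node_a, []).append(e.cosine)
        scores.setdefault(e.node_b, []).append(e.cosine)

    def threshold(u: int) -> float:
        ordered = sorted(scores[u], reverse=True)
        if len(ordered) <= k:
            return float("-inf")
        return ordered[k - 1]

    kept = []
    for e in candidates:
        if e.cosine >= threshold(e.node_a) and e.cosine >= threshold(e.node_b):
            kept.append(e)
    return kept


def bf_group_peaks(peaks: list[Peak], tol: float) -> list[list[Peak]]:
    """Single-linkage grouping of pooled peaks via pairwise union-find."""
    n = len(peaks)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(peaks[i].mz - peaks[j].mz) <= tol:
                parent[find(i)] = find(j)
    groups: dict[int, list[Peak]] = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    return [sorted(g, key=lambda p: p.mz) for g in sorted(groups.values(), key=lambda g: min(p.mz for p in g))]
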