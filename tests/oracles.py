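"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and where possible the libraries)
used by the package itself, so agreement is informative.
"""

from __future__ import annotations

import math

import numpy as np


def rank_average_ties(v: np.ndarray) -> np.ndarray:
    """1-based ranks with average ties, via explicit sorting."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation as Pearson correlation of tie-averaged ranks."""
    rx = rank_average_ties(x)
    ry = rank_average_ties(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    return float((rx @ ry) / denom)


def spearman_p_t_approx(rho: float, n: int) -> float:
    """Two-sided p from the t approximation on n-2 df."""
    from scipy import stats  # the CDF itself is not what is under test

    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x @ y) / math.sqrt((x @ x) * (y @ y)))


def fisher_z_matrix(ts: np.ndarray) -> np.ndarray:
    """Pairwise atanh(Pearson r) by explicit double loop."""
    n = ts.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = math.atanh(pearson_r(ts[:, i], ts[:, j]))
    return out


def symmetrize_loop(counts: np.ndarray, vols: np.ndarray, spv: int) -> np.ndarray:
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = (counts[i, j] + counts[j, i]) / (spv * (vols[i] + vols[j]))
    return out


def degree_sums_loop(sc: np.ndarray, fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sDC, fDC) per ROI for one subject, by explicit loops."""
    n = sc.shape[0]
    sdc = np.zeros(n)
    fdc = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i and sc[i, j] > 0:
                sdc[i] += sc[i, j]
                fdc[i] += fc[i, j]
    return sdc, fdc


def coupling_loop(sc: np.ndarray, fc: np.ndarray, min_edges: int = 3) -> np.ndarray:
    """Per-ROI Spearman between nonzero SC weights and matching FC values."""
    n = sc.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        idx = [j for j in range(n) if j != i and sc[i, j] > 0]
        if len(idx) >= min_edges:
            out[i] = spearman_rho(sc[i, idx], fc[i, idx])
    return out


def alff_direct_dft(ts: np.ndarray, dt: float, band: tuple[float, float]) -> np.ndarray:
    """Raw ALFF by explicit O(T^2) discrete Fourier transform."""
    ts = np.asarray(ts, float)
    n_t, n_rois = ts.shape
    x = ts - ts.mean(axis=0, keepdims=True)
    freqs = np.array([k / (n_t * dt) for k in range(n_t // 2 + 1)])
    in_band = [k for k, f in enumerate(freqs) if band[0] <= f <= band[1]]
    out = np.zeros(n_rois)
    t = np.arange(n_t)
    for r in range(n_rois):
        amps = []
        for k in in_band:
            coef = np.sum(x[:, r] * np.exp(-2j * np.pi * k * t / n_t))
            amps.append(2.0 * abs(coef) / n_t)
        out[r] = np.mean(amps)
    return out


def edge_cv(stack: np.ndarray, i: int, j: int) -> float:
    vals = stack[:, i, j]
    return float(np.std(vals, ddof=1) / np.mean(vals))
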