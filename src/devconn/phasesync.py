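"""Weighted phase lag index (wPLI) connectivity.

The wPLI quantifies how consistently one signal's phase leads or lags
another's, weighting each observation by the magnitude of the imaginary
part of the cross-spectrum.  With analytic signals ``zx(t)``, ``zy(t)``
and instantaneous cross-spectrum ``S(t) = zx(t) * conj(zy(t))``,

    wPLI = |sum_t Im S(t)| / sum_t |Im S(t)|

which lies in [0, 1] and is blind to zero-lag (volume-conducted)
coupling, since zero lag makes Im S identically zero.  Observations are
time samples within a trial; trial-wise values are mean-averaged into a
single adjacency entry per region pair, band, and subject.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import hilbert

from .containers import BROADBAND, AdjacencyMatrix, ParcelTimeSeries

logger = logging.getLogger(__name__)


def analytic_phase(trial: np.ndarray) -> np.ndarray:
    """Analytic (complex) representation of each parcel's mean-centred signal.

    ``trial`` is parcels x samples.  The real part of the output equals the
    mean-centred input; the angle is the instantaneous phase.  Raises on a
    constant (zero after centring) parcel, whose phase is undefined.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim == 1:
        trial = trial[np.newaxis, :]
    if trial.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(trial)):
        raise ValueError("non-finite input")
    centred = trial - trial.mean(axis=-1, keepdims=True)
    degenerate = np.all(centred == 0, axis=-1)
    if degenerate.any():
        raise ValueError(
            f"constant signal in parcel(s) {np.flatnonzero(degenerate).tolist()}: "
            "instantaneous phase undefined"
        )
    return hilbert(centred, axis=-1)


def wpli_trial(zx: np.ndarray, zy: np.ndarray) -> float:
    """Single-trial wPLI between two analytic signals.

    Returns 0 by convention when the imaginary cross-spectrum vanishes
    identically (e.g. identical signals), which is logged: the PLI family
    is blind to zero-lag coupling by construction.
    """
    zx = np.asarray(zx, dtype=complex)
    zy = np.asarray(zy, dtype=complex)
    if zx.shape != zy.shape:
        raise ValueError("signal length mismatch")
    s = zx * np.conj(zy)
    im = np.imag(s)
    denom = np.abs(im).sum()
    # a denominator at roundoff level relative to |S| means Im S == 0
    # analytically (zero-lag coupling), to which the PLI family is blind
    if denom <= 1e-12 * np.abs(s).sum():
        logger.debug("wPLI denominator zero (no imaginary cross-spectrum); returning 0")
        return 0.0
    return float(abs(im.sum()) / denom)


def wpli_adjacency(ts: ParcelTimeSeries) -> AdjacencyMatrix:
    """Trial-averaged wPLI adjacency for a band-filtered time series.

    Entry (i, j) is the arithmetic mean over trials of the single-trial
    wPLI between parcels i and j. Broadband input is rejected: the
    estimator is only meaningful on narrowband signals.
    """
    if ts.band_label == BROADBAND:
        raise ValueError("wPLI requires band-filtered input, got broadband")
    if ts.n_trials < 1:
        raise ValueError("need at least one trial")
    p = ts.n_parcels
    acc = np.zeros((p, p))
    for trial in ts.data:
        z = analytic_phase(trial)
        abs_z = np.abs(z)
        # row-by-row to bound memory at O(p n) even for 90-parcel data
        for i in range(p - 1):
            im = np.imag(z[i] * np.conj(z[i + 1 :]))
            num = np.abs(im.sum(axis=-1))
            den = np.abs(im).sum(axis=-1)
            floor = 1e-12 * (abs_z[i] * abs_z[i + 1 :]).sum(axis=-1)
            w = np.where(den > floor, num / np.maximum(den, 1e-300), 0.0)
            acc[i, i + 1 :] += w
    avg = acc / ts.n_trials
    avg = avg + avg.T
    return AdjacencyMatrix(values=avg, band=ts.band_label, subject_id=ts.subject_id)


def grand_average(matrices: list[AdjacencyMatrix]) -> AdjacencyMatrix:
    """Element-wise mean of same-band, same-shape adjacency matrices."""
    if not matrices:
        raise ValueError("empty collection")
    band = matrices[0].band
    shape = matrices[0].values.shape
    for m in matrices:
        if m.band != band:
            raise ValueError(f"mixed bands: {m.band} vs {band}")
        if m.values.shape != shape:
            raise ValueError("mixed adjacency shapes")
    mean = np.mean([m.values for m in matrices], axis=0)
    return AdjacencyMatrix(values=mean, band=band, subject_id="grand_average")


def top_percentile_edges(adj: AdjacencyMatrix, percentile: float = 95.0) -> np.ndarray:
    """Upper-triangle edges whose weight strictly exceeds the nearest-rank percentile.

    Returns a structured-free (k, 3) float array of rows ``(i, j, weight)``
    with i < j (0-based). Nearest-rank convention: the threshold is the
    ``ceil(q/100 * m)``-th smallest of the m upper-triangle weights; ties at
    the threshold are excluded (strict exceedance). An all-zero matrix
    yields an empty list, which is logged.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    iu, ju = np.triu_indices(adj.n_parcels, k=1)
    w = adj.values[iu, ju]
    m = w.size
    rank = int(np.ceil(percentile / 100.0 * m))
    thr = np.sort(w)[rank - 1]
    keep = w > thr
    if not keep.any():
        logger.info("top_percentile_edges: no edges exceed the percentile threshold")
    return np.column_stack([iu[keep], ju[keep], w[keep]]).astype(float)
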