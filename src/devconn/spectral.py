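"""Band filtering, Welch PSD, band power, and age-correlation maps.

Signals are filtered into the four canonical bands (theta 4-7 Hz, alpha
8-14 Hz, beta 15-30 Hz, gamma 31-80 Hz) with a zero-phase 4th-order
Butterworth. Per-trial PSDs are estimated on mean-centred signals with
Welch's method and averaged across trials; band power is the mean PSD
over the bins inside a band (closed interval on both edges). Regional
band power is then correlated with age across subjects, with a
significance cutoff expressed on the r scale via the t distribution:
``r_threshold(n, t) = t / sqrt((n - 2) + t**2)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import BROADBAND, ParcelTimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")


#: Canonical band definitions.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 14.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 80.0),
}


@dataclass
class PsdSpectrum:
    """Trial-averaged power spectral density, ``power[parcel, frequency]``."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


def _design_bandpass(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.f_hi >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {nyq} Hz"
        )
    return signal.butter(order, (band.f_lo, band.f_hi), btype="bandpass", fs=fs, output="sos")


def bandpass_filter(ts: ParcelTimeSeries, band: BandDefinition) -> ParcelTimeSeries:
    """Zero-phase band-pass filter into ``band`` (forward-backward Butterworth).

    Zero-phase application matters downstream: the wPLI estimator works on
    instantaneous phases, which a causal filter's group delay would skew.
    """
    sos = _design_bandpass(band, ts.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, ts.data, axis=-1)
    return ts.with_data(filtered, band_label=band.name)


def trial_psd_welch(
    ts: ParcelTimeSeries,
    nperseg: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hamming",
) -> PsdSpectrum:
    """Welch PSD per trial on mean-centred signals, averaged across trials.

    Default segmentation is eight segments with 50% overlap and a Hamming
    taper (``nperseg = floor(n_samples / 4.5)``), the conventional default
    of Welch routines; override via ``nperseg``/``overlap_fraction``/
    ``window``.
    """
    if ts.n_trials < 1:
        raise ValueError("need at least one trial")
    n = ts.n_samples
    if nperseg is None:
        nperseg = int(n // 4.5)
    if nperseg < 2 or nperseg > n:
        raise ValueError(f"Welch segment length {nperseg} invalid for {n} samples")
    noverlap = int(nperseg * overlap_fraction)
    centred = ts.data - ts.data.mean(axis=-1, keepdims=True)
    freqs, pxx = signal.welch(
        centred,
        fs=ts.sampling_rate_hz,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        axis=-1,
    )
    return PsdSpectrum(frequencies=freqs, power=pxx.mean(axis=0))


def band_average_psd(spec: PsdSpectrum, band: BandDefinition) -> np.ndarray:
    """Mean PSD over grid frequencies f with ``f_lo <= f <= f_hi``, per parcel."""
    mask = (spec.frequencies >= band.f_lo) & (spec.frequencies <= band.f_hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return spec.power[..., mask].mean(axis=-1)


def r_threshold(n: int, t_crit: float) -> float:
    """Pearson-r magnitude corresponding to a t cutoff at ``n - 2`` df.

    Inverts ``t = r sqrt(n-2) / sqrt(1-r^2)``; e.g. with n=324 subjects and
    t=3.5 the regional-significance cutoff is r ~= 0.19.
    """
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    if t_crit < 0:
        raise ValueError("t_crit must be non-negative")
    return t_crit / np.sqrt((n - 2) + t_crit**2)


@dataclass
class CorrelationMap:
    """Per-parcel Pearson correlation of band power with age."""

    r: np.ndarray
    n: int
    t_equiv: np.ndarray
    significant: np.ndarray

    def to_frame(self, band: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": band,
                "parcel": np.arange(1, len(self.r) + 1),
                "r": self.r,
                "t": self.t_equiv,
                "significant": self.significant,
            }
        )


def age_correlation_map(
    band_power: np.ndarray, cohort: pd.DataFrame, t_crit: float = 3.5
) -> CorrelationMap:
    """Pearson correlation of per-parcel power with age across subjects.

    ``band_power`` rows must align with cohort rows. A parcel with zero
    power variance has undefined r; it is reported as NaN (never a silent
    zero) with a warning, and flagged non-significant.
    """
    power = np.asarray(band_power, dtype=float)
    ages = np.asarray(cohort["age_years"], dtype=float)
    n = len(ages)
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation map")
    if power.shape[0] != n:
        raise ValueError("band_power rows must align with the cohort table")

    ac = ages - ages.mean()
    pc = power - power.mean(axis=0)
    sd_a = np.sqrt((ac**2).sum())
    sd_p = np.sqrt((pc**2).sum(axis=0))
    degenerate = sd_p == 0
    if sd_a == 0:
        raise ValueError("ages have zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ pc) / (sd_a * sd_p)
        r = np.clip(r, -1.0, 1.0)
        r[degenerate] = np.nan
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} parcel(s) with zero power variance: r undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    thr = r_threshold(n, t_crit)
    significant = np.abs(r) >= thr
    significant[degenerate] = False
    return CorrelationMap(r=r, n=n, t_equiv=t, significant=significant)


def subject_band_power_table(
    spectra: dict[str, PsdSpectrum], bands: dict[str, BandDefinition]
) -> pd.DataFrame:
    """Long-format band-power table: ``subject_id, band, parcel, power``."""
    rows = []
    for subject_id, spec in spectra.items():
        for band in bands.values():
            bp = band_average_psd(spec, band)
            for parcel, p in enumerate(bp, start=1):
                rows.append((subject_id, band.name, parcel, p))
    return pd.DataFrame(rows, columns=["subject_id", "band", "parcel", "power"])
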