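"""Synthetic cohorts and parcel-level oscillatory time series.

The study-scale recordings this pipeline was designed for (parcellated
resting-state neural signals across a 6-45 year cohort) are not publicly
deposited, so this module generates surrogates with *known* ground
truth: narrowband oscillations in canonical frequency bands, pairwise
phase-lagged coupling whose strength follows a configured linear,
quadratic or logarithmic function of age, age-dependent spectral power,
additive broadband noise, and age-dependent trial attrition.

Narrowband sources are white noise band-filtered into the target band
(not pure sinusoids), so the wPLI estimator sees realistic phase jitter
rather than degenerate 0/1 values. Phase-lagged copies are produced by
a frequency-domain fractional-sample delay sized to the requested lag at
the band's centre frequency; the lag must avoid 0 and pi, which are
invisible to the wPLI by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .containers import BROADBAND, ParcelTimeSeries, validate_cohort
from .spectral import DEFAULT_BANDS, BandDefinition, _design_bandpass
from .trajectories import MODEL_KINDS, TrajectoryModel, predict


def generate_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (6.0, 45.0),
    sex_ratio: float = 0.5,
    seed: int = 0,
    n_trials: int = 20,
) -> pd.DataFrame:
    """Generate a cohort table with ages uniform on ``age_range``.

    ``sex_ratio`` is the expected female fraction. Trial counts are
    constant here; age-dependent attrition is applied separately by
    :func:`apply_trial_attrition`.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"inverted age range ({lo}, {hi})")
    if not 0 <= sex_ratio <= 1:
        raise ValueError("sex_ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n_subjects)
    sex = np.where(rng.random(n_subjects) < sex_ratio, "female", "male")
    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_subjects)],
            "age_years": ages,
            "sex": sex,
            "n_trials": n_trials,
        }
    )
    return validate_cohort(cohort)


@dataclass(frozen=True)
class CouplingSpec:
    """Phase-lagged coupling between one parcel pair in one band.

    ``kind``/``coefficients`` define the trajectory k(age) of the mixing
    weight, evaluated through the same model family the fitting engine
    estimates and clipped into [0, 1].
    """

    pair: tuple[int, int]
    band: str
    kind: str
    coefficients: tuple

    def strength(self, age: float) -> float:
        model = TrajectoryModel(kind=self.kind, coefficients=self.coefficients)
        return float(np.clip(predict(model, np.asarray([age]))[0], 0.0, 1.0))


@dataclass(frozen=True)
class PowerTrend:
    """Linear per-year fractional amplitude trend for one parcel and band."""

    parcel: int
    band: str
    slope: float


@dataclass
class GroundTruthConfig:
    """Everything the generator needs to emit a subject's signals."""

    bands: tuple[str, ...] = ("theta", "alpha")
    couplings: tuple[CouplingSpec, ...] = ()
    power_trends: tuple[PowerTrend, ...] = ()
    # default noise keeps the wPLI estimator in its realistic mid-range:
    # broadband SD 3 against unit-SD narrowband sources puts uncoupled pairs
    # near the estimator's null level and full coupling near ~0.9 rather
    # than a saturated 1.0
    noise_sd: float = 3.0
    phase_lag: float = np.pi / 4
    trial_length_s: float = 10.0
    sampling_rate_hz: float = 600.0
    age_ref_years: float = 6.0
    band_definitions: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.phase_lag < np.pi:
            raise ValueError(
                "phase_lag must lie strictly inside (0, pi): zero-lag and "
                "antiphase coupling are invisible to the wPLI"
            )
        for name in self.bands:
            if name not in self.band_definitions:
                raise ValueError(f"band {name!r} has no definition")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length_s * self.sampling_rate_hz))

    def amplitude(self, parcel: int, band: str, age: float) -> float:
        amp = 1.0
        for trend in self.power_trends:
            if trend.parcel == parcel and trend.band == band:
                amp = 1.0 + trend.slope * (age - self.age_ref_years)
        return max(amp, 0.05)


def _narrowband(white: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Band-filter white noise and standardise each signal to unit SD."""
    sos = _design_bandpass(band, fs)
    nb = _signal.sosfiltfilt(sos, white, axis=-1)
    nb = nb - nb.mean(axis=-1, keepdims=True)
    sd = nb.std(axis=-1, keepdims=True)
    return nb / np.maximum(sd, 1e-12)


def _fractional_delay(sig: np.ndarray, delay_s: float, fs: float) -> np.ndarray:
    """Delay signals along the last axis by ``delay_s`` via the frequency domain."""
    n = sig.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shift = np.exp(-2j * np.pi * freqs * delay_s)
    return np.fft.irfft(np.fft.rfft(sig, axis=-1) * shift, n=n, axis=-1)


def synth_subject_timeseries(
    cohort_row,
    truth: GroundTruthConfig,
    n_parcels: int,
    n_trials: int | None = None,
    seed: int = 0,
) -> ParcelTimeSeries:
    """Generate one subject's trials x parcels x samples array.

    Per band, every parcel receives an independent unit-SD narrowband
    source scaled by its power trend at this subject's age. For each
    coupled pair (i, j), parcel j's band content is replaced by the
    mixture ``k * delayed(source_i) + (1 - k) * own_source`` where the
    delay realises the configured phase lag at the band's centre
    frequency and k = k(age) clipped to [0, 1]. Broadband Gaussian noise
    with SD ``truth.noise_sd`` is added everywhere.
    """
    age = float(cohort_row["age_years"])
    if n_trials is None:
        n_trials = int(cohort_row["n_trials"])
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    for spec in truth.couplings:
        if max(spec.pair) >= n_parcels:
            raise ValueError(
                f"coupling references parcel {max(spec.pair)} >= n_parcels {n_parcels}"
            )
    fs = truth.sampling_rate_hz
    n = truth.n_samples
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_parcels, n)) * truth.noise_sd
    for band_name in truth.bands:
        band = truth.band_definitions[band_name]
        white = rng.standard_normal((n_trials, n_parcels, n))
        sources = _narrowband(white, band, fs)
        band_content = sources.copy()
        f_c = 0.5 * (band.f_lo + band.f_hi)
        delay_s = truth.phase_lag / (2.0 * np.pi * f_c)
        for spec in truth.couplings:
            if spec.band != band_name:
                continue
            i, j = spec.pair
            k = spec.strength(age)
            delayed = _fractional_delay(sources[:, i, :], delay_s, fs)
            band_content[:, j, :] = k * delayed + (1.0 - k) * sources[:, j, :]
        amps = np.array(
            [truth.amplitude(p, band_name, age) for p in range(n_parcels)]
        )
        data += amps[np.newaxis, :, np.newaxis] * band_content
    return ParcelTimeSeries(
        subject_id=str(cohort_row["subject_id"]),
        data=data,
        sampling_rate_hz=fs,
        band_label=BROADBAND,
    )


def synth_cohort_timeseries(
    cohort: pd.DataFrame,
    truth: GroundTruthConfig,
    n_parcels: int,
    seed: int = 0,
) -> dict[str, ParcelTimeSeries]:
    """Generate time series for every cohort row, one child seed per subject."""
    validate_cohort(cohort)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    out = {}
    for child, (_, row) in zip(children, cohort.iterrows()):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        ts = synth_subject_timeseries(row, truth, n_parcels, seed=sub_seed)
        out[ts.subject_id] = ts
    return out


def apply_trial_attrition(
    ts: ParcelTimeSeries, age_years: float, attrition_rule, seed: int = 0
) -> ParcelTimeSeries:
    """Randomly drop trials so the count follows ``attrition_rule(age)``.

    Emulates age-dependent data loss (younger subjects move more, so more
    of their trials are rejected). The retained trials are a random
    subset with original order preserved; a rule asking for more trials
    than exist is a no-op.
    """
    target = int(round(float(attrition_rule(age_years))))
    if target < 1:
        raise ValueError(f"attrition rule yields {target} trials at age {age_years}")
    if target >= ts.n_trials:
        return ts
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(ts.n_trials, size=target, replace=False))
    return ts.with_data(ts.data[keep])


def example_truth(
    n_parcels: int = 10,
    bands: tuple[str, ...] = ("theta", "alpha"),
    coupling_kind: str = "logarithmic",
    noise_sd: float = 3.0,
) -> GroundTruthConfig:
    """A ready-made ground truth: one strongly coupled pair per band.

    Coupling weights are kept inside k ~ 0.1-0.6, the zone where the
    measured wPLI responds roughly linearly to the mixing weight; above
    that the estimator saturates toward 1 and would flatten whatever
    trajectory shape is configured. The default logarithmic form
    k(age) = 0.28*log10(age - 5) + 0.10 rises steeply through childhood
    (0.10 at age 6) and plateaus near 0.55 by age 45. The second parcel
    of each band's pair also carries a +2%/year power trend so the PSD
    branch has a known positive age correlation to find.
    """
    if coupling_kind == "logarithmic":
        coeffs = (0.28, 1.0, -5.0, 0.10)
    elif coupling_kind == "quadratic":
        # inverted U: vertex at (30, 0.6), k(6) ~ 0.15, k(45) ~ 0.42
        coeffs = (-0.00078, 0.0468, -0.102)
    elif coupling_kind == "linear":
        coeffs = (0.012, 0.03)
    else:
        raise ValueError(f"unknown kind {coupling_kind!r}")
    couplings = []
    trends = []
    for b, band in enumerate(bands):
        pair = ((2 * b) % n_parcels, (2 * b + 1) % n_parcels)
        couplings.append(
            CouplingSpec(pair=pair, band=band, kind=coupling_kind, coefficients=coeffs)
        )
        trends.append(PowerTrend(parcel=pair[1], band=band, slope=0.02))
    return GroundTruthConfig(
        bands=bands,
        couplings=tuple(couplings),
        power_trends=tuple(trends),
        noise_sd=noise_sd,
    )
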