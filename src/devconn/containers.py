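"""Core data containers shared across the pipeline.

The pipeline operates on three kinds of objects: a cohort table (one row
per subject: identifier, age in years, sex, trial count), per-subject
parcellated time series (trials x parcels x samples at a known sampling
rate), and per-subject, per-band symmetric wPLI adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Column order for cohort CSV files.
COHORT_COLUMNS = ("subject_id", "age_years", "sex", "n_trials")

#: Label used for unfiltered (full-bandwidth) signals.
BROADBAND = "broadband"


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table and return it unchanged.

    Requires the four standard columns, unique subject ids, strictly
    positive ages and trial counts, and sex labels in {female, male}.
    """
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["subject_id"].duplicated().any():
        raise ValueError("cohort subject_ids are not unique")
    if not (cohort["age_years"] > 0).all():
        raise ValueError("ages must be positive")
    if not (cohort["n_trials"] >= 1).all():
        raise ValueError("trial counts must be >= 1")
    bad_sex = set(cohort["sex"].unique()) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"unrecognised sex labels: {sorted(bad_sex)}")
    return cohort


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table from CSV (``subject_id,age_years,sex,n_trials``)."""
    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort)
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


@dataclass
class ParcelTimeSeries:
    """Per-subject parcellated signals: ``data[trial, parcel, sample]``.

    ``band_label`` is :data:`BROADBAND` for unfiltered data, or a band
    name (e.g. ``"alpha"``) after band-pass filtering.
    """

    subject_id: str
    data: np.ndarray
    sampling_rate_hz: float
    band_label: str = BROADBAND

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x parcels x samples, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, band_label: str | None = None) -> "ParcelTimeSeries":
        return replace(
            self,
            data=data,
            band_label=self.band_label if band_label is None else band_label,
        )


@dataclass
class AdjacencyMatrix:
    """Symmetric parcels x parcels matrix of trial-averaged wPLI values."""

    values: np.ndarray
    band: str
    subject_id: str = "grand_average"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("wPLI adjacency entries must lie in [0, 1]")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]
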