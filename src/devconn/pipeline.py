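"""End-to-end orchestration: config, confound control, I/O, and the full run.

The pipeline ties the stages together in the order the analysis
prescribes: trial balancing against age-related attrition, band-pass
filtering, then two branches — a spectral branch (Welch PSD, band power,
age-correlation maps) and a connectivity branch (wPLI adjacency, node
strength, global efficiency, cross-validated curve selection,
permutation inference, FDR control, gradients, and model SD). Every
stochastic stage consumes a named child seed derived from one master
seed, so a run is fully reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import (
    BROADBAND,
    AdjacencyMatrix,
    ParcelTimeSeries,
    validate_cohort,
    write_cohort_csv,
)
from .graphmetrics import global_efficiency, inverse_length, node_strength, shortest_path_lengths
from .phasesync import wpli_adjacency
from .spectral import (
    DEFAULT_BANDS,
    BandDefinition,
    age_correlation_map,
    band_average_psd,
    bandpass_filter,
    trial_psd_welch,
)
from .trajectories import (
    MODEL_KINDS,
    bh_fdr,
    curve_gradient,
    cv_select_model,
    model_sd,
    permutation_pvalue,
)

logger = logging.getLogger(__name__)

_STAGE_SEEDS = ("simulate", "balance", "cv", "permutation")


@dataclass
class PipelineConfig:
    """Tunable parameters of a full analysis run."""

    bands: tuple[str, ...] = ("theta", "alpha")
    band_definitions: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    sampling_rate_hz: float = 600.0
    trial_length_s: float = 10.0
    n_cv_iterations: int = 1000
    n_permutations: int = 15000
    fdr_q: float = 0.05
    t_crit: float = 3.5
    balance_age_cutoff_years: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cv_iterations < 1 or self.n_permutations < 1:
            raise ValueError("iteration counts must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGE_SEEDS))
        return {
            name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(_STAGE_SEEDS, children)
        }

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["band_definitions"] = {
            k: [v.f_lo, v.f_hi] for k, v in self.band_definitions.items()
        }
        d["bands"] = list(self.bands)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band_definitions" in d:
            d["band_definitions"] = {
                k: BandDefinition(k, *v) for k, v in d["band_definitions"].items()
            }
        if "bands" in d:
            d["bands"] = tuple(d["bands"])
        return cls(**d)


def balance_trials(
    cohort_ts: dict[str, ParcelTimeSeries],
    cohort: pd.DataFrame,
    cutoff_years: float = 11.0,
    seed: int = 0,
) -> tuple[dict[str, ParcelTimeSeries], pd.DataFrame]:
    """Equalise trial counts against age-related attrition.

    The threshold is the rounded mean trial count among subjects younger
    than ``cutoff_years``; every subject with more trials keeps a random
    subset of exactly that many (original order preserved), so the
    amount of data entering the analysis no longer correlates with age.
    """
    validate_cohort(cohort)
    young = cohort["age_years"] < cutoff_years
    if not young.any():
        raise ValueError(
            f"no subjects under {cutoff_years} years: balancing threshold undefined"
        )
    counts = np.array([cohort_ts[s].n_trials for s in cohort["subject_id"]])
    threshold = int(round(counts[np.asarray(young)].mean()))
    rng = np.random.default_rng(seed)
    out_ts = {}
    new_counts = []
    for sid, n in zip(cohort["subject_id"], counts):
        ts = cohort_ts[sid]
        if n > threshold:
            keep = np.sort(rng.choice(n, size=threshold, replace=False))
            ts = ts.with_data(ts.data[keep])
        out_ts[sid] = ts
        new_counts.append(ts.n_trials)
    new_cohort = cohort.copy()
    new_cohort["n_trials"] = new_counts
    logger.info("balance_trials: threshold %d trials (cutoff %.1f y)", threshold, cutoff_years)
    return out_ts, new_cohort


@dataclass
class ResultsBundle:
    """All tables produced by one pipeline run."""

    cohort: pd.DataFrame
    band_power: pd.DataFrame
    correlation_maps: pd.DataFrame
    adjacency: dict
    metrics_strength: pd.DataFrame
    metrics_ge: pd.DataFrame
    fits: pd.DataFrame
    gradients: pd.DataFrame
    manifest: dict


def _fit_one(x, y, config: PipelineConfig, cv_seed: int, perm_seed: int, age_grid):
    sel = cv_select_model(x, y, n_iterations=config.n_cv_iterations, seed=cv_seed)
    inf = permutation_pvalue(
        sel.selected_kind, x, y, n_permutations=config.n_permutations, seed=perm_seed
    )
    grad = curve_gradient(inf.model, age_grid)
    sd = model_sd(inf.model, age_grid)
    return sel, inf, grad, sd


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame,
    cohort_ts: dict[str, ParcelTimeSeries],
    out_dir=None,
) -> ResultsBundle:
    """Execute the full analysis on a cohort of parcellated time series.

    Stages: balance -> band-pass -> {PSD branch, connectivity branch} ->
    curve fitting with permutation inference and BH-FDR across parcels
    within each band. If ``out_dir`` is given, all tables, the adjacency
    store, and a manifest are written there.
    """
    t0 = time.time()
    validate_cohort(cohort)
    seeds = config.stage_seeds()
    subjects = list(cohort["subject_id"])
    ages = np.asarray(cohort["age_years"], dtype=float)
    age_grid = np.arange(np.floor(ages.min()), np.floor(ages.max()) + 1)

    cohort_ts, cohort = balance_trials(
        cohort_ts, cohort, config.balance_age_cutoff_years, seed=seeds["balance"]
    )
    logger.info("stage=balance elapsed=%.1fs seed=%d", time.time() - t0, seeds["balance"])

    n_parcels = cohort_ts[subjects[0]].n_parcels
    bands = {name: config.band_definitions[name] for name in config.bands}

    # --- spectral branch ---
    bp_rows = []
    for sid in subjects:
        spec = trial_psd_welch(cohort_ts[sid])
        for band in bands.values():
            power = band_average_psd(spec, band)
            for parcel, p in enumerate(power, start=1):
                bp_rows.append((sid, band.name, parcel, p))
    band_power = pd.DataFrame(bp_rows, columns=["subject_id", "band", "parcel", "power"])
    corr_frames = []
    for band in bands.values():
        mat = (
            band_power[band_power["band"] == band.name]
            .pivot(index="subject_id", columns="parcel", values="power")
            .loc[subjects]
            .to_numpy()
        )
        cmap = age_correlation_map(mat, cohort, t_crit=config.t_crit)
        corr_frames.append(cmap.to_frame(band.name))
    correlation_maps = pd.concat(corr_frames, ignore_index=True)
    logger.info("stage=psd elapsed=%.1fs", time.time() - t0)

    # --- connectivity branch ---
    adjacency: dict[tuple[str, str], AdjacencyMatrix] = {}
    strength_rows, ge_rows = [], []
    for band in bands.values():
        for sid in subjects:
            filtered = bandpass_filter(cohort_ts[sid], band)
            adj = wpli_adjacency(filtered)
            adjacency[(sid, band.name)] = adj
            strength = node_strength(adj)
            ge = global_efficiency(shortest_path_lengths(inverse_length(adj)))
            for parcel, s in enumerate(strength, start=1):
                strength_rows.append((sid, band.name, parcel, s))
            ge_rows.append((sid, band.name, ge))
        logger.info("stage=connectivity band=%s elapsed=%.1fs", band.name, time.time() - t0)
    metrics_strength = pd.DataFrame(
        strength_rows, columns=["subject_id", "band", "parcel", "strength"]
    )
    metrics_ge = pd.DataFrame(ge_rows, columns=["subject_id", "band", "global_efficiency"])

    # --- trajectory fitting ---
    cv_ss = np.random.SeedSequence(seeds["cv"]).spawn(len(bands) * (n_parcels + 1))
    pm_ss = np.random.SeedSequence(seeds["permutation"]).spawn(len(bands) * (n_parcels + 1))
    cv_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in cv_ss]
    pm_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in pm_ss]
    fit_rows, grad_rows = [], []
    s_i = 0
    for band in bands.values():
        strength_mat = (
            metrics_strength[metrics_strength["band"] == band.name]
            .pivot(index="subject_id", columns="parcel", values="strength")
            .loc[subjects]
            .to_numpy()
        )
        band_p = []
        band_records = []
        for parcel in range(n_parcels):
            sel, inf, grad, sd = _fit_one(
                ages, strength_mat[:, parcel], config, cv_seeds[s_i], pm_seeds[s_i], age_grid
            )
            s_i += 1
            band_p.append(inf.p_perm)
            band_records.append((f"{parcel + 1}", sel, inf, grad, sd))
        # GE: one curve per band, FDR'd across bands afterwards
        ge_y = (
            metrics_ge[metrics_ge["band"] == band.name]
            .set_index("subject_id")
            .loc[subjects, "global_efficiency"]
            .to_numpy()
        )
        sel, inf, grad, sd = _fit_one(ages, ge_y, config, cv_seeds[s_i], pm_seeds[s_i], age_grid)
        s_i += 1
        band_records.append(("GE", sel, inf, grad, sd))
        significant = bh_fdr(np.asarray(band_p), q=config.fdr_q)
        for rec_i, (parcel_label, sel, inf, grad, sd) in enumerate(band_records):
            is_ge = parcel_label == "GE"
            q_sig = bool(significant[rec_i]) if not is_ge else bool(inf.p_perm < config.fdr_q)
            coeffs = dict.fromkeys(
                ("a1", "a2", "b1", "b2", "b3", "c1", "c2", "c3", "c4"), np.nan
            )
            keys = {
                "linear": ("a1", "a2"),
                "quadratic": ("b1", "b2", "b3"),
                "logarithmic": ("c1", "c2", "c3", "c4"),
            }[inf.model.kind]
            for key, val in zip(keys, inf.model.coefficients):
                coeffs[key] = val
            fit_rows.append(
                {
                    "band": band.name,
                    "parcel": parcel_label,
                    "selected_model": inf.model.kind,
                    **coeffs,
                    "median_residual_linear": sel.median_residuals["linear"],
                    "median_residual_quadratic": sel.median_residuals["quadratic"],
                    "median_residual_log": sel.median_residuals["logarithmic"],
                    "F": inf.F_obs,
                    "p_perm": inf.p_perm,
                    "q_significant": q_sig,
                    "model_sd": sd,
                }
            )
            for year, g in zip(age_grid, grad):
                grad_rows.append((band.name, parcel_label, int(year), g))
        logger.info("stage=fit band=%s elapsed=%.1fs", band.name, time.time() - t0)

    fits = pd.DataFrame(fit_rows)
    gradients = pd.DataFrame(grad_rows, columns=["band", "parcel", "age_year", "gradient"])
    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stage_seeds": seeds,
        "n_subjects": len(subjects),
        "n_parcels": n_parcels,
        "elapsed_s": round(time.time() - t0, 2),
        "complete": True,
    }
    bundle = ResultsBundle(
        cohort=cohort,
        band_power=band_power,
        correlation_maps=correlation_maps,
        adjacency=adjacency,
        metrics_strength=metrics_strength,
        metrics_ge=metrics_ge,
        fits=fits,
        gradients=gradients,
        manifest=manifest,
    )
    if out_dir is not None:
        write_results(bundle, out_dir)
    return bundle


def _fmt_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results(bundle: ResultsBundle, out_dir) -> None:
    """Write all result tables, the adjacency store, and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(bundle.cohort, out / "cohort.csv")
    _fmt_table(bundle.band_power, out / "band_power.tsv")
    _fmt_table(bundle.correlation_maps, out / "correlation_maps.tsv")
    _fmt_table(bundle.metrics_strength, out / "strength.tsv")
    _fmt_table(bundle.metrics_ge, out / "global_efficiency.tsv")
    _fmt_table(bundle.fits, out / "fits.tsv")
    _fmt_table(bundle.gradients, out / "gradients.tsv")
    with h5py.File(out / "adjacency.h5", "w") as f:
        for (sid, band), adj in bundle.adjacency.items():
            ds = f.create_dataset(f"{sid}/{band}", data=adj.values)
            ds.attrs["band"] = band
            ds.attrs["subject_id"] = sid
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))


def save_timeseries_h5(cohort_ts: dict[str, ParcelTimeSeries], path) -> None:
    """Store per-subject time series: one HDF5 group per subject."""
    with h5py.File(path, "w") as f:
        for sid, ts in cohort_ts.items():
            ds = f.create_dataset(f"{sid}/data", data=ts.data)
            ds.attrs["sampling_rate_hz"] = ts.sampling_rate_hz
            ds.attrs["band_label"] = ts.band_label


def load_timeseries_h5(path) -> dict[str, ParcelTimeSeries]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            ds = f[sid]["data"]
            out[sid] = ParcelTimeSeries(
                subject_id=sid,
                data=ds[()],
                sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                band_label=str(ds.attrs["band_label"]),
            )
    return out


def export_visualisation(
    adj: AdjacencyMatrix,
    labels: list[str],
    out_prefix,
    percentile: float = 95.0,
    coordinates: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write glass-brain-viewer style ``.node``/``.edge`` plain-text files.

    The ``.edge`` file is the dense adjacency thresholded at the given
    percentile (sub-threshold entries zeroed); the ``.node`` file lists
    one row per parcel: x y z colour size label, with node size set to
    strength and colour to the node index.
    """
    from .phasesync import top_percentile_edges

    if len(labels) != adj.n_parcels:
        raise ValueError(
            f"{len(labels)} labels for {adj.n_parcels} parcels"
        )
    edges = top_percentile_edges(adj, percentile)
    dense = np.zeros_like(adj.values)
    for i, j, w in edges:
        dense[int(i), int(j)] = dense[int(j), int(i)] = w
    out_prefix = Path(out_prefix)
    edge_path = out_prefix.with_suffix(".edge")
    node_path = out_prefix.with_suffix(".node")
    np.savetxt(edge_path, dense, fmt="%.10g", delimiter="\t")
    if coordinates is None:
        coordinates = np.zeros((adj.n_parcels, 3))
    strength = node_strength(adj)
    with open(node_path, "w") as f:
        for p in range(adj.n_parcels):
            x, y, z = coordinates[p]
            f.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{p + 1}\t{strength[p]:.6g}\t{labels[p]}\n")
    return node_path, edge_path


def read_edge_file(path) -> np.ndarray:
    """Parse a dense ``.edge`` matrix back into an array."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)
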