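"""End-to-end pipeline: simulate/load -> preprocess -> spectra -> coherent
sources per band -> directed connectivity -> behavioral prediction.

A single validated configuration drives every stage; all stage artifacts and
a provenance record (parameters, package versions, per-subject seeds, content
hashes) are written to the output directory.  The public entry points are
:func:`run_pipeline` for cohorts and :func:`analyze_subject` for one
recording.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__ as _pkg_version
from .beamform import CoherentSourceSet, find_coherent_sources
from .connectivity import (ConnectivityGraph, DualEKFSettings, TPDCResult,
                           band_tpdc, bootstrap_significance, build_graph,
                           dual_ekf, select_order, time_reversal_check, tpdc)
from .forward import HeadModel, LeadField, build_grid, compute_leadfield
from .predict import (assemble_features, correlate_with_timing, svm_predict,
                      validate_scores)
from .preprocess import Recording, run_preprocessing
from .simulate import CohortConfig, fibonacci_sensors, make_dataset
from .spectral import band_power, epochs_tf, get_band

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


class ConfigError(PipelineError):
    exit_code = 2


class DataError(PipelineError):
    exit_code = 3


class NumericalError(PipelineError):
    exit_code = 4


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 25
    duration: float = 120.0
    srate: float = 1024.0
    n_sensors: int = 128
    snr_db: float = 10.0
    score_noise_sd: float = 3.0


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_cut: float = 0.5
    high_cut: float = 300.0
    filter_order: int = 4
    notch_freqs: list = Field(default_factory=lambda: [60.0, 120.0, 180.0])
    epoch_length: float = 1.0
    run_ica: bool = True
    interpolate_residual: bool = True


class SpectralSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nw: float = 2.0
    k_tapers: int = 3
    window_length: float = 1.0
    step: float = 0.05


class SourceSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_spacing: float = 5.0
    regularization: float = 0.05
    n_max: int = 4
    n_permutations: int = 1000
    percentile: float = 99.0
    bands: list = Field(default_factory=lambda: ["alpha", "beta", "gamma"])


class ConnectivitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    order: int | None = 5           # None -> information-criterion scan
    estimator: str = "ekf"
    q: float = 1e-4
    warmup: float = 2.0
    n_bootstrap: int = 1000
    bootstrap_window: float = 1.0
    threshold_reduction: str = "percentile"
    threshold_percentile: float = 99.0
    decimate: int = 4
    run_trt: bool = True


class PredictionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "classification"
    scheme: str = "repeated-75/25"
    n_splits: int = 5
    gamma: float = 0.25
    targets: list = Field(default_factory=lambda: ["group", "CELF"])


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str | None = None
    input_edf_paths: list | None = None
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    spectral: SpectralSection = Field(default_factory=SpectralSection)
    sources: SourceSection = Field(default_factory=SourceSection)
    connectivity: ConnectivitySection = Field(
        default_factory=ConnectivitySection)
    prediction: PredictionSection = Field(default_factory=PredictionSection)


def load_config(source) -> PipelineConfig:
    """Build a config from a YAML file path, YAML string, or dict."""
    import yaml

    try:
        if isinstance(source, dict):
            return PipelineConfig(**source)
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        payload = yaml.safe_load(text) or {}
        return PipelineConfig(**payload)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def read_eeg(path) -> Recording:
    """Read an EDF/BDF file as a Recording in microvolts."""
    from .io import read_edf

    try:
        return read_edf(path)
    except Exception as exc:
        raise DataError(f"failed to read EEG file {path}: {exc}") from exc


def read_montage(path):
    """Read SFP/ELC sensor positions (labels, (n, 3) mm array)."""
    from .io import read_montage as _rm

    try:
        return _rm(path)
    except Exception as exc:
        raise DataError(f"failed to read montage {path}: {exc}") from exc


def attach_montage(recording: Recording, labels, positions) -> Recording:
    """Match montage positions to the recording's channels by label.

    Unmatched channels are dropped with a warning; returns a new Recording.
    """
    lookup = {lb: i for i, lb in enumerate(labels)}
    keep, pos = [], []
    for ci, lb in enumerate(recording.channel_labels):
        if lb in lookup:
            keep.append(ci)
            pos.append(positions[lookup[lb]])
    missing = len(recording.channel_labels) - len(keep)
    if missing:
        logger.warning("%d channels have no montage position and were "
                       "dropped", missing)
    if not keep:
        raise DataError("no channels matched the montage")
    return Recording(data=recording.data[keep], srate=recording.srate,
                     channel_labels=[recording.channel_labels[i]
                                     for i in keep],
                     sensor_positions=np.asarray(pos, float))


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    band_power: pd.DataFrame
    source_sets: dict           # band -> CoherentSourceSet
    graphs: dict                # band -> ConnectivityGraph
    report: dict


@dataclass
class PipelineResult:
    subjects: list
    feature_table: object
    prediction_reports: dict
    timing_correlations: pd.DataFrame | None
    provenance: dict


def _decimate(signals: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return signals
    from scipy.signal import decimate as _dec

    return _dec(signals, factor, axis=-1, zero_phase=True)


def analyze_subject(
    recording: Recording,
    leadfield: LeadField,
    config: PipelineConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, dict, dict]:
    """Run preprocessing, spectra, source search and connectivity for one
    recording.  Returns (band_power table, source sets, graphs, report)."""
    pp, sp, so, co = (config.preprocess, config.spectral, config.sources,
                      config.connectivity)
    eps, ica_res, report = run_preprocessing(
        recording, low_cut=pp.low_cut, high_cut=pp.high_cut,
        filter_order=pp.filter_order, notch_freqs=tuple(pp.notch_freqs),
        epoch_length=pp.epoch_length, run_ica=pp.run_ica,
        interpolate_residual=pp.interpolate_residual, random_state=seed)
    tfr = epochs_tf(eps.data, eps.srate, NW=sp.nw, K=sp.k_tapers)
    bp = band_power(tfr)

    source_sets: dict = {}
    graphs: dict = {}
    srate_dec = eps.srate / co.decimate
    for band_name in so.bands:
        band = get_band(band_name)
        sset = find_coherent_sources(
            eps, band, leadfield, n_max=so.n_max, reg=so.regularization,
            n_perm=so.n_permutations, percentile=so.percentile,
            seed=seed, NW=sp.nw, K=sp.k_tapers)
        source_sets[band_name] = sset
        n_src = len(sset)
        if n_src < 2:
            graphs[band_name] = ConnectivityGraph(edges=[], n_nodes=n_src,
                                                  band=band_name)
            continue
        signals = np.stack([s.signal.data for s in sset.sources])
        signals = _decimate(signals, co.decimate)
        # deflation can leave later sources with signals nearly collinear
        # with earlier ones; such duplicates make the MVAR regression
        # rank-deficient and carry no extra connectivity information
        keep = [0]
        for i in range(1, signals.shape[0]):
            r = np.abs(np.corrcoef(signals[keep + [i]])[-1, :-1])
            if signals[i].std() > 0 and np.max(r) < 0.98:
                keep.append(i)
        if len(keep) < signals.shape[0]:
            logger.warning("dropping %d near-duplicate source signals in "
                           "band %s", signals.shape[0] - len(keep), band_name)
            signals = signals[keep]
        if signals.shape[0] < 2:
            graphs[band_name] = ConnectivityGraph(edges=[], n_nodes=n_src,
                                                  band=band_name)
            continue
        p = co.order or select_order(signals, p_max=15)
        try:
            settings = DualEKFSettings(q=co.q, warmup=co.warmup)
            if co.estimator == "ekf":
                model = dual_ekf(signals, p, srate_dec, settings)
                result = tpdc(model, band)
            else:
                mat = band_tpdc(signals, p, srate_dec, band,
                                estimator="static")
                result = TPDCResult(
                    pi=mat[:, :, None, None], freqs=np.zeros(1),
                    times=np.zeros(1), band=band, band_matrix=mat)
            thr = bootstrap_significance(
                signals, p, srate_dec, band, n_boot=co.n_bootstrap,
                window_length=co.bootstrap_window, seed=seed,
                estimator=co.estimator, settings=settings,
                reduction=co.threshold_reduction,
                percentile=co.threshold_percentile)
            trt = None
            if co.run_trt:
                trt = time_reversal_check(
                    signals, p, srate_dec, band, estimator=co.estimator,
                    settings=settings, seed=seed,
                    window_length=co.bootstrap_window,
                    n_boot_sd=min(50, co.n_bootstrap))
            g = build_graph(result, thr, trt)
            if len(keep) < n_src:
                # remap node ids back to the original source ranks
                from dicsnet.connectivity import Edge
                g = ConnectivityGraph(
                    edges=[Edge(source=keep[e.source], target=keep[e.target],
                                strength=e.strength,
                                significant=e.significant,
                                trt_pass=e.trt_pass,
                                bidirectional=e.bidirectional)
                           for e in g.edges],
                    n_nodes=n_src, band=band_name)
            graphs[band_name] = g
        except np.linalg.LinAlgError as exc:
            # residual collinearity after de-duplication: no identifiable
            # directed structure in this band
            logger.warning("connectivity degenerate in band %s (%s); "
                           "emitting an empty graph", band_name, exc)
            graphs[band_name] = ConnectivityGraph(edges=[], n_nodes=n_src,
                                                  band=band_name)
        except FloatingPointError as exc:
            raise NumericalError(
                f"connectivity failed in band {band_name}: {exc}") from exc
    return bp, source_sets, graphs, report


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | dict,
                 outdir: str | None = None) -> PipelineResult:
    """Execute the full pipeline on a synthetic cohort (or EDF inputs).

    Stage artifacts (band-power table, source peaks, edge lists, feature
    table, prediction report) and a provenance JSON are written to
    ``outdir`` when given.
    """
    if isinstance(config, dict):
        config = load_config(config)
    outdir = outdir or config.outdir
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    sim = config.simulate
    head = HeadModel()
    grid = build_grid(head, spacing=config.sources.grid_spacing)
    if config.input_edf_paths:
        raise ConfigError(
            "EDF-input cohorts need a montage per file; use read_eeg + "
            "analyze_subject directly for measured data")
    sensors = fibonacci_sensors(sim.n_sensors)
    leadfield = compute_leadfield(head, sensors, grid)
    cohort_cfg = CohortConfig(
        n_per_group=sim.n_per_group, duration=sim.duration, srate=sim.srate,
        n_sensors=sim.n_sensors, snr_db=sim.snr_db,
        score_noise_sd=sim.score_noise_sd, seed=config.seed)
    subjects = make_dataset(cohort_cfg, leadfield=leadfield)

    results: list[SubjectResult] = []
    all_sources: dict = {}
    all_graphs: dict = {}
    groups: dict = {}
    score_rows = []
    for sub in subjects:
        bp, ssets, graphs, report = analyze_subject(
            sub.recording, leadfield, config,
            seed=sub.ground_truth.subject_seed)
        results.append(SubjectResult(
            subject_id=sub.subject_id, group=sub.group, band_power=bp,
            source_sets=ssets, graphs=graphs, report=report))
        all_sources[sub.subject_id] = ssets
        all_graphs[sub.subject_id] = graphs
        groups[sub.subject_id] = sub.group
        score_rows.append({"subject": sub.subject_id, "group": sub.group,
                           **sub.scores})
    scores = validate_scores(pd.DataFrame(score_rows))

    features = assemble_features(all_sources, all_graphs,
                                 bands=list(config.sources.bands),
                                 groups=groups)
    reports = {}
    pr = config.prediction
    for target in pr.targets:
        if target == "group":
            y = np.asarray(features.groups)
            mode = "classification"
        else:
            y = scores.set_index("subject").loc[features.subjects,
                                                target].to_numpy()
            mode = "regression"
        reports[target] = svm_predict(
            features.values, y, mode=mode, seed=config.seed,
            scheme=pr.scheme, n_splits=pr.n_splits, gamma=pr.gamma,
            target_name=target)

    timing = correlate_with_timing(
        features.to_dataframe(),
        scores[["subject", "age_first_ci", "age_bilateral_ci",
                "age_ha_fit"]])

    provenance = {
        "package_version": _pkg_version,
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "subject_seeds": {s.subject_id: int(s.ground_truth.subject_seed)
                          for s in subjects},
        "parameters": {
            "filter_order": config.preprocess.filter_order,
            "notch_freqs": config.preprocess.notch_freqs,
            "surrogate_permutations": config.sources.n_permutations,
            "surrogate_percentile": config.sources.percentile,
            "bootstrap_iterations": config.connectivity.n_bootstrap,
            "svm_kernel": "poly",
            "svm_gamma": config.prediction.gamma,
            "svm_grid": "degree,C in 1..10",
        },
        "artifact_hashes": {},
    }

    if out:
        bp_all = pd.concat(
            [r.band_power.assign(subject=r.subject_id) for r in results],
            ignore_index=True)
        bp_all.to_csv(out / "band_power.tsv", sep="\t", index=False)
        from .beamform import source_peaks_table
        peaks = pd.concat(
            [source_peaks_table(r.source_sets).assign(subject=r.subject_id)
             for r in results], ignore_index=True)
        peaks.to_csv(out / "sources.tsv", sep="\t", index=False)
        edges = pd.concat(
            [g.to_dataframe().assign(subject=r.subject_id)
             for r in results for g in r.graphs.values()],
            ignore_index=True)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        features.to_dataframe().to_csv(out / "features.tsv", sep="\t",
                                       index=False)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        with open(out / "prediction.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in reports.items()}, fh,
                      indent=1)
        for name in ("band_power.tsv", "sources.tsv", "edges.tsv",
                     "features.tsv", "scores.tsv", "prediction.json"):
            provenance["artifact_hashes"][name] = _hash_file(out / name)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1)

    return PipelineResult(subjects=results, feature_table=features,
                          prediction_reports=reports,
                          timing_correlations=timing, provenance=provenance)


def verify_artifacts(outdir) -> bool:
    """Check that no stage artifact was mutated since the pipeline run."""
    out = Path(outdir)
    with open(out / "provenance.json") as fh:
        prov = json.load(fh)
    for name, digest in prov.get("artifact_hashes", {}).items():
        if _hash_file(out / name) != digest:
            return False
    return True
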