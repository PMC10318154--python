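"""Ground-truth EEG simulation: coupled dipole sources, sensor projection,
cohorts with behavioral scores.

The generative model is a stable multivariate autoregressive (MVAR) process
over a small number of spatially fixed dipole sources.  Band-limited
oscillations are obtained by shaping each source's innovation with a resonant
AR(2) (center frequency / bandwidth parameterized), so the whole generator
remains a single linear system whose directed-coupling structure (and hence
partial directed coherence) is known exactly.  Source activity is projected to
scalp sensors through the three-shell spherical forward model at a requested
broadband SNR, and per-subject behavioral scores are produced by a stored
linear map of the true coupling features plus Gaussian noise.

Every random draw flows from one master seed through
``numpy.random.SeedSequence``: subject s of a cohort uses
``SeedSequence([master_seed, s])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .forward import HeadModel, LeadField
from .preprocess import Recording


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the MVAR companion matrix; < 1 means stable."""
    A = np.asarray(coeffs, float)
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("coeffs must be (p, n, n)")
    p, n, _ = A.shape
    if p == 0:
        return 0.0
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class SourceScenario:
    """A fixed configuration of coupled dipole sources.

    positions : (n_sources, 3) mm, strictly inside the brain shell
    orientations : (n_sources, 3) unit dipole orientations
    mvar_coeffs : (p, n, n) lag matrices; entry [r, i, j] couples source j
        (lag r+1) into source i
    innovation_cov : (n, n) SPD covariance of the innovations
    band_profiles : per-source (center_hz, bandwidth_hz) of the resonant
        AR(2) innovation shaping
    snr_db : sensor-level broadband SNR; ``None`` / inf means noiseless
    """

    positions: np.ndarray
    orientations: np.ndarray
    mvar_coeffs: np.ndarray
    innovation_cov: np.ndarray
    band_profiles: list
    snr_db: float | None = 10.0
    seed: int = 0
    brain_radius: float = 71.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        self.mvar_coeffs = np.asarray(self.mvar_coeffs, float)
        if self.mvar_coeffs.size == 0:
            self.mvar_coeffs = self.mvar_coeffs.reshape(0, self.n_sources,
                                                        self.n_sources)
        self.innovation_cov = np.asarray(self.innovation_cov, float)
        self.validate()

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def order(self) -> int:
        return self.mvar_coeffs.shape[0]

    def validate(self) -> None:
        n = self.n_sources
        if self.orientations.shape != (n, 3):
            raise ValueError("orientations must be (n_sources, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must have unit norm")
        if self.mvar_coeffs.shape[1:] != (n, n):
            raise ValueError("mvar_coeffs must be (p, n, n)")
        if self.innovation_cov.shape != (n, n):
            raise ValueError("innovation_cov must be (n, n)")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T,
                           atol=1e-10):
            raise ValueError("innovation_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.innovation_cov) <= 0):
            raise ValueError("innovation_cov must be positive definite")
        if len(self.band_profiles) != n:
            raise ValueError("need one band profile per source")
        radius = companion_spectral_radius(self.mvar_coeffs)
        if radius >= 1.0:
            raise ValueError(
                f"unstable MVAR coefficients: companion spectral radius "
                f"{radius:.4f} >= 1")
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r >= self.brain_radius):
            raise ValueError("source positions must lie strictly inside the "
                             "brain shell")

    def true_adjacency(self) -> np.ndarray:
        """Directed boolean matrix: [i, j] True when source j drives source i."""
        n = self.n_sources
        adj = np.zeros((n, n), dtype=bool)
        if self.order:
            adj = np.any(np.abs(self.mvar_coeffs) > 1e-12, axis=0)
        np.fill_diagonal(adj, False)
        return adj


def _ar2_shape(e: np.ndarray, center_hz: float, bandwidth_hz: float,
               srate: float) -> np.ndarray:
    """Resonant AR(2) shaping of a white innovation sequence.

    Poles at radius exp(-pi * bw / srate) and angle 2*pi*f0/srate give a
    resonance of roughly ``bandwidth_hz`` full width at ``center_hz``.  The
    output is rescaled to the input's standard deviation so coupling strengths
    keep their meaning.
    """
    from scipy.signal import lfilter

    r = np.exp(-np.pi * bandwidth_hz / srate)
    theta = 2 * np.pi * center_hz / srate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    out = lfilter([1.0], a, e)
    sd_in = e.std()
    sd_out = out.std()
    if sd_out > 0:
        out *= sd_in / sd_out
    return out


def generate_mvar_sources(scenario: SourceScenario, duration: float,
                          srate: float = 1024.0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the source MVAR process; returns (n_sources, samples).

    A burn-in of ``10 * p * srate`` samples is generated and discarded so the
    returned stretch is a stationary realization.  Deterministic given the
    scenario seed (or an explicit ``rng``).
    """
    scenario.validate()
    n, p = scenario.n_sources, scenario.order
    T = int(round(duration * srate))
    if T < 100 * max(p, 1):
        raise ValueError("duration too short: need at least 100*p samples")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    burn = 10 * p * int(round(srate))
    total = T + burn
    chol = np.linalg.cholesky(scenario.innovation_cov)
    e = (chol @ rng.standard_normal((n, total)))
    u = np.empty_like(e)
    for i, prof in enumerate(scenario.band_profiles):
        if prof is None:
            u[i] = e[i]  # white innovation (no band shaping)
        else:
            f0, bw = prof
            u[i] = _ar2_shape(e[i], f0, bw, srate)
    A = scenario.mvar_coeffs
    if p == 0:
        x = u
    else:
        from ._kernels import mvar_recurse
        Astack = np.ascontiguousarray(np.concatenate(list(A), axis=1))
        x = mvar_recurse(Astack, np.ascontiguousarray(u), p)
    return x[:, burn:]


def _pink_noise(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise (equal power per octave), unit variance per row."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * gain, n=shape[-1], axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def project_to_sensors(
    sources: np.ndarray,
    scenario: SourceScenario,
    leadfield: LeadField,
    snr_db: float | None = None,
    srate: float = 1024.0,
    channel_labels: list | None = None,
    rng: np.random.Generator | None = None,
    noise_color: str = "pink",
) -> Recording:
    """Project source time series through the lead field and add sensor noise.

    Each source is assigned the lead-field column of the nearest grid voxel
    (must be within one grid spacing) combined with the scenario orientation.
    Additive sensor noise — 1/f ("pink", default, matching the broadband
    background of resting EEG) or white — is scaled so the ratio of clean
    broadband power to noise power matches ``snr_db`` (falls back to the
    scenario's).
    """
    sources = np.atleast_2d(np.asarray(sources, float))
    if sources.shape[0] != scenario.n_sources:
        raise ValueError("sources rows must match scenario.n_sources")
    if snr_db is None:
        snr_db = scenario.snr_db
    grid = leadfield.grid
    n_ch = leadfield.n_channels
    clean = np.zeros((n_ch, sources.shape[1]))
    for s in range(scenario.n_sources):
        v, dist = grid.nearest(scenario.positions[s])
        if dist > grid.spacing:
            raise ValueError(
                f"source {s} at {scenario.positions[s]} is {dist:.1f} mm from "
                f"the nearest grid voxel (> spacing {grid.spacing} mm)")
        l = leadfield.voxel_columns(v) @ scenario.orientations[s]
        clean += np.outer(l, sources[s])
    data = clean
    if snr_db is not None and np.isfinite(snr_db):
        if rng is None:
            rng = np.random.default_rng(scenario.seed + 1)
        p_clean = np.mean(clean ** 2)
        if noise_color == "pink":
            noise = _pink_noise(clean.shape, rng)
        elif noise_color == "white":
            noise = rng.standard_normal(clean.shape)
        else:
            raise ValueError(f"unknown noise_color {noise_color!r}")
        p_noise_target = p_clean / (10.0 ** (snr_db / 10.0))
        noise *= np.sqrt(p_noise_target / np.mean(noise ** 2))
        data = clean + noise
    if channel_labels is None:
        channel_labels = [f"E{i+1}" for i in range(n_ch)]
    return Recording(data=data, srate=srate, channel_labels=channel_labels,
                     sensor_positions=leadfield.sensors.copy())


def add_artifacts(recording: Recording, kinds=("blink",),
                  rng: np.random.Generator | None = None,
                  blink_rate_hz: float = 0.25,
                  line_freq: float = 60.0,
                  amplitude: float = 50.0) -> Recording:
    """Inject stereotyped artifacts (blink / line / muscle) for testing.

    Blinks are ~300-ms raised-cosine pulses with a frontal topography; line
    noise is a fixed-frequency sinusoid with a smooth topography; muscle is
    high-pass filtered noise bursts on lateral channels.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = recording.data.copy()
    n_ch, T = x.shape
    pos = recording.sensor_positions
    t = np.arange(T) / recording.srate
    if "blink" in kinds:
        topo = np.clip(pos[:, 1], 0, None)
        topo = topo / (topo.max() + 1e-12)
        width = int(0.3 * recording.srate)
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        n_blinks = max(1, int(blink_rate_hz * T / recording.srate))
        series = np.zeros(T)
        for _ in range(n_blinks):
            s = rng.integers(0, T - width)
            series[s:s + width] += pulse
        x += amplitude * np.outer(topo, series)
    if "line" in kinds:
        topo = 0.5 + 0.5 * rng.random(n_ch)
        series = np.sin(2 * np.pi * line_freq * t + rng.uniform(0, 2 * np.pi))
        x += 0.3 * amplitude * np.outer(topo, series)
    if "muscle" in kinds:
        from scipy.signal import butter, sosfilt
        topo = np.abs(pos[:, 0]) / (np.abs(pos[:, 0]).max() + 1e-12)
        sos = butter(4, 30.0, btype="highpass", fs=recording.srate,
                     output="sos")
        burst = sosfilt(sos, rng.standard_normal(T))
        gate = (rng.random(T // int(recording.srate) + 1) < 0.2)
        gate = np.repeat(gate, int(recording.srate))[:T].astype(float)
        x += 0.5 * amplitude * np.outer(topo, burst * gate)
    return recording.copy_with(x)


@dataclass
class GroundTruth:
    """What the generator knows: scenario, adjacency, and the score map."""

    scenario: SourceScenario
    true_adjacency: np.ndarray
    score_coeffs: dict          # score name -> (intercept, weights)
    subject_seed: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.true_adjacency, bool)
        if np.any(np.diag(adj)):
            raise ValueError("true adjacency diagonal must be False")
        self.true_adjacency = adj

    def true_features(self) -> np.ndarray:
        """Flattened coupling coefficients (the generator's feature vector)."""
        return coupling_features(self.scenario)


def coupling_features(scenario: SourceScenario) -> np.ndarray:
    """Off-diagonal coupling magnitudes summed over lags, flattened row-major."""
    n = scenario.n_sources
    if scenario.order == 0:
        return np.zeros(n * (n - 1))
    mags = np.abs(scenario.mvar_coeffs).sum(axis=0)
    off = ~np.eye(n, dtype=bool)
    return mags[off]


SCORE_NAMES = ("CELF", "WRDC", "VOC", "MORPH", "SEN", "EFFIC", "RCOMP")

#: CELF composite ranges implied by the grouping rule: high-language >= 100,
#: low-language <= 85, normal-hearing centered at 100.
_GROUP_CELF = {"HL": (100.0, 120.0), "LL": (60.0, 85.0), "NH": (85.0, 115.0)}


def default_group_scenarios(seed: int = 0) -> dict:
    """Three group templates with disjoint directed couplings.

    Four sources (occipital alpha, parietal alpha, frontal beta, temporal
    gamma).  The high-language-like template couples sources bidirectionally,
    the low-language-like template uses weaker unidirectional coupling on
    different edges, and the control template has no cross coupling.
    """
    positions = np.array([
        [20.0, -45.0, 15.0],   # occipital-ish
        [-35.0, -20.0, 30.0],  # parietal
        [25.0, 40.0, 20.0],    # frontal
        [-45.0, 5.0, -5.0],    # temporal
    ])
    orientations = np.array([
        [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0]])
    band_profiles = [(10.0, 2.0), (11.0, 2.0), (20.0, 4.0), (40.0, 8.0)]
    p = 5
    n = 4

    def coeffs(edges):
        A = np.zeros((p, n, n))
        for i in range(n):
            A[0, i, i] = 0.25   # mild self-memory on top of AR(2) shaping
        for (i, j, w, lag) in edges:
            A[lag, i, j] = w
        return A

    # edges as (target, driver, weight, lag)
    hl_edges = [(1, 0, 0.45, 1), (0, 1, 0.30, 2), (2, 1, 0.40, 1),
                (3, 2, 0.45, 1), (2, 3, 0.30, 2)]
    ll_edges = [(0, 1, 0.40, 1), (3, 0, 0.40, 1)]
    nh_edges = []
    cov = np.eye(n)
    out = {}
    for name, edges in (("HL", hl_edges), ("LL", ll_edges), ("NH", nh_edges)):
        out[name] = SourceScenario(
            positions=positions, orientations=orientations,
            mvar_coeffs=coeffs(edges), innovation_cov=cov,
            band_profiles=band_profiles, snr_db=10.0, seed=seed)
    return out


@dataclass
class CohortConfig:
    """Study-condition defaults for a simulated cohort.

    4 sources, MVAR order 5, 128 sensors at 1024 Hz, 2-minute recordings
    (a desk-scale stand-in for 7-minute sessions), 25 subjects per group at
    10 dB sensor SNR, score noise of 3 standard-score points.
    """

    n_per_group: int = 25
    duration: float = 120.0
    srate: float = 1024.0
    n_sensors: int = 128
    snr_db: float = 10.0
    score_noise_sd: float = 3.0
    grid_spacing: float = 10.0
    seed: int = 0
    groups: dict | None = None


@dataclass
class Subject:
    subject_id: str
    group: str
    recording: Recording
    scores: dict
    ground_truth: GroundTruth


def fibonacci_sensors(n: int, radius: float = 85.0) -> np.ndarray:
    """Quasi-uniform sensor positions on the upper scalp (Fibonacci lattice)."""
    k = np.arange(n)
    # cover the upper ~3/4 sphere the way an EEG net does
    z = 1.0 - 1.55 * (k + 0.5) / n
    phi = k * (np.pi * (3.0 - np.sqrt(5.0)))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts * radius


def _score_map(features: np.ndarray, group: str,
               rng: np.random.Generator, noise_sd: float) -> tuple[dict, dict]:
    """Linear map of true features to the seven behavioral scores."""
    lo, hi = _GROUP_CELF[group]
    base = 0.5 * (lo + hi)
    span = 0.5 * (hi - lo)
    scores = {}
    coeffs = {}
    reference = 0.35  # typical coupling-magnitude scale
    f = features - reference
    for k, name in enumerate(SCORE_NAMES):
        w = np.zeros_like(f)
        if f.size:
            w[k % f.size] = span
        val = base + float(w @ f) + rng.normal(0, noise_sd)
        scores[name] = float(np.clip(val, lo, hi))
        coeffs[name] = {"intercept": base, "weights": w.tolist(),
                        "reference": reference, "clip": [lo, hi]}
    return scores, coeffs


def _intervention_ages(group: str, rng: np.random.Generator) -> dict:
    """CI/hearing-aid intervention ages in months (NaN for controls)."""
    if group == "NH":
        return {"age_first_ci": float("nan"),
                "age_bilateral_ci": float("nan"),
                "age_ha_fit": float("nan")}
    first = rng.uniform(9, 24) if group == "HL" else rng.uniform(18, 48)
    return {"age_first_ci": float(first),
            "age_bilateral_ci": float(first + rng.uniform(10, 22)),
            "age_ha_fit": float(max(2.0, first - rng.uniform(4, 10)))}


def make_dataset(config: CohortConfig,
                 leadfield: LeadField | None = None) -> list:
    """Generate a cohort of (Recording, scores, GroundTruth) subjects.

    Scores are a stored linear map of the true coupling features plus
    Gaussian noise of ``score_noise_sd``; subject s derives its seed from
    ``SeedSequence([config.seed, s])`` (recorded in the ground truth).
    """
    if config.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group for "
                         "cross-validation downstream")
    groups = config.groups or default_group_scenarios(config.seed)
    if leadfield is None:
        from .forward import build_grid, compute_leadfield
        head = HeadModel()
        grid = build_grid(head, spacing=config.grid_spacing)
        sensors = fibonacci_sensors(config.n_sensors)
        leadfield = compute_leadfield(head, sensors, grid)
    subjects = []
    s_index = 0
    for gname, template in groups.items():
        for k in range(config.n_per_group):
            ss = np.random.SeedSequence([config.seed, s_index])
            sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(ss)
            scenario = dataclasses.replace(template, seed=sub_seed,
                                           snr_db=config.snr_db)
            src = generate_mvar_sources(scenario, config.duration,
                                        config.srate, rng=rng)
            rec = project_to_sensors(src, scenario, leadfield,
                                     snr_db=config.snr_db,
                                     srate=config.srate, rng=rng)
            feats = coupling_features(scenario)
            scores, coeffs = _score_map(feats, gname, rng,
                                        config.score_noise_sd)
            scores.update(_intervention_ages(gname, rng))
            gt = GroundTruth(scenario=scenario,
                             true_adjacency=scenario.true_adjacency(),
                             score_coeffs=coeffs, subject_seed=sub_seed)
            subjects.append(Subject(
                subject_id=f"sub-{s_index:03d}", group=gname,
                recording=rec, scores=scores, ground_truth=gt))
            s_index += 1
    return subjects
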