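"""Frequency-domain beamforming: cross-spectral density, LCMV/DICS spatial
filters, iterative coherent-source search with surrogate significance, pooled
source signals and source time-series extraction.

The spatial filter at a voxel with (orientation-optimised) lead field ``l``
and regularised cross-spectral/covariance matrix ``C_l = C + l_reg*mean_eig*I``
is the linear constrained minimum-variance solution

    w = C_l^-1 l / (l^H C_l^-1 l),    w^H l = 1 ,

whose output power ``w^H C w`` maps band-limited activity (DICS).  Sources are
found iteratively: the strongest power voxel seeds a pooled reference signal;
subsequent iterations maximise magnitude-squared coherence to that reference
after the found topographies are projected out of the data, and stop when the
candidate fails a within-subject surrogate threshold (epoch-shuffle Monte
Carlo, 99th percentile by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .preprocess import Epochs
from .spectral import BandDefinition, TaperSet, make_tapers, tapered_fft

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-spectral density
# ---------------------------------------------------------------------------

@dataclass
class CrossSpectrum:
    """Band-averaged channels x channels cross-spectral density.

    ``csd`` is Hermitian PSD; ``epoch_spectra`` keeps the per-epoch tapered
    eigencoefficients (M, n_channels, K, n_band_bins) so surrogate shuffles
    and reference cross-spectra can be formed without re-transforming.
    """

    csd: np.ndarray
    band: BandDefinition
    n_frames: int
    freqs: np.ndarray
    epoch_spectra: np.ndarray
    scale: float
    srate: float = 0.0

    def __post_init__(self) -> None:
        herm = np.max(np.abs(self.csd - self.csd.conj().T))
        if herm > 1e-10 * max(np.max(np.abs(self.csd)), 1e-300):
            raise ValueError("CSD is not Hermitian")
        ev = np.linalg.eigvalsh(self.csd)
        if ev.min() < -1e-10 * max(ev.max(), 1e-300):
            raise ValueError("CSD has a significantly negative eigenvalue")


def _band_eigencoefficients(epochs: Epochs, band: BandDefinition,
                            tapers: TaperSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Tapered DFT coefficients restricted to the band's bins.

    Returns (X (M, C, K, B), band freqs, one-sided density scale).
    """
    L = epochs.L
    srate = epochs.srate
    freqs = np.fft.rfftfreq(L, d=1.0 / srate)
    mask = band.bin_mask(freqs)
    if not mask.any():
        raise ValueError(f"band {band.name} has no frequency bins at "
                         f"resolution {srate / L:.3f} Hz")
    X = tapered_fft(epochs.data, tapers)[..., mask]  # (M, C, K, B)
    # interior rfft bins carry the factor-2 one-sided density scaling
    scale = 2.0 / srate
    return X, freqs[mask], scale


def csd(epochs: Epochs, band: BandDefinition,
        tapers: TaperSet | None = None,
        NW: float = 2.0, K: int = 3,
        min_frames: int = 10) -> CrossSpectrum:
    """Multitaper cross-spectral density averaged over epochs and band bins.

    The diagonal equals the multitaper band power (mean of S_MT over the
    band's bins and epochs) per channel.
    """
    if epochs.M < min_frames:
        raise ValueError(f"need at least {min_frames} epochs, got {epochs.M}")
    if tapers is None:
        tapers = make_tapers(epochs.L, NW=NW, K=K)
    X, bfreqs, scale = _band_eigencoefficients(epochs, band, tapers)
    M, C_, K_, B = X.shape
    mat = np.einsum("mikb,mjkb->ij", X, X.conj()) / (M * K_ * B) * scale
    mat = 0.5 * (mat + mat.conj().T)
    return CrossSpectrum(csd=mat, band=band, n_frames=M, freqs=bfreqs,
                         epoch_spectra=X, scale=scale, srate=epochs.srate)


def magnitude_squared_coherence(cs: CrossSpectrum, i: int, j: int) -> float:
    c = cs.csd
    return float(np.abs(c[i, j]) ** 2 / (c[i, i].real * c[j, j].real))


# ---------------------------------------------------------------------------
# LCMV / DICS spatial filters
# ---------------------------------------------------------------------------

@dataclass
class SpatialFilter:
    """Scalar (optimal-orientation) beamformer weights for one voxel."""

    weights: np.ndarray       # (n_channels,), complex or real
    orientation: np.ndarray   # (3,) unit vector
    leadfield: np.ndarray     # (n_channels,) optimal-orientation lead field
    regularization: float


def _regularize(C: np.ndarray, reg: float) -> np.ndarray:
    n = C.shape[0]
    mean_eig = np.trace(C).real / n
    return C + reg * mean_eig * np.eye(n)


def lcmv_weights(l3: np.ndarray, C: np.ndarray,
                 reg: float = 0.05) -> SpatialFilter:
    """Unit-gain minimum-variance weights with optimal orientation.

    ``l3`` is the (n_channels, 3) lead-field block of the voxel.  The source
    orientation maximising output power solves the generalized eigenproblem
    of the projected 3x3 matrix l3^H C_l^-1 l3 (smallest eigenvalue); the
    weights are ``C_l^-1 l / (l^H C_l^-1 l)`` for the resulting scalar lead
    field ``l``.
    """
    l3 = np.asarray(l3)
    if reg < 0:
        raise ValueError("regularization must be >= 0")
    C_l = _regularize(C, reg)
    ev = np.linalg.eigvalsh(C_l)
    if ev.min() <= ev.max() * 1e-14:
        raise np.linalg.LinAlgError(
            "covariance is singular; increase the regularization parameter")
    Ci_l3 = np.linalg.solve(C_l, l3)
    G = np.real(l3.conj().T @ Ci_l3)
    evals, evecs = np.linalg.eigh(G)
    ori = evecs[:, 0]  # smallest eigenvalue -> maximal output power
    if ori[np.argmax(np.abs(ori))] < 0:
        ori = -ori
    l_opt = l3 @ ori
    Ci_l = Ci_l3 @ ori
    denom = np.real(l_opt.conj() @ Ci_l)
    w = Ci_l / denom
    return SpatialFilter(weights=w, orientation=ori, leadfield=l_opt,
                         regularization=reg)


def matched_filter(l3: np.ndarray, C: np.ndarray,
                   reg: float = 0.05) -> SpatialFilter:
    """Unit-gain matched (non-adaptive) filter at the DICS-optimal orientation.

    ``w = l / (l^T l)`` does not cancel sources coherent with the target the
    way the adaptive minimum-variance weights do, so it is the filter of
    choice for extracting source time series whose mutual coherence is the
    quantity of interest (the covariance enters only through the orientation
    choice).  Leakage from other sources is instantaneous mixing, which the
    time-reversal check downstream is designed to flag.
    """
    opt = lcmv_weights(l3, C, reg)
    l = opt.leadfield.real
    w = l / (l @ l)
    return SpatialFilter(weights=w, orientation=opt.orientation,
                         leadfield=l, regularization=reg)


def _scan_all(leadfield: LeadField, C: np.ndarray, reg: float):
    """Vectorised LCMV scan of every grid voxel.

    Returns (W (V, n_channels) weights, Lopt (V, n_channels), power (V,)).
    """
    C_l = _regularize(C, reg)
    L = leadfield.matrix  # (C, 3V)
    V = leadfield.grid.n_voxels
    Ci_L = np.linalg.solve(C_l, L.astype(C_l.dtype))
    Lb = L.T.reshape(V, 3, -1)             # (V, 3, C)
    CiLb = Ci_L.T.reshape(V, 3, -1)        # (V, 3, C)
    G = np.real(np.einsum("vic,vjc->vij", Lb.conj(), CiLb))
    evals, evecs = np.linalg.eigh(G)
    ori = evecs[:, :, 0]                   # (V, 3)
    # canonical sign
    flip = np.take_along_axis(
        ori, np.argmax(np.abs(ori), axis=1)[:, None], axis=1)[:, 0] < 0
    ori[flip] *= -1
    Lopt = np.einsum("vic,vi->vc", Lb, ori)
    CiL = np.einsum("vic,vi->vc", CiLb, ori)
    denom = np.real(np.einsum("vc,vc->v", Lopt.conj(), CiL))
    W = CiL / denom[:, None]
    power = np.real(np.einsum("vc,cd,vd->v", W.conj(), C, W))
    return W, Lopt, power


def source_map(
    cs: CrossSpectrum,
    leadfield: LeadField,
    reference: np.ndarray | None = None,
    reg: float = 0.05,
) -> np.ndarray:
    """Per-voxel band power, or coherence to a reference signal.

    Without a reference the map is the DICS power ``w^H C w``.  With
    ``reference`` — the reference signal segmented like the epochs,
    shape (M, L) — the map is the magnitude-squared coherence between each
    voxel's estimated signal and the reference at the band.
    """
    W, Lopt, power = _scan_all(leadfield, cs.csd, reg)
    if reference is None:
        return power
    c_r, s_r = reference_cross_spectra(cs, reference)
    num = np.abs(W.conj() @ c_r) ** 2
    coh = num / (power * s_r)
    return np.clip(coh.real, 0.0, 1.0)


def reference_cross_spectra(cs: CrossSpectrum, reference: np.ndarray,
                            tapers: TaperSet | None = None):
    """Sensor-to-reference cross-spectral vector and reference band power.

    ``reference`` is (M, L): the reference signal cut into the same epochs.
    """
    X = cs.epoch_spectra  # (M, C, K, B)
    M, C_, K_, B = X.shape
    ref = np.asarray(reference, float)
    if ref.shape[0] != M:
        raise ValueError("reference epochs must match the CSD's epochs")
    if tapers is None:
        tapers = make_tapers(ref.shape[1], NW=2.0, K=K_)
    Y = tapered_fft(ref, tapers)  # (M, K, F)
    Yb = _select_band_bins(Y, cs, ref.shape[1])
    c_r = np.einsum("mikb,mkb->i", X, Yb.conj()) / (M * K_ * B) * cs.scale
    s_r = float(np.einsum("mkb,mkb->", Yb, Yb.conj()).real
                / (M * K_ * B) * cs.scale)
    return c_r, s_r


def _select_band_bins(Y: np.ndarray, cs: CrossSpectrum, L: int) -> np.ndarray:
    """Select the band's rfft bins from reference spectra (M, K, F)."""
    df = cs.srate / L
    idx = np.round(cs.freqs / df).astype(int)
    return Y[..., idx]


# ---------------------------------------------------------------------------
# surrogate significance
# ---------------------------------------------------------------------------

def surrogate_threshold(signals: np.ndarray, statistic, n_perm: int = 1000,
                        percentile: float = 99.0, seed: int = 0) -> float:
    """Generic within-subject surrogate threshold.

    ``signals`` is (n_signals, M, L): epoched signals.  Each permutation
    shuffles the epoch order independently per signal, the statistic is
    evaluated on the shuffled set, and the threshold is the requested
    percentile of the surrogate distribution.
    """
    sig = np.asarray(signals, float)
    if sig.ndim != 3:
        raise ValueError("signals must be (n_signals, M, L)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if np.any(sig.std(axis=(1, 2)) == 0):
        raise ValueError("degenerate (constant) signal")
    rng = np.random.default_rng(seed)
    M = sig.shape[1]
    stats = np.empty(n_perm)
    for it in range(n_perm):
        shuffled = np.stack([s[rng.permutation(M)] for s in sig])
        stats[it] = statistic(shuffled)
    return float(np.percentile(stats, percentile))


def band_coherence(x_epochs: np.ndarray, y_epochs: np.ndarray, srate: float,
                   band: BandDefinition, tapers: TaperSet | None = None,
                   NW: float = 2.0, K: int = 3) -> float:
    """Band-averaged magnitude-squared coherence of two epoched signals."""
    Xb, Yb = _pair_band_spectra(x_epochs, y_epochs, srate, band, tapers, NW, K)
    return _coherence_from_spectra(Xb, Yb)


def _pair_band_spectra(x_epochs, y_epochs, srate, band, tapers=None,
                       NW=2.0, K=3):
    x = np.asarray(x_epochs, float)
    y = np.asarray(y_epochs, float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("signals must both be (M, L)")
    L = x.shape[1]
    if tapers is None:
        tapers = make_tapers(L, NW=NW, K=K)
    freqs = np.fft.rfftfreq(L, d=1.0 / srate)
    mask = band.bin_mask(freqs)
    X = tapered_fft(x, tapers)[..., mask]  # (M, K, B)
    Y = tapered_fft(y, tapers)[..., mask]
    return X, Y


def _coherence_from_spectra(X: np.ndarray, Y: np.ndarray) -> float:
    sxy = (X * Y.conj()).mean(axis=(0, 1))   # per band bin
    sxx = (np.abs(X) ** 2).mean(axis=(0, 1))
    syy = (np.abs(Y) ** 2).mean(axis=(0, 1))
    coh = np.abs(sxy) ** 2 / (sxx * syy)
    return float(coh.mean())


def surrogate_coherence_threshold(
    x_epochs: np.ndarray, y_epochs: np.ndarray, srate: float,
    band: BandDefinition, n_perm: int = 1000, percentile: float = 99.0,
    seed: int = 0, tapers: TaperSet | None = None,
    NW: float = 2.0, K: int = 3,
) -> float:
    """Epoch-shuffle surrogate threshold for two-signal band coherence.

    Equivalent to :func:`surrogate_threshold` with the coherence statistic,
    but reuses the per-epoch spectra so 1000 permutations cost milliseconds.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if np.asarray(x_epochs).std() == 0 or np.asarray(y_epochs).std() == 0:
        raise ValueError("degenerate (constant) signal")
    X, Y = _pair_band_spectra(x_epochs, y_epochs, srate, band, tapers, NW, K)
    rng = np.random.default_rng(seed)
    M = X.shape[0]
    stats = np.empty(n_perm)
    for it in range(n_perm):
        perm = rng.permutation(M)
        stats[it] = _coherence_from_spectra(X, Y[perm])
    return float(np.percentile(stats, percentile))


# ---------------------------------------------------------------------------
# pooled source signals and extraction
# ---------------------------------------------------------------------------

@dataclass
class SourceSignal:
    """A source-space time series with pooling provenance."""

    data: np.ndarray            # (n_samples,) concatenated kept epochs
    voxels: np.ndarray          # contributing voxel indices
    weights: np.ndarray         # pooling weights, sum to 1
    band: str = ""

    def epoched(self, M: int, L: int) -> np.ndarray:
        return self.data.reshape(M, L)


def extract_timeseries(filt: SpatialFilter, epochs: Epochs) -> np.ndarray:
    """Beamformed voxel time series, concatenated in kept-epoch order."""
    w = np.real(filt.weights)
    return np.einsum("c,mcl->ml", w, epochs.data).reshape(-1)


def pool_source_signal(voxel_signals: np.ndarray, srate: float,
                       band: BandDefinition,
                       voxels: np.ndarray | None = None) -> SourceSignal:
    """Combine cluster voxel signals into one pooled source signal.

    Each voxel's weight is proportional to its band power (second-order
    spectrum) in the analysed band, normalised to sum 1.  Signals are
    sign-aligned to the cluster's first principal component before the
    weighted sum.
    """
    sig = np.atleast_2d(np.asarray(voxel_signals, float))
    V, T = sig.shape
    if voxels is None:
        voxels = np.arange(V)
    if V == 1:
        return SourceSignal(data=sig[0].copy(), voxels=np.asarray(voxels),
                            weights=np.array([1.0]), band=band.name)
    freqs = np.fft.rfftfreq(T, d=1.0 / srate)
    mask = band.bin_mask(freqs)
    spec = np.abs(np.fft.rfft(sig, axis=1)) ** 2
    bp = spec[:, mask].mean(axis=1)
    if bp.sum() <= 0:
        bp = np.ones(V)
    weights = bp / bp.sum()
    # sign alignment to the first principal component
    u, s, vt = np.linalg.svd(sig, full_matrices=False)
    pc1 = vt[0]
    signs = np.sign(sig @ pc1)
    signs[signs == 0] = 1.0
    pooled = (weights * signs) @ sig
    # canonical overall sign: align with the highest-weight voxel (the PC
    # direction itself has arbitrary polarity, as does any EEG source)
    lead = int(np.argmax(weights))
    if pooled @ sig[lead] < 0:
        pooled = -pooled
    return SourceSignal(data=pooled, voxels=np.asarray(voxels),
                        weights=weights, band=band.name)


# ---------------------------------------------------------------------------
# iterative coherent-source search
# ---------------------------------------------------------------------------

@dataclass
class CoherentSource:
    voxel: int
    position: np.ndarray
    band: str
    amplitude: float
    significant: bool
    statistic: str          # 'power' (first iteration) or 'coherence'
    threshold: float
    filter: SpatialFilter = None
    signal: SourceSignal = None   # pooled cluster signal


@dataclass
class CoherentSourceSet:
    """Ordered significant coherent sources for one band."""

    sources: list
    band: str
    percentile: float
    reference: SourceSignal | None = None
    reference_iteration: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sources)

    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude for s in self.sources])

    def positions(self) -> np.ndarray:
        if not self.sources:
            return np.zeros((0, 3))
        return np.stack([s.position for s in self.sources])


def _shuffled_csd(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """CSD after independently permuting the epoch order of every channel."""
    M, C_, K_, B = X.shape
    Xp = np.empty_like(X)
    for c in range(C_):
        Xp[:, c] = X[rng.permutation(M), c]
    return np.einsum("mikb,mjkb->ij", Xp, Xp.conj()) / (M * K_ * B)


def find_coherent_sources(
    epochs: Epochs,
    band: BandDefinition,
    leadfield: LeadField,
    n_max: int = 4,
    reg: float = 0.05,
    n_perm: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
    tapers: TaperSet | None = None,
    NW: float = 2.0,
    K: int = 3,
    cluster_frac: float = 0.9,
) -> CoherentSourceSet:
    """Iterative DICS search for significant coherent sources in one band.

    Iteration 1 takes the strongest power voxel, tested against an
    epoch-shuffle surrogate distribution of the maximum power over the grid
    (fixed spatial filters, shuffled cross-spectra); its pooled cluster
    signal becomes the coherence reference.  Each later iteration projects
    the found source topographies out of the data (rank-1 deflation),
    rescans for the voxel with maximal coherence to the reference, and stops
    when the candidate's coherence falls below the surrogate threshold (the
    stated percentile of the shuffled maximum-coherence distribution) or
    ``n_max`` sources were found.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if tapers is None:
        tapers = make_tapers(epochs.L, NW=NW, K=K)
    cs = csd(epochs, band, tapers=tapers)
    X = cs.epoch_spectra.copy()
    M, C_, K_, B = X.shape
    rng = np.random.default_rng(seed)
    grid = leadfield.grid
    data = epochs      # progressively deflated copy
    lf_cur = leadfield  # lead field deflated in step with the data: the
    # unit-gain constraint must live in the same subspace as the data, or
    # the scan buys its gain in the projected-out direction

    sources: list[CoherentSource] = []
    reference: SourceSignal | None = None
    ref_epoched = None
    ref_iter: list[int] = []
    C_mat = cs.csd.copy()

    for it in range(n_max):
        W, Lopt, power = _scan_all(lf_cur, C_mat, reg)
        if it == 0:
            stat_map = power
            stat_name = "power"
            # surrogate: the same adaptive max-power functional evaluated on
            # per-channel epoch-shuffled cross-spectra (exchangeable with the
            # observed statistic under the no-source null)
            surr = np.empty(n_perm)
            for k in range(n_perm):
                Cp = _shuffled_csd(X, rng) * cs.scale
                surr[k] = float(_scan_all(lf_cur, Cp, reg)[2].max())
            thresh = float(np.percentile(surr, percentile))
        else:
            c_r, s_r = reference_cross_spectra(
                CrossSpectrum(csd=C_mat, band=band, n_frames=M,
                              freqs=cs.freqs, epoch_spectra=X,
                              scale=cs.scale, srate=epochs.srate),
                ref_epoched)
            num = np.abs(W.conj() @ c_r) ** 2
            stat_map = np.clip(num / (power * s_r), 0.0, 1.0)
            stat_name = "coherence"
            Yb = _select_band_bins(
                tapered_fft(ref_epoched, tapers), cs, epochs.L)
            surr = np.empty(n_perm)
            for k in range(n_perm):
                perm = rng.permutation(M)
                c_rp = np.einsum("mikb,mkb->i", X, Yb[perm].conj()) \
                    / (M * K_ * B) * cs.scale
                nump = np.abs(W.conj() @ c_rp) ** 2
                surr[k] = np.max(np.clip(nump / (power * s_r), 0.0, 1.0))
            thresh = float(np.percentile(surr, percentile))

        cand = int(np.argmax(stat_map))
        value = float(stat_map[cand])
        if value <= thresh:
            break
        if sources and value >= sources[-1].amplitude and stat_name == \
                sources[-1].statistic:
            break  # enforce decreasing amplitude across iterations

        filt = lcmv_weights(lf_cur.voxel_columns(cand), C_mat, reg)
        # cluster: voxels within one grid spacing of the peak whose map value
        # exceeds cluster_frac of the peak
        d = np.linalg.norm(grid.positions - grid.positions[cand], axis=1)
        members = np.flatnonzero((d <= grid.spacing + 1e-9)
                                 & (stat_map >= cluster_frac * value))
        # signals are extracted with unit-gain matched filters: adaptive
        # weights cancel coherent sources, which would destroy the very
        # coherence/connectivity structure the signals feed downstream
        vox_sigs = np.stack([
            extract_timeseries(
                matched_filter(lf_cur.voxel_columns(v), C_mat, reg), data)
            for v in members])
        pooled = pool_source_signal(vox_sigs, epochs.srate, band,
                                    voxels=members)
        if it == 0:
            reference = pooled
            ref_epoched = pooled.epoched(M, epochs.L)
        ref_iter.append(0)

        sources.append(CoherentSource(
            voxel=cand, position=grid.positions[cand].copy(), band=band.name,
            amplitude=value, significant=True, statistic=stat_name,
            threshold=thresh, filter=filt, signal=pooled))

        # rank-1 deflation of the found topography (data, spectra, CSD and
        # lead field together, so later unit-gain constraints stay inside
        # the remaining signal subspace)
        l = filt.leadfield.real
        P = np.eye(C_) - np.outer(l, l) / (l @ l)
        data = data.copy_with(np.einsum("cd,mdl->mcl", P, data.data))
        X = np.einsum("cd,mdkb->mckb", P.astype(X.dtype), X)
        C_mat = P @ C_mat @ P.conj().T
        C_mat = 0.5 * (C_mat + C_mat.conj().T)
        lf_cur = LeadField(matrix=P @ lf_cur.matrix, grid=lf_cur.grid,
                           head=lf_cur.head, sensors=lf_cur.sensors)

    return CoherentSourceSet(sources=sources, band=band.name,
                             percentile=percentile, reference=reference,
                             reference_iteration=ref_iter)


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

#: Affine stub mapping model head coordinates (mm) to MNI-like coordinates:
#: identity orientation with a fixed anterior/superior shift.  Reported for
#: orientation only; the spherical model is not registered to a template.
MNI_AFFINE_STUB = np.array([
    [1.0, 0.0, 0.0, 0.0],
    [0.0, 1.0, 0.0, -18.0],
    [0.0, 0.0, 1.0, 18.0],
    [0.0, 0.0, 0.0, 1.0],
])


def export_source_map_nifti(values: np.ndarray, leadfield: LeadField,
                            path: str) -> None:
    """Write a per-voxel map as a NIfTI volume on the model grid."""
    import nibabel as nib

    grid = leadfield.grid
    sp = grid.spacing
    pos = grid.positions
    mins = pos.min(axis=0)
    ijk = np.round((pos - mins) / sp).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape, dtype=np.float32)
    vol[tuple(ijk.T)] = values
    affine = np.diag([sp, sp, sp, 1.0])
    affine[:3, 3] = mins
    nib.save(nib.Nifti1Image(vol, affine), path)


def source_peaks_table(source_sets: dict):
    """TSV-ready table of source peaks per band (position, amplitude)."""
    import pandas as pd

    rows = []
    for band_name, sset in source_sets.items():
        for rank, src in enumerate(sset.sources, start=1):
            rows.append({
                "band": band_name, "rank": rank,
                "x_mm": src.position[0], "y_mm": src.position[1],
                "z_mm": src.position[2],
                "amplitude": src.amplitude, "statistic": src.statistic,
                "threshold": src.threshold,
            })
    return pd.DataFrame(rows)
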