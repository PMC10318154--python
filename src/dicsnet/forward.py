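"""Analytic three-shell spherical head model: dipole potentials, source grid,
lead field.

The head is modelled as three concentric shells (brain, skull, scalp) with
piecewise-constant conductivity.  The potential of a current dipole inside the
innermost shell is expanded in spherical harmonics; within each shell the
radial dependence is ``A r^n + B r^-(n+1)``, and the coefficients follow from
continuity of potential and radial current at the interfaces plus a no-flux
condition at the scalp surface.  Because the interface algebra is independent
of the dipole position, the per-harmonic transfer gains are solved once per
head model and reused for every dipole.

With a dipole of moment ``m`` at radius ``b`` on the z-axis, the scalp
potential at colatitude ``g`` and azimuth ``phi`` is

    V = 1/(4 pi s1 R^2) * sum_n (b/R)^(n-1) g_n
            [ n m_r P_n(cos g) + m_t P_n'(cos g) sin g cos phi ] ,

where ``g_n`` is the shell-transfer gain (``(2n+1)/n`` in the homogeneous
limit), ``s1`` the brain conductivity and ``R`` the scalp radius.  The series
is truncated adaptively when terms fall below 1e-8 of the running sum.

Units: positions and radii in mm, conductivities in S/m, dipole moments in
nAm; potentials are returned in microvolts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_N_MAX = 300
_REL_TOL = 1e-8


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell head: radii (mm) brain < skull < scalp, S/m each."""

    radii: tuple[float, float, float] = (71.0, 79.0, 85.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        if not np.all(np.diff(r) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not all(c > 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


def shell_transfer_gains(head: HeadModel, n_max: int = _N_MAX) -> np.ndarray:
    """Per-harmonic gains g_n, n = 1..n_max.

    For each harmonic order the five shell coefficients (one homogeneous term
    in the brain, two in the skull, two in the scalp) are the solution of a
    5x5 linear system expressing continuity of potential and of radial current
    density at both interfaces and zero current through the scalp surface.
    Radii are normalised by the scalp radius so powers stay representable.
    """
    r1, r2, R = (np.asarray(head.radii, float) / head.radii[-1])
    s1, s2, s3 = head.conductivities
    gains = np.empty(n_max + 1)
    gains[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 (coefficients of u^n and u^-(n+1))
        # source: unit-coefficient particular term u^-(n+1) in region 1
        def up(u):   # u^n and derivative
            return u ** n, n * u ** (n - 1)

        def um(u):   # u^-(n+1) and derivative
            return u ** -(n + 1), -(n + 1) * u ** -(n + 2)

        p1, dp1 = up(r1); m1, dm1 = um(r1)
        p2, dp2 = up(r2); m2, dm2 = um(r2)
        pR, dpR = up(R); mR, dmR = um(R)
        A = np.array([
            # V continuous at r1:  A1 p1 - A2 p1 - B2 m1 = -m1
            [p1, -p1, -m1, 0.0, 0.0],
            # s dV/dr continuous at r1
            [s1 * dp1, -s2 * dp1, -s2 * dm1, 0.0, 0.0],
            # V continuous at r2
            [0.0, p2, m2, -p2, -m2],
            # s dV/dr continuous at r2
            [0.0, s2 * dp2, s2 * dm2, -s3 * dp2, -s3 * dm2],
            # no radial current at scalp surface
            [0.0, 0.0, 0.0, dpR, dmR],
        ])
        rhs = np.array([-m1, -s1 * dm1, 0.0, 0.0, 0.0])
        sol = np.linalg.solve(A, rhs)
        A3, B3 = sol[3], sol[4]
        gains[n] = A3 * pR + B3 * mR
    return gains


def _series_sums(head: HeadModel, gains: np.ndarray,
                 b: float, cos_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive sums S1 = sum q_n n P_n(x), S2 = sum q_n P_n'(x),
    with q_n = (b/R)^(n-1) g_n, truncated at relative tolerance 1e-8."""
    R = head.scalp_radius
    x = np.asarray(cos_g, float)
    ratio = b / R
    S1 = np.zeros_like(x)
    S2 = np.zeros_like(x)
    # Legendre recurrences
    P_nm2 = np.ones_like(x)        # P_0
    P_nm1 = x.copy()               # P_1
    dP_nm2 = np.zeros_like(x)      # P_0'
    dP_nm1 = np.ones_like(x)       # P_1'
    q = 1.0  # (b/R)^(n-1) at n=1
    for n in range(1, gains.size):
        if n == 1:
            P_n, dP_n = P_nm1, dP_nm1
        else:
            P_n = ((2 * n - 1) * x * P_nm1 - (n - 1) * P_nm2) / n
            dP_n = dP_nm2 + (2 * n - 1) * P_nm1
            P_nm2, P_nm1 = P_nm1, P_n
            dP_nm2, dP_nm1 = dP_nm1, dP_n
        coef = q * gains[n]
        t1 = coef * n * P_n
        t2 = coef * dP_n
        S1 += t1
        S2 += t2
        mag = max(np.max(np.abs(t1)), np.max(np.abs(t2)))
        ref = max(np.max(np.abs(S1)), np.max(np.abs(S2)), 1e-300)
        if mag < _REL_TOL * ref and n > 2:
            break
        q *= ratio
    return S1, S2


def dipole_potential(
    head: HeadModel,
    sensors: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Scalp potentials (uV) of a current dipole inside the brain shell.

    ``sensors`` is (n_sensors, 3) in mm and must lie on the scalp shell
    (within 1% of the scalp radius); ``dipole_pos`` (mm) must be strictly
    inside the brain shell; ``dipole_moment`` is a 3-vector in nAm.
    """
    sensors = np.atleast_2d(np.asarray(sensors, float))
    pos = np.asarray(dipole_pos, float) - np.asarray(head.center, float)
    m = np.asarray(dipole_moment, float)
    R = head.scalp_radius
    b = float(np.linalg.norm(pos))
    if b >= head.brain_radius:
        raise ValueError(
            f"dipole at radius {b:.1f} mm is not inside the brain shell "
            f"(radius {head.brain_radius:.1f} mm)")
    sens = sensors - np.asarray(head.center, float)
    rs = np.linalg.norm(sens, axis=1)
    if np.any(np.abs(rs - R) > 0.01 * R):
        raise ValueError("sensors must lie on the scalp shell; project them "
                         "radially first (see compute_leadfield)")
    er = sens / rs[:, None]
    if gains is None:
        gains = shell_transfer_gains(head)

    if b < 1e-9:
        # central dipole: only the n=1 term survives and the radial axis
        # drops out of the result
        r0 = np.array([0.0, 0.0, 1.0])
    else:
        r0 = pos / b
    x = er @ r0  # cos of angle dipole-axis / sensor
    np.clip(x, -1.0, 1.0, out=x)
    S1, S2 = _series_sums(head, gains, b, x)
    m_r = float(r0 @ m)
    # V = c * [S1 * (r0.m) + S2 * ((er - x r0).m)]
    tang = er @ m - x * m_r
    s1 = head.conductivities[0]
    R_m = R * 1e-3  # mm -> m
    c = 1.0 / (4.0 * np.pi * s1 * R_m ** 2)
    v_volts_per_am = c * (S1 * m_r + S2 * tang)
    # nAm moments, uV output: 1e-9 * 1e6
    return v_volts_per_am * 1e-3


@dataclass(frozen=True)
class SourceGrid:
    """Cubic lattice of candidate source locations inside the brain shell."""

    positions: np.ndarray  # (n_voxels, 3) mm
    spacing: float         # mm

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def nearest(self, point: np.ndarray) -> tuple[int, float]:
        d = np.linalg.norm(self.positions - np.asarray(point, float), axis=1)
        i = int(np.argmin(d))
        return i, float(d[i])


def build_grid(head: HeadModel, spacing: float = 5.0,
               margin: float = 0.95) -> SourceGrid:
    """Cubic lattice clipped to a sphere of radius ``margin * brain_radius``."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing >= head.brain_radius:
        raise ValueError("spacing must be smaller than the brain radius")
    r = head.brain_radius * margin
    n = int(np.floor(r / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= r
    pts = pts[inside] + np.asarray(head.center, float)
    return SourceGrid(positions=pts, spacing=float(spacing))


@dataclass
class LeadField:
    """Lead-field matrix: channels x (n_voxels * 3), average-referenced.

    Column triplets hold the potentials of unit dipoles along the canonical
    x/y/z orientation basis at each grid voxel, in uV per nAm.
    """

    matrix: np.ndarray        # (n_channels, n_voxels * 3)
    grid: SourceGrid
    head: HeadModel
    sensors: np.ndarray       # (n_channels, 3) mm, on the scalp shell

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def voxel_columns(self, voxel: int) -> np.ndarray:
        """(n_channels, 3) lead-field block of one voxel."""
        return self.matrix[:, 3 * voxel:3 * voxel + 3]


def project_sensors_to_scalp(head: HeadModel, sensors: np.ndarray) -> np.ndarray:
    """Project sensor positions radially onto the scalp shell (mm)."""
    sens = np.atleast_2d(np.asarray(sensors, float)) - np.asarray(head.center, float)
    r = np.linalg.norm(sens, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("sensor at the head center cannot be projected")
    mism = np.max(np.abs(r - head.scalp_radius))
    if mism > 1e-6 * head.scalp_radius:
        logger.info("projecting sensors radially onto the scalp shell "
                    "(max radial mismatch %.2f mm)", mism)
    proj = sens * (head.scalp_radius / r)[:, None]
    return proj + np.asarray(head.center, float)


def compute_leadfield(head: HeadModel, sensors: np.ndarray,
                      grid: SourceGrid) -> LeadField:
    """Lead field for all grid voxels; columns re-referenced to the average."""
    sens = project_sensors_to_scalp(head, sensors)
    gains = shell_transfer_gains(head)
    n_ch = sens.shape[0]
    center = np.asarray(head.center, float)
    er = (sens - center) / head.scalp_radius
    cols = np.empty((n_ch, grid.n_voxels * 3))
    for v in range(grid.n_voxels):
        pos = grid.positions[v] - center
        cols[:, 3 * v:3 * v + 3] = _leadfield_block(head, gains, er, pos)
    cols -= cols.mean(axis=0, keepdims=True)
    return LeadField(matrix=cols, grid=grid, head=head, sensors=sens)


def _leadfield_block(head: HeadModel, gains: np.ndarray, er: np.ndarray,
                     pos: np.ndarray) -> np.ndarray:
    """(n_channels, 3) potentials of unit x/y/z dipoles at ``pos``.

    The harmonic sums depend only on the dipole position, so a single series
    evaluation yields all three orientation columns (the potential is linear
    in the moment).
    """
    b = float(np.linalg.norm(pos))
    if b >= head.brain_radius:
        raise ValueError(
            f"dipole at radius {b:.1f} mm is not inside the brain shell")
    r0 = pos / b if b > 1e-9 else np.array([0.0, 0.0, 1.0])
    x = np.clip(er @ r0, -1.0, 1.0)
    S1, S2 = _series_sums(head, gains, b, x)
    s1 = head.conductivities[0]
    R_m = head.scalp_radius * 1e-3
    c = 1e-3 / (4.0 * np.pi * s1 * R_m ** 2)  # unit nAm dipole -> uV
    # V(m) = c [ S1 (r0.m) + S2 (er.m - x (r0.m)) ]
    return c * (np.outer(S1 - S2 * x, r0) + S2[:, None] * er)
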