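"""Single-sphere magnetic forward model and source grids.

The head is modelled as a homogeneous conducting sphere centred at the
origin. The magnetic field of a current dipole inside the sphere has the
closed form (Sarvas)::

    B(r) = mu0/(4 pi F^2) * ( F (Q x r0) - ((Q x r0) . r) grad F )

with ``a = r - r0``, ``F = a (r a + r^2 - r0 . r)``. A dipole whose moment
is parallel to its position vector (a "radial" dipole) produces no field
outside the sphere; a dipole at the centre likewise produces none. Both
cases return a zero vector here rather than raising.

Planar gradiometer channels are modelled as the finite difference of the
radial field component at the two coil centres of a pair, divided by the
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import SensorArray

__all__ = [
    "sarvas_field",
    "leadfield_sphere",
    "make_sensor_array",
    "default_eye_positions",
    "ForwardGrid",
    "make_forward_grid",
    "HEAD_RADIUS",
    "SENSOR_RADIUS",
]

MU0_OVER_4PI = 1e-7
HEAD_RADIUS = 0.09
SENSOR_RADIUS = 0.102


def sarvas_field(dipole_pos: np.ndarray, dipole_moment: np.ndarray,
                 points: np.ndarray) -> np.ndarray:
    """Magnetic field of current dipoles in a conducting sphere.

    Parameters
    ----------
    dipole_pos : ndarray, shape (..., 3)
        Dipole positions (m), inside the sphere, origin at sphere centre.
    dipole_moment : ndarray, shape (..., 3)
        Dipole moments (A m), broadcastable against ``dipole_pos``.
    points : ndarray, shape (npts, 3)
        Field points (m), outside the sphere.

    Returns
    -------
    B : ndarray, shape (..., npts, 3)
        Magnetic field in tesla.
    """
    r0 = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    q = np.broadcast_to(np.atleast_2d(np.asarray(dipole_moment, dtype=float)), r0.shape)
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    r = pts[None, :, :]                       # (1, C, 3)
    r0b = r0[:, None, :]                      # (P, 1, 3)
    a_vec = r - r0b                           # (P, C, 3)
    a = np.linalg.norm(a_vec, axis=-1)        # (P, C)
    rn = np.linalg.norm(pts, axis=-1)[None, :]  # (1, C)
    adotr = np.einsum("pck,pck->pc", a_vec, np.broadcast_to(r, a_vec.shape))
    r0dotr = np.einsum("pk,ck->pc", r0, pts)

    F = a * (rn * a + rn ** 2 - r0dotr)       # (P, C)
    coef_r = a ** 2 / np.where(rn == 0, np.inf, rn) + adotr / np.where(a == 0, np.inf, a) + 2 * a + 2 * rn
    coef_r0 = a + 2 * rn + adotr / np.where(a == 0, np.inf, a)
    gradF = coef_r[..., None] * r - coef_r0[..., None] * r0b  # (P, C, 3)

    qxr0 = np.cross(q, r0)                    # (P, 3)
    qxr0dotr = np.einsum("pk,ck->pc", qxr0, pts)

    with np.errstate(divide="ignore", invalid="ignore"):
        B = MU0_OVER_4PI / (F ** 2)[..., None] * (
            F[..., None] * qxr0[:, None, :] - qxr0dotr[..., None] * gradF
        )
    # dipole at centre or radial moment: Q x r0 == 0 -> field is exactly 0;
    # also guards the F->0 singularity for degenerate geometry.
    B = np.where(np.isfinite(B), B, 0.0)
    zero = np.linalg.norm(qxr0, axis=-1) < 1e-300
    if np.any(zero):
        B[zero] = 0.0
    if np.asarray(dipole_pos).ndim == 1:
        return B[0]
    return B


def leadfield_sphere(dipole_pos: np.ndarray, dipole_moment: np.ndarray,
                     sensors: SensorArray) -> np.ndarray:
    """Planar-gradiometer responses (T/m) of dipoles in the sphere.

    Returns shape ``(n_channels,)`` for a single dipole or
    ``(n_dipoles, n_channels)`` for a batch.
    """
    coils = sensors.coil_centres()            # (n_ch, 2, 3)
    n_ch = coils.shape[0]
    pts = coils.reshape(-1, 3)
    single = np.asarray(dipole_pos).ndim == 1
    B = sarvas_field(np.atleast_2d(dipole_pos), np.atleast_2d(dipole_moment), pts)
    # radial projection along the site normal (shared by both coils of a channel)
    ch_normals = np.repeat(sensors.normals, 2, axis=0)     # (n_ch, 3)
    coil_normals = np.repeat(ch_normals, 2, axis=0)        # (n_ch * 2, 3)
    Br = np.einsum("pck,ck->pc", B, coil_normals).reshape(B.shape[0], n_ch, 2)
    resp = (Br[:, :, 0] - Br[:, :, 1]) / sensors.baseline
    return resp[0] if single else resp


def make_sensor_array(n_sites: int = 102, radius: float = SENSOR_RADIUS,
                      baseline: float = 0.0168) -> SensorArray:
    """Mirror-symmetric spherical-cap gradiometer layout.

    Sites are arranged on rings of constant polar angle; each ring's
    azimuths are symmetric about the midsagittal (y-z) plane so the layout
    is exactly mirror-symmetric in x. The default 102-site layout uses six
    rings (6, 12, 18, 22, 22, 22 sites).
    """
    if n_sites == 102:
        ring_counts = [6, 12, 18, 22, 22, 22]
        ring_thetas = np.deg2rad([18, 36, 54, 72, 90, 108])
    else:
        # generic cap: distribute over ceil(sqrt) rings, keep mirror symmetry
        n_rings = max(2, int(np.ceil(np.sqrt(n_sites / 3))))
        ring_thetas = np.deg2rad(np.linspace(18, 108, n_rings))
        weights = np.sin(ring_thetas)
        counts = np.maximum(1, np.round(weights / weights.sum() * n_sites).astype(int))
        while counts.sum() > n_sites:
            counts[np.argmax(counts)] -= 1
        while counts.sum() < n_sites:
            counts[np.argmax(weights)] += 1
        ring_counts = list(counts)

    pos = []
    for theta, n in zip(ring_thetas, ring_counts):
        # azimuths measured from +x toward +y; the set {90 + 360 j/n} deg is
        # invariant under phi -> 180 - phi, i.e. mirror symmetric about x=0
        phis = np.deg2rad(90.0 + 360.0 * np.arange(n) / n)
        for phi in phis:
            pos.append([
                radius * np.sin(theta) * np.cos(phi),
                radius * np.sin(theta) * np.sin(phi),
                radius * np.cos(theta),
            ])
    positions = np.array(pos)
    normals = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    # tangent basis: e_theta (latitudinal) and e_phi (azimuthal)
    x, y, z = positions.T
    rho = np.hypot(x, y)
    rho = np.where(rho < 1e-12, 1e-12, rho)
    e_phi = np.column_stack([-y / rho, x / rho, np.zeros_like(z)])
    e_theta = np.cross(e_phi, normals)
    e_theta /= np.linalg.norm(e_theta, axis=1, keepdims=True)
    return SensorArray(positions=positions, normals=normals,
                       tangent1=e_theta, tangent2=e_phi, baseline=baseline)


def default_eye_positions() -> np.ndarray:
    """Two eye centres, anterior-inferior, mirrored about the midline (m)."""
    return np.array([[-0.030, 0.080, -0.020],
                     [0.030, 0.080, -0.020]])


def _tangential_basis(points: np.ndarray) -> np.ndarray:
    """Per-point orthonormal tangential (non-radial) basis, shape (P, 2, 3)."""
    r = np.linalg.norm(points, axis=1, keepdims=True)
    rad = np.where(r > 1e-9, points / np.where(r == 0, 1, r), np.array([0.0, 0.0, 1.0]))
    helper = np.tile(np.array([0.0, 0.0, 1.0]), (points.shape[0], 1))
    near_pole = np.abs(rad[:, 2]) > 0.9
    helper[near_pole] = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(helper, rad)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(rad, t1)
    return np.stack([t1, t2], axis=1)


@dataclass
class ForwardGrid:
    """Volumetric source grid with per-point tangential leadfields.

    ``leadfield`` has shape (n_channels, n_points, 2): the gradiometer
    responses of unit dipoles along the two tangential basis vectors of
    each grid point.
    """

    points: np.ndarray           # (P, 3)
    spacing: float
    leadfield: np.ndarray        # (n_ch, P, 2)
    tangentials: np.ndarray      # (P, 2, 3)
    sensors: SensorArray
    eye_positions: np.ndarray = field(default_factory=default_eye_positions)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def eye_region_mask(self, radius: float = 0.03, edge_angle_deg: float = 30.0,
                        edge_radius_frac: float = 0.85) -> np.ndarray:
        """Points in the eye area, its vicinity, or the head edge near it."""
        d = np.linalg.norm(self.points[:, None, :] - self.eye_positions[None], axis=-1)
        near_eye = (d < radius).any(axis=1)
        rn = np.linalg.norm(self.points, axis=1)
        pn = self.points / np.where(rn[:, None] == 0, 1, rn[:, None])
        en = self.eye_positions / np.linalg.norm(self.eye_positions, axis=1, keepdims=True)
        cosang = pn @ en.T
        edge = (rn > edge_radius_frac * HEAD_RADIUS) & (
            cosang > np.cos(np.deg2rad(edge_angle_deg))).any(axis=1)
        return near_eye | edge

    def occipital_point(self) -> int:
        """Index of a deep posterior grid point (for placing brain sources)."""
        cand = np.linalg.norm(self.points, axis=1) < 0.8 * HEAD_RADIUS
        y = np.where(cand, self.points[:, 1], np.inf)
        return int(np.argmin(y))


def make_forward_grid(sensors: SensorArray, spacing: float = 0.007,
                      head_radius: float = HEAD_RADIUS,
                      eye_positions: Optional[np.ndarray] = None,
                      include_eyes: bool = True,
                      chunk: int = 512) -> ForwardGrid:
    """Cubic-lattice grid inside the sphere plus shells around the eyes.

    Eye-region points are added so ocular sources are localizable by
    leadfield correlation; all points stay strictly inside the conductor.
    """
    if eye_positions is None:
        eye_positions = default_eye_positions()
    rmax = 0.92 * head_radius
    n_half = int(np.floor(rmax / spacing))
    ax = np.arange(-n_half, n_half + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    if include_eyes:
        fine = spacing / 2.0
        shells = []
        for eye in eye_positions:
            n_f = int(np.ceil(0.015 / fine))
            axf = np.arange(-n_f, n_f + 1) * fine
            Xf, Yf, Zf = np.meshgrid(axf, axf, axf, indexing="ij")
            sh = np.column_stack([Xf.ravel(), Yf.ravel(), Zf.ravel()]) + eye
            sh = sh[np.linalg.norm(sh - eye, axis=1) <= 0.015]
            sh = sh[np.linalg.norm(sh, axis=1) <= 0.985 * head_radius]
            shells.append(sh)
        pts = np.vstack([pts] + shells)

    tang = _tangential_basis(pts)
    n_ch = sensors.n_channels
    G = np.empty((n_ch, pts.shape[0], 2))
    for start in range(0, pts.shape[0], chunk):
        sl = slice(start, min(start + chunk, pts.shape[0]))
        for k in range(2):
            G[:, sl, k] = leadfield_sphere(pts[sl], tang[sl, k], sensors).T
    return ForwardGrid(points=pts, spacing=spacing, leadfield=G,
                       tangentials=tang, sensors=sensors,
                       eye_positions=np.asarray(eye_positions))
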