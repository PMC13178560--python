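"""Rotation conventions, cylinder fitting, tube-frame transforms, surface unrolling.

Conventions
-----------
Orientations are intrinsic ZYZ Euler angles in degrees — ``rot`` about z,
``tilt`` about the new y, ``psi`` about the new z — the RELION particle
convention.  The matrix ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` maps body-frame
vectors into the tomogram (lab) frame.  Canonical ranges: ``tilt`` in
[0, 180], ``rot`` and ``psi`` in (-180, 180].  Gimbal ties are broken as
``rot := 0`` when ``tilt = 0`` and ``psi := 0`` when ``tilt = 180``.

The body frame of a coat complex is fixed throughout the package:

* body +x — circumferential arch axis, pointing from the delta end to the
  beta3 end of the arch;
* body +y — stripe stacking direction, approximately the tube axis;
* body +z — outward membrane normal.

Positions are in Angstrom; the canonical particle table is a pandas
DataFrame with the columns in :data:`TABLE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    FitDegenerateError,
    InvalidAngleError,
    InvalidRotationError,
    UnmappableParticleError,
)

# --------------------------------------------------------------------------
# particle table schema (the lingua franca of every pipeline stage)
# --------------------------------------------------------------------------

TABLE_COLUMNS = [
    "particle_id",
    "tomo_id",
    "tube_id",
    "x_A",
    "y_A",
    "z_A",
    "rot_deg",
    "tilt_deg",
    "psi_deg",
    "score",
]

_POS_COLS = ["x_A", "y_A", "z_A"]
_ANG_COLS = ["rot_deg", "tilt_deg", "psi_deg"]


def make_table(
    positions: np.ndarray,
    eulers_deg: np.ndarray,
    *,
    particle_ids=None,
    tomo_id: str = "synthetic",
    tube_id: str = "tube_1",
    scores=None,
) -> pd.DataFrame:
    """Assemble a canonical particle table from arrays."""
    positions = np.asarray(positions, dtype=float)
    eulers_deg = np.asarray(eulers_deg, dtype=float)
    n = len(positions)
    if particle_ids is None:
        particle_ids = np.arange(n)
    if scores is None:
        scores = np.zeros(n)
    return pd.DataFrame(
        {
            "particle_id": np.asarray(particle_ids, dtype=int),
            "tomo_id": tomo_id,
            "tube_id": tube_id,
            "x_A": positions[:, 0],
            "y_A": positions[:, 1],
            "z_A": positions[:, 2],
            "rot_deg": eulers_deg[:, 0],
            "tilt_deg": eulers_deg[:, 1],
            "psi_deg": eulers_deg[:, 2],
            "score": np.asarray(scores, dtype=float),
        }
    )


def table_positions(table: pd.DataFrame) -> np.ndarray:
    """(N, 3) positions in Angstrom."""
    return table[_POS_COLS].to_numpy(dtype=float)


def table_eulers(table: pd.DataFrame) -> np.ndarray:
    """(N, 3) ZYZ Euler angles in degrees."""
    return table[_ANG_COLS].to_numpy(dtype=float)


def table_rotations(table: pd.DataFrame) -> np.ndarray:
    """(N, 3, 3) body->lab rotation matrices."""
    return eulers_to_matrices(table_eulers(table))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    """One oriented subtomogram position.

    ``position`` is in Angstrom; ``euler_deg`` is the (rot, tilt, psi)
    ZYZ triple in degrees mapping body frame -> lab frame.
    """

    particle_id: int
    position: np.ndarray
    euler_deg: tuple
    tomo_id: str = ""
    tube_id: str = ""
    score: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)) or not np.all(
            np.isfinite(self.euler_deg)
        ):
            raise InvalidAngleError("non-finite pose components")

    @property
    def rotation(self) -> np.ndarray:
        return euler_to_matrix(self.euler_deg)


def pose_from_row(row) -> Pose:
    """Build a :class:`Pose` from one particle-table row."""
    return Pose(
        particle_id=int(row["particle_id"]),
        position=np.array([row["x_A"], row["y_A"], row["z_A"]], dtype=float),
        euler_deg=(float(row["rot_deg"]), float(row["tilt_deg"]), float(row["psi_deg"])),
        tomo_id=str(row.get("tomo_id", "")),
        tube_id=str(row.get("tube_id", "")),
        score=float(row.get("score", 0.0)),
    )


@dataclass(frozen=True)
class CylinderFit:
    """Least-squares cylinder: point on axis, unit axis direction, radius (A)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float))
        d = np.asarray(self.axis_direction, float)
        object.__setattr__(self, "axis_direction", d)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    @property
    def diameter_nm(self) -> float:
        return 2.0 * self.radius / 10.0


@dataclass(frozen=True)
class HelicalParams:
    """Per-subunit helical lattice parameters.

    ``twist`` is signed degrees per subunit (sign = handedness as seen with
    the tube axis pointing +z); ``rise`` is Angstrom per subunit.
    """

    twist: float
    rise: float

    def __post_init__(self):
        if not self.rise > 0:
            raise ValueError("rise must be positive")
        if self.twist == 0 or not np.isfinite(self.twist):
            raise ValueError("twist must be finite and nonzero")

    @property
    def units_per_turn(self) -> float:
        return 360.0 / abs(self.twist)

    @property
    def pitch_A(self) -> float:
        return self.units_per_turn * self.rise

    @property
    def pitch_nm(self) -> float:
        return self.pitch_A / 10.0

    @property
    def handedness(self) -> str:
        return "right" if self.twist > 0 else "left"


# --------------------------------------------------------------------------
# Euler <-> matrix
# --------------------------------------------------------------------------


def wrap_angle_deg(angle):
    """Wrap angle(s) to the canonical (-180, 180] range."""
    a = np.asarray(angle, dtype=float)
    w = ((-a + 180.0) % 360.0)
    w = 180.0 - w  # maps to (-180, 180]
    return w if w.ndim else float(w)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(euler_deg) -> np.ndarray:
    """ZYZ Euler angles (degrees) -> proper rotation matrix (body -> lab)."""
    e = np.asarray(euler_deg, dtype=float)
    if e.shape != (3,) or not np.all(np.isfinite(e)):
        raise InvalidAngleError(f"expected 3 finite angles, got {euler_deg!r}")
    rot, tilt, psi = np.deg2rad(e)
    return _rz(rot) @ _ry(tilt) @ _rz(psi)


def eulers_to_matrices(eulers_deg: np.ndarray) -> np.ndarray:
    """Vectorized :func:`euler_to_matrix` for an (N, 3) array."""
    e = np.deg2rad(np.asarray(eulers_deg, dtype=float))
    if e.ndim != 2 or e.shape[1] != 3 or not np.all(np.isfinite(e)):
        raise InvalidAngleError("expected an (N, 3) array of finite angles")
    ca, cb, cg = np.cos(e).T
    sa, sb, sg = np.sin(e).T
    R = np.empty((len(e), 3, 3))
    R[:, 0, 0] = ca * cb * cg - sa * sg
    R[:, 0, 1] = -ca * cb * sg - sa * cg
    R[:, 0, 2] = ca * sb
    R[:, 1, 0] = sa * cb * cg + ca * sg
    R[:, 1, 1] = -sa * cb * sg + ca * cg
    R[:, 1, 2] = sa * sb
    R[:, 2, 0] = -sb * cg
    R[:, 2, 1] = sb * sg
    R[:, 2, 2] = cb
    return R


def matrix_to_euler(rotation: np.ndarray, *, atol: float = 1e-6) -> tuple:
    """Proper rotation matrix -> canonical ZYZ Euler angles (degrees).

    Raises :class:`InvalidRotationError` unless the input is orthonormal
    within ``atol`` with determinant +1.  Gimbal ties follow the package
    convention (rot := 0 at tilt = 0; psi := 0 at tilt = 180).
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise InvalidRotationError("expected a finite 3x3 matrix")
    if np.max(np.abs(R @ R.T - np.eye(3))) > 10 * atol or np.linalg.det(R) < 0:
        raise InvalidRotationError("matrix is not a proper rotation")

    # atan2 form is well conditioned at both gimbal poles
    sb = float(np.hypot(R[0, 2], R[1, 2]))
    tilt = float(np.arctan2(sb, R[2, 2]))
    if sb > 1e-12:
        rot = float(np.arctan2(R[1, 2], R[0, 2]))
        psi = float(np.arctan2(R[2, 1], -R[2, 0]))
    elif R[2, 2] > 0:  # tilt == 0: R = Rz(rot + psi)
        rot = 0.0
        psi = float(np.arctan2(R[1, 0], R[0, 0]))
    else:  # tilt == 180: R = Rz(rot - psi) @ Ry(pi)
        psi = 0.0
        rot = float(np.arctan2(-R[1, 0], -R[0, 0]))
    out = tuple(wrap_angle_deg(np.rad2deg([rot, tilt, psi])))
    # tilt from atan2 of a non-negative sine is already in [0, 180]
    return out


def rotation_angle_rad(R: np.ndarray) -> float:
    """Geodesic rotation angle of a rotation matrix, in radians."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


# --------------------------------------------------------------------------
# relative pose
# --------------------------------------------------------------------------


def relative_pose(a: Pose, b: Pose):
    """Displacement of ``b`` in ``a``'s body frame and the relative rotation.

    Returns ``(d, R_rel)`` with ``d = Ra^T (x_b - x_a)`` (Angstrom) and
    ``R_rel = Ra^T Rb``; ``relative_pose(a, a)`` is ``(0, I)``.
    """
    Ra = a.rotation
    d = Ra.T @ (b.position - a.position)
    return d, Ra.T @ b.rotation


# --------------------------------------------------------------------------
# cylinder fitting
# --------------------------------------------------------------------------


def _axis_distances(points, axis_point, direction):
    diff = points - axis_point
    along = diff @ direction
    return np.linalg.norm(diff - np.outer(along, direction), axis=1)


def _orthobasis(d):
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def fit_cylinder(points) -> CylinderFit:
    """Fit an axis + radius to points on a cylindrical surface.

    Minimizes ``sum_i (distance_i_to_axis - radius)^2`` by nonlinear least
    squares over (axis point, axis direction), with the radius eliminated
    analytically as the mean axial distance.  The initial axis is taken from
    the PCA eigenvector (all three are tried; the best fit wins), which
    handles both long tubes and flat rings.

    Raises :class:`FitDegenerateError` for < 6 points, collinear input, or
    points spanning <= 90 degrees of arc about the fitted axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(pts) < 6:
        raise FitDegenerateError("need at least 6 points for a cylinder fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * svals[0] + 1e-12:
        raise FitDegenerateError("points are collinear")

    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    best = None
    for d0 in vt:  # try each principal direction as the initial axis
        e1, e2 = _orthobasis(d0)

        def residuals(p, d0=d0, e1=e1, e2=e2):
            d = d0 + p[2] * e1 + p[3] * e2
            d = d / np.linalg.norm(d)
            c = centroid + p[0] * e1 + p[1] * e2
            dist = _axis_distances(pts, c, d)
            return dist - dist.mean()

        sol = least_squares(residuals, np.zeros(4), method="lm")
        d = d0 + sol.x[2] * e1 + sol.x[3] * e2
        d = d / np.linalg.norm(d)
        c = centroid + sol.x[0] * e1 + sol.x[1] * e2
        dist = _axis_distances(pts, c, d)
        rms = float(np.sqrt(np.mean((dist - dist.mean()) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, c, d, float(dist.mean()))

    rms, c, d, radius = best
    if radius <= 0 or not np.isfinite(radius):
        raise FitDegenerateError("degenerate radius")
    # arc-coverage check: angular span about the fitted axis must exceed 90 deg
    e1, e2 = _orthobasis(d)
    diff = pts - c
    theta = np.sort(np.arctan2(diff @ e2, diff @ e1))
    gaps = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
    span = 2 * np.pi - gaps.max()
    if span <= np.pi / 2:
        raise FitDegenerateError(
            f"points span only {np.rad2deg(span):.1f} deg of arc (> 90 required)"
        )
    # canonical axis point: foot of the centroid on the axis
    c = c + ((centroid - c) @ d) * d
    return CylinderFit(axis_point=c, axis_direction=d, radius=radius, rms_residual=rms)


# --------------------------------------------------------------------------
# tube-frame canonicalization
# --------------------------------------------------------------------------


def _rotation_between(u, v):
    """Minimal rotation taking unit vector u onto unit vector v."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        e1, _ = _orthobasis(u)
        return 2.0 * np.outer(e1, e1) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def apply_rigid(table: pd.DataFrame, R: np.ndarray, t: np.ndarray) -> pd.DataFrame:
    """Apply the rigid motion x -> R x + t to every pose in a table."""
    out = table.copy()
    pos = table_positions(table) @ R.T + np.asarray(t, float)
    rots = R @ table_rotations(table)
    eulers = np.array([matrix_to_euler(m) for m in rots])
    out[_POS_COLS] = pos
    out[_ANG_COLS] = eulers
    return out


def to_tube_frame(table: pd.DataFrame, fit: CylinderFit) -> pd.DataFrame:
    """Rigidly move a table into the canonical tube frame.

    The fitted axis becomes +z through the origin.  The axis sign is chosen
    so particle order (ascending ``particle_id``) runs toward +z; the
    in-plane rotation and z offset are anchored on the lowest-id particle
    (azimuth 0, z = 0).  Purely rigid: all pairwise distances and relative
    rotations are preserved.
    """
    pos = table_positions(table)
    order = np.argsort(table["particle_id"].to_numpy())
    d = fit.axis_direction.copy()
    proj = pos @ d
    if proj[order[-1]] < proj[order[0]]:
        d = -d
    R0 = _rotation_between(d, np.array([0.0, 0.0, 1.0]))
    q = (pos - fit.axis_point) @ R0.T
    first = order[0]
    phi0 = np.arctan2(q[first, 1], q[first, 0])
    Rc = _rz(-phi0) @ R0
    t = -Rc @ fit.axis_point
    moved = apply_rigid(table, Rc, t)
    moved["z_A"] = moved["z_A"] - float(moved["z_A"].to_numpy()[first])
    return moved


# --------------------------------------------------------------------------
# surface unrolling
# --------------------------------------------------------------------------

_SEAM_DEG = 150.0  # particles past this azimuth may wrap across the theta = pi seam


def unroll(table: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Unroll a tube-frame table onto the (u, z) plane.

    ``u = radius * theta`` with ``theta = atan2(y, x)`` in (-pi, pi]; the
    seam sits at theta = pi and particles near it are flagged so that
    displacement math can wrap.  Also reports each particle's in-plane
    angle: the azimuth of the body x axis within the local surface tangent
    plane (0 = circumferential, 90 = axial).
    """
    pos = table_positions(table)
    r = np.hypot(pos[:, 0], pos[:, 1])
    if np.any(r < 1.0):
        bad = table["particle_id"].to_numpy()[r < 1.0]
        raise UnmappableParticleError(
            f"particles {bad.tolist()} are within 1 A of the tube axis"
        )
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    rots = table_rotations(table)
    ct, st = np.cos(theta), np.sin(theta)
    xs = np.stack([-st, ct, np.zeros_like(ct)], axis=1)  # +theta tangent
    ys = np.tile([0.0, 0.0, 1.0], (len(theta), 1))  # tube axis
    bodyx = rots[:, :, 0]
    inplane = np.rad2deg(
        np.arctan2(np.sum(bodyx * ys, axis=1), np.sum(bodyx * xs, axis=1))
    )
    return pd.DataFrame(
        {
            "particle_id": table["particle_id"].to_numpy(),
            "u_A": radius * theta,
            "z_A": pos[:, 2],
            "theta_deg": np.rad2deg(theta),
            "inplane_deg": inplane,
            "near_seam": np.abs(np.rad2deg(theta)) > _SEAM_DEG,
        },
        index=table.index,
    )


def wrapped_displacement(theta_a_deg, z_a, theta_b_deg, z_b, radius):
    """Seam-aware unrolled displacement a -> b: (du, dz) in Angstrom."""
    dtheta = wrap_angle_deg(np.asarray(theta_b_deg) - np.asarray(theta_a_deg))
    du = np.deg2rad(dtheta) * radius
    return du, np.asarray(z_b) - np.asarray(z_a)
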