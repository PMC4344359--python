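"""Reciprocal-space geometry for still-shot diffraction.

Conventions
-----------
* The orientation matrix ``A`` (the UB matrix of Busing & Levy) maps an
  integer Miller index ``h`` (column vector) to a reciprocal-space vector
  ``q = A @ h`` in inverse ångströms.  Rows/columns: ``A[i, j]`` is the
  i-th laboratory-Cartesian component of the j-th reciprocal basis vector.
* The beam travels along ``beam.direction`` (unit vector, default +z);
  the incident wavevector is ``S0 = direction / wavelength`` so that a
  reciprocal lattice point ``q`` is in the exact reflecting condition when
  ``|q + S0| = 1/wavelength``.
* The signed Ewald offset is positive when ``q`` lies outside the Ewald
  sphere and negative inside.  Partiality depends only on its magnitude;
  the sign is kept so that orientation derivatives are smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Beam",
    "MosaicModel",
    "Crystal",
    "MisorientationResult",
    "crystal_from_cell",
    "reciprocal_vector",
    "resolution",
    "ewald_offset",
    "rotation_about_axis",
    "beam_perpendicular_axes",
    "apply_rotations",
    "decompose_misorientation",
]

_TOL = 1e-6


@dataclass(frozen=True)
class Beam:
    """Monochromatic (or spectrally sampled) X-ray beam.

    Parameters
    ----------
    wavelength : float
        Nominal wavelength in Å (> 0).
    direction : array-like of 3 floats
        Unit vector along the beam travel direction (laboratory frame).
    spectrum : sequence of (wavelength, weight) pairs, optional
        Per-shot spectrum for polychromatic partiality; weights need not
        be normalised but at least one must be positive.
    """

    wavelength: float
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    spectrum: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-3:
            raise ValueError(f"beam direction must be a unit vector, |d| = {n:.6f}")
        object.__setattr__(self, "direction", d / n)
        if self.spectrum is not None:
            spec = np.atleast_2d(np.asarray(self.spectrum, dtype=float))
            if spec.shape[1] != 2:
                raise ValueError("spectrum must be (wavelength, weight) pairs")
            if np.any(spec[:, 0] <= 0) or np.any(spec[:, 1] < 0):
                raise ValueError("spectrum wavelengths must be > 0 and weights >= 0")
            if not np.any(spec[:, 1] > 0):
                raise ValueError("spectrum must contain at least one positive weight")
            object.__setattr__(self, "spectrum", spec)

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector S0 = direction / wavelength (Å⁻¹)."""
        return self.direction / self.wavelength


@dataclass(frozen=True)
class MosaicModel:
    """Two-parameter crystal-imperfection model.

    ``d_eff`` is the effective mosaic block size in Å (contributes a
    resolution-independent term ``1/d_eff`` to the reciprocal-lattice-point
    radius); ``eta_full`` is the effective *full-width* angular mosaic
    spread in radians (contributes ``(eta_full/2)/d``).
    ``d_eff = inf`` is permitted only together with ``eta_full > 0``.
    """

    d_eff: float
    eta_full: float

    def __post_init__(self):
        if not self.d_eff > 0:
            raise ValueError(f"d_eff must be positive, got {self.d_eff}")
        if self.eta_full < 0:
            raise ValueError(f"eta_full must be non-negative, got {self.eta_full}")
        if math.isinf(self.d_eff) and self.eta_full == 0:
            raise ValueError(
                "d_eff = inf with eta_full = 0 gives a zero-radius reciprocal "
                "lattice point; partiality would be undefined"
            )

    @classmethod
    def from_degrees(cls, d_eff: float, eta_deg: float, half_width: bool = False) -> "MosaicModel":
        """Build from an angular spread quoted in degrees.

        ``half_width=True`` interprets ``eta_deg`` as the half-width value
        (as printed in some program output) and doubles it.
        """
        eta = math.radians(eta_deg) * (2.0 if half_width else 1.0)
        return cls(d_eff=d_eff, eta_full=eta)


def _spacegroup(label: str) -> gemmi.SpaceGroup:
    sg = gemmi.find_spacegroup_by_name(label)
    if sg is None:
        raise ValueError(f"unknown space/point group label: {label!r}")
    return sg


@dataclass(frozen=True)
class Crystal:
    """Oriented crystal: unit cell, UB matrix, symmetry and mosaic model."""

    cell: tuple  # (a, b, c, alpha, beta, gamma) in Å / degrees
    A: np.ndarray  # 3x3, Å⁻¹; q = A @ h
    point_group: str  # space-group or point-group Hermann-Mauguin label
    mosaic: MosaicModel

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.shape != (3, 3):
            raise ValueError("A must be a 3x3 matrix")
        if abs(np.linalg.det(A)) < 1e-30:
            raise ValueError("orientation matrix A is singular")
        object.__setattr__(self, "A", A)
        cell = tuple(float(x) for x in self.cell)
        if len(cell) != 6 or any(x <= 0 for x in cell):
            raise ValueError("cell must be six positive numbers")
        object.__setattr__(self, "cell", cell)
        # A must reproduce the cell metric: G* = A^T A vs gemmi's reciprocal metric
        gstar_a = A.T @ A
        gstar_c = self._gemmi_cell().reciprocal_metric_tensor()
        gstar_cell = np.array(
            [
                [gstar_c.u11, gstar_c.u12, gstar_c.u13],
                [gstar_c.u12, gstar_c.u22, gstar_c.u23],
                [gstar_c.u13, gstar_c.u23, gstar_c.u33],
            ]
        )
        scale = max(np.abs(gstar_cell).max(), 1e-30)
        if np.abs(gstar_a - gstar_cell).max() > 1e-4 * scale:
            raise ValueError("orientation matrix A is inconsistent with the unit cell metric")

    def _gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    @property
    def spacegroup(self) -> gemmi.SpaceGroup:
        return _spacegroup(self.point_group)

    def d_spacing(self, hkl) -> float:
        """Resolution d = 1/|A h| in Å (cell metric, orientation-free)."""
        return self._gemmi_cell().calculate_d(list(int(i) for i in hkl))


def crystal_from_cell(
    cell: Sequence[float],
    point_group: str,
    mosaic: MosaicModel,
    U: Optional[np.ndarray] = None,
) -> Crystal:
    """Construct a crystal from cell parameters and an optional rotation U.

    The zero-rotation reciprocal basis ``B`` is taken from the gemmi
    fractionalisation matrix (reciprocal basis vectors as columns), and
    ``A = U @ B``.
    """
    gcell = gemmi.UnitCell(*cell)
    B = np.array(gcell.frac.mat.tolist()).T
    if U is None:
        A = B
    else:
        U = np.asarray(U, dtype=float)
        A = U @ B
    return Crystal(cell=tuple(cell), A=A, point_group=point_group, mosaic=mosaic)


def reciprocal_vector(crystal: Crystal, hkl) -> np.ndarray:
    """q = A · h in Å⁻¹.  ``hkl`` may be a single index triple or (N, 3)."""
    h = np.asarray(hkl, dtype=float)
    if h.ndim == 1:
        return crystal.A @ h
    return h @ crystal.A.T


def resolution(crystal: Crystal, hkl) -> float:
    """Resolution d = 1/|q| in Å (infinite for h = 0)."""
    q = reciprocal_vector(crystal, hkl)
    n = np.linalg.norm(q, axis=-1)
    if np.ndim(n) == 0:
        return 1.0 / float(n) if n > 0 else math.inf
    with np.errstate(divide="ignore"):
        return np.where(n > 0, 1.0 / np.where(n > 0, n, 1.0), np.inf)


def ewald_offset(q, beam: Beam, wavelength_override: Optional[float] = None):
    """Signed distance from q to the Ewald sphere surface (Å⁻¹).

    Δr_h = |q + S0| − 1/λ, positive outside the sphere, negative inside.
    ``wavelength_override`` evaluates the offset on the Ewald sphere of a
    different wavelength (same beam direction), as needed for the
    polychromatic sum.
    """
    lam = beam.wavelength if wavelength_override is None else wavelength_override
    if lam <= 0:
        raise ValueError("wavelength_override must be positive")
    s0 = beam.direction / lam
    q = np.asarray(q, dtype=float)
    return np.linalg.norm(q + s0, axis=-1) - 1.0 / lam


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by ``angle`` (rad) about ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def beam_perpendicular_axes(beam: Beam) -> tuple[np.ndarray, np.ndarray]:
    """Fixed laboratory axes (x̂, ŷ) orthogonal to each other and to the beam.

    For the default +z beam these are the laboratory x and y axes; for a
    general beam direction they are built deterministically by
    Gram-Schmidt against the laboratory axis least aligned with the beam.
    """
    b = beam.direction
    ref = np.eye(3)[np.argmin(np.abs(b))]
    x = ref - np.dot(ref, b) * b
    x /= np.linalg.norm(x)
    y = np.cross(b, x)
    return x, y


def apply_rotations(crystal: Crystal, theta_x: float, theta_y: float, beam: Beam) -> Crystal:
    """Perturb the orientation: A' = R_y(θ_y) · R_x(θ_x) · A.

    The rotation axes are the fixed laboratory axes perpendicular to the
    beam returned by :func:`beam_perpendicular_axes`; cell and mosaic
    parameters are untouched.
    """
    if not (math.isfinite(theta_x) and math.isfinite(theta_y)):
        raise ValueError("rotation angles must be finite")
    ax, ay = beam_perpendicular_axes(beam)
    R = rotation_about_axis(ay, theta_y) @ rotation_about_axis(ax, theta_x)
    return replace(crystal, A=R @ crystal.A)


@dataclass(frozen=True)
class MisorientationResult:
    """Decomposed misorientation between two indexing solutions.

    ``r_z`` is the rotation about the beam axis (degrees); ``r_xy`` the
    residual rotation about an axis perpendicular to the beam (degrees),
    minimal over lattice-symmetry-equivalent reorientations;
    ``sym_op_used`` the triplet of the point-group operator applied.
    """

    r_z: float
    r_xy: float
    sym_op_used: str


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Polar decomposition: the proper rotation closest to M (Frobenius)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def _rotation_angle(R: np.ndarray) -> float:
    return math.acos(min(1.0, max(-1.0, (np.trace(R) - 1.0) / 2.0)))


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation matrix."""
    t = np.trace(R)
    if t > 0:
        w = math.sqrt(1.0 + t) / 2.0
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
        q = np.array([w, x, y, z])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1e-30, 1.0 + R[i, i] - R[j, j] - R[k, k])) * 2
        v = np.zeros(3)
        v[i] = s / 4
        v[j] = (R[j, i] + R[i, j]) / s
        v[k] = (R[k, i] + R[i, k]) / s
        w = (R[k, j] - R[j, k]) / s
        q = np.array([w, *v])
    return q / np.linalg.norm(q)


def _swing_twist_angles(R: np.ndarray, axis: np.ndarray) -> tuple[float, float]:
    """Split R = swing · twist: twist about ``axis``, swing about an axis ⊥ it.

    Returns (twist angle, swing angle) in radians, both non-negative.
    The swing angle is exactly invariant under extra twist rotations
    applied on either side of R.
    """
    w, x, y, z = _quat_from_matrix(R)
    v = np.array([x, y, z])
    proj = np.dot(v, axis)
    tw = np.array([w, *(proj * axis)])
    n = np.linalg.norm(tw)
    if n < 1e-15:  # pure 180° swing
        return 0.0, math.pi
    tw /= n
    twist_angle = 2.0 * math.acos(min(1.0, abs(tw[0])))
    # swing = q * conj(twist)
    qw, qv = w, v
    tw_w, tw_v = tw[0], tw[1:]
    sw_w = qw * tw_w + np.dot(qv, tw_v)
    sw_v = -qw * tw_v + tw_w * qv - np.cross(qv, tw_v)
    sw_norm = math.sqrt(sw_w**2 + float(np.dot(sw_v, sw_v)))
    swing_angle = 2.0 * math.acos(min(1.0, abs(sw_w / sw_norm)))
    return twist_angle, swing_angle


def _proper_reciprocal_rotations(sg: gemmi.SpaceGroup) -> list[tuple[str, np.ndarray]]:
    """Integer matrices g (acting on Miller indices, h → g h) for the proper
    rotations of the point group, deduplicated over translations."""
    seen = {}
    for op in sg.operations().sym_ops:
        W = np.array(op.rot, dtype=float) / op.DEN
        if np.linalg.det(W) < 0:
            continue
        g = W.T  # reciprocal-space action
        key = tuple(np.round(g.ravel(), 6))
        if key not in seen:
            seen[key] = (op.triplet(), g)
    return list(seen.values())


def decompose_misorientation(
    crystal_model: Crystal, crystal_true: Crystal, beam: Beam
) -> MisorientationResult:
    """Minimal-angle misorientation between two orientation matrices,
    split into beam-axis (r_z) and perpendicular (r_xy) rotations.

    All proper point-group rotations g are tried; the rotation taking
    ``A_model`` to ``A_true · g`` with the smallest total angle is
    decomposed (swing-twist about the beam axis).  Angles in degrees.
    """
    if not np.allclose(crystal_model.cell, crystal_true.cell, rtol=1e-6):
        raise ValueError("crystals have different unit cells")
    if crystal_model.point_group != crystal_true.point_group:
        raise ValueError("crystals have different point groups")
    Am_inv = np.linalg.inv(crystal_model.A)
    best = None
    for triplet, g in _proper_reciprocal_rotations(crystal_model.spacegroup):
        R = _nearest_rotation(crystal_true.A @ g @ Am_inv)
        ang = _rotation_angle(R)
        if best is None or ang < best[0]:
            best = (ang, triplet, R)
    _, triplet, R = best
    twist, swing = _swing_twist_angles(R, beam.direction)
    return MisorientationResult(
        r_z=math.degrees(twist), r_xy=math.degrees(swing), sym_op_used=triplet
    )
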