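"""Per-frame scaling and orientation postrefinement.

Each still image gets its own linear scale ``G`` and isotropic
temperature factor ``B``; optionally the two orientation angles
``theta_x, theta_y`` about the laboratory axes perpendicular to the beam
are refined as well ("postrefinement").  The fit minimises, over the
matched observations h of one frame,

    sum_h [ I_obs(h) − G · exp(−2 B sin²θ_B / λ²) · P_h(θx, θy) · I_ref(h) ]²

against a reference intensity set, with the partiality P_h recomputed
from the θ-perturbed orientation in ``postrefine`` mode and held at its
θ = 0 value in ``scale_only`` mode.  With sin θ_B = λ/2d the
Debye-Waller factor reduces to exp(−B / 2d²), independent of λ.

Scale equivariance: multiplying every reference intensity by c divides
the fitted G by c (the model side carries G·I_ref).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Literal, Optional, Tuple

import gemmi
import numpy as np
from scipy.optimize import least_squares

from .geometry import Beam, Crystal, beam_perpendicular_axes, rotation_about_axis
from .partiality import PartialityRecord, intersection_radius, partiality_mono, rlp_radius, r_zero

__all__ = [
    "Observation",
    "Frame",
    "ReferenceSet",
    "FitConfig",
    "FitReport",
    "remove_negative",
    "scale_residuals",
    "fit_frame",
    "debye_waller",
]

Mode = Literal["scale_only", "postrefine"]


@dataclass(frozen=True)
class Observation:
    """One integrated Bragg-spot measurement on one frame."""

    hkl: Tuple[int, int, int]
    I_raw: float
    sigma: float
    d: float
    partiality_record: Optional[PartialityRecord] = None

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class Frame:
    """A single still image: crystal model, beam, per-frame parameters
    and the list of observations."""

    frame_id: str
    crystal: Crystal
    beam: Beam
    observations: List[Observation]
    G: float = 1.0
    B: float = 0.0
    theta_x: float = 0.0
    theta_y: float = 0.0
    rejected: bool = False

    def with_observations(self, obs: List[Observation]) -> "Frame":
        return replace(self, observations=list(obs))


class ReferenceSet:
    """Reference full-spot intensities keyed by symmetry-reduced index.

    Friedel mates are collapsed (reference intensities are treated as
    non-anomalous).  ``point_group`` is any space- or point-group label
    gemmi recognises.
    """

    def __init__(self, intensities: Dict[tuple, float], point_group: str):
        self.point_group = point_group
        sg = gemmi.find_spacegroup_by_name(point_group)
        if sg is None:
            raise ValueError(f"unknown symmetry label {point_group!r}")
        self._sg = sg
        self._gops = sg.operations()
        self._asu = gemmi.ReciprocalAsu(sg)
        self._table: Dict[tuple, float] = {}
        for hkl, val in intensities.items():
            v = float(val)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"reference intensity for {hkl} must be finite and >= 0")
            self._table[self.reduce(hkl)] = v

    def reduce(self, hkl) -> tuple:
        new_hkl, _ = self._asu.to_asu([int(i) for i in hkl], self._gops)
        return tuple(new_hkl)

    def lookup(self, hkl) -> Optional[float]:
        return self._table.get(self.reduce(hkl))

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()

    def scaled(self, c: float) -> "ReferenceSet":
        return ReferenceSet({k: v * c for k, v in self._table.items()}, self.point_group)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for per-frame fitting."""

    min_obs: int = 10
    max_iter: int = 100
    ftol: float = 1e-8
    b_bounds: Tuple[float, float] = (-25.0, 100.0)
    theta_bound: float = math.radians(1.0)  # rad
    weighted: bool = False  # 1/sigma² residual weighting
    use_partiality: bool = True


@dataclass(frozen=True)
class FitReport:
    frame_id: str
    mode: str
    n_obs: int
    G: float
    B: float
    theta_x_deg: float
    theta_y_deg: float
    rms_before: float
    rms_after: float
    n_iter: int
    converged: bool


def debye_waller(B: float, d) -> np.ndarray | float:
    """exp(−2 B sin²θ_B/λ²) = exp(−B / 2d²)."""
    d = np.asarray(d, dtype=float)
    out = np.exp(-B / (2.0 * d**2))
    return float(out) if out.ndim == 0 else out


def remove_negative(frame: Frame) -> Frame:
    """Drop observations with non-positive raw intensity.

    Negative (and zero) measurements are removed before per-frame
    scaling, mirroring standard practice for partial-intensity scaling.
    """
    kept = [o for o in frame.observations if o.I_raw > 0]
    return frame.with_observations(kept)


def _matched_arrays(frame: Frame, reference: ReferenceSet):
    """hkl (n,3), I_obs, sigma, d, I_ref for observations with a reference entry."""
    rows = []
    for o in frame.observations:
        ref = reference.lookup(o.hkl)
        if ref is None:
            continue
        rows.append((o.hkl, o.I_raw, o.sigma, o.d, ref))
    if not rows:
        return (np.zeros((0, 3), int), np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0))
    hkl = np.array([r[0] for r in rows], dtype=int)
    cols = np.array([[r[1], r[2], r[3], r[4]] for r in rows], dtype=float)
    return hkl, cols[:, 0], cols[:, 1], cols[:, 2], cols[:, 3]


def _partialities(frame: Frame, hkl: np.ndarray, d: np.ndarray, theta_x: float, theta_y: float):
    """Partiality of each index at the θ-perturbed orientation (vectorised)."""
    ax, ay = beam_perpendicular_axes(frame.beam)
    R = rotation_about_axis(ay, theta_y) @ rotation_about_axis(ax, theta_x)
    q = hkl @ (R @ frame.crystal.A).T
    dr = np.linalg.norm(q + frame.beam.s0, axis=1) - 1.0 / frame.beam.wavelength
    return partiality_mono(frame.crystal.mosaic, d, dr), dr


def scale_residuals(
    frame: Frame,
    reference: ReferenceSet,
    params,
    mode: Mode = "postrefine",
    config: FitConfig = FitConfig(),
) -> np.ndarray:
    """Residual vector of the scaling target at the given parameters.

    ``params`` is ``(G, B, theta_x, theta_y)`` (θ ignored in
    ``scale_only`` mode, where partiality is evaluated at θ = 0).
    """
    G, B, tx, ty = (list(params) + [0.0, 0.0])[:4]
    hkl, i_obs, sigma, d, i_ref = _matched_arrays(frame, reference)
    n_free = 2 if mode == "scale_only" else 4
    if len(i_obs) < n_free:
        raise ValueError(
            f"frame {frame.frame_id}: {len(i_obs)} matched observations "
            f"< {n_free} free parameters"
        )
    if mode == "scale_only":
        tx = ty = 0.0
    if config.use_partiality:
        P, _ = _partialities(frame, hkl, d, tx, ty)
    else:
        P = np.ones_like(d)
    model = G * debye_waller(B, d) * P * i_ref
    res = i_obs - model
    if config.weighted:
        res = res / sigma
    return res


def _refresh_partiality(frame: Frame, theta_x: float, theta_y: float) -> List[Observation]:
    """Rebuild each observation's partiality record at the θ-perturbed
    orientation."""
    if not frame.observations:
        return []
    hkl = np.array([o.hkl for o in frame.observations], dtype=int)
    d = np.array([o.d for o in frame.observations], dtype=float)
    P, dr = _partialities(frame, hkl, d, theta_x, theta_y)
    mos = frame.crystal.mosaic
    rq = rlp_radius(mos, d)
    rf = intersection_radius(rq, dr)
    r0 = r_zero(mos)
    out = []
    for i, o in enumerate(frame.observations):
        rec = PartialityRecord(
            hkl=o.hkl,
            d=float(d[i]),
            delta_r=float(dr[i]),
            r_q=float(rq[i]),
            r_zero=r0,
            r_f=float(rf[i]),
            partiality=float(P[i]),
            accepted=abs(dr[i]) <= rq[i],
        )
        out.append(replace(o, partiality_record=rec))
    return out


def fit_frame(
    frame: Frame,
    reference: ReferenceSet,
    mode: Mode = "postrefine",
    config: FitConfig = FitConfig(),
) -> Tuple[Frame, FitReport]:
    """Fit (G, B) or (G, B, θx, θy) for one frame by trust-region least
    squares.

    G is refined on a log scale (enforcing G > 0); B and θ are bounded
    per ``config``.  Initialisation: G from the ratio of summed matched
    intensities at B = 0, θ = 0.  A frame that fails to converge or has
    fewer matched observations than ``config.min_obs`` is returned with
    ``rejected=True`` rather than raising.
    """
    hkl, i_obs, sigma, d, i_ref = _matched_arrays(frame, reference)
    n_free = 2 if mode == "scale_only" else 4
    if len(i_obs) < n_free:
        raise ValueError(
            f"frame {frame.frame_id}: {len(i_obs)} matched observations "
            f"< {n_free} free parameters"
        )
    if len(i_obs) < config.min_obs:
        rep = FitReport(frame.frame_id, mode, len(i_obs), frame.G, frame.B, 0.0, 0.0,
                        math.nan, math.nan, 0, False)
        return replace(frame, rejected=True), rep

    if config.use_partiality:
        P0, _ = _partialities(frame, hkl, d, 0.0, 0.0)
    else:
        P0 = np.ones_like(d)
    denom = float(np.sum(P0 * i_ref))
    g0 = float(np.sum(i_obs)) / denom if denom > 0 else 1.0
    g0 = max(g0, 1e-6)

    w = 1.0 / sigma if config.weighted else np.ones_like(sigma)

    def residuals(x):
        G = math.exp(x[0])
        B = x[1]
        tx, ty = (x[2], x[3]) if mode == "postrefine" else (0.0, 0.0)
        if config.use_partiality:
            P, _ = _partialities(frame, hkl, d, tx, ty)
        else:
            P = P0
        return w * (i_obs - G * debye_waller(B, d) * P * i_ref)

    lo = [-50.0, config.b_bounds[0]]
    hi = [50.0, config.b_bounds[1]]
    x0 = [math.log(g0), 0.0]
    if mode == "postrefine":
        lo += [-config.theta_bound] * 2
        hi += [config.theta_bound] * 2
        x0 += [0.0, 0.0]

    r0 = residuals(np.array(x0))
    rms_before = float(np.sqrt(np.mean(r0**2)))
    try:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.ftol,
            gtol=1e-12,
            max_nfev=config.max_iter * (len(x0) + 1),
        )
        converged = bool(sol.status > 0)
    except Exception:
        rep = FitReport(frame.frame_id, mode, len(i_obs), frame.G, frame.B, 0.0, 0.0,
                        rms_before, math.nan, 0, False)
        return replace(frame, rejected=True), rep

    G = math.exp(sol.x[0])
    B = float(sol.x[1])
    tx, ty = (float(sol.x[2]), float(sol.x[3])) if mode == "postrefine" else (0.0, 0.0)
    rms_after = float(np.sqrt(np.mean(sol.fun**2)))
    fitted = replace(frame, G=G, B=B, theta_x=tx, theta_y=ty, rejected=not converged)
    fitted = fitted.with_observations(_refresh_partiality(fitted, tx, ty))
    rep = FitReport(
        frame.frame_id, mode, len(i_obs), G, B,
        math.degrees(tx), math.degrees(ty), rms_before, rms_after,
        int(sol.nfev), converged,
    )
    return fitted, rep
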