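"""Still-shot partiality from the two-parameter mosaic model.

A still exposure records only part of each reflection's full integrated
intensity because, without rotation, a reciprocal lattice point (rlp)
merely intersects the Ewald sphere instead of sweeping through it.
Crystal imperfection widens the rlp into a ball of radius

    r_Q(d) = 1/d_eff + (eta_full / 2) / d

where ``d_eff`` is the effective mosaic block size (Å) and ``eta_full``
the effective full-width angular mosaic spread (rad).  The ball/sphere
intersection is a spherical cap whose area is approximated by a flat
circle of radius ``r_F = sqrt(r_Q² − Δr²)`` with ``Δr`` the distance
from the rlp centre to the Ewald sphere.  Partiality is the
area-to-volume ratio of the intersection, normalised by the same ratio
for the F000 point at the reciprocal-space origin (which always sits
exactly on the sphere and whose angular broadening vanishes):

    P = (π r_F² / V_Q) / (π r_0² / V_0) = r_F² · r_0 / r_Q³,
    r_0 = r_Q(d → ∞) = 1/d_eff.

P is 1 only in the limit eta_full = 0, Δr = 0; with angular spread it
peaks below 1 at Δr = 0 and falls to 0 at |Δr| = r_Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Beam, Crystal, MosaicModel, ewald_offset, reciprocal_vector

__all__ = [
    "PartialityRecord",
    "rlp_radius",
    "intersection_radius",
    "partiality_mono",
    "partiality_poly",
    "correct_to_full",
    "resample_spectrum",
    "partiality_record",
]


@dataclass(frozen=True)
class PartialityRecord:
    """Per-reflection geometry and partiality bookkeeping.

    ``accepted`` is False whenever the rlp ball misses the Ewald sphere
    (|delta_r| > r_q); such measurements carry no Bragg signal under the
    model and are discarded before correction.
    """

    hkl: tuple
    d: float
    delta_r: float
    r_q: float
    r_zero: float
    r_f: float
    partiality: float
    accepted: bool


def rlp_radius(mosaic: MosaicModel, d) -> np.ndarray | float:
    """Effective reciprocal-lattice-point radius r_Q at resolution d (Å⁻¹).

    The size term ``1/d_eff`` is resolution-independent; the angular term
    ``(eta_full/2)/d`` grows with resolution.  ``d = inf`` (the F000
    point) returns the size term alone.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("resolution d must be positive (or inf)")
    size_term = 0.0 if math.isinf(mosaic.d_eff) else 1.0 / mosaic.d_eff
    with np.errstate(divide="ignore"):
        angular = np.where(np.isinf(d_arr), 0.0, (mosaic.eta_full / 2.0) / np.where(np.isinf(d_arr), 1.0, d_arr))
    out = size_term + angular
    return float(out) if np.ndim(d) == 0 else out


def r_zero(mosaic: MosaicModel) -> float:
    """Radius of the F000 reciprocal lattice point (size term only)."""
    return rlp_radius(mosaic, math.inf)


def intersection_radius(r_q, delta_r) -> np.ndarray | float:
    """Radius r_F of the circle approximating the Ewald-sphere/rlp cap.

    r_F = sqrt(r_Q² − Δr²) inside the ball, 0 once |Δr| ≥ r_Q
    (right-triangle construction; the chord through the ball).
    """
    r_q = np.asarray(r_q, dtype=float)
    if np.any(r_q <= 0):
        raise ValueError("r_q must be positive")
    dr = np.asarray(delta_r, dtype=float)
    out = np.sqrt(np.maximum(0.0, r_q**2 - dr**2))
    return float(out) if out.ndim == 0 else out


def partiality_mono(mosaic: MosaicModel, d, delta_r) -> np.ndarray | float:
    """Monochromatic partiality P ∈ [0, 1].

    P = r_F² · r_0 / r_Q³ with r_F the intersection-circle radius, r_Q
    the rlp radius at resolution ``d`` and r_0 the F000 radius.  Accepts
    scalars or broadcastable arrays for ``d`` and ``delta_r``.
    """
    if math.isinf(mosaic.d_eff):
        raise ValueError(
            "partiality is undefined for d_eff = inf: the F000 normaliser "
            "1/d_eff vanishes"
        )
    rq = rlp_radius(mosaic, d)
    r0 = r_zero(mosaic)
    rf = intersection_radius(rq, delta_r)
    out = np.clip((np.asarray(rf) ** 2) * r0 / np.asarray(rq) ** 3, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def resample_spectrum(spectrum: np.ndarray, max_points: int = 512) -> np.ndarray:
    """Weight-conserving aggregation of a dense spectrum to ≤ max_points.

    Consecutive samples (ordered in wavelength) are pooled; each pooled
    point carries the summed weight at the weight-averaged wavelength.
    """
    spec = np.atleast_2d(np.asarray(spectrum, dtype=float))
    if spec.shape[0] <= max_points:
        return spec
    edges = np.linspace(0, spec.shape[0], max_points + 1).astype(int)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        w = spec[lo:hi, 1].sum()
        if w > 0:
            lam = np.average(spec[lo:hi, 0], weights=spec[lo:hi, 1])
        else:
            lam = spec[lo:hi, 0].mean()
        out.append((lam, w))
    return np.array(out)


def partiality_poly(mosaic: MosaicModel, crystal: Crystal, hkl, beam: Beam) -> float:
    """Polychromatic partiality: spectrum-weighted mean of the
    monochromatic partiality with the energy-dependent Ewald offset.

    Each spectral line of wavelength λ_i defines its own Ewald sphere;
    Δr_h(λ_i) is evaluated at fixed orientation and the monochromatic
    partialities are averaged with the (internally normalised) weights.
    """
    if beam.spectrum is None:
        raise ValueError("beam has no spectrum; use partiality_mono")
    spec = beam.spectrum
    wsum = spec[:, 1].sum()
    if wsum <= 0:
        raise ValueError("spectrum weights sum to zero")
    q = reciprocal_vector(crystal, hkl)
    qn = float(np.linalg.norm(q))
    d = math.inf if qn == 0 else 1.0 / qn
    total = 0.0
    for lam, w in spec:
        if w <= 0:
            continue
        dr = ewald_offset(q, beam, wavelength_override=float(lam))
        total += w * partiality_mono(mosaic, d, dr)
    return total / wsum


def correct_to_full(I, sigma, P, p_min: float = 0.0, accepted=True):
    """Scale a partial measurement to its full-spot equivalent.

    Returns ``(I_full, sigma_full, accepted)`` with I_full = I/P and
    sigma_full = sigma/P.  The measurement is rejected (NaN outputs)
    when the caller-supplied geometric flag is False (|Δr| > r_Q) or
    when P < p_min; ``p_min = 0`` reproduces the bare geometric filter.
    """
    I = np.asarray(I, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("partiality must lie in [0, 1]")
    ok = np.asarray(accepted, dtype=bool) & (P >= max(p_min, 1e-300)) & (P > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i_full = np.where(ok, I / np.where(ok, P, 1.0), np.nan)
        s_full = np.where(ok, sigma / np.where(ok, P, 1.0), np.nan)
    if i_full.ndim == 0:
        return float(i_full), float(s_full), bool(ok)
    return i_full, s_full, ok


def partiality_record(
    crystal: Crystal,
    beam: Beam,
    hkl,
    mosaic: Optional[MosaicModel] = None,
) -> PartialityRecord:
    """Full per-reflection record for one Miller index at the crystal's
    current orientation (monochromatic)."""
    mos = mosaic if mosaic is not None else crystal.mosaic
    q = reciprocal_vector(crystal, hkl)
    qn = float(np.linalg.norm(q))
    d = math.inf if qn == 0 else 1.0 / qn
    dr = float(ewald_offset(q, beam))
    rq = rlp_radius(mos, d)
    rf = intersection_radius(rq, dr)
    p = partiality_mono(mos, d, dr)
    return PartialityRecord(
        hkl=tuple(int(i) for i in np.asarray(hkl).ravel()),
        d=d,
        delta_r=dr,
        r_q=rq,
        r_zero=r_zero(mos),
        r_f=rf,
        partiality=p,
        accepted=abs(dr) <= rq,
    )
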