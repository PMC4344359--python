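"""Synthetic still-shot data with the statistical structure the pipeline
assumes.

The generator works at the reflection level (no pixels, no detector):
ground-truth intensities follow Wilson statistics with a Debye-Waller
resolution falloff; each frame gets a uniformly random orientation, a
log-normal scale G, a temperature factor B, partiality attenuation under
the two-parameter mosaic model, Gaussian measurement noise, and a small
deliberate misorientation between the recorded ("indexed") orientation
and the true one, so that orientation recovery can be scored.

All randomness flows from one seed; each frame draws from its own
substream, so adding frames never changes earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .geometry import Beam, Crystal, MosaicModel, crystal_from_cell, rotation_about_axis
from .merge_qc import merge, per_lattice_cutoff, qc_report, unique_indices_in_range
from .partiality import partiality_mono, rlp_radius
from .postrefine import (
    FitConfig,
    Frame,
    Observation,
    ReferenceSet,
    debye_waller,
    fit_frame,
    remove_negative,
)

__all__ = [
    "SimConfig",
    "FrameTruth",
    "generate_truth",
    "generate_frames",
    "protocol_experiment",
    "PROTOCOLS",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic still-shot experiment.

    Defaults follow the regime of the thermolysin XFEL analysis this
    pipeline targets: wavelength 1.269 Å, mosaic block size 4220 Å and a
    0.168° half-width (0.336° full-width) mosaic spread, with an
    orthorhombic test cell small enough to keep per-frame reflection
    counts in the hundreds.
    """

    cell: Tuple[float, ...] = (55.0, 60.0, 70.0, 90.0, 90.0, 90.0)
    point_group: str = "P 21 21 21"
    d_max: float = 30.0  # low-resolution limit, Å
    d_min: float = 2.2  # high-resolution limit, Å
    n_frames: int = 25
    wavelength: float = 1.269  # Å
    d_eff: float = 4220.0  # mosaic block size, Å
    eta_full_deg: float = 0.336  # full-width mosaic spread, degrees
    mosaic_jitter: float = 0.0  # fractional per-frame jitter on both mosaic parameters
    g_median: float = 1.0  # log-normal scale distribution
    g_sigma: float = 0.3  # sigma of ln G
    b_range: Tuple[float, float] = (0.0, 10.0)  # per-frame B, Å²
    truth_scale: float = 1000.0  # mean low-resolution truth intensity
    b_truth: float = 25.0  # Wilson falloff of the truth, Å²
    gain: float = 1.0  # noise: sigma² = gain·I + background²
    background_sigma: float = 15.0  # puts the resolution edge near I/σ ≈ 0.5
    orientation_err_deg: float = 0.03  # magnitude of the injected R_xy error
    record_fraction: float = 1.0  # fraction of accepted reflections recorded
    seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0 or self.d_max <= self.d_min:
            raise ValueError("need 0 < d_min < d_max")
        for name in ("wavelength", "d_eff", "truth_scale", "g_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mosaic(self) -> MosaicModel:
        return MosaicModel(d_eff=self.d_eff, eta_full=math.radians(self.eta_full_deg))

    @property
    def beam(self) -> Beam:
        return Beam(wavelength=self.wavelength)


@dataclass(frozen=True)
class FrameTruth:
    """Generating parameters of one frame, for scoring recovery."""

    frame_id: str
    crystal_true: Crystal
    G: float
    B: float


def _truth_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))


def _frame_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1, index)))


def generate_truth(config: SimConfig) -> Tuple[ReferenceSet, Dict[tuple, bool]]:
    """Wilson-distributed ground-truth intensities for every unique index.

    Acentric reflections draw from an exponential distribution, centric
    ones from the half-normal-squared (one-degree chi-square) law, both
    with mean ⟨I⟩(d) = truth_scale · exp(−B_truth/2d²).  Returns the
    reference set and per-index centricity flags.  Deterministic under
    ``config.seed``.
    """
    rng = _truth_rng(config)
    hkl = unique_indices_in_range(config.cell, config.point_group, config.d_max, config.d_min)
    if len(hkl) == 0:
        raise ValueError("resolution range contains no Miller indices")
    gcell = gemmi.UnitCell(*config.cell)
    sg = gemmi.find_spacegroup_by_name(config.point_group)
    gops = sg.operations()
    d = np.array([gcell.calculate_d([int(a), int(b), int(c)]) for a, b, c in hkl])
    mean = config.truth_scale * debye_waller(config.b_truth, d)
    centric = np.array([
        gops.is_reflection_centric([int(a), int(b), int(c)]) for a, b, c in hkl
    ])
    # acentric: Exp(mean); centric: mean * chi2_1 (both have the right mean)
    i_ac = rng.exponential(scale=np.where(mean > 0, mean, 1.0))
    i_ce = mean * rng.standard_normal(len(hkl)) ** 2
    intensities = np.where(centric, i_ce, i_ac)
    table = {tuple(int(x) for x in row): float(v) for row, v in zip(hkl, intensities)}
    flags = {tuple(int(x) for x in row): bool(c) for row, c in zip(hkl, centric)}
    return ReferenceSet(table, config.point_group), flags


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalised Gaussian quaternion."""
    q = rng.standard_normal(4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _full_sphere_indices(config: SimConfig) -> Tuple[np.ndarray, np.ndarray]:
    """All Miller indices (both Friedel branches) in the resolution range,
    with their d-spacings."""
    gcell = gemmi.UnitCell(*config.cell)
    hmax = [int(x / config.d_min) + 1 for x in (gcell.a, gcell.b, gcell.c)]
    h, k, l = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1, -hmax[2]:hmax[2] + 1]
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    gstar = gcell.reciprocal_metric_tensor()
    G = np.array([
        [gstar.u11, gstar.u12, gstar.u13],
        [gstar.u12, gstar.u22, gstar.u23],
        [gstar.u13, gstar.u23, gstar.u33],
    ])
    d = 1.0 / np.sqrt(np.einsum("ij,jk,ik->i", hkl, G, hkl))
    keep = (d >= config.d_min) & (d <= config.d_max)
    return hkl[keep], d[keep]


def generate_frames(
    truth: ReferenceSet, config: SimConfig
) -> Tuple[List[Frame], List[FrameTruth]]:
    """Simulate still frames against a ground-truth intensity set.

    Per frame: a uniformly random true orientation; every index with
    |Δr| ≤ r_Q under the true mosaic model is recorded with
    I_raw = G · exp(−B/2d²) · P_true · I_truth + ε,  ε ~ N(0, σ),
    σ = (gain·max(I_model,0) + background²)^½; the stored ("indexed")
    orientation is the true one rotated by ``orientation_err_deg`` about
    a random axis perpendicular to the beam.
    """
    beam = config.beam
    hkl_all, d_all = _full_sphere_indices(config)
    frames: List[Frame] = []
    truths: List[FrameTruth] = []
    for i in range(config.n_frames):
        rng = _frame_rng(config, i)
        U = _random_rotation(rng)
        mos = config.mosaic
        if config.mosaic_jitter > 0:
            f1 = 1.0 + config.mosaic_jitter * rng.standard_normal()
            f2 = 1.0 + config.mosaic_jitter * rng.standard_normal()
            mos = MosaicModel(d_eff=config.d_eff * max(f1, 0.1),
                              eta_full=math.radians(config.eta_full_deg) * max(f2, 0.0))
        crystal_true = crystal_from_cell(config.cell, config.point_group, mos, U=U)
        G = config.g_median * math.exp(config.g_sigma * rng.standard_normal())
        B = rng.uniform(*config.b_range)

        q = hkl_all @ crystal_true.A.T
        dr = np.linalg.norm(q + beam.s0, axis=1) - 1.0 / config.wavelength
        rq = rlp_radius(mos, d_all)
        acc = np.abs(dr) <= rq
        if not np.any(acc):
            raise ValueError(
                f"frame {i}: no reflections within acceptance; mosaic parameters "
                f"(d_eff={mos.d_eff}, eta_full={mos.eta_full}) too small for this geometry"
            )
        sel = np.where(acc)[0]
        if config.record_fraction < 1.0:
            keep = rng.random(len(sel)) < config.record_fraction
            sel = sel[keep]
        P = partiality_mono(mos, d_all[sel], dr[sel])
        i_truth = np.array([truth.lookup(h) for h in hkl_all[sel]], dtype=float)
        dw = debye_waller(B, d_all[sel])
        i_model = G * dw * P * i_truth
        sigma = np.sqrt(config.gain * np.maximum(i_model, 0.0) + config.background_sigma**2)
        sigma = np.maximum(sigma, 1e-9)
        noise = rng.standard_normal(len(sel)) * sigma if (
            config.gain > 0 or config.background_sigma > 0
        ) else np.zeros(len(sel))
        i_raw = i_model + noise

        # indexed orientation: true one rotated by R_xy about a random ⊥-beam axis
        if config.orientation_err_deg > 0:
            phi = rng.uniform(0, 2 * math.pi)
            axis = np.array([math.cos(phi), math.sin(phi), 0.0])  # ⊥ default +z beam
            b = beam.direction
            axis = axis - np.dot(axis, b) * b
            axis /= np.linalg.norm(axis)
            R_err = rotation_about_axis(axis, math.radians(config.orientation_err_deg))
            crystal_indexed = replace(crystal_true, A=R_err @ crystal_true.A)
        else:
            crystal_indexed = crystal_true

        obs = [
            Observation(
                hkl=tuple(int(x) for x in hkl_all[j]),
                I_raw=float(i_raw[n]),
                sigma=float(sigma[n]),
                d=float(d_all[j]),
            )
            for n, j in enumerate(sel)
        ]
        fid = f"sim_{i:05d}"
        frames.append(Frame(frame_id=fid, crystal=crystal_indexed, beam=beam, observations=obs))
        truths.append(FrameTruth(frame_id=fid, crystal_true=crystal_true, G=G, B=B))
    return frames, truths


# ---------------------------------------------------------------------------
# protocol comparison

PROTOCOLS = {
    # name: (fit mode, partiality correction, I/sigma bin cutoff)
    "scale_only": ("scale_only", False, 0.5),
    "scale_only_fixedres": ("scale_only", False, None),
    "postrefine": ("postrefine", True, 0.5),
    "postrefine_fixedres": ("postrefine", True, None),
}


def run_protocol(
    frames: Sequence[Frame],
    reference: ReferenceSet,
    config: SimConfig,
    protocol: str,
    fit_config: Optional[FitConfig] = None,
    split_seed: int = 0,
    n_pairs: int = 20_000,
    p_min: float = 0.1,
):
    """Run one processing protocol end-to-end on prepared frames.

    Returns (merged set, QC report, fit reports).  Protocols mirror the
    standard comparison: scale-only fits (G, B) with no partiality
    correction; postrefine protocols correct partiality and refine the
    orientation; the *_fixedres variants disable the per-lattice I/σ
    cutoff.  ``p_min`` floors the partiality used for correction
    (guarding against exploding I/P variance); it is ignored by the
    scale-only protocols.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}")
    mode, use_part, threshold = PROTOCOLS[protocol]
    fc = fit_config or FitConfig()
    fc = replace(fc, use_partiality=use_part)
    fitted, reports = [], []
    for f in frames:
        f = per_lattice_cutoff(f, threshold)
        f = remove_negative(f)
        if len(f.observations) < fc.min_obs:
            continue
        ff, rep = fit_frame(f, reference, mode=mode, config=fc)
        reports.append(rep)
        if not ff.rejected:
            fitted.append(ff)
    if not fitted:
        raise ValueError(f"protocol {protocol}: no frames survived fitting")
    merged = merge(
        fitted, config.point_group, d_range=(config.d_max, config.d_min),
        anomalous=False, use_partiality=use_part, p_min=p_min if use_part else 0.0,
    )
    qc = qc_report(
        merged, frames=fitted, seed=split_seed, n_pairs=n_pairs,
        use_partiality=use_part, p_min=p_min if use_part else 0.0,
    )
    return merged, qc, reports


def truth_correlation(merged, reference: ReferenceSet) -> float:
    """Pearson correlation between merged and ground-truth intensities
    over the common symmetry-unique indices."""
    truth_tab = pd.DataFrame(
        [(h, k, l, v) for (h, k, l), v in reference.items()],
        columns=["h", "k", "l", "I_true"],
    )
    j = merged.table.merge(truth_tab, on=["h", "k", "l"])
    if len(j) < 3:
        raise ValueError("too few common indices with the truth")
    return float(pearsonr(j["I"], j["I_true"])[0])


def protocol_experiment(
    config: SimConfig,
    protocols: Sequence[str] = ("scale_only", "postrefine"),
    split_seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline under several protocols on identical frames.

    Returns a table (statistics × protocols) reporting merged-vs-truth
    correlation, multiplicity, completeness and the QC statistics, one
    column per protocol.
    """
    if not protocols:
        raise ValueError("no protocols requested")
    truth, _ = generate_truth(config)
    frames, _ = generate_frames(truth, config)
    cols = {}
    for proto in protocols:
        merged, qc, reports = run_protocol(
            frames, truth, config, proto, split_seed=split_seed
        )
        cols[proto] = {
            "n_frames_merged": merged.n_frames,
            "n_unique": qc.n_unique,
            "multiplicity": qc.multiplicity_mean,
            "completeness": qc.completeness,
            "cc_truth": truth_correlation(merged, truth),
            "cc_half": qc.cc_half,
            "r_split": qc.r_split,
            "moment_ratio": qc.moment_ratio,
            "mean_abs_l": qc.mean_abs_l,
            "mean_l2": qc.mean_l2,
            "nz_max_dev_acentric": qc.nz_max_dev_acentric,
            "nz_max_dev_centric": qc.nz_max_dev_centric,
        }
    return pd.DataFrame(cols)
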