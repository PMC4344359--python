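"""Merging of corrected still-shot intensities and intensity-distribution QC.

Covers per-lattice resolution cutoffs, symmetry-reduced merging with
multiplicity/completeness accounting, semi-dataset agreement statistics
(CC_1/2 and R_split), Wilson second-moment checks, the Padilla-Yeates
L-test and the cumulative N(z) test against the acentric/centric Wilson
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd
from scipy.special import erf
from scipy.stats import pearsonr

from .postrefine import Frame, debye_waller

__all__ = [
    "MergedSet",
    "QCReport",
    "resolution_shells",
    "per_lattice_cutoff",
    "corrected_intensities",
    "merge",
    "semi_dataset_stats",
    "wilson_moment",
    "l_test",
    "nz_test",
    "shell_i_over_sigma",
    "qc_report",
    "unique_indices_in_range",
]


# ---------------------------------------------------------------------------
# resolution shells


def resolution_shells(d: np.ndarray, n_bins: int, d_range: Optional[Tuple[float, float]] = None):
    """Assign equal-volume resolution shells (uniform in 1/d³).

    Returns (bin index per observation, shell edges in d).  Shell 0 is the
    lowest-resolution (largest d) shell.  ``d_range`` is (d_max, d_min).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 resolution shells")
    d = np.asarray(d, dtype=float)
    if d_range is None:
        d_max, d_min = float(np.max(d)), float(np.min(d))
    else:
        d_max, d_min = d_range
    s3 = 1.0 / d**3
    edges_s3 = np.linspace(1.0 / d_max**3, 1.0 / d_min**3, n_bins + 1)
    idx = np.clip(np.searchsorted(edges_s3, s3, side="right") - 1, 0, n_bins - 1)
    d_edges = edges_s3 ** (-1.0 / 3.0)
    return idx, d_edges


def per_lattice_cutoff(frame: Frame, threshold: Optional[float], n_bins: int = 10) -> Frame:
    """Truncate one frame at the resolution where its signal dies.

    Observations are binned into ``n_bins`` equal-volume shells; scanning
    from low to high resolution, the frame is cut at the first shell
    whose mean I/σ drops below ``threshold`` (that shell and everything
    beyond it are dropped).  ``threshold=None`` disables the cutoff
    (fixed-resolution protocols).
    """
    if threshold is None:
        return frame
    if n_bins < 2:
        raise ValueError("need at least 2 resolution shells")
    obs = frame.observations
    if not obs:
        return frame
    d = np.array([o.d for o in obs])
    i_over_sig = np.array([o.I_raw / o.sigma for o in obs])
    idx, _ = resolution_shells(d, n_bins)
    keep_mask = np.ones(len(obs), dtype=bool)
    cut = False
    for b in range(n_bins):
        sel = idx == b
        if cut:
            keep_mask[sel] = False
            continue
        if not np.any(sel):
            continue
        if float(np.mean(i_over_sig[sel])) < threshold:
            cut = True
            keep_mask[sel] = False
    return frame.with_observations([o for o, k in zip(obs, keep_mask) if k])


# ---------------------------------------------------------------------------
# merging


@dataclass
class MergedSet:
    """Symmetry-reduced merged intensities with bookkeeping.

    ``table`` columns: h, k, l, sign (±1, Friedel branch; +1 everywhere
    when Friedel mates are collapsed), d, I, sigma, multiplicity,
    centric (bool).
    """

    table: pd.DataFrame
    point_group: str
    cell: tuple
    d_range: Tuple[float, float]  # (d_max, d_min)
    completeness: float
    n_frames: int
    anomalous: bool
    shell_completeness: Optional[pd.DataFrame] = None

    @property
    def intensities(self) -> np.ndarray:
        return self.table["I"].to_numpy()


def unique_indices_in_range(cell, point_group: str, d_max: float, d_min: float) -> np.ndarray:
    """All symmetry-unique Miller indices (Friedel-collapsed) with
    d_min ≤ d ≤ d_max, as an (n, 3) integer array."""
    gcell = gemmi.UnitCell(*cell)
    sg = gemmi.find_spacegroup_by_name(point_group)
    if sg is None:
        raise ValueError(f"unknown symmetry label {point_group!r}")
    gops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    hmax = [int(x / d_min) + 1 for x in (gcell.a, gcell.b, gcell.c)]
    h, k, l = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1, -hmax[2]:hmax[2] + 1]
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    gstar = gcell.reciprocal_metric_tensor()
    G = np.array([
        [gstar.u11, gstar.u12, gstar.u13],
        [gstar.u12, gstar.u22, gstar.u23],
        [gstar.u13, gstar.u23, gstar.u33],
    ])
    q2 = np.einsum("ij,jk,ik->i", hkl, G, hkl)
    d = 1.0 / np.sqrt(q2)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    reduced = {tuple(asu.to_asu([int(a) for a in row], gops)[0]) for row in hkl}
    return np.array(sorted(reduced), dtype=int)


def corrected_intensities(frame: Frame, use_partiality: bool = True, p_min: float = 0.0):
    """Fully corrected intensities of one fitted frame.

    I_corr = I_raw / (G · exp(−B/2d²) · P); observations outside the
    geometric acceptance (|Δr| > r_Q) or below ``p_min`` are dropped.
    Returns a DataFrame (h, k, l, d, I, sigma).
    """
    rows = []
    for o in frame.observations:
        P = 1.0
        if use_partiality:
            rec = o.partiality_record
            if rec is None or not rec.accepted or rec.partiality < max(p_min, 1e-300):
                continue
            P = rec.partiality
        scale = frame.G * debye_waller(frame.B, o.d) * P
        if scale <= 0:
            continue
        rows.append((*o.hkl, o.d, o.I_raw / scale, o.sigma / scale))
    return pd.DataFrame(rows, columns=["h", "k", "l", "d", "I", "sigma"])


def merge(
    frames: Sequence[Frame],
    point_group: str,
    d_range: Optional[Tuple[float, float]] = None,
    anomalous: bool = True,
    use_partiality: bool = True,
    p_min: float = 0.0,
    n_shells: int = 10,
) -> MergedSet:
    """Merge corrected observations from fitted frames.

    Each observation is mapped to its symmetry-reduced index (Friedel
    mates kept separate when ``anomalous``); the merged intensity is the
    unweighted mean of duplicates and the merged σ is the larger of the
    propagated estimate and the sample-scatter estimate (for
    multiplicity ≥ 2).  Completeness is reported against every unique
    index of the cell/point group within the resolution range.
    """
    frames = [f for f in frames if not f.rejected]
    if not frames:
        raise ValueError("no frames to merge")
    sg = gemmi.find_spacegroup_by_name(point_group)
    if sg is None:
        raise ValueError(f"unknown symmetry label {point_group!r}")
    gops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    cell = frames[0].crystal.cell

    parts = []
    for f in frames:
        df = corrected_intensities(f, use_partiality=use_partiality, p_min=p_min)
        if len(df):
            parts.append(df)
    if not parts:
        raise ValueError("no accepted observations to merge")
    obs = pd.concat(parts, ignore_index=True)

    if d_range is None:
        d_range = (float(obs["d"].max()), float(obs["d"].min()))
    d_max, d_min = d_range
    obs = obs[(obs["d"] >= d_min) & (obs["d"] <= d_max)].reset_index(drop=True)
    if not len(obs):
        raise ValueError("no observations inside the resolution range")

    red = np.empty((len(obs), 3), dtype=int)
    sign = np.empty(len(obs), dtype=int)
    for i, (h, k, l) in enumerate(obs[["h", "k", "l"]].to_numpy()):
        new_hkl, isym = asu.to_asu([int(h), int(k), int(l)], gops)
        red[i] = new_hkl
        sign[i] = 1 if isym % 2 == 1 else -1  # odd isym: direct, even: Friedel mate
    obs["h"], obs["k"], obs["l"] = red[:, 0], red[:, 1], red[:, 2]
    obs["sign"] = sign if anomalous else 1

    grouped = obs.groupby(["h", "k", "l", "sign"], sort=True)
    agg = grouped.agg(
        I=("I", "mean"),
        d=("d", "mean"),
        multiplicity=("I", "size"),
        scatter=("I", "std"),
        sumsig2=("sigma", lambda s: float(np.sum(np.square(s)))),
    ).reset_index()
    n = agg["multiplicity"].to_numpy().astype(float)
    propagated = np.sqrt(agg["sumsig2"].to_numpy()) / n
    scatter = np.nan_to_num(agg["scatter"].to_numpy(), nan=0.0) / np.sqrt(n)
    agg["sigma"] = np.where(n >= 2, np.maximum(propagated, scatter), propagated)
    agg["centric"] = [
        gops.is_reflection_centric([int(h), int(k), int(l)])
        for h, k, l in agg[["h", "k", "l"]].to_numpy()
    ]
    table = agg[["h", "k", "l", "sign", "d", "I", "sigma", "multiplicity", "centric"]]

    full = unique_indices_in_range(cell, point_group, d_max, d_min)
    present = {tuple(r) for r in table[["h", "k", "l"]].to_numpy()}
    completeness = len({tuple(r) for r in full} & present) / max(len(full), 1)

    # per-shell completeness over the unique index set
    gcell = gemmi.UnitCell(*cell)
    d_full = np.array([gcell.calculate_d([int(a), int(b), int(c)]) for a, b, c in full])
    idx, d_edges = resolution_shells(d_full, n_shells, d_range)
    shell_rows = []
    for b in range(n_shells):
        sel = idx == b
        tot = int(np.sum(sel))
        got = sum(1 for row in full[sel] if tuple(row) in present)
        shell_rows.append((d_edges[b], d_edges[b + 1], tot, got, got / tot if tot else math.nan))
    shells = pd.DataFrame(shell_rows, columns=["d_max", "d_min", "n_theory", "n_obs", "completeness"])

    return MergedSet(
        table=table,
        point_group=point_group,
        cell=tuple(cell),
        d_range=(d_max, d_min),
        completeness=float(completeness),
        n_frames=len(frames),
        anomalous=anomalous,
        shell_completeness=shells,
    )


def semi_dataset_stats(
    frames: Sequence[Frame],
    point_group: str,
    split_seed: int = 0,
    **merge_kwargs,
) -> Tuple[float, float]:
    """CC_1/2 and R_split from a random half-and-half split of the frames.

    Frames are split into two halves (seeded), each half merged
    independently, and over the common indices:

        CC_1/2  = Pearson correlation of the two merged intensity sets
        R_split = 2^(−1/2) · Σ|I₁ − I₂| / (½ Σ(I₁ + I₂))
    """
    frames = [f for f in frames if not f.rejected]
    if len(frames) < 2:
        raise ValueError("need at least two frames for semi-dataset statistics")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(len(frames))
    half1 = [frames[i] for i in perm[: len(frames) // 2]]
    half2 = [frames[i] for i in perm[len(frames) // 2:]]
    m1 = merge(half1, point_group, **merge_kwargs)
    m2 = merge(half2, point_group, **merge_kwargs)
    keys = ["h", "k", "l", "sign"]
    j = m1.table.merge(m2.table, on=keys, suffixes=("_1", "_2"))
    if not len(j):
        raise ValueError("half-datasets share no indices")
    i1, i2 = j["I_1"].to_numpy(), j["I_2"].to_numpy()
    cc_half = float(pearsonr(i1, i2)[0]) if len(j) > 1 else 1.0
    denom = 0.5 * float(np.sum(i1 + i2))
    r_split = float(np.sum(np.abs(i1 - i2)) / (math.sqrt(2.0) * denom)) if denom else math.inf
    return cc_half, r_split


# ---------------------------------------------------------------------------
# intensity-distribution statistics


def wilson_moment(intensities) -> float:
    """Second-moment ratio ⟨I²⟩/⟨I⟩² (acentric Wilson theory: 2.0;
    centric: 3.0)."""
    I = np.asarray(intensities, dtype=float)
    if I.size < 2 or not np.all(np.isfinite(I)):
        raise ValueError("need at least two finite intensities")
    mean = I.mean()
    if mean == 0:
        raise ValueError("mean intensity is zero")
    return float(np.mean(I**2) / mean**2)


def _ks_deviation(sample: np.ndarray, theory_cdf) -> float:
    """Exact sup-deviation between the empirical CDF of ``sample`` and a
    theoretical CDF (evaluated at the sample points, both one-sided)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    t = theory_cdf(x)
    upper = np.arange(1, n + 1) / n - t
    lower = t - np.arange(0, n) / n
    return float(max(upper.max(), lower.max(), 0.0))


@dataclass
class LTestResult:
    mean_abs_l: float
    mean_l2: float
    l_values: np.ndarray
    nl_grid: np.ndarray  # |L| grid
    nl_observed: np.ndarray  # cumulative N(|L|)
    nl_theory: np.ndarray  # acentric untwinned: N(|L|) = |L|
    max_dev: float


def l_test(
    merged: "MergedSet | np.ndarray",
    n_pairs: int = 100_000,
    seed: int = 0,
    n_shells: int = 10,
    max_pairs_per_reflection: int = 10,
) -> LTestResult:
    """Padilla-Yeates L-test: L = (I₁−I₂)/(I₁+I₂) over pairs of
    unrelated reflections of similar resolution.

    For untwinned acentric data ⟨|L|⟩ = 1/2, ⟨L²⟩ = 1/3 and the
    cumulative distribution is N(|L|) = |L|.  Pairs are drawn at random
    within resolution shells (seeded); passing a bare intensity array
    pairs uniformly at random (single shell).
    """
    rng = np.random.default_rng(seed)
    hkl_key = None
    if isinstance(merged, MergedSet):
        I = merged.table["I"].to_numpy()
        d = merged.table["d"].to_numpy()
        # Friedel branches of one index are symmetry-related; never pair them
        hkl_key = (
            merged.table["h"].to_numpy() * 10_000_019
            + merged.table["k"].to_numpy() * 4099
            + merged.table["l"].to_numpy()
        )
        shell_idx, _ = resolution_shells(d, n_shells) if len(I) > n_shells else (np.zeros(len(I), int), None)
    else:
        I = np.asarray(merged, dtype=float)
        shell_idx = np.zeros(len(I), dtype=int)
    if len(I) < 4:
        raise ValueError("too few reflections for the L-test")
    ls = []
    budget = n_pairs
    shells = np.unique(shell_idx)
    counts = np.array([np.sum(shell_idx == s) for s in shells], dtype=float)
    alloc = np.maximum(1, np.round(budget * counts / counts.sum())).astype(int)
    for s, n_s in zip(shells, alloc):
        members = np.where(shell_idx == s)[0]
        if len(members) < 2:
            continue
        cap = len(members) * max_pairs_per_reflection // 2
        take = min(n_s, max(cap, 1))
        a = rng.integers(0, len(members), size=take)
        b = rng.integers(0, len(members), size=take)
        ok = a != b
        if hkl_key is not None:
            ok &= hkl_key[members[a]] != hkl_key[members[b]]
        i1, i2 = I[members[a[ok]]], I[members[b[ok]]]
        s12 = i1 + i2
        nz = s12 != 0
        ls.append((i1[nz] - i2[nz]) / s12[nz])
    if not ls:
        raise ValueError("no valid L pairs")
    L = np.concatenate(ls)
    if len(L) < 100:
        raise ValueError(f"only {len(L)} L pairs; statistic unstable below 100")
    absL = np.abs(L)
    grid = np.linspace(0.0, 1.0, 101)
    observed = np.searchsorted(np.sort(absL), grid, side="right") / len(absL)
    theory = grid  # acentric untwinned: N(|L|) = |L|
    return LTestResult(
        mean_abs_l=float(absL.mean()),
        mean_l2=float(np.mean(L**2)),
        l_values=L,
        nl_grid=grid,
        nl_observed=observed,
        nl_theory=theory,
        max_dev=_ks_deviation(absL, lambda x: np.clip(x, 0.0, 1.0)),
    )


@dataclass
class NZTestResult:
    z_grid: np.ndarray
    nz_acentric_observed: Optional[np.ndarray]
    nz_acentric_theory: np.ndarray  # 1 − exp(−z)
    nz_centric_observed: Optional[np.ndarray]
    nz_centric_theory: np.ndarray  # erf(sqrt(z/2))
    max_dev_acentric: Optional[float]
    max_dev_centric: Optional[float]


def nz_test(
    merged: MergedSet,
    n_shells: int = 10,
    min_shell: int = 20,
    z_max: float = 6.0,
    n_grid: int = 121,
) -> NZTestResult:
    """Cumulative N(z) test of z = I/⟨I⟩ against Wilson theory.

    Intensities are normalised by their resolution-shell mean (shells
    with fewer than ``min_shell`` reflections are excluded), separately
    for the acentric and centric classes; the empirical cumulative
    distribution is compared with 1 − e^(−z) (acentric) and
    erf(√(z/2)) (centric).  A class absent from the point group (e.g.
    centrics in P1) reports None.
    """
    tab = merged.table
    grid = np.linspace(0.0, z_max, n_grid)
    out = {}
    for name, sel in (("acentric", ~tab["centric"]), ("centric", tab["centric"])):
        sub = tab[sel]
        if len(sub) == 0:
            out[name] = (None, None)
            continue
        d = sub["d"].to_numpy()
        I = sub["I"].to_numpy()
        nsh = min(n_shells, max(1, len(sub) // min_shell))
        if nsh >= 2:
            idx, _ = resolution_shells(d, nsh)
        else:
            idx = np.zeros(len(sub), dtype=int)
        zs = []
        for b in np.unique(idx):
            m = idx == b
            if np.sum(m) < min_shell:
                continue
            mean = I[m].mean()
            if mean <= 0:
                continue
            zs.append(I[m] / mean)
        if not zs:
            out[name] = (None, None)
            continue
        z = np.concatenate(zs)
        emp = np.searchsorted(np.sort(z), grid, side="right") / len(z)
        if name == "acentric":
            cdf = lambda x: 1.0 - np.exp(-x)
        else:
            cdf = lambda x: erf(np.sqrt(np.maximum(x, 0.0) / 2.0))
        out[name] = (emp, _ks_deviation(z, cdf))
    return NZTestResult(
        z_grid=grid,
        nz_acentric_observed=out["acentric"][0],
        nz_acentric_theory=1.0 - np.exp(-grid),
        nz_centric_observed=out["centric"][0],
        nz_centric_theory=erf(np.sqrt(grid / 2.0)),
        max_dev_acentric=out["acentric"][1],
        max_dev_centric=out["centric"][1],
    )


def shell_i_over_sigma(merged: MergedSet, n_shells: int = 10) -> pd.DataFrame:
    """Per-shell and overall ⟨I⟩/⟨σ⟩ (equal-volume shells).

    The last row (shell = -1) is the overall value.
    """
    tab = merged.table
    d = tab["d"].to_numpy()
    I = tab["I"].to_numpy()
    s = tab["sigma"].to_numpy()
    idx, d_edges = resolution_shells(d, n_shells, merged.d_range)
    rows = []
    for b in range(n_shells):
        m = idx == b
        if np.any(m):
            rows.append((b, d_edges[b], d_edges[b + 1], int(m.sum()), I[m].mean() / s[m].mean()))
        else:
            rows.append((b, d_edges[b], d_edges[b + 1], 0, math.nan))
    rows.append((-1, d_edges[0], d_edges[-1], len(I), I.mean() / s.mean()))
    return pd.DataFrame(rows, columns=["shell", "d_max", "d_min", "n", "i_over_sigma"])


@dataclass
class QCReport:
    """Bundle of merged-data quality statistics."""

    moment_ratio: float
    mean_abs_l: float
    mean_l2: float
    nl_max_dev: float
    nz_max_dev_acentric: Optional[float]
    nz_max_dev_centric: Optional[float]
    cc_half: Optional[float]
    r_split: Optional[float]
    i_over_sigma: pd.DataFrame = field(repr=False)
    multiplicity_mean: float = math.nan
    completeness: float = math.nan
    n_unique: int = 0

    def to_dict(self) -> dict:
        d = {
            "moment_ratio": self.moment_ratio,
            "mean_abs_l": self.mean_abs_l,
            "mean_l2": self.mean_l2,
            "nl_max_dev": self.nl_max_dev,
            "nz_max_dev_acentric": self.nz_max_dev_acentric,
            "nz_max_dev_centric": self.nz_max_dev_centric,
            "cc_half": self.cc_half,
            "r_split": self.r_split,
            "multiplicity_mean": self.multiplicity_mean,
            "completeness": self.completeness,
            "n_unique": self.n_unique,
            "i_over_sigma_overall": float(
                self.i_over_sigma.loc[self.i_over_sigma["shell"] == -1, "i_over_sigma"].iloc[0]
            ),
        }
        return d


def qc_report(
    merged: MergedSet,
    frames: Optional[Sequence[Frame]] = None,
    seed: int = 0,
    n_shells: int = 10,
    n_pairs: int = 100_000,
    **merge_kwargs,
) -> QCReport:
    """Assemble the full QC report for a merged set (and, when the frames
    are supplied, the semi-dataset statistics)."""
    acentric = merged.table.loc[~merged.table["centric"], "I"].to_numpy()
    moment = wilson_moment(acentric if len(acentric) >= 2 else merged.intensities)
    lt = l_test(merged, n_pairs=n_pairs, seed=seed, n_shells=n_shells)
    nz = nz_test(merged, n_shells=n_shells)
    cc = rs = None
    if frames is not None:
        cc, rs = semi_dataset_stats(
            frames, merged.point_group, split_seed=seed,
            d_range=merged.d_range, anomalous=merged.anomalous, **merge_kwargs,
        )
    return QCReport(
        moment_ratio=moment,
        mean_abs_l=lt.mean_abs_l,
        mean_l2=lt.mean_l2,
        nl_max_dev=lt.max_dev,
        nz_max_dev_acentric=nz.max_dev_acentric,
        nz_max_dev_centric=nz.max_dev_centric,
        cc_half=cc,
        r_split=rs,
        i_over_sigma=shell_i_over_sigma(merged, n_shells),
        multiplicity_mean=float(merged.table["multiplicity"].mean()),
        completeness=merged.completeness,
        n_unique=int(len(merged.table)),
    )
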