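"""Readers, writers and the pipeline driver.

Native interchange formats are plain TSV with documented headers:

``frames.tsv`` — one row per frame:
    frame_id, a, b, c, alpha, beta, gamma, point_group,
    a00..a22 (row-major UB matrix, Å⁻¹), wavelength,
    beam_x, beam_y, beam_z, d_eff, eta_full_deg (or eta_half_deg),
    G, B, theta_x, theta_y

``observations.tsv`` — one row per measurement:
    frame_id, h, k, l, I, sigma

A reference intensity table is ``h k l I`` (whitespace- or
tab-separated).  Merged output is TSV plus an optional MTZ export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .geometry import Beam, Crystal, MosaicModel
from .merge_qc import MergedSet, QCReport
from .postrefine import FitReport, Frame, Observation, ReferenceSet

log = logging.getLogger("stillmerge")

__all__ = [
    "ParseError",
    "write_frames",
    "read_frames",
    "write_reference",
    "read_reference",
    "write_merged",
    "write_merged_mtz",
    "write_qc_json",
    "write_fit_reports",
    "write_curves",
    "crystal_to_dict",
    "crystal_from_dict",
    "RunConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


_FRAME_COLS = (
    ["frame_id", "a", "b", "c", "alpha", "beta", "gamma", "point_group"]
    + [f"a{i}{j}" for i in range(3) for j in range(3)]
    + ["wavelength", "beam_x", "beam_y", "beam_z", "d_eff"]
)


def crystal_to_dict(crystal: Crystal, beam: Beam) -> dict:
    """JSON-style experiment descriptor for one crystal/beam pair."""
    d = {
        "cell": list(crystal.cell),
        "A": [float(x) for x in crystal.A.ravel()],  # row-major
        "point_group": crystal.point_group,
        "d_eff": crystal.mosaic.d_eff,
        "eta_full_deg": math.degrees(crystal.mosaic.eta_full),
        "wavelength": beam.wavelength,
        "beam_direction": [float(x) for x in beam.direction],
    }
    if beam.spectrum is not None:
        d["spectrum"] = [[float(a), float(b)] for a, b in beam.spectrum]
    return d


def crystal_from_dict(d: dict) -> Tuple[Crystal, Beam]:
    mosaic = MosaicModel.from_degrees(
        d["d_eff"],
        d["eta_half_deg"] * 2 if "eta_half_deg" in d else d["eta_full_deg"],
    )
    crystal = Crystal(
        cell=tuple(d["cell"]),
        A=np.array(d["A"], dtype=float).reshape(3, 3),
        point_group=d["point_group"],
        mosaic=mosaic,
    )
    beam = Beam(
        wavelength=d["wavelength"],
        direction=np.array(d.get("beam_direction", [0, 0, 1]), dtype=float),
        spectrum=np.array(d["spectrum"]) if "spectrum" in d else None,
    )
    return crystal, beam


def write_frames(frames: Sequence[Frame], directory) -> None:
    """Write frames.tsv + observations.tsv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frows, orows = [], []
    for f in frames:
        c = f.crystal
        frows.append(
            [f.frame_id, *c.cell, c.point_group, *c.A.ravel(), f.beam.wavelength,
             *f.beam.direction, c.mosaic.d_eff, math.degrees(c.mosaic.eta_full),
             f.G, f.B, f.theta_x, f.theta_y]
        )
        for o in f.observations:
            orows.append([f.frame_id, *o.hkl, o.I_raw, o.sigma])
    cols = _FRAME_COLS + ["eta_full_deg", "G", "B", "theta_x", "theta_y"]
    pd.DataFrame(frows, columns=cols).to_csv(directory / "frames.tsv", sep="\t", index=False)
    pd.DataFrame(orows, columns=["frame_id", "h", "k", "l", "I", "sigma"]).to_csv(
        directory / "observations.tsv", sep="\t", index=False
    )


def _parse_table(path: Path, required: Sequence[str], numeric: Sequence[str],
                 int_cols: Sequence[str] = ()) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                             f"in column {col!r} on line {line}")
        df[col] = vals
    for col in int_cols:
        frac = df[col] % 1
        if (frac != 0).any():
            line = int((frac != 0).idxmax()) + 2
            raise ParseError(f"{path}: non-integer Miller index in column {col!r} on line {line}")
        df[col] = df[col].astype(int)
    return df


def read_frames(directory) -> List[Frame]:
    """Read frames written by :func:`write_frames` (round-trips values)."""
    directory = Path(directory)
    fpath, opath = directory / "frames.tsv", directory / "observations.tsv"
    numeric = [c for c in _FRAME_COLS if c not in ("frame_id", "point_group")]
    fdf = _parse_table(fpath, _FRAME_COLS, numeric)
    if "eta_full_deg" in fdf.columns:
        fdf["eta_full_deg"] = pd.to_numeric(fdf["eta_full_deg"])
        eta_deg = fdf["eta_full_deg"]
    elif "eta_half_deg" in fdf.columns:
        eta_deg = 2.0 * pd.to_numeric(fdf["eta_half_deg"])
    else:
        raise ParseError(f"{fpath}: need an eta_full_deg or eta_half_deg column")
    for extra in ("G", "B", "theta_x", "theta_y"):
        if extra in fdf.columns:
            fdf[extra] = pd.to_numeric(fdf[extra])
    odf = _parse_table(
        opath, ["frame_id", "h", "k", "l", "I", "sigma"],
        ["h", "k", "l", "I", "sigma"], int_cols=["h", "k", "l"],
    )
    obs_by_frame = dict(tuple(odf.groupby("frame_id", sort=False)))
    frames = []
    for i, row in fdf.iterrows():
        mosaic = MosaicModel.from_degrees(float(row["d_eff"]), float(eta_deg[i]))
        crystal = Crystal(
            cell=tuple(float(row[c]) for c in ("a", "b", "c", "alpha", "beta", "gamma")),
            A=np.array([float(row[f"a{i_}{j}"]) for i_ in range(3) for j in range(3)]).reshape(3, 3),
            point_group=str(row["point_group"]),
            mosaic=mosaic,
        )
        beam = Beam(
            wavelength=float(row["wavelength"]),
            direction=np.array([float(row[c]) for c in ("beam_x", "beam_y", "beam_z")]),
        )
        group = obs_by_frame.get(row["frame_id"])
        obs = []
        if group is not None:
            for _, orow in group.iterrows():
                obs.append(
                    Observation(
                        hkl=(int(orow["h"]), int(orow["k"]), int(orow["l"])),
                        I_raw=float(orow["I"]),
                        sigma=float(orow["sigma"]),
                        d=crystal.d_spacing((int(orow["h"]), int(orow["k"]), int(orow["l"]))),
                    )
                )
        else:
            log.warning("frame %s has no observations", row["frame_id"])
        frames.append(
            Frame(
                frame_id=str(row["frame_id"]), crystal=crystal, beam=beam, observations=obs,
                G=float(row.get("G", 1.0)), B=float(row.get("B", 0.0)),
                theta_x=float(row.get("theta_x", 0.0)), theta_y=float(row.get("theta_y", 0.0)),
            )
        )
    return frames


def write_reference(reference: ReferenceSet, path) -> None:
    rows = [(h, k, l, v) for (h, k, l), v in sorted(reference.items())]
    pd.DataFrame(rows, columns=["h", "k", "l", "I"]).to_csv(path, sep="\t", index=False)


def read_reference(path, point_group: str) -> ReferenceSet:
    df = _parse_table(Path(path), ["h", "k", "l", "I"], ["h", "k", "l", "I"],
                      int_cols=["h", "k", "l"])
    table = {(int(r.h), int(r.k), int(r.l)): float(r.I) for r in df.itertuples()}
    return ReferenceSet(table, point_group)


def write_merged(merged: MergedSet, path) -> None:
    merged.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_merged_mtz(merged: MergedSet, path) -> None:
    """Optional export to a standard merged-reflection MTZ file."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.find_spacegroup_by_name(merged.point_group)
    mtz.set_cell_for_all(gemmi.UnitCell(*merged.cell))
    mtz.add_dataset("stillmerge")
    mtz.add_column("IMEAN", "J")
    mtz.add_column("SIGIMEAN", "Q")
    tab = merged.table
    if merged.anomalous:
        # collapse Friedel branches for the file export
        tab = tab.groupby(["h", "k", "l"], as_index=False).agg(
            I=("I", "mean"), sigma=("sigma", "mean")
        )
    data = tab[["h", "k", "l", "I", "sigma"]].to_numpy(dtype=float)
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def write_fit_reports(reports: Sequence[FitReport], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(path, sep="\t", index=False)


def write_qc_json(qc: QCReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc.to_dict(), fh, indent=2)


def write_curves(lt, nz, directory) -> None:
    """N(L) and N(z) curves as CSV for plotting."""
    directory = Path(directory)
    pd.DataFrame({
        "abs_l": lt.nl_grid, "n_l_observed": lt.nl_observed, "n_l_theory": lt.nl_theory,
    }).to_csv(directory / "nl_curve.csv", index=False)
    cols = {"z": nz.z_grid, "acentric_theory": nz.nz_acentric_theory,
            "centric_theory": nz.nz_centric_theory}
    if nz.nz_acentric_observed is not None:
        cols["acentric_observed"] = nz.nz_acentric_observed
    if nz.nz_centric_observed is not None:
        cols["centric_observed"] = nz.nz_centric_observed
    pd.DataFrame(cols).to_csv(directory / "nz_curve.csv", index=False)


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class RunConfig:
    """One end-to-end processing run (encodes a protocol choice)."""

    protocol: str = "postrefine"  # key of simdata.PROTOCOLS
    frames_dir: Optional[str] = None  # input frames (TSV pair); None → simulate
    reference_path: Optional[str] = None  # reference table; None → iterated mean-of-merged
    out_dir: str = "stillmerge_out"
    d_max: float = 30.0
    d_min: float = 2.2
    point_group: str = "P 21 21 21"
    anomalous: bool = False
    p_min: float = 0.1  # partiality floor; 0 reproduces the bare geometric filter
    cutoff_override: Optional[float] = None  # overrides the protocol's I/σ threshold
    n_shells: int = 10
    seed: int = 0
    sim_seed: int = 0
    n_frames: int = 25
    write_mtz: bool = False


def _self_reference(frames, point_group, d_range, use_partiality) -> ReferenceSet:
    """Mean-of-merged bootstrap reference (one outer iteration): merge the
    frames at their current parameters and use the result as I_ref."""
    from .merge_qc import merge

    merged = merge(frames, point_group, d_range=d_range, anomalous=False,
                   use_partiality=use_partiality)
    table = {
        (int(r.h), int(r.k), int(r.l)): max(float(r.I), 0.0)
        for r in merged.table.itertuples()
    }
    return ReferenceSet(table, point_group)


def run_pipeline(rc: RunConfig) -> dict:
    """Run simulate/load → filter → fit → merge → QC, writing artifacts.

    Outputs under ``rc.out_dir``: corrected.tsv (per-reflection partiality
    columns), fit_reports.tsv, merged.tsv (+ merged.mtz optionally),
    qc.json, nl_curve.csv, nz_curve.csv.  Deterministic given the seeds.
    """
    from .merge_qc import l_test, merge, nz_test, qc_report
    from .partiality import partiality_record
    from .postrefine import FitConfig, fit_frame, remove_negative
    from .merge_qc import per_lattice_cutoff
    from .simdata import PROTOCOLS, SimConfig, generate_frames, generate_truth

    if rc.protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {rc.protocol!r}; choose from {sorted(PROTOCOLS)}")
    mode, use_part, threshold = PROTOCOLS[rc.protocol]
    if rc.cutoff_override is not None:
        threshold = rc.cutoff_override
    out = Path(rc.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if rc.frames_dir is not None:
        frames = read_frames(rc.frames_dir)
    else:
        sim = SimConfig(seed=rc.sim_seed, n_frames=rc.n_frames, d_max=rc.d_max,
                        d_min=rc.d_min, point_group=rc.point_group)
        truth, _ = generate_truth(sim)
        frames, _ = generate_frames(truth, sim)
        write_frames(frames, out / "frames")
        if rc.reference_path is None:
            write_reference(truth, out / "reference.tsv")
    log.info("loaded %d frames, %d observations", len(frames),
             sum(len(f.observations) for f in frames))

    n_neg = sum(sum(1 for o in f.observations if o.I_raw <= 0) for f in frames)
    prepared = []
    for f in frames:
        f = per_lattice_cutoff(f, threshold, n_bins=rc.n_shells)
        f = remove_negative(f)
        if f.observations:
            prepared.append(f)
    log.info("removed %d negative measurements; %d frames with observations "
             "after cutoff (threshold=%s)", n_neg, len(prepared), threshold)
    if not prepared:
        raise RuntimeError("no frames left after filtering")

    if rc.reference_path is not None:
        reference = read_reference(rc.reference_path, rc.point_group)
    elif rc.frames_dir is None:
        reference = read_reference(out / "reference.tsv", rc.point_group)
    else:
        reference = _self_reference(prepared, rc.point_group, (rc.d_max, rc.d_min), use_part)

    fc = FitConfig(use_partiality=use_part)
    fitted, reports = [], []
    for f in prepared:
        try:
            ff, rep = fit_frame(f, reference, mode=mode, config=fc)
        except ValueError as exc:
            log.warning("frame %s skipped: %s", f.frame_id, exc)
            continue
        reports.append(rep)
        if not ff.rejected:
            fitted.append(ff)
    log.info("fitted %d frames (%d rejected)", len(fitted), len(prepared) - len(fitted))
    if not fitted:
        raise RuntimeError("no frames converged in fitting")
    write_fit_reports(reports, out / "fit_reports.tsv")

    # corrected per-reflection table with partiality columns
    crows = []
    for f in fitted:
        for o in f.observations:
            rec = o.partiality_record
            if rec is None:
                rec = partiality_record(f.crystal, f.beam, o.hkl)
            crows.append([f.frame_id, *o.hkl, o.I_raw, o.sigma, rec.delta_r, rec.r_q,
                          rec.partiality, rec.accepted])
    pd.DataFrame(crows, columns=["frame_id", "h", "k", "l", "I", "sigma", "delta_r",
                                 "r_q", "partiality", "accepted"]).to_csv(
        out / "corrected.tsv", sep="\t", index=False)

    merged = merge(fitted, rc.point_group, d_range=(rc.d_max, rc.d_min),
                   anomalous=rc.anomalous, use_partiality=use_part,
                   p_min=rc.p_min if use_part else 0.0, n_shells=rc.n_shells)
    write_merged(merged, out / "merged.tsv")
    if rc.write_mtz:
        write_merged_mtz(merged, out / "merged.mtz")
    log.info("merged %d unique indices, completeness %.3f, mean multiplicity %.2f",
             len(merged.table), merged.completeness,
             float(merged.table["multiplicity"].mean()))

    qc = qc_report(merged, frames=fitted if len(fitted) >= 2 else None, seed=rc.seed,
                   n_shells=rc.n_shells, use_partiality=use_part)
    write_qc_json(qc, out / "qc.json")
    lt = l_test(merged, seed=rc.seed, n_shells=rc.n_shells)
    nz = nz_test(merged, n_shells=rc.n_shells)
    write_curves(lt, nz, out)
    return {
        "n_frames_in": len(frames),
        "n_negative_removed": n_neg,
        "n_frames_fitted": len(fitted),
        "n_unique": int(len(merged.table)),
        "completeness": merged.completeness,
        "qc": qc.to_dict(),
    }
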