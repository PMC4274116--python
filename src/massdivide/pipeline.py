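"""End-to-end pipeline: unwrap -> segment -> track -> detect -> statistics.

Also owns the on-disk formats: multi-page 32-bit float TIFF stacks (OPD in
nm, page order = time order), JSON ledgers/manifests, and the CSV tables for
regions, tracks, events and asymmetry records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig
from .division import DivisionEvent, detect_divisions, measure_division_times
from .segment import compute_confluence, measure_regions, segment_cells
from .stats import (AsymmetryRecord, asymmetry_dynamics, heatmap_matrix,
                    population_curves)
from .synthetic import GroundTruth, PhaseFrame
from .tracking import CellTrack, build_tracks
from .unwrap import UnwrapModel, unwrap_frame

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and frame."""


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_stack(path, frames: list[PhaseFrame], channel: str = "opd") -> None:
    data = np.stack([getattr(f, channel) for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack(path, intensity_path=None, pixel_size: float = 1.0,
               wavelength: float = 530.0,
               frame_interval: float = 3.0) -> list[PhaseFrame]:
    opd = tifffile.imread(path)
    if opd.ndim == 2:
        opd = opd[None]
    inten = tifffile.imread(intensity_path) if intensity_path is not None \
        else np.zeros_like(opd)
    if inten.ndim == 2:
        inten = inten[None]
    return [PhaseFrame(opd=o.astype(float), intensity=i.astype(float),
                       pixel_size=pixel_size, wavelength=wavelength,
                       time=k * frame_interval)
            for k, (o, i) in enumerate(zip(opd, inten))]


def write_ledger(path, truth: GroundTruth) -> None:
    payload = {
        "times": truth.times.tolist(),
        "masses": {k: np.where(np.isfinite(v), v, None).tolist()
                   for k, v in truth.masses.items()},
        "events": truth.events,
        "delta_m": {k: np.where(np.isfinite(v), v, None).tolist()
                    for k, v in truth.delta_m.items()},
        "total_mass": truth.total_mass.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def regions_table(frames_regions, confluences=None) -> pd.DataFrame:
    rows = []
    for k, regions in enumerate(frames_regions):
        for r in regions:
            rows.append({
                "frame": k, "label": r.label, "t_min": r.time,
                "mass_pg": r.mass, "area_um2": r.area,
                "perimeter_px": r.perimeter, "mean_phase_nm": r.mean_phase,
                "shape_factor": r.shape_factor,
                "x_um": r.centroid[1], "y_um": r.centroid[0],
            })
    df = pd.DataFrame(rows)
    if confluences is not None and not df.empty:
        df["confluence_pct"] = df["frame"].map(dict(enumerate(confluences)))
    return df


def tracks_table(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, r in zip(tr.frames, tr.regions):
            rows.append({
                "track_id": tr.track_id, "frame": frame, "t_min": r.time,
                "label": r.label, "mass_pg": r.mass,
                "mean_phase_nm": r.mean_phase, "shape_factor": r.shape_factor,
                "x_um": r.centroid[1], "y_um": r.centroid[0],
            })
    return pd.DataFrame(rows)


def events_table(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        tim, trp = measure_division_times(ev)
        rows.append({
            "event_id": ev.event_id, "parent_track": ev.parent_track,
            "d1_track": ev.d1_track, "d2_track": ev.d2_track,
            "t_furrow_min": ev.t_furrow, "m_parent_pg": ev.m_parent,
            "m_d1_pg": ev.m_d1, "m_d2_pg": ev.m_d2, "dm0": ev.dm0,
            "entry_mid_min": ev.entry_mid,
            "exit_mid_min_d1": ev.exit_mid_d1,
            "exit_mid_min_d2": ev.exit_mid_d2,
            "time_in_mitosis_min": tim, "time_rounded_post_min": trp,
        })
    return pd.DataFrame(rows)


def records_table(records: list[AsymmetryRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": r.event_id, "dm0": r.dm0, "rate_per_min": r.rate,
        "theta_rad": r.theta, "valid": r.valid,
    } for r in records])


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def run_pipeline(frames: list[PhaseFrame], config: PipelineConfig,
                 out_dir=None, unwrap_model: UnwrapModel | None = None) -> dict:
    """Run every stage on a phase movie and (optionally) write all tables.

    Returns a dict with frames' regions, tracks, events, asymmetry records,
    population summary (when events exist), and the run manifest.
    """
    # -- validation ----------------------------------------------------
    for k, frame in enumerate(frames):
        try:
            frame.validate_finite()
        except ValueError as exc:
            raise PipelineError(f"stage=validate frame={k}: {exc}") from exc

    # -- unwrap --------------------------------------------------------
    masks = []
    if unwrap_model is not None:
        corrected = []
        for k, frame in enumerate(frames):
            try:
                fr, mask = unwrap_frame(frame, unwrap_model,
                                        beta=config.walker_beta)
            except Exception as exc:
                raise PipelineError(f"stage=unwrap frame={k}: {exc}") from exc
            corrected.append(fr)
            masks.append(mask)
        frames = corrected

    # -- segment + measure ---------------------------------------------
    frames_regions, confluences = [], []
    for k, frame in enumerate(frames):
        try:
            labels = segment_cells(frame, config.segmentation)
            frames_regions.append(measure_regions(labels, frame,
                                                  config.segmentation))
            confluences.append(compute_confluence(labels))
        except Exception as exc:
            raise PipelineError(f"stage=segment frame={k}: {exc}") from exc
    logger.info("segmented %d regions over %d frames",
                sum(map(len, frames_regions)), len(frames))

    # -- track ---------------------------------------------------------
    times = [f.time for f in frames]
    tracks = build_tracks(frames_regions, max_disp=config.max_disp, times=times)
    logger.info("built %d tracks", len(tracks))

    # -- detect divisions ----------------------------------------------
    events = detect_divisions(tracks, adherent=config.adherent,
                              params=config.division, n_frames=len(frames))
    logger.info("detected %d division events", len(events))

    # -- statistics ------------------------------------------------------
    records = [asymmetry_dynamics(ev) for ev in events]
    summary = population_curves(events, tracks) if events else None

    manifest = {
        "package_version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "n_frames": len(frames),
        "n_regions": int(sum(map(len, frames_regions))),
        "n_tracks": len(tracks),
        "n_events": len(events),
        "versions": _versions(),
    }

    results = {
        "frames_regions": frames_regions, "confluences": confluences,
        "tracks": tracks, "events": events, "records": records,
        "summary": summary, "manifest": manifest, "wrap_masks": masks,
    }
    if out_dir is not None:
        _write_results(Path(out_dir), results, config)
    return results


def _versions() -> dict:
    import skimage
    import sklearn
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__}


def _write_results(out: Path, results: dict, config: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    regions_table(results["frames_regions"],
                  results["confluences"]).to_csv(out / "regions.csv", index=False)
    tracks_table(results["tracks"]).to_csv(out / "tracks.csv", index=False)
    events_table(results["events"]).to_csv(out / "events.csv", index=False)
    records_table(results["records"]).to_csv(out / "asymmetry.csv", index=False)
    if results["records"]:
        heatmap_matrix(results["records"], signed=True).to_csv(
            out / "heatmap_signed.csv")
        heatmap_matrix(results["records"], signed=False).to_csv(
            out / "heatmap_abs.csv")
    if results["summary"] is not None:
        results["summary"].mean_abs_dm.to_csv(out / "mean_abs_dm.csv",
                                              index=False)
        results["summary"].mass_cv.to_csv(out / "mass_cv.csv", index=False)
        results["summary"].growth_vs_time.to_csv(out / "growth_vs_time.csv",
                                                 index=False)
        results["summary"].growth_vs_mass.to_csv(out / "growth_vs_mass.csv",
                                                 index=False)
    config.to_yaml(out / "config.yaml")
    manifest = dict(results["manifest"])
    manifest["output_sha256"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
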