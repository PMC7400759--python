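"""End-to-end orchestration: screening -> disc -> registration -> measurement
-> per-second A/V aggregation, and the statistical analysis bundle.

Every frame that is dropped -- non-fundus, below the quality gate, failed
registration, failed measurement -- is logged with its reason, so the kept /
discarded bookkeeping of a run is fully reconstructible from the reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import (DiscNotFoundError, FundusAVRError, NoUsableFramesError,
                     RegistrationError, SchemaError)
from .registration import Pose, apply_pose, estimate_pose, locate_disc
from .screening import VideoFrames, is_fundus, score_quality, select_reference
from .stats import (compare_group_means, compare_slopes, fit_mixed_model,
                    roc_analysis, sens_spec_at, validate_observation_table)
from .vessels import VesselSeed, compute_av_series

__all__ = ["screen_frames", "measure_video", "analyze_table",
           "load_seed_pair", "av_records_frame"]

log = logging.getLogger(__name__)


def screen_frames(video: VideoFrames, config: PipelineConfig
                  ) -> tuple[pd.DataFrame, dict]:
    """Screen every frame: fundus flag, disc detection, quality score.

    Returns the per-frame report and a dict of per-frame disc locations for
    the frames where detection succeeded.
    """
    rows, discs = [], {}
    for i, frame in enumerate(video.frames):
        flag, conf = is_fundus(frame, threshold=config.is_fundus_threshold)
        disc = None
        if flag:
            try:
                disc = locate_disc(frame)
                discs[i] = disc
            except DiscNotFoundError as exc:
                log.info("frame %d: disc not found (%s)", i, exc)
        q = score_quality(frame, disc=disc, frame_index=i)
        rows.append({
            "frame_index": i, "timestamp_s": video.timestamp(i),
            "is_fundus": flag, "confidence": conf,
            "disc_score": q.disc_score, "vessel_clarity": q.vessel_clarity,
            "sharpness": q.sharpness, "brightness": q.brightness,
            "total": q.total,
            "usable": bool(flag and q.total >= config.q_min),
        })
        if not rows[-1]["usable"]:
            reason = "non-fundus" if not flag else f"quality {q.total:.1f} < {config.q_min:g}"
            log.info("frame %d dropped at screening: %s", i, reason)
    return pd.DataFrame(rows), discs


def load_seed_pair(path: str | Path) -> tuple[VesselSeed, VesselSeed]:
    """Read the paired vessel seeds from JSON: a list of two objects with
    ``x``, ``y`` and optional ``claimed_class``."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list) or len(data) != 2:
        raise SchemaError("seeds file must contain exactly two seed objects")
    seeds = []
    for i, d in enumerate(data):
        if "x" not in d or "y" not in d:
            raise SchemaError(f"seed {i} is missing 'x' or 'y'")
        seeds.append(VesselSeed(position=(float(d["x"]), float(d["y"])),
                                claimed_class=d.get("claimed_class", "unknown")))
    return seeds[0], seeds[1]


def measure_video(video: VideoFrames,
                  seed_pair: tuple[VesselSeed, VesselSeed],
                  config: PipelineConfig) -> dict:
    """Run the full imaging chain on one video.

    Returns a dict with the screening report, disc report, pose table,
    per-vessel measurement rows and the per-second A/V records.
    """
    config.validate()
    screening, discs = screen_frames(video, config)
    usable = screening.loc[screening["usable"], "frame_index"].tolist()
    if not usable:
        raise NoUsableFramesError("no usable frames after screening")
    qscores = [score_from_row(r) for _, r in screening.iterrows() if r["usable"]]
    ref_index = select_reference(qscores)
    reference = video.frames[ref_index]

    ref_disc = discs.get(ref_index)
    if ref_disc is not None:
        for s in seed_pair:
            s.warn_if_off_locus(ref_disc.center, ref_disc.radius)

    disc_rows = [{"frame_index": i, "cx": d.center[0], "cy": d.center[1],
                  "radius_px": d.radius, "confidence": d.confidence}
                 for i, d in sorted(discs.items())]

    pose_rows, registered = [], []
    for i in usable:
        if i == ref_index:
            pose, sim, status = Pose(0.0, 0.0, 0.0), 1.0, "reference"
            registered.append((i, video.frames[i].astype(float)))
        else:
            try:
                pose, sim = estimate_pose(video.frames[i], reference)
                status = "registered"
                registered.append((i, apply_pose(video.frames[i], pose)))
            except RegistrationError as exc:
                pose, sim, status = Pose(np.nan, np.nan, 0.0), np.nan, "failed"
                log.info("frame %d dropped at registration: %s", i, exc)
        pose_rows.append({"frame_index": i, "x_px": pose.x, "y_px": pose.y,
                          "alpha_deg": pose.alpha, "similarity": sim,
                          "status": status})

    details: list[dict] = []
    records = compute_av_series(
        registered, seed_pair, fps=config.fps, n_side=config.n_side,
        step_px=config.step_px, profile_halfwidth_px=config.profile_halfwidth_px,
        min_ok=config.min_ok_points, details_out=details,
    )
    return {
        "screening": screening,
        "disc_report": pd.DataFrame(disc_rows),
        "pose_table": pd.DataFrame(pose_rows),
        "measurements": pd.DataFrame(details),
        "av_records": records,
        "reference_index": ref_index,
        "config": config.to_dict(),
    }


def score_from_row(row):
    """Rebuild a quality-score object from a screening report row."""
    from .screening import QualityScore
    return QualityScore(
        frame_index=int(row["frame_index"]), disc_score=float(row["disc_score"]),
        vessel_clarity=float(row["vessel_clarity"]),
        sharpness=float(row["sharpness"]), brightness=float(row["brightness"]),
    )


def av_records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def analyze_table(table: pd.DataFrame, config: PipelineConfig,
                  seed: int | None = None) -> dict:
    """Run the whole statistical layer on an observation table.

    Each analysis runs independently: a failure (e.g. a single-class ROC) is
    surfaced as an ``error`` entry while the others are still emitted.
    """
    config.validate()
    df = validate_observation_table(table)
    seed = config.seed if seed is None else seed
    out: dict = {"config": config.to_dict(), "seed": seed,
                 "n_obs": len(df), "n_patients": int(df["patient_id"].nunique())}
    split, boundary = config.icp_split, config.boundary

    def attempt(name, fn):
        try:
            out[name] = _as_jsonable(fn())
        except FundusAVRError as exc:
            out[name] = {"error": str(exc)}
            log.warning("analysis %s failed: %s", name, exc)

    attempt("mixed_model_low", lambda: fit_mixed_model(df, lambda icp: icp < split))
    attempt("mixed_model_high", lambda: fit_mixed_model(df, lambda icp: icp >= split))
    attempt("slope_comparison", lambda: compare_slopes(df, split_mmHg=split))
    attempt("group_means", lambda: compare_group_means(
        df[df["mean_icp_mmHg"] >= split], boundary_mmHg=boundary))
    attempt("roc", lambda: roc_analysis(df, boundary_mmHg=boundary,
                                        cutoff=config.cutoff,
                                        n_bootstrap=config.n_bootstrap, seed=seed))
    attempt("sens_spec", lambda: sens_spec_at(df, cutoff=config.cutoff,
                                              boundary_mmHg=boundary))
    return out
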