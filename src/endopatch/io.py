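"""Readers/writers: multi-page TIFF movies (TCYX, 16-bit) with a JSON
metadata sidecar, CSV tables for ground truth, spots, tracks and events,
and PNG export of kymographs with a burned-in 20 s scale bar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kymography import Kymograph
from .patch_tracking import Spot, Track
from .synth_movie import GroundTruthEvent, Movie


def write_movie_tiff(movie: Movie, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF, dimension order TCYX, clipped to
    16-bit unsigned, plus a ``<stem>.json`` metadata sidecar."""
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_interval_s": movie.frame_interval_s,
        "channel_names": list(movie.channel_names),
    }, indent=2))
    return path


def read_movie_tiff(path: str | Path) -> Movie:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 3:  # single channel stored as TYX
        data = data[:, None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Movie(data,
                 pixel_size_nm=float(meta.get("pixel_size_nm", 65.0)),
                 frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
                 channel_names=tuple(meta.get("channel_names",
                                              ("green", "red")[:data.shape[1]])))


def ground_truth_frame(truths: list[GroundTruthEvent]) -> pd.DataFrame:
    rows = []
    for ev in truths:
        rows.append({
            "event_id": ev.event_id,
            "channel": ev.channel,
            "onset_frame": ev.onset_frame,
            "offset_frame": ev.offset_frame,
            "red_onset_frame": ev.red_onset_frame,
            "red_offset_frame": ev.red_offset_frame,
            "true_lifetime_s": ev.true_lifetime_s,
            "true_lifetime_red_s": ev.true_lifetime_red_s,
            "site_angle_rad": ev.site_angle_rad,
            "true_threshold_fraction": ev.true_threshold_fraction,
            "motility_class": ev.motility_class,
            "amplitude": ev.amplitude,
        })
    return pd.DataFrame(rows)


def trajectories_frame(truths: list[GroundTruthEvent]) -> pd.DataFrame:
    """Long-format (event_id, frame, x, y) trajectory table; x = col, y = row."""
    rows = []
    for ev in truths:
        for i, (r, c) in enumerate(ev.trajectory):
            rows.append({"event_id": ev.event_id, "frame": ev.onset_frame + i,
                         "x": c, "y": r})
    return pd.DataFrame(rows)


def write_ground_truth(truths: list[GroundTruthEvent], directory: str | Path,
                       prefix: str = "ground_truth") -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events_path = directory / f"{prefix}_events.csv"
    traj_path = directory / f"{prefix}_trajectories.csv"
    ground_truth_frame(truths).to_csv(events_path, index=False)
    trajectories_frame(truths).to_csv(traj_path, index=False)
    return events_path, traj_path


def spots_frame(spots_by_frame: list[list[Spot]]) -> pd.DataFrame:
    rows = []
    for spots in spots_by_frame:
        for s in spots:
            rows.append({"frame": s.frame, "channel": s.channel,
                         "x": s.position[1], "y": s.position[0],
                         "intensity": s.raw_intensity,
                         "background": s.local_background})
    return pd.DataFrame(rows)


def tracks_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for s in tr.spots:
            rows.append({"track_id": tr.track_id, "frame": s.frame,
                         "channel": tr.channel,
                         "x": s.position[1], "y": s.position[0],
                         "intensity": s.raw_intensity,
                         "background": s.local_background,
                         "motility_class": tr.motility_class,
                         "excluded_crowded": tr.excluded_crowded})
    return pd.DataFrame(rows)


def outline_frame(outline) -> pd.DataFrame:
    return pd.DataFrame({"row": outline.boundary[:, 0],
                         "col": outline.boundary[:, 1]})


def kymograph_csv(kymo: Kymograph, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, kymo.values, delimiter=",")
    return path


def kymograph_png(kymo: Kymograph, path: str | Path,
                  scale_bar_s: float = 20.0) -> Path:
    """Render a kymograph to PNG (cortex at top for the radial flavor) with
    a burned-in time scale bar of ``scale_bar_s`` seconds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    values = kymo.values
    if kymo.flavor == "radial":
        values = values[::-1]  # cortex (largest radius) at top
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(values, aspect="auto", cmap="magma", interpolation="nearest")
    ax.set_xlabel("time (frames)")
    ax.set_ylabel("arc length (px)" if kymo.flavor == "circumferential"
                  else "position along ray (px)")
    bar_frames = scale_bar_s / kymo.frame_interval_s
    y = values.shape[0] * 0.95
    ax.plot([1, 1 + bar_frames], [y, y], color="white", lw=3)
    ax.set_title(f"{kymo.flavor} kymograph ({kymo.channel})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_tiff_array(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, values.astype(np.float32))
    return path
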