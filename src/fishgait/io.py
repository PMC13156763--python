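"""File formats: videos, coordinate tables, configs and result CSVs.

Videos are exchanged as lossless image stacks: multi-page TIFF files (the
standard scientific-imaging container, readable by ImageJ/Fiji and any TIFF
reader) or directories of numbered PNG frames.  All tables are plain CSV
with a commented header documenting units and conventions: 0-based frame
indices, pixel coordinates x-right / y-down with origin at the crop's
top-left, angles in radians, times in seconds, lengths in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracker import FrameMidline, TrackerParams, TrackSeries

__all__ = [
    "SetupConfig",
    "read_config",
    "write_config",
    "read_video",
    "write_video",
    "write_track_csv",
    "read_track_csv",
    "write_table",
    "read_table",
    "mm_per_px_from_arena",
]


# ---------------------------------------------------------------------------
# video I/O


def write_video(path, frames) -> Path:
    """Write frames (2-D grayscale or 3-D RGB uint8 arrays) losslessly.

    ``.tif``/``.tiff`` -> multi-page TIFF; a path without suffix (or an
    existing directory) -> numbered PNG frames inside it.
    """
    path = Path(path)
    frames = [np.asarray(f) for f in frames]
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        stack = np.stack(frames)
        photometric = "rgb" if stack.ndim == 4 else "minisblack"
        tifffile.imwrite(path, stack, photometric=photometric)
        return path
    if path.suffix == "" or path.is_dir():
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", f)
        return path
    raise IOError(
        f"unsupported video container {path.suffix!r}; use .tif/.tiff or a "
        "directory of PNG frames"
    )


def read_video(path) -> list[np.ndarray]:
    """Read a TIFF stack or a PNG frame directory into a frame list.
    RGB frames are converted to grayscale by channel averaging."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such video: {path}")
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise IOError(f"no frame_*.png files in {path}")
        frames = [iio.imread(f) for f in files]
    else:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = list(stack)
    out = []
    for f in frames:
        if f.ndim == 3:
            f = f.mean(axis=2).round().astype(np.uint8)
        out.append(np.asarray(f))
    return out


# ---------------------------------------------------------------------------
# setup configuration


@dataclass
class SetupConfig:
    """Scriptable video-setup: segment, crop, arena and calibration.

    The arena polygon is given in pixel coordinates of the *cropped* frame;
    the physical arena width (mm) across the polygon's bounding box sets
    the mm/px calibration.
    """

    video: str = ""
    segment_start: float = 0.0
    segment_end: float | None = None
    crop: tuple[int, int, int, int] | None = None  # x, y, w, h
    arena_polygon: list[tuple[float, float]] = field(default_factory=list)
    arena_mm: tuple[float, float] = (210.0, 144.0)
    fps: float = 100.0
    size_class: str = "large_adult"

    def tracker_params(self, **overrides) -> TrackerParams:
        return TrackerParams.for_size_class(self.size_class, **overrides)

    def mm_per_px(self) -> float:
        if not self.arena_polygon:
            raise ValueError("arena polygon required for calibration")
        return mm_per_px_from_arena(self.arena_polygon, self.arena_mm[0])

    def validate(self, video_duration: float | None = None) -> None:
        if self.segment_end is not None and self.segment_end <= self.segment_start:
            raise ValueError("segment_end must exceed segment_start")
        if video_duration is not None:
            end = self.segment_end if self.segment_end is not None else video_duration
            if end > video_duration + 1e-9:
                raise ValueError("segment extends past the video duration")
        if self.crop is not None and self.arena_polygon:
            _, _, w, h = self.crop
            xs = [p[0] for p in self.arena_polygon]
            ys = [p[1] for p in self.arena_polygon]
            if min(xs) < 0 or min(ys) < 0 or max(xs) > w or max(ys) > h:
                raise ValueError("arena polygon must lie inside the crop")


def mm_per_px_from_arena(polygon, arena_width_mm: float) -> float:
    """Calibration: physical arena width / pixel width of the arena
    polygon's bounding box."""
    xs = np.asarray([p[0] for p in polygon], dtype=float)
    width_px = xs.max() - xs.min()
    if width_px <= 0:
        raise ValueError("degenerate arena polygon")
    return arena_width_mm / width_px


_CONFIG_DOC = """# fishgait setup configuration
# Keys (one per line, key = value):
#   video          path of the input video (.tif stack or PNG directory)
#   segment_start  analysis segment start, seconds
#   segment_end    analysis segment end, seconds (omit for end of video)
#   crop           x,y,w,h crop rectangle in px (origin: full-frame top-left)
#   arena_polygon  x1,y1;x2,y2;... arena outline in cropped-frame px
#   arena_mm       physical arena width,height in mm (calibration)
#   fps            frames per second
#   size_class     large_adult | small_adult | juvenile | larva
# Pixel coordinates are x-right / y-down, 0-based frame indices.
"""


def write_config(path, cfg: SetupConfig) -> Path:
    path = Path(path)
    lines = [_CONFIG_DOC]
    lines.append(f"video = {cfg.video}")
    lines.append(f"segment_start = {cfg.segment_start}")
    if cfg.segment_end is not None:
        lines.append(f"segment_end = {cfg.segment_end}")
    if cfg.crop is not None:
        lines.append("crop = " + ",".join(str(v) for v in cfg.crop))
    if cfg.arena_polygon:
        lines.append(
            "arena_polygon = "
            + ";".join(f"{x},{y}" for x, y in cfg.arena_polygon)
        )
    lines.append(f"arena_mm = {cfg.arena_mm[0]},{cfg.arena_mm[1]}")
    lines.append(f"fps = {cfg.fps}")
    lines.append(f"size_class = {cfg.size_class}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path) -> SetupConfig:
    cfg = SetupConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "video":
            cfg.video = val
        elif key == "segment_start":
            cfg.segment_start = float(val)
        elif key == "segment_end":
            cfg.segment_end = float(val)
        elif key == "crop":
            cfg.crop = tuple(int(v) for v in val.split(","))  # type: ignore[assignment]
        elif key == "arena_polygon":
            cfg.arena_polygon = [
                tuple(float(c) for c in pt.split(","))  # type: ignore[misc]
                for pt in val.split(";")
                if pt.strip()
            ]
        elif key == "arena_mm":
            w, h = val.split(",")
            cfg.arena_mm = (float(w), float(h))
        elif key == "fps":
            cfg.fps = float(val)
        elif key == "size_class":
            cfg.size_class = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


# ---------------------------------------------------------------------------
# coordinate tables


def _track_columns(n: int) -> list[str]:
    cols = ["frame", "flag", "c_x", "c_y"]
    for i in range(1, n + 1):
        cols += [f"s{i}_x", f"s{i}_y"]
    cols += ["head_x", "head_y", "foreground_area"]
    return cols


def write_track_csv(path, track: TrackSeries, extra_flags=None) -> Path:
    """Per-frame coordinates CSV.

    Commented header documents: 0-based frame index, pixel units, image
    coordinates x-right / y-down, S points ordered caudal (s1 = tail) to
    cranial, plus the calibration needed to re-load the series.
    """
    path = Path(path)
    n = track.n_midline
    rows = []
    for i, fm in enumerate(track.frames):
        row = {
            "frame": fm.frame_index,
            "flag": fm.flag if extra_flags is None else extra_flags[i],
            "c_x": fm.C[0],
            "c_y": fm.C[1],
        }
        for j in range(n):
            row[f"s{j + 1}_x"] = fm.S[j, 0]
            row[f"s{j + 1}_y"] = fm.S[j, 1]
        row["head_x"] = fm.head[0]
        row["head_y"] = fm.head[1]
        row["foreground_area"] = fm.foreground_area
        rows.append(row)
    df = pd.DataFrame(rows, columns=_track_columns(n))
    header = (
        "# fishgait track: one row per frame (0-based index), pixel units,\n"
        "# image coordinates x-right / y-down, origin at the crop top-left.\n"
        "# s1..sN are midline points ordered caudal (tail) -> cranial;\n"
        "# head is the extra cranial point.\n"
        f"# fps: {track.fps}\n"
        f"# mm_per_px: {track.mm_per_px}\n"
        f"# n_midline: {n}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_track_csv(path) -> TrackSeries:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    n = int(meta.get("n_midline", sum(1 for c in df.columns if c.endswith("_x")) - 2))
    frames = []
    for _, row in df.iterrows():
        S = np.array([[row[f"s{j + 1}_x"], row[f"s{j + 1}_y"]] for j in range(n)])
        frames.append(
            FrameMidline(
                frame_index=int(row["frame"]),
                C=np.array([row["c_x"], row["c_y"]]),
                S=S,
                head=np.array([row["head_x"], row["head_y"]]),
                foreground_area=float(row.get("foreground_area", np.nan)),
                flag=str(row["flag"]),
            )
        )
    return TrackSeries(
        fps=float(meta.get("fps", 100.0)),
        mm_per_px=float(meta.get("mm_per_px", 1.0)),
        frames=frames,
    )


def write_table(path, df: pd.DataFrame, doc: str = "") -> Path:
    """CSV with an optional commented documentation header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in doc.strip().splitlines():
            fh.write(f"# {line}\n" if not line.startswith("#") else line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(path, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return path
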