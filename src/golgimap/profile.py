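"""Line-scan intensity profiles: extraction, normalization, smoothing.

Reimplements the Fiji/BAR "multichannel profile" step: sample each channel
along a user-drawn line (bilinear interpolation, averaged over a small
perpendicular width), then rescale each channel to [0, 1] and smooth with a
centered moving average before peaks are read off.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import MultiChannelImage, ROLES


class ROIError(ValueError):
    """A line ROI is invalid or does not fit the image."""


@dataclass(frozen=True)
class LineROI:
    """An oriented line segment through one Golgi stack in one cell.

    ``p0`` and ``p1`` are (x, y) endpoint coordinates in pixels (sub-pixel
    allowed).  Intensities are averaged over ``width_px`` lines at unit
    perpendicular spacing and sampled every ``sample_step_px`` along the arc.
    """

    cell_id: str
    stack_id: str
    p0: tuple[float, float]
    p1: tuple[float, float]
    width_px: int = 3
    sample_step_px: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ROIError(f"ROI {self.stack_id}: p0 and p1 coincide")
        if self.width_px < 1:
            raise ROIError(f"ROI {self.stack_id}: width_px must be >= 1")
        if self.sample_step_px <= 0:
            raise ROIError(f"ROI {self.stack_id}: sample_step_px must be > 0")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def reversed(self) -> "LineROI":
        return LineROI(
            cell_id=self.cell_id,
            stack_id=self.stack_id,
            p0=self.p1,
            p1=self.p0,
            width_px=self.width_px,
            sample_step_px=self.sample_step_px,
        )


@dataclass
class IntensityProfile:
    """Per-channel intensity versus arc length for one ROI.

    ``raw`` holds extracted intensities; ``normalized`` and ``smoothed`` are
    filled by :func:`normalize_profile` and :func:`smooth_profile`.
    Channels whose raw trace is constant are flagged in
    ``degenerate_channels`` (their normalized trace is all zeros).
    """

    roi: LineROI
    positions_px: np.ndarray
    positions_nm: np.ndarray
    raw: dict[str, np.ndarray]
    channel_roles: dict[str, str]  # role -> channel name
    pixel_size_nm: float
    normalized: dict[str, np.ndarray] | None = None
    smoothed: dict[str, np.ndarray] | None = None
    degenerate_channels: set[str] = field(default_factory=set)
    smooth_window: int | None = None
    # True when p0 -> p1 runs along the canonical (lexicographic) endpoint
    # order; peak finding uses this to report positions on a fixed axis so
    # distances are bit-identical however the line was drawn.
    canonical: bool = True

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.raw)

    def channel_for_role(self, role: str) -> str:
        if role not in self.channel_roles:
            raise ROIError(f"profile has no channel for role {role!r}")
        return self.channel_roles[role]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "position_px": self.positions_px,
            "position_nm": self.positions_nm,
        }
        for name, arr in self.raw.items():
            cols[f"raw_{name}"] = arr
        for label, group in (("normalized", self.normalized), ("smoothed", self.smoothed)):
            if group is not None:
                for name, arr in group.items():
                    cols[f"{label}_{name}"] = arr
        return pd.DataFrame(cols)


def extract_profile(image: MultiChannelImage, roi: LineROI) -> IntensityProfile:
    """Sample every channel along the ROI (raw intensities only).

    Arc-length positions run from ``p0`` toward ``p1`` at
    ``roi.sample_step_px`` spacing; each sample is the mean of bilinearly
    interpolated values over ``width_px`` parallel lines.

    The sampling grid is anchored at the lexicographically smaller endpoint,
    so swapping ``p0`` and ``p1`` samples the identical physical points and
    reverses the profile bit-exactly.  When the arc length is not a multiple
    of the step, the reversed ROI's first sample therefore sits at the
    (sub-step) remainder rather than at 0; ``positions_px`` records the true
    arc length of every sample from ``p0``.
    """
    image.require_roles()
    p0 = np.asarray(roi.p0, dtype=float)
    p1 = np.asarray(roi.p1, dtype=float)
    length = roi.length_px
    n = int(np.floor(length / roi.sample_step_px)) + 1
    t = np.arange(n) * roi.sample_step_px
    canonical = tuple(roi.p0) <= tuple(roi.p1)
    c0, c1 = (p0, p1) if canonical else (p1, p0)
    u = (c1 - c0) / length
    v = np.array([-u[1], u[0]])
    offsets = np.arange(roi.width_px) - (roi.width_px - 1) / 2.0

    # coords[width, sample], along the canonical direction
    xs = c0[0] + t[None, :] * u[0] + offsets[:, None] * v[0]
    ys = c0[1] + t[None, :] * u[1] + offsets[:, None] * v[1]

    h, w = image.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ROIError(
            f"ROI {roi.stack_id} samples [{xs.min():.1f}, {xs.max():.1f}] x "
            f"[{ys.min():.1f}, {ys.max():.1f}] px, outside the {w}x{h} image "
            "(width averaging included)"
        )

    raw = {}
    for name in image.channels:
        vals = ndimage.map_coordinates(
            np.asarray(image.channel(name), dtype=float),
            [ys, xs],
            order=1,
            mode="nearest",
        )
        arr = vals.mean(axis=0)
        raw[name] = arr if canonical else arr[::-1].copy()

    if canonical:
        positions = t
    else:
        positions = (length - (n - 1) * roi.sample_step_px) + t
    return IntensityProfile(
        roi=roi,
        positions_px=positions,
        positions_nm=positions * image.pixel_size_nm,
        raw=raw,
        channel_roles=dict(image.roles),
        pixel_size_nm=image.pixel_size_nm,
        canonical=canonical,
    )


def normalize_profile(profile: IntensityProfile) -> IntensityProfile:
    """Per-channel min-max rescaling to [0, 1], in place.

    A constant channel cannot be rescaled; it maps to all zeros and is
    flagged as degenerate rather than raising.
    """
    normalized = {}
    for name, arr in profile.raw.items():
        lo = float(arr.min())
        hi = float(arr.max())
        if hi > lo:
            normalized[name] = (arr - lo) / (hi - lo)
        else:
            normalized[name] = np.zeros_like(arr)
            profile.degenerate_channels.add(name)
    profile.normalized = normalized
    return profile


def smooth_profile(profile: IntensityProfile, window: int = 5) -> IntensityProfile:
    """Centered moving average with reflect padding, in place.

    ``window`` must be odd and no longer than the profile; ``window=1`` is
    the identity.
    """
    if profile.normalized is None:
        raise ValueError("normalize_profile must run before smooth_profile")
    n = len(profile.positions_px)
    if window % 2 == 0:
        raise ValueError(f"smoothing window must be odd, got {window}")
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds profile length {n}")
    pad = window // 2
    smoothed = {}
    for name, arr in profile.normalized.items():
        if pad:
            padded = np.pad(arr, pad, mode="reflect")
            # accumulate symmetric pairs so a reversed profile smooths to
            # the bit-exact reversal (pairwise addition commutes in IEEE)
            acc = padded[pad:pad + n].copy()
            for j in range(1, pad + 1):
                acc += padded[pad - j:pad - j + n] + padded[pad + j:pad + j + n]
            smoothed[name] = acc / window
        else:
            smoothed[name] = arr.copy()
    profile.smoothed = smoothed
    profile.smooth_window = window
    return profile


# ----------------------------------------------------------------------- I/O


def read_rois_csv(path: str | Path) -> list[LineROI]:
    """ROI table with columns stack_id, x0, y0, x1, y1 (+ optional cell_id,
    width_px, sample_step_px)."""
    df = pd.read_csv(path)
    required = {"stack_id", "x0", "y0", "x1", "y1"}
    missing = required - set(df.columns)
    if missing:
        raise ROIError(f"{path}: ROI CSV missing columns {sorted(missing)}")
    rois = []
    for _, row in df.iterrows():
        kwargs = {}
        if "width_px" in df.columns and not pd.isna(row["width_px"]):
            kwargs["width_px"] = int(row["width_px"])
        if "sample_step_px" in df.columns and not pd.isna(row["sample_step_px"]):
            kwargs["sample_step_px"] = float(row["sample_step_px"])
        rois.append(
            LineROI(
                cell_id=str(row["cell_id"]) if "cell_id" in df.columns else str(row["stack_id"]),
                stack_id=str(row["stack_id"]),
                p0=(float(row["x0"]), float(row["y0"])),
                p1=(float(row["x1"]), float(row["y1"])),
                **kwargs,
            )
        )
    return rois


def read_rois_json(path: str | Path) -> list[LineROI]:
    """JSON list of objects with the same fields as the CSV reader."""
    with open(path) as fh:
        records = json.load(fh)
    rois = []
    for rec in records:
        rois.append(
            LineROI(
                cell_id=str(rec.get("cell_id", rec["stack_id"])),
                stack_id=str(rec["stack_id"]),
                p0=(float(rec["x0"]), float(rec["y0"])),
                p1=(float(rec["x1"]), float(rec["y1"])),
                width_px=int(rec.get("width_px", 3)),
                sample_step_px=float(rec.get("sample_step_px", 0.5)),
            )
        )
    return rois


def read_imagej_line_roi(
    source: str | Path | bytes,
    cell_id: str = "cell0",
    stack_id: str = "roi0",
    width_px: int = 3,
) -> LineROI:
    """Best-effort reader for ImageJ ``.roi`` files of type *line*.

    Parses only the straight-line subset of the format: magic ``Iout``,
    ROI type byte 6 == 3 (line), endpoint floats at offsets 18..33
    (big-endian x1, y1, x2, y2).  Anything else raises.
    """
    data = source if isinstance(source, bytes) else Path(source).read_bytes()
    if len(data) < 34 or data[:4] != b"Iout":
        raise ROIError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type != 3:
        raise ROIError(f"only straight-line ROIs are supported (type byte {roi_type})")
    x1, y1, x2, y2 = struct.unpack(">4f", data[18:34])
    return LineROI(
        cell_id=cell_id, stack_id=stack_id, p0=(x1, y1), p1=(x2, y2), width_px=width_px
    )


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)
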