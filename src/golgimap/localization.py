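"""Peak localization and signed peak-to-peak distances.

Each channel's peak is the global maximum of its smoothed normalized
profile, refined to sub-sample precision by a three-point parabolic fit.
The three pairwise distances (cis→TGN, TGN→POI, cis→POI) are signed by the
cis→TGN orientation convention: whatever direction the line was drawn, the
cis-/medial marker is upstream of TGN38, so a positive TGN→POI distance
places the protein of interest downstream of the TGN and a negative one
upstream.  QC rejects low-prominence peaks, profiles with strong secondary
peaks (non-separated stacks) and near-edge-on stacks whose projected axis
collapses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .image import MultiChannelImage
from .profile import IntensityProfile, LineROI, extract_profile, normalize_profile, smooth_profile

logger = logging.getLogger(__name__)

ROLE_ORDER = ("cis", "tgn", "poi")


class DegenerateChannelError(ValueError):
    """Peak requested on an all-zero (constant) channel."""


@dataclass(frozen=True)
class PeakFit:
    """Sub-pixel peak location and prominence for one channel."""

    channel: str
    position_px: float
    position_nm: float
    prominence: float


def find_peak(profile: IntensityProfile, role: str) -> PeakFit:
    """Locate the peak of the channel assigned to ``role``.

    Position: global argmax of the smoothed trace, refined by fitting a
    parabola through the argmax and its two neighbours.  A plateau of tied
    maxima returns the centroid of the tied run (no parabola).  Prominence:
    peak height minus the higher of the two minima flanking it out to the
    profile ends, measured on the smoothed normalized trace.

    Positions are reported in arc length along the line's canonical
    orientation, so peak-to-peak distances are bit-identical whichever
    direction the line was drawn.
    """
    if profile.smoothed is None:
        raise ValueError("profile must be normalized and smoothed before peak finding")
    channel = profile.channel_for_role(role)
    if channel in profile.degenerate_channels:
        raise DegenerateChannelError(
            f"channel {channel!r} (role {role}) is constant; no peak is defined"
        )
    y = profile.smoothed[channel]
    if not profile.canonical:
        y = y[::-1]
    t = profile.positions_px
    step = float(t[1] - t[0]) if len(t) > 1 else 1.0

    i = int(np.argmax(y))
    ymax = y[i]
    # plateau of exact ties -> centroid of the contiguous tied run
    j0, j1 = i, i
    while j0 > 0 and y[j0 - 1] == ymax:
        j0 -= 1
    while j1 < len(y) - 1 and y[j1 + 1] == ymax:
        j1 += 1
    if j1 > j0:
        pos = (j0 + j1) / 2.0 * step
        i = (j0 + j1) // 2
    elif 0 < i < len(y) - 1:
        # symmetric grouping keeps the fit bit-identical under reversal
        denom = (y[i - 1] + y[i + 1]) - 2.0 * y[i]
        delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
        pos = (i + float(np.clip(delta, -0.5, 0.5))) * step
    else:
        pos = i * step

    left_min = float(y[: i + 1].min())
    right_min = float(y[i:].min())
    prominence = float(ymax - max(left_min, right_min))
    return PeakFit(
        channel=channel,
        position_px=pos,
        position_nm=pos * profile.pixel_size_nm,
        prominence=prominence,
    )


class OrientationUndefinedError(ValueError):
    """cis and TGN peaks coincide exactly; the stack axis direction is undefined."""


def signed_distances(s_cis: float, s_tgn: float, s_poi: float) -> dict[str, float]:
    """Signed pairwise distances from peak arc-length positions (same units in/out).

    The sign convention orients every stack cis→TGN: with
    sigma = sign(s_tgn - s_cis), d_ab = sigma * (s_b - s_a).  The result is
    independent of the direction the line was drawn, and
    d_cis_poi = d_cis_tgn + d_tgn_poi holds exactly.
    """
    sigma = np.sign(s_tgn - s_cis)
    if sigma == 0:
        raise OrientationUndefinedError(
            "cis and TGN peaks coincide; cannot orient the stack axis"
        )
    return {
        "d_cis_tgn": float(sigma * (s_tgn - s_cis)),
        "d_tgn_poi": float(sigma * (s_poi - s_tgn)),
        "d_cis_poi": float(sigma * (s_poi - s_cis)),
    }


@dataclass(frozen=True)
class QCThresholds:
    """Operational stand-ins for the by-eye exclusion of unusable stacks.

    ``min_axis_nm`` defaults to twice the pixel size at measurement time
    when left as None.
    """

    prominence_min: float = 0.3
    secondary_ratio: float = 0.5
    min_axis_nm: float | None = None


def qc_stack(
    profile: IntensityProfile,
    peaks: dict[str, PeakFit],
    distances: dict[str, float] | None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[bool, list[str]]:
    """Quality-control one stack measurement; returns (pass, reasons).

    Fails on: any channel prominence below ``prominence_min``; any channel
    with a secondary peak whose prominence reaches ``secondary_ratio`` times
    the primary's (non-separated stacks); projected cis→TGN axis shorter
    than ``min_axis_nm`` (edge-on stack); undefined orientation.
    """
    reasons: list[str] = []
    min_axis = thresholds.min_axis_nm
    if min_axis is None:
        min_axis = 2.0 * profile.pixel_size_nm

    for role in ROLE_ORDER:
        if role not in peaks:
            reasons.append(f"no peak for role {role}")
            continue
        pk = peaks[role]
        if pk.prominence < thresholds.prominence_min:
            reasons.append(
                f"low prominence in {pk.channel} ({pk.prominence:.2f} < "
                f"{thresholds.prominence_min})"
            )
        y = profile.smoothed[pk.channel]
        if not profile.canonical:
            y = y[::-1]
        floor = thresholds.secondary_ratio * pk.prominence
        if floor > 0:
            idx, props = signal.find_peaks(y, prominence=floor)
            step = profile.positions_px[1] - profile.positions_px[0] if len(y) > 1 else 1.0
            primary_i = pk.position_px / step
            secondary = [k for k in idx if abs(k - primary_i) > 1.0]
            if secondary:
                reasons.append(f"secondary peak in {pk.channel} (non-separated stacks)")

    if distances is None:
        reasons.append("orientation undefined (cis and TGN peaks coincide)")
    elif distances["d_cis_tgn"] < min_axis:
        reasons.append(
            f"projected cis-TGN axis {distances['d_cis_tgn']:.0f} nm < "
            f"{min_axis:.0f} nm (edge-on stack)"
        )
    return (len(reasons) == 0, reasons)


@dataclass
class StackMeasurement:
    """Peak positions, the three signed distances and QC verdict for one ROI."""

    cell_id: str
    stack_id: str
    protein: str
    peaks: dict[str, PeakFit]
    d_tgn_poi: float
    d_cis_tgn: float
    d_cis_poi: float
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)
    cis_marker: str = ""

    def as_record(self) -> dict:
        rec = {
            "protein": self.protein,
            "cell_id": self.cell_id,
            "stack_id": self.stack_id,
            "cis_marker": self.cis_marker,
            "d_tgn_poi_nm": self.d_tgn_poi,
            "d_cis_tgn_nm": self.d_cis_tgn,
            "d_cis_poi_nm": self.d_cis_poi,
            "qc_pass": self.qc_pass,
            "qc_reasons": "; ".join(self.qc_reasons),
        }
        for role, pk in self.peaks.items():
            rec[f"prominence_{role}"] = pk.prominence
        return rec


def measure_stack(
    image: MultiChannelImage,
    roi: LineROI,
    smooth_window: int = 5,
    thresholds: QCThresholds = QCThresholds(),
    protein: str | None = None,
) -> StackMeasurement:
    """Full per-stack pipeline: extract → normalize → smooth → peaks →
    signed distances → QC."""
    profile = extract_profile(image, roi)
    normalize_profile(profile)
    smooth_profile(profile, smooth_window)

    peaks: dict[str, PeakFit] = {}
    degenerate: list[str] = []
    for role in ROLE_ORDER:
        try:
            peaks[role] = find_peak(profile, role)
        except DegenerateChannelError:
            degenerate.append(role)

    distances = None
    if not degenerate:
        try:
            distances = signed_distances(
                peaks["cis"].position_nm,
                peaks["tgn"].position_nm,
                peaks["poi"].position_nm,
            )
        except OrientationUndefinedError:
            distances = None

    qc_pass, reasons = qc_stack(profile, peaks, distances, thresholds)
    for role in degenerate:
        reasons.append(f"degenerate (constant) channel for role {role}")
        qc_pass = False
    nan = float("nan")
    return StackMeasurement(
        cell_id=roi.cell_id,
        stack_id=roi.stack_id,
        protein=profile.channel_roles["poi"] if protein is None else protein,
        peaks=peaks,
        d_tgn_poi=distances["d_tgn_poi"] if distances else nan,
        d_cis_tgn=distances["d_cis_tgn"] if distances else nan,
        d_cis_poi=distances["d_cis_poi"] if distances else nan,
        qc_pass=qc_pass,
        qc_reasons=reasons,
        cis_marker=profile.channel_roles["cis"],
    )


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell mean of each signed distance over QC-passing stacks;
    one cell is one data point downstream."""

    cell_id: str
    protein: str
    cis_marker: str
    d_tgn_poi: float
    d_cis_tgn: float
    d_cis_poi: float
    n_stacks_used: int


def aggregate_cells(measurements: list[StackMeasurement]) -> list[CellMeasurement]:
    """Unweighted per-cell mean over QC-passing stacks.

    Cells whose every stack failed QC are dropped and the exclusion logged.
    """
    if not measurements:
        raise ValueError("no stack measurements to aggregate")
    by_cell: dict[str, list[StackMeasurement]] = {}
    for m in measurements:
        by_cell.setdefault(m.cell_id, []).append(m)

    cells = []
    for cell_id, ms in by_cell.items():
        passing = [m for m in ms if m.qc_pass]
        if not passing:
            logger.info(
                "cell %s excluded: all %d stacks failed QC (%s)",
                cell_id,
                len(ms),
                "; ".join(r for m in ms for r in m.qc_reasons),
            )
            continue
        cells.append(
            CellMeasurement(
                cell_id=cell_id,
                protein=passing[0].protein,
                cis_marker=passing[0].cis_marker,
                d_tgn_poi=float(np.mean([m.d_tgn_poi for m in passing])),
                d_cis_tgn=float(np.mean([m.d_cis_tgn for m in passing])),
                d_cis_poi=float(np.mean([m.d_cis_poi for m in passing])),
                n_stacks_used=len(passing),
            )
        )
    return cells


def reference_distance(cells: list[CellMeasurement]) -> dict[str, float]:
    """Dataset-wide mean cis→TGN38 distance, one value per cis-marker identity.

    This is the dotted-line reference: the average TGN38–GM130 (or
    TGN38–giantin) distance over every cell in the dataset that used that
    marker.
    """
    by_marker: dict[str, list[float]] = {}
    for c in cells:
        by_marker.setdefault(c.cis_marker, []).append(c.d_cis_tgn)
    return {marker: float(np.mean(vals)) for marker, vals in by_marker.items()}


def measurements_frame(measurements: list[StackMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.as_record() for m in measurements])


def cells_frame(cells: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": c.protein,
                "cell_id": c.cell_id,
                "cis_marker": c.cis_marker,
                "d_tgn_poi_nm": c.d_tgn_poi,
                "d_cis_tgn_nm": c.d_cis_tgn,
                "d_cis_poi_nm": c.d_cis_poi,
                "n_stacks_used": c.n_stacks_used,
            }
            for c in cells
        ]
    )
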