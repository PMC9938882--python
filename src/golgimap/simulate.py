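"""Synthetic Golgi-stack renderer with ground truth.

A Golgi stack is modelled as three parallel fluorescent layers (cis-/medial
marker, TGN38, protein of interest) offset along the stack axis.  The stack
sits at an arbitrary in-plane angle and an out-of-plane tilt; the tilt
compresses every axial offset by cos(tilt) in the image plane, which is the
projection bias that makes absolute inter-layer distances unmeasurable on
real micrographs and motivates relative measurements.

Each layer is an anisotropic 2D Gaussian: short axis (the stack axis) with
``ridge_sigma_nm``, long axis spanning ``ridge_length_nm``.  The microscope
PSF is Gaussian, so the blurred layer is again a Gaussian with summed
variances; layers are rendered directly at that blurred covariance, which is
exact for this model and fast.  Detection noise is Poisson photon counting
plus additive Gaussian read noise, matching photon-counting confocal
acquisition; a noise-free mode returns the expectation image for exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .image import MultiChannelImage
from .profile import LineROI

LAYERS = ("cis", "tgn", "poi")


class GeometryError(ValueError):
    """Stack geometry does not fit the requested canvas."""


@dataclass(frozen=True)
class StackGeometry:
    """Pose and layer layout of one Golgi stack.

    ``layer_offsets_nm`` are the true axial positions of (cis, tgn, poi)
    along the stack axis, with cis fixed at 0 by construction.  Offsets
    measured in the image plane are these values times ``cos(tilt)``.
    """

    center_xy: tuple[float, float]
    axis_angle_inplane: float
    tilt_outofplane: float
    layer_offsets_nm: tuple[float, float, float]
    ridge_length_nm: float = 600.0
    ridge_sigma_nm: float = 60.0

    def __post_init__(self) -> None:
        if self.layer_offsets_nm[0] != 0.0:
            raise ValueError("cis layer offset must be 0 by construction")
        if not 0.0 <= self.tilt_outofplane < math.pi / 2:
            raise ValueError("tilt_outofplane must lie in [0, pi/2)")
        if self.ridge_length_nm <= 0 or self.ridge_sigma_nm <= 0:
            raise ValueError("ridge dimensions must be positive")

    @property
    def axis_unit(self) -> tuple[float, float]:
        """Unit vector of the projected stack axis (x, y)."""
        return (math.cos(self.axis_angle_inplane), math.sin(self.axis_angle_inplane))

    @property
    def projection_factor(self) -> float:
        return math.cos(self.tilt_outofplane)

    def projected_offsets_nm(self) -> dict[str, float]:
        """In-plane offsets for the three layer pairs, in nm."""
        c, t, p = (o * self.projection_factor for o in self.layer_offsets_nm)
        return {"cis_tgn": t - c, "cis_poi": p - c, "tgn_poi": p - t}


@dataclass(frozen=True)
class ImagingModel:
    """Acquisition model: sampling, PSF and photon statistics.

    ``photon_scale`` is the expected photon count at a layer peak before
    background.  With ``noise=False`` the expectation image (still scaled
    to photons) is returned without Poisson or read noise.
    """

    pixel_size_nm: float = 40.0
    psf_sigma_nm: float = 90.0
    photon_scale: float = 100.0
    read_noise_sd: float = 2.0
    background_level: float = 10.0
    noise: bool = True
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-stack truth sidecar row."""

    cell_id: str
    stack_id: str
    protein: str
    geometry: StackGeometry
    projected_offsets_nm: dict[str, float]

    def as_record(self) -> dict:
        g = self.geometry
        rec = {
            "cell_id": self.cell_id,
            "stack_id": self.stack_id,
            "protein": self.protein,
            "tilt_rad": g.tilt_outofplane,
            "axis_angle_rad": g.axis_angle_inplane,
            "true_cis_tgn_nm": g.layer_offsets_nm[1] - g.layer_offsets_nm[0],
            "true_tgn_poi_nm": g.layer_offsets_nm[2] - g.layer_offsets_nm[1],
            "true_cis_poi_nm": g.layer_offsets_nm[2] - g.layer_offsets_nm[0],
        }
        for k, v in self.projected_offsets_nm.items():
            rec[f"proj_{k}_nm"] = v
        return rec


# --------------------------------------------------------------------- render


def _expected_channels(
    geoms_and_amps: Sequence[tuple[StackGeometry, float]],
    model: ImagingModel,
    shape: tuple[int, int],
) -> np.ndarray:
    """Noise-free expectation (photons, background excluded), one plane per layer."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    px = model.pixel_size_nm
    out = np.zeros((3, h, w))
    for geom, amp in geoms_and_amps:
        if amp == 0.0:
            continue
        cx, cy = geom.center_xy
        ux, uy = geom.axis_unit
        # blurred covariance: ridge sigma (+) PSF along the axis,
        # half-length (+) PSF laterally
        sa = math.hypot(geom.ridge_sigma_nm, model.psf_sigma_nm) / px
        sl = math.hypot(geom.ridge_length_nm / 2.0, model.psf_sigma_nm) / px
        proj = geom.projection_factor
        dx = xs - cx
        dy = ys - cy
        a = dx * ux + dy * uy  # along-axis coordinate, px
        b = -dx * uy + dy * ux  # lateral coordinate, px
        lat = np.exp(-0.5 * (b / sl) ** 2)
        for k, off_nm in enumerate(geom.layer_offsets_nm):
            s = off_nm * proj / px
            _check_inside(cx + s * ux, cy + s * uy, sa + sl, shape, geom)
            out[k] += amp * np.exp(-0.5 * ((a - s) / sa) ** 2) * lat
    return out


def _check_inside(x: float, y: float, margin_px: float, shape: tuple[int, int], geom) -> None:
    h, w = shape
    if not (0 <= x - 0 and x <= w - 1 and 0 <= y and y <= h - 1):
        raise GeometryError(
            f"stack layer at ({x:.1f}, {y:.1f}) px falls outside the "
            f"{w}x{h} canvas (geometry center {geom.center_xy}, "
            f"tilt {math.degrees(geom.tilt_outofplane):.1f} deg)"
        )


def default_canvas(geom: StackGeometry, model: ImagingModel) -> tuple[int, int]:
    """Square canvas comfortably containing the rotated stack plus PSF support."""
    px = model.pixel_size_nm
    extent_nm = (
        max(abs(o) for o in geom.layer_offsets_nm)
        + geom.ridge_length_nm / 2.0
        + 3.0 * (model.psf_sigma_nm + geom.ridge_sigma_nm)
    )
    half = int(math.ceil(extent_nm / px)) + 2
    side = 2 * half + 1
    return (side, side)


def _apply_noise(expected: np.ndarray, model: ImagingModel, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(expected).astype(float)
    if model.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, model.read_noise_sd, size=expected.shape)
    return counts


def render_scene(
    geoms: Sequence[StackGeometry],
    model: ImagingModel,
    shape: tuple[int, int] | None = None,
    channels: tuple[str, str, str] = ("cis_marker", "TGN38", "poi"),
    rng: np.random.Generator | None = None,
    amplitudes: Sequence[float] | None = None,
) -> MultiChannelImage:
    """Render one image containing any number of stacks (expectations add)."""
    if not geoms:
        raise ValueError("at least one stack geometry required")
    if shape is None:
        sides = [default_canvas(g, model) for g in geoms]
        side = max(s[0] for s in sides)
        # an explicit off-center geometry grows the canvas to contain it
        for g, s in zip(geoms, sides):
            if g.center_xy is not None:
                half = s[0] // 2
                side = max(side, int(math.ceil(max(g.center_xy))) + half + 1)
        shape = (side, side)
        geoms = [
            replace(g, center_xy=(side // 2, side // 2))
            if g.center_xy is None
            else g
            for g in geoms
        ]
    if amplitudes is None:
        amplitudes = [1.0] * len(geoms)
    expected = _expected_channels(list(zip(geoms, amplitudes)), model, shape)
    expected = model.photon_scale * expected + model.background_level
    if model.noise:
        if rng is None:
            rng = np.random.default_rng(model.rng_seed)
        data = _apply_noise(expected, model, rng)
    else:
        data = expected
    roles = {"cis": channels[0], "tgn": channels[1], "poi": channels[2]}
    return MultiChannelImage(
        data=data, channels=channels, pixel_size_nm=model.pixel_size_nm, roles=roles
    )


def render_stack(
    geom: StackGeometry,
    model: ImagingModel,
    shape: tuple[int, int] | None = None,
    channels: tuple[str, str, str] = ("cis_marker", "TGN38", "poi"),
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
    stack_id: str = "stack0",
    protein: str = "poi",
) -> tuple[MultiChannelImage, GroundTruth]:
    """Render a single stack and return the image with its truth sidecar."""
    if geom.center_xy is None:
        side = default_canvas(geom, model)[0]
        geom = replace(geom, center_xy=(side // 2, side // 2))
        shape = (side, side)
    image = render_scene([geom], model, shape=shape, channels=channels, rng=rng)
    truth = GroundTruth(
        cell_id=cell_id,
        stack_id=stack_id,
        protein=protein,
        geometry=geom,
        projected_offsets_nm=geom.projected_offsets_nm(),
    )
    return image, truth


def add_distractor_stack(
    image: MultiChannelImage,
    geom2: StackGeometry,
    model: ImagingModel,
    intensity: float = 1.0,
) -> MultiChannelImage:
    """Add a second (noiseless) stack to an existing image.

    Used to construct non-separated Golgi stacks for QC tests: with
    ``intensity=0`` the image is returned bit-identical; on noise-free
    images the result equals rendering both stacks together.
    """
    extra = _expected_channels([(geom2, intensity)], model, image.shape)
    return MultiChannelImage(
        data=image.data + model.photon_scale * extra,
        channels=image.channels,
        pixel_size_nm=image.pixel_size_nm,
        roles=dict(image.roles),
    )


# --------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class ProteinSpec:
    """One protein of interest to simulate: its true axial offset from TGN38
    (positive = downstream of the TGN) and the sampling depth."""

    name: str
    true_tgn_offset_nm: float
    n_cells: int
    stacks_per_cell: int = 3
    cis_marker: str = "GM130"

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.stacks_per_cell < 1:
            raise ValueError("n_cells and stacks_per_cell must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions shared by every simulated stack.

    ``cis_tgn_offset_nm`` is the axial distance between the cis-/medial
    marker and TGN38 — it sets the dataset-wide reference distance.  Tilts
    are drawn Uniform(0, ``tilt_max_rad``); an optional acceptance cutoff
    emulates the experimenter keeping only near-in-plane stacks.
    ``offset_jitter_nm`` is per-stack biological variability of the TGN and
    POI layer positions.
    """

    cis_tgn_offset_nm: float = 400.0
    tilt_max_rad: float = math.radians(30.0)
    tilt_accept_max_rad: float | None = None
    offset_jitter_nm: float = 20.0
    ridge_length_nm: float = 600.0
    ridge_sigma_nm: float = 60.0
    roi_width_px: int = 3
    roi_margin_nm: float = 600.0


@dataclass
class CohortDataset:
    """Images, auto-ROIs and ground truth for a simulated cohort."""

    images: list[MultiChannelImage]
    rois: list[LineROI]
    truth: list[GroundTruth]
    config: CohortConfig
    model: ImagingModel

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_record() for t in self.truth])


def draw_geometry(
    rng: np.random.Generator,
    config: CohortConfig,
    true_tgn_offset_nm: float,
) -> StackGeometry:
    """Draw one stack pose + layer layout under the cohort's conditions."""
    angle = rng.uniform(0.0, 2.0 * math.pi)
    cutoff = config.tilt_accept_max_rad
    while True:
        tilt = rng.uniform(0.0, config.tilt_max_rad)
        if cutoff is None or tilt <= cutoff:
            break
    jit = config.offset_jitter_nm
    tgn = config.cis_tgn_offset_nm + (rng.normal(0.0, jit) if jit > 0 else 0.0)
    poi = tgn + true_tgn_offset_nm + (rng.normal(0.0, jit) if jit > 0 else 0.0)
    return StackGeometry(
        center_xy=None,  # centered on the auto-sized canvas at render time
        axis_angle_inplane=angle,
        tilt_outofplane=tilt,
        layer_offsets_nm=(0.0, tgn, poi),
        ridge_length_nm=config.ridge_length_nm,
        ridge_sigma_nm=config.ridge_sigma_nm,
    )


def _auto_roi(
    geom: StackGeometry,
    model: ImagingModel,
    config: CohortConfig,
    cell_id: str,
    stack_id: str,
) -> LineROI:
    """Line through the true stack center along the true projected axis."""
    px = model.pixel_size_nm
    cx, cy = geom.center_xy
    ux, uy = geom.axis_unit
    offs = [o * geom.projection_factor for o in geom.layer_offsets_nm]
    lo = (min(offs) - config.roi_margin_nm) / px
    hi = (max(offs) + config.roi_margin_nm) / px
    return LineROI(
        cell_id=cell_id,
        stack_id=stack_id,
        p0=(cx + lo * ux, cy + lo * uy),
        p1=(cx + hi * ux, cy + hi * uy),
        width_px=config.roi_width_px,
    )


def render_cohort(
    protein_specs: Sequence[ProteinSpec],
    model: ImagingModel,
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> CohortDataset:
    """Render every stack of every cell of every protein, with auto-ROIs.

    The auto-ROI for each stack is drawn through the true stack center along
    the true projected axis — fixed before any measurement runs, mirroring
    how lines were drawn from the marker channels without looking at the
    protein of interest.
    """
    if not protein_specs:
        raise ValueError("protein_specs must not be empty")
    if config is None:
        config = CohortConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(model.rng_seed if rng is None else rng)

    images: list[MultiChannelImage] = []
    rois: list[LineROI] = []
    truth: list[GroundTruth] = []
    for spec in protein_specs:
        for ci in range(spec.n_cells):
            cell_id = f"{spec.name}_cell{ci:03d}"
            for si in range(spec.stacks_per_cell):
                stack_id = f"{cell_id}_s{si}"
                geom = draw_geometry(rng, config, spec.true_tgn_offset_nm)
                side = default_canvas(geom, model)[0]
                geom = replace(geom, center_xy=(side // 2, side // 2))
                image = render_scene(
                    [geom],
                    model,
                    shape=(side, side),
                    channels=(spec.cis_marker, "TGN38", spec.name),
                    rng=rng,
                )
                images.append(image)
                rois.append(_auto_roi(geom, model, config, cell_id, stack_id))
                truth.append(
                    GroundTruth(
                        cell_id=cell_id,
                        stack_id=stack_id,
                        protein=spec.name,
                        geometry=geom,
                        projected_offsets_nm=geom.projected_offsets_nm(),
                    )
                )
    return CohortDataset(images=images, rois=rois, truth=truth, config=config, model=model)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write per-stack TIFFs, the ROI table and the ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_rows = []
    for image, roi in zip(dataset.images, dataset.rois):
        image.to_tiff(out / f"{roi.stack_id}.tif")
        roi_rows.append(
            {
                "cell_id": roi.cell_id,
                "stack_id": roi.stack_id,
                "x0": roi.p0[0],
                "y0": roi.p0[1],
                "x1": roi.p1[0],
                "y1": roi.p1[1],
                "width_px": roi.width_px,
            }
        )
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    dataset.truth_frame().to_csv(out / "truth.csv", index=False)
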