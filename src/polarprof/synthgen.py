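"""Synthetic sporulating-cell micrographs with known ground truth.

Renders populations of rod-shaped bacteria (straight rods with hemispherical
caps) into multi-channel 2-D images: a phase-like cell-body channel, a
membrane-stain channel (shell along the outline plus a bright transverse band
at each division septum, emulating FM4-64), and a fluorescent-reporter
channel whose spatial pattern is one of five localization classes observed in
sporulating *B. subtilis*:

- ``uniform_cyto``            cytoplasmic fill of the whole cell body
- ``uniform_membrane``        follows the membrane shell uniformly
- ``divisome_ring``           transverse band at a stated axial position
- ``polar_cap``               decorates the shell at one cell pole
- ``compartment_restricted``  membrane shell weighted per compartment
  (the pattern of a compartmentalized transmembrane protein such as SpoIIE,
  or of a compartment-specific transcriptional reporter)

Ground truth (per-cell geometry, class, disjoint pixel masks, expected
forespore reporter fraction) is recorded so every downstream stage of the
pipeline can be scored against planted values. Rendering is deterministic:
identical (cells, parameters, seed) produce bit-identical scenes.

Image model: ideal per-channel density fields are blurred with a Gaussian PSF,
a constant background offset (density units) is added, and optionally shot
noise and read noise are applied as

    counts = Poisson(photon_scale * ideal) + Normal(0, read_noise^2),

clipped at zero. ``photon_scale=None`` disables noise and returns the ideal
(blurred) field itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "CLASS_LABELS",
    "CellGeometry",
    "RenderParams",
    "SyntheticScene",
    "PopulationSpec",
    "build_cell",
    "render_scene",
    "sample_population",
    "simulate_population",
    "cell_coordinate_fields",
    "render_ring_frames",
    "write_scene",
    "read_scene",
    "write_truth",
    "read_truth",
]

CLASS_LABELS = (
    "uniform_cyto",
    "uniform_membrane",
    "divisome_ring",
    "polar_cap",
    "compartment_restricted",
)

#: septa with min(s, 1-s) <= POLAR_CUT are considered polar (sporulation-like)
POLAR_CUT = 0.3


@dataclass(frozen=True)
class CellGeometry:
    """Ground-truth description of one rod-shaped cell.

    The cell is a straight capsule: a cylinder of total pole-to-pole length
    ``length_um`` and width ``width_um`` closed by hemispherical caps. The
    axial fraction ``snorm`` runs 0..1 from an arbitrary pole (orientation is
    assigned downstream, from the detected polar septum).
    """

    length_um: float
    width_um: float
    centroid_px: tuple[float, float] = (0.0, 0.0)
    angle_rad: float = 0.0
    septa_snorm: tuple[float, ...] = ()
    compartments: tuple[tuple[float, float, str], ...] = ()
    class_label: str = "uniform_cyto"
    compartment_enrichment: Mapping[str, float] = field(default_factory=dict)
    reporter_density: float = 1.0
    ring_snorm: float | None = None
    cap_pole: int = 0

    @property
    def polar_septa(self) -> tuple[float, ...]:
        return tuple(s for s in self.septa_snorm if min(s, 1 - s) <= POLAR_CUT)


def build_cell(
    length_um: float,
    width_um: float,
    septa_snorm: Sequence[float] = (),
    class_label: str = "uniform_cyto",
    enrichment: Mapping[str, float] | None = None,
    *,
    centroid_px: tuple[float, float] = (0.0, 0.0),
    angle_rad: float = 0.0,
    reporter_density: float = 1.0,
    ring_snorm: float | None = None,
    cap_pole: int = 0,
) -> CellGeometry:
    """Validate geometry and derive the compartment partition from the septa.

    A single polar septum (min(s, 1-s) <= 0.3) yields compartments labeled
    ``forespore`` (the smaller side) and ``mother``; a single medial septum
    yields ``comp_0``/``comp_1``; no septum yields one ``whole`` compartment;
    multiple septa yield ``comp_i``. Compartments partition [0, 1] exactly
    with boundaries at the septa.
    """
    if not (0 < width_um < length_um):
        raise ValueError(f"need 0 < width ({width_um}) < length ({length_um})")
    septa = tuple(float(s) for s in septa_snorm)
    if any(not (0.0 < s < 1.0) for s in septa):
        raise ValueError(f"septa must lie strictly inside (0, 1): {septa}")
    if any(b <= a for a, b in zip(septa, septa[1:])):
        raise ValueError(f"septa must be strictly increasing: {septa}")
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class_label {class_label!r}")

    bounds = (0.0, *septa, 1.0)
    if not septa:
        labels = ["whole"]
    elif len(septa) == 1:
        s = septa[0]
        if min(s, 1 - s) <= POLAR_CUT:
            labels = ["forespore", "mother"] if s <= 0.5 else ["mother", "forespore"]
        else:
            labels = ["comp_0", "comp_1"]
    else:
        labels = [f"comp_{i}" for i in range(len(septa) + 1)]
    compartments = tuple(
        (bounds[i], bounds[i + 1], labels[i]) for i in range(len(labels))
    )

    enr = dict(enrichment) if enrichment is not None else {lab: 1.0 for lab in labels}
    missing = [lab for lab in labels if lab not in enr]
    if missing:
        raise ValueError(f"enrichment missing labels {missing}")
    if any(v < 0 for v in enr.values()):
        raise ValueError("enrichment densities must be >= 0")
    if reporter_density < 0:
        raise ValueError("reporter_density must be >= 0")

    return CellGeometry(
        length_um=float(length_um),
        width_um=float(width_um),
        centroid_px=tuple(centroid_px),
        angle_rad=float(angle_rad),
        septa_snorm=septa,
        compartments=compartments,
        class_label=class_label,
        compartment_enrichment=enr,
        reporter_density=float(reporter_density),
        ring_snorm=ring_snorm,
        cap_pole=int(cap_pole),
    )


@dataclass(frozen=True)
class RenderParams:
    """Optics and camera model for scene rendering.

    psf_sigma_um   Gaussian PSF standard deviation (0 disables blur)
    bg_*           per-channel background offsets, density units
    photon_scale   photons per density unit; None disables all noise
    read_noise     Gaussian read-noise sigma, photon counts
    Shell/septum thicknesses are in pixels; the septum is rendered brighter
    than the lateral shell (``septum_factor``) because it carries two
    apposed membranes.
    """

    psf_sigma_um: float = 0.08
    bg_phase: float = 0.2
    bg_membrane: float = 0.2
    bg_reporter: float = 0.2
    photon_scale: float | None = None
    read_noise: float = 0.0
    phase_density: float = 1.0
    membrane_density: float = 1.0
    septum_factor: float = 2.0
    shell_px: float = 2.0
    septum_px: float = 2.0

    def background(self, channel: str) -> float:
        return {"phase": self.bg_phase, "membrane": self.bg_membrane,
                "reporter": self.bg_reporter}[channel]


@dataclass
class SyntheticScene:
    """Rendered multi-channel image plus its ground truth.

    ``channels`` are the observed images (noisy if noise is enabled);
    ``ideal`` are the blurred, background-added noise-free fields. The
    ground-truth ``mask`` is a label image (cell k -> label k, disjoint by
    construction) and ``cells`` carries one record per cell with its
    geometry and expected forespore reporter fraction.
    """

    channels: dict[str, np.ndarray]
    ideal: dict[str, np.ndarray]
    pixel_size_um: float
    ground_truth: dict
    seed: int
    render_params: RenderParams

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def truth_mask(self) -> np.ndarray:
        return self.ground_truth["mask"]


def _axis_vectors(angle_rad: float) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    n = np.array([-d[1], d[0]])
    return d, n


def _cell_fields_local(cell: CellGeometry, pixel_size_um: float, shape):
    """Per-pixel (u_px, v_px, dist_px, slices) for the cell's bounding box."""
    L = cell.length_um / pixel_size_um
    hw = 0.5 * cell.width_um / pixel_size_um
    d, n = _axis_vectors(cell.angle_rad)
    c = np.asarray(cell.centroid_px, dtype=float)
    pole0 = c - d * (L / 2.0)
    pole1 = c + d * (L / 2.0)
    pad = hw + 4.0
    rmin = int(max(0, np.floor(min(pole0[0], pole1[0]) - pad)))
    rmax = int(min(shape[0], np.ceil(max(pole0[0], pole1[0]) + pad) + 1))
    cmin = int(max(0, np.floor(min(pole0[1], pole1[1]) - pad)))
    cmax = int(min(shape[1], np.ceil(max(pole0[1], pole1[1]) + pad) + 1))
    if rmin >= rmax or cmin >= cmax:
        raise ValueError("cell lies outside the image bounds")
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    rel_r = rr - pole0[0]
    rel_c = cc - pole0[1]
    u = rel_r * d[0] + rel_c * d[1]
    v = rel_r * n[0] + rel_c * n[1]
    uc = np.clip(u, hw, L - hw)
    dist = np.hypot(u - uc, v)
    return u, v, dist, (slice(rmin, rmax), slice(cmin, cmax)), L, hw


def cell_coordinate_fields(
    cell: CellGeometry, shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-image (snorm, dist_px, inside) fields for one cell.

    Convenience for oracles: snorm is the axial fraction of each pixel
    (clipped to [0, 1]), dist_px the distance to the capsule centerline
    segment, inside the cell-body mask.
    """
    u, _v, dist, sl, L, hw = _cell_fields_local(cell, pixel_size_um, shape)
    snorm = np.zeros(shape)
    dist_full = np.full(shape, np.inf)
    inside = np.zeros(shape, dtype=bool)
    snorm[sl] = np.clip(u / L, 0.0, 1.0)
    dist_full[sl] = dist
    inside[sl] = dist <= hw
    return snorm, dist_full, inside


def _compartment_weight(cell: CellGeometry, snorm: np.ndarray) -> np.ndarray:
    bounds = np.array([b for (_a, b, _l) in cell.compartments[:-1]])
    labels = [lab for (_a, _b, lab) in cell.compartments]
    dens = np.array([cell.compartment_enrichment[lab] for lab in labels])
    idx = np.searchsorted(bounds, snorm, side="right")
    return dens[idx]


def _render_cell_channels(cell, rp: RenderParams, pixel_size_um, shape):
    """Ideal (pre-blur) contributions of one cell: phase, membrane, reporter,
    body mask, plus the per-compartment reporter integrals."""
    u, _v, dist, sl, L, hw = _cell_fields_local(cell, pixel_size_um, shape)
    inside = dist <= hw
    shell = inside & (dist >= hw - rp.shell_px)
    snorm = np.clip(u / L, 0.0, 1.0)

    membrane = rp.membrane_density * shell.astype(float)
    for s in cell.septa_snorm:
        band = inside & (np.abs(u - s * L) <= rp.septum_px / 2.0)
        membrane += rp.membrane_density * rp.septum_factor * band

    cls = cell.class_label
    if cls == "uniform_cyto":
        reporter = inside.astype(float)
    elif cls == "uniform_membrane":
        reporter = shell.astype(float)
    elif cls == "divisome_ring":
        s = cell.ring_snorm if cell.ring_snorm is not None else 0.5
        reporter = (inside & (np.abs(u - s * L) <= rp.septum_px / 2.0)).astype(float)
    elif cls == "polar_cap":
        cap_len = 1.5 * hw
        if cell.cap_pole == 0:
            cap = shell & (u <= cap_len)
        else:
            cap = shell & (u >= L - cap_len)
        reporter = cap.astype(float)
    elif cls == "compartment_restricted":
        reporter = shell.astype(float) * _compartment_weight(cell, snorm)
    else:  # pragma: no cover - guarded in build_cell
        raise ValueError(f"unknown class_label {cls!r}")
    reporter *= cell.reporter_density

    comp_sums = {}
    for (a, b, lab) in cell.compartments:
        m = inside & (snorm >= a) & (snorm < b if b < 1.0 else snorm <= b)
        comp_sums[lab] = float(reporter[m].sum())

    phase = rp.phase_density * inside.astype(float)
    return sl, phase, membrane, reporter, inside, comp_sums


def render_scene(
    cells: Sequence[CellGeometry],
    render_params: RenderParams = RenderParams(),
    pixel_size_um: float = 0.065,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    overlap_tolerance_px: int = 0,
) -> SyntheticScene:
    """Render cells into a (phase, membrane, reporter) scene.

    Raises if the image shape is empty or cells overlap by more than
    ``overlap_tolerance_px`` pixels. Identical arguments give bit-identical
    output (one :class:`numpy.random.Generator` seeded with ``seed`` drives
    all noise, consumed in a fixed channel order).
    """
    if len(image_shape) != 2 or min(image_shape) <= 0:
        raise ValueError(f"empty image shape {image_shape}")
    rp = render_params
    shape = tuple(int(x) for x in image_shape)
    names = ("phase", "membrane", "reporter")
    ideal = {k: np.zeros(shape) for k in names}
    truth_mask = np.zeros(shape, dtype=np.int32)
    records = []

    for k, cell in enumerate(cells, start=1):
        sl, phase, membrane, reporter, inside, comp_sums = _render_cell_channels(
            cell, rp, pixel_size_um, shape
        )
        overlap = int(np.count_nonzero(truth_mask[sl][inside]))
        if overlap > overlap_tolerance_px:
            raise ValueError(f"cell {k} overlaps existing cells by {overlap} px")
        ideal["phase"][sl] += phase
        ideal["membrane"][sl] += membrane
        ideal["reporter"][sl] += reporter
        truth_mask[sl][inside] = k
        total = sum(comp_sums.values())
        fs = comp_sums.get("forespore", np.nan)
        records.append(
            {
                "label": k,
                "geometry": cell,
                "reporter_compartment_sums": comp_sums,
                "forespore_fraction": (fs / total) if total > 0 and not np.isnan(fs) else np.nan,
            }
        )

    sigma_px = rp.psf_sigma_um / pixel_size_um
    for k in names:
        if sigma_px > 0:
            ideal[k] = ndimage.gaussian_filter(ideal[k], sigma_px)
        ideal[k] = ideal[k] + rp.background(k)

    rng = np.random.default_rng(seed)
    channels = {}
    for k in names:
        if rp.photon_scale is None:
            channels[k] = ideal[k].copy()
        else:
            img = rng.poisson(rp.photon_scale * ideal[k]).astype(float)
            if rp.read_noise > 0:
                img = img + rng.normal(0.0, rp.read_noise, size=shape)
            channels[k] = np.clip(img, 0.0, None)

    ground_truth = {"mask": truth_mask, "cells": records}
    return SyntheticScene(
        channels=channels,
        ideal=ideal,
        pixel_size_um=pixel_size_um,
        ground_truth=ground_truth,
        seed=int(seed),
        render_params=rp,
    )


# ---------------------------------------------------------------------------
# population sampling


@dataclass(frozen=True)
class SizeDist:
    """Truncated-normal size distribution (units: um)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        return float(np.clip(self.mean, self.lo, self.hi))


@dataclass(frozen=True)
class PopulationSpec:
    """Describes the population of cells to simulate.

    Defaults emulate a sporulating culture: rods 2-5 um long, 0.8-1 um wide,
    polar septa at an axial fraction drawn uniformly from [0.15, 0.30]
    (asymmetric, sporulation-like placement), reporter restricted to the
    forespore compartment except in a ``mis_fraction`` of cells where it
    fills both compartments (uncompartmentalized activity). ``leak_density``
    is the residual mother-compartment reporter density of properly
    compartmentalized cells.
    """

    n_cells: int = 100
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"compartment_restricted": 1.0}
    )
    length_um: SizeDist = SizeDist(3.2, 0.6, 2.0, 5.0)
    width_um: SizeDist = SizeDist(0.9, 0.05, 0.8, 1.0)
    septum_rule: str = "polar"  # "none" | "polar" | "midcell"
    septum_low: float = 0.15
    septum_high: float = 0.30
    mis_fraction: float = 0.0
    leak_density: float = 0.05
    seed: int = 0
    image_shape: tuple[int, int] | None = None
    margin_px: float = 6.0

    def __post_init__(self):
        tot = sum(self.class_mixture.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"class mixture must sum to 1 (got {tot})")
        if not 0.0 <= self.mis_fraction <= 1.0:
            raise ValueError("mis_fraction must be in [0, 1]")
        if self.septum_rule not in ("none", "polar", "midcell"):
            raise ValueError(f"unknown septum rule {self.septum_rule!r}")


def sample_population(
    spec: PopulationSpec, pixel_size_um: float = 0.065
) -> tuple[list[CellGeometry], "pandas.DataFrame"]:
    """Draw cell geometries and the ground-truth table for a population.

    Cells are laid out on a square grid with a pitch large enough that a
    rod of the maximum length at any orientation stays inside its tile, so
    the population is overlap-free by construction. Returns the geometries
    (placed, ready for :func:`render_scene`) and a truth table with one row
    per cell (label, class, sizes, septum position, mis-compartmentalized
    flag).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    pitch = spec.length_um.hi / pixel_size_um + 2 * spec.margin_px
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    shape_needed = (int(nrow * pitch + 2 * spec.margin_px),
                    int(ncol * pitch + 2 * spec.margin_px))
    if spec.image_shape is not None:
        if spec.image_shape[0] < shape_needed[0] or spec.image_shape[1] < shape_needed[1]:
            raise ValueError(
                f"{n} cells need at least shape {shape_needed}, got {spec.image_shape}"
            )
        shape = spec.image_shape
    else:
        shape = shape_needed

    class_names = sorted(spec.class_mixture)
    probs = np.array([spec.class_mixture[c] for c in class_names])

    cells: list[CellGeometry] = []
    rows = []
    for i in range(n):
        gr, gc = divmod(i, ncol)
        center = (
            spec.margin_px + (gr + 0.5) * pitch + rng.uniform(-2, 2),
            spec.margin_px + (gc + 0.5) * pitch + rng.uniform(-2, 2),
        )
        length = spec.length_um.draw(rng)
        width = spec.width_um.draw(rng)
        angle = rng.uniform(0, np.pi)
        cls = class_names[rng.choice(len(class_names), p=probs)]

        if spec.septum_rule == "none":
            septa: tuple[float, ...] = ()
        elif spec.septum_rule == "polar":
            s = rng.uniform(spec.septum_low, spec.septum_high)
            if rng.random() < 0.5:  # pole choice is random
                s = 1.0 - s
            septa = (round(s, 6),)
        else:  # midcell
            septa = (round(rng.uniform(0.45, 0.55), 6),)

        mis = bool(rng.random() < spec.mis_fraction) if septa else False
        enrichment = None
        if cls == "compartment_restricted" and septa:
            labels = ["forespore", "mother"]
            if mis:
                enrichment = {lab: 1.0 for lab in labels}
            else:
                enrichment = {"forespore": 1.0, "mother": spec.leak_density}
            if min(septa[0], 1 - septa[0]) > POLAR_CUT:  # medial: generic labels
                enrichment = {"comp_0": 1.0, "comp_1": 1.0 if mis else spec.leak_density}
        cell = build_cell(
            length,
            width,
            septa,
            class_label=cls,
            enrichment=enrichment,
            centroid_px=center,
            angle_rad=angle,
            ring_snorm=septa[0] if (cls == "divisome_ring" and septa) else None,
            cap_pole=int(rng.random() < 0.5),
        )
        cells.append(cell)
        rows.append(
            {
                "label": i + 1,
                "class_label": cls,
                "length_um": length,
                "width_um": width,
                "septum_snorm": septa[0] if septa else np.nan,
                "miscompartmentalized": mis,
                "centroid_r": center[0],
                "centroid_c": center[1],
                "angle_rad": angle,
            }
        )

    truth = pd.DataFrame(rows)
    truth.attrs["image_shape"] = shape
    return cells, truth


def simulate_population(
    spec: PopulationSpec,
    render_params: RenderParams = RenderParams(),
    pixel_size_um: float = 0.065,
) -> tuple[SyntheticScene, "pandas.DataFrame"]:
    """Sample a population and render it; the render seed derives from the
    population seed so (spec, render_params) fully determine the scene."""
    cells, truth = sample_population(spec, pixel_size_um)
    shape = truth.attrs["image_shape"]
    scene = render_scene(
        cells,
        render_params=render_params,
        pixel_size_um=pixel_size_um,
        image_shape=shape,
        seed=spec.seed + 1,
    )
    fs = [rec["forespore_fraction"] for rec in scene.ground_truth["cells"]]
    truth = truth.assign(forespore_fraction=fs)
    truth.attrs["image_shape"] = shape
    return scene, truth


def render_ring_frames(
    radii_px: Sequence[float],
    image_shape: tuple[int, int] = (64, 64),
    center: tuple[float, float] | None = None,
    density: float = 1.0,
    thickness_px: float = 2.0,
    psf_sigma_px: float = 1.0,
) -> np.ndarray:
    """Frames of a constricting division ring seen edge-on.

    Each frame shows a vertical bar of half-height ``radii_px[t]`` (the
    projected ring diameter shrinks as the ring constricts), blurred with a
    Gaussian PSF. Used to exercise kymograph extraction on a ring whose
    aperture closes over time, as an FtsZ ring does during septation.
    """
    if center is None:
        center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    frames = []
    for rad in radii_px:
        bar = (np.abs(cc - center[1]) <= thickness_px / 2.0) & (
            np.abs(rr - center[0]) <= rad
        )
        img = density * bar.astype(float)
        if psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, psf_sigma_px)
        frames.append(img)
    return np.stack(frames)


# ---------------------------------------------------------------------------
# I/O: multi-channel TIFF + ground-truth JSON with RLE masks


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    values = flat[starts]
    return {
        "shape": list(mask.shape),
        "starts": starts.tolist(),
        "lengths": lengths.tolist(),
        "values": values.tolist(),
    }


def _rle_decode(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=np.int32)
    for s, ln, v in zip(rle["starts"], rle["lengths"], rle["values"]):
        flat[s : s + ln] = v
    return flat.reshape(shape)


def write_scene(scene: SyntheticScene, path) -> None:
    """Write the observed channels as a multi-page 16-bit TIFF, channel names
    and pixel size in the image description."""
    names = list(scene.channels)
    stack = np.stack([scene.channels[k] for k in names])
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    meta = {"channels": names, "pixel_size_um": scene.pixel_size_um}
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))


def read_scene(path) -> tuple[dict[str, np.ndarray], float]:
    """Read a multi-channel TIFF written by :func:`write_scene` (or any
    C-page stack; channels default to phase/membrane/reporter order)."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or ""
    if stack.ndim == 2:
        stack = stack[None]
    try:
        meta = json.loads(desc)
        names = meta["channels"]
        px = float(meta.get("pixel_size_um", 0.065))
    except (json.JSONDecodeError, KeyError, TypeError):
        names = ["phase", "membrane", "reporter"][: stack.shape[0]]
        px = 0.065
    return {n: stack[i].astype(float) for i, n in enumerate(names)}, px


def _geometry_to_dict(cell: CellGeometry) -> dict:
    d = dataclasses.asdict(cell)
    d["compartment_enrichment"] = dict(cell.compartment_enrichment)
    return d


def write_truth(scene: SyntheticScene, path) -> None:
    cells = [
        {
            "label": rec["label"],
            "forespore_fraction": None
            if np.isnan(rec["forespore_fraction"])
            else rec["forespore_fraction"],
            "geometry": _geometry_to_dict(rec["geometry"]),
        }
        for rec in scene.ground_truth["cells"]
    ]
    payload = {
        "pixel_size_um": scene.pixel_size_um,
        "seed": scene.seed,
        "cells": cells,
        "mask_rle": _rle_encode(scene.ground_truth["mask"]),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["mask"] = _rle_decode(payload.pop("mask_rle"))
    for rec in payload["cells"]:
        g = rec["geometry"]
        g["septa_snorm"] = tuple(g["septa_snorm"])
        g["compartments"] = tuple(tuple(c) for c in g["compartments"])
        g["centroid_px"] = tuple(g["centroid_px"])
        rec["geometry"] = CellGeometry(**g)
        if rec["forespore_fraction"] is None:
            rec["forespore_fraction"] = np.nan
    return payload
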