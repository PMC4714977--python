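"""Cell segmentation and centerline meshing.

Segmentation thresholds a smoothed phase-like channel after subtracting a
scaled membrane channel. The subtraction makes septa — which carry two
apposed, brightly stained membranes — dip below threshold, so cells in a
chain separate into distinct connected components at their shared septum.
The subtraction weight defaults to the value that zeroes the mean septal
score on a noiseless calibration scene (one cell, medial septum).

Meshing fits a straight centerline from the principal axis of the cell's
pixel cloud; this is exact for straight rods and a documented approximation
for bent cells (which this package does not attempt to mesh). Cells touching
the image border are flagged and excluded by default, since their truncated
profiles would bias population averages.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure

from .synthgen import RenderParams, build_cell, render_scene

__all__ = [
    "LabelMask",
    "CellMesh",
    "SegParams",
    "BorderCellError",
    "segment_cells",
    "extract_mesh",
    "extract_meshes",
    "load_masks",
    "write_mask",
    "calibrate_membrane_weight",
    "match_labels",
    "iou_table",
]


class BorderCellError(ValueError):
    """Raised when meshing a cell that touches the image border."""


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    pixel_size_um: float = 0.065

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("label mask must be non-negative")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


@dataclass
class CellMesh:
    """Centerline parameterization of one segmented cell.

    ``centerline_px`` are ordered points along the principal axis;
    ``s_um`` the cumulative axial coordinate (strictly increasing, 0..L);
    ``halfwidth_um`` the local half-width from perpendicular pixel extents.
    ``pole0_px``/``axis`` let any pixel be projected onto the axis:
    u = (p - pole0) . axis, snorm = u / length_px.
    """

    cell_id: int
    centerline_px: np.ndarray
    s_um: np.ndarray
    halfwidth_um: np.ndarray
    outline_px: np.ndarray
    pixels: np.ndarray  # (K, 2) labeled pixel coordinates
    pole0_px: np.ndarray
    axis: np.ndarray
    length_px: float
    pixel_size_um: float
    border: bool = False

    @property
    def length_um(self) -> float:
        return float(self.s_um[-1])

    @property
    def width_um(self) -> float:
        return float(2.0 * np.mean(self.halfwidth_um))

    def axial_fraction(self, pixels: np.ndarray) -> np.ndarray:
        """Project pixel coordinates onto the long axis -> snorm in [0, 1)."""
        rel = np.asarray(pixels, dtype=float) - self.pole0_px
        u = rel @ self.axis
        return np.clip(u / self.length_px, 0.0, np.nextafter(1.0, 0.0))


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters.

    ``membrane_weight`` controls septum splitting: ``None`` uses the
    calibrated weight that zeroes the septal score, so chained cells
    separate into distinct labels at their shared septum (the minicell
    workflow); 0 disables the subtraction, keeping a divided sporangium as
    one cell spanning its polar septum (the sporulation workflow, where the
    profile must cover both compartments).
    """

    smooth_sigma_px: float = 1.0
    membrane_weight: float | None = None  # None -> calibrated default
    threshold_frac: float = 0.3
    min_area_px: int = 40
    max_area_px: int | None = None


@functools.lru_cache(maxsize=8)
def calibrate_membrane_weight(
    render_params: RenderParams = RenderParams(),
    pixel_size_um: float = 0.065,
    smooth_sigma_px: float = 1.0,
) -> float:
    """Subtraction weight that zeroes the septal score.

    Renders a noiseless one-cell calibration scene with a medial septum,
    smooths both channels as :func:`segment_cells` will, and returns the
    weight that drives the septal score (phase - w*membrane) to zero across
    the whole septal band (pixelwise max of phase/membrane over the band,
    with a 5% safety margin), so a septum always becomes a separator.
    """
    rp = RenderParams(
        psf_sigma_um=render_params.psf_sigma_um,
        bg_phase=0.0, bg_membrane=0.0, bg_reporter=0.0,
        photon_scale=None, read_noise=0.0,
        phase_density=render_params.phase_density,
        membrane_density=render_params.membrane_density,
        septum_factor=render_params.septum_factor,
        shell_px=render_params.shell_px,
        septum_px=render_params.septum_px,
    )
    from .synthgen import cell_coordinate_fields

    L, W = 4.0, 0.9
    shape = (96, 96)
    cell = build_cell(L, W, [0.5], centroid_px=(48.0, 48.0))
    scene = render_scene([cell], rp, pixel_size_um, shape, seed=0)
    snorm, _dist, inside = cell_coordinate_fields(cell, shape, pixel_size_um)
    L_px = L / pixel_size_um
    band = inside & (np.abs(snorm - 0.5) * L_px <= rp.septum_px / 2.0)
    ph = ndimage.gaussian_filter(scene.channels["phase"], smooth_sigma_px)
    mem = ndimage.gaussian_filter(scene.channels["membrane"], smooth_sigma_px)
    return float(1.05 * np.max(ph[band] / mem[band]))


def segment_cells(
    phase: np.ndarray,
    membrane: np.ndarray,
    params: SegParams = SegParams(),
    pixel_size_um: float = 0.065,
) -> LabelMask:
    """Threshold smoothed (phase - w*membrane) and label 4-connected cells.

    A blank (featureless) input yields an empty mask rather than an error.
    Components outside [min_area_px, max_area_px] are dropped.
    """
    phase = np.asarray(phase, dtype=float)
    membrane = np.asarray(membrane, dtype=float)
    if phase.shape != membrane.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {membrane.shape}")
    w = params.membrane_weight
    if w is None:
        w = calibrate_membrane_weight(smooth_sigma_px=params.smooth_sigma_px)
    sig = params.smooth_sigma_px
    score = ndimage.gaussian_filter(phase - np.median(phase), sig) - w * ndimage.gaussian_filter(
        membrane - np.median(membrane), sig
    )
    med = np.median(score)
    hi = np.percentile(score, 99.5)
    mad = np.median(np.abs(score - med))
    if hi - med <= 6.0 * mad + 1e-12:  # featureless image
        return LabelMask(np.zeros(phase.shape, dtype=np.int32), pixel_size_um)
    fg = score > med + params.threshold_frac * (hi - med)
    labels, _n = ndimage.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    areas = np.bincount(labels.ravel())
    kill = areas < params.min_area_px
    if params.max_area_px is not None:
        kill |= areas > params.max_area_px
    kill[0] = False
    labels[kill[labels]] = 0
    # relabel consecutively
    ids = np.unique(labels)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(ids.size)
    return LabelMask(remap[labels], pixel_size_um)


def extract_mesh(
    mask: LabelMask,
    cell_id: int,
    pixel_size_um: float | None = None,
    allow_border: bool = False,
    min_area_px: int = 20,
) -> CellMesh:
    """Principal-axis centerline mesh for one labeled cell.

    The centerline runs along the first principal component of the pixel
    cloud, extended to the extreme pixel projections and resampled at 0.5 px
    spacing; half-widths come from the perpendicular pixel extents in axial
    windows. Border-touching cells raise :class:`BorderCellError` unless
    ``allow_border`` is set.
    """
    px = pixel_size_um if pixel_size_um is not None else mask.pixel_size_um
    lab = mask.labels
    coords = np.argwhere(lab == cell_id)
    if coords.size == 0:
        raise ValueError(f"cell_id {cell_id} not present in mask")
    if coords.shape[0] < min_area_px:
        raise ValueError(f"cell {cell_id} area {coords.shape[0]} below min_area_px")
    border = bool(
        coords[:, 0].min() == 0
        or coords[:, 1].min() == 0
        or coords[:, 0].max() == lab.shape[0] - 1
        or coords[:, 1].max() == lab.shape[1] - 1
    )
    if border and not allow_border:
        raise BorderCellError(f"cell {cell_id} touches the image border")

    xy = coords.astype(float)
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    _u_svd, _s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    u = centered @ axis
    v = centered @ vt[1]
    umin, umax = u.min(), u.max()

    pad = np.zeros((lab.shape[0] + 2, lab.shape[1] + 2))
    pad[1:-1, 1:-1] = lab == cell_id
    contours = measure.find_contours(pad, 0.5)
    outline = max(contours, key=len) - 1.0

    # length and pole from the 0.5-level contour of the *smoothed* mask:
    # smoothing suppresses the staircase corners of the binary boundary, so
    # the axial extent varies smoothly with cell orientation
    smooth = ndimage.gaussian_filter(pad, 1.0)
    cont_s = max(measure.find_contours(smooth, 0.5), key=len) - 1.0
    u_out = (cont_s - centroid) @ axis
    length_px = float(u_out.max() - u_out.min())
    pole0 = centroid + u_out.min() * axis

    n_pts = max(int(np.ceil(length_px / 0.5)) + 1, 5)
    s_px = np.linspace(0.0, length_px, n_pts)
    centerline = pole0 + s_px[:, None] * axis[None, :]

    # local half-width from perpendicular extents in axial windows
    nbin = max(int(length_px // 2), 3)
    edges = np.linspace(umin - 0.5, umax + 0.5, nbin + 1)
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, nbin - 1)
    hw_bins = np.full(nbin, np.nan)
    for b in range(nbin):
        sel = idx == b
        if sel.any():
            hw_bins[b] = 0.5 * (v[sel].max() - v[sel].min() + 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:]) - u_out.min()
    good = ~np.isnan(hw_bins)
    halfwidth_px = np.interp(s_px, centers[good], hw_bins[good])

    return CellMesh(
        cell_id=int(cell_id),
        centerline_px=centerline,
        s_um=(s_px + 0.0) * px,
        halfwidth_um=halfwidth_px * px,
        outline_px=outline,
        pixels=coords,
        pole0_px=pole0,
        axis=axis,
        length_px=float(length_px),
        pixel_size_um=px,
        border=border,
    )


def extract_meshes(mask: LabelMask, **kwargs) -> list[CellMesh]:
    """Meshes for all cells; border-touching and tiny cells are skipped."""
    out = []
    for cid in mask.cell_ids:
        try:
            out.append(extract_mesh(mask, int(cid), **kwargs))
        except (BorderCellError, ValueError):
            continue
    return out


def load_masks(path, pixel_size_um: float = 0.065) -> LabelMask:
    """Load an externally produced label mask (integer TIFF or PNG).

    Float-valued files and negative labels are rejected; each label must be
    a single 4-connected component.
    """
    p = str(path)
    if p.lower().endswith(".png"):
        from PIL import Image

        arr = np.asarray(Image.open(p))
    else:
        arr = tifffile.imread(p)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"mask file {p} is not integer-valued (dtype {arr.dtype})")
    mask = LabelMask(arr.astype(np.int32), pixel_size_um)
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for cid in mask.cell_ids:
        _lab, n = ndimage.label(mask.labels == cid, structure=struct)
        if n != 1:
            raise ValueError(f"label {cid} is not a single 4-connected component")
    return mask


def write_mask(mask: LabelMask, path) -> None:
    arr = mask.labels
    dtype = np.uint16 if arr.max() < 2**16 else np.int32
    tifffile.imwrite(path, arr.astype(dtype), photometric="minisblack")


def match_labels(mask: LabelMask, truth_mask: np.ndarray) -> dict[int, int]:
    """Map each recovered cell id to the ground-truth label it overlaps most."""
    out = {}
    for cid in mask.cell_ids:
        sel = mask.labels == cid
        vals = truth_mask[sel]
        vals = vals[vals > 0]
        out[int(cid)] = int(np.bincount(vals).argmax()) if vals.size else 0
    return out


def iou_table(mask: LabelMask, truth_mask: np.ndarray) -> "pandas.DataFrame":
    """Per-recovered-cell IoU against its best-overlap ground-truth cell."""
    import pandas as pd

    rows = []
    mapping = match_labels(mask, truth_mask)
    for cid, tid in mapping.items():
        pred = mask.labels == cid
        if tid == 0:
            rows.append({"cell_id": cid, "truth_label": 0, "iou": 0.0})
            continue
        tru = truth_mask == tid
        inter = np.count_nonzero(pred & tru)
        union = np.count_nonzero(pred | tru)
        rows.append({"cell_id": cid, "truth_label": tid, "iou": inter / union})
    return pd.DataFrame(rows)
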