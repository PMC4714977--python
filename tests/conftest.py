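import numpy as np
import pytest
from hypothesis import settings

from polarprof import synthgen as sg
from polarprof.segment import SegParams, extract_meshes, segment_cells

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# noiseless, no-PSF, zero-background optics: pixel sums are exact
EXACT_RP = sg.RenderParams(
    psf_sigma_um=0.0, bg_phase=0.0, bg_membrane=0.0, bg_reporter=0.0,
    photon_scale=None, read_noise=0.0,
)

PX = 0.065


def render_single(cell, shape=(96, 96), rp=sg.RenderParams(), seed=0):
    return sg.render_scene([cell], rp, PX, shape, seed=seed)


def segment_whole(scene):
    """Sporulation-mode segmentation (no septum splitting) + meshes."""
    mask = segment_cells(
        scene.channels["phase"], scene.channels["membrane"],
        SegParams(membrane_weight=0.0), scene.pixel_size_um,
    )
    return mask, extract_meshes(mask)


@pytest.fixture(scope="session")
def divided_cell_scene():
    """One polar-divided cell, forespore-restricted reporter, noiseless."""
    cell = sg.build_cell(
        3.25, 0.9, [0.2], class_label="compartment_restricted",
        enrichment={"forespore": 1.0, "mother": 0.05},
        centroid_px=(48.0, 48.0), angle_rad=0.4,
    )
    return render_single(cell)


@pytest.fixture(scope="session")
def mixed_population():
    """60-cell noiseless population with 20% planted mis-compartmentalization."""
    spec = sg.PopulationSpec(n_cells=60, mis_fraction=0.2, seed=11)
    return sg.simulate_population(spec)


def brute_force_bins(mesh, image, n_bins, background=0.0):
    """Independent per-pixel oracle for axial binning: explicit loop over the
    cell's labeled pixels, project each onto the centerline, accumulate."""
    sums = np.zeros(n_bins)
    img = np.asarray(image, dtype=float)
    for r, c in mesh.pixels:
        rel = np.array([r, c], dtype=float) - mesh.pole0_px
        u = rel @ mesh.axis
        snorm = min(max(u / mesh.length_px, 0.0), np.nextafter(1.0, 0.0))
        b = min(int(snorm * n_bins), n_bins - 1)
        sums[b] += img[r, c] - background
    return np.clip(sums, 0.0, None)


def grid_fit_decay(t, y, n=400):
    """Grid-search oracle for the exponential-decay fit."""
    slope, logn0 = np.polyfit(t, np.log(y), 1)
    k0 = max(-slope, 1e-4)
    n0s = np.exp(logn0) * np.linspace(0.5, 1.5, n)
    ks = k0 * np.linspace(0.3, 3.0, n)
    sse = np.array([
        [np.sum((n0 * np.exp(-k * t) - y) ** 2) for k in ks] for n0 in n0s
    ])
    i, j = np.unravel_index(sse.argmin(), sse.shape)
    return n0s[i], ks[j], sse[i, j]


def grid_fit_mm(S, v, n=400):
    """Grid-search oracle for the Michaelis-Menten fit."""
    vmaxs = v.max() * np.linspace(0.5, 2.0, n)
    kms = np.geomspace(S.min() / 10, S.max() * 10, n)
    sse = np.array([
        [np.sum((vm * S / (km + S) - v) ** 2) for km in kms] for vm in vmaxs
    ])
    i, j = np.unravel_index(sse.argmin(), sse.shape)
    return vmaxs[i], kms[j], sse[i, j]
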