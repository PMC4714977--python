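"""Long-axis fluorescence profiles, septum detection, orientation, averaging.

The per-cell observable is the ratio of reporter to membrane-stain signal in
axial bins along the cell's long axis. Dividing by the membrane signal
corrects for local membrane area, which matters because septa and pole caps
pack extra membrane into a short axial window; for a membrane-bound reporter
a flat ratio then means uniform coverage per unit membrane. Profiles are
normalized to unit mean over valid bins, making them invariant to per-channel
gain and directly comparable across cells.

Septa are detected as prominent local maxima of the membrane profile inside
an edge-exclusion zone (pole caps are membrane-bright and would otherwise be
called septa). Cells with a single polar septum are flipped so the forespore
pole sits at s = 0, and population-average profiles are built on an absolute
micrometre grid from that aligned pole.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .segment import CellMesh

__all__ = [
    "AxialProfile",
    "SeptumCall",
    "OrientedProfile",
    "PopulationProfile",
    "SeptumParams",
    "axial_profile",
    "estimate_background",
    "detect_septa",
    "orient_and_align",
    "average_profiles",
    "random_pole_profiles",
    "kymograph",
]

DIVISION_STATES = ("predivisional", "polar_divided", "midcell_divided", "multi_septate")


@dataclass
class AxialProfile:
    """Binned reporter/membrane profile of one cell.

    Bins are half-open intervals [i/n, (i+1)/n) in the axial fraction snorm.
    ``ratio`` is reporter/membrane per bin, normalized to unit mean over
    valid bins (NaN where the membrane signal is ~0). ``usable`` is False
    when more than 25% of bins lack membrane signal.
    """

    cell_id: int
    n_bins: int
    reporter: np.ndarray
    membrane: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    length_um: float
    usable: bool = True
    norm_mode: str = "unit_mean"

    @property
    def edges_snorm(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def centers_snorm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def flipped(self) -> "AxialProfile":
        return replace(
            self,
            reporter=self.reporter[::-1].copy(),
            membrane=self.membrane[::-1].copy(),
            ratio=self.ratio[::-1].copy(),
            valid=self.valid[::-1].copy(),
        )


@dataclass(frozen=True)
class SeptumCall:
    position_snorm: float
    prominence: float
    polar: bool


@dataclass
class OrientedProfile:
    """Axial profile after orientation; if oriented, the forespore pole is at
    s = 0 and a polar septum (if any) lies at snorm <= 0.5."""

    profile: AxialProfile
    division_state: str
    septum_snorm: float | None = None
    septa: tuple[SeptumCall, ...] = ()
    flipped: bool = False
    oriented: bool = True

    @property
    def forespore_interval(self) -> tuple[float, float]:
        if self.division_state == "predivisional" or self.septum_snorm is None:
            raise ValueError(
                "forespore quantities are undefined for a predivisional cell"
            )
        return (0.0, float(self.septum_snorm))


@dataclass
class PopulationProfile:
    """Mean +/- SEM ratio versus absolute distance from the aligned pole."""

    grid_um: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    min_n: int = 1


def estimate_background(image: np.ndarray, labels: np.ndarray, n_sigma: float = 3.0) -> float:
    """Per-channel background: sigma-clipped mean of non-cell pixels.

    A clipped mean rather than the histogram mode: photon-counting images at
    low flux are discrete, where the mode collapses to 0 while the mean stays
    unbiased; the clip guards against stray cell signal in the background.
    """
    bg = np.asarray(image, dtype=float)[np.asarray(labels) == 0]
    if bg.size == 0:
        return 0.0
    mu, sd = bg.mean(), bg.std()
    if sd > 0:
        sel = np.abs(bg - mu) <= n_sigma * sd
        if sel.any():
            mu = bg[sel].mean()
    return float(mu)


def axial_profile(
    mesh: CellMesh,
    reporter: np.ndarray,
    membrane: np.ndarray,
    n_bins: int = 50,
    background: tuple[float, float] = (0.0, 0.0),
    eps: float = 1e-9,
    max_invalid_frac: float = 0.25,
) -> AxialProfile:
    """Bin background-subtracted reporter and membrane sums along the axis.

    Every labeled pixel is assigned to the bin of its projected axial
    fraction; per-pixel background (reporter, membrane) is subtracted before
    summing and the per-bin sums are floored at zero (flooring per pixel
    would rectify noise and bias dim regions upward). The ratio is computed
    per bin where the membrane sum exceeds ``eps`` and normalized to unit
    mean over valid bins.

    ``n_bins`` is a ceiling: a cell shorter than ``n_bins`` pixels is binned
    at ~1 bin per pixel of length (never fewer than 11), since finer bins
    would be empty and alias the profile. The effective count is forced odd:
    a symmetric rod always has a pixel projecting exactly onto the cell
    center, which with an even bin count sits on a bin edge and makes the
    binning chirality-dependent (left-right mirroring would move that pixel
    across the edge); an odd count puts the symmetry center mid-bin.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    n_bins = min(n_bins, max(11, int(np.floor(mesh.length_px))))
    if n_bins % 2 == 0:
        n_bins -= 1
    bg_rep, bg_mem = background
    if bg_rep < 0 or bg_mem < 0:
        raise ValueError("background offsets must be >= 0")
    pix = mesh.pixels
    snorm = mesh.axial_fraction(pix)
    bins = np.minimum((snorm * n_bins).astype(int), n_bins - 1)
    rep = np.asarray(reporter, dtype=float)[pix[:, 0], pix[:, 1]] - bg_rep
    mem = np.asarray(membrane, dtype=float)[pix[:, 0], pix[:, 1]] - bg_mem
    rep_bins = np.clip(np.bincount(bins, weights=rep, minlength=n_bins), 0.0, None)
    mem_bins = np.clip(np.bincount(bins, weights=mem, minlength=n_bins), 0.0, None)
    valid = mem_bins > eps
    ratio = np.full(n_bins, np.nan)
    usable = valid.mean() >= 1.0 - max_invalid_frac
    if valid.any():
        raw = rep_bins[valid] / mem_bins[valid]
        m = raw.mean()
        if m > 0:
            ratio[valid] = raw / m
        else:
            ratio[valid] = 0.0
    else:
        usable = False
    return AxialProfile(
        cell_id=mesh.cell_id,
        n_bins=n_bins,
        reporter=rep_bins,
        membrane=mem_bins,
        ratio=ratio,
        valid=valid,
        length_um=mesh.length_um,
        usable=usable,
    )


@dataclass(frozen=True)
class SeptumParams:
    edge_excl: float = 0.1       # fraction of the axis excluded at each pole
    prominence_alpha: float = 1.5  # x median interior membrane density
    polar_cut: float = 0.3
    smooth_bins: float = 1.0     # Gaussian sigma (bins) applied before peak finding


def detect_septa(profile: AxialProfile, params: SeptumParams = SeptumParams()) -> list[SeptumCall]:
    """Septa = prominent membrane-profile maxima away from the poles.

    Peaks are sought in the per-bin membrane density for bins whose centers
    lie in [edge_excl, 1-edge_excl]; the prominence floor is
    ``prominence_alpha`` times the median interior density. The profile is
    lightly smoothed first (``smooth_bins``) to suppress pixel-to-bin
    aliasing of the membrane shell. Calls are sorted by position. Returns an
    empty list when no septum is present.
    """
    centers = profile.centers_snorm
    interior = (centers >= params.edge_excl) & (centers <= 1.0 - params.edge_excl)
    dens = profile.membrane.astype(float)
    if (~profile.valid).any() and profile.valid.sum() >= 2:
        # fill empty bins by interpolation so gaps do not masquerade as peaks
        dens = np.interp(centers, centers[profile.valid], dens[profile.valid])
    if params.smooth_bins > 0:
        dens = ndimage.gaussian_filter1d(dens, params.smooth_bins)
    if not interior.any():
        return []
    med = np.median(dens[interior])
    if med <= 0:
        med = np.median(dens[dens > 0]) if (dens > 0).any() else 1.0
    # pad so a peak at the interior edge is still detectable
    y = dens.copy()
    y[~interior] = dens[interior].min()
    peaks, props = signal.find_peaks(y, prominence=params.prominence_alpha * med)
    calls = []
    for p, prom in zip(peaks, props["prominences"]):
        if not interior[p]:
            continue
        s = float(centers[p])
        calls.append(
            SeptumCall(
                position_snorm=s,
                prominence=float(prom),
                polar=min(s, 1.0 - s) <= params.polar_cut,
            )
        )
    calls.sort(key=lambda c: c.position_snorm)
    return calls


def _flip_call(c: SeptumCall) -> SeptumCall:
    return SeptumCall(1.0 - c.position_snorm, c.prominence, c.polar)


def orient_and_align(
    profile: AxialProfile | OrientedProfile,
    septa: list[SeptumCall] | None = None,
    pole: int | None = None,
    polar_cut: float = 0.3,
) -> OrientedProfile:
    """Flip the profile so the forespore pole is at s = 0.

    One polar septum: the cell is ``polar_divided`` and flipped (if needed)
    so the septum sits at snorm <= 0.5; the forespore is [0, septum]. One
    medial septum (snorm in (polar_cut, 1-polar_cut)): ``midcell_divided``,
    oriented the same way (smaller compartment at the origin) so that a
    septum detected just past the polar cut keeps a meaningful density
    ratio. Two or more septa: ``multi_septate``, oriented to the most
    polar septum (prominence ties break toward the more polar candidate).
    No septum: ``predivisional``; orientation is set only when the caller
    supplies a ``pole`` (0 keeps the current direction, 1 flips).
    Orienting an already oriented profile is the identity.
    """
    if isinstance(profile, OrientedProfile):
        return profile
    septa = list(septa) if septa is not None else []

    if not septa:
        if pole is None:
            return OrientedProfile(profile, "predivisional", oriented=False)
        prof = profile.flipped() if pole == 1 else profile
        return OrientedProfile(prof, "predivisional", flipped=pole == 1, oriented=True)

    if len(septa) == 1:
        s = septa[0].position_snorm
        state = "polar_divided" if min(s, 1 - s) <= polar_cut else "midcell_divided"
        anchor = septa[0]
    else:
        state = "multi_septate"
        # most polar septum; break prominence ties toward the pole
        anchor = min(septa, key=lambda c: (min(c.position_snorm, 1 - c.position_snorm),
                                           -c.prominence))
    flip = anchor.position_snorm > 0.5
    prof = profile.flipped() if flip else profile
    calls = tuple(sorted(
        (_flip_call(c) if flip else c for c in septa), key=lambda c: c.position_snorm
    ))
    sep = (1.0 - anchor.position_snorm) if flip else anchor.position_snorm
    return OrientedProfile(
        prof, state, septum_snorm=float(sep), septa=calls, flipped=flip, oriented=True
    )


def average_profiles(
    oriented: list[OrientedProfile],
    spacing_um: float = 0.065,
    window_um: float = 3.0,
    min_n: int = 1,
) -> PopulationProfile:
    """Population mean +/- SEM on an absolute-um grid from the aligned pole.

    Each cell's unit-mean ratio is linearly interpolated from its bin
    centers onto the grid, out to its own length only; grid points supported
    by fewer than ``min_n`` cells are masked (NaN).
    """
    if not oriented:
        raise ValueError("average_profiles needs at least one profile")
    grid = np.arange(0.0, window_um + spacing_um / 2, spacing_um)
    rows = []
    for op in oriented:
        if not op.oriented:
            raise ValueError("all profiles must be oriented before averaging")
        p = op.profile
        if not p.usable:
            continue
        x = p.centers_snorm * p.length_um
        ok = p.valid & np.isfinite(p.ratio)
        if ok.sum() < 2:
            continue
        vals = np.interp(grid, x[ok], p.ratio[ok])
        vals[grid > p.length_um] = np.nan
        rows.append(vals)
    mean = np.full_like(grid, np.nan)
    sem = np.full_like(grid, np.nan)
    n = np.zeros_like(grid, dtype=int)
    if rows:
        mat = np.vstack(rows)
        n = np.sum(~np.isnan(mat), axis=0)
        has = n >= max(min_n, 1)
        mean[has] = np.nanmean(mat[:, has], axis=0)
        sem[has] = 0.0
        multi = has & (n > 1)
        if multi.any():
            sd = np.nanstd(mat[:, multi], axis=0, ddof=1)
            sem[multi] = sd / np.sqrt(n[multi])
    return PopulationProfile(grid_um=grid, mean=mean, sem=sem, n=n, min_n=min_n)


def random_pole_profiles(
    profiles: list[AxialProfile],
    n_poles: int,
    seed: int,
    spacing_um: float = 0.065,
    window_um: float = 3.0,
    min_n: int = 1,
) -> tuple[PopulationProfile, list[tuple[int, int]]]:
    """Average profiles of undivided cells aligned at randomly chosen poles.

    Samples ``n_poles`` (cell, pole) pairs without replacement (each cell
    contributes up to two poles) with a seeded generator, orients each cell
    at its sampled pole, and averages. Mirrors the control analysis of
    pole-localization claims, where no septum defines an orientation.
    """
    pairs = [(i, p) for i in range(len(profiles)) for p in (0, 1)]
    if n_poles > len(pairs):
        raise ValueError(f"n_poles={n_poles} exceeds available poles {len(pairs)}")
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(pairs), size=n_poles, replace=False)
    chosen = [pairs[i] for i in chosen_idx]
    oriented = [
        orient_and_align(profiles[i], septa=[], pole=p) for (i, p) in chosen
    ]
    pop = average_profiles(oriented, spacing_um, window_um, min_n)
    return pop, chosen


def kymograph(
    frames: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    n_samples: int | None = None,
    order: int = 1,
) -> np.ndarray:
    """Sample intensity along a line in every frame -> (time x position).

    ``frames`` is a (T, H, W) stack (T >= 2); ``line`` the (row, col)
    endpoints. Intensities are linearly interpolated at ``n_samples`` evenly
    spaced points (default: ceil(line length) + 1).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("kymograph needs a (T, H, W) stack with T >= 2")
    (r0, c0), (r1, c1) = line
    H, W = frames.shape[1:]
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= H - 1 and 0 <= c <= W - 1):
            raise ValueError(f"line endpoint {(r, c)} outside image {frames.shape[1:]}")
    if n_samples is None:
        n_samples = int(np.ceil(np.hypot(r1 - r0, c1 - c0))) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    rr = r0 + t * (r1 - r0)
    cc = c0 + t * (c1 - c0)
    out = np.empty((frames.shape[0], n_samples))
    for i in range(frames.shape[0]):
        out[i] = ndimage.map_coordinates(frames[i], [rr, cc], order=order, mode="nearest")
    return out
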