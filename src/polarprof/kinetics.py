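"""Curve fitting for protein-turnover and phosphatase kinetics.

Two models, both fit by unweighted nonlinear least squares on the linear
scale (scipy's Levenberg-Marquardt / trust-region via ``curve_fit``):

- single-exponential decay N(t) = N0 * exp(-k t) for translation-shutoff
  chase experiments; t1/2 = ln2 / k. Started from a log-linear regression.
  A fitted rate k <= 0 is reported as "stable" (no finite half-life), the
  behaviour of a substrate whose protease is absent.
- Michaelis-Menten v = Vmax * S / (Km + S) for multiple-turnover phosphatase
  assays; velocities are per-enzyme turnover rates (min^-1). Started from
  Vmax ~= max(v) and Km ~= the substrate concentration at half-max by
  interpolation. When all S >> Km the fit pins Vmax but Km is weakly
  identified and flagged.

Western-blot style level normalization divides each band by its loading
control and rescales so the reference lane equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "DecayFit",
    "MMDataset",
    "MMFit",
    "fit_exponential_decay",
    "fit_michaelis_menten",
    "normalize_levels",
]

_K_STABLE = 1e-9  # min^-1; fitted rates at or below this are "stable"


@dataclass(frozen=True)
class DecaySeries:
    """Chase time course: times in minutes, levels in arbitrary units > 0."""

    times_min: np.ndarray
    levels: np.ndarray
    loading: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "levels", y)
        if t.shape != y.shape or t.size < 3:
            raise ValueError("need matching times/levels with >= 3 points")
        if (np.diff(t) <= 0).any() or (t < 0).any():
            raise ValueError("times must be >= 0 and strictly increasing")
        if (y <= 0).any():
            raise ValueError("levels must be positive")
        if self.loading is not None:
            ld = np.asarray(self.loading, dtype=float)
            object.__setattr__(self, "loading", ld)
            if ld.shape != y.shape or (ld <= 0).any():
                raise ValueError("loading controls must be positive and aligned")


@dataclass
class DecayFit:
    n0: float
    k_per_min: float
    t_half_min: float  # inf when stable
    sse: float
    converged: bool
    stable: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.n0 * np.exp(-self.k_per_min * np.asarray(t, dtype=float))


def _exp_model(t, n0, k):
    return n0 * np.exp(-k * t)


def fit_exponential_decay(series: DecaySeries) -> DecayFit:
    """Least-squares single-exponential fit; t1/2 = ln2 / k.

    Loading-normalized levels are used when a loading control is present.
    """
    t = series.times_min
    y = series.levels if series.loading is None else series.levels / series.loading
    slope, logn0 = np.polyfit(t, np.log(y), 1)
    p0 = (float(np.exp(logn0)), max(-slope, _K_STABLE))
    try:
        popt, _ = curve_fit(_exp_model, t, y, p0=p0, maxfev=10000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    n0, k = float(popt[0]), float(popt[1])
    sse = float(np.sum((_exp_model(t, n0, k) - y) ** 2))
    stable = k <= _K_STABLE
    t_half = np.inf if stable else float(np.log(2.0) / k)
    return DecayFit(n0=n0, k_per_min=k, t_half_min=t_half, sse=sse,
                    converged=converged, stable=stable)


@dataclass(frozen=True)
class MMDataset:
    """Substrate concentrations (uM, > 0) and per-enzyme velocities (min^-1)."""

    substrate_uM: np.ndarray
    velocity_per_min: np.ndarray
    enzyme_uM: float = 0.05

    def __post_init__(self):
        S = np.asarray(self.substrate_uM, dtype=float)
        v = np.asarray(self.velocity_per_min, dtype=float)
        object.__setattr__(self, "substrate_uM", S)
        object.__setattr__(self, "velocity_per_min", v)
        if S.shape != v.shape or S.size < 4:
            raise ValueError("need matching S/v with >= 4 points")
        if (S <= 0).any():
            raise ValueError("substrate concentrations must be > 0")


@dataclass
class MMFit:
    vmax_per_min: float
    km_uM: float
    sse: float
    converged: bool
    km_weakly_identified: bool
    vmax_se: float | None = None
    km_se: float | None = None

    def predict(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.vmax_per_min * S / (self.km_uM + S)


def _mm_model(S, vmax, km):
    return vmax * S / (km + S)


def _mm_initial_guess(S, v):
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    order = np.argsort(S)
    Ss, vs = S[order], v[order]
    above = np.flatnonzero(vs >= half)
    if above.size and above[0] > 0:
        i = above[0]
        f = (half - vs[i - 1]) / (vs[i] - vs[i - 1])
        km0 = float(Ss[i - 1] + f * (Ss[i] - Ss[i - 1]))
    else:
        km0 = float(Ss[0])
    return vmax0, max(km0, 1e-6)


def fit_michaelis_menten(
    data: MMDataset, bootstrap: int = 0, seed: int = 0
) -> MMFit:
    """Least-squares Michaelis-Menten fit with optional bootstrap SEs.

    Raises when the velocities are constant (Km unidentifiable). Bootstrap
    standard errors resample data points with replacement (seeded).
    """
    S, v = data.substrate_uM, data.velocity_per_min
    if np.ptp(v) <= 1e-12 * max(abs(v).max(), 1.0):
        raise ValueError("velocities are constant: Km is unidentifiable")
    p0 = _mm_initial_guess(S, v)
    try:
        popt, _ = curve_fit(_mm_model, S, v, p0=p0,
                            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    vmax, km = float(popt[0]), float(popt[1])
    sse = float(np.sum((_mm_model(S, vmax, km) - v) ** 2))
    weak = bool(km < S.min() / 5.0 or km > S.max() * 5.0)
    fit = MMFit(vmax_per_min=vmax, km_uM=km, sse=sse, converged=converged,
                km_weakly_identified=weak)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        vs, ks = [], []
        for _ in range(bootstrap):
            idx = rng.integers(0, S.size, S.size)
            try:
                pb, _ = curve_fit(_mm_model, S[idx], v[idx], p0=(vmax, km),
                                  bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=5000)
                vs.append(pb[0])
                ks.append(pb[1])
            except RuntimeError:
                continue
        if len(vs) >= 2:
            fit.vmax_se = float(np.std(vs, ddof=1))
            fit.km_se = float(np.std(ks, ddof=1))
    return fit


def normalize_levels(
    bands: np.ndarray, loading: np.ndarray | None = None, reference_index: int = 0
) -> np.ndarray:
    """Loading-corrected levels relative to a reference lane.

    out_i = (band_i / loading_i) / (band_ref / loading_ref); out_ref == 1.
    """
    b = np.asarray(bands, dtype=float)
    ld = np.ones_like(b) if loading is None else np.asarray(loading, dtype=float)
    if b.shape != ld.shape:
        raise ValueError("bands and loading must have equal length")
    if (ld <= 0).any():
        raise ValueError("loading controls must be > 0")
    if not 0 <= reference_index < b.size:
        raise ValueError("reference_index out of range")
    if b[reference_index] <= 0:
        raise ValueError("reference band must be > 0")
    corr = b / ld
    return corr / corr[reference_index]
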