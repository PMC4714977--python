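"""Population statistics: sigma-F compartmentalization calls, enrichment rule.

Two classifiers operate on the per-cell quantities produced upstream:

1. sigma-F activity compartmentalization. For a polar-divided cell the share
   of background-subtracted reporter in the forespore (f_fs) and the ratio of
   per-unit-length densities between forespore and mother (rho) are computed
   from the oriented axial profile. Explicit thresholds replace the original
   by-eye scoring: rho >= 2 is forespore-specific, rho <= 0.5 mother-cell,
   anything in between "both"; cells with total signal below ``activity_min``
   are inactive. Predivisional cells get predivisional_active/inactive.

2. Enrichment rule for rare bright cells (minicell experiments): a cell is
   flagged when its mean reporter intensity exceeds the population mean by
   more than two population standard deviations (single pass, divisor n, no
   outlier trimming).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axialprofile import OrientedProfile

__all__ = [
    "CATEGORIES",
    "ActivityThresholds",
    "CompartmentCall",
    "EnrichmentResult",
    "compartment_fractions",
    "call_sigmaF_activity",
    "activity_threshold_from_controls",
    "enrichment_calls",
    "summarize_population",
]

CATEGORIES = (
    "forespore_specific",
    "mother_cell",
    "both",
    "inactive",
    "predivisional_active",
    "predivisional_inactive",
)


@dataclass
class CompartmentCall:
    """Per-cell compartmentalization measurements (category filled by
    :func:`call_sigmaF_activity`)."""

    cell_id: int
    f_fs: float
    rho: float
    total: float
    division_state: str
    septum_snorm: float | None
    length_um: float
    category: str | None = None


@dataclass(frozen=True)
class ActivityThresholds:
    activity_min: float = 0.0
    rho_hi: float = 2.0
    rho_lo: float = 0.5

    def __post_init__(self):
        if self.rho_lo >= self.rho_hi:
            raise ValueError("need rho_lo < rho_hi")
        if self.rho_lo <= 0 or self.activity_min < 0:
            raise ValueError("thresholds must be positive")


def compartment_fractions(op: OrientedProfile) -> CompartmentCall:
    """Forespore reporter fraction and density ratio from an oriented profile.

    f_fs = sum of reporter bins with center < septum / sum over all bins;
    rho = (forespore sum / septum) / (mother sum / (1 - septum)), i.e. the
    ratio of per-unit-length densities (infinite when the mother density is
    zero). For cells without a polar septum f_fs and rho are NaN and only the
    total is reported.
    """
    p = op.profile
    total = float(p.reporter.sum())
    if op.division_state == "predivisional" or op.septum_snorm is None:
        return CompartmentCall(
            cell_id=p.cell_id, f_fs=np.nan, rho=np.nan, total=total,
            division_state=op.division_state, septum_snorm=None,
            length_um=p.length_um,
        )
    s = float(op.septum_snorm)
    fs_sel = p.centers_snorm < s
    fs_sum = float(p.reporter[fs_sel].sum())
    mo_sum = total - fs_sum
    if total <= 0:
        f_fs, rho = np.nan, np.nan
    else:
        f_fs = fs_sum / total
        d_fs = fs_sum / s
        d_mo = mo_sum / (1.0 - s)
        rho = np.inf if d_mo == 0 else d_fs / d_mo
    return CompartmentCall(
        cell_id=p.cell_id, f_fs=f_fs, rho=rho, total=total,
        division_state=op.division_state, septum_snorm=s, length_um=p.length_um,
    )


def call_sigmaF_activity(
    call: CompartmentCall, thresholds: ActivityThresholds = ActivityThresholds()
) -> str:
    """Assign the compartmentalization category and store it on the call."""
    th = thresholds
    if call.division_state == "predivisional" or call.septum_snorm is None:
        cat = "predivisional_active" if call.total > th.activity_min else "predivisional_inactive"
    elif call.total <= th.activity_min or not np.isfinite(call.f_fs):
        cat = "inactive"
    elif call.rho >= th.rho_hi:
        cat = "forespore_specific"
    elif call.rho <= th.rho_lo:
        cat = "mother_cell"
    else:
        cat = "both"
    call.category = cat
    return cat


def activity_threshold_from_controls(totals: np.ndarray, q: float = 99.0) -> float:
    """activity_min from an inactive control population: its q-th percentile."""
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        return 0.0
    return float(np.percentile(totals, q))


@dataclass
class EnrichmentResult:
    """Mean+2SD enrichment flags over a cell population.

    mu and sigma are computed over all cells (population SD, divisor n);
    flag_k is the strict inequality I_k > mu + 2*sigma.
    """

    intensities: np.ndarray
    lengths_um: np.ndarray | None
    mu: float
    sigma: float
    threshold: float
    flags: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def enrichment_calls(
    intensities: np.ndarray, lengths_um: np.ndarray | None = None, n_sd: float = 2.0
) -> EnrichmentResult:
    """Flag cells whose mean intensity exceeds mu + n_sd * sigma (strict)."""
    I = np.asarray(intensities, dtype=float)
    if I.size < 2:
        raise ValueError("enrichment rule needs at least 2 cells")
    if (I < 0).any():
        raise ValueError("intensities must be >= 0")
    if lengths_um is not None:
        lengths_um = np.asarray(lengths_um, dtype=float)
        if lengths_um.shape != I.shape:
            raise ValueError("lengths and intensities must align")
    mu = float(I.mean())
    sigma = float(I.std(ddof=0))
    thr = mu + n_sd * sigma
    return EnrichmentResult(
        intensities=I, lengths_um=lengths_um, mu=mu, sigma=sigma,
        threshold=thr, flags=I > thr,
    )


def summarize_population(
    calls: list[CompartmentCall],
    enrichment: EnrichmentResult | None = None,
    truth_categories: list[str] | None = None,
) -> dict:
    """Counts/percentages per category plus optional enrichment-by-length and
    confusion-matrix summaries.

    The headline rate ``miscompartmentalized_pct`` is the percentage of
    divided, active cells whose activity is NOT forespore-specific (i.e.
    categories 'both' or 'mother_cell').
    """
    if not calls:
        raise ValueError("summarize_population needs at least one call")
    if any(c.category is None for c in calls):
        raise ValueError("calls must be categorized first (call_sigmaF_activity)")
    cats = pd.Series([c.category for c in calls])
    counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
    pct = 100.0 * counts / counts.sum()
    table = pd.DataFrame({"count": counts, "percent": pct})

    divided_active = counts[["forespore_specific", "mother_cell", "both"]].sum()
    mis = counts[["mother_cell", "both"]].sum()
    out = {
        "categories": table,
        "n_cells": int(counts.sum()),
        "n_divided_active": int(divided_active),
        "miscompartmentalized_pct": float(100.0 * mis / divided_active)
        if divided_active > 0
        else np.nan,
    }

    if enrichment is not None:
        out["n_flagged"] = enrichment.n_flagged
        out["enriched_pct"] = 100.0 * enrichment.n_flagged / enrichment.flags.size
        if enrichment.lengths_um is not None and enrichment.n_flagged > 0:
            out["median_length_flagged_um"] = float(
                np.median(enrichment.lengths_um[enrichment.flags])
            )
            out["median_length_unflagged_um"] = float(
                np.median(enrichment.lengths_um[~enrichment.flags])
            )

    if truth_categories is not None:
        if len(truth_categories) != len(calls):
            raise ValueError("truth_categories must align with calls")
        conf = pd.crosstab(
            pd.Series(truth_categories, name="truth"),
            pd.Series([c.category for c in calls], name="called"),
        )
        out["confusion"] = conf
        agree = sum(t == c.category for t, c in zip(truth_categories, calls))
        out["category_accuracy"] = agree / len(calls)
    return out
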