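"""Evaluation metrics: diode-band deviation statistics, DVH coverage,
gamma analysis and Gy-to-percent conversion.

Measured-vs-planned and measured-vs-live-calculated deviations are
summarized by the standard deviation (sigma, sample n-1 denominator) and
the mean absolute difference (MAD) over the diodes receiving between 60%
and 85% of the maximum planned dose — the high-gradient band that is
most sensitive to motion.  Coverage is V95%: the percentage of target
voxels at or above 95% of the prescription.  Gamma analysis uses global
normalization and a minimum dose threshold (default 5% of the reference
maximum) with 2%/2mm criteria by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Volume


# ---------------------------------------------------------------------------
# diode band and deviation statistics
# ---------------------------------------------------------------------------


def select_diodes(
    planned_dose: np.ndarray, lo: float = 0.60, hi: float = 0.85
) -> np.ndarray:
    """Indices of diodes receiving [lo, hi] of the maximum planned dose
    (inclusive bounds; maximum taken over the full-fraction planned
    diode doses)."""
    d = np.asarray(planned_dose, dtype=float)
    if d.size == 0:
        raise ValueError("empty diode dose vector")
    dmax = d.max()
    if dmax <= 0:
        warnings.warn("all-zero planned diode doses; empty selection")
        return np.array([], dtype=int)
    frac = d / dmax
    return np.nonzero((frac >= lo - 1e-12) & (frac <= hi + 1e-12))[0]


def deviation_stats(
    measured: np.ndarray, reference: np.ndarray, selection: np.ndarray
) -> tuple[float, float]:
    """(sigma, MAD) of measured - reference over the selected diodes.

    sigma is the sample standard deviation (n-1 denominator) and is
    undefined for fewer than two selected diodes (raises).
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape:
        raise ValueError("measured and reference must have equal length")
    sel = np.asarray(selection, dtype=int)
    if sel.size < 2:
        raise ValueError("sigma needs at least two selected diodes")
    d = measured[sel] - reference[sel]
    return float(np.std(d, ddof=1)), float(np.mean(np.abs(d)))


@dataclass
class DeviationSeries:
    """sigma/MAD of measured-vs-planned (P) and measured-vs-calculated
    (C) cumulative doses, indexed by delivered MU."""

    table: pd.DataFrame  # columns: mu, sigma_p, mad_p, sigma_c, mad_c

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def deviation_series(
    measured_cum: np.ndarray,
    planned_cum: np.ndarray,
    calculated_cum: np.ndarray,
    mu_axis: np.ndarray,
    selection: np.ndarray,
) -> DeviationSeries:
    """Deviation statistics at every evaluation point.

    All inputs are cumulative diode doses with shape
    ``(n_points, n_diodes)`` on a shared, non-decreasing MU axis; the
    statistics at each point use the doses accumulated up to that MU.
    """
    arrays = [np.asarray(a, dtype=float) for a in (measured_cum, planned_cum, calculated_cum)]
    mu_axis = np.asarray(mu_axis, dtype=float)
    if not all(a.shape == arrays[0].shape for a in arrays) or len(mu_axis) != len(arrays[0]):
        raise ValueError("misaligned MU axes or diode counts")
    if np.any(np.diff(mu_axis) < -1e-9):
        raise ValueError("MU axis must be non-decreasing")
    rows = []
    for k in range(len(mu_axis)):
        sp, mp = deviation_stats(arrays[0][k], arrays[1][k], selection)
        sc, mc = deviation_stats(arrays[0][k], arrays[2][k], selection)
        rows.append((mu_axis[k], sp, mp, sc, mc))
    return DeviationSeries(
        pd.DataFrame(rows, columns=["mu", "sigma_p", "mad_p", "sigma_c", "mad_c"])
    )


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def v_threshold(
    dose: Volume | np.ndarray,
    mask: np.ndarray,
    prescription_gy: float,
    fraction: float = 0.95,
) -> float:
    """Percent of the masked volume receiving >= fraction * prescription."""
    values = dose.values if isinstance(dose, Volume) else np.asarray(dose)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty structure mask")
    return 100.0 * float(np.sum(values[mask] >= fraction * prescription_gy)) / n


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------


@dataclass
class GammaResult:
    gamma_map: np.ndarray          # NaN where below the dose threshold
    pass_rate_pct: float
    dd_percent: float
    dta_mm: float
    low_threshold: float
    norm_dose: float
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "pass_rate_pct": self.pass_rate_pct,
            "dd_percent": self.dd_percent,
            "dta_mm": self.dta_mm,
            "low_threshold": self.low_threshold,
            "norm_dose": self.norm_dose,
            "n_evaluated": self.n_evaluated,
            "max_gamma": float(np.nanmax(self.gamma_map))
            if self.n_evaluated
            else float("nan"),
        }


def _search_offsets(ndim: int, dta_mm: float, radius_factor: float,
                    step_fraction: float) -> np.ndarray:
    step = dta_mm * step_fraction
    radius = dta_mm * radius_factor
    n = int(np.floor(radius / step))
    axes = [np.arange(-n, n + 1) * step] * ndim
    grids = np.meshgrid(*axes, indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    dist2 = np.sum(offs**2, axis=1)
    offs = offs[dist2 <= radius**2 + 1e-9]
    order = np.argsort(np.sum(offs**2, axis=1), kind="stable")
    return offs[order]


def gamma(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing_mm,
    dd_percent: float = 2.0,
    dta_mm: float = 2.0,
    low_threshold: float = 0.05,
    norm_dose: float | None = None,
    radius_factor: float = 3.0,
    step_fraction: float = 0.1,
) -> GammaResult:
    """Global-normalization gamma index between two dose distributions.

    ``gamma(r) = min_{r'} sqrt(|r - r'|^2 / dta^2 +
    (D_e(r') - D_r(r))^2 / (dd * D_norm)^2)`` with ``D_norm`` the
    reference maximum unless ``norm_dose`` overrides it.  Points with
    reference dose below ``low_threshold * D_norm`` are excluded.  The
    minimization searches a lattice of ``dta * step_fraction`` steps out
    to ``dta * radius_factor``, interpolating the evaluated dose
    linearly, and prunes points whose running minimum already beats the
    remaining distance term.  Works for 2-D and 3-D distributions on a
    common grid.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("reference and evaluated must share a grid")
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing.size == 1:
        spacing = np.full(ref.ndim, spacing[0])
    if spacing.size != ref.ndim:
        raise ValueError("spacing must match dimensionality")

    dnorm = float(ref.max()) if norm_dose is None else float(norm_dose)
    if dnorm <= 0:
        raise ValueError("non-positive normalization dose")
    mask = ref >= low_threshold * dnorm
    if not np.any(mask):
        raise ValueError("all points below the low-dose threshold")

    dd_abs = dd_percent / 100.0 * dnorm
    pts_idx = np.argwhere(mask).astype(float)              # (P, ndim) voxel idx
    ref_vals = ref[mask]
    offsets = _search_offsets(ref.ndim, dta_mm, radius_factor, step_fraction)

    best = np.full(len(pts_idx), np.inf)
    active = np.ones(len(pts_idx), dtype=bool)
    for off in offsets:
        dist2 = float(np.sum(off**2)) / dta_mm**2
        np.less(dist2, best, out=active)                   # still improvable
        if not active.any():
            break
        coords = (pts_idx[active] + off / spacing).T
        ev_vals = ndimage.map_coordinates(ev, coords, order=1, mode="nearest")
        cand = dist2 + ((ev_vals - ref_vals[active]) / dd_abs) ** 2
        best[active] = np.minimum(best[active], cand)

    gmap = np.full(ref.shape, np.nan)
    gmap[mask] = np.sqrt(best)
    pass_rate = 100.0 * float(np.sum(np.sqrt(best) <= 1.0 + 1e-9)) / len(best)
    return GammaResult(
        gmap, pass_rate, dd_percent, dta_mm, low_threshold, dnorm, int(len(best))
    )


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------


def gy_to_percent(value_gy: float, fraction_dose_gy: float) -> float:
    """Express a dose in percent of the fraction dose, at one decimal."""
    if fraction_dose_gy <= 0:
        raise ValueError("fraction dose must be positive")
    return round(100.0 * value_gy / fraction_dose_gy, 1)
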