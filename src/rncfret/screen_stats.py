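"""Plate-level statistics and decisions for the FRET screen.

Hits are called against the plate's own vehicle (DMSO) baseline: a compound
is a hit when its duplicate-averaged E_FRET deviates more than 3 baseline
SDs from the baseline mean AND both single-pair values deviate more than
1.75 SD on the same side, after passing two quality-control gates (donor
bead intensity within 0.9-1.1× baseline, well background below 1.2×
baseline).  The module also provides the Z′ assay-window statistic, per-plate
CV and signal-to-background, and 4-parameter logistic dose-response fitting.
All SDs are sample SDs (n−1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fret_engine import FretPair, average_adjacent_pairs
from .plate_model import COMPOUND_COLUMNS, PlateLayout

__all__ = [
    "ControlStats",
    "DmsoBaseline",
    "CompoundResult",
    "DoseResponseFit",
    "dmso_baseline",
    "qc_gate",
    "call_hit",
    "call_hits_table",
    "compound_results",
    "z_prime",
    "min_separation_for_z_prime",
    "plate_cv",
    "signal_to_background",
    "fit_dose_response",
    "plate_summary",
]


@dataclass(frozen=True)
class ControlStats:
    """Mean/SD of positive and negative control E_FRET values."""

    mean_p: float
    sd_p: float
    mean_n: float
    sd_n: float

    def __post_init__(self) -> None:
        if self.sd_p < 0 or self.sd_n < 0:
            raise ValueError("control SDs must be >= 0")


@dataclass(frozen=True)
class DmsoBaseline:
    """Per-plate vehicle-control baseline (n single-pair E_FRET values)."""

    plate_id: str
    mean_efret: float
    sd_efret: float
    n: int
    mean_donor_intensity: float  # AU/µm² over control D wells
    mean_background: float  # AU per pixel over control wells

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("baseline needs n >= 2 control pairs")
        if self.sd_efret < 0:
            raise ValueError("baseline SD must be >= 0")


@dataclass
class CompoundResult:
    """Duplicate E_FRET values, QC flags and the hit decision for one compound."""

    compound_id: str
    efret_1: float
    efret_2: float
    qc_donor: bool
    qc_background: bool
    efret_avg: float = math.nan
    z_score: float = math.nan
    hit: bool = False
    direction: str = "none"  # increase | decrease | none


@dataclass
class DoseResponseFit:
    """4-parameter logistic fit: r(x) = bottom + (top−bottom)/(1+(EC50/x)^hill)."""

    doses_uM: np.ndarray
    responses: np.ndarray
    bottom: float = math.nan
    top: float = math.nan
    ec50_uM: float = math.nan
    hill: float = math.nan
    converged: bool = False

    def predict(self, doses) -> np.ndarray:
        return _four_pl(np.asarray(doses, dtype=float), self.bottom, self.top,
                        self.ec50_uM, self.hill)


def _sample_sd(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


def dmso_baseline(control_pairs: Sequence[FretPair], plate_id: str = "plate") -> DmsoBaseline:
    """Mean/SD of control-pair E_FRET plus donor-intensity and background levels."""
    if len(control_pairs) < 2:
        raise ValueError("need at least 2 DMSO control pairs for a baseline")
    e = np.array([p.efret for p in control_pairs], dtype=float)
    donor = np.array([p.d_well.mean_intensity for p in control_pairs], dtype=float)
    bg = np.array(
        [p.d_well.background for p in control_pairs]
        + [p.da_well.background for p in control_pairs],
        dtype=float,
    )
    return DmsoBaseline(
        plate_id=plate_id,
        mean_efret=float(np.mean(e)),
        sd_efret=_sample_sd(e),
        n=len(control_pairs),
        mean_donor_intensity=float(np.mean(donor)),
        mean_background=float(np.mean(bg)),
    )


def qc_gate(
    donor_intensities: Sequence[float],
    backgrounds: Sequence[float],
    baseline: DmsoBaseline,
    donor_bounds: tuple[float, float] = (0.9, 1.1),
    background_max_fold: float = 1.2,
) -> tuple[bool, bool]:
    """Compound-artifact gates relative to the DMSO baseline.

    ``qc_donor`` passes iff *every* donor well's mean bead intensity lies
    strictly inside ``donor_bounds`` × baseline donor mean; ``qc_background``
    passes iff *every* well's background stays below ``background_max_fold``
    × baseline background.
    """
    donor_arr = np.asarray(donor_intensities, dtype=float)
    bg_arr = np.asarray(backgrounds, dtype=float)
    if donor_arr.size == 0 or bg_arr.size == 0:
        raise ValueError("QC gate needs donor intensities and backgrounds")
    lo, hi = donor_bounds
    ratios = donor_arr / baseline.mean_donor_intensity
    qc_donor = bool(np.all((ratios > lo) & (ratios < hi)))
    qc_background = bool(np.all(bg_arr < background_max_fold * baseline.mean_background))
    return qc_donor, qc_background


def call_hit(
    result: CompoundResult,
    baseline: DmsoBaseline,
    avg_sd_mult: float = 3.0,
    single_sd_mult: float = 1.75,
) -> CompoundResult:
    """Apply the averaged-±3SD / both-singles-±1.75SD hit rule to one compound.

    A hit requires both QC gates to pass, the duplicate average to deviate
    more than ``avg_sd_mult`` baseline SDs, and both single values to deviate
    more than ``single_sd_mult`` SDs on the same side as the average.
    """
    if baseline.sd_efret == 0:
        raise ValueError("degenerate plate: DMSO baseline SD is zero")
    avg = average_adjacent_pairs(result.efret_1, result.efret_2)
    z = (avg - baseline.mean_efret) / baseline.sd_efret
    z1 = (result.efret_1 - baseline.mean_efret) / baseline.sd_efret
    z2 = (result.efret_2 - baseline.mean_efret) / baseline.sd_efret
    side = np.sign(z)
    singles_ok = (side * z1 > single_sd_mult) and (side * z2 > single_sd_mult)
    hit = (
        result.qc_donor
        and result.qc_background
        and abs(z) > avg_sd_mult
        and bool(singles_ok)
    )
    result.efret_avg = avg
    result.z_score = float(z)
    result.hit = hit
    result.direction = ("increase" if z > 0 else "decrease") if hit else "none"
    return result


def call_hits_table(
    efret_1,
    efret_2,
    qc_donor,
    qc_background,
    baseline: DmsoBaseline,
    avg_sd_mult: float = 3.0,
    single_sd_mult: float = 1.75,
) -> pd.DataFrame:
    """Vectorized hit calling over arrays of duplicate E values and QC flags."""
    if baseline.sd_efret == 0:
        raise ValueError("degenerate plate: DMSO baseline SD is zero")
    e1 = np.asarray(efret_1, dtype=float)
    e2 = np.asarray(efret_2, dtype=float)
    qc_d = np.asarray(qc_donor, dtype=bool)
    qc_b = np.asarray(qc_background, dtype=bool)
    avg = 0.5 * (e1 + e2)
    z = (avg - baseline.mean_efret) / baseline.sd_efret
    z1 = (e1 - baseline.mean_efret) / baseline.sd_efret
    z2 = (e2 - baseline.mean_efret) / baseline.sd_efret
    side = np.sign(z)
    valid = ~np.isnan(z)
    hit = (
        valid
        & qc_d
        & qc_b
        & (np.abs(z) > avg_sd_mult)
        & (side * z1 > single_sd_mult)
        & (side * z2 > single_sd_mult)
    )
    direction = np.where(hit, np.where(z > 0, "increase", "decrease"), "none")
    return pd.DataFrame(
        {"efret_1": e1, "efret_2": e2, "efret_avg": avg, "z_score": z,
         "qc_donor": qc_d, "qc_background": qc_b, "hit": hit, "direction": direction}
    )


def compound_results(
    pairs: pd.DataFrame,
    wells: pd.DataFrame,
    layout: PlateLayout,
    baseline: DmsoBaseline,
    avg_sd_mult: float = 3.0,
    single_sd_mult: float = 1.75,
    donor_bounds: tuple[float, float] = (0.9, 1.1),
    background_max_fold: float = 1.2,
) -> pd.DataFrame:
    """Full per-compound table (fixed schema) from pair and well tables."""
    by_pair = pairs.set_index("pair_id")
    by_well = wells.set_index("well")
    rows = []
    e1s, e2s, qds, qbs, cids = [], [], [], [], []
    for cid in sorted(layout.compound_quartets):
        d1, da1, d2, da2 = layout.compound_quartets[cid]
        e1 = float(by_pair.at[f"{cid}_1", "efret"])
        e2 = float(by_pair.at[f"{cid}_2", "efret"])
        donor = [float(by_well.at[w, "mean_intensity"]) for w in (d1, d2)]
        bgs = [float(by_well.at[w, "background"]) for w in (d1, da1, d2, da2)]
        qc_d, qc_b = qc_gate(donor, bgs, baseline, donor_bounds, background_max_fold)
        cids.append(cid); e1s.append(e1); e2s.append(e2); qds.append(qc_d); qbs.append(qc_b)
    calls = call_hits_table(e1s, e2s, qds, qbs, baseline, avg_sd_mult, single_sd_mult)
    calls.insert(0, "compound_id", cids)
    calls.insert(0, "plate_id", layout.plate_id)
    return calls.loc[:, COMPOUND_COLUMNS]


def z_prime(controls: ControlStats) -> float:
    """Z′ = 1 − 3(SD_P + SD_N)/|Mean_P − Mean_N|; > 0.5 means screenable."""
    sep = abs(controls.mean_p - controls.mean_n)
    if sep == 0:
        raise ValueError("Z' undefined for equal control means")
    return 1.0 - 3.0 * (controls.sd_p + controls.sd_n) / sep


def min_separation_for_z_prime(
    sd_p: float, sd_n: float, z_target: float = 0.5
) -> float:
    """Smallest |Mean_P − Mean_N| achieving a given Z′ at fixed control SDs."""
    if z_target >= 1:
        raise ValueError("Z' is bounded above by 1")
    return 3.0 * (sd_p + sd_n) / (1.0 - z_target)


def plate_cv(e_values) -> float:
    """Coefficient of variation (100 × sample SD / mean) of E_FRET values."""
    e = np.asarray(e_values, dtype=float)
    if e.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = float(np.mean(e))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * _sample_sd(e) / mean


def signal_to_background(d_signal: float, background: float) -> float:
    """Mean donor-well bead signal divided by mean background (same units)."""
    if background <= 0:
        raise ValueError("S/B undefined for non-positive background")
    return d_signal / background


def _four_pl(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def fit_dose_response(doses_uM, responses) -> DoseResponseFit:
    """Least-squares 4PL fit of E_FRET (or ΔE) responses against dose.

    Initial values come from the data (bottom/top from the extreme doses,
    EC50 from mid-response interpolation, hill = 1); EC50 is bounded to
    [min dose/10, max dose×10].  The fit is flagged unconverged for flat
    data, optimizer failure, a span indistinguishable from the residual
    noise, or an EC50 beyond the top dose (plateau not sampled).
    """
    x = np.asarray(doses_uM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and responses must have equal length")
    if x.size < 4:
        raise ValueError("dose-response fitting needs at least 4 points")
    if np.any(x <= 0):
        raise ValueError("doses must be strictly positive")
    fit = DoseResponseFit(doses_uM=x, responses=y)
    order = np.argsort(x)
    y_lo = float(np.mean(y[order[:max(1, x.size // 6)]]))
    y_hi = float(np.mean(y[order[-max(1, x.size // 6):]]))
    if y_lo == y_hi:
        return fit  # flat data: not converged
    mid = 0.5 * (y_lo + y_hi)
    # dose whose response is closest to the midpoint as the EC50 seed
    ec50_0 = float(x[np.argmin(np.abs(y - mid))])
    ec50_0 = float(np.clip(ec50_0, x.min() / 10.0, x.max() * 10.0))
    span = abs(y_hi - y_lo)
    p0 = [y_lo, y_hi, ec50_0, 1.0]
    bounds = (
        [y.min() - 10 * span - 1e-9, y.min() - 10 * span - 1e-9, x.min() / 10.0, 0.1],
        [y.max() + 10 * span + 1e-9, y.max() + 10 * span + 1e-9, x.max() * 10.0, 10.0],
    )
    try:
        popt, _ = curve_fit(
            _four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except (RuntimeError, ValueError):
        return fit
    fit.bottom, fit.top, fit.ec50_uM, fit.hill = (float(v) for v in popt)
    resid = y - fit.predict(x)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    fitted_span = abs(fit.top - fit.bottom)
    fit.converged = bool(
        fitted_span > max(2.0 * rms, 1e-12) and fit.ec50_uM < x.max()
    )
    return fit


def plate_summary(
    baseline: DmsoBaseline,
    compounds: pd.DataFrame,
    pixel_size: float = 0.325,
) -> dict:
    """One summary row per plate: baseline, CV, S/B, QC failures, hit counts.

    S/B follows the screen's convention — mean raw (background-inclusive)
    donor bead intensity over mean background, compared in per-area units.
    """
    bg_per_area = baseline.mean_background / pixel_size ** 2
    s_over_b = signal_to_background(
        baseline.mean_donor_intensity + bg_per_area, bg_per_area
    )
    n_qc_failed = int((~(compounds["qc_donor"] & compounds["qc_background"])).sum())
    return {
        "plate_id": baseline.plate_id,
        "dmso_mean": baseline.mean_efret,
        "dmso_sd": baseline.sd_efret,
        "n_dmso": baseline.n,
        "cv_pct": 100.0 * baseline.sd_efret / baseline.mean_efret,
        "s_over_b": s_over_b,
        "n_compounds": int(len(compounds)),
        "n_qc_failed": n_qc_failed,
        "n_hits_up": int((compounds["direction"] == "increase").sum()),
        "n_hits_down": int((compounds["direction"] == "decrease").sum()),
    }
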