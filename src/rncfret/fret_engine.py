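"""FRET efficiency from donor quenching.

One FRET value comes from a matched pair of wells (or solution samples):
donor-only (D) and donor+acceptor (D+A).  Energy transfer quenches the donor,
so efficiency is measured as the fractional decrease of donor fluorescence:

    E_FRET (%) = (1 − F_DA / F_D) × 100

where F_D and F_DA are donor intensities of the D and D+A samples.  On solid
support these are means over selected beads of per-area bead intensity; in
solution they are blank-subtracted peak emission intensities normalized to
each sample's ¹⁴C-derived RNC concentration.  Negative efficiencies are
reported, not clamped — compounds can (artifactually) brighten the D+A
channel, and screens must keep the sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .plate_model import (
    PAIR_COLUMNS,
    PlateLayout,
    WellMeasurement,
)

__all__ = [
    "FretError",
    "FretPair",
    "EmissionSpectrum",
    "compute_efret",
    "average_adjacent_pairs",
    "peak_intensity",
    "solution_efret",
    "release_fold_change",
    "pair_wells",
    "read_spectra_csv",
]


class FretError(ValueError):
    """Raised when a FRET quantity is undefined for the given inputs."""


def compute_efret(f_d, f_da):
    """E_FRET (%) = (1 − F_DA/F_D) × 100.  Accepts scalars or arrays.

    F_D must be strictly positive; the result is not clamped and may be
    negative.  Scale-invariant: (cF_D, cF_DA) gives the same value.
    """
    f_d_arr = np.asarray(f_d, dtype=float)
    if np.any(f_d_arr <= 0):
        raise FretError("F_D must be > 0 for E_FRET to be defined")
    out = (1.0 - np.asarray(f_da, dtype=float) / f_d_arr) * 100.0
    if np.isscalar(f_d) and np.isscalar(f_da):
        return float(out)
    return out


def average_adjacent_pairs(e1, e2):
    """Arithmetic mean of two adjacent pair measurements (the duplicate design)."""
    e1_arr = np.asarray(e1, dtype=float)
    e2_arr = np.asarray(e2, dtype=float)
    out = 0.5 * (e1_arr + e2_arr)
    if np.isscalar(e1) and np.isscalar(e2):
        return float(out)
    return out


@dataclass
class FretPair:
    """A matched D / D+A well pair and its FRET efficiency."""

    d_well: WellMeasurement
    da_well: WellMeasurement
    pair_id: str = ""

    @property
    def f_d(self) -> float:
        return self.d_well.mean_intensity

    @property
    def f_da(self) -> float:
        return self.da_well.mean_intensity

    @property
    def efret(self) -> float:
        return compute_efret(self.f_d, self.f_da)


@dataclass
class EmissionSpectrum:
    """A fluorescence emission spectrum (CFP: λex 430 nm, λem 450-600 nm).

    ``rnc_concentration_nM`` carries the sample's ¹⁴C-derived concentration
    when available, used to normalize solution FRET at unequal yields.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    sample_kind: str = "D"  # D, DA, BLANK_D, BLANK_DA
    rnc_concentration_nM: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("spectrum must be 1-D")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


def peak_intensity(spectrum: EmissionSpectrum, n_peaks: int = 5) -> float:
    """Mean of the ``n_peaks`` largest emission intensities (~475 nm for CFP)."""
    if spectrum.intensities.size < n_peaks:
        raise FretError(f"spectrum has fewer than {n_peaks} points")
    top = np.sort(spectrum.intensities)[-n_peaks:]
    return float(np.mean(top))


def solution_efret(
    d: EmissionSpectrum,
    da: EmissionSpectrum,
    blanks: tuple[EmissionSpectrum, EmissionSpectrum],
) -> float:
    """Solution-phase E_FRET from D, D+A and matched blank spectra.

    Each sample's peak intensity is blank-subtracted and divided by that
    sample's RNC concentration (the ¹⁴C correction), making D and D+A
    comparable when readthrough yields differ; E then follows from donor
    quenching.  Adding a constant offset to a sample and its matched blank
    leaves the result unchanged.
    """
    blank_d, blank_da = blanks
    if d.rnc_concentration_nM is None or da.rnc_concentration_nM is None:
        raise FretError("D and D+A spectra need rnc_concentration_nM for the ¹⁴C correction")
    if d.rnc_concentration_nM <= 0 or da.rnc_concentration_nM <= 0:
        raise FretError("RNC concentrations must be positive")
    f_d = (peak_intensity(d) - peak_intensity(blank_d)) / d.rnc_concentration_nM
    f_da = (peak_intensity(da) - peak_intensity(blank_da)) / da.rnc_concentration_nM
    if f_d <= 0:
        raise FretError("blank-corrected donor signal is non-positive")
    return compute_efret(f_d, f_da)


def release_fold_change(e_bound: float, e_released: float) -> float:
    """Fold change of E_FRET upon release of the chain from the ribosome."""
    if e_bound <= 0:
        raise FretError("fold change undefined for non-positive bound E_FRET")
    return e_released / e_bound


# ---------------------------------------------------------------------------
# plate-level pairing
# ---------------------------------------------------------------------------


def pair_wells(
    wells: pd.DataFrame, layout: PlateLayout, plate_id: str | None = None
) -> pd.DataFrame:
    """Build the per-pair FRET table from a per-well measurement table.

    Emits one row per D/D+A pair (two per compound, one per DMSO pair) with
    columns ``plate_id,pair_id,d_well,da_well,F_D,F_DA,efret``.  Pairs whose
    donor intensity is undefined or non-positive get NaN efficiency rather
    than raising, so one failed well cannot abort a plate.
    """
    plate_id = plate_id or layout.plate_id
    by_well = wells.set_index("well")

    def one(pair_id: str, d: str, da: str) -> dict:
        f_d = float(by_well.at[d, "mean_intensity"]) if d in by_well.index else math.nan
        f_da = float(by_well.at[da, "mean_intensity"]) if da in by_well.index else math.nan
        if f_d > 0 and not math.isnan(f_da):
            e = compute_efret(f_d, f_da)
        else:
            e = math.nan
        return {
            "plate_id": plate_id, "pair_id": pair_id, "d_well": d, "da_well": da,
            "F_D": f_d, "F_DA": f_da, "efret": e,
        }

    rows = []
    for cid in sorted(layout.compound_quartets):
        for rep, (d, da) in enumerate(layout.compound_pairs(cid), start=1):
            rows.append(one(f"{cid}_{rep}", d, da))
    for i, (d, da) in enumerate(layout.dmso_pairs, start=1):
        pid = layout.wells[d].pair_id or f"dmso_{i:02d}"
        rows.append(one(pid, d, da))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def read_spectra_csv(path) -> list[EmissionSpectrum]:
    """Read spectra from CSV columns ``wavelength_nm,intensity,sample_kind``."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "intensity", "sample_kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectra CSV requires columns {sorted(required)}")
    spectra = []
    for kind, sub in df.groupby("sample_kind", sort=False):
        sub = sub.sort_values("wavelength_nm")
        spectra.append(
            EmissionSpectrum(
                sub["wavelength_nm"].to_numpy(),
                sub["intensity"].to_numpy(),
                sample_kind=str(kind),
            )
        )
    return spectra
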