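"""Biochemical and geometric calculators for bead-immobilized RNCs.

Ribosome-bound nascent chain complexes (RNCs) are quantified by ¹⁴C
scintillation counting and immobilized on Ni-chelating agarose beads; this
module holds the desk arithmetic around that workflow:

* RNC concentration from counts per minute (output in pmol/ml == nM),
* bead surface density of bound molecules and its comparison with the
  theoretical saturation density of ribosomes hexagonally packed on a plane,
* capture efficiency of a binding reaction,
* bead-batch planning at constant aggregate surface area, and
* the effective local concentration of molecules bound to a bead.

Bead surface area is the nominal sphere area (πd² per bead) at the nominal
diameter; agarose beads are porous, but the saturation framing deliberately
uses the geometric area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

AVOGADRO = 6.02214e23  # 1/mol

#: densest packing fraction of equal circles in the plane (hexagonal lattice)
HEX_PACKING = math.pi / (2.0 * math.sqrt(3.0))

#: ribosome radius in µm (25 nm diameter)
RIBOSOME_RADIUS_UM = 0.0125


@dataclass(frozen=True)
class ScintillationRecord:
    """One ¹⁴C scintillation measurement of a sample/blank pair.

    ``cpm_s``/``cpm_b`` are counts per minute of sample and matched blank,
    ``counting_efficiency`` the fraction of decays registered (0.95 for ¹⁴C
    on the counters used), ``specific_activity`` the label's dpm/pmol and
    ``volume_ml`` the counted volume.
    """

    cpm_s: float
    cpm_b: float
    counting_efficiency: float = 0.95
    specific_activity: float = 400.0  # dpm/pmol
    volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.counting_efficiency <= 1.0:
            raise ValueError("counting efficiency must be in (0, 1]")
        if self.specific_activity <= 0:
            raise ValueError("specific activity must be positive")
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")


@dataclass(frozen=True)
class RibosomeGeometry:
    """Packing coefficient and ribosome radius for the saturation model."""

    eta_h: float = HEX_PACKING
    radius_um: float = RIBOSOME_RADIUS_UM

    def __post_init__(self) -> None:
        if not 0.0 < self.eta_h <= 1.0:
            raise ValueError("packing coefficient must be in (0, 1]")
        if self.radius_um <= 0:
            raise ValueError("ribosome radius must be positive")


@dataclass(frozen=True)
class BeadBatch:
    """A batch of nominally identical spherical beads."""

    nominal_diameter_um: float
    count: int

    def __post_init__(self) -> None:
        if self.nominal_diameter_um <= 0:
            raise ValueError("bead diameter must be positive")
        if self.count < 0:
            raise ValueError("bead count must be >= 0")

    @property
    def per_bead_area_um2(self) -> float:
        """Sphere surface area πd² of one bead."""
        return math.pi * self.nominal_diameter_um ** 2

    @property
    def per_bead_volume_um3(self) -> float:
        return math.pi * self.nominal_diameter_um ** 3 / 6.0

    @property
    def total_area_um2(self) -> float:
        return self.count * self.per_bead_area_um2


def rnc_concentration(rec: ScintillationRecord) -> float:
    """RNC concentration in nM from a scintillation record.

    (cpm_S − cpm_B) / (CE × SA × vol) gives pmol/ml, numerically equal to nM.
    """
    if rec.cpm_s < rec.cpm_b:
        raise ValueError(
            f"sample counts ({rec.cpm_s}) below blank ({rec.cpm_b}): negative concentration"
        )
    return (rec.cpm_s - rec.cpm_b) / (
        rec.counting_efficiency * rec.specific_activity * rec.volume_ml
    )


def saturation_density(geom: RibosomeGeometry = RibosomeGeometry()) -> float:
    """Theoretical max ribosomes/µm² on a flat surface: η_h / (π r²)."""
    return geom.eta_h / (math.pi * geom.radius_um ** 2)


def surface_density(molecules_bound: float, batch: BeadBatch) -> float:
    """Bound molecules per µm² of aggregate nominal bead surface."""
    if batch.count == 0:
        raise ValueError("cannot compute surface density for zero beads")
    if molecules_bound < 0:
        raise ValueError("molecules_bound must be >= 0")
    return molecules_bound / batch.total_area_um2


def saturation_fraction(
    density_per_um2: float, geom: RibosomeGeometry = RibosomeGeometry()
) -> float:
    """Achieved surface density as a fraction of geometric saturation."""
    return density_per_um2 / saturation_density(geom)


def capture_efficiency(bound_pmol: float, input_pmol: float) -> float:
    """Percent of RNCs in a binding reaction that ended up bead-bound."""
    if input_pmol <= 0:
        raise ValueError("input amount must be positive")
    if bound_pmol < 0:
        raise ValueError("bound amount must be >= 0")
    if bound_pmol > input_pmol:
        raise ValueError("bound amount exceeds input: impossible capture > 100%")
    return 100.0 * bound_pmol / input_pmol


def moles_to_molecules(amount_mol: float) -> float:
    """Convert an amount of substance to a molecule count (N_A × n)."""
    if amount_mol < 0:
        raise ValueError("amount must be >= 0")
    return amount_mol * AVOGADRO


def plan_bead_batches(
    target_area_um2: float, diameters_um: Sequence[float]
) -> list[BeadBatch]:
    """Bead counts per diameter giving the same aggregate surface area.

    count = round(target_area / πd²); e.g. the area of 2×10⁵ 17-µm beads is
    matched by 5×10⁴ 34-µm beads or ~5.8×10³ 100-µm beads.
    """
    if target_area_um2 <= 0:
        raise ValueError("target area must be positive")
    batches = []
    for d in diameters_um:
        if d <= 0:
            raise ValueError("bead diameters must be positive")
        count = int(round(target_area_um2 / (math.pi * d ** 2)))
        batches.append(BeadBatch(d, count))
    return batches


def effective_bound_concentration(
    density_per_um2: float, bead_radius_um: float
) -> float:
    """Effective molar concentration of molecules bound to a bead's surface.

    Treats all bound molecules as dissolved in the bead's own spherical
    volume: density × 4πR² / ((4/3)πR³ N_A) = 3·density / (R·N_A), converted
    to mol/L (1 µm³ = 1e-15 L).
    """
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    if bead_radius_um <= 0:
        raise ValueError("bead radius must be positive")
    molecules_per_um3 = 3.0 * density_per_um2 / bead_radius_um
    return molecules_per_um3 * 1e15 / AVOGADRO
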