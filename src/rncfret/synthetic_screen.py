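"""Forward simulator for the solid-support FRET screen.

Produces plate-level ground truth and rendered well images with the
statistical structure the analysis assumes, so every downstream stage can be
verified without instrument data.  The model: ~600 nominal 17-µm beads
settle per 1,536-format well as a monolayer; a single image covers 19% of
the well area; donor-only (D) wells show beads at an intensity scale *s*,
the matched D+A wells at *s·(1 − E/100)* for the pair's true FRET
efficiency E.  On top of that: bead-to-bead brightness variation, a small
fraction of defocused beads, elongated non-circular artifact objects, a
smooth multiplicative illumination field, flat background autofluorescence,
additive Gaussian read noise (Poisson shot noise optional), and per-compound
artifacts (donor quench/enhancement, added background) affecting a
configurable fraction of the library.

Defaults reproduce the screen's operating point: 600 beads/well, 19% imaged
fraction, 17 ± 1 µm beads (gravity-segregated to 16.5-22.5 µm), a baseline
E_FRET of 29%, a donor amplitude giving signal-to-background ≈ 2.6, and 10%
of compounds carrying optical artifacts.

Seeding: a single integer seed drives counter-based per-well substreams
(SeedSequence entropy = (seed, stream, well-index)), so any well is
reproducible in isolation and plates are bit-identical across reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .fret_engine import EmissionSpectrum
from .plate_model import (
    BEAD_KINDS,
    PLATE_SHAPES,
    PlateLayout,
    WellImage,
    WellKind,
    well_sort_key,
    write_well_image,
)

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "ScreenTruth",
    "draw_screen_truth",
    "spike_hits",
    "render_well_image",
    "WellImageSet",
    "simulate_plate",
    "sample_measurements",
    "simulate_screen_statistical",
    "synthetic_emission_spectrum",
    "synthetic_solution_set",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic screen; defaults are the study conditions."""

    plate_format: int = 1536
    beads_per_well: int = 600
    imaged_fraction: float = 0.19
    image_shape: tuple[int, int] = (2048, 2048)
    pixel_size: float = 0.325  # µm/pixel

    bead_diameter_mean: float = 17.0  # µm
    bead_diameter_sd: float = 1.0
    bead_diameter_limits: tuple[float, float] = (16.5, 22.5)  # gravity segregation
    brightness_cv: float = 0.10
    min_separation_factor: float = 1.05  # × mean of the two bead diameters

    defocus_fraction: float = 0.03
    defocus_sigma_um: float = 4.0
    artifact_rate: float = 0.05  # artifact objects per bead
    artifact_axis_ratio: float = 3.0
    artifact_minor_um: tuple[float, float] = (6.0, 10.0)

    illumination_amplitude: float = 0.15
    background_level: float = 200.0  # AU per pixel
    read_noise_sd: float = 10.0  # AU per pixel
    noise_model: str = "gaussian"  # gaussian | poisson (shot noise added first)

    donor_amplitude: float = 324.0  # AU per pixel above background (D beads)
    baseline_efret: float = 29.0  # true E of the DMSO/vehicle pairs (%)

    compound_artifact_fraction: float = 0.10
    donor_artifact_low: tuple[float, float] = (0.70, 0.85)
    donor_artifact_high: tuple[float, float] = (1.15, 1.30)
    background_artifact_range: tuple[float, float] = (1.30, 1.80)

    hit_spikes: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_SHAPES:
            raise ConfigurationError(f"unknown plate format {self.plate_format}")
        if not 0.0 < self.imaged_fraction <= 1.0:
            raise ConfigurationError("imaged_fraction must be in (0, 1]")
        if self.beads_per_well < 0:
            raise ConfigurationError("beads_per_well must be >= 0")
        for name in ("brightness_cv", "defocus_fraction", "compound_artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be >= 0")
        if self.pixel_size <= 0 or self.bead_diameter_mean <= 0:
            raise ConfigurationError("pixel_size and bead diameter must be positive")
        lo, hi = self.bead_diameter_limits
        if not 0 < lo < hi:
            raise ConfigurationError("bead diameter limits must satisfy 0 < low < high")
        if not -100.0 < self.baseline_efret < 100.0:
            raise ConfigurationError("baseline_efret must lie in (-100, 100)")
        if self.illumination_amplitude < 0 or self.illumination_amplitude >= 1:
            raise ConfigurationError("illumination_amplitude must be in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigurationError("noise_model must be 'gaussian' or 'poisson'")

    @property
    def expected_beads_per_image(self) -> float:
        return self.beads_per_well * self.imaged_fraction

    @property
    def pixel_area(self) -> float:
        return self.pixel_size ** 2


@dataclass
class ScreenTruth:
    """Ground truth for one simulated plate.

    ``wells``: per-well kind, compound, true E_FRET (%), donor amplitude
    scale (AU above background), true background (AU) and imaged bead count.
    ``compounds``: per-compound true effect (ΔE, donor-scale multiplier,
    background multiplier).  ``beads``: per-object centres (µm), diameters,
    brightness factors and object class.  ``field_params`` describe the
    plate's illumination surface.
    """

    wells: pd.DataFrame
    compounds: pd.DataFrame
    beads: pd.DataFrame
    field_params: dict
    config: SimulationConfig
    seed: int

    def well_amplitude(self, well: str) -> float:
        """Bead pixel amplitude in a well: donor scale, quenched on D+A side."""
        row = self.wells.loc[well]
        kind = WellKind(row["kind"])
        if kind in (WellKind.BLANK_D, WellKind.BLANK_DA):
            return 0.0
        amp = float(row["donor_scale"])
        if kind in (WellKind.DA, WellKind.DMSO_DA):
            amp *= 1.0 - float(row["efret_true"]) / 100.0
        return amp


def _well_rng(seed: int, stream: int, well_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, well_index]))


def _field_surface(shape: tuple[int, int], params: Mapping[str, float]) -> np.ndarray:
    y2 = (np.arange(shape[0], dtype=float) - params["cy"]) ** 2
    x2 = (np.arange(shape[1], dtype=float) - params["cx"]) ** 2
    r2 = y2[:, None] + x2[None, :]
    return 1.0 - params["amplitude"] * r2 / params["r_norm2"]


def _place_objects(
    rng: np.random.Generator,
    n_beads: int,
    n_artifacts: int,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Dart-throwing placement of beads/artifacts with pairwise separation.

    Centres keep a distance of ``min_separation_factor`` × the mean of the
    two objects' footprints (beads settle in a non-touching monolayer).
    Objects that cannot be placed after many attempts are dropped.
    """
    h_um = config.image_shape[0] * config.pixel_size
    w_um = config.image_shape[1] * config.pixel_size
    lo, hi = config.bead_diameter_limits
    mu, sd = config.bead_diameter_mean, config.bead_diameter_sd

    rows: list[dict] = []
    xs = np.empty(0)
    ys = np.empty(0)
    radii = np.empty(0)

    def try_place(radius_um: float) -> tuple[float, float] | None:
        nonlocal xs, ys, radii
        for _ in range(80):
            x = rng.uniform(0, w_um)
            y = rng.uniform(0, h_um)
            if xs.size:
                min_d = config.min_separation_factor * (radii + radius_um)
                if np.any((xs - x) ** 2 + (ys - y) ** 2 < min_d ** 2):
                    continue
            xs = np.append(xs, x)
            ys = np.append(ys, y)
            radii = np.append(radii, radius_um)
            return x, y
        return None

    for _ in range(n_beads):
        # truncated normal diameter by rejection (limits are a few SD wide)
        for _ in range(100):
            d = rng.normal(mu, sd)
            if lo <= d <= hi:
                break
        else:
            d = mu
        pos = try_place(d / 2.0)
        if pos is None:
            continue
        rows.append(
            {
                "x_um": pos[0], "y_um": pos[1], "diameter_um": d,
                "brightness": max(rng.normal(1.0, config.brightness_cv), 0.05),
                "kind": "defocused" if rng.random() < config.defocus_fraction else "bead",
                "axis_ratio": 1.0, "angle": 0.0,
            }
        )
    for _ in range(n_artifacts):
        minor = rng.uniform(*config.artifact_minor_um)
        major = minor * config.artifact_axis_ratio
        pos = try_place(major / 2.0)
        if pos is None:
            continue
        rows.append(
            {
                "x_um": pos[0], "y_um": pos[1], "diameter_um": minor,
                "brightness": max(rng.normal(1.0, config.brightness_cv), 0.05),
                "kind": "artifact",
                "axis_ratio": config.artifact_axis_ratio,
                "angle": rng.uniform(0, math.pi),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["x_um", "y_um", "diameter_um", "brightness", "kind", "axis_ratio", "angle"],
    )


def draw_screen_truth(
    layout: PlateLayout,
    config: SimulationConfig,
    seed: int | None = None,
    place_beads: bool = True,
) -> ScreenTruth:
    """Draw the full ground truth (no images) for one plate.

    ``place_beads=False`` skips per-bead geometry (centres, diameters) and
    leaves only well-level truth — enough for the statistical fast path and
    much faster for full plates.  Well-level draws are unaffected.
    """
    seed = config.seed if seed is None else seed
    plate_rng = _well_rng(seed, 0, 0)

    h, w = config.image_shape
    field_params = {
        "cy": (0.5 + 0.1 * plate_rng.uniform(-1, 1)) * h,
        "cx": (0.5 + 0.1 * plate_rng.uniform(-1, 1)) * w,
        "amplitude": config.illumination_amplitude,
        "r_norm2": float(h ** 2 + w ** 2),  # distance to corner bounds r²
    }

    comp_rows = []
    for cid in sorted(layout.compound_quartets):
        donor_mult, bg_mult = 1.0, 1.0
        if plate_rng.random() < config.compound_artifact_fraction:
            if plate_rng.random() < 0.5:
                rng_range = (
                    config.donor_artifact_low
                    if plate_rng.random() < 0.5
                    else config.donor_artifact_high
                )
                donor_mult = plate_rng.uniform(*rng_range)
            else:
                bg_mult = plate_rng.uniform(*config.background_artifact_range)
        comp_rows.append(
            {
                "compound_id": cid, "delta_efret": 0.0,
                "donor_multiplier": donor_mult, "background_multiplier": bg_mult,
            }
        )
    compounds = pd.DataFrame(
        comp_rows,
        columns=["compound_id", "delta_efret", "donor_multiplier", "background_multiplier"],
    )
    comp_idx = compounds.set_index("compound_id")

    well_rows = []
    bead_frames = []
    names = sorted(layout.wells, key=lambda n: well_sort_key(n, layout.plate_format))
    for name in names:
        role = layout.wells[name]
        if role.kind is WellKind.EMPTY:
            continue
        idx = well_sort_key(name, layout.plate_format)
        donor_scale = config.donor_amplitude
        background = config.background_level
        efret = config.baseline_efret
        if role.compound_id is not None:
            eff = comp_idx.loc[role.compound_id]
            donor_scale *= float(eff["donor_multiplier"])
            background *= float(eff["background_multiplier"])
            efret += float(eff["delta_efret"])
        n_beads = 0
        if role.kind in BEAD_KINDS and config.beads_per_well > 0:
            rng_w = _well_rng(seed, 1, idx)
            n_beads = int(rng_w.binomial(config.beads_per_well, config.imaged_fraction))
            if place_beads:
                n_art = int(rng_w.poisson(config.artifact_rate * n_beads))
                objs = _place_objects(rng_w, n_beads, n_art, config)
                objs.insert(0, "well", name)
                bead_frames.append(objs)
                n_beads = int((objs["kind"] != "artifact").sum())
        well_rows.append(
            {
                "well": name, "well_index": idx, "kind": role.kind.value,
                "compound_id": role.compound_id, "pair_id": role.pair_id,
                "efret_true": efret, "donor_scale": donor_scale,
                "background": background, "n_beads": n_beads,
            }
        )
    wells = pd.DataFrame(
        well_rows,
        columns=["well", "well_index", "kind", "compound_id", "pair_id",
                 "efret_true", "donor_scale", "background", "n_beads"],
    ).set_index("well", drop=False)
    wells.index.name = None
    beads = (
        pd.concat(bead_frames, ignore_index=True)
        if bead_frames
        else pd.DataFrame(
            columns=["well", "x_um", "y_um", "diameter_um", "brightness",
                     "kind", "axis_ratio", "angle"]
        )
    )
    truth = ScreenTruth(wells, compounds, beads, field_params, config, seed)
    if config.hit_spikes:
        truth = spike_hits(truth, dict(config.hit_spikes))
    return truth


def spike_hits(
    truth: ScreenTruth,
    compounds: Mapping[str, float] | Sequence[str],
    delta_e: float | None = None,
) -> ScreenTruth:
    """Shift listed compounds' true E_FRET by ΔE; everything else untouched.

    ``compounds`` is a mapping {compound_id: ΔE} or a list used with a common
    ``delta_e``.  Returns a new ScreenTruth; the input is not mutated.
    """
    if not isinstance(compounds, Mapping):
        if delta_e is None:
            raise ValueError("delta_e required when compounds is a plain list")
        compounds = {cid: delta_e for cid in compounds}
    known = set(truth.compounds["compound_id"])
    unknown = sorted(set(compounds) - known)
    if unknown:
        raise KeyError(f"unknown compounds: {unknown}")
    wells = truth.wells.copy()
    comp = truth.compounds.copy()
    for cid, delta in compounds.items():
        comp.loc[comp["compound_id"] == cid, "delta_efret"] += delta
        wells.loc[wells["compound_id"] == cid, "efret_true"] += delta
    return ScreenTruth(wells, comp, truth.beads, truth.field_params, truth.config, truth.seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _add_disk(canvas: np.ndarray, cx_px: float, cy_px: float, r_px: float,
              amplitude: float, blur_px: float = 0.0) -> None:
    pad = int(math.ceil(r_px + 2 + 4 * blur_px))
    h, w = canvas.shape
    y0, y1 = max(0, int(cy_px) - pad), min(h, int(cy_px) + pad + 1)
    x0, x1 = max(0, int(cx_px) - pad), min(w, int(cx_px) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy_px, xx - cx_px)
    cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)  # uniform disk, soft 1-px edge
    if blur_px > 0:
        cov = ndi.gaussian_filter(cov, blur_px)
    canvas[y0:y1, x0:x1] += amplitude * cov


def _add_ellipse(canvas: np.ndarray, cx_px: float, cy_px: float, a_px: float,
                 b_px: float, angle: float, amplitude: float) -> None:
    pad = int(math.ceil(a_px + 2))
    h, w = canvas.shape
    y0, y1 = max(0, int(cy_px) - pad), min(h, int(cy_px) + pad + 1)
    x0, x1 = max(0, int(cx_px) - pad), min(w, int(cx_px) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy_px, xx - cx_px
    u = (dx * math.cos(angle) + dy * math.sin(angle)) / a_px
    v = (-dx * math.sin(angle) + dy * math.cos(angle)) / b_px
    q = np.sqrt(u ** 2 + v ** 2)
    signed = (q - 1.0) * b_px  # approximate signed distance to the boundary
    canvas[y0:y1, x0:x1] += amplitude * np.clip(0.5 - signed, 0.0, 1.0)


def render_well_image(
    truth: ScreenTruth, well_name: str, config: SimulationConfig | None = None
) -> WellImage:
    """Render one well as a quantized 16-bit image; deterministic per well.

    In-focus beads are uniform disks with a soft 1-pixel edge; defocused
    beads are additionally blurred; artifacts are elongated soft ellipses.
    The composed scene plus the well's flat background is modulated by the
    plate's illumination surface, then noise is added and the image is
    quantized to uint16.
    """
    config = config or truth.config
    if well_name not in truth.wells.index:
        raise KeyError(f"well {well_name!r} not in truth")
    row = truth.wells.loc[well_name]
    px = config.pixel_size
    canvas = np.zeros(config.image_shape, dtype=float)
    amp = truth.well_amplitude(well_name)
    objs = truth.beads[truth.beads["well"] == well_name]
    for obj in objs.itertuples(index=False):
        obj_amp = (config.donor_amplitude if obj.kind == "artifact" else amp) * obj.brightness
        if obj_amp == 0.0:
            continue
        if obj.kind == "artifact":
            _add_ellipse(
                canvas, obj.x_um / px, obj.y_um / px,
                obj.axis_ratio * obj.diameter_um / 2.0 / px,
                obj.diameter_um / 2.0 / px, obj.angle, obj_amp,
            )
        else:
            blur = config.defocus_sigma_um / px if obj.kind == "defocused" else 0.0
            _add_disk(
                canvas, obj.x_um / px, obj.y_um / px,
                obj.diameter_um / 2.0 / px, obj_amp, blur,
            )
    field = _field_surface(config.image_shape, truth.field_params)
    img = (canvas + float(row["background"])) * field
    rng = _well_rng(truth.seed, 2, int(row["well_index"]))
    if config.noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return WellImage(img, pixel_size=px, well_name=well_name, channel="donor")


class WellImageSet(Mapping):
    """Lazy mapping well-name -> rendered :class:`WellImage`.

    Covers the bead-bearing wells of the truth (D/D+A, DMSO, blanks); images
    are rendered on access so a full plate never has to sit in memory.
    """

    def __init__(self, truth: ScreenTruth, config: SimulationConfig | None = None):
        self.truth = truth
        self.config = config or truth.config
        kinds = {k.value for k in BEAD_KINDS}
        self._names = [
            w for w in self.truth.wells.index if self.truth.wells.at[w, "kind"] in kinds
        ]

    def __getitem__(self, well: str) -> WellImage:
        if well not in self.truth.wells.index:
            raise KeyError(well)
        return render_well_image(self.truth, well, self.config)

    def __iter__(self):
        return iter(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def write(self, out_dir, plate_id: str | None = None) -> list[Path]:
        plate_id = plate_id or "plate"
        return [write_well_image(self[w], out_dir, plate_id) for w in self._names]


def simulate_plate(
    layout: PlateLayout, config: SimulationConfig, seed: int | None = None
) -> tuple[ScreenTruth, WellImageSet]:
    """Ground truth plus (lazily rendered) well images for one plate."""
    truth = draw_screen_truth(layout, config, seed=seed)
    return truth, WellImageSet(truth, config)


# ---------------------------------------------------------------------------
# statistical fast path
# ---------------------------------------------------------------------------


def _measured_well_means(
    rng: np.random.Generator,
    amplitude: np.ndarray,
    n_beads: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample measured (mean, SD) per-area bead intensity for wells.

    Under the generator's model the per-bead measured per-area intensity is
    Gaussian: amplitude/pixel-area scaled by a N(1, CV) brightness factor
    plus a small pixel-noise term averaged over the bead's ~2×10³ pixels.
    The well mean over n beads is therefore exactly Gaussian — no rendering
    needed for plate-scale statistics.
    """
    per_area = amplitude / config.pixel_area
    n = np.maximum(n_beads, 1)
    n_px_bead = math.pi * (config.bead_diameter_mean / 2.0) ** 2 / config.pixel_area
    bead_noise_var = (config.read_noise_sd / config.pixel_area) ** 2 / n_px_bead
    mean_sd = np.sqrt((per_area * config.brightness_cv) ** 2 / n + bead_noise_var / n)
    means = per_area + mean_sd * rng.standard_normal(per_area.shape)
    bead_sd = np.sqrt((per_area * config.brightness_cv) ** 2 + bead_noise_var)
    sds = bead_sd * np.sqrt(rng.chisquare(np.maximum(n - 1, 1)) / np.maximum(n - 1, 1))
    return means, sds


def sample_measurements(
    truth: ScreenTruth,
    config: SimulationConfig | None = None,
    wells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-well measurement table drawn from the model without rendering.

    The shortcut assumes every imaged bead passes the selection gates, which
    holds up to edge effects for the default geometry; use the image path
    when segmentation itself is under test.  Deterministic per well (its own
    substream), independent of which wells are requested.
    """
    config = config or truth.config
    sub = truth.wells if wells is None else truth.wells.loc[list(wells)]
    kinds = {k.value for k in BEAD_KINDS}
    rows = []
    for well in sub.index:
        row = sub.loc[well]
        rng = _well_rng(truth.seed, 3, int(row["well_index"]))
        if row["kind"] not in kinds or row["n_beads"] == 0:
            rows.append((well, 0, math.nan, 0.0, float(row["background"])))
            continue
        amp = truth.well_amplitude(well)
        mean, sd = _measured_well_means(
            rng, np.array([amp]), np.array([row["n_beads"]]), config
        )
        n_bg_px = 0.9 * config.image_shape[0] * config.image_shape[1]
        bg = float(row["background"]) + 1.2533 * config.read_noise_sd / math.sqrt(
            n_bg_px
        ) * rng.standard_normal()
        rows.append((well, int(row["n_beads"]), float(mean[0]), float(sd[0]), bg))
    return pd.DataFrame(
        rows, columns=["well", "n_beads", "mean_intensity", "sd_intensity", "background"]
    )


def simulate_screen_statistical(
    n_compounds: int,
    config: SimulationConfig,
    seed: int,
    n_dmso_pairs: int = 32,
    delta_efret=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized plate statistics for large-scale screens (no images).

    Each compound's true E is the baseline plus its entry of ``delta_efret``
    (default: all zero, a fully null screen); compound artifacts are drawn
    at the configured fraction.  Returns ``(compounds, dmso)``:

    * compounds: ``compound_id, efret_1, efret_2, d1_intensity, d2_intensity,
      max_background, donor_multiplier, background_multiplier``
    * dmso: ``efret, d_intensity, background``

    Uses the same exact-Gaussian well-mean model as
    :func:`sample_measurements`; intended for null hit-rate and power
    studies where rendering 10⁵ compounds is pointless.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    delta = np.zeros(n_compounds) if delta_efret is None else np.asarray(delta_efret, float)
    if delta.shape != (n_compounds,):
        raise ValueError("delta_efret must have one entry per compound")
    quench = 1.0 - (config.baseline_efret + delta) / 100.0
    quench0 = 1.0 - config.baseline_efret / 100.0

    donor_mult = np.ones(n_compounds)
    bg_mult = np.ones(n_compounds)
    is_artifact = rng.random(n_compounds) < config.compound_artifact_fraction
    donor_side = rng.random(n_compounds) < 0.5
    low_side = rng.random(n_compounds) < 0.5
    lo_lo, lo_hi = config.donor_artifact_low
    hi_lo, hi_hi = config.donor_artifact_high
    d_art = np.where(
        low_side, rng.uniform(lo_lo, lo_hi, n_compounds),
        rng.uniform(hi_lo, hi_hi, n_compounds),
    )
    b_art = rng.uniform(*config.background_artifact_range, n_compounds)
    donor_mult = np.where(is_artifact & donor_side, d_art, donor_mult)
    bg_mult = np.where(is_artifact & ~donor_side, b_art, bg_mult)

    def well_block(amplitude: np.ndarray) -> np.ndarray:
        n = rng.binomial(config.beads_per_well, config.imaged_fraction, amplitude.shape)
        mean, _ = _measured_well_means(rng, amplitude, n, config)
        return mean

    amp_c = config.donor_amplitude * donor_mult
    d1 = well_block(amp_c)
    da1 = well_block(amp_c * quench)
    d2 = well_block(amp_c)
    da2 = well_block(amp_c * quench)
    e1 = (1.0 - da1 / d1) * 100.0
    e2 = (1.0 - da2 / d2) * 100.0
    compounds = pd.DataFrame(
        {
            "compound_id": [f"c{i + 1:06d}" for i in range(n_compounds)],
            "efret_1": e1, "efret_2": e2,
            "d1_intensity": d1, "d2_intensity": d2,
            "max_background": config.background_level * bg_mult,
            "donor_multiplier": donor_mult, "background_multiplier": bg_mult,
        }
    )
    amp0 = np.full(n_dmso_pairs, config.donor_amplitude)
    dd = well_block(amp0)
    dda = well_block(amp0 * quench0)
    dmso = pd.DataFrame(
        {
            "efret": (1.0 - dda / dd) * 100.0,
            "d_intensity": dd,
            "background": np.full(n_dmso_pairs, config.background_level),
        }
    )
    return compounds, dmso


# ---------------------------------------------------------------------------
# synthetic solution spectra
# ---------------------------------------------------------------------------


def synthetic_emission_spectrum(
    peak_amplitude: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    sample_kind: str = "D",
    rnc_concentration_nM: float | None = None,
    rng: np.random.Generator | None = None,
) -> EmissionSpectrum:
    """CFP-like emission spectrum on 450-600 nm at 1-nm steps.

    Two-lobed band (main peak ~475 nm, shoulder ~503 nm) scaled to
    ``peak_amplitude`` at the maximum, plus a flat baseline and optional
    Gaussian noise.
    """
    wl = np.arange(450.0, 601.0)
    shape = np.exp(-0.5 * ((wl - 475.0) / 14.0) ** 2) + 0.55 * np.exp(
        -0.5 * ((wl - 503.0) / 20.0) ** 2
    )
    shape /= shape.max()
    intens = baseline + peak_amplitude * shape
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        intens = intens + rng.normal(0.0, noise_sd, wl.shape)
    return EmissionSpectrum(
        wl, np.clip(intens, 0, None), sample_kind=sample_kind,
        rnc_concentration_nM=rnc_concentration_nM,
    )


def synthetic_solution_set(
    true_efret: float,
    conc_d_nM: float = 2.0,
    conc_da_nM: float = 2.0,
    peak_d: float = 100.0,
    blank_peak: float = 8.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Matched D / D+A / blank spectra whose corrected ratio encodes true E.

    The donor sample's blank-subtracted peak is proportional to its
    concentration; the D+A sample's is additionally quenched by (1 − E/100).
    Returns ``(d, da, (blank_d, blank_da))`` ready for solution FRET.
    """
    rng = np.random.default_rng(seed)
    quench = 1.0 - true_efret / 100.0
    d = synthetic_emission_spectrum(
        blank_peak + peak_d * conc_d_nM, noise_sd=noise_sd, sample_kind="D",
        rnc_concentration_nM=conc_d_nM, rng=rng,
    )
    da = synthetic_emission_spectrum(
        blank_peak + peak_d * conc_da_nM * quench, noise_sd=noise_sd, sample_kind="DA",
        rnc_concentration_nM=conc_da_nM, rng=rng,
    )
    blank_d = synthetic_emission_spectrum(
        blank_peak, noise_sd=noise_sd, sample_kind="BLANK_D", rng=rng
    )
    blank_da = synthetic_emission_spectrum(
        blank_peak, noise_sd=noise_sd, sample_kind="BLANK_DA", rng=rng
    )
    return d, da, (blank_d, blank_da)
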