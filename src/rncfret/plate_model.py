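"""Plates, wells, images and the tabular files the screening pipeline touches.

The screen runs in microtiter plates (96, 384 or 1,536 wells).  Each FRET
measurement comes from a *pair* of wells: one carrying donor-only (D) beads
and one carrying donor+acceptor (D+A) beads.  Compounds are tested in
duplicate, i.e. one compound occupies a quartet of wells (two D/D+A pairs),
so a 1,536-well plate holds up to 320 compounds plus vehicle (DMSO) control
pairs.  This module defines the layout model, well-name arithmetic, the
plate-map CSV dialect, the per-bead / per-well / per-compound result table
schemas, and TIFF readers/writers for single-channel well images.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PLATE_SHAPES",
    "LayoutError",
    "WellKind",
    "WellRole",
    "PlateLayout",
    "WellImage",
    "WellMeasurement",
    "well_name_to_index",
    "index_to_well_name",
    "all_well_names",
    "parse_plate_map",
    "write_plate_map",
    "default_layout_1536",
    "BEAD_COLUMNS",
    "WELL_COLUMNS",
    "COMPOUND_COLUMNS",
    "PAIR_COLUMNS",
    "write_results_tables",
    "read_bead_table",
    "read_well_table",
    "read_compound_table",
    "read_pair_table",
    "write_well_image",
    "read_well_image",
]

#: rows x columns for each supported plate format
PLATE_SHAPES: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

_WELL_RE = re.compile(r"^([A-Z]{1,2})(\d{1,2})$")


class LayoutError(ValueError):
    """Raised when a plate layout or well name violates the plate model."""


def _row_labels(n_rows: int) -> list[str]:
    """Row letters A..Z then AA, AB, ... (AF is row 32 of a 1,536 plate)."""
    labels = []
    for i in range(n_rows):
        if i < 26:
            labels.append(chr(ord("A") + i))
        else:
            labels.append("A" + chr(ord("A") + i - 26))
    return labels


def well_name_to_index(name: str, plate_format: int) -> tuple[int, int]:
    """Map a well name like ``"A01"`` to 0-based (row, column) indices.

    Inverse of :func:`index_to_well_name`; row-major ordering.
    """
    if plate_format not in PLATE_SHAPES:
        raise LayoutError(f"unknown plate format {plate_format!r}")
    n_rows, n_cols = PLATE_SHAPES[plate_format]
    m = _WELL_RE.match(str(name).strip().upper())
    if not m:
        raise LayoutError(f"malformed well name {name!r}")
    row_label, col_str = m.groups()
    labels = _row_labels(n_rows)
    if row_label not in labels:
        raise LayoutError(
            f"row {row_label!r} outside format {plate_format} (rows {labels[0]}-{labels[-1]})"
        )
    col = int(col_str)
    if not 1 <= col <= n_cols:
        raise LayoutError(f"column {col} outside format {plate_format} (1-{n_cols})")
    return labels.index(row_label), col - 1


def index_to_well_name(row: int, col: int, plate_format: int) -> str:
    if plate_format not in PLATE_SHAPES:
        raise LayoutError(f"unknown plate format {plate_format!r}")
    n_rows, n_cols = PLATE_SHAPES[plate_format]
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise LayoutError(f"index ({row}, {col}) outside format {plate_format}")
    return f"{_row_labels(n_rows)[row]}{col + 1:02d}"


def all_well_names(plate_format: int) -> list[str]:
    """All well names of a format in row-major order."""
    n_rows, n_cols = PLATE_SHAPES[plate_format]
    return [index_to_well_name(r, c, plate_format) for r in range(n_rows) for c in range(n_cols)]


def well_sort_key(name: str, plate_format: int) -> int:
    r, c = well_name_to_index(name, plate_format)
    return r * PLATE_SHAPES[plate_format][1] + c


class WellKind(str, enum.Enum):
    """Role of a well in the paired donor / donor+acceptor design."""

    D = "D"                  # compound well, donor-only beads
    DA = "DA"                # compound well, donor+acceptor beads
    BLANK_D = "BLANK_D"      # non-fluorescent control translation (donor side)
    BLANK_DA = "BLANK_DA"
    DMSO_D = "DMSO_D"        # vehicle (0.1% DMSO) baseline control
    DMSO_DA = "DMSO_DA"
    BUFFER = "BUFFER"        # buffer only
    EMPTY = "EMPTY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_COMPOUND_KINDS = {WellKind.D, WellKind.DA}
_DMSO_KINDS = {WellKind.DMSO_D, WellKind.DMSO_DA}
#: well kinds that receive beads when a plate is prepared
BEAD_KINDS = _COMPOUND_KINDS | _DMSO_KINDS | {WellKind.BLANK_D, WellKind.BLANK_DA}
#: donor-side kinds (the denominator channel of the FRET ratio)
DONOR_KINDS = {WellKind.D, WellKind.DMSO_D, WellKind.BLANK_D}


@dataclass(frozen=True)
class WellRole:
    """What a single well contains.

    ``compound_id`` is present iff the well is a compound well (kind D/DA);
    ``dose_uM`` only together with a compound.  ``pair_id`` names the D/D+A
    pair a well belongs to (used for compound duplicates and DMSO pairs).
    """

    kind: WellKind
    compound_id: str | None = None
    dose_uM: float | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        kind = WellKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in _COMPOUND_KINDS:
            if not self.compound_id:
                raise LayoutError(f"compound well of kind {kind} requires a compound_id")
        elif self.compound_id is not None:
            raise LayoutError(f"compound_id not allowed for kind {kind}")
        if self.dose_uM is not None and self.compound_id is None:
            raise LayoutError("dose_uM only allowed together with compound_id")


@dataclass
class PlateLayout:
    """Well roles, compound quartets and DMSO pairs for one plate.

    ``wells`` maps well name -> :class:`WellRole` for every non-EMPTY well;
    unlisted wells are implicitly EMPTY.  Each compound maps to exactly four
    distinct wells ``(D1, DA1, D2, DA2)`` (duplicate paired design).
    """

    plate_format: int
    wells: dict[str, WellRole]
    compound_quartets: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)
    dmso_pairs: list[tuple[str, str]] = field(default_factory=list)
    plate_id: str = "plate"

    # -- construction ---------------------------------------------------
    @classmethod
    def from_wells(
        cls, plate_format: int, wells: Mapping[str, WellRole], plate_id: str = "plate"
    ) -> "PlateLayout":
        """Build a layout, deriving quartets and DMSO pairs from the roles."""
        wells = dict(wells)
        quartets = _derive_quartets(plate_format, wells)
        dmso_pairs = _derive_pairs(
            plate_format, wells, WellKind.DMSO_D, WellKind.DMSO_DA, "DMSO"
        )
        layout = cls(plate_format, wells, quartets, dmso_pairs, plate_id)
        layout.validate()
        return layout

    # -- queries --------------------------------------------------------
    def role_of(self, well: str) -> WellRole:
        well_name_to_index(well, self.plate_format)  # validates the name
        return self.wells.get(well, WellRole(WellKind.EMPTY))

    @property
    def n_addressable_wells(self) -> int:
        n_rows, n_cols = PLATE_SHAPES[self.plate_format]
        return n_rows * n_cols

    def compound_pairs(self, compound_id: str) -> list[tuple[str, str]]:
        d1, da1, d2, da2 = self.compound_quartets[compound_id]
        return [(d1, da1), (d2, da2)]

    def wells_of_kind(self, *kinds: WellKind) -> list[str]:
        kindset = set(kinds)
        names = [w for w, r in self.wells.items() if r.kind in kindset]
        names.sort(key=lambda w: well_sort_key(w, self.plate_format))
        return names

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.plate_format not in PLATE_SHAPES:
            raise LayoutError(f"unknown plate format {self.plate_format!r}")
        problems: list[str] = []
        for w in self.wells:
            try:
                well_name_to_index(w, self.plate_format)
            except LayoutError as exc:
                problems.append(str(exc))
        by_compound: dict[str, list[str]] = {}
        for w, role in self.wells.items():
            if role.kind in _COMPOUND_KINDS:
                by_compound.setdefault(role.compound_id, []).append(w)
        for cid, ws in sorted(by_compound.items()):
            kinds = [self.wells[w].kind for w in ws]
            if len(ws) != 4 or len(set(ws)) != 4:
                problems.append(f"compound {cid!r} maps to {len(ws)} wells, expected 4")
            elif kinds.count(WellKind.D) != 2 or kinds.count(WellKind.DA) != 2:
                problems.append(f"compound {cid!r} must have two D and two DA wells")
        if set(by_compound) != set(self.compound_quartets):
            problems.append("compound_quartets inconsistent with well roles")
        for cid, quartet in self.compound_quartets.items():
            if len(set(quartet)) != 4:
                problems.append(f"compound {cid!r} quartet wells not distinct")
            for w in quartet:
                if self.wells.get(w) is None or self.wells[w].compound_id != cid:
                    problems.append(f"quartet well {w} does not belong to compound {cid!r}")
        dmso_wells = [w for pair in self.dmso_pairs for w in pair]
        if len(set(dmso_wells)) != len(dmso_wells):
            problems.append("DMSO pairs share wells")
        for d, da in self.dmso_pairs:
            if self.wells.get(d, WellRole(WellKind.EMPTY)).kind is not WellKind.DMSO_D:
                problems.append(f"DMSO pair well {d} is not DMSO_D")
            if self.wells.get(da, WellRole(WellKind.EMPTY)).kind is not WellKind.DMSO_DA:
                problems.append(f"DMSO pair well {da} is not DMSO_DA")
        if set(dmso_wells) & set(w for q in self.compound_quartets.values() for w in q):
            problems.append("DMSO wells overlap compound wells")
        if self.plate_format == 1536 and len(self.compound_quartets) > 320:
            problems.append(
                f"{len(self.compound_quartets)} compounds exceed the 320-compound "
                "capacity of a 1,536-well plate"
            )
        if len(self.wells) > self.n_addressable_wells:
            problems.append("more listed wells than addressable wells")
        if problems:
            raise LayoutError("; ".join(problems))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateLayout):
            return NotImplemented
        return (
            self.plate_format == other.plate_format
            and self.plate_id == other.plate_id
            and self.wells == other.wells
            and self.compound_quartets == other.compound_quartets
            and sorted(self.dmso_pairs) == sorted(other.dmso_pairs)
        )


def _derive_pairs(
    plate_format: int,
    wells: Mapping[str, WellRole],
    d_kind: WellKind,
    da_kind: WellKind,
    label: str,
) -> list[tuple[str, str]]:
    d_wells = sorted(
        (w for w, r in wells.items() if r.kind is d_kind),
        key=lambda w: well_sort_key(w, plate_format),
    )
    da_wells = sorted(
        (w for w, r in wells.items() if r.kind is da_kind),
        key=lambda w: well_sort_key(w, plate_format),
    )
    if len(d_wells) != len(da_wells):
        raise LayoutError(
            f"{label}: {len(d_wells)} donor wells vs {len(da_wells)} donor+acceptor wells"
        )
    by_pair_id: dict[str, dict[str, str]] = {}
    have_ids = all(wells[w].pair_id for w in d_wells + da_wells) and d_wells
    if have_ids:
        for w in d_wells + da_wells:
            side = "d" if wells[w].kind is d_kind else "da"
            entry = by_pair_id.setdefault(wells[w].pair_id, {})
            if side in entry:
                raise LayoutError(f"{label}: duplicate {side} well for pair {wells[w].pair_id!r}")
            entry[side] = w
        pairs = []
        for pid in sorted(by_pair_id):
            entry = by_pair_id[pid]
            if set(entry) != {"d", "da"}:
                raise LayoutError(f"{label}: pair {pid!r} is incomplete")
            pairs.append((entry["d"], entry["da"]))
        return pairs
    return list(zip(d_wells, da_wells))


def _derive_quartets(
    plate_format: int, wells: Mapping[str, WellRole]
) -> dict[str, tuple[str, str, str, str]]:
    by_compound: dict[str, dict[str, WellRole]] = {}
    for w, role in wells.items():
        if role.kind in _COMPOUND_KINDS:
            by_compound.setdefault(role.compound_id, {})[w] = role
    quartets: dict[str, tuple[str, str, str, str]] = {}
    offenders: list[str] = []
    for cid in sorted(by_compound):
        sub = by_compound[cid]
        kinds = [r.kind for r in sub.values()]
        if len(sub) != 4 or kinds.count(WellKind.D) != 2 or kinds.count(WellKind.DA) != 2:
            offenders.append(f"{cid!r} ({len(sub)} wells)")
            continue
        pairs = _derive_pairs(plate_format, sub, WellKind.D, WellKind.DA, f"compound {cid!r}")
        (d1, da1), (d2, da2) = sorted(pairs, key=lambda p: well_sort_key(p[0], plate_format))
        quartets[cid] = (d1, da1, d2, da2)
    if offenders:
        raise LayoutError(
            "compounds without exactly 2 D + 2 DA wells: " + ", ".join(offenders)
        )
    return quartets


# ---------------------------------------------------------------------------
# plate-map CSV dialect: well,role,compound_id,dose_uM,pair_id
# ---------------------------------------------------------------------------

PLATE_MAP_COLUMNS = ["well", "role", "compound_id", "dose_uM", "pair_id"]


def parse_plate_map(
    source, plate_format: int, plate_id: str = "plate"
) -> PlateLayout:
    """Read a plate-map CSV (or DataFrame) into a validated :class:`PlateLayout`.

    Expected columns: ``well,role,compound_id,dose_uM,pair_id`` with one row
    per non-EMPTY well; unlisted wells are EMPTY.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype={"well": str, "role": str, "compound_id": str, "pair_id": str})
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"plate map missing columns: {missing}")
    dupes = df["well"][df["well"].duplicated()].tolist()
    if dupes:
        raise LayoutError(f"duplicate well rows: {sorted(set(dupes))}")
    wells: dict[str, WellRole] = {}
    for row in df.itertuples(index=False):
        kind = WellKind(str(row.role))
        if kind is WellKind.EMPTY:
            continue
        cid = None if pd.isna(row.compound_id) or row.compound_id == "" else str(row.compound_id)
        dose = None if pd.isna(row.dose_uM) else float(row.dose_uM)
        pid = None if pd.isna(row.pair_id) or row.pair_id == "" else str(row.pair_id)
        wells[str(row.well)] = WellRole(kind, cid, dose, pid)
    return PlateLayout.from_wells(plate_format, wells, plate_id=plate_id)


def layout_to_frame(layout: PlateLayout) -> pd.DataFrame:
    rows = []
    for w in sorted(layout.wells, key=lambda w: well_sort_key(w, layout.plate_format)):
        r = layout.wells[w]
        rows.append(
            {
                "well": w,
                "role": r.kind.value,
                "compound_id": r.compound_id,
                "dose_uM": r.dose_uM,
                "pair_id": r.pair_id,
            }
        )
    return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def write_plate_map(layout: PlateLayout, path) -> None:
    layout_to_frame(layout).to_csv(path, index=False)


def default_layout_1536(
    n_compounds: int = 320,
    n_dmso_pairs: int = 32,
    plate_id: str = "plate",
    dose_uM: float | None = None,
    compound_prefix: str = "c",
) -> PlateLayout:
    """The shipped 1,536-well arrangement.

    Compounds occupy columns 1-40 in quartets of adjacent wells
    ``(D, DA, D, DA)`` — 10 compounds per row, 32 rows = 320 compounds.
    DMSO control pairs sit in columns 41-42 (one pair per row, 32 pairs);
    remaining wells (columns 43-48 and unused compound/DMSO slots) are BUFFER.
    """
    if not 0 <= n_compounds <= 320:
        raise LayoutError("a 1,536 plate holds at most 320 compound quartets")
    if not 0 <= n_dmso_pairs <= 32:
        raise LayoutError("the default layout holds at most 32 DMSO pairs")
    wells: dict[str, WellRole] = {}
    width = len(str(max(n_compounds, 1)))
    for i in range(n_compounds):
        row, block = divmod(i, 10)
        cid = f"{compound_prefix}{i + 1:0{max(width, 4)}d}"
        cols = [block * 4 + j for j in range(4)]
        names = [index_to_well_name(row, c, 1536) for c in cols]
        for rep, (d, da) in enumerate(((names[0], names[1]), (names[2], names[3])), start=1):
            pid = f"{cid}_{rep}"
            wells[d] = WellRole(WellKind.D, cid, dose_uM, pid)
            wells[da] = WellRole(WellKind.DA, cid, dose_uM, pid)
    for i in range(n_dmso_pairs):
        pid = f"dmso_{i + 1:02d}"
        wells[index_to_well_name(i, 40, 1536)] = WellRole(WellKind.DMSO_D, pair_id=pid)
        wells[index_to_well_name(i, 41, 1536)] = WellRole(WellKind.DMSO_DA, pair_id=pid)
    for name in all_well_names(1536):
        if name not in wells:
            wells[name] = WellRole(WellKind.BUFFER)
    return PlateLayout.from_wells(1536, wells, plate_id=plate_id)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass
class WellImage:
    """Single-channel grayscale image of (part of) one well.

    ``pixel_size`` is the physical pixel pitch in µm; physical positions are
    measured in µm from the centre of the top-left pixel, row-major, 0-based.
    """

    pixels: np.ndarray
    pixel_size: float = 0.325
    well_name: str = ""
    channel: str = "donor"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 64:
            raise ValueError("well image must be 2-D with dimensions >= 64x64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.min(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size ** 2


@dataclass
class WellMeasurement:
    """Per-well summary over beads that passed all selection gates."""

    well_name: str
    n_beads: int
    mean_intensity: float  # AU/µm², background-subtracted; NaN when n_beads == 0
    sd_intensity: float
    background: float  # AU per pixel

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if self.n_beads == 0 and not math.isnan(self.mean_intensity):
            raise ValueError("mean_intensity undefined (NaN) when no beads passed")
        if self.sd_intensity < 0:
            raise ValueError("sd_intensity must be >= 0")


def write_well_image(image: WellImage, directory, plate_id: str) -> Path:
    """Write a well image as 16-bit grayscale TIFF ``<plate_id>_<well>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{plate_id}_{image.well_name}.tif"
    data = np.asarray(image.pixels)
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_well_image(path, pixel_size: float = 0.325, channel: str = "donor") -> WellImage:
    path = Path(path)
    data = tifffile.imread(path)
    well = path.stem.rsplit("_", 1)[-1]
    return WellImage(data, pixel_size=pixel_size, well_name=well, channel=channel)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

BEAD_COLUMNS = [
    "plate_id", "well", "bead_id", "x_um", "y_um", "diameter_um",
    "circularity", "intensity_per_um2", "passed", "reject_reason",
]
WELL_COLUMNS = ["plate_id", "well", "n_beads", "mean_intensity", "sd_intensity", "background"]
COMPOUND_COLUMNS = [
    "plate_id", "compound_id", "efret_1", "efret_2", "efret_avg",
    "z_score", "qc_donor", "qc_background", "hit", "direction",
]
PAIR_COLUMNS = ["plate_id", "pair_id", "d_well", "da_well", "F_D", "F_DA", "efret"]

_STR_COLUMNS = {"plate_id", "well", "compound_id", "reject_reason", "direction",
                "pair_id", "d_well", "da_well"}


def _check_schema(df: pd.DataFrame, columns: Sequence[str], name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")
    return df.loc[:, list(columns)]


def _read_table(path, columns: Sequence[str], name: str) -> pd.DataFrame:
    dtype = {c: str for c in columns if c in _STR_COLUMNS}
    df = pd.read_csv(path, dtype=dtype)
    return _check_schema(df, columns, name)


def read_bead_table(path) -> pd.DataFrame:
    return _read_table(path, BEAD_COLUMNS, "per-bead")


def read_well_table(path) -> pd.DataFrame:
    return _read_table(path, WELL_COLUMNS, "per-well")


def read_compound_table(path) -> pd.DataFrame:
    return _read_table(path, COMPOUND_COLUMNS, "per-compound")


def read_pair_table(path) -> pd.DataFrame:
    return _read_table(path, PAIR_COLUMNS, "per-pair")


def write_results_tables(
    beads: pd.DataFrame,
    wells: pd.DataFrame,
    compounds: pd.DataFrame,
    out_dir,
) -> dict[str, Path]:
    """Write the three fixed-schema result tables; round-trips losslessly.

    Raises if a bead references a well absent from the per-well table.
    """
    beads = _check_schema(beads, BEAD_COLUMNS, "per-bead")
    wells = _check_schema(wells, WELL_COLUMNS, "per-well")
    compounds = _check_schema(compounds, COMPOUND_COLUMNS, "per-compound")
    known = set(zip(wells["plate_id"], wells["well"]))
    bad = sorted(
        {(p, w) for p, w in zip(beads["plate_id"], beads["well"]) if (p, w) not in known}
    )
    if bad:
        raise ValueError(f"beads reference unknown wells: {bad[:10]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("beads", beads), ("wells", wells), ("compounds", compounds)):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
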