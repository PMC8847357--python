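"""Shared fixtures: reduced-scale configs and small layouts for fast tests.

Unit tests that exercise mechanics (I/O, determinism, gating logic) run on a
512x512 field with ~19 beads; statistical and closure properties use the
full default configuration, which encodes the screen's operating conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from rncfret.plate_model import PlateLayout, WellKind, WellRole, index_to_well_name
from rncfret.synthetic_screen import SimulationConfig


@pytest.fixture
def fast_cfg() -> SimulationConfig:
    """Small imaged field (166 µm)², ~19 beads/image; all else default."""
    return dataclasses.replace(
        SimulationConfig(), image_shape=(512, 512), beads_per_well=100
    )


def pair_layout(
    n_pairs: int, plate_format: int = 1536, plate_id: str = "pairs"
) -> PlateLayout:
    """A layout holding only DMSO-type D/D+A control pairs, two wells each."""
    wells: dict[str, WellRole] = {}
    n_cols = {96: 12, 384: 24, 1536: 48}[plate_format]
    per_row = n_cols // 2
    for i in range(n_pairs):
        row, slot = divmod(i, per_row)
        pid = f"pair_{i + 1:02d}"
        wells[index_to_well_name(row, 2 * slot, plate_format)] = WellRole(
            WellKind.DMSO_D, pair_id=pid
        )
        wells[index_to_well_name(row, 2 * slot + 1, plate_format)] = WellRole(
            WellKind.DMSO_DA, pair_id=pid
        )
    return PlateLayout.from_wells(plate_format, wells, plate_id=plate_id)
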