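"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import statistics

import pytest

from sphscreen import PlateLayout, WormRecord


def make_layout(
    plate_id: str = "P1",
    n_clones: int = 8,
    repeat_index: int = 1,
    drop_role: str | None = None,
) -> PlateLayout:
    """A small plate: controls at A1/H12 (empty), D6 (up), E7 (down),
    experimental clones filling from A2 onward."""
    assignments = {
        "A1": ("L4440", "empty_vector"),
        "H12": ("L4440", "empty_vector"),
        "D6": ("unc-11", "up_control"),
        "E7": ("gfp", "down_control"),
    }
    if drop_role:
        assignments = {
            w: (c, r) for w, (c, r) in assignments.items() if r != drop_role
        }
    wells = [
        f"{row}{col}"
        for row in "ABCDEFGH"
        for col in range(1, 13)
        if f"{row}{col}" not in ("A1", "H12", "D6", "E7")
    ]
    for i in range(n_clones):
        assignments[wells[i]] = (f"c{i + 1:03d}", "experimental")
    return PlateLayout(plate_id=plate_id, assignments=assignments,
                       repeat_index=repeat_index)


def records_with_rfs(
    plate_id: str, well: str, rfs_values: list[float], ext: float = 256.0
) -> list[WormRecord]:
    """Worm records whose per-worm RFS are exactly ``rfs_values``."""
    return [
        WormRecord(plate_id, well, tof=ext * 0.45, ext=ext, green=ext * 2.0 ** v)
        for v in rfs_values
    ]


def brute_force_robust_z(values: list[float]) -> list[float]:
    """Independent median/MAD computation via the statistics module."""
    med = statistics.median(values)
    mad = statistics.median([abs(v - med) for v in values])
    return [(v - med) / mad for v in values]


@pytest.fixture
def small_layout() -> PlateLayout:
    return make_layout()
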