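"""Normalization: RFS, well medians, robust Z-scores, clone scoring."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sphscreen import (
    DegenerateDispersionError,
    GeneratorConfig,
    PlateFailureError,
    WellSummary,
    generate_screen,
    normalize_plate,
    robust_z,
    score_clone,
    score_clones,
    summarize_plate,
    summarize_well,
    worm_rfs,
)
from sphscreen.normalize import MAD_NORMAL_CONSISTENCY

from .conftest import brute_force_robust_z, make_layout, records_with_rfs


class TestWormRFS:
    @pytest.mark.parametrize(
        "green,ext,expected",
        [(1024, 256, 2.0), (100, 100, 0.0), (50, 200, -2.0)],
    )
    def test_log2_ratio(self, green, ext, expected):
        assert worm_rfs(green, ext) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("green,ext", [(0, 100), (100, 0), (100, -5)])
    def test_domain_errors(self, green, ext):
        with pytest.raises(ValueError):
            worm_rfs(green, ext)

    def test_joint_scaling_invariance_and_green_shift(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            green, ext, c = rng.uniform(1, 1000, 3)
            assert worm_rfs(c * green, c * ext) == pytest.approx(
                worm_rfs(green, ext), abs=1e-9
            )
            assert worm_rfs(c * green, ext) == pytest.approx(
                worm_rfs(green, ext) + math.log2(c), abs=1e-9
            )


class TestSummarizeWell:
    def test_odd_count_median(self, small_layout):
        recs = records_with_rfs("P1", "A2", [1.0, 2.0, 3.0, 1.5, 2.5])
        s = summarize_well(recs, small_layout)
        assert s.median_rfs == pytest.approx(2.0)
        assert s.n_worms == 5
        assert s.clone_id == "c001"

    def test_even_count_median_is_mean_of_central_pair(self, small_layout):
        recs = records_with_rfs("P1", "A2", [1.0, 2.0, 3.0, 10.0, 0.5, 2.2])
        s = summarize_well(recs, small_layout, min_worms=5)
        # sorted: 0.5 1 2 2.2 3 10 -> (2 + 2.2)/2
        assert s.median_rfs == pytest.approx(2.1)

    def test_below_min_worms_has_no_median_and_is_flagged(self, small_layout):
        recs = records_with_rfs("P1", "A2", [1.0, 2.0])
        s = summarize_well(recs, small_layout, min_worms=5)
        assert s.median_rfs is None
        assert "low_count" in s.flags

    def test_well_absent_from_layout_is_structural_error(self, small_layout):
        recs = records_with_rfs("P1", "G11", [1.0] * 5)
        with pytest.raises(ValueError, match="absent"):
            summarize_well(recs, small_layout)

    def test_summarize_plate_emits_zero_count_wells(self, small_layout):
        recs = records_with_rfs("P1", "A2", [1.0] * 6)
        summaries = summarize_plate(recs, small_layout)
        by_well = {s.well: s for s in summaries}
        assert by_well["A2"].n_worms == 6
        assert by_well["A3"].n_worms == 0  # assigned but no objects
        assert by_well["A3"].median_rfs is None


class TestRobustZ:
    def test_hand_example(self):
        assert robust_z([1, 2, 3, 4, 5]).tolist() == [-2, -1, 0, 1, 2]

    def test_value_at_median_scores_zero(self):
        z = robust_z([3.0, 7.0, 5.0, 9.0, 1.0])
        assert z[2] == 0.0

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDispersionError):
            robust_z([5, 5, 5, 5])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            robust_z([1.0, 2.0])

    def test_scaled_option_divides_by_consistency_factor(self):
        vals = [1.0, 2.0, 4.0, 8.0, 9.0]
        np.testing.assert_allclose(
            robust_z(vals, scaled=True) * MAD_NORMAL_CONSISTENCY,
            robust_z(vals),
            rtol=1e-12,
        )

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(3, 40))
            vals = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n)
            vals = [float(v) for v in vals]
            try:
                expected = brute_force_robust_z(vals)
            except ZeroDivisionError:
                continue
            np.testing.assert_allclose(robust_z(vals), expected, atol=1e-12)


def _plate_summaries(rfs_by_well: dict[str, float], layout) -> list[WellSummary]:
    out = []
    for well, (clone, role) in layout.assignments.items():
        if well in rfs_by_well:
            out.append(
                WellSummary(layout.plate_id, well, clone, role, 50,
                            rfs_by_well[well])
            )
    return out


class TestNormalizePlate:
    def test_median_well_scores_zero(self):
        layout = make_layout("P1", n_clones=91)
        wells = layout.wells_with_role("experimental")
        summaries = _plate_summaries(
            {w: float(i + 1) for i, w in enumerate(wells)}, layout
        )
        normalized, stats = normalize_plate(summaries)
        mid = [s for s in normalized if s.median_rfs == 46.0]
        assert mid and mid[0].rz == 0.0
        assert not stats.degenerate

    def test_location_invariance(self):
        layout = make_layout("P1", n_clones=20)
        rng = np.random.default_rng(3)
        wells = layout.wells_with_role("experimental")
        base = {w: float(v) for w, v in zip(wells, rng.normal(1, 0.4, len(wells)))}
        shifted = {w: v + 1.7 for w, v in base.items()}
        rz_a = [s.rz for s in normalize_plate(_plate_summaries(base, layout))[0]]
        rz_b = [s.rz for s in normalize_plate(_plate_summaries(shifted, layout))[0]]
        np.testing.assert_allclose(rz_a, rz_b, atol=1e-12)

    def test_controls_scored_but_excluded_from_statistics(self):
        layout = make_layout("P1", n_clones=20)
        rng = np.random.default_rng(11)
        wells = layout.wells_with_role("experimental")
        exp = {w: float(v) for w, v in zip(wells, rng.normal(1, 0.3, len(wells)))}
        # up control planted log2(6) above the plate median
        values = dict(exp)
        exp_vals = sorted(exp.values())
        med = float(np.median(exp_vals))
        values["D6"] = med + math.log2(6)
        values["A1"] = med
        values["H12"] = med
        values["E7"] = med - 1.0
        normalized, stats = normalize_plate(_plate_summaries(values, layout))
        mad = float(np.median(np.abs(np.array(exp_vals) - med)))
        up = next(s for s in normalized if s.well == "D6")
        assert up.rz == pytest.approx(math.log2(6) / mad, rel=1e-12)
        # control values did not move the statistics
        assert stats.median == pytest.approx(med)
        assert stats.mad == pytest.approx(mad)

    def test_experimental_median_rz_invariants(self):
        # For every normalized plate: median(rZ) = 0 and median(|rZ|) = 1.
        layout = make_layout("P1", n_clones=91)
        rng = np.random.default_rng(5)
        wells = layout.wells_with_role("experimental")
        vals = {w: float(v) for w, v in zip(wells, rng.normal(0, 1, len(wells)))}
        normalized, _ = normalize_plate(_plate_summaries(vals, layout))
        rz = np.array(
            [s.rz for s in normalized if s.role == "experimental"]
        )
        assert float(np.median(rz)) == pytest.approx(0.0, abs=1e-12)
        assert float(np.median(np.abs(rz))) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_usable_wells_is_plate_failure(self):
        layout = make_layout("P1", n_clones=5)
        wells = layout.wells_with_role("experimental")
        summaries = _plate_summaries({w: 1.0 for w in wells}, layout)
        with pytest.raises(PlateFailureError, match="P1"):
            normalize_plate(summaries, min_experimental=8)

    def test_zero_mad_falls_back_to_centering_and_flags(self):
        layout = make_layout("P1", n_clones=10)
        wells = layout.wells_with_role("experimental")
        vals = {w: 1.0 for w in wells}
        vals[wells[0]] = 3.0  # a single hit on an otherwise flat plate
        normalized, stats = normalize_plate(_plate_summaries(vals, layout))
        assert stats.degenerate
        by_well = {s.well: s for s in normalized}
        assert by_well[wells[0]].rz == pytest.approx(2.0)  # centered, scale 1
        assert all("degenerate_mad" in s.flags for s in normalized)

    def test_plate_offset_does_not_change_rz(self):
        # Normalization is per plate: a log2 offset applied to one
        # plate's green signals shifts its medians but not its rZ.
        cfg = GeneratorConfig(n_plates=2, clones_per_plate=30, noise_sd=0.2,
                              plate_offset_sd=0.0, sterile_fraction=0.0, seed=9)
        records, layouts, _ = generate_screen(cfg)
        layout = layouts[0]

        def rz_for(records):
            summaries = summarize_plate(
                [r for r in records if r.plate_id == layout.plate_id], layout
            )
            normalized, _ = normalize_plate(summaries)
            return {s.well: s.rz for s in normalized if s.rz is not None}

        base = rz_for(records)
        shifted_records = [
            r.__class__(r.plate_id, r.well, r.tof, r.ext, r.green * 2.0 ** 0.8)
            if r.plate_id == layout.plate_id
            else r
            for r in records
        ]
        shifted = rz_for(shifted_records)
        for well in base:
            assert shifted[well] == pytest.approx(base[well], abs=1e-9)


class TestCloneScore:
    def _summary(self, plate, rfs, rz=None, flags=()):
        return WellSummary(plate, "A2", "c001", "experimental", 50, rfs, rz,
                           set(flags))

    def test_mean_rz_of_two_repeats(self):
        s = score_clone(
            [self._summary("P1R1", 3.0, 1.2), self._summary("P1R2", 2.0, 0.8)]
        )
        assert s.mean_rz == pytest.approx(1.0)
        assert s.repeat_fold_change == pytest.approx(2.0)  # 2^|3-2|
        assert s.status == {"ok"}

    def test_single_repeat_flagged_missing(self):
        s = score_clone([self._summary("P1R1", 3.0, 1.2)])
        assert s.mean_rz is None
        assert "missing_repeat" in s.status

    def test_sterile_repeat_excluded_and_flagged(self):
        s = score_clone(
            [
                self._summary("P1R1", 3.0, 1.2, flags={"sterile"}),
                self._summary("P1R2", 2.0, 0.8),
            ]
        )
        assert "sterile" in s.status
        assert s.rfs_repeats == [2.0]

    def test_score_clones_groups_by_repeat_order(self):
        summaries = [
            self._summary("P1R2", 2.0, 0.8),
            self._summary("P1R1", 3.0, 1.2),
        ]
        (score,) = score_clones(summaries, {"P1R1": 1, "P1R2": 2})
        assert score.rfs_repeats == [3.0, 2.0]
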