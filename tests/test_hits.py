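"""Hit calling: tail selection, validation t-test, counterscreen, pipeline."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import t as t_dist

from sphscreen import (
    CloneScore,
    ConfigError,
    GeneratorConfig,
    HitRecord,
    InsufficientReplicatesError,
    PipelineConfig,
    ScreenData,
    apply_counterscreen,
    generate_screen,
    run_full_screen,
    secondary_ttest,
    select_tail_candidates,
)
from sphscreen.io import write_hit_table


def _score(clone, mean_rz, status=("ok",)):
    return CloneScore(clone, [mean_rz, mean_rz], [mean_rz, mean_rz],
                      mean_rz, 1.0, set(status))


class TestTailSelection:
    def test_five_percent_of_1000_is_25_per_side(self):
        scores = [_score(f"c{i:04d}", float(i)) for i in range(1000)]
        hits = select_tail_candidates(scores, tail_fraction=0.05)
        up = [h for h in hits if h.direction == "up"]
        down = [h for h in hits if h.direction == "down"]
        assert len(up) == 25 and len(down) == 25
        assert {h.clone_id for h in up} == {f"c{i:04d}" for i in range(975, 1000)}
        assert {h.clone_id for h in down} == {f"c{i:04d}" for i in range(25)}

    def test_planted_separation_recovers_exactly(self):
        rng = np.random.default_rng(2)
        scores = [_score(f"null{i:04d}", float(v))
                  for i, v in enumerate(rng.normal(0, 1, 950))]
        planted_up = [_score(f"up{i}", 20.0 + i) for i in range(25)]
        planted_down = [_score(f"dn{i}", -20.0 - i) for i in range(25)]
        hits = select_tail_candidates(scores + planted_up + planted_down,
                                      tail_fraction=0.05)
        assert {h.clone_id for h in hits} == (
            {s.clone_id for s in planted_up} | {s.clone_id for s in planted_down}
        )

    def test_flagged_clones_excluded_first(self):
        scores = [_score(f"c{i:03d}", float(i)) for i in range(100)]
        scores[99].status = {"sterile"}
        hits = select_tail_candidates(scores, tail_fraction=0.04)
        up = [h.clone_id for h in hits if h.direction == "up"]
        assert "c099" not in up and "c098" in up

    def test_ignore_flags_tolerates_named_status(self):
        scores = [_score(f"c{i:03d}", float(i)) for i in range(100)]
        scores[99].status = {"low_repeatability"}
        hits = select_tail_candidates(
            scores, tail_fraction=0.04, ignore_flags={"low_repeatability"}
        )
        assert "c099" in {h.clone_id for h in hits}

    def test_degenerate_distribution_is_deterministic_with_warning(self):
        scores = [_score(f"c{i}", 1.0) for i in range(20)]
        with pytest.warns(UserWarning, match="degenerate"):
            hits1 = select_tail_candidates(scores, tail_fraction=0.2)
        with pytest.warns(UserWarning):
            hits2 = select_tail_candidates(scores, tail_fraction=0.2)
        assert [(h.clone_id, h.direction) for h in hits1] == [
            (h.clone_id, h.direction) for h in hits2
        ]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6])
    def test_invalid_tail_fraction(self, bad):
        with pytest.raises(ConfigError):
            select_tail_candidates([_score("a", 1.0)], tail_fraction=bad)

    def test_shrinking_tail_never_grows_candidates(self):
        rng = np.random.default_rng(5)
        scores = [_score(f"c{i:03d}", float(v))
                  for i, v in enumerate(rng.normal(0, 1, 200))]
        wide = {h.clone_id for h in select_tail_candidates(scores, 0.10)}
        narrow = {h.clone_id for h in select_tail_candidates(scores, 0.04)}
        assert narrow <= wide


def _welch_one_tailed_oracle(a, b, direction):
    """Independent Welch computation from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return float(t_dist.sf(t, df) if direction == "up" else t_dist.cdf(t, df))


class TestSecondaryTTest:
    def test_identical_groups_with_spread_give_half(self):
        vals = [1.0, 1.2, 0.8, 1.0]
        assert secondary_ttest(vals, vals, "up") == pytest.approx(0.5)

    def test_clear_separation_matches_oracle(self):
        cand = [2.0, 2.1, 1.9, 2.0]
        ctrl = [1.0, 1.1, 0.9, 1.0]
        p = secondary_ttest(cand, ctrl, "up")
        assert p < 0.001
        assert p == pytest.approx(_welch_one_tailed_oracle(cand, ctrl, "up"),
                                  rel=1e-9)

    def test_wrong_sided_candidate_gives_large_p(self):
        cand = [0.5, 0.6, 0.4, 0.5]
        ctrl = [1.0, 1.1, 0.9, 1.0]
        assert secondary_ttest(cand, ctrl, "up") > 0.5
        assert secondary_ttest(cand, ctrl, "down") < 0.01

    def test_pooled_variance_option_matches_oracle_shape(self):
        cand = [2.0, 2.3, 1.8, 2.1]
        ctrl = [1.0, 1.2, 0.9, 1.1, 1.0, 0.8]
        p_welch = secondary_ttest(cand, ctrl, "up", equal_var=False)
        p_pooled = secondary_ttest(cand, ctrl, "up", equal_var=True)
        assert 0 < p_pooled < 0.05 and 0 < p_welch < 0.05
        assert p_welch != p_pooled

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            secondary_ttest([1.0], [1.0, 2.0], "up")

    def test_zero_variance_resolved_by_sign(self):
        assert secondary_ttest([2, 2], [1, 1], "up") == 0.0
        assert secondary_ttest([2, 2], [1, 1], "down") == 1.0
        assert secondary_ttest([1, 1], [1, 1], "up") == 0.5


class TestCounterscreen:
    def _hit(self, clone="c1", p=0.01):
        return HitRecord(clone, "up", 3.0, secondary_p=p)

    def test_rule_matrix(self):
        hits = [self._hit("a", 0.01), self._hit("b", 0.01), self._hit("c", 0.20)]
        out = apply_counterscreen(hits, {"a": 0.40, "b": 0.01, "c": 0.50})
        calls = {h.clone_id: h.call for h in out}
        assert calls == {
            "a": "validated",
            "b": "excluded_counterscreen",
            "c": "rejected",
        }

    def test_missing_counterscreen_never_silently_validated(self):
        (h,) = apply_counterscreen([self._hit("a", 0.01)], {})
        assert h.call == "candidate"
        assert "missing_counterscreen" in h.flags

    def test_shrinking_alpha_never_grows_validated_set(self):
        # Monotonicity holds for the secondary criterion; the
        # counterscreen p-values here sit well above every alpha so the
        # exclusion rule does not bind.
        sec_p = np.random.default_rng(6).random(100)
        counter = {f"c{i}": 0.5 for i in range(100)}
        prev = None
        for alpha in (0.10, 0.05, 0.01):
            hits = [self._hit(f"c{i}", float(p)) for i, p in enumerate(sec_p)]
            validated = {
                h.clone_id
                for h in apply_counterscreen(hits, counter, alpha=alpha)
                if h.call == "validated"
            }
            if prev is not None:
                assert validated <= prev
            prev = validated


def _small_screen(seed=0, noise=0.2):
    gen = GeneratorConfig(n_plates=2, clones_per_plate=40, noise_sd=noise,
                          plate_offset_sd=0.0, sterile_fraction=0.0, seed=seed)
    rec, lay, truth = generate_screen(gen)
    fu = GeneratorConfig(**{**gen.__dict__, "n_repeats": 4, "seed": seed + 1})
    rec2, lay2, _ = generate_screen(fu, clone_effects=dict(truth.clone_effects))
    cs = GeneratorConfig(**{**gen.__dict__, "n_repeats": 4, "seed": seed + 2})
    rec3, lay3, _ = generate_screen(
        cs, clone_effects={c: 1.0 for c in truth.clone_effects}
    )
    return (ScreenData(rec, lay), ScreenData(rec2, lay2),
            ScreenData(rec3, lay3), truth)


class TestFullScreen:
    def test_counterscreen_perturbers_excluded(self):
        gen = GeneratorConfig(n_plates=2, clones_per_plate=40, noise_sd=0.0,
                              plate_offset_sd=0.0, sterile_fraction=0.0, seed=3)
        rec, lay, truth = generate_screen(gen)
        planted = sorted(truth.planted_hits())
        fu = GeneratorConfig(**{**gen.__dict__, "n_repeats": 4, "seed": 4})
        rec2, lay2, _ = generate_screen(fu, clone_effects=dict(truth.clone_effects))
        # two planted clones also move the cytoplasmic-GFP reporter
        counter_effects = {c: 1.0 for c in truth.clone_effects}
        for c in planted[:2]:
            counter_effects[c] = 3.0
        cs = GeneratorConfig(**{**gen.__dict__, "n_repeats": 4, "seed": 5})
        rec3, lay3, _ = generate_screen(cs, clone_effects=counter_effects)
        hits, summary = run_full_screen(
            ScreenData(rec, lay), ScreenData(rec2, lay2), ScreenData(rec3, lay3)
        )
        calls = {h.clone_id: h.call for h in hits}
        for c in planted[:2]:
            assert calls[c] == "excluded_counterscreen"
        for c in planted[2:]:
            assert calls[c] == "validated"
        assert summary.n_excluded_counterscreen == 2

    def test_determinism_byte_identical_hit_tables(self, tmp_path):
        primary, secondary, counter, _ = _small_screen(seed=11)
        cfg = PipelineConfig()
        hits1, _ = run_full_screen(primary, secondary, counter, cfg)
        hits2, _ = run_full_screen(primary, secondary, counter, cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_hit_table(hits1, p1)
        write_hit_table(hits2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_shrinking_alpha_shrinks_validated(self):
        primary, secondary, counter, _ = _small_screen(seed=12, noise=0.3)
        strict = PipelineConfig(alpha=0.01)
        loose = PipelineConfig(alpha=0.05)
        v_strict = {
            h.clone_id
            for h in run_full_screen(primary, secondary, counter, strict)[0]
            if h.call == "validated"
        }
        v_loose = {
            h.clone_id
            for h in run_full_screen(primary, secondary, counter, loose)[0]
            if h.call == "validated"
        }
        assert v_strict <= v_loose

    def test_stage_failure_names_the_stage(self):
        primary, secondary, counter, _ = _small_screen(seed=13)
        # corrupt the primary: drop all layouts
        from sphscreen.hits import PipelineError

        with pytest.raises(PipelineError, match="normalize"):
            run_full_screen(ScreenData(primary.records, []), secondary, counter)
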