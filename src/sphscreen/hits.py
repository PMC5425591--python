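"""Multi-round hit calling.

The screen calls hits in three rounds:

1. **Primary (genome-wide, duplicate):** clones surviving QC are ranked
   by their repeat-averaged robust Z-score, and the two tails of the
   distribution (5% total mass, split evenly) become candidates; the
   tail sign fixes each candidate's direction (up/down) once and for
   all.
2. **Secondary (validation, quadruplicate):** each candidate's per-
   repeat median RFS is compared to the pooled empty-vector wells of
   its plate set with a one-tailed two-sample t-test (Welch by
   default), alternative matching the locked direction; p < alpha is
   required.
3. **Counterscreen (cytoplasmic-GFP strain):** the same t-test machinery
   runs on a strain expressing cytoplasmic GFP; clones that also move
   that reporter (p < alpha) change fluorescence nonspecifically —
   e.g. through general expression effects — and are excluded. A clone
   is a validated hit iff p < alpha in the secondary screen AND
   p >= alpha in the counterscreen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .config import ConfigError, PipelineConfig
from .io import PlateLayout, WormRecord
from .normalize import (
    CloneScore,
    WellSummary,
    normalize_plate,
    score_clones,
    summarize_plate,
)
from .qc import flag_low_repeatability, flag_sterile, qc_plate

__all__ = [
    "InsufficientReplicatesError",
    "PipelineError",
    "HitRecord",
    "ScreenData",
    "ScreenSummary",
    "select_tail_candidates",
    "secondary_ttest",
    "apply_counterscreen",
    "run_full_screen",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate values on one side of a t-test."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class HitRecord:
    """One candidate gene through the calling rounds.

    ``call`` is one of ``candidate`` (awaiting validation),
    ``validated``, ``excluded_counterscreen`` or ``rejected``.
    """

    clone_id: str
    direction: str  # "up" | "down"
    mean_rz: float
    secondary_p: float | None = None
    counterscreen_p: float | None = None
    call: str = "candidate"
    flags: set[str] = field(default_factory=set)


@dataclass
class ScreenData:
    """One screen's raw material: per-worm records plus plate maps."""

    records: list[WormRecord]
    layouts: list[PlateLayout]


@dataclass
class ScreenSummary:
    """Per-stage counts of the full run."""

    n_clones: int = 0
    n_eligible: int = 0
    n_candidates: int = 0
    n_candidates_up: int = 0
    n_candidates_down: int = 0
    n_validated_up: int = 0
    n_validated_down: int = 0
    n_excluded_counterscreen: int = 0
    n_rejected: int = 0
    plate_verdicts: dict[str, str] = field(default_factory=dict)
    repeatability: tuple[float, float] | None = None

    @property
    def n_validated(self) -> int:
        return self.n_validated_up + self.n_validated_down


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


def select_tail_candidates(
    scores: Sequence[CloneScore],
    tail_fraction: float = 0.05,
    ignore_flags: frozenset[str] | set[str] = frozenset(),
) -> list[HitRecord]:
    """Pick the two tails of the mean-rZ distribution as candidates.

    With total tail mass f over N eligible clones, the ceil(f/2·N)
    highest mean-rZ clones become ``up`` candidates and the same number
    of lowest become ``down`` candidates. Clones flagged sterile, low
    repeatability or missing a repeat are excluded beforehand (status
    flags named in ``ignore_flags`` are tolerated instead — the
    pipeline uses this when the genome-wide repeatability rule governs
    plate redos rather than candidacy). Ties at the cut are broken by
    clone_id so the selection is deterministic.
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ConfigError(f"tail_fraction must be in (0, 0.5], got {tail_fraction}")
    ignore = set(ignore_flags) | {"ok"}
    eligible = [
        s for s in scores if not (s.status - ignore) and s.mean_rz is not None
    ]
    if not eligible:
        return []
    n = len(eligible)
    k = math.ceil(tail_fraction / 2.0 * n)
    values = {s.mean_rz for s in eligible}
    if len(values) == 1:
        warnings.warn(
            "mean rZ distribution is degenerate (all values equal); "
            "tail selection falls back to clone_id order",
            stacklevel=2,
        )
    by_high = sorted(eligible, key=lambda s: (-s.mean_rz, s.clone_id))
    by_low = sorted(eligible, key=lambda s: (s.mean_rz, s.clone_id))
    up = by_high[:k]
    taken = {s.clone_id for s in up}
    down = [s for s in by_low if s.clone_id not in taken][:k]
    hits = [
        HitRecord(clone_id=s.clone_id, direction="up", mean_rz=s.mean_rz)
        for s in up
    ] + [
        HitRecord(clone_id=s.clone_id, direction="down", mean_rz=s.mean_rz)
        for s in down
    ]
    return hits


# ---------------------------------------------------------------------------
# Validation t-test
# ---------------------------------------------------------------------------


def secondary_ttest(
    candidate: Sequence[float],
    control: Sequence[float],
    direction: str,
    equal_var: bool = False,
) -> float:
    """One-tailed two-sample t-test of candidate vs empty-vector wells.

    ``direction`` must be locked from the primary screen before the test
    is run ("up": alternative candidate > control; "down": <). The
    counterscreen passes ``direction="change"`` for a two-sided test —
    a nonspecific reporter change in either direction is disqualifying.
    Welch's unequal-variance form is the default; ``equal_var=True``
    pools. Degenerate zero-variance samples are resolved by the sign of
    the mean difference (no evidence -> 0.5 one-tailed, 1.0 two-sided).
    """
    if direction not in {"up", "down", "change"}:
        raise ValueError(
            f"direction must be 'up', 'down' or 'change', got {direction!r}"
        )
    a = np.asarray(candidate, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 values per group, got {a.size} and {b.size}"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("t-test requires finite values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if direction == "change":
            return 1.0 if diff == 0.0 else 0.0
        if diff == 0.0:
            return 0.5
        consistent = (diff > 0) == (direction == "up")
        return 0.0 if consistent else 1.0
    alternative = {"up": "greater", "down": "less", "change": "two-sided"}[direction]
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.pvalue)


def apply_counterscreen(
    hits: Iterable[HitRecord],
    gfp_screen_p: Mapping[str, float],
    alpha: float = 0.05,
) -> list[HitRecord]:
    """Apply the cytoplasmic-GFP exclusion rule to secondary-passing hits.

    Only candidates with secondary p < alpha are considered: those with
    a counterscreen p < alpha are excluded; those with p >= alpha become
    validated. A clone missing from the counterscreen keeps its
    ``candidate`` call with a ``missing_counterscreen`` flag — it is
    never silently validated.
    """
    out = []
    for h in hits:
        if h.secondary_p is not None and h.secondary_p < alpha:
            if h.clone_id not in gfp_screen_p:
                h.flags.add("missing_counterscreen")
                h.call = "candidate"
            else:
                h.counterscreen_p = gfp_screen_p[h.clone_id]
                if h.counterscreen_p < alpha:
                    h.call = "excluded_counterscreen"
                else:
                    h.call = "validated"
        else:
            h.call = "rejected"
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _summarize_screen(
    data: ScreenData, config: PipelineConfig
) -> tuple[dict[str, list[WellSummary]], dict[str, int]]:
    """Summarize + sterile-flag every plate of one screen (no rZ yet)."""
    by_plate: dict[str, list[WormRecord]] = {}
    for r in data.records:
        by_plate.setdefault(r.plate_id, []).append(r)
    layouts = {l.plate_id: l for l in data.layouts}
    unknown = set(by_plate) - set(layouts)
    if unknown:
        raise ValueError(f"records for plates without a layout: {sorted(unknown)}")
    summaries: dict[str, list[WellSummary]] = {}
    for plate_id, layout in layouts.items():
        plate_summaries = summarize_plate(
            by_plate.get(plate_id, []), layout, min_worms=config.min_worms
        )
        flag_sterile(plate_summaries, fraction=config.sterile_fraction)
        summaries[plate_id] = plate_summaries
    repeat_index = {l.plate_id: l.repeat_index for l in data.layouts}
    return summaries, repeat_index


def _process_screen(
    data: ScreenData, config: PipelineConfig
) -> tuple[dict[str, list[WellSummary]], dict[str, int]]:
    """Summarize + sterile-flag + normalize every plate of one screen.

    Returns per-plate normalized summaries and the plate -> repeat map.
    Sterile wells are flagged (and excluded from the plate statistics)
    before any robust Z-score is computed.
    """
    summaries, repeat_index = _summarize_screen(data, config)
    for plate_id, plate_summaries in summaries.items():
        normalized, _ = normalize_plate(
            plate_summaries,
            min_experimental=config.min_experimental_wells,
            mad_scaled=config.mad_scaled,
        )
        summaries[plate_id] = normalized
    return summaries, repeat_index


def _replicate_values(
    summaries: dict[str, list[WellSummary]],
    clone_id: str,
) -> tuple[list[float], list[float]]:
    """Per-repeat clone medians and pooled same-plate empty-vector medians."""
    clone_values: list[float] = []
    control_values: list[float] = []
    for plate_summaries in summaries.values():
        on_plate = False
        for s in plate_summaries:
            if (
                s.role == "experimental"
                and s.clone_id == clone_id
                and s.median_rfs is not None
                and "sterile" not in s.flags
            ):
                clone_values.append(s.median_rfs)
                on_plate = True
        if on_plate:
            control_values.extend(
                s.median_rfs
                for s in plate_summaries
                if s.role == "empty_vector" and s.median_rfs is not None
            )
    return clone_values, control_values


def _followup_pvalues(
    data: ScreenData,
    hits: Sequence[HitRecord],
    config: PipelineConfig,
    stage: str,
    two_sided: bool = False,
) -> dict[str, float]:
    """One-tailed p-values for each candidate from a 4-repeat screen.

    Clones failing the validation-round repeatability rule (largest
    pairwise fold change > repeat_fold_secondary, strict) get no
    p-value and are flagged by the caller. The t-test works on raw
    per-repeat median RFS, so no plate normalization is needed here.
    """
    summaries, _ = _summarize_screen(data, config)
    pvalues: dict[str, float] = {}
    for h in hits:
        cand, ctrl = _replicate_values(summaries, h.clone_id)
        if len(cand) < 2 or len(ctrl) < 2:
            continue
        fold = 2.0 ** (max(cand) - min(cand))
        if fold > config.repeat_fold_secondary:
            h.flags.add(f"low_repeatability_{stage}")
            continue
        pvalues[h.clone_id] = secondary_ttest(
            cand,
            ctrl,
            "change" if two_sided else h.direction,
            equal_var=config.equal_var,
        )
    return pvalues


def run_full_screen(
    primary: ScreenData,
    secondary: ScreenData,
    counterscreen: ScreenData,
    config: PipelineConfig | None = None,
) -> tuple[list[HitRecord], ScreenSummary]:
    """Run normalize -> QC-filter -> tails -> secondary t-test -> counterscreen.

    Returns the hit table (one record per candidate) and a per-stage
    summary. Any stage failure aborts with the stage named.
    """
    config = config or PipelineConfig()
    summary = ScreenSummary()

    try:
        prim_summaries, repeat_index = _process_screen(primary, config)
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    try:
        all_summaries = [s for plate in prim_summaries.values() for s in plate]
        scores = score_clones(all_summaries, repeat_index)
        flag_low_repeatability(scores, threshold=config.repeat_fold_primary)
        summary.n_clones = len(scores)
        scores_by_plate: dict[str, list[CloneScore]] = {}
        clone_plates: dict[str, set[str]] = {}
        for s in all_summaries:
            if s.role == "experimental":
                clone_plates.setdefault(s.clone_id, set()).add(s.plate_id)
        for score in scores:
            for plate_id in clone_plates.get(score.clone_id, ()):
                scores_by_plate.setdefault(plate_id, []).append(score)
        for plate_id, plate_summaries in prim_summaries.items():
            qc = qc_plate(
                plate_summaries,
                scores_by_plate.get(plate_id, ()),
                up_min=config.control_up_min,
                down_max=config.control_down_max,
                redo_fraction=config.redo_fraction,
            )
            summary.plate_verdicts[plate_id] = qc.verdict
        from .qc import repeatability_report

        try:
            summary.repeatability = repeatability_report(scores)
        except Exception:
            summary.repeatability = None
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        ignore = (
            frozenset()
            if config.exclude_low_repeat_primary
            else frozenset({"low_repeatability"})
        )
        tolerated = ignore | {"ok"}
        summary.n_eligible = sum(1 for s in scores if not (s.status - tolerated))
        hits = select_tail_candidates(
            scores, tail_fraction=config.tail_fraction, ignore_flags=ignore
        )
        summary.n_candidates = len(hits)
        summary.n_candidates_up = sum(1 for h in hits if h.direction == "up")
        summary.n_candidates_down = len(hits) - summary.n_candidates_up
    except Exception as exc:
        raise PipelineError("tails", str(exc)) from exc

    try:
        secondary_p = _followup_pvalues(secondary, hits, config, "secondary")
        if config.bh_correction and secondary_p:
            clones = sorted(secondary_p)
            adjusted = sps.false_discovery_control(
                [secondary_p[c] for c in clones], method="bh"
            )
            secondary_p = dict(zip(clones, map(float, adjusted)))
        for h in hits:
            h.secondary_p = secondary_p.get(h.clone_id)
    except Exception as exc:
        raise PipelineError("secondary", str(exc)) from exc

    try:
        passing = [
            h for h in hits if h.secondary_p is not None and h.secondary_p < config.alpha
        ]
        counter_p = _followup_pvalues(
            counterscreen, passing, config, "counterscreen", two_sided=True
        )
        apply_counterscreen(hits, counter_p, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError("counterscreen", str(exc)) from exc

    summary.n_validated_up = sum(
        1 for h in hits if h.call == "validated" and h.direction == "up"
    )
    summary.n_validated_down = sum(
        1 for h in hits if h.call == "validated" and h.direction == "down"
    )
    summary.n_excluded_counterscreen = sum(
        1 for h in hits if h.call == "excluded_counterscreen"
    )
    summary.n_rejected = sum(1 for h in hits if h.call == "rejected")
    return hits, summary
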