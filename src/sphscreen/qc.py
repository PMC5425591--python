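"""Screen quality control.

Three rules guard the screen:

* in-plate controls must behave — the unc-11 RNAi well (which blocks
  synaptobrevin recycling and strands SpH at the surface) must come out
  well above the L4440 empty-vector baseline, and the gfp RNAi well
  (which knocks the reporter itself down) well below it;
* replicates must agree — clones whose between-repeat fold change
  exceeds the threshold (strictly) are flagged as low repeatability,
  and a plate with too many flagged clones earns a ``redo`` verdict;
* sterile/lethal clones are detected from depressed progeny counts:
  a well with fewer worms than 20% of the plate-average (strictly less)
  is flagged sterile and scored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .normalize import CloneScore, WellSummary

__all__ = [
    "QCError",
    "PlateQC",
    "control_folds",
    "check_controls",
    "flag_sterile",
    "flag_low_repeatability",
    "repeatability_report",
    "qc_plate",
]


class QCError(ValueError):
    """A QC rule cannot be evaluated on the given data."""


@dataclass
class PlateQC:
    """QC verdict for one plate.

    ``control_folds`` maps control roles to their linear fold change
    versus the mean empty-vector signal. Verdicts: ``pass``; ``redo``
    when the repeatability rule triggers on too many of the plate's
    clones; ``fail`` when the controls do not separate.
    """

    plate_id: str
    control_folds: dict[str, float] = field(default_factory=dict)
    n_low_repeat_clones: int = 0
    n_clones: int = 0
    sterile_wells: list[str] = field(default_factory=list)
    degenerate_mad: bool = False
    verdict: str = "pass"


def control_folds(summaries: Sequence[WellSummary]) -> dict[str, float]:
    """Linear fold change of each control role versus the empty-vector mean.

    fold(role) = 2^(median RFS of the role's well − mean empty-vector
    median RFS). With several wells per role the role's medians are
    averaged on the log2 scale first.
    """
    empties = [
        s.median_rfs
        for s in summaries
        if s.role == "empty_vector" and s.median_rfs is not None
    ]
    if not empties:
        raise QCError(
            f"plate {summaries[0].plate_id if summaries else '?'}: no "
            "empty-vector wells with a defined median RFS"
        )
    baseline = float(np.mean(empties))
    folds: dict[str, float] = {}
    for role in ("up_control", "down_control", "empty_vector"):
        values = [
            s.median_rfs
            for s in summaries
            if s.role == role and s.median_rfs is not None
        ]
        if values:
            folds[role] = 2.0 ** (float(np.mean(values)) - baseline)
    return folds


def check_controls(
    summaries: Sequence[WellSummary],
    up_min: float = 2.0,
    down_max: float = 0.7,
) -> PlateQC:
    """Partial plate QC from the control wells alone.

    Passing requires fold(up_control) >= ``up_min`` and
    fold(down_control) <= ``down_max``; a missing control well fails the
    check it belongs to only if the other one also cannot rescue the
    plate — absent controls are reported via the layout design check,
    here they simply cannot demonstrate separation, so the verdict is
    ``fail``.
    """
    if not summaries:
        raise QCError("no well summaries given")
    folds = control_folds(summaries)
    qc = PlateQC(plate_id=summaries[0].plate_id, control_folds=folds)
    up_ok = "up_control" in folds and folds["up_control"] >= up_min
    down_ok = "down_control" in folds and folds["down_control"] <= down_max
    if not (up_ok and down_ok):
        qc.verdict = "fail"
    return qc


def flag_sterile(
    summaries: Sequence[WellSummary], fraction: float = 0.20
) -> list[WellSummary]:
    """Flag sterile/lethal wells of one plate by depressed progeny counts.

    A non-control (experimental) well is flagged iff its worm count is
    strictly less than ``fraction`` × the mean worm count over the
    plate's non-control wells — the mean includes the candidate well
    itself, and a well at exactly the threshold is NOT flagged. Flags
    are added in place; the flagged summaries are returned.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    counts = [s.n_worms for s in summaries if s.role == "experimental"]
    if len(counts) < 2:
        return []
    mean_count = float(np.mean(counts))
    threshold = fraction * mean_count
    flagged = []
    for s in summaries:
        if s.role == "experimental" and s.n_worms < threshold:
            s.flags.add("sterile")
            flagged.append(s)
    return flagged


def flag_low_repeatability(
    scores: Iterable[CloneScore], threshold: float = 1.5
) -> list[CloneScore]:
    """Flag clones whose between-repeat fold change exceeds the threshold.

    The inequality is strict: a clone at exactly the threshold passes.
    Flags are added in place (replacing ``ok``); flagged clones are
    returned.
    """
    if threshold < 1.0:
        raise ValueError(f"repeatability threshold must be >= 1, got {threshold}")
    flagged = []
    for s in scores:
        if s.repeat_fold_change is not None and s.repeat_fold_change > threshold:
            s.status.discard("ok")
            s.status.add("low_repeatability")
            flagged.append(s)
    return flagged


def repeatability_report(
    scores: Sequence[CloneScore],
) -> tuple[float, float]:
    """Replicate agreement over the screen: (Pearson r, fraction within 2-fold).

    Pearson correlation is computed between the first two repeats' log2
    median RFS over clones that carry both; the second number is the
    fraction of those clones whose between-repeat fold change is <= 2.
    """
    pairs = [
        (s.rfs_repeats[0], s.rfs_repeats[1])
        for s in scores
        if len(s.rfs_repeats) >= 2
    ]
    if len(pairs) < 3:
        raise QCError("repeatability needs >= 3 clones with both repeats")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise QCError("repeat vector is constant; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    folds = [
        s.repeat_fold_change
        for s in scores
        if s.repeat_fold_change is not None
    ]
    within = sum(1 for f in folds if f <= 2.0) / len(folds)
    return r, float(within)


def qc_plate(
    summaries: Sequence[WellSummary],
    clone_scores: Sequence[CloneScore] = (),
    up_min: float = 2.0,
    down_max: float = 0.7,
    redo_fraction: float = 0.25,
) -> PlateQC:
    """Full QC verdict for one plate.

    ``fail`` when the controls invert or do not separate; ``redo`` when
    more than ``redo_fraction`` of the plate's scored clones were
    flagged low repeatability; ``pass`` otherwise. Sterile wells and a
    degenerate (zero-MAD) normalization are reported but by themselves
    do not change the verdict.
    """
    qc = check_controls(summaries, up_min=up_min, down_max=down_max)
    qc.sterile_wells = [s.well for s in summaries if "sterile" in s.flags]
    qc.degenerate_mad = any("degenerate_mad" in s.flags for s in summaries)
    qc.n_clones = len(clone_scores)
    qc.n_low_repeat_clones = sum(
        1 for s in clone_scores if "low_repeatability" in s.status
    )
    if qc.verdict == "pass" and qc.n_clones > 0:
        if qc.n_low_repeat_clones / qc.n_clones > redo_fraction:
            qc.verdict = "redo"
    return qc
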