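"""Per-worm normalization and plate-wise robust scoring.

The screen's signal chain is:

1. per worm, the relative fluorescent signal
   ``RFS = log2(green / EXT)`` — dividing by the extinction integral
   cancels worm size, and the log2 transform linearizes fold changes;
2. per well, the median RFS over its worms represents the well;
3. per plate, well medians are converted to robust Z-scores
   ``rZ = (x - median(x)) / MAD(x)`` with the *unscaled* median absolute
   deviation, estimated from that plate's experimental wells only
   (controls are scored against the same statistics but excluded from
   their estimation);
4. per clone, the rZ of the replicate plates are averaged, and the
   between-repeat fold change ``2^|ΔRFS|`` is kept for repeatability QC.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import PlateLayout, WormRecord, normalize_well

__all__ = [
    "DegenerateDispersionError",
    "PlateFailureError",
    "WellSummary",
    "CloneScore",
    "PlateStats",
    "MAD_NORMAL_CONSISTENCY",
    "worm_rfs",
    "summarize_well",
    "summarize_plate",
    "robust_z",
    "normalize_plate",
    "score_clone",
    "score_clones",
]

#: Factor making the MAD a consistent estimator of sigma for normal data.
#: The screen statistic uses the bare MAD; this is only applied when a
#: caller explicitly asks for sigma-comparable units.
MAD_NORMAL_CONSISTENCY = 1.4826


class DegenerateDispersionError(ValueError):
    """MAD of the values is zero; a robust Z-score is undefined."""


class PlateFailureError(ValueError):
    """A plate has too few usable wells to be normalized."""


@dataclass
class WellSummary:
    """Per-well aggregate: worm count, median RFS and (later) its rZ.

    ``median_rfs`` is left undefined (None) when the well yielded fewer
    than ``min_worms`` objects; ``rz`` is undefined until the plate has
    been normalized. ``flags`` accumulate QC annotations (``low_count``,
    ``sterile``, ``degenerate_mad``).
    """

    plate_id: str
    well: str
    clone_id: str
    role: str
    n_worms: int
    median_rfs: float | None
    rz: float | None = None
    flags: set[str] = field(default_factory=set)


@dataclass
class CloneScore:
    """Per-clone aggregate across the replicate plates.

    ``mean_rz`` is defined only with at least two usable repeats;
    ``repeat_fold_change`` is the largest pairwise fold change between
    repeats on the linear scale (``2^(max - min)`` of the log2 medians),
    which for the two-repeat genome-wide round reduces to ``2^|Δ|``.
    """

    clone_id: str
    rfs_repeats: list[float]
    rz_repeats: list[float]
    mean_rz: float | None
    repeat_fold_change: float | None
    status: set[str] = field(default_factory=lambda: {"ok"})


@dataclass(frozen=True)
class PlateStats:
    """Location/scale used to normalize one plate."""

    plate_id: str
    median: float
    mad: float
    scale: float
    n_used: int
    degenerate: bool


def worm_rfs(green: float, ext: float) -> float:
    """Relative fluorescent signal of one worm: log2(green / EXT)."""
    if ext <= 0:
        raise ValueError(f"EXT must be positive, got {ext!r}")
    if green <= 0:
        raise ValueError(
            f"green must be positive for the log transform, got {green!r} "
            "(zero-signal records should be filtered upstream)"
        )
    return math.log2(green / ext)


def summarize_well(
    records: Sequence[WormRecord],
    layout: PlateLayout,
    min_worms: int = 5,
) -> WellSummary:
    """Summarize one well's worms into its median RFS.

    The even-count median is the mean of the central pair. Wells with
    fewer than ``min_worms`` objects carry no signal: the median is left
    undefined and the summary is flagged ``low_count``.
    """
    if not records:
        raise ValueError("summarize_well needs the records of one well")
    plate = records[0].plate_id
    well = normalize_well(records[0].well)
    for r in records:
        if r.plate_id != plate or normalize_well(r.well) != well:
            raise ValueError("records span more than one (plate, well)")
    try:
        clone, role = layout.assignments[well]
    except KeyError:
        raise ValueError(
            f"well {well} of plate {plate} is absent from the layout"
        ) from None
    n = len(records)
    if n < min_worms:
        return WellSummary(plate, well, clone, role, n, None, flags={"low_count"})
    median = statistics.median(worm_rfs(r.green, r.ext) for r in records)
    return WellSummary(plate, well, clone, role, n, float(median))


def summarize_plate(
    records: Iterable[WormRecord],
    layout: PlateLayout,
    min_worms: int = 5,
) -> list[WellSummary]:
    """Summarize every assigned well of one plate.

    Wells in the layout that yielded no objects at all still get a
    summary with ``n_worms = 0`` — sterile/lethal detection depends on
    seeing the empty wells.
    """
    by_well: dict[str, list[WormRecord]] = {}
    for r in records:
        if r.plate_id != layout.plate_id:
            raise ValueError(
                f"record for plate {r.plate_id} passed with layout "
                f"{layout.plate_id}"
            )
        by_well.setdefault(normalize_well(r.well), []).append(r)
    summaries = []
    for well in sorted(layout.assignments, key=lambda w: w):
        clone, role = layout.assignments[well]
        if role == "unused":
            continue
        recs = by_well.pop(well, [])
        if recs:
            summaries.append(summarize_well(recs, layout, min_worms=min_worms))
        else:
            summaries.append(
                WellSummary(layout.plate_id, well, clone, role, 0, None,
                            flags={"low_count"})
            )
    if by_well:
        extra = ", ".join(sorted(by_well))
        raise ValueError(
            f"plate {layout.plate_id}: records for wells absent from the "
            f"layout: {extra}"
        )
    return summaries


def robust_z(values: Sequence[float], scaled: bool = False) -> np.ndarray:
    """Robust Z-scores: (x - median(x)) / MAD(x), MAD unscaled.

    ``scaled=True`` divides instead by 1.4826·MAD for sigma-comparable
    units. Requires at least 3 finite values and a strictly positive
    MAD; a zero MAD means the batch has no usable dispersion and raises
    :class:`DegenerateDispersionError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("robust_z needs at least 3 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("robust_z requires finite values")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    if mad == 0.0:
        raise DegenerateDispersionError("MAD is zero; dispersion is degenerate")
    scale = mad * MAD_NORMAL_CONSISTENCY if scaled else mad
    return (arr - med) / scale


def _plate_location_scale(
    values: np.ndarray, scaled: bool
) -> tuple[float, float, float, bool]:
    """Median, MAD, working scale and degeneracy flag for one plate.

    A zero MAD (possible only in near-noiseless data) falls back to
    median-centering with unit scale — the ordering information is kept
    and the plate is flagged rather than aborting the run; the
    standalone :func:`robust_z` remains strict.
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad == 0.0:
        return med, mad, 1.0, True
    return med, mad, mad * MAD_NORMAL_CONSISTENCY if scaled else mad, False


def normalize_plate(
    summaries: Sequence[WellSummary],
    min_experimental: int = 8,
    mad_scaled: bool = False,
    exclude_flags: frozenset[str] | set[str] = frozenset({"sterile"}),
) -> tuple[list[WellSummary], PlateStats]:
    """Attach robust Z-scores to the well summaries of one plate.

    The median/MAD are estimated from the plate's experimental wells
    with a defined median RFS, excluding wells carrying any of
    ``exclude_flags`` (sterile/lethal wells are removed before the
    statistics are computed). Control wells are scored against the same
    plate statistics but never contribute to them. Excluded wells and
    wells without a defined median keep ``rz = None``.
    """
    if not summaries:
        raise PlateFailureError("no well summaries given")
    plate_id = summaries[0].plate_id
    exclude = set(exclude_flags)

    def usable(s: WellSummary) -> bool:
        return s.median_rfs is not None and not (s.flags & exclude)

    exp_values = [
        s.median_rfs for s in summaries if s.role == "experimental" and usable(s)
    ]
    if len(exp_values) < min_experimental:
        raise PlateFailureError(
            f"plate {plate_id}: only {len(exp_values)} usable experimental "
            f"wells (need >= {min_experimental})"
        )
    med, mad, scale, degenerate = _plate_location_scale(
        np.asarray(exp_values, dtype=float), mad_scaled
    )
    stats = PlateStats(plate_id, med, mad, scale, len(exp_values), degenerate)
    out = []
    for s in summaries:
        new = replace(s, flags=set(s.flags))
        if degenerate:
            new.flags.add("degenerate_mad")
        if usable(new):
            new.rz = (new.median_rfs - med) / scale
        out.append(new)
    return out, stats


def score_clone(
    summaries: Sequence[WellSummary], clone_id: str | None = None
) -> CloneScore:
    """Aggregate one clone's well summaries across repeat plates.

    ``summaries`` must be ordered by repeat index. Sterile repeats and
    repeats without a defined median/rZ are dropped from the aggregate
    and reflected in the status flags; degraded data is flagged, never
    fatal.
    """
    if not summaries:
        raise ValueError("score_clone needs at least one well summary")
    clone = clone_id or summaries[0].clone_id
    status: set[str] = set()
    rfs: list[float] = []
    rz: list[float] = []
    for s in summaries:
        if "sterile" in s.flags:
            status.add("sterile")
            continue
        if s.median_rfs is None:
            status.add("low_count")
            continue
        rfs.append(s.median_rfs)
        if s.rz is not None:
            rz.append(s.rz)
    mean_rz = float(np.mean(rz)) if len(rz) >= 2 else None
    if len(rfs) >= 2:
        fold = 2.0 ** (max(rfs) - min(rfs))
    else:
        fold = None
    if len(rz) < 2:
        status.add("missing_repeat")
    if not status:
        status = {"ok"}
    return CloneScore(
        clone_id=clone,
        rfs_repeats=rfs,
        rz_repeats=rz,
        mean_rz=mean_rz,
        repeat_fold_change=fold,
        status=status,
    )


def score_clones(
    summaries: Iterable[WellSummary],
    repeat_index: Mapping[str, int],
) -> list[CloneScore]:
    """Group experimental-well summaries by clone and score each clone.

    ``repeat_index`` maps plate_id to its repeat number, ordering each
    clone's summaries. Control wells (shared clone ids across plates)
    are not scored.
    """
    by_clone: dict[str, list[WellSummary]] = {}
    for s in summaries:
        if s.role != "experimental":
            continue
        by_clone.setdefault(s.clone_id, []).append(s)
    scores = []
    for clone in sorted(by_clone):
        group = sorted(
            by_clone[clone], key=lambda s: (repeat_index[s.plate_id], s.plate_id)
        )
        scores.append(score_clone(group, clone_id=clone))
    return scores
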