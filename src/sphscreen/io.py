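"""File formats for the screen pipeline.

The pipeline touches four kinds of text tables:

* per-object COPAS exports (tab-delimited, one row per worm; the sorter
  reports time-of-flight, extinction and integrated green fluorescence
  for each object it scans),
* plate maps (CSV) assigning every well a clone identifier and a role,
* behavioral/molecular endpoint CSVs (paralysis counts, locomotion
  tracks, qPCR Ct values),
* the pipeline's own outputs (well summaries, clone scores, QC reports,
  hit tables), all tab-delimited with a header row.

All readers validate their input and collect rejected rows with line
numbers rather than dropping them silently; all writers are atomic
(temp file + rename) and end with a newline.
"""

from __future__ import annotations

import csv
import math
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "FormatError",
    "WormRecord",
    "PlateLayout",
    "EndpointTable",
    "CopasDialect",
    "CopasTable",
    "ROLES",
    "EXPECTED_CONTROL_COUNTS",
    "parse_well",
    "format_well",
    "normalize_well",
    "read_copas_table",
    "write_copas_table",
    "read_plate_layout",
    "read_plate_layouts",
    "write_plate_layouts",
    "write_hit_table",
    "read_hit_table",
    "write_well_summaries",
    "write_clone_scores",
    "write_qc_report",
    "write_truth",
    "read_paralysis_csv",
    "write_paralysis_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_qpcr_csv",
    "atomic_write_text",
]

ROLES = frozenset(
    {"experimental", "empty_vector", "up_control", "down_control", "unused"}
)

#: Per-plate control design: two empty-vector (L4440) wells, one
#: up-regulated control (unc-11 RNAi) and one down-regulated control
#: (gfp RNAi) on every experimental plate.
EXPECTED_CONTROL_COUNTS = {"empty_vector": 2, "up_control": 1, "down_control": 1}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Well addresses
# ---------------------------------------------------------------------------

_WELL_RE = re.compile(r"^\s*([A-Ha-h])\s*(0?[1-9]|1[0-2])\s*$")


def parse_well(well: str) -> tuple[int, int]:
    """Parse a 96-well address like ``A1`` or ``a01`` to (row, column).

    Rows run A–H (0–7), columns 1–12 (0–11). Leading zeros and case are
    normalized away.
    """
    m = _WELL_RE.match(well)
    if m is None:
        raise FormatError(f"invalid well address: {well!r}")
    return ord(m.group(1).upper()) - ord("A"), int(m.group(2)) - 1


def format_well(row: int, col: int) -> str:
    """Format (row, column) indices back to the canonical ``A1`` form."""
    if not (0 <= row < 8 and 0 <= col < 12):
        raise ValueError(f"well indices out of range: ({row}, {col})")
    return f"{chr(ord('A') + row)}{col + 1}"


def normalize_well(well: str) -> str:
    """Canonicalize a well address (``a01`` -> ``A1``)."""
    return format_well(*parse_well(well))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class WormRecord:
    """One COPAS object read: a single worm passing the flow cell.

    ``ext`` (extinction integral) is the optical-density proxy for worm
    size; ``green`` is the integrated synapto-pHluorin fluorescence.
    Records entering normalization must have ``ext > 0``.
    """

    plate_id: str
    well: str
    tof: float
    ext: float
    green: float


@dataclass
class PlateLayout:
    """Mapping from wells of one physical plate to (clone, role).

    ``repeat_index`` identifies which replicate of the screen this plate
    belongs to (clones are run in duplicate in the genome-wide round and
    in quadruplicate in the validation round).
    """

    plate_id: str
    assignments: dict[str, tuple[str, str]]
    repeat_index: int = 1

    def __post_init__(self) -> None:
        canon: dict[str, tuple[str, str]] = {}
        for well, (clone, role) in self.assignments.items():
            w = normalize_well(well)
            if role not in ROLES:
                raise FormatError(f"unknown role {role!r} for well {w}")
            if w in canon:
                raise FormatError(f"duplicate well {w} on plate {self.plate_id}")
            canon[w] = (clone, role)
        self.assignments = canon
        if self.repeat_index < 1:
            raise FormatError(f"repeat_index must be >= 1, got {self.repeat_index}")

    def role_of(self, well: str) -> str:
        return self.assignments[normalize_well(well)][1]

    def clone_of(self, well: str) -> str:
        return self.assignments[normalize_well(well)][0]

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(
            (w for w, (_, r) in self.assignments.items() if r == role),
            key=parse_well,
        )

    def design_warnings(self) -> list[str]:
        """Check the expected control layout; return human-readable warnings."""
        warnings = []
        for role, expected in EXPECTED_CONTROL_COUNTS.items():
            n = len(self.wells_with_role(role))
            if n != expected:
                warnings.append(
                    f"plate {self.plate_id}: expected {expected} {role} "
                    f"well(s), found {n}"
                )
        return warnings


@dataclass
class EndpointTable:
    """Cumulative paralysis counts for one replicate of a drug assay.

    Worms sit on aldicarb (or levamisole) plates and are scored for
    paralysis at fixed intervals; ``n_paralyzed[i]`` is the cumulative
    count at ``timepoints_min[i]`` out of ``n_total`` animals.
    """

    assay: str
    strain: str
    replicate: int
    timepoints_min: list[int]
    n_total: int
    n_paralyzed: list[int]

    def __post_init__(self) -> None:
        if self.assay not in {"aldicarb", "levamisole"}:
            raise FormatError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise FormatError("replicate index must be >= 1")
        if self.n_total < 1:
            raise FormatError("n_total must be positive")
        if len(self.timepoints_min) != len(self.n_paralyzed):
            raise FormatError("timepoints and counts are misaligned")
        if any(t < 0 for t in self.timepoints_min):
            raise FormatError("timepoints must be nonnegative")
        if list(self.timepoints_min) != sorted(self.timepoints_min):
            raise FormatError("timepoints must be ordered")
        prev = 0
        for t, n in zip(self.timepoints_min, self.n_paralyzed):
            if n < prev:
                raise FormatError(
                    f"paralyzed count decreases at t={t} min "
                    f"(replicate {self.replicate})"
                )
            if n > self.n_total:
                raise FormatError(
                    f"paralyzed count {n} exceeds n_total {self.n_total}"
                )
            prev = n


# ---------------------------------------------------------------------------
# COPAS object tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CopasDialect:
    """Declared shape of a COPAS export.

    Instrument software varies in its column naming, so the logical
    fields (plate, well, tof, ext, green) are mapped to header names;
    matching is case-insensitive and extra columns are ignored.
    """

    sep: str = "\t"
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "plate": "plate",
            "well": "well",
            "tof": "TOF",
            "ext": "EXT",
            "green": "green",
        }
    )


@dataclass
class CopasTable:
    """Parsed COPAS table: accepted records plus rejected-row audit trail."""

    records: list[WormRecord]
    rejected: list[tuple[int, str]]  # (1-based line number, reason)

    def __iter__(self) -> Iterator[WormRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_copas_table(path: str | Path, dialect: CopasDialect | None = None) -> CopasTable:
    """Read a per-worm COPAS export.

    Rows with non-numeric fields, non-positive EXT, negative green/TOF
    or an unparseable well address are rejected and reported with their
    line numbers; they are never silently dropped.
    """
    dialect = dialect or CopasDialect()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.sep)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        lower = [h.strip().lower() for h in header]
        col_idx: dict[str, int] = {}
        for logical, name in dialect.columns.items():
            try:
                col_idx[logical] = lower.index(name.strip().lower())
            except ValueError:
                raise FormatError(
                    f"{path}: missing required column {name!r} (field {logical})"
                ) from None
        records: list[WormRecord] = []
        rejected: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                plate = row[col_idx["plate"]].strip()
                well = normalize_well(row[col_idx["well"]])
                tof = float(row[col_idx["tof"]])
                ext = float(row[col_idx["ext"]])
                green = float(row[col_idx["green"]])
            except (IndexError, ValueError, FormatError) as exc:
                rejected.append((lineno, f"unparseable row: {exc}"))
                continue
            if not all(map(math.isfinite, (tof, ext, green))):
                rejected.append((lineno, "non-finite value"))
            elif ext <= 0:
                rejected.append((lineno, f"non-positive EXT ({ext:g})"))
            elif green < 0:
                rejected.append((lineno, f"negative green ({green:g})"))
            elif tof < 0:
                rejected.append((lineno, f"negative TOF ({tof:g})"))
            else:
                records.append(WormRecord(plate, well, tof, ext, green))
    return CopasTable(records=records, rejected=rejected)


def write_copas_table(
    records: Iterable[WormRecord], path: str | Path, dialect: CopasDialect | None = None
) -> None:
    dialect = dialect or CopasDialect()
    cols = dialect.columns
    lines = [dialect.sep.join(cols[f] for f in ("plate", "well", "tof", "ext", "green"))]
    for r in records:
        lines.append(
            dialect.sep.join(
                (r.plate_id, r.well, _fmt(r.tof), _fmt(r.ext), _fmt(r.green))
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plate maps
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = ("plate", "well", "clone_id", "role", "repeat_index")


def read_plate_layouts(path: str | Path) -> list[PlateLayout]:
    """Read a plate-map CSV (columns plate, well, clone_id, role, repeat_index).

    Returns one layout per plate, in first-appearance order. Duplicate
    wells and unknown role tokens are format errors.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        fields = [f.strip().lower() for f in reader.fieldnames]
        for col in _LAYOUT_COLUMNS:
            if col not in fields:
                raise FormatError(f"{path}: missing required column {col!r}")
        by_plate: dict[str, dict[str, tuple[str, str]]] = {}
        repeat: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
            plate = row["plate"]
            well = normalize_well(row["well"])
            role = row["role"]
            if role not in ROLES:
                raise FormatError(f"{path}:{lineno}: unknown role {role!r}")
            try:
                rep = int(row["repeat_index"])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: bad repeat_index {row['repeat_index']!r}"
                ) from None
            plate_wells = by_plate.setdefault(plate, {})
            if well in plate_wells:
                raise FormatError(
                    f"{path}:{lineno}: duplicate well {well} on plate {plate}"
                )
            plate_wells[well] = (row["clone_id"], role)
            if plate in repeat and repeat[plate] != rep:
                raise FormatError(
                    f"{path}:{lineno}: conflicting repeat_index for plate {plate}"
                )
            repeat[plate] = rep
    if not by_plate:
        raise FormatError(f"{path}: no layout rows")
    return [
        PlateLayout(plate_id=p, assignments=wells, repeat_index=repeat[p])
        for p, wells in by_plate.items()
    ]


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read a plate map that must describe exactly one plate."""
    layouts = read_plate_layouts(path)
    if len(layouts) != 1:
        raise FormatError(f"{path}: expected a single plate, found {len(layouts)}")
    return layouts[0]


def write_plate_layouts(layouts: Iterable[PlateLayout], path: str | Path) -> None:
    lines = [",".join(_LAYOUT_COLUMNS)]
    for layout in layouts:
        for well in sorted(layout.assignments, key=parse_well):
            clone, role = layout.assignments[well]
            lines.append(
                f"{layout.plate_id},{well},{clone},{role},{layout.repeat_index}"
            )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hit tables and other pipeline outputs
# ---------------------------------------------------------------------------


def _fmt(x: float | None) -> str:
    """Format a real to 6 significant digits; None becomes NA."""
    if x is None:
        return "NA"
    return f"{x:.6g}"


def _parse_optional(s: str) -> float | None:
    return None if s == "NA" else float(s)


_HIT_COLUMNS = (
    "clone_id",
    "direction",
    "mean_rz",
    "secondary_p",
    "counterscreen_p",
    "call",
)


def write_hit_table(hits: Sequence, path: str | Path) -> None:
    """Write candidate/hit records as TSV.

    Rows are sorted by (direction, |mean rZ| descending, clone_id) so
    the file order is deterministic even under ties.
    """
    ordered = sorted(
        hits, key=lambda h: (h.direction, -abs(h.mean_rz), h.clone_id)
    )
    lines = ["\t".join(_HIT_COLUMNS)]
    for h in ordered:
        lines.append(
            "\t".join(
                (
                    h.clone_id,
                    h.direction,
                    _fmt(h.mean_rz),
                    _fmt(h.secondary_p),
                    _fmt(h.counterscreen_p),
                    h.call,
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_hit_table(path: str | Path) -> list:
    from .hits import HitRecord  # deferred: io <-> hits layering

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for col in _HIT_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        hits = []
        for row in reader:
            hits.append(
                HitRecord(
                    clone_id=row["clone_id"],
                    direction=row["direction"],
                    mean_rz=float(row["mean_rz"]),
                    secondary_p=_parse_optional(row["secondary_p"]),
                    counterscreen_p=_parse_optional(row["counterscreen_p"]),
                    call=row["call"],
                )
            )
    return hits


def write_well_summaries(summaries: Sequence, path: str | Path) -> None:
    lines = ["\t".join(("plate", "well", "clone_id", "role", "n_worms",
                        "median_rfs", "rz", "flags"))]
    for s in summaries:
        lines.append(
            "\t".join(
                (
                    s.plate_id,
                    s.well,
                    s.clone_id,
                    s.role,
                    str(s.n_worms),
                    _fmt(s.median_rfs),
                    _fmt(s.rz),
                    ";".join(sorted(s.flags)) or "-",
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_clone_scores(scores: Sequence, path: str | Path) -> None:
    lines = ["\t".join(("clone_id", "rfs_repeats", "rz_repeats", "mean_rz",
                        "repeat_fold_change", "status"))]
    for s in scores:
        lines.append(
            "\t".join(
                (
                    s.clone_id,
                    ";".join(_fmt(v) for v in s.rfs_repeats) or "-",
                    ";".join(_fmt(v) for v in s.rz_repeats) or "-",
                    _fmt(s.mean_rz),
                    _fmt(s.repeat_fold_change),
                    ";".join(sorted(s.status)),
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_qc_report(plate_qcs: Sequence, path: str | Path) -> None:
    lines = ["\t".join(("plate", "fold_up_control", "fold_down_control",
                        "n_low_repeat_clones", "n_clones", "sterile_wells",
                        "degenerate_mad", "verdict"))]
    for q in plate_qcs:
        lines.append(
            "\t".join(
                (
                    q.plate_id,
                    _fmt(q.control_folds.get("up_control")),
                    _fmt(q.control_folds.get("down_control")),
                    str(q.n_low_repeat_clones),
                    str(q.n_clones),
                    ";".join(q.sterile_wells) or "-",
                    str(q.degenerate_mad).lower(),
                    q.verdict,
                )
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_truth(truth, path: str | Path) -> None:
    """Write planted ground truth (clone effects + anomalies) as TSV."""
    lines = ["\t".join(("kind", "key", "value"))]
    for clone in sorted(truth.clone_effects):
        lines.append(f"clone_effect\t{clone}\t{_fmt(truth.clone_effects[clone])}")
    for plate, well in sorted(truth.sterile_wells):
        lines.append(f"sterile_well\t{plate}:{well}\t1")
    for plate in sorted(truth.plate_offsets):
        lines.append(f"plate_offset\t{plate}\t{_fmt(truth.plate_offsets[plate])}")
    lines.append(f"noise_sd\t-\t{_fmt(truth.noise_sd)}")
    lines.append(f"worms_per_well\t-\t{truth.worms_per_well}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Endpoint CSVs
# ---------------------------------------------------------------------------


def read_paralysis_csv(path: str | Path) -> list[EndpointTable]:
    """Read tidy paralysis counts.

    Columns: assay, strain, replicate, time_min, n_total, n_paralyzed;
    one row per (strain, replicate, timepoint).
    """
    path = Path(path)
    rows: dict[tuple[str, str, int], dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"assay", "strain", "replicate", "time_min", "n_total", "n_paralyzed"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        for row in reader:
            key = (row["assay"], row["strain"], int(row["replicate"]))
            entry = rows.setdefault(key, {"n_total": int(row["n_total"]), "points": []})
            if entry["n_total"] != int(row["n_total"]):
                raise FormatError(
                    f"{path}: inconsistent n_total for {key[1]} replicate {key[2]}"
                )
            entry["points"].append((int(row["time_min"]), int(row["n_paralyzed"])))
    tables = []
    for (assay, strain, rep), entry in rows.items():
        pts = sorted(entry["points"])
        tables.append(
            EndpointTable(
                assay=assay,
                strain=strain,
                replicate=rep,
                timepoints_min=[t for t, _ in pts],
                n_total=entry["n_total"],
                n_paralyzed=[n for _, n in pts],
            )
        )
    return tables


def write_paralysis_csv(tables: Iterable[EndpointTable], path: str | Path) -> None:
    lines = ["assay,strain,replicate,time_min,n_total,n_paralyzed"]
    for t in tables:
        for tp, n in zip(t.timepoints_min, t.n_paralyzed):
            lines.append(f"{t.assay},{t.strain},{t.replicate},{tp},{t.n_total},{n}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_tracks_csv(path: str | Path) -> list:
    """Read locomotion tracks (columns strain, worm_id, time_s, velocity_mm_s)."""
    from .endpoints import LocomotionTrack

    path = Path(path)
    by_worm: dict[tuple[str, str], list[tuple[float, float]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"strain", "worm_id", "time_s", "velocity_mm_s"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        for row in reader:
            by_worm.setdefault((row["strain"], row["worm_id"]), []).append(
                (float(row["time_s"]), float(row["velocity_mm_s"]))
            )
    tracks = []
    for (strain, _worm), pts in by_worm.items():
        pts.sort()
        times = [t for t, _ in pts]
        tracks.append(
            LocomotionTrack(
                strain=strain,
                frame_times_s=times,
                signed_velocity=[v for _, v in pts],
                duration_s=times[-1] - times[0] if len(times) > 1 else 0.0,
            )
        )
    return tracks


def write_tracks_csv(tracks: Iterable, path: str | Path) -> None:
    lines = ["strain,worm_id,time_s,velocity_mm_s"]
    for i, tr in enumerate(tracks):
        for t, v in zip(tr.frame_times_s, tr.signed_velocity):
            lines.append(f"{tr.strain},w{i + 1},{_fmt(t)},{_fmt(v)}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_qpcr_csv(path: str | Path):
    """Read qPCR Ct values (columns condition, gene, reference, ct) as a DataFrame."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    required = {"condition", "gene", "reference", "ct"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing required column(s) {sorted(required - set(df.columns))}"
        )
    df["reference"] = df["reference"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` atomically (temp file in the same directory,
    then rename), so an interrupted run never leaves a partial table."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
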