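"""Synthetic screen and endpoint data with planted ground truth.

No raw data from a real COPAS screen is bundled, so every downstream
stage is exercised against generated data whose truth is known exactly:

* **Screen generator** — per-worm extinction (EXT) is log-normal (worm
  sizes are right-skewed); green fluorescence is proportional to EXT
  times the clone's multiplicative effect times a log2-scale Gaussian
  well noise and a per-plate offset:

      green = base_green_per_ext · EXT · effect · 2^(offset + well_noise)

  so the RFS = log2(green/EXT) cancels worm size by construction, the
  way the EXT normalization intends. Control wells carry the observed
  control magnitudes (6-fold up for the unc-11 well, 0.5-fold for the
  gfp well); a configurable fraction of clones is planted as hits and a
  further fraction as sterile/lethal (progeny drawn Binomial(nominal,
  0.1), safely below the 20% rule). A single master seed streams into
  per-plate substreams so each plate is independently reproducible.

* **Paralysis generator** — discrete-time survival: each still-moving
  worm paralyzes in a 10-minute interval with the strain's hazard.

* **Track generator** — per-frame signed velocities from a three-state
  (forward/backward/immobile) process with specified stationary
  fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import ConfigError
from .endpoints import LocomotionTrack
from .io import EndpointTable, PlateLayout, WormRecord, format_well

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "CONTROL_WELLS",
    "CONTROL_CLONES",
    "generate_screen",
    "generate_paralysis_data",
    "generate_tracks",
]

#: Fixed positions of the four control wells on every plate: two
#: empty-vector (L4440) wells, one up control (unc-11 RNAi), one down
#: control (gfp RNAi).
CONTROL_WELLS: dict[str, str] = {
    "A1": "empty_vector",
    "H12": "empty_vector",
    "D6": "up_control",
    "E7": "down_control",
}

CONTROL_CLONES: dict[str, str] = {
    "empty_vector": "L4440",
    "up_control": "unc-11",
    "down_control": "gfp",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the screen design: 10 plate layouts of 92
    experimental clones plus 4 control wells, every clone duplicated
    (two repeats) in the genome-wide round, 5% of clones planted as
    hits at the control magnitudes (6-fold up / 0.5-fold down), and a
    log2-scale well noise of 0.25 (a free choice — the replicate
    scatter it produces is of the order the published repeat
    reproducibility implies, see the docs).
    """

    n_plates: int = 10
    clones_per_plate: int = 92
    n_repeats: int = 2
    hit_fraction: float = 0.05
    up_effect: float = 6.0
    down_effect: float = 0.5
    sterile_fraction: float = 0.02
    base_green_per_ext: float = 2.0
    ext_lognormal_params: tuple[float, float] = (5.5, 0.3)
    noise_sd: float = 0.25
    plate_offset_sd: float = 0.15
    worms_per_well: int = 50
    sterile_yield: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates < 1 or self.clones_per_plate < 1 or self.n_repeats < 1:
            raise ConfigError("plate/clone/repeat counts must be positive")
        if self.clones_per_plate > 96 - len(CONTROL_WELLS):
            raise ConfigError(
                f"at most {96 - len(CONTROL_WELLS)} experimental wells per plate"
            )
        if self.hit_fraction > 0.5:
            raise ConfigError(
                "hit_fraction > 0.5: the planted tails would overlap the controls"
            )
        if self.hit_fraction < 0.0:
            raise ConfigError("hit_fraction must be nonnegative")
        if self.up_effect <= 0 or self.down_effect <= 0:
            raise ConfigError("effects must be strictly positive")
        if self.noise_sd < 0 or self.plate_offset_sd < 0:
            raise ConfigError("noise SDs must be nonnegative")
        if not (0.0 <= self.sterile_fraction < 1.0):
            raise ConfigError("sterile_fraction must be in [0, 1)")
        if self.worms_per_well < 1:
            raise ConfigError("worms_per_well must be positive")

    @property
    def n_clones(self) -> int:
        return self.n_plates * self.clones_per_plate

    @property
    def n_planted(self) -> int:
        return round(self.hit_fraction * self.n_clones)


@dataclass
class SyntheticTruth:
    """Planted per-clone effects and well anomalies, for recovery scoring."""

    clone_effects: dict[str, float]
    sterile_wells: set[tuple[str, str]]
    plate_offsets: dict[str, float]
    noise_sd: float
    worms_per_well: int

    def planted_hits(self) -> dict[str, float]:
        """Experimental clones with a non-null planted effect."""
        controls = set(CONTROL_CLONES.values())
        return {
            c: e
            for c, e in self.clone_effects.items()
            if e != 1.0 and c not in controls
        }

    def sterile_clones(self, layouts: Sequence[PlateLayout]) -> set[str]:
        clones = set()
        for layout in layouts:
            for well, (clone, role) in layout.assignments.items():
                if (layout.plate_id, well) in self.sterile_wells:
                    clones.add(clone)
        return clones


def _experimental_wells() -> list[str]:
    wells = []
    for row in range(8):
        for col in range(12):
            w = format_well(row, col)
            if w not in CONTROL_WELLS:
                wells.append(w)
    return wells


def _assign_effects(
    config: GeneratorConfig, clone_ids: Sequence[str]
) -> tuple[dict[str, float], set[str]]:
    """Plant hit effects (half up, half down) and sterile clones, disjointly."""
    rng = np.random.default_rng([config.seed, 7])
    effects = {c: 1.0 for c in clone_ids}
    n_hits = config.n_planted
    order = list(rng.permutation(len(clone_ids)))
    hit_idx = order[:n_hits]
    n_up = math.ceil(n_hits / 2)
    for j, i in enumerate(hit_idx):
        effects[clone_ids[i]] = config.up_effect if j < n_up else config.down_effect
    n_sterile = round(config.sterile_fraction * len(clone_ids))
    sterile = {clone_ids[i] for i in order[n_hits : n_hits + n_sterile]}
    return effects, sterile


def generate_screen(
    config: GeneratorConfig,
    clone_effects: Mapping[str, float] | None = None,
    sterile_clones: set[str] | None = None,
) -> tuple[list[WormRecord], list[PlateLayout], SyntheticTruth]:
    """Generate a COPAS-like screen with known planted truth.

    Every clone appears on exactly ``n_repeats`` repeat plates of the
    same layout; each plate carries the four control wells. When
    ``clone_effects`` is given (e.g. for the validation round, which
    re-arrays the primary candidates at four repeats), those clones are
    laid out instead of drawing a fresh planted set. Identical config
    (and seed) gives identical output.
    """
    if clone_effects is None:
        n_digits = len(str(config.n_clones))
        clone_ids = [f"clone{idx + 1:0{n_digits}d}" for idx in range(config.n_clones)]
        effects, sterile = _assign_effects(config, clone_ids)
        if sterile_clones is not None:
            sterile = set(sterile_clones)
    else:
        control_ids = set(CONTROL_CLONES.values())
        clone_ids = sorted(set(clone_effects) - control_ids)
        effects = dict(clone_effects)
        sterile = set(sterile_clones or ())
    for role, clone in CONTROL_CLONES.items():
        effects.setdefault(
            clone,
            {"empty_vector": 1.0,
             "up_control": config.up_effect,
             "down_control": config.down_effect}[role],
        )

    exp_wells = _experimental_wells()
    per_plate = config.clones_per_plate
    n_designs = math.ceil(len(clone_ids) / per_plate)
    mu_ext, sd_ext = config.ext_lognormal_params

    records: list[WormRecord] = []
    layouts: list[PlateLayout] = []
    sterile_wells: set[tuple[str, str]] = set()
    plate_offsets: dict[str, float] = {}

    for d in range(n_designs):
        design_clones = clone_ids[d * per_plate : (d + 1) * per_plate]
        assignments: dict[str, tuple[str, str]] = {
            well: (CONTROL_CLONES[role], role) for well, role in CONTROL_WELLS.items()
        }
        for well, clone in zip(exp_wells, design_clones):
            assignments[well] = (clone, "experimental")
        for r in range(config.n_repeats):
            plate_id = f"P{d + 1:02d}R{r + 1}"
            layouts.append(
                PlateLayout(
                    plate_id=plate_id,
                    assignments=dict(assignments),
                    repeat_index=r + 1,
                )
            )
            rng = np.random.default_rng([config.seed, 1000 + d, r])
            offset = (
                rng.normal(0.0, config.plate_offset_sd)
                if config.plate_offset_sd > 0
                else 0.0
            )
            plate_offsets[plate_id] = float(offset)
            for well in sorted(assignments):
                clone, role = assignments[well]
                is_sterile = role == "experimental" and clone in sterile
                if is_sterile:
                    n = int(rng.binomial(config.worms_per_well, config.sterile_yield))
                    sterile_wells.add((plate_id, well))
                else:
                    n = int(rng.poisson(config.worms_per_well))
                if n == 0:
                    continue
                ext = rng.lognormal(mu_ext, sd_ext, size=n)
                tof = 0.45 * ext * rng.lognormal(0.0, 0.05, size=n)
                well_noise = (
                    rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                )
                green = (
                    config.base_green_per_ext
                    * ext
                    * effects[clone]
                    * 2.0 ** (offset + well_noise)
                )
                records.extend(
                    WormRecord(plate_id, well, float(t), float(e), float(g))
                    for t, e, g in zip(tof, ext, green)
                )

    truth = SyntheticTruth(
        clone_effects=effects,
        sterile_wells=sterile_wells,
        plate_offsets=plate_offsets,
        noise_sd=config.noise_sd,
        worms_per_well=config.worms_per_well,
    )
    return records, layouts, truth


# ---------------------------------------------------------------------------
# Endpoint generators
# ---------------------------------------------------------------------------


def generate_paralysis_data(
    hazard: float | Sequence[float],
    n_worms: int = 30,
    timepoints: Sequence[int] = tuple(range(10, 130, 10)),
    n_replicates: int = 3,
    seed: int = 0,
    strain: str = "strain",
    assay: str = "aldicarb",
) -> list[EndpointTable]:
    """Cumulative paralysis counts from a discrete-time survival process.

    ``hazard`` is the per-interval paralysis probability, scalar or one
    value per timepoint. 25–35 worms per replicate and 10-minute
    intervals over 2 h mirror the assay design.
    """
    tps = list(timepoints)
    hz = [float(hazard)] * len(tps) if np.isscalar(hazard) else [float(h) for h in hazard]
    if len(hz) != len(tps):
        raise ConfigError("hazard must be scalar or one value per timepoint")
    if any(not (0.0 <= h <= 1.0) for h in hz):
        raise ConfigError("hazard must lie in [0, 1]")
    if n_worms < 1 or n_replicates < 1:
        raise ConfigError("n_worms and n_replicates must be positive")
    rng = np.random.default_rng([seed, 11])
    tables = []
    for rep in range(1, n_replicates + 1):
        moving = n_worms
        cumulative = 0
        counts = []
        for h in hz:
            newly = int(rng.binomial(moving, h)) if moving > 0 else 0
            cumulative += newly
            moving -= newly
            counts.append(cumulative)
        tables.append(
            EndpointTable(
                assay=assay,
                strain=strain,
                replicate=rep,
                timepoints_min=tps,
                n_total=n_worms,
                n_paralyzed=counts,
            )
        )
    return tables


def generate_tracks(
    speed_mean_mm_s: float = 0.15,
    speed_sd_mm_s: float = 0.03,
    forward_fraction: float = 0.9,
    immobile_fraction: float = 0.02,
    duration_s: float = 40.0,
    frame_rate_hz: float = 20.0,
    n_tracks: int = 15,
    seed: int = 0,
    strain: str = "strain",
) -> list[LocomotionTrack]:
    """Signed per-frame velocities from a three-state locomotion process.

    Each frame is forward (positive velocity), backward (negative) or
    immobile (zero) with the given stationary fractions; speeds are
    truncated-normal. 40 s at the given frame rate matches the
    locomotion-rate measurement window.
    """
    if frame_rate_hz <= 0:
        raise ConfigError("frame rate must be positive")
    if duration_s <= 0 or n_tracks < 1:
        raise ConfigError("duration and track count must be positive")
    for name, frac in (("forward", forward_fraction), ("immobile", immobile_fraction)):
        if not (0.0 <= frac <= 1.0):
            raise ConfigError(f"{name}_fraction must be in [0, 1]")
    if forward_fraction + immobile_fraction > 1.0 + 1e-12:
        raise ConfigError("state fractions must sum to at most 1")
    backward_fraction = max(0.0, 1.0 - forward_fraction - immobile_fraction)
    rng = np.random.default_rng([seed, 13])
    n_frames = max(1, int(round(duration_s * frame_rate_hz)))
    times = np.arange(n_frames) / frame_rate_hz
    probs = np.array([forward_fraction, backward_fraction, immobile_fraction])
    probs = probs / probs.sum()
    tracks = []
    for _ in range(n_tracks):
        states = rng.choice(3, size=n_frames, p=probs)
        speeds = rng.normal(speed_mean_mm_s, speed_sd_mm_s, size=n_frames)
        speeds = np.abs(speeds)
        velocity = np.where(
            states == 0, speeds, np.where(states == 1, -speeds, 0.0)
        )
        tracks.append(
            LocomotionTrack(
                strain=strain,
                frame_times_s=list(map(float, times)),
                signed_velocity=list(map(float, velocity)),
                duration_s=float(duration_s),
            )
        )
    return tracks
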