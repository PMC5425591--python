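"""Behavioral and molecular endpoint analytics.

Hits from the screen are validated on live animals and transcripts:

* **Paralysis kinetics** — worms on aldicarb (acetylcholinesterase
  inhibitor; resistance indicates reduced acetylcholine release) or
  levamisole (postsynaptic receptor agonist; normal sensitivity with
  aldicarb resistance localizes the defect presynaptically) are scored
  for paralysis every 10 minutes; curves report mean ± SEM of the
  paralyzed fraction across replicates.

* **Locomotion summaries** — tracked worms yield signed per-frame
  velocities (positive = forward); summaries are time-weighted mean
  speed and the forward/backward/immobile time fractions.

* **Relative expression** — qPCR by the ΔCt method with assumed perfect
  efficiency: one cycle difference = one 2-fold expression change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ParalysisCurve",
    "LocomotionTrack",
    "paralysis_curve",
    "compare_paralysis",
    "locomotion_summary",
    "relative_expression",
    "qpcr_fold_changes",
]


@dataclass
class ParalysisCurve:
    """Mean paralyzed fraction over time, with SEM across replicates.

    ``replicate_fractions`` (replicates × timepoints) is retained so
    timepoint comparisons can be made downstream. SEM uses the sample
    standard deviation (n−1); with a single replicate it is reported
    as 0.
    """

    strain: str
    timepoints_min: list[int]
    mean_fraction: list[float]
    sem: list[float]
    n_replicates: int
    replicate_fractions: np.ndarray = field(repr=False, default=None)


@dataclass
class LocomotionTrack:
    """One worm's signed velocity trace (mm/s; positive = forward)."""

    strain: str
    frame_times_s: list[float]
    signed_velocity: list[float]
    duration_s: float

    def __post_init__(self) -> None:
        if len(self.frame_times_s) != len(self.signed_velocity):
            raise ValueError("frame times and velocities are misaligned")
        t = self.frame_times_s
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("frame times must be strictly increasing")


def paralysis_curve(tables: Sequence) -> ParalysisCurve:
    """Aggregate one strain's replicate paralysis tables into a curve."""
    if not tables:
        raise ValueError("paralysis_curve needs at least one replicate table")
    strain = tables[0].strain
    tps = list(tables[0].timepoints_min)
    for t in tables:
        if t.strain != strain:
            raise ValueError("tables mix strains")
        if list(t.timepoints_min) != tps:
            raise ValueError(
                f"replicate {t.replicate}: timepoints misaligned with "
                f"replicate {tables[0].replicate}"
            )
    fracs = np.array(
        [[n / t.n_total for n in t.n_paralyzed] for t in tables], dtype=float
    )
    mean = fracs.mean(axis=0)
    if len(tables) > 1:
        sem = fracs.std(axis=0, ddof=1) / math.sqrt(len(tables))
    else:
        sem = np.zeros_like(mean)
    return ParalysisCurve(
        strain=strain,
        timepoints_min=tps,
        mean_fraction=list(map(float, mean)),
        sem=list(map(float, sem)),
        n_replicates=len(tables),
        replicate_fractions=fracs,
    )


def compare_paralysis(
    curve_a: ParalysisCurve, curve_b: ParalysisCurve, timepoint: int
) -> tuple[float, float]:
    """Unpaired two-tailed t-test of per-replicate paralyzed fractions
    at one timepoint. Returns (mean difference a − b, p-value)."""
    for c in (curve_a, curve_b):
        if timepoint not in c.timepoints_min:
            raise ValueError(f"timepoint {timepoint} min absent from curve")
        if c.n_replicates < 2:
            raise ValueError("compare_paralysis needs >= 2 replicates per curve")
    a = curve_a.replicate_fractions[:, curve_a.timepoints_min.index(timepoint)]
    b = curve_b.replicate_fractions[:, curve_b.timepoints_min.index(timepoint)]
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return diff, 1.0 if diff == 0.0 else 0.0
    p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return diff, p


def locomotion_summary(
    track: LocomotionTrack, immobile_speed_mm_s: float = 0.02
) -> tuple[float, float, float, float]:
    """(mean speed, forward, backward, immobile fractions) of one track.

    A frame is immobile iff |velocity| < threshold, else forward for
    positive velocity, backward for negative. Fractions are
    time-weighted (each frame weighted by its sampling interval) and
    sum to 1; mean speed is the time-weighted mean |velocity| over
    non-immobile frames (0 if the worm never moves).
    """
    v = np.asarray(track.signed_velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty track")
    t = np.asarray(track.frame_times_s, dtype=float)
    if v.size == 1:
        w = np.array([1.0])
    else:
        dt = np.diff(t)
        w = np.concatenate([dt, dt[-1:]])
    total = w.sum()
    immobile = np.abs(v) < immobile_speed_mm_s
    forward = (~immobile) & (v > 0)
    backward = (~immobile) & (v < 0)
    f_imm = float(w[immobile].sum() / total)
    f_fwd = float(w[forward].sum() / total)
    f_bwd = float(w[backward].sum() / total)
    moving = ~immobile
    if moving.any():
        mean_speed = float(np.average(np.abs(v[moving]), weights=w[moving]))
    else:
        mean_speed = 0.0
    return mean_speed, f_fwd, f_bwd, f_imm


def relative_expression(
    ct_target_mut: float,
    ct_ref_mut: float,
    ct_target_wt: float,
    ct_ref_wt: float,
) -> float:
    """Fold change of a target transcript in mutant vs wild type (ΔCt method).

    ΔCt = Ct_target − Ct_reference within each condition;
    ΔΔCt = ΔCt_mut − ΔCt_wt; fold = 2^(−ΔΔCt). Perfect amplification
    efficiency (exact doubling per cycle) is assumed.
    """
    values = (ct_target_mut, ct_ref_mut, ct_target_wt, ct_ref_wt)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_mut - ct_ref_mut) - (ct_target_wt - ct_ref_wt)
    return 2.0 ** (-ddct)


def qpcr_fold_changes(df, control_condition: str = "wt"):
    """Per-(condition, gene) fold changes from a tidy Ct table.

    ``df`` has columns condition, gene, reference (bool marking the
    reference-gene rows) and ct; technical replicates are averaged
    before the ΔCt arithmetic. Returns a DataFrame with columns
    condition, gene, fold_change for every non-reference gene and
    non-control condition.
    """
    import pandas as pd

    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")
    mean_ct = df.groupby(["condition", "gene"])["ct"].mean()
    ref_genes = sorted(df.loc[df["reference"], "gene"].unique())
    if len(ref_genes) != 1:
        raise ValueError(f"expected exactly one reference gene, found {ref_genes}")
    ref = ref_genes[0]
    rows = []
    for cond in sorted(set(df["condition"]) - {control_condition}):
        for gene in sorted(set(df.loc[~df["reference"], "gene"])):
            if (cond, gene) not in mean_ct.index:
                continue
            fold = relative_expression(
                mean_ct[(cond, gene)],
                mean_ct[(cond, ref)],
                mean_ct[(control_condition, gene)],
                mean_ct[(control_condition, ref)],
            )
            rows.append({"condition": cond, "gene": gene, "fold_change": fold})
    return pd.DataFrame(rows, columns=["condition", "gene", "fold_change"])
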