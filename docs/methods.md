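# Methods

## Signal model and normalization

A COPAS object read gives, per worm, a time-of-flight (length proxy),
an extinction integral EXT (optical density, a worm-size proxy) and an
integrated green fluorescence. Because a bigger worm carries more
synapto-pHluorin regardless of vesicle cycling, the per-worm statistic
is the size-normalized **relative fluorescent signal**
`RFS = log2(green/EXT)`; the log2 transform linearizes fold changes so
that a k-fold fluorescence change is a shift of log2 k. The median RFS
over a well's worms represents the well — the median rather than the
mean because a well's object list regularly contains debris-like
outliers, and the even-count median is the conventional mean of the
central pair.

Plate effects (bacterial growth, incubation, sorter drift) shift whole
plates, so well medians are normalized **per plate** with the robust
Z-score `rZ = (x − median)/MAD`, where MAD is the *unscaled* median
absolute deviation. The location and scale are estimated from the
plate's experimental wells only; control wells are scored against the
same statistics but excluded from their estimation, since controls are
planted at extreme values by design and would inflate the MAD. A
`mad_scaled` switch divides instead by 1.4826·MAD for σ-comparable
units; the screen statistic itself uses the bare MAD. Per-plate
normalization makes every clone's rZ exactly invariant to any additive
log2 offset applied to one plate, which is the tested contract. A
pooled variant (all plates as one batch) would preserve genuine
between-plate biology at the cost of that invariance; per-plate is the
default and the only mode used by the pipeline.

**Degenerate dispersion.** `robust_z` requires MAD > 0 and raises
otherwise — on real data a zero-MAD plate means the instrument
returned constant values. Inside `normalize_plate`, however, the exact
zero-noise limit (reachable only with synthetic data, and used as a
pipeline sanity check) would make every null well identical and MAD
exactly 0 while the ordering information is still perfectly valid; the
plate then falls back to median-centering with unit scale and every
summary is flagged `degenerate_mad`, surfacing in the QC report
instead of aborting the run.

## Clone scoring and repeatability

Clones run in duplicate in the genome-wide round; the two rZ values
are averaged. Between-repeat agreement is summarized as
`repeat_fold_change = 2^(max−min)` of the per-repeat log2 medians —
for two repeats this is `2^|Δ|`, and for the quadruplicate validation
round it generalizes to the largest pairwise fold. The repeatability
rules are strict inequalities (a clone at exactly the threshold
passes): fold > 1.5 flags a clone in the genome-wide round, fold > 2
removes it in the validation round.

The genome-wide 1.5-fold rule governs **plate redos**, not gene
exclusion: a flagged clone stays scored and eligible, and a plate
where more than `redo_fraction` (default 25%) of clones are flagged is
verdicted `redo`. This mirrors screening practice — irreproducible
plates are re-measured, not silently censored, and censoring at the
1.5-fold level would discard ≈10% of all clones (true hits included)
at realistic noise. The stricter reading (drop flagged clones from
candidacy) is available as `exclude_low_repeat_primary=True`.

Sterile/lethal clones are detected from depressed progeny: a well with
strictly fewer worms than 20% of the plate-average count over
non-control wells (the average includes the candidate well) is flagged
before normalization, excluded from the plate statistics, and its
clone is scored separately rather than entering the tails.

## Hit calling

1. **Tails.** Eligible clones (two usable repeats, not sterile) are
   ranked by mean rZ; the top and bottom `⌈f/2·N⌉` (default f = 5%
   total, split evenly) become candidates, the tail fixing each
   clone's direction once. Ties at the cut break by clone id, making
   the selection deterministic even on degenerate inputs.
2. **Validation.** Each candidate's per-repeat median RFS
   (quadruplicate) is compared to the pooled empty-vector wells of its
   plate set with a one-tailed two-sample t-test whose alternative
   matches the locked direction. Welch's unequal-variance form is the
   default (well replicate variances are not guaranteed equal);
   `equal_var=True` pools. Zero-variance degenerate samples are
   resolved by the sign of the mean difference (0.5 when there is no
   evidence). No multiple-testing correction is applied by default,
   matching the raw p < 0.05 design; a Benjamini–Hochberg switch
   exists.
3. **Counterscreen.** The same machinery runs on a cytoplasmic-GFP
   strain, *two-sided*: a nonspecific reporter change in either
   direction (e.g. a general expression effect) disqualifies the
   clone. A clone is validated iff validation p < α and counterscreen
   p ≥ α (default α = 0.05). Clones missing from the counterscreen —
   including those its own repeatability rule removes — keep their
   candidate call with a `missing_counterscreen` flag; they are never
   silently validated.

Two properties of the joint rule are worth knowing. First, its
recovery ceiling is below 1 by construction: with a null counterscreen
the p ≥ α requirement alone removes an α-fraction of true hits by
chance, and the fold-change rules remove a further few percent, so
measured sensitivity at realistic noise sits near 0.9 with precision
at 1.0. Second, the validated set is monotone in α only through the
validation criterion; shrinking the shared α simultaneously loosens
the counterscreen exclusion, so the joint rule is not globally
monotone.

## Synthetic screen generator

The generator emulates the study design so every stage has a planted
truth: per-worm EXT is log-normal (worm sizes are right-skewed; the
default log-scale mean 5.5 and SD 0.3 put EXT near typical COPAS
extinction integrals), and

```
green = base_green_per_ext · EXT · effect · 2^(plate_offset + well_noise)
```

so RFS cancels worm size by construction. Defaults are the study
conditions: 10 plate designs × 92 experimental clones plus four fixed
control wells (two L4440, one unc-11-like up control at effect 6.0,
one gfp-like down control at 0.5), every clone duplicated, planted
hits at the control magnitudes filling the 5% tails (half up, half
down), 2% of clones sterile (progeny drawn Binomial(nominal, 0.1),
safely under the 20% rule; boundary cases get dedicated fixtures), and
a nominal 50 worms per well (Poisson) for the F1-generation readout.
The per-well log2 noise SD defaults to 0.25 — a free choice, since no
noise magnitude is published; it puts the fraction of repeats within
2-fold near the high-90s% the published repeat-reproducibility
implies. The plate-offset SD defaults to 0.15 so that raw-RFS
replicate scatter, which includes offsets, stays of the same order.
The master seed streams into per-plate substreams
(`default_rng([seed, design, repeat])`), so each plate is
independently reproducible and identical configs are byte-identical.

What the generator does *not* model: axial fluorescence profiles along
the worm (one integrated green value per worm is assumed), RNAi
penetrance biology, spatial (edge/row) plate artifacts, and
worm-to-worm biological variance beyond size (well noise is shared by
a well's worms, so within-well RFS spread comes from size alone).
Passing tests therefore demonstrate the correctness of the statistics
under this model, not robustness to spatial artifacts or per-animal
expression noise.

Endpoint generators: paralysis counts follow a discrete-time survival
process (per-10-min hazard, cumulative counts nondecreasing by
construction; 30 worms × 3 replicates over 2 h by default), and
locomotion tracks draw per-frame states i.i.d. from the specified
forward/backward/immobile fractions with truncated-normal speeds over
a 40 s window at 20 Hz.

## Endpoint analytics

Paralysis curves report the per-timepoint mean and SEM (sample SD,
n−1, over replicates; 0 for a single replicate) of the paralyzed
fraction; curve comparisons are unpaired two-tailed Welch t-tests on
per-replicate fractions at one timepoint. Locomotion summaries
classify a frame immobile iff |velocity| < 0.02 mm/s — no published
numeric threshold exists, so the default is an explicit config value —
else forward/backward by sign (head orientation is upstream of this
package); fractions are time-weighted over total time, so the three
always sum to 1, and mean speed averages |velocity| over moving frames
only. Relative expression uses the ΔCt method with assumed perfect
efficiency (2-fold per cycle): `fold = 2^−((Ct_t−Ct_r)_mut −
(Ct_t−Ct_r)_wt)`.

## Numerical and interface choices

All thresholds (1.5, 2.0, 0.05, 0.20, 5 worms, 0.02 mm/s, 5% tails,
control bounds 2.0/0.7) live in `PipelineConfig`/YAML, not in code.
Readers collect rejected rows with line numbers rather than dropping
them; writers are atomic (temp file + rename) and emit 6-significant-
digit reals, so regenerated tables are byte-identical. Hit tables sort
by (direction, |mean rZ| descending, clone id). Every CLI run writes a
manifest (config snapshot, input SHA-256 digests, seed, stage timings,
outputs), emitted even on failure with the failing stage named.

Problem sizes used by the test suite and the acceptance script — a
920-clone screen in duplicate plus quadruplicate follow-ups, five
noisy replicate screens, and 2000 t-test null simulations — were
chosen so the statistics of interest (tail counts, type-I error within
±0.01, sensitivity/precision) are measured with adequate resolution
while a full run stays in the tens of seconds on one CPU.

## Known limitations

Sensitivity estimates inherit the generator's simplifications above;
the pooled-plates normalization mode is implemented but untested
against real multi-batch drift; the counterscreen join is by clone id
only (no fuzzy matching of re-arrayed libraries); and paralysis
kinetics are compared pointwise rather than with a survival model,
matching the assay's published analysis rather than extending it.
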