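# Methods

## Scope and data model

`droptox` analyses multi-tile, multi-timepoint, four-channel droplet
microscopy: brightfield, an effector-tracker channel, a target-tracker
channel, and a viability channel. Tiles are independent fields of view;
no stitching or cross-tile deduplication is attempted. An experiment is
held in memory as one `(time, channel, height, width)` uint16 array per
tile and on disk as one multi-page TIFF per tile (pages time-major,
channel-minor) described by a `layout.yaml`.

## Poisson co-encapsulation

Each species' per-droplet count is Poisson with mean
λ = concentration × dilution_factor × droplet_volume, the two species
independent (separate inlets). Defaults: 7×10⁶ effector and 10×10⁶ target
cells/mL, 70 pL droplets, dilution 0.5 — two aqueous inlets at equal flow
each contribute half the droplet volume. The effective in-droplet
concentration is rarely stated explicitly in assay descriptions, so the
dilution factor is an explicit parameter rather than a constant.
Normalisation checks truncate the support at k = 50, where the residual
mass at these λ is far below double precision. Observed loadings in real
chips typically fall somewhat short of the naive prediction (sedimentation
and clumping at the inlets); `compare_observed_predicted` reports that gap
per class and makes no attempt to fit it.

## Synthetic experiment generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated, and its per-droplet/per-cell record is
the oracle in every end-to-end test.

* **Geometry.** Droplets are hex-packed with a pitch of
  2 r_max + 8 px (r_max = mean radius + 3 SD), keeping interiors disjoint
  under jitter, and kept at least one radius plus margin inside the tile.
  Radii are normal (50 ± 2 µm diameter, clipped at ±3 SD) and constant
  over time. Defaults: 15 tiles of 512² px at 1 µm/px, ≈1,000 droplets —
  a desk-scale stand-in for the 15 × 15 tiles of ~1,365² px a real run
  produces; the tiling itself carries no information, only droplet counts
  do.
* **Motion.** Per-frame centre jitter is N(0, 0.8 px) clipped at ±2.5 px
  (immobilized droplets barely move). A configurable 2 % of droplets are
  movers: at one random frame they jump into a lattice slot deliberately
  left vacant at layout time, guaranteeing a displacement far above any
  sensible tracking gate while preserving non-overlap. Movers are the
  planted removal case for the tracker.
* **Cells.** Counts are Poisson per species; positions are uniform in the
  disk eroded by a cell radius + 2 px, resampled until pairwise separation
  is ≥1.6 cell diameters (cells are solid objects; the separation also
  keeps rendered spots resolvable — it relaxes only if a configuration
  cannot be found, which at these occupancies essentially never happens).
  Cells ride rigidly with their droplet. Cell division is not simulated.
* **Optics.** Brightfield: light background (3000 counts) with a
  Gaussian-profile dark annulus (depth 2000, σ 1.3 px) at each rim.
  Cells are 2-D Gaussian spots with FWHM equal to the cell diameter
  (10 µm). Target tracker: constant amplitude 3000. Effector tracker:
  amplitude 3000 decaying exponentially with a 10 h half-life (calcein-type
  dyes fade gradually; the default keeps effectors detectable over the
  window). Viability: uniform background 100 everywhere, plus an
  amplitude-3000 spot at a dead cell's position from its death hour
  onward (the stain is stable once on). "Alive = 0" is emulated as
  viability-at-background, so the pipeline must background-correct.
  Additive Gaussian noise (SD 20) everywhere. No aberration,
  bleed-through, shrinkage or intra-droplet motility is modelled: the
  renders carry the minimum structure the pipeline needs, so passing
  tests certify the algorithms, not robustness to real optics.
* **Fates.** A target co-encapsulated with ≥1 effector receives a lytic
  hit with probability `killer_prob` (default 0.2, a typical potent-killer
  fraction for primary NK cells); its death hour is drawn from a default
  distribution shaped after reported kinetics — 86 % of hits within 4 h,
  52 % of those within the first hour, the remainder spread over later
  hours. Targets in effector-free droplets die spontaneously with 5 %
  probability over the window (matching ~95 % control viability), at an
  hour uniform over the span; keeping spontaneous death out of the paired
  stratum makes the measured killer fraction an unbiased estimate of
  `killer_prob`, which the recovery tests rely on. Any cell may be dead
  at t = 0 with probability 0.02, exercising the downstream exclusion
  rule. Effector death is otherwise not simulated (off by default).

Everything is driven by one `numpy` generator seeded from the config;
reruns are bit-identical.

## Droplet detection

Brightfield frames are percentile contrast-stretched (1–99 by default),
edge-filtered (Canny, σ 2) and run through a circular Hough transform over
radii 0.8–1.2× the nominal radius in 1 px steps. Peaks below a normalised
accumulator score of 0.35 are rejected — clean rims score ≳0.5, background
far less. Because Canny fires on both edges of the rim annulus, the Hough
radius locks onto an edge rather than the annulus centre line; each radius
is therefore refined to the darkest ring by a radial-profile argmin (0.25
px grid, ±3 px). Detections are non-maximum-suppressed at a minimum
centre distance of r_min and dropped if their disk crosses the tile
border (partial droplets corrupt counts). Detection is deterministic:
re-running a frame gives identical output.

## Tracking

Consecutive frames are linked by greedy globally-nearest matching: the
smallest centre distance ≤ the gate is paired first, both detections
retired, ties broken by lower index. This coincides with the optimal
assignment when spacing ≫ jitter and never lets two droplets claim one
partner. The gate defaults to half the nominal radius — above a radius
the matcher could pick up a different droplet. Chains spanning every
frame are `complete`; a broken chain is `removed_mover` when detections
existed at the frame where it broke (the droplet jumped out of the gate)
and `removed_gap` when that frame was empty (a missed detection). Gap
bridging (re-acquiring a droplet after a missed frame) is deliberately not
attempted. Removed tracks stay in the output with their status — every
exclusion is auditable, never silent.

## Per-droplet cell analysis

For each complete track, timepoint and fluorescence channel: square crop
of side 2(r + 4 px) + 1; white top-hat with a disk of 1.5× the cell radius
(sequence-decomposed footprint); non-droplet pixels zeroed; Otsu threshold
over the in-disk pixels. Two guards handle degenerate crops: if the
in-disk spread (99.8th percentile minus median) is below a contrast floor
of 150 counts the droplet is declared empty (Otsu on pure noise is
meaningless), and any component whose intensity peak lies within 2 px of
the rim is discarded as the clipped tail of a source outside the droplet
(a genuine cell's peak sits well inside). Components are 8-connected
(diagonal adjacency is routine for Gaussian-ish blobs) and filtered to
0.25–4× the nominal cell area. Components holding several intensity peaks
(≥half the component maximum, ≥one cell radius apart, after light
smoothing) are split into one object per peak — touching cells otherwise
merge into a single count; this peak split is the only declumping
performed (no watershed).

Occupancy is the (effector, target) count at t = 0, frozen thereafter.
Each viability object is attributed to the cell type whose nearest
tracker-object centroid lies within one cell diameter, falling back to
the t = 0 tracker positions when a tracker channel has decayed to
emptiness; unassignable objects count as `dead_unknown`.

## Death calling and kinetics

The viability background is the droplet's own in-disk median at t = 0;
corrected intensities make "alive = 0" literal. A death is called at the
first frame the corrected trace exceeds θ = 150 counts (≈7.5 noise SD,
≈5 % of the post-death amplitude) and stays above it for `persistence`
frames (default 1 — hourly sampling is coarse; raise it for noisy data).
Eligibility for the cytotoxicity readout: occupancy exactly 1:1 and no
dead cell at t = 0; every exclusion is logged with its reason, and
eligible + excluded reconcile exactly with the complete-track total.
Killer fraction counts target deaths only (effector deaths in pairs are
recorded but not counted). The fast/slow boundary defaults to 4 h.
Multiplicity (two targets dying in one droplet, needed for serial-killer
detection) is recovered from the cumulative dead-count increments per
track, which is exact because the viability stain stays on.

## Validation harness

`validate_against_truth` mirrors a script-vs-manual comparison with the
generator's record standing in for manual counts, at t = 3, 4 and 10 h by
default. Compared: droplet count (complete tracks vs non-mover truth —
the pipeline removes movers by design), droplets per occupancy class,
1:1 pairing count, and cumulative dead-cell count per timepoint. Counts
are compared as percent deviation with a max(truth, 1) denominator guard;
the occupancy-class distribution is compared on class fractions
(percentage-point differences scaled by the guard), since a raw relative
deviation on a class containing one or two droplets would swing between 0
and 100 % on a single droplet and measure nothing. The report carries
every per-metric value and the overall maximum.

## Problem sizes and numerical choices

The default generator scale (15 × 512² px tiles, ≈1,000 droplets, 11
timepoints) runs the full image pipeline in a few minutes on one CPU and
is the scale at which the validation bound is computed; unit and property
tests use 1–3 tiles. Monte-Carlo checks use 10⁵ droplets
(encapsulation) and 2,000 pairs × 5 seeds (killer-fraction recovery),
with 3-SE (single-run) or 1-SE (mean-across-seeds) bands. CSV tables are
written without an index and re-read with round-trip float parsing, so
write → read → write is byte-identical.

## Known limitations

* The optical model is deliberately minimal; performance on real
  microscopy (uneven illumination, bleed-through, debris, deformed
  droplets) is untested by construction.
* Overlapping cells are only separated when their intensity peaks are
  resolvable; truly coincident cells undercount.
* No gap bridging: a droplet missed at one frame is excluded rather than
  re-acquired, trading yield for identity safety.
* Distinguishing a dead effector from a dead target after complete
  tracker decay rests on t = 0 positions and fails for cells that moved
  far since — such objects end up as `dead_unknown` rather than guessed.
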