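# Methods

`beehoming` models how a bumblebee (*Bombus terrestris*) relocates an
inconspicuous nest hole in a cylindrical flight arena when the two visual
cue constellations that normally mark it — three small dark cylinders on a
10-cm ring around the nest and three dark stripes on the rotatable arena
wall — are rotated into conflict. This note records the models, the
numerical choices, and what the synthetic data can and cannot show.

## Arena and scene model

The arena is a closed cylinder (radius 75 cm, height 90 cm) whose lower
80 cm of wall rotates; the upper 10 cm is fixed. A condition
`theta_cyl/theta_str` rotates the cylinder constellation and the wall
stripe pattern rigidly about the arena centre, so each constellation points
at its own *fictive nest* (the habituation nest position rotated by the
constellation's angle); the directed difference of the two angles is the
cue-conflict angle. Because neither the nest hole nor the arena entrance
is part of the rendered scene, two conditions with equal directed conflict
are global rotations of one another, which reduces any set of conditions
to equivalence classes keyed by the conflict angle (twelve typical
conditions collapse to seven classes).

Geometry that the source material fixes only pictorially was
reconstructed as follows and is configurable:

* nest at 30 cm from the arena centre (azimuth 0);
* stripe centres at wall azimuths −25°, +25° (the pair flanking the
  nest) and +135° (the remote third stripe); each stripe is 12 cm wide
  and spans the full rotatable wall height (80 cm);
* cylinder phases 30°, 150°, 270° on the 10-cm ring. The 150° phase is
  constrained by the documented nest-snapshot appearance: seen from the
  nest at 6 cm altitude the third stripe must be fully hidden behind one
  cylinder, and only partly hidden at 15 cm. The renderer reproduces both
  facts with this phase; equally spaced phases that ignore the constraint
  (e.g. 90/210/330) do not occlude the third stripe at all.

Surface brightness is flat (no shading or texture): wall 1.0, stripes and
cylinders 0.0 (the red stripes are dark to a bee), floor 0.5 (wood
chips), ceiling 1.0 (white mesh). Floor and ceiling values are guesses —
nothing in the source fixes them — and are exposed in the config.

## Rendering

Panoramas are equirectangular (azimuth −180…180°, elevation −90…90°),
one ray per pixel through the pixel centre, nearest-hit against the wall
cylinder, floor and ceiling planes, and the three cue cylinders (capped
sides plus top discs). The default resolution is 1°/px (360×180); all
analyses here use 2°/px (180×90) for speed — both appear in the source
material, which is internally inconsistent on this point. Every ray in the
closed arena hits a surface, so the paired distance map is finite; its
reciprocal is the *nearness* (cm⁻¹).

Contrast-weighted nearness (CwN) is the Michelson contrast
`(I_max − I_min)/(I_max + I_min)` over each pixel's 3×3 neighbourhood
(azimuth wraps, elevation windows are clipped at the poles) multiplied by
nearness. It approximates the magnitude response of the motion-detector
arrays that encode closeness of contours during translation: only nearby
high-contrast edges survive.

View grids cover a square lattice (default spacing 2 cm, 4 cm in the
test battery) clipped to the arena disc with a 1-cm wall margin; lattice
points inside cylinder footprints are flagged invalid. All grid views are
rendered facing +x.

## View comparison

Because equirectangular images oversample the poles, all image sums weight
row v by `w(v) = sin(pi (v + 0.5)/N_v)` (≈1 at the equator, →0 at the
poles). Two rotational profiles over all integer-pixel azimuth shifts α:

* **rotIDF** — the weighted r.m.s. brightness difference
  `d(α) = sqrt( Σ w(v) (I_cur(u+α,v) − I_mem(u,v))² / (N_u Σ w) )`;
  its minimum is the best alignment and residual mismatch.
* **rotSimF** — the weighted normalized cross-correlation of CwN images;
  written with the square root of the product of weighted energies in the
  denominator so that a perfect match scores exactly 1 (the printed form
  of the formula omits the root but names a correlation coefficient).

Both are evaluated by rFFT cross-correlation along azimuth, algebraically
identical to the direct sums (unit tests pin them to direct triple-sum
oracles at <1e−9). Round-off residues below a 1e−12 relative floor are
clamped so a view compared with itself scores an exact zero. Extremum ties
break toward the smallest |α|, then positive α.

## Homing models

All models memorize the habituation scene only and output a unit homing
vector per lattice point.

* **ALV** — mean of six unit bearings (three cylinder axes, three stripe
  angular centres on the wall), identified geometrically with a perfect
  compass and no occlusion. Homing vector = normalize(ALV_current −
  ALV_nest); this sign convention converges on the nest in habituation
  and is kept globally.
* **B1 / CwN1** — one nest snapshot; the scalar landscape of min-rotIDF
  (resp. max-rotSimF) over the grid is descended (resp. ascended) via
  masked central differences.
* **Bn / CwNn** — n ∈ {4, 8} snapshots on a circle of radius 5 or 15 cm
  around the nest, each oriented toward the nest (first pose at phase 0°,
  configurable; results are phase-robust in the battery). Since grid views
  face +x and memories face the nest, the optimal shift of a grid view
  against snapshot *i* *is* the world heading that snapshot votes for.
  Votes are fused by a weighted circular mean; weights are
  `S_dmin/d_i` for brightness (best match weight 1) and `sim_i/max sim`
  for CwN. Points where the vote sum nearly cancels are flagged invalid.

## Potential and basins

Where homing vectors converge is extracted by a Helmholtz–Hodge
decomposition: the curl-free part of the field is −∇φ with
∇²φ = −div V. φ is computed in open-boundary ("natural") form: the
divergence is evaluated by central differences at cells whose full
five-point stencil lies inside the arena disc and convolved with the
free-space 2D Green's function (log kernel; cell self-term uses the
equal-area disc radius). This choice was made after comparing three
formulations on analytic oracles:

* homogeneous-Neumann masked Poisson loses boundary-flux fields entirely
  (a quadratic-bowl inflow has constant divergence, so the zero-mean
  projection annihilates it);
* face-based least-squares with natural boundary conditions recovers the
  bowl but the stair-stepped disc boundary converts tangential flow into
  spurious divergence, producing artefact basins at the wall;
* the Green's-function form recovers the bowl to r > 0.9999, returns an
  exactly flat potential for any discretely divergence-free rotation, is
  exactly linear and exactly equivariant under quarter-turn rotations.

Its known limitation: flow through the wall ring is ignored (the
boundary-cell divergence is not sourced), and a unit-magnitude vortex that
is *not* discretely divergence-free (the normalized point vortex) leaves
an O(h) core artefact — about 9 % of a unit bowl range at a 4-cm lattice,
halving with the lattice step. Solver residual (r.m.s. of V + ∇φ) and the
unscaled range are reported in the potential metadata.

φ is affinely rescaled to [0, 1] over valid cells. *Basins* are
4-connected components of φ ≤ isohypse (default 0.15, swept over
0.10–0.29 in the comparison); each records its deepest cell and area, and
point-membership tests allow a one-lattice-cell tolerance.

## Behavioural analysis

Flights (74 Hz, ≤300 s) are filtered to the search-related altitude band
3–20.63 cm (walking cut-off; 75th percentile of flight height). Each
flight's x-y samples are smoothed with `scipy.stats.gaussian_kde`
(Scott's rule, factor n^(−1/6)), evaluated on the analysis lattice,
clipped to the arena disc and renormalized to integrate to one, so a
30-second successful return weighs as much as a five-minute search; the
search map is the plain mean over flights. The *search area* is the set
of cells at ≥1/3 of the map maximum.

## Synthetic flights

The original recordings are not deposited, so the behaviour stages are
exercised with a generator that reproduces the statistics the analysis
relies on, with no claim of flight biomechanics:

* horizontal path: AR(1) (discrete Ornstein–Uhlenbeck, time constant
  1.5 s) toward a set point that switches between attractor-centred
  search bouts (per-axis s.d. 8 cm, exponential dwell, mean 6 s — the
  few-second revisit timescale of arena searches; occupancy proportional
  to attractor weights) and diffuse wandering about the centre (s.d.
  34 cm); positions beyond the wall are folded back radially;
* altitude: log-space AR(1) (time constant 0.5 s) with a log-normal
  stationary law calibrated to median 6 cm and 75th percentile 20.63 cm,
  clipped to the arena height.

Scenario presets place attractors at a condition's fictive nests:
`stripes_dominant` (0.15/0.70), `both_nests` (0.40/0.40), and the
negative control `compromise_control` (single attractor at the midpoint —
behaviour the real bees did not show). Everything is deterministic given
the seed.

What passing tests show: the pipeline recovers planted search structure
(attractor locations to within half the search spread, occupancies to
±0.05, the altitude percentile to ±1 cm over 20 full-length flights) and
ranks a matching model potential above a rotated mismatch. What they do
not show: anything about real bee kinematics, learning flights, or the
actual magnitude of real F1 scores — the published mean F1 values depend
on the undeposited recordings and are out of scope here.

## Model-behaviour comparison

Predicted (basin) and observed (search-area) masks are compared cell-wise
on the model lattice: confusion counts, precision, recall, F1 (F1 = 0
where undefined, flagged). F1 is swept over isohypses 0.10–0.29 in steps
of 0.01; per condition the models' F1 samples are compared with a
Kruskal–Wallis test, then pairwise Dunn z-tests with tie correction and
Bonferroni multiplication. Dunn's test is implemented here (verified
against an exact rational-arithmetic rank computation); Kruskal–Wallis
comes from scipy.

## Problem sizes used in the shipped battery

Panoramas at 2°/px; habituation and altitude batteries on a 4-cm lattice
(~1085 views per grid), cue-conflict basin geometry on the native 2-cm
lattice (~4300 views); synthetic datasets of 8 flights × 120 s for
pipeline recovery and 20 flights × 300 s for altitude calibration. At
these sizes the full analysis reruns from scratch in a few minutes on one
CPU.

## Known limitations

* The arena reconstruction is flat-shaded and texture-free; brightness
  models stay more informative across altitude changes here than over a
  textured floor, and the CwN models weight the near cylinder ring more
  strongly than wall stripes. Consequently the CwN multi-snapshot model
  tracks the displaced cylinder constellation in conflicts (one basin at
  the cylinders' fictive nest) rather than splitting between both fictive
  nests, and basin minima often sit on ring cylinders (~10 cm from the
  fictive nest).
* The ALV compromise location lies close to the cylinders' fictive nest
  (4–6 cm depending on lattice), i.e. the compromise is strongly
  cylinder-biased in this geometry.
* The compass-based ALV model is equivariant under rotations of the whole
  world (cues, nest and memory together); rotating only the cue
  constellations while keeping the memorized vector fixed changes its
  field, unlike the view-based models, which scan all rotations and are
  exactly equivariant.
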