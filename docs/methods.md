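# Methods

## Acoustic field model

The simulator models each array element as a flat circular piston vibrating
uniformly at a single frequency in a lossless, free-field medium. This is
the faithful idealization of the device's operating conditions: the cell
chamber is a minimally reflective membrane and an absorber sits in the far
field, so reflections and standing waves are neglected, as are nonlinear
propagation, transient burst edges and microbubble dynamics (the bursts are
30 cycles long, so the field is quasi-continuous over most of each burst).

On the beam axis the Rayleigh integral reduces to the closed form
`p(z) = 2|sin((k/2)(√(z²+a²) − z))|`, which the package uses both as the
fast axial profile and as the normalization anchor for the off-axis
quadrature. Off axis, `|∫ e^{ikR}/R dS|` is evaluated by midpoint
quadrature over concentric rings, multiplied by `k/2π` so the two routes
coincide on the axis. Ring widths and arc lengths are at most λ/20 by
default (`elements_per_wavelength = 20`); each ring's element count is
forced even so the element set is exactly mirror-symmetric, making
simulated maps symmetric under x↔−x and y↔−y to floating-point accumulation
error. At this density the on-axis quadrature error stays below 0.2 % of
the local amplitude across z = 8–70 mm, and halving the element size moves
field values by well under 0.5 %. Discretizations coarser than λ/5 are
refused outright rather than silently degraded. Repeated requests for the
same plane are cached, since the planning pipeline and its oracle tests
revisit identical slices.

Default parameters: radius 10 mm (nominal 20-mm crystal), 1 MHz, sound
speed 1524 m/s (37 °C bath; pass 1532 m/s to emulate 42 °C — a 0.52 %
change, consistent with the rounded 0.53 % figure usually quoted).
All amplitudes are relative; pascal-level calibration is a hardware
procedure and out of scope. A real crystal's effective aperture is smaller
than nominal (the measured near–far-field transition sits nearer 45 mm
than the ideal-piston 66 mm), so the simulated optimal plane (13.5 mm)
need not equal a measured one (16 mm for one physical transducer); no
attempt is made to fit an effective aperture.

## Treatment planning

Heterogeneity of a slice is the *population* standard deviation of pressure
over grid points inside a circular mask centred on the axis — a descriptive
statistic of a fixed grid, not a sample estimate, hence the population
form. The default mask radius, 5.25 mm, is the inscribed circle of the
10.5 × 10.5 mm characterization scan. Heterogeneity is computed on pressure
(not intensity); `std(c·P) = c·std(P)`, so the argmin over planes is
invariant under common rescaling, and `std/mean` is available when a fully
scale-free quantity is wanted. The optimal distance is the argmin over the
explored range (default 10–20 mm; the 13–17 mm sub-range used for display
elsewhere is available by passing that slice list), ties broken toward the
smaller distance, i.e. toward higher peak intensity. The calibration point
is the grid point whose relative intensity `(p/p_max)²` is closest to 0.9,
ties broken by radial distance, then x, then y — fully deterministic on a
grid. Cross-talk is `10·log₁₀(I/I_max)` with `I(offset)` the *maximum*
intensity at radial distance ≥ offset (a conservative, worst-case reading);
−6 and −18 dB contour polygons are extracted for reporting. The 16 mm
neighbour offset is the geometric reconstruction of a 26 mm housing pitch
minus a 10 mm crystal radius.

## Dosimetry

All quantities are closed-form unit arithmetic and are exact: duty cycle
`100·(cycles/f)/T_burst`, PRF `1/T_burst`, volume concentration
`100·V_added/V_media` (the conventional denominator — media volume alone),
bubble:cell ratio `c_stock·V_added/N_cells`, and submersion time
`equalization + n_sites·(exposure + switch)` sequentially (the operator
switch counted after every site, including the last, which is what makes
1 + 6×1 = 7 min) or `equalization + exposure` concurrently (1.5 min).

## Fluorescence quantification

Otsu's threshold is computed exhaustively over every split between
consecutive unique intensity values (vectorized cumulative sums), returning
the midpoint of the best split; ties take the lowest threshold and constant
images raise a degenerate-histogram error instead of guessing. This keeps
the tie-break and error contract explicit; the scikit-image implementation
is used in the test suite as an independent cross-check of the partition.

Nuclei: Otsu on blue → 8-connected components → components smaller than
`min_object_area` (default 30 px at the generator's scale; configurable —
the filter exists to suppress noise specks, and no principled biological
value is claimed) → sequential relabelling. Cell boundaries: the pixelwise
maximum of min–max-normalized blue and green (maximum rather than mean so
GFP-negative cells remain visible through their nuclei), Otsu-thresholded,
then split by a nuclei-seeded watershed on the inverted combined image —
one cell object per nucleus, each a superset of its nucleus; with an empty
green channel this degenerates exactly to the nuclei objects.

Positivity uses the inclusive criterion `Ī_obj ≥ Ī_bg + n·σ_bg` with
n = 3 by default. Background statistics are computed per channel over all
pixels not covered by any object of the relevant object set (cell
boundaries for green scoring, nuclei for red scoring). The decision is
invariant under affine intensity rescaling `I → aI + b, a > 0`, and the
positive set at n = 3 nests inside the n = 2 set. Per-FOV fractions are
counts over the number of cell objects; an empty FOV reports missing (not
zero) fractions and is excluded from the unweighted per-replicate mean.

## Detachment

The computational input is the marker ("dot") image derived from manual
cell identification on phase-contrast images — automated phase-contrast
detection is deliberately out of scope. Dots are connected components
larger than one pixel (isolated pixels are treated as noise). Cell loss is
`100·(mean_after − mean_before)/mean_before`, bounded below by −100 % and
invariant to spot ordering; a zero baseline raises rather than dividing.

## Statistical decision tree

With n = 3 replicates per cell, per-cell normality testing is impossible,
so Shapiro–Wilk runs on the pooled residuals from cell means; Bartlett runs
across the nine cells. Both passing at α = 0.05 routes to a balanced
fixed-effects two-way ANOVA with interaction (balance makes the
sum-of-squares type immaterial; unbalanced inputs are refused, not
approximated), with Tukey HSD on significant main effects pooled over the
other factor. Otherwise Kruskal–Wallis is applied per factor on data pooled
over the other factor — rank tests cannot assess interactions, which are
reported as "not assessed" — with pairwise two-sided Wilcoxon rank-sum
tests, Holm-adjusted (no adjustment method is canonical here; Holm is the
conservative default). No multiplicity correction is applied across the
three response variables, matching per-response reporting. In the
zero-residual limit (identical values within every cell but signal between
levels) the F statistic is reported as infinite with p = 0 rather than NaN.
A permutation-F null reproduces the parametric treatment p-value within
Monte-Carlo error on small synthetic tables (tested).

## Synthetic data generators

Every generator is a pure function of its parameters and seed
(`numpy.random.default_rng`), and each exists to emulate one input class at
the study's conditions:

- **Scans**: noise-free Rayleigh fields plus additive zero-mean Gaussian
  amplitude noise, clipped at zero (hydrophones report magnitudes). At 1 %
  of peak noise the chosen optimal plane moves by at most one 0.5 mm step
  in ≥95 % of seeds (tested).
- **FOVs**: non-overlapping cells placed by rejection sampling; nuclei are
  bright disks in blue (offset 1200 over a background of mean 100, sd 8 on
  the 12-bit scale); transfected cells add 400 over the whole cell disk in
  green; apoptotic cells add 400 over the nucleus in red. Cells also carry
  a small negative shading (−6) in the antibody channels, emulating
  displacement of faintly fluorescent medium; this keeps a negative cell's
  mean strictly below the background mean so the noiseless limit is exactly
  recoverable under the inclusive criterion. Positive flags are assigned
  deterministically — `round(fraction·n)` cells after a seeded shuffle — so
  requested fractions are met exactly when integral. Default 100 cells per
  512×512 FOV at 5 % transfection approximates the treated-group regime.
  The generator does not emulate illumination gradients, staining
  variability, out-of-focus light or overlapping/mitotic cells, so passing
  recovery tests demonstrate correctness of the scoring chain, not
  robustness to real microscopy artefacts.
- **Dot images**: k disjoint dots; the after-image keeps
  `round((1−loss)·k)` of them, so the loss statistic round-trips exactly.
- **Replicate tables**: cell-wise Normal(mean, sd) draws — the minimal
  assumption consistent with reporting group means ± sd and using ANOVA —
  with presets carrying the reported transfection / cell-loss / apoptosis
  group statistics (3 treatments × 3 temperatures × 3 replicates).

## Problem sizes and verification scale

The characterization pipeline is exercised at the study's own scale
(10.5 mm slices at 0.7 mm pitch over 10–20 mm; one 40 × 40 mm wide scan).
Simulation studies in the test suite use deliberately compact sizes chosen
to keep the statistical conclusions sharp: 50-seed FOV-recovery runs at
60 cells per 384×384 FOV, 100-seed ANOVA power runs, 400–1000-seed type-I
error runs. Absolute biological outcome levels (transfection percentages
measured on real cells, etc.) are properties of the biology, not of this
code, and are represented only through the generator presets.

## Known limitations

- The ideal-piston simulator does not reproduce a physical crystal's
  effective aperture; measured and simulated optimal planes differ.
- Segmentation assumes convex, non-confluent cells; heavily confluent
  monolayers would need a stronger boundary model than Otsu + watershed.
- The nonparametric branch tests factors marginally; a genuine
  treatment × temperature interaction is invisible on that branch.
- Replicate tables are generated independently normal; any real
  within-replicate correlation structure is not modelled.
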