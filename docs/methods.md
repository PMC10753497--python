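# Methods

## The cellular automaton

The model describes collective invasion of a tumor spheroid placed at a
low-density cleft between two dense 3D collagen lattices. It is a
deterministic automaton on a regular voxel lattice (spacing Δx = 10 µm, one
voxel ≈ one cell diameter). Each voxel *i* carries two scalar fields, both
dimensionless in [0, 1]: cell density c_i and ECM density m_i. There is no
single-cell resolution, no mechanics, no nutrient field and no cell death;
the automaton's claim is that proliferation, density-dependent
collagenolysis and substrate-/space-limited migration with in-plane
guidance suffice to reproduce the observed partitioning of invasion between
a cleft and the bulk matrix.

### Initial condition

The lattice (default 60 × 60 × 31 voxels) holds bulk matrix at density
`ecm_3d` everywhere except a horizontal slab of `2·cleft_half_thickness+1`
voxel layers at mid-height set to `ecm_int` — the cleft. A sphere of radius
`spheroid_radius` (default 100 µm) centred on the cleft plane is fully
occupied by cells (c = 1). The spheroid volume holds no bulk matrix
(cells have replaced it), but the pre-existing cleft runs *through* the
spheroid footprint: slab voxels keep `ecm_int` inside the sphere. This
matters because migration requires substrate (f(0) = 0, below): without the
through-going channel the spheroid interior would be immobile, the cleft
would be fed only by the one-voxel rim ring, and the simulated interface
sheet would be an order of magnitude too sparse relative to bulk invasion.
A zero-radius spheroid is a valid cell-free matrix control.

### Update rules

Each step applies, in order, proliferation → degradation → migration (the
order sensitivity is O(Δt) and covered by tests); the counters use
Δt = 0.48 h so the default 100 steps span the 48 h culture window.

**Proliferation.** c_i ← min(1, c_i · 2^(Δt/T_d)), with T_d = 24 h, the
doubling time of MV3 melanoma cells. Carrying capacity 1 expresses volume
exclusion.

**Degradation.** m_i ← max(0, m_i · (1 − δ · L_i)) with
L_i = (c_i + Σ_{j∈N(i)} c_j) / (1 + |N(i)|), N(i) the Von Neumann
(6-face) neighbourhood truncated at lattice boundaries. The decay is linear
in all seven local cell densities and keeps m ≥ 0 without clamping for
δ·L ≤ 1. δ = 0 models broad-spectrum MMP inhibition.

**Migration.** From the pre-step fields, each ordered voxel pair (i, j),
j ∈ N(i), carries a flux

    J(i→j) = μ · c_i · f(m_j) · (1 − c_j) · g_ij / Z_i,
    Z_i = max(1, Σ_j f(m_j) · g_ij),

applied simultaneously. The flux response f has two regimes: f(m) = m /
ECM_crit rises linearly to its unique maximum f(ECM_crit) = 1 — the ECM is
the migration substrate — and f(m) = exp(−k·(m − ECM_crit)) decays
exponentially above the critical density — steric hindrance by dense
matrix. ECM_crit = 0.1 throughout. g_ij = `guidance_g` (default 2) when i
and j are in-plane neighbours inside the cleft slab, else 1: the minimal
anisotropy that turns the cleft into a guidance track. Z_i caps a voxel's
total export at μ·c_i.

Two safeguards enforce the [0, 1] range without breaking conservation: the
available-space factor (1 − c_j) on each flux, and a per-target inflow
rescaling s_j = min(1, (1 − c_j)/inflow_j) under which unsent flux simply
stays at its source. The rescaling is conservative — it ignores the space
freed by the target's own outflow within the same step — but it is exact,
symmetric, and makes migration conserve total cell mass to machine
precision. Boundaries are no-flux (closed dish).

All directional accumulations sum opposite neighbours pairwise per axis, so
lattice mirror symmetries of symmetric initial conditions are preserved
bit-exactly, not just approximately; a scalar triple-loop reference
implementation reproduces the vectorized step bit-for-bit on small
lattices.

### Parameters and calibration

| parameter | default | meaning / rationale |
|---|---|---|
| dx | 10 µm | lattice spacing, one cell diameter |
| dt | 0.48 h | 100 steps ≈ 48 h culture window |
| t_d | 24 h | MV3 doubling time |
| mu | 0.6 | mobility; cleft front speeds ~0.3–0.5 voxel/step, matching ~400 µm in 48 h |
| ecm_crit | 0.1 | measured cleft density of the high-density assay sits at the response optimum |
| ecm_int | 0.10 / 0.26 | measured cleft densities, high / low assay |
| ecm_3d | 0.87 / 0.55 | calibrated bulk densities, high / low assay (below) |
| decay_k | 20 | steepness of hindrance above ecm_crit (below) |
| guidance_g | 2 | in-plane cleft amplification |
| delta | scanned (grid 0–0.5, step 0.005) | degradation constant, the fitted quantity |

The cleft densities are measured quantities; the bulk densities and the
hindrance steepness are not printed and were calibrated — as in the
original fitting workflow — so the automaton reproduces the observed
invasion regimes: with `decay_k = 20` and `ecm_3d = 0.87`, switching
degradation off abolishes 3D invasion in the high-density condition
(interface fraction 1.000, bulk < 2% of emigrated mass) while the
interface sheet persists; with `ecm_3d = 0.55` the low-density condition
stays interface-dominant but with substantially more 3D invasion, as
observed. A smaller steepness (e.g. k = 10) leaks enough bulk flux at high
density that the no-collagenolysis regime is lost.

### Invasion summary

Emigrated mass is measured outside the *initial* spheroid footprint — a
cylindrical exclusion through the cleft slab (the rim drawn in the top
view at 0 h) and the initial sphere elsewhere. Interface mass sums cleft-
slab voxels beyond the rim (planar distance), bulk mass all other voxels
outside the sphere (3D distance); the two regions partition the emigration
territory, so radial shell profiles (half-open annuli [k·w, (k+1)·w) in rim
distance, using each region's own distance convention) sum exactly to the
emigrated mass. The interface fraction is interface/(interface+bulk); with
no emigration it is reported as NaN, never as 0, so scan tables stay
honest.

### Scan and fit

The landscape scan varies (`ecm_3d`, δ) at a fixed intermediate cleft
density of 0.18 (the mean of the two assay values); its orientation —
interface fraction non-decreasing in `ecm_3d`, non-increasing in δ — is a
tested property. Because `ecm_int ≤ ecm_3d` is enforced, the default
`ecm_3d` grid starts at 0.20 (15 points, step 0.05).

The condition fit scans δ (grid 0–0.5, step 0.005; fitted optima lie at
0.01–0.03, so a coarser grid cannot resolve them) separately for the two
assay parameter sets and minimizes a 1:1-weighted squared error against
the measured targets: interface fraction 0.80 (high; 2000 of 2500
emigrated cells) and 0.60 (low; a ~25% relative decrease), plus a relative
interface-mass target for the low condition (0.4× the high condition's
fitted interface mass, i.e. 60% fewer interface cells). The high condition
is fitted on its fraction alone and sets the mass scale; ties break toward
smaller δ. With the defaults this yields δ_high = 0.025, δ_low = 0.010,
ratio 2.5; refining the grid twofold moves the ratio by ~10%.

## The synthetic pattern generator

The generator replaces the study's microscopy data with labeled nuclei
point clouds whose statistics match the printed totals and distances. Per
seeded draw (numpy `default_rng`):

- **core** — `n_core` = 1000 nuclei uniform in the sphere (radius 150 µm);
- **interface** — 2000 nuclei in an annulus around the rim, radial rim
  distance from a truncated exponential (decay 150 µm, cutoff 400 µm;
  the printed "up to ~400 µm"), z uniform in a 20 µm cleft band (three
  nuclear layers — the jammed sheet is ~3× a monolayer); a `monolayer`
  flag collapses the band for surface-assay controls;
- **bulk_top / bulk_bottom** — 350 / 150 nuclei on 6–12 jittered radial
  strand axes per gel (Gaussian jitter σ = 12 µm), rim distances from a
  truncated exponential of decay length 175 µm, cut at 175 µm (top) and
  150 µm (bottom) — the printed "150–175 µm" range.

The bulk compartments then pass through the cross-section measurement
geometry: half-sectioning deletes the y < 0 half-space, and imaging depth
deletes nuclei whose independent position along the imaging axis (uniform
over 230 µm) exceeds 185 µm. The interface is measured from an untruncated
top view, as in the experiment, so its 2000 cells are recovered in full.
Strand axes are azimuthally equispaced with an even count and cells are
allocated to strands round-robin: a stratified design under which any
section plane through the centre removes almost exactly half the bulk
cells. This keeps the ×2.5 sampling correction an unbiased, low-variance
inverse (remaining noise is the depth-thinning binomial, ~3–4%); fully
random strand placement would make single-pattern corrected counts vary by
a factor of ~2, which is why real quantifications average many spheroids.
The ground-truth table records per-shell counts (same half-open binning as
the quantification) before and after truncation, emitted totals including
inside-rim stragglers, and six-furthest distances.

What the generator does *not* emulate: strand mechanics or branching,
nucleus shapes and segmentation errors, optical attenuation with depth,
partial nuclei at the section plane (points are dimensionless), or
spheroid-to-spheroid variability. Passing round-trip tests therefore
validate the quantification arithmetic, not a segmentation pipeline.

## Quantification conventions

- Shell assignment is a half-open centre-point rule: rim distance in
  [k·w, (k+1)·w), edge points to the outer shell; nuclei inside the rim go
  to an explicit rim bucket, never silently dropped.
- Interface (and core) nuclei use planar xy rim distance (top view); bulk
  nuclei use 3D distance (side view).
- Maximum migration distance is the mean of the six furthest nuclei; with
  fewer than six it degrades to the mean of all (consistent at n = 6).
- The sampling correction is 1/(half_fraction · depth_fraction) with the
  depth fraction rounded to the nearest 0.05, so (0.5, 185, 230) gives
  exactly 2.5; a raw-ratio mode is available by flag.
- Covered area rasterizes nuclei as 5 µm-radius discs (pixel 2 µm), closes
  gaps up to 20 µm and fills holes. A plain point-closing cannot satisfy
  both natural sanity checks (a dense square keeps its area; a lone
  nucleus covers one nucleus disc), hence the disc rasterization.
- Invasion-zone thickness at a queried rim distance is the z-extent of
  nuclei within ±window/2, plus one nominal nucleus diameter (a monolayer
  reads 10 µm); empty windows report NaN.
- Per-cell signal is (total − background)/n, floored at 0.

## Problem sizes and numerics

Default runs use the 60 × 60 × 31 lattice (111,600 voxels) for 100 steps
(~2 s per run); the two-condition fit evaluates 202 runs (~7 min on one
CPU). Tests use reduced lattices (≤ 31³) except where the property is
about the default configuration. All simulation stages are deterministic;
generator stages are reproducible per seed, with per-stage seeds derived
from one global seed via `numpy.random.SeedSequence`. States persist as
NPZ with dx, dt and step attributes; configs are flat YAML mirroring the
dataclass fields with unknown keys rejected.

## Known limitations

- The continuum automaton spreads bulk invasion over the whole spheroid
  surface instead of a few discrete strands, so near the fitted optimum
  the interface fraction is steep in δ: the fitted low-density δ sits on
  this shoulder, and switching degradation off there changes the fraction
  by ~35–40% rather than leaving it strictly unchanged — the model
  reproduces the *regime* (interface-dominant with residual 3D invasion)
  rather than the exact invariance.
- Model "mass" is a dimensionless density sum; only ratios and fractions
  are compared to counted cells.
- The fitted δ values are grid points; the ratio inherits the grid
  resolution (~±10% under twofold refinement).
- The degradation law ignores diffusible proteases: collagenolysis is
  strictly local to cell-occupied neighbourhoods.
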