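# Methods

This note documents the models behind `vinescan`: what the synthetic
vineyard and the acquisition simulator emulate, how the reconstruction and
the alpha-shape volume estimator work, the parameters that matter, and the
numerical and design choices that were genuinely open.

## 1. Synthetic vineyard (`vinescan.scene`)

A scene is one trellised row along +X. Every woody element is a conical
frustum (`Segment`): per vine a trunk (r ≈ 2.5 cm) up to the 1.0 m training
height, a continuous cordon (r = 1.5 cm) along the row, and the one-year
canes. Canes are chains of 2–4 frusta, base radius 3.2–5 mm tapering to
1.2–2 mm (the crop's branches are thinner than 1 cm in diameter), length
0.7–1.2 m, roughly vertical with a half-normal tilt (sd 8°, capped at 20°)
whose cross-row component is damped ×0.3 by the vertical trellis. Each cane
carries 0–3 short laterals (0.10–0.35 m, 25–60° off the cane axis, radii
down to 0.6 mm) — the fine "end details" that make real pruning wood a
tangle rather than a comb, and the part that optical sensing tends to miss.

Cane bases are spread over the full 1.1 m vine pitch (spurs sit along the
whole cordon, so adjacent vines' canes interleave), 10–16 canes per vine,
which puts per-vine pruning wood at a realistic few tenths of a kilogram.
A cane that would cross its batch boundary is mirrored inward about its
base, so every shoot segment belongs to exactly one batch.

The trellis adds two wires (r = 1.5 mm at 1.35/1.65 m), posts (r = 4 cm) at
batch boundaries, and a white marker sphere (r = 5 cm) on each boundary
post, mirroring the physical references used to delimit 10-vine batches.
Wires are modelled but carry negligible volume and are excluded from the
ground truth, as are trunks, cordons and posts.

**Ground truth.** Batch shoot volume is the exact frustum sum
π·h/3·(r₀² + r₀r₁ + r₁²) over the shoot segments based in the batch
interval; biomass is `wood_density × volume` with a configured density of
450 kg/m³ (a dry-wood figure; a configuration default, not a measured
value). The default layout is 5 treatments × 3 plots × 10 vines = 150
vines.

`sample_surface` places rings of points on every frustum at a chosen
spacing, with azimuthal phase jitter so that exact rings do not hand
cospherical degeneracies to the Delaunay code. It is the "perfect scanner"
used by the resolution-limited volume-recovery tests.

## 2. Acquisition simulator (`vinescan.simulate`)

The rig is a sideways-mounted 2D time-of-flight scanner at 1.20 m height,
~1 m from the row, sweeping a plane perpendicular to travel: 270° field of
view, 0.25° or 0.5° angular steps (541 beams at 0.5°), 0.5–20 m range
window, 25 or 50 Hz. The beam-angle convention is θ = 0 along +Y
(horizontal, toward the row), positive toward +Z, FOV symmetric about 0.

Ranging is exact ray–primitive intersection (frustum lateral surfaces,
marker spheres, the ground plane; end caps of thin frusta are ignored) plus
a Gaussian error of sd 12 mm, one constant in-run bias drawn within
±30 mm, and 1 mm range quantization. Beam divergence is not modelled: a
pencil ray either hits a 3 mm wire or misses it, where a real ~20 mm
footprint at 1 m would return from every frame. This is the main
qualitative gap between simulated and real clouds of thin targets.

Platform motion is a straight line at ≤ 0.83 m/s (the platform stays below
3 km/h; 0.5 m/s at 50 Hz gives the nominal 10 mm inter-slice spacing) with:

* slow sinusoidal lateral wobble, amplitude 2 cm (uneven alley surface);
* residual attitude sway of 0.004 rad — the vehicle's ~1° terrain-induced
  roll/pitch/yaw is largely cancelled by the stabilising gimbal between
  sensor and boom, so only ~0.2° leaks through;
* white per-frame attitude jitter of 0.003 rad (boom/servo micro-vibration,
  a few millimetres at 1 m range). This decorrelates the beam-grid
  alignment from frame to frame, which is what lets sub-centimetre targets
  (wires, thin canes) be sampled stochastically rather than in coherent
  bursts.

The GNSS stream is generated at 10 Hz (20 Hz selectable) with 2 cm Gaussian
position noise, encoded as `$GPGGA` sentences with correct XOR checksums
and 7-decimal minute fields (~0.2 mm resolution), about a configurable
geodetic origin via a spherical tangent-plane approximation — adequate for
a sub-200 m row, not for geodesy.

## 3. Registration (`vinescan.register`)

Each valid beam is converted to sensor-plane coordinates, y = r·cosθ,
z = mount_height + r·sinθ, then moved into the local frame with the pose at
the scan timestamp: p → R_z(yaw)·R_y(pitch)·R_x(roll)·p + t, followed by an
optional X-shear x += s_y·y + s_z·z (identity by default; the shear is the
configurable stand-in for a tilted-sensor correction whose exact form is
not pinned down).

Pose position comes from the GNSS fixes, linearly interpolated — exact for
a constant-speed straight run. By default only the **along-track**
coordinate is taken from the fixes (`encoder_axes="x"`): the stream is the
advance encoder, the platform is assumed on its nominal line, and the
scanner is the origin of the local frame. The alternative `"xyz"` mode
interpolates the full fix position; it injects the 2 cm GNSS altitude noise
directly into point heights and is kept for rigs that genuinely track in
3D. Yaw comes from the smoothed local travel direction (a ±1 s secant
through the fixes) or is held at zero; roll/pitch default to zero —
unmodelled residual attitude becomes a few millimetres of smear at 1 m
range. Frames outside fix coverage are dropped and counted, never
extrapolated.

## 4. Shoot-cloud filtering (`vinescan.filters`)

Default stage order (each stage a strict subset, all counts logged):

1. **crop** to the batch's half-open x-interval [x0, x1);
2. **cut** below the bud plane: keep z ≥ z0 with z0 = 1.0 m, the training
   height. This removes soil, stump and trunk returns. The plane grazes the
   cordon, so a thin ribbon of upper-cordon returns stays in the shoot
   cloud — as in a manually placed cross-section, which cannot cut below
   the buds without losing the cane bases;
3. **mask training structures**: points inside cylinders around the known
   post axes (extended to swallow the boundary markers) are split into a
   structure cloud. Wires are left in the cloud by default — their volume
   contribution is negligible — but wire masks are available;
4. **SOR**: for each point, the mean Euclidean distance d_i to its k = 64
   nearest neighbours; points with d_i > mean(d) + 1·sd(d) are removed in a
   single pass. The underlying published rule is ambiguous ("average
   distance … greater than the standard deviation"); the conventional
   mean + n·σ form with n = 1 follows the semantics of the usual
   point-cloud tooling, and the literal `threshold = σ` reading is
   available via a flag. k is clamped to N−1 for small clouds.

## 5. Alpha-shape volume (`vinescan.alphashape`)

The estimator is built directly on `scipy.spatial.Delaunay`:

* circumradii come from solving the 3×3 circumcentre system per
  tetrahedron, vectorised; the system determinant is 6× the signed volume,
  so it doubles as the degeneracy test (|det| ≤ 1e-12 at unit scale ⇒
  excluded). If the tetrahedralization itself fails (e.g. coplanar input),
  the points are jittered by 1 nm with a fixed seed and retried;
* the α-complex keeps tetrahedra with circumradius ≤ α; **α is a length in
  metres** (circumradius threshold) — α = 0.1 means 0.1 m; a squared-radius
  convention is deliberately not used;
* volume is the sum of retained tetrahedron volumes (disjoint interiors ⇒
  exact); the boundary surface is the set of faces owned by exactly one
  retained tetrahedron; connected components are computed over face
  adjacency. Retained sets are nested in α, so volume is monotone and
  reaches the convex-hull volume for α ≥ max circumradius.

**Alpha selection.** The working α is the smallest candidate whose largest
face-connected component covers ≥ 99 % of the points. The published
criterion — the smallest volume that still gives "a solid surface free from
voids" — is visual; the single-biggest-solid reading makes it operational
and robust: a strict `n_components == 1` test turned out to veto every
candidate on realistic clouds because some isolated 4-point sliver
(≈ 1e-9 m³ out of ~7000 points) almost always survives filtering somewhere
in an 11 m batch. The rule therefore extends the same 1 % stray-point
tolerance that coverage already grants to uncovered points; component
counts are still computed and reported. On batches simulated at the
operational settings the rule selects α = 0.1 m across seeds.

**Structure subtraction.** Post/marker returns get their own complex at the
selected α and V_without = max(0, V_total − V_structures).

## 6. What volumes mean here (and what they do not)

Three regimes matter:

* **Dense two-sided coverage** (the `sample_surface` regime, spacing ≤ 5 mm
  on every branch): the α = 0.1 complex fills each cane like a sausage and
  the volume recovers the analytic truth to within ~15–20 % (inscribed-
  polygon deficit at 3–5 mm radii, SOR-trimmed tips, the bud-plane cut).
  This is the regime in which absolute accuracy is a meaningful claim, and
  it requires branch separations above 2α: four points within a sphere of
  diameter 2α are enough to span a gap, so canes closer than ~0.2 m are
  webbed together and the volume inflates. The recovery tests therefore use
  a sparse, near-vertical cane template (3 canes/vine, 0.3 m spacing) with
  wires masked out.
* **One-sided noisy scanning** (the field-like regime): each thin cane
  appears as a fuzzy quasi-1D curve of returns. Its α-complex is a tube of
  roughly the fuzz radius (noise + residual motion), which both hides the
  true cross-section and adds bridging webs: the absolute volume is biased
  — the demo batch reports ~0.05 m³ against a 7e-4 m³ truth — but it scales
  with the amount and extent of wood, which is why it is used as a
  *regressor* against biomass, never as a measurement. One-sided scanning
  of sub-centimetre branches cannot recover absolute volume even at zero
  noise: the α-complex of a space curve has essentially no interior.
* **Counting instead of enclosing**: the number of scan slices that return
  from a batch (`n_scans`) is the simplest correlate and is carried through
  the statistical layer alongside the volumes.

## 7. Statistical layer (`vinescan.stats`)

Per-batch records (treatment, plot, n_scans, n_points, V_total, V_without,
biomass) feed ordinary least squares with the classical slope t-test — no
robust errors, no multiple-testing correction — pooled and per treatment
(groups with n < 3 are skipped with a warning). The ANOVA for
`biomass ~ predictor + treatment` uses sequential (type-I) sums of squares
with the predictor entered first, built from nested OLS fits so the entry
order is exactly as stated. Under a pure-noise response its predictor
p-values are uniform, which the test suite checks with a KS test over 500
seeded replicates.

On synthetic data with biomass = ρ·V_true + 10 % CV noise over 15 batches,
the pipeline volume attains R² ≥ 0.7 against biomass — a qualitative
analogue of field behaviour, not a reproduction of any field estimate
(those depend on undeposited data).

## 8. Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → register → filter (per batch) → alpha →
report from one YAML config; a single master seed is split per stage
(scene, trajectory, biomass noise) via `numpy.random.SeedSequence`, and the
manifest records config, seeds, per-file SHA-256 checksums and counts.
Re-running with the same config and seed is bit-identical.

Default problem sizes were chosen to exercise the full method at desk
scale: acceptance-style runs use one 10-vine batch (~12 m of row, ~1300
frames × 541 beams, ~10⁴ filtered shoot points), the demo uses six 2-vine
batches, and the recovery tests sample ~5×10⁴–10⁵ surface points.

## 9. Known limitations

* No beam-divergence footprint, multi-echo returns or intensity: thin
  targets are under-detected relative to a real scanner, and reflectance-
  based filtering cannot be emulated.
* The tangent-plane geodetic model ignores datum and curvature effects
  beyond a few hundred metres.
* Flat ground; canopy/leaf occlusion is out of scope (the target crop is
  defoliated).
* Linear pose interpolation and a smoothed-secant heading assume smooth,
  nearly straight passes; there is no IMU fusion, loop closure or
  dual-side scan matching.
* Passing synthetic tests bounds implementation error, not model error:
  real clouds add footprint effects, occlusion, scan loss and registration
  drift that the generator does not emulate.
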