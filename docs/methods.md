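# Methods note

This note records the physical model, the parameter choices, what the
synthetic image generator does and does not emulate, and the numerical and
design decisions baked into `maskblock`.

## 1. Physical model and assumptions

**Droplets are rigid spheres under gravity and linear (Stokes) drag.**
For a droplet of radius `r`, density `ρ`, in air of dynamic viscosity `η`,
the relaxation time is

```
τ = 2 ρ r² / (9 η)
```

and the equations of motion `dv/dt = g − v/τ` integrate in closed form.
Eliminating time gives the trajectory height as an explicit function of
horizontal position `x` (launch point `(x₀, y₀)`, speed `v₀`, angle `θ₀`):

```
y(x) = y₀ + (tan θ₀ + τg / (v₀ cos θ₀)) (x − x₀) + τ² g · ln(1 − (x − x₀)/(τ v₀ cos θ₀))
```

with terminal settling speed `v_T = τg` and a finite **maximum horizontal
range** `R = τ v₀ cos θ₀`: drag exhausts all horizontal momentum in a finite
distance.  Requesting the height beyond the range raises
`StalledFlightError`.  The trajectory is strictly concave, so a droplet
whose height at the target plane is above the floor never touched the floor
earlier; the floor check reduces to a single evaluation per plane.

Assumptions this entails, matching the deliberately frugal experiment being
modelled:

- Stokes (low-Reynolds) drag for all sizes, including the large droplets for
  which it is only approximate; the model is used *relatively* (barrier vs.
  no barrier on the same population), which cancels much of this bias.
- No evaporation, break-up, coalescence, air currents, or turbulent jet
  entrainment.  Small droplets therefore "stall" (aerosolize) and are simply
  counted as such; aerosol transport is explicitly out of scope.
- Instantaneous launch from a point nozzle with a single speed and a uniform
  angle spread.

**Barriers.**  A cloth at distance `d` from the nozzle is a plane with two
parameters: tunneling probability `p` (a droplet passes with probability
`p`, independently of size) and deceleration factor `f` (a passing droplet
retains speed `f·v` and continues from the barrier plane at its current
flight angle).  Multiple barriers act independently in sequence.

**Fates and SBBC.**  Each droplet ends as one of `hit_roi` (reached the
screen inside the central region of interest), `hit_screen`, `blocked`,
`stalled`, or `fell`.  The Simulated Ballistic Blocking Capacity is the
percentage of emitted droplet **volume** removed from the ROI relative to a
barrier-free run of the *same* droplet population:

```
SBBC = (1 − V_roi(barrier) / V_roi(free)) × 100 %
```

Volume, not count, because stain area on the screen is governed by deposited
liquid volume.

## 2. Parameters, units, defaults

All internal quantities are SI (metres, seconds, kg, Pa·s); micrometres and
centimetres appear only at the API boundary (diameters in `EmissionModel`,
`*_cm` keys in JSON configs).

| Parameter | Default | Rationale |
|---|---|---|
| Air viscosity `η` | 1.873 × 10⁻⁵ Pa·s | air at ≈ 30 °C |
| Droplet density `ρ` | 995.7 kg/m³ | water at ≈ 30 °C |
| `g` | 9.81 m/s² | standard gravity |
| Launch speed | 3 m/s | conversational speech jet |
| Launch angle | uniform in ±10° | nozzle spray cone |
| Diameter distribution | lognormal, mean 54 µm, SD 52.3 µm, truncated below 7 µm | measured stain-population shape; the truncation floor is the smallest resolvable stain |
| Droplet count | 100 000 | Monte-Carlo resolution ≪ 1 % on SBBC |
| Nozzle → screen distance | 0.19 m | face-to-face conversational distance |
| Nozzle height | 0.10 m | centred on a 0.20 m screen (design choice; the model is translation-invariant in height apart from the floor) |
| ROI | ±0.02 m band about nozzle height | central stain region actually scanned |
| Barrier positions (studies) | 1.5, 6.83, 12.17, 17.5 cm | near-nozzle to near-screen sweep, equally spaced |

Truncated-lognormal sampling: the untruncated `(μ, σ)` are moment-matched to
the requested mean/SD (`σ² = ln(1 + (sd/mean)²)`, `μ = ln mean − σ²/2`),
then sampled by inverse-CDF restricted above the truncation point.  The
truncated distribution's mean therefore exceeds the nominal mean slightly;
tests verify it against quadrature of the truncated density.

## 3. Imaging pipeline

- **Binarization**: Otsu's threshold by default (`skimage.filters
  .threshold_otsu`), or a fixed threshold.  A perfectly uniform image has no
  Otsu threshold; it is treated as stain-free (all background) and a warning
  is logged.  This is the physically correct reading of a blank scan and is
  what makes an opaque barrier give BBC = 100 % exactly.
- **Stain detection**: 8-connected labelling (`connectivity=2`),
  `min_area = 3` pixels.  At the default 4800 dpi scan resolution one pixel
  is ≈ 5.3 µm, so a 7 µm stain (the physical floor) covers ≥ 1–2 px; the
  3 px floor removes salt-and-pepper specks without touching real stains.
  Equivalent diameter is `2·√(area/π)`.
- **BBC**: per-image dark-pixel fraction → group means → `BBC = 100 (1 −
  m_obstacle / m_free)`.  Uncertainty is first-order propagation of the
  replicate standard errors (SD with `ddof = 1` over replicates):
  `σ_BBC = 100 · hypot(se_o / m_no, m_o · se_no / m_no²)`, which stays finite
  when the obstacle group is blank; it is `None` with fewer than two
  replicates per group.  Descriptive stain statistics use `ddof = 0` by
  default (population SD of the detected stains).

## 4. Synthetic image generator

`maskblock.synthetic` renders what a flatbed scan of the central screen
window would look like for a simulated impact set: dark circular disks on a
white background, one per droplet reaching the window, disk diameter =
`spread_factor ×` droplet diameter (default 1.0; real stains spread wider
than the droplet, but the factor is relative and cancels in BBC).  Default
window: 1 cm × 1 cm at 4800 dpi, centred on the nozzle height.

It **does** emulate: finite scanner resolution (disks below ~1 px are drawn
at a minimum radius of 0.5 px), salt-and-pepper scanner noise (default rate
10⁻⁴), optional Gaussian blur, replicate-to-replicate Monte-Carlo scatter,
and it records area- and volume-based ground truth per configuration.

It does **not** emulate: ink bleeding/wicking anisotropy, overlapping-stain
coalescence physics (overlaps simply merge into one connected component),
grayscale density variation with droplet volume, paper texture, scanner
vignetting, or any transverse jet physics — the transverse (horizontal in
the scan) coordinate is drawn uniformly across the window, a documented
convention, since the 2-D flight model has no transverse dynamics.  Ground
truth is therefore *area of drawn disks*, and the pixel-measured BBC is
validated to agree with it to a few percentage points, not exactly.

## 5. Numerical choices

- **Two SBBC estimators.**  `simulate_experiment` applies per-droplet
  Bernoulli transmission with common random numbers (one uniform per droplet
  per barrier, from a stream independent of emission), so the surviving set
  at tunneling probability `p` is exactly nested in the set at `p' > p`:
  Monte-Carlo SBBC is exactly monotone in `p` without extra variance.
  `expected_sbbc` instead computes `100 (1 − p·V(f,d)/V_free)` by
  deterministically flying every droplet with speed retention `f`; it has no
  barrier-sampling variance and is *exactly affine in `p`* — the estimator
  used for calibration.
- **`(p, f)` calibration** (`fit_pf`): `V(f, d)` is piecewise constant in
  `f` (a droplet either reaches the ROI or not), so the weighted-LS
  objective is minimised by a scan over `f` (coarse grid of 101 points, then
  a local grid at step 10⁻³) with the exactly optimal `p` per `f` from the
  closed-form quadratic minimiser, clipped to `[0, 1]`.  Ties break toward
  smaller `p`, then smaller `f` (the most conservative cloth).  Nozzle →
  barrier flight segments and the free ROI volume are computed once and
  cached; one fit takes well under a second at 30 000 droplets.
- **Linear trend fits** use `numpy.linalg.lstsq`; a fit is flagged (not
  clamped) if it extrapolates above 100 % inside the observed span.  The
  slope comparison reports `|slope_obs − slope_sim| / |slope_obs| × 100`.
- **Mann-Whitney U** (one-tailed, H₁: second group stochastically larger):
  exact enumeration of all `C(n, n_b)` group assignments for combined
  `n ≤ 12` with the midrank tie rule (`U = #{b > a} + ½·#{b = a}`), falling
  back to SciPy's asymptotic test for larger samples.  The exact path is
  cross-checked against `scipy.stats.mannwhitneyu(method="exact")` in tests.
- **Seeding.**  All randomness flows from `numpy.random.SeedSequence`;
  emission and barrier streams are spawned children of the experiment seed,
  and per-(configuration, replicate) render seeds are derived with
  `generate_state` and reduced below 2³¹.  Identical seeds reproduce
  byte-identical CSVs and PNGs.

## 6. Design decisions on open questions

- **Nozzle height 0.10 m, screen 0–0.20 m**: the bench rig is not fully
  specified; any height well above the maximum droplet drop (< 2 cm for
  droplets that reach the screen) is equivalent.  0.10 m centres the spray
  on the screen and keeps the floor irrelevant for screen-reaching droplets
  while still letting slow large droplets `fall`.
- **ROI = ±2 cm band**: wide enough to capture essentially all ballistic
  arrivals at ±10°, narrow enough to represent a scanned central window.
- **Library-first shape**: importable API plus narrative `examples/`; the
  CLI is a thin `click` wrapper over the same functions and adds no logic.
- **Problem sizes in tests**: 100 000 droplets where distributional claims
  are asserted, 5 000–30 000 where only identities or tolerant comparisons
  are needed, keeping the full suite near ten seconds.

## 7. Limitations

- Stokes drag is quantitatively wrong for the largest droplets (Re > 1);
  absolute ranges and SBBCs for those sizes are approximate even though the
  relative comparisons are robust.
- The `(p, f)` cloth model ignores size-dependent penetration, fibre
  re-aerosolization, and saturation of wet cloth.
- Aerosols (stalled droplets) are counted but not transported; no statement
  about airborne transmission follows from this package.
- The synthetic generator validates the *pipeline*, not the scanner: BBC
  accuracy against real scans depends on staining chemistry not modelled
  here.
- The exact rank test is limited to 12 combined observations before the
  asymptotic approximation takes over; with triplicates (the intended use)
  the smallest attainable one-tailed p-value is 1/20.
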