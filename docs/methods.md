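# Methods

This note documents the models, numerical choices, and limitations
behind `capsuleps`: what is computed, under which assumptions, and
what the synthetic benchmarks do and do not demonstrate.

## Imaging and illumination model

**Camera.** An ideal pinhole at the camera-frame origin, looking down
the −ζ axis; visible points have depth z < 0 in millimetres.  Pixel
coordinates (x, y) are continuous offsets from the principal point
(x right, y down) in pixels, as is the focal length f.  A point imaged
at (x, y) with depth z sits at M = (−xz/f, −yz/f, z) mm.  This mixed
pixel/mm convention makes expressions like ξᵢf/z + x (pixels) and
ξᵢ + xz/f (mm) dimensionally consistent; it is asserted in one place
(`geometry`).  Lens distortion is out of scope: inputs are assumed
distortion-corrected.

**Lights.** Each LED is a *near point source*: its incident direction
varies per surface point (no parallel-ray approximation is valid at
20 mm working distance with a 5.5 mm baseline).  Illuminance decays
with the inverse square of the propagation distance and with the
cosine of the angle between the propagation direction and the LED's
principal emission axis (default (0, 0, −1)).  For a light in the
camera plane this combines to a = f³/(z²q³), with q the norm of the
unnormalized illumination direction.  Cosines used as attenuations are
clamped absolute values: under the z < 0 sign convention the literal
dot products can come out negative while the physical factor is
positive.

**Surface reflectance.** Wet mucosa is modelled as two-fold: a
Lambertian body term plus a specular lobe where the mirror condition
(incident angle = reflected angle) approximately holds.  The renderer
uses Blinn–Phong: per channel c,

    I_c = Φ a (k_d ρ_c max(0, l̂·N) + k_s max(0, ĥ·N)^α),

with l̂ the unit direction to the light, ĥ the half vector of l̂ and
the view direction, and N the outward normal.  The specular lobe
carries the (white) source colour, not the surface albedo — this is
standard Blinn–Phong practice and is what makes highlights
*low-saturation* and therefore detectable by the saturation/intensity
rule.  No shadows, no interreflection, dark environment.

## Default scene and rig

| parameter | default | units | rationale |
|---|---|---|---|
| image size / f | 640×480 / 565 | px | matches the target endoscopic camera |
| principal point | (320, 240) | px | a pixel row/column lies exactly on each symmetry axis of the rig, so the rounded centroid of a symmetric highlight is not forced half a pixel off the mirror point |
| LED distance d | 5.5 | mm | capsule-head geometry, four LEDs at 0°/90°/180°/270° in the camera plane |
| plane depth | −21.37 | mm | focus-optimized working distance of the bench target |
| cap height / sphere radius | 4 / 6 | mm | polyp-sized dome with apex at −17.37 mm; the 6 mm sphere keeps the rim slope below the view-ray tangency so the depth map is continuous over the whole frame (a full hemisphere at this distance has a ~0.75 mm occlusion jump at its silhouette, which no integration scheme marching across it can undo — measured ≥1 mm RMSE over the outer plane) |
| albedo ρ | (0.85, 0.45, 0.40) | — | desaturated mucosal pink |
| k_d, k_s, α | 0.8, 0.6, 300 | — | k_s is the smallest value at which the lobe core drops below the 0.3 saturation gate (at 0.4 the highlight is undetectable by the rule it exists to exercise); α gives a compact core of tens of pixels |
| working depth range | [−100, −3] | mm | the camera's depth of field; also the seed-search interval |

The renderer works in linear radiometry (float); quantization to
8/16-bit happens only on explicit export.  Optional additive Gaussian
noise (fraction of the image maximum, seeded RNG) is off by default.

## Highlight detection

Pixels with saturation < 0.3 and intensity > 0.9 of the image maximum
(both configurable; the relative intensity gate makes detection
exposure-invariant), 8-connected, regions under 5 px dropped,
intensity-weighted centroid rounded to the nearest pixel.  The
largest-area region across the four images is the specular (σ) region;
ties go to the lowest source index; the other three lights form the
Lambertian (δ) set.  Grayscale inputs fall back to the intensity rule
alone.

The thresholded region covers only the lobe *core*.  The lobe tails
still violate the Lambertian model for another ~20 px (measured ~50%
excess irradiance 8 px from the lobe centre, ~3% at 16 px, <0.1%
beyond ~21 px at α = 300), so downstream consumers dilate each image's
exclusion mask by 18 binary-dilation steps, and the reconstruction
additionally *demotes* (prefers last, without excluding) pairs
containing an image within a 30-step dilation.  Both radii follow from
the contamination profile of the default shininess and scale with it.

## Seed-depth estimation

For an ordered Lambertian pair the irradiance ratio cancels albedo and
the normal's magnitude, leaving F_ξ z_x + F_η z_y = z F_ζ.  The mirror
condition at the highlight pixel, after eliminating its scale factor,
yields closed forms z_x = −z G_ξ/G_ζ, z_y = −z G_η/G_ζ with
b = √(x²+y²+f²) and

    G_ξ = xzq_σ + (xz + ξ_σ f) b
    G_η = yzq_σ + (yz + η_σ f) b
    G_ζ = zq_σ b² + zb³ + f(xξ_σ + yη_σ − fζ_σ) b.

Substitution gives the scalar energy E(z) = F_ξG_ξ + F_ηG_η + F_ζG_ζ,
which vanishes identically at the true depth when the pixel satisfies
the mirror condition exactly and the δ images are ideally Lambertian
(verified to machine precision against an independent vector-geometry
mirror oracle).  These G-terms are the algebraically consistent set;
note that quoting the gradient closed forms *without* the factor b in
the denominator (a form that circulates) breaks the identity.

With three δ images there are three pairs.  The estimator minimizes
the sum of squared *normalized* pair energies (each divided by the sum
of its three term magnitudes, making pairs comparable and the
objective dimensionless) over the working range: a 512-point grid scan
followed by bounded scalar minimization to 10⁻⁴ mm.  A single-pair
mode (two brightest δ images) exists for comparison, but note that on
a symmetry axis of the rig the symmetric pair is structurally
degenerate (E ≡ 0), which is why the combined objective is the
default.  Per-pixel statuses: `converged`, `edge` (minimum at the
interval boundary), `ambiguous` (a second well-separated grid minimum
within 10% of the best); only converged pixels enter region
statistics.  The centroid pixel's estimate is the recommended seed.

Sensitivities worth knowing: the energy root moves ≈0.3–0.4 mm per
pixel of displacement from the true mirror point, and ≈0.6 mm per
percent of relative error between the δ illuminances.  Seed accuracy
is therefore limited jointly by centroid rounding (≤0.5 px) and by
residual specular contamination of the δ images, not by the solver.

## Depth-map integration

The ratio PDE is discretized with first-order one-sided differences
selected by sgn(F_ξ), sgn(F_η), giving the fixed-point update

    Z = (|F_ξ| Z_up,x + |F_η| Z_up,y + Δ·s) / (|F_ξ| + |F_η|),

s = Z·F_ζ, Δ = 1 px.  F and s depend on Z, so each pixel is solved by
fixed-point iteration from the mean of its accepted neighbors
(tolerance 10⁻⁶ mm, ≤50 iterations, bracketing root solve as
fallback).  Swapping the ordered image pair negates F and s, so every
stencil exists in two orientations; information can be pulled from
either side of the characteristic.

Propagation is a deterministic fast march from the seed over the
8-connected grid: priority is highlight-mask membership last, then
number of accepted neighbors (descending), then squared Euclidean
distance from the seed (a circular front crosses the cap's rim
radially, which measurably beats a square front), then pixel index.
Each pixel, when popped, considers every usable image pair (excluding
masked images, preferring non-demoted then brighter pairs) and uses
the first admissible stencil in this order:

1. both one-sided axis differences on one side (`xy`) — among pairs
   admitting one, the pair with the largest normalized characteristic
   strength (|F_ξ|+|F_η|)/Σ(I q⁴) wins, since weak-|F| pairs divide by
   near-zero;
2. a single dominant-axis difference completed by the lagged
   cross-gradient stored at the anchor neighbor (`xg`/`yg`);
3. the diagonal difference (step Δ√2) corrected by the lagged
   perpendicular gradient (`diagg`);
4. the uncorrected single-axis / diagonal forms.

Lagged per-pixel gradients (clamped to ±3 mm/px) are recorded at
acceptance from accepted-neighbor differences.  Pixels with fewer than
two usable images are left invalid; degenerate-|F| pixels fall back to
the accepted-neighbor mean and are flagged.  Accepted depths are
clamped to the working range.  The seed pixel reproduces its boundary
value exactly, and the march is RNG-free and deterministic.

A caution for verification: the transport equation has no relaxation
mechanism, so plain Gauss–Seidel sweeps over the grid drift along the
characteristic null-space and do not converge to a unique solution —
the discrete system is well-posed only together with a causal
dependency order.  The test suite therefore checks the march against
an iterative re-solution of the same causally-ordered equations
(randomized sweep order, iterated to convergence), which reproduces
the march to <10⁻³ mm.

## Evaluation

RMSE = √mean((Z−Z_true)²) and relative RMSE = √mean((|Z−Z_true|/|Z_true|)²)
over the common valid mask, plus signed and relative error maps.

## What the synthetic benchmarks show — and what they don't

The generator reproduces the geometry and radiometry the method
assumes: exact pinhole projection, exactly known light positions and
equal intensities, linear response, no noise, no interreflection, no
shadows, homogeneous albedo.  Passing tests therefore demonstrate the
*correctness and numerical behaviour* of the algorithms, including
their response to the one model violation the scene deliberately
contains — the Blinn–Phong specular lobe, which contaminates the
Lambertian equations near each highlight.  They do not demonstrate
robustness to sensor noise, calibration error, vignetting, tissue
texture, motion, or wet-surface reflectance beyond Blinn–Phong; the
radiometry module's response inversion and denoising exist for real
images but the synthetic pipeline exercises only the linear path.

Measured behaviour at the default 640×480 scene (all recomputed by
`scripts/acceptance.py` and the test suite; no figure here is typed in
from elsewhere): seeding the march at the centroid's *ground-truth*
depth gives ≈0.075 mm RMSE (the scheme's discretization floor);
estimating the seed adds +0.064 mm of seed error which the transport
field amplifies by ≈1.8–1.9× across the frame, for ≈0.13 mm /
≈0.63% end to end; perturbing the seed by ±0.9355 mm yields ≈1.73 /
≈1.94 mm (8.2% / 9.2%).  The seed-error amplification factor is a
property of the method's characteristic field, not of this
implementation.

## Known limitations

- First-order accuracy: errors concentrate where the surface gradient
  changes fast (the cap rim) and are then transported outward; the
  entire region beyond a feature inherits the error of crossing it.
- A single seed: any seed-depth error shifts and tilts the whole
  reconstruction (≈1.9× RMS amplification); occluding contours break
  the integration domain entirely (kept out of the default scene for
  exactly that reason).
- Specular-tail contamination: the Lambertian equations are biased
  within ~20 px of every highlight; masks and demotion mitigate but
  do not remove the effect, and the seed pixel necessarily sits inside
  the worst of it.
- The energy root is steep in both pixel position and illuminance
  ratio, so seed accuracy is intrinsically sub-millimetre rather than
  sub-0.01 mm.
- Pixels where fewer than two images survive masking (the overlap of
  all four dilated highlight disks, ~5 px at the frame centre of the
  default scene) are unreconstructable by construction.
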