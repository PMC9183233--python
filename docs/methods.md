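# Methods

This note documents the models, parameter choices and numerical decisions
behind `ms2gastrula`, and what the synthetic-data tests do and do not show
about real movies.

## Coordinate, time and intensity conventions

Voxel indices are 0-based; the physical center of voxel `i` along an axis
with spacing `d` is `(i + 0.5)·d`. All distances are in µm; the default
calibration is 0.36 µm/px in xy and 1 µm in z (anisotropy ratio ≈ 2.8,
which the distance transform, watershed seeding, blob enhancement and axis
measurements all take into account via physical-coordinate sampling). Time
is minutes into nc14, computed from the movie's `t0_nc14` frame index — the
time base is metadata, not inferred from the 13th syncytial division.
Intensities are arbitrary units (AU); no absolute calibration to mRNA
counts is attempted. The dorso-ventral axis is y, ventral positive.

## Synthetic embryo generator

The generator emulates the statistical structure the analysis assumes, not
the optics of the microscope.

**Geometry.** Three regions on a flat field: a central mesoderm (ME) band,
two single-row mesectoderm (MSE) stripes at ±12 µm, neuroectoderm (NE)
rows outside. Defaults: 24 nuclei per region, 6 µm spacing, 0.8 µm
placement jitter.

**Traces.** Per nucleus and frame,

    value(t) = b(t) · (B0 + S(t)·A(t)) + ε(t),   b(t) = max(1 − β·t, 0)

with shared background `B0 = 50 AU`, bleaching rate `β = 0.004/min`
(≈ 25% loss over 62 min, typical of confocal time-lapse at this cadence),
and Gaussian noise `ε ~ N(0, (5 AU)·b(t))` — noise tracks overall
brightness, keeping the signal:background ratio of ON frames roughly
constant as the movie bleaches, as in real acquisitions where the ON margin
sits several noise SDs above background. The bleaching factor multiplies
background *and* signal; this is both the physical behavior of a shared
fluorophore pool and what makes the pipeline's bleaching normalization an
exact inverse of the generator at zero noise. Linear decline was chosen
over exponential to match the pipeline's straight-line baseline fit and
keep closed-form checks exact; the rate is small enough that the two are
indistinguishable over one nc14.

`S(t)` is a two-state telegraph process, started ON at the nucleus's onset
(onsets uniform on [25, 35] min for MSE nuclei; ME/NE are silent).
Switching probabilities default to `p_on = 0.85`, `p_off = 0.07` per
15-s frame: duty ≈ 0.92 with mean ON runs of ~3.5 min — sustained
transcription with short interruptions, the regime these mesectodermal
reporters operate in. Sparser bursting would make 15-min window means
duty-noise-dominated, which is not the regime the windowed fold-change
rule was designed for. `A(t)` is `amp_pre = 100 AU`, doubling
(`step_factor = 2`) for a Binomial(n_MSE, `p_step = 0.4`) subset of MSE
nuclei at `t_invagination + N(0, step_jitter_sd)`; the step is
instantaneous with 2-min default jitter.

**Movement.** y is constant before `t_constriction` (42 min); with
`roll_amplitude > 0` the whole field drifts dorsally over
[`t_constriction`, `t_invagination`] (tilted mounting); MSE/NE then move
ventrally by `invagination_displacement = 12 µm` over
[`t_invagination` = 50, `t_end` = 62] min while ME nuclei descend
`8 µm` in z. Both phases follow a smoothstep, so the speed profile peaks
mid-phase and the ventral-speed extremum lies inside the invagination
window by construction. Per-frame positional noise (SD 0.15 µm) emulates
centroid measurement error. The invagination drift is coherent in the lab
frame (as seen in a tilted or off-center view); profiles are oriented so
the invagination direction is positive.

**Rendering.** Nuclei are anisotropic 3D Gaussians (σ = r/2 with
r = 3 µm) of peak 2000 AU; the spot channel carries a 15% nuclear fill
(free MCP) plus one punctum (σ = 0.5 µm) per transcribing nucleus at a
per-nucleus fixed random offset inside the nucleus (fixed offsets give
spot-mobility tests an exact zero baseline), with peak proportional to the
trace value above background. Additive Gaussian noise, clipped and
quantized to uint16 (12-bit-class acquisition modeled simply; no PSF
convolution, no Poisson statistics by default, no membranes, no mitoses).

**Presets.** `control` uses the timings above; `fog_like` delays
invagination to 60 min and stretches gastrulation to 75 min; `acat_like`
zeroes the invagination movement and the stepping fraction.

## Segmentation

The enhancement filter is a log-Gaussian radial band-pass in the Fourier
domain, centered at `f0 = 1/(2·blob_radius)` with FWHM of 1 octave,
evaluated on physical frequencies (z frequencies scaled by the anisotropy).
The binarization threshold defaults to Otsu on the first frame's enhanced
volume and is then held fixed for the movie — the percentile contrast
rescaling (1 / 99.8 percentiles to [0, 1]) makes that fixed threshold
robust to bleaching. Size bounds default to [0.25×, 4×] the sphere volume
implied by `blob_radius`. Watershed seeds are local maxima of the
anisotropic Euclidean distance transform, lightly smoothed (σ = 1 µm
equivalent) and non-max-suppressed at `blob_radius` in physical distance
within each connected component, so EDT plateaus contribute one seed per
nucleus and no component loses all its seeds (the watershed can split but
never merge). Thickening by one voxel uses nearest-label expansion, which
cannot fuse objects; contested voxels go to the nearer object.

## Tracking

Literal nearest-neighbour rule: each detection looks for the nearest
detection at t−1 within a strict 6 µm cap, falling back to t−2 only when
t−1 offers none in range; lacking a candidate it starts a new track; two or
more claims on the same previous detection turn all claimants into new
tracks. Within a frame, detections are evaluated in input order and exact
distance ties break toward the lower candidate index — deterministic for a
given input. A t−2 detection is only a candidate while it is still the tail
of its track; allowing already-continued detections would fork tracks and
break the one-track-per-detection partition. MSE nuclei do not divide in
the analysis window, so no division handling exists.

## Trace processing

The ON comparison is inclusive (smoothed ≥ 1.2 × baseline) and "at least
5 ON frames" counts cumulative, not necessarily consecutive, frames. The
pass-2 baseline is a straight line refitted to the inactive-nuclei mean;
the bleach curve is the width-5 median-smoothed inactive mean normalized to
its value at the movie start, so curvature in the decay is captured even
though the baseline is linear. Normalization divides by the bleach curve
(rather than subtracting a percentage); on linearly-bleached noise-free
input this returns exactly the generated `S(t)·A(t)`. Onset is the time of
the first ON frame after smoothing. The *klar* compensation multiplies
normalized values by 1 − 0.11, removing the ~11% excess brightness of
optically cleared knock-down embryos. With zero inactive nuclei after pass
1 the caller falls back to the global baseline with a warning.

## Milestones and transition

The movement profile is the per-frame mean DV speed of the selected nuclei,
median-smoothed over 5 frames. Peaks need prominence ≥ 0.2 × the global
maximum; a profile whose maximum is below 0.3 µm/min or below 8 robust
SDs (MAD-based) of the profile noise yields no milestones (failed
invagination; on simulated cohorts intact profiles score z ≈ 16–22 and
failed ones ≤ 5). With two peaks, invagination starts at the inter-peak
minimum and constriction at the (interpolated) onset of the first peak;
with one peak, invagination starts where the ventral speed first crosses
0.2 × peak height, and gastrulation ends where it falls back below that
level, both linearly interpolated between frames.

The transition point is the exhaustive two-plateau least-squares
changepoint (minimum segment 4 frames), accepted only when the one-plateau
SSE exceeds the two-plateau SSE by a factor ≥ 2 — the automated counterpart
of "only embryos with a clear change in levels". Cohort-level detection
windows the search to open at the 0.9 quantile of active-nucleus onsets:
the mean trace's activity-onset ramp is otherwise a larger level change
than the gastrulation step and would capture the changepoint. On
20-embryo simulated cohorts the median detected transition is ~50 min for
control timing and ~60 min for fog-like timing.

The increasing-nucleus rule is deliberately conservative: for a ×2 step it
only tolerates step times from −2.6 to +4.5 min around the invagination
reference (outside that range the 15-min window means cannot reach 1.7×).
Recovery tests therefore use cohorts with 1-min step jitter
("well-separated"), where precision ≈ 1.0 and recall ≈ 0.95; at the default
2-min jitter roughly one in eight true steppers falls below the fold
criterion, which also dilutes the reported fraction of increasing nuclei
relative to the generator's `p_step`.

Pooled R² is the squared Pearson correlation of per-embryo (event time,
transition time) pairs after excluding embryos without an accepted
transition; a degenerate constant variable returns 0 with a warning, and
fewer than 3 pairs is an error.

## Spot and shape metrics

DoG localization uses sigmas 0.36/0.9 µm (scaled per axis by the voxel
calibration), keeps a peak only above 3 SDs of the DoG response, and
refines it by the positive-DoG weighted centroid of the 3×3×3
neighborhood. The His2Av window is a single z-plane 5×5 px mean, averaging
only valid pixels at image borders. Spot mobility differences the
spot-minus-centroid *offset vector* between adjacent observed frames
(nuclear translation cancels exactly; the alternative distance-to-centroid
reading does not have that property), then applies a centered 8-frame
rolling median; gaps yield undefined speeds rather than interpolation.
Nuclear axis lengths are `2·sqrt(5·λ)` of the voxel-coordinate covariance
eigenvalues — the exact full-axis lengths of the equivalent uniform solid
ellipsoid; accuracy requires the smallest semi-axis to span several voxels
(tests use ≥ 500-voxel objects). Cell contact length dilates both the cell
and each mesoderm cell by one pixel (8-connected unit square) and counts
the intersection; it is symmetric by construction. Region-level factor
curves weight each nucleus equally rather than pooling voxels.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale by design: rendered
stacks of ~112×112×14 voxels over 8 frames (14 nuclei), trace-level
cohorts of 72 nuclei × 280 frames, and 20-embryo cohorts for timing
statistics. The generator reproduces the *statistical* structure the rules
depend on — baselines, bleaching, bursts, steps, phased movement — but not
optical blur, Poisson noise, segmentation artifacts from touching
chromatin, mitotic waves, or curvature of the embryo surface; passing
recovery tests therefore validates the pipeline's logic and numerics, not
its performance on degraded real movies. Membrane segmentation is consumed
as external 2D label images, never computed. Statistical testing beyond R²
is out of scope.
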