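# Methods

This note documents the models implemented in `hemoveloc`, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical decisions taken where the design was open.

## Flow phantom

### Triphasic inflow waveform

Peripheral femoral flow is triphasic: a systolic forward lobe, an
early-diastolic backflow phase, and low late-diastolic forward flow.
`make_triphasic_waveform` builds this shape from three raised-cosine
lobes.  A raised cosine `A/2·(1 − cos 2πt/w)` starts and ends at zero
value and zero slope, so the composite waveform is C¹-smooth and
strictly periodic, and its integral `A·w/2` lets every lobe be
calibrated to a requested volume in closed form.  Lobe boundaries are
snapped to sample points; because the trapezoidal rule integrates a
full cosine period exactly on a uniform grid that contains both
endpoints, the positive and negative phase volumes match the requested
9.6 mL and 2.3 mL to machine precision rather than to a discretization
tolerance.

Defaults: period 1 s (60 bpm); systolic lobe 30% of the period,
backflow lobe 20%, diastole the remaining 50%; 15% of the forward
volume carried by the diastolic bump.  These fractions are a choice —
the experimentally measured waveform shape is not recoverable
numerically — selected to give a physiologically plausible femoral
shape; with the default volumes they yield a peak systolic flow of
54.4 mL/s, consistent with the peak systolic flow rate of the flow
conditions being emulated (54.2 mL/s).  The generator is a calibrated
surrogate, not a replica of any measured curve.

The outlet split (superficial 44% / deep 56% of mean flow) is
implemented as a time-invariant proportional split.  The physical
split is shaped by the downstream Windkessel impedances and is
time-varying; modeling that is out of scope, so a hook accepts a
user-supplied SFA waveform instead.

### Fluid properties

Blood-mimicking fluid: ρ = 1144 kg/m³, μ = 4.17 mPa·s (within the
physiological range of blood).  The transitional-flow worked numbers
(Reynolds number, Kolmogorov length) use their own printed inputs in
mm/kg/s units (ρ = 1.14·10⁻⁶ kg/mm³, μ = 4.16·10⁻⁶ kg/(mm·s)), which
correspond to a slightly different density (1140 kg/m³); both constants
are exposed explicitly rather than silently reconciled.

### Womersley and Poiseuille profiles

For fully developed pulsatile flow in a rigid straight tube, the
waveform is Fourier-decomposed (FFT over one uniformly sampled cycle)
and each harmonic of angular frequency ω maps to the Womersley
solution

    u_k(r) = (Q_k / πR²) · (1 − J₀(Λ r/R)/J₀(Λ)) / (1 − 2J₁(Λ)/(Λ J₀(Λ))),
    Λ = i^{3/2} α,   α = R √(ωρ/μ),

with the steady term the Poiseuille parabola `2Q₀/(πR²)(1 − r²/R²)`.
The default 20 harmonics reproduce the default waveform through the
flow integral to well under 1% RMS.  No-slip is enforced exactly at
r = ±R.  The inverse map (`flow_rate_from_centerline`, the
Doppler-ultrasound emulation) divides each harmonic of a centerline
velocity series by the same solution's centerline-velocity-per-unit-flow
factor; forward and inverse share the Bessel kernel, and their
consistency is checked against the independent flow-integral route and
closed forms in the tests.  An optional multiplicative bias parameter
(default 1.0, never applied silently) emulates the systematic
peak-velocity overestimation of clinical pulsed-wave Doppler.

### Stenotic-jet field

The post-stenotic flow surrogate is built from a streamfunction
ψ(x, y) so that incompressibility is structural, with two parts:

* a parabolic channel profile whose core half-width follows the wall
  contraction into the throat (width factor 1 − area_reduction, so the
  throat mean velocity scales by 1/(1 − AR), e.g. 4× for a 75%-area
  stenosis) but reopens only over `jet_length` downstream — the
  persisting jet;
* a recirculation term ∝ sin(2π y/h_wall(x)), zero on the walls and
  centerline so it carries no net flux, windowed to the region just
  downstream of the throat, with default relative strength 0.075
  (reversed-flow speeds ≈ 30% of the jet, matching the qualitative
  picture of post-stenotic recirculation).

Velocities are obtained by applying the *same* second-order central
differences to ψ (vx = D_y ψ, vy = −D_x ψ), so the discrete divergence
D_x vx + D_y vy cancels identically at interior nodes and the
trapezoidal cross-sectional flux telescopes exactly to ψ_top − ψ_bottom
at every station.  For this reason the sub-grid residual velocities in
the single node row outside the clamped wall are retained (zeroing
them would break the telescoping); the lumen mask excludes them from
all analysis.  The 2D line flux is tied to the 3D waveform through an
effective out-of-plane depth of πR/2, chosen so the inlet mean
velocity equals Q/(πR²); the depth is stored in the field's attrs.
This is a kinematic surrogate with the right continuity, jet scaling
and recirculation topology — not a Navier–Stokes solution; it carries
no turbulence, no jet breakdown and no cycle-to-cycle variation.

### Particle rendering and clutter

Tracers are rendered as Gaussian blobs (diameter 3 px, σ = d/2.355,
per-particle brightness uniform in [0.6, 1]·0.55·full-scale) at a
default seeding of 0.05 particles/px², standard synthetic-PIV
practice.  Particles are advected by midpoint (RK2) integration of the
bilinearly interpolated field over 1/frame_rate and re-injected at the
inflow boundary with a fresh transverse coordinate when they leave the
domain, keeping the density stationary.  All randomness flows from a
single integer seed per call; stacks are bitwise reproducible.  The
sequence records the physical position of its lower-left corner
(calibration), which anchors PIV output grids in the lab frame.

Clutter emulates strong, slowly moving tissue signal: a smooth random
pattern under a broad Gaussian envelope whose drift at a prescribed
speed is represented by the truncated Taylor expansion of the shifted
pattern.  This guarantees the added component's Casorati matrix has
*exact* rank ≤ the requested clutter rank while still showing
frame-to-frame motion — a construction chosen precisely so the SVD
filter's behavior can be scored against a known-rank target.  The
injected component is returned alongside the frames so benchmarks can
subtract it exactly.

What the synthetic data do **not** emulate: ultrasound point-spread
functions and speckle, acoustic attenuation and beamforming, optical
refraction, compliant wall motion, out-of-plane motion, and
turbulence.  Passing tests therefore demonstrate the correctness of
the analysis chain on controlled inputs, not the field performance of
either imaging modality on real recordings.

## PIV

Displacements are estimated per interrogation window by zero-mean
cross-correlation computed via FFT with zero padding to twice the
window and per-displacement normalization by the overlap area — the
minimum-bias ("unbiased") estimator, which removes the triangular
loss-of-pairs envelope that biases plain circular correlation toward
zero.  Planes are scaled so the peak is a correlation coefficient in
[0, 1].  The peak is searched within ±0.45·window and localized to
subpixel precision by a 3-point Gaussian fit per axis (parabolic
fallback when a neighbor is non-positive).  Correlation averaging
(echoPIV) averages the normalized planes of a block of consecutive
frame pairs before the peak search, one output field per block.

Multipass refinement runs the window schedule in order, interpolating
the previous pass's displacement onto the refined grid and applying it
as a symmetric integer window offset (first frame −s//2, second frame
s + that).  Window deformation is deliberately not implemented; for
strongly sheared regions this is an accuracy-limiting simplification.
Between passes the normalized median test (threshold 2, ε = 0.1 px,
8-neighborhood) flags outliers, which are replaced by the mean of
valid neighbors.  Zero-variance windows are flagged invalid and filled
the same way.

Conventions fixed where the pipelines' printed output rates leave a
unique choice: optical PIV pairs frames non-overlapping
((0,1), (2,3), …; 8000 fps → 4000 raw fields/s → 400 fields/s after
the 10-ensemble block average) and echoPIV pairs sliding with
correlation-averaging blocks of 10 (9000 fps / 3 angles = 3000
correlations/s → 300 fields/s).  In both modes the frames of a pair
are adjacent, so velocity = displacement × pixel size × frame rate;
the pair rate only sets the output field rate.  The final vector
spacing is last window × (1 − overlap) × pixel size (0.42 mm for the
optical preset at 52.5 µm pixels; 0.22 mm for the echo preset at
110 µm).  The echo postprocessing order — 3×3 mask-normalized Gaussian
in space, then the 3-field temporal moving average — is a fixed choice
where either order would be defensible.

## Clutter filtering

The Casorati matrix (pixels × frames) is decomposed by thin SVD per
contiguous acquisition block.  Filtering retains components with
1-based index in (low, high].  Threshold detection uses the similarity
matrix of the *magnitudes* of the spatial singular vectors: the raw
vectors are orthogonal by construction, so their correlation is
uninformative, whereas tissue components share a spatial energy
support and correlate strongly in magnitude.  The clutter subspace is
taken as the contiguous leading block whose similarity to the first
component stays ≥ 0.3; a running-mean variant was rejected because the
trivial self-similarity term drags the mean and overshoots the block
edge.  With no detectable block the filter returns (1, rank) with a
warning; both thresholds can always be set manually.  When a
precomputed decomposition is supplied, the filter acts as the linear
projector onto the selected spatial subspace, making it additive
across sequences — the form used by the known-clutter benchmarks.

## Hemodynamic parameters

* **Flow rate** from a diameter profile: Q(t) = π ∫ u(r,t)|r| dr by
  the trapezoidal rule on the native radial grid, equivalent to
  averaging the two half-diameter contributions.  Profiles that stop
  short of the wall are extended linearly to zero at ±R with a
  warning.
* **Vector complexity**: VC = 1 − √(x̄² + ȳ²) with x̄, ȳ the mean
  cosine/sine of θᵢ = atan2(v_y, v_x) over the region of interest,
  per time sample.  VC is invariant under global rotation and axis
  swap, so the atan2 argument convention is immaterial.  Vectors
  slower than 10⁻⁶ cm/s are excluded (direction undefined); a sample
  with no valid vector reports NaN.
* **TAWSS**: at each wall vertex the wall-parallel velocity component
  is sampled by linear interpolation at 8 points over 2 mm along the
  inward normal; a weighted cubic least-squares fit constrained
  through zero at the wall (basis s, s², s³ — a single-segment cubic
  spline) with weights ∝ wall distance (down-weighting the least
  reliable nearest-wall samples) gives the wall gradient;
  WSS(t) = μ·du/dn and TAWSS is the cycle average of |WSS|.  The fit
  is exact for parabolic profiles, hence the steady Poiseuille check
  against 2μu_max/R.  Vertices with fewer than 4 valid samples are
  NaN.  Magnitude-averaging (rather than signed averaging) is a fixed
  convention.
* **Reynolds number / Kolmogorov length**: Re = vρL/μ and
  η = l_c·Re^(−3/4) under isotropic-turbulence scaling.  With the
  printed transitional-flow inputs these evaluate to Re = 3780 and
  η = 0.0185 mm; the implementation returns the formula value (a
  printed rounding of 0.019 mm exists for the latter).

## Agreement statistics

Cycles are aligned at peak systole, defined as the maximum of the
spatial-mean speed inside the mask (earliest sample on ties — the
alignment statistic is a fixed choice), cropped to one period,
resampled to a 100-point normalized cycle, and ensemble-averaged with
per-node/phase SD.  Ensembles are compared after bilinear spatial and
linear temporal resampling onto the reference grid; reference nodes
outside the test mask are excluded pairwise and counts are always
reported.  Differences are taken between velocity *magnitudes*
(speeds), pooled over all nodes and phases (or the peak-systole phase
only), and summarized as mean ± 1.96·SD limits of agreement plus
per-node mean/SD difference maps.  No significance testing is
performed; the statistics are purely descriptive.

## Pipeline, units, determinism

Interfaces use cm/s for velocity, mm for length, mL/s for flow, Pa for
stress; conversions live inside operations and file formats carry unit
attributes (a velocity HDF5 without a units attribute is rejected
outright).  The end-to-end driver validates its config against a
schema before any compute, derives every stage seed from the single
run seed, logs all thresholds actually used (SVD ranks, PIV schedule)
in a run manifest, and is deterministic: identical config + seed give
identical outputs.

The demo configuration is deliberately demo-scale: 0.05 s cycles at
500 fps rendering and a two-pass 32/16 schedule, so the full chain
(synthesis → rendering → PIV → VC → agreement) completes in seconds;
the same code paths run the full-scale presets unchanged.  Test and
acceptance problem sizes (image extents of a few hundred pixels, tens
of frames, single-cycle ensembles) were likewise chosen as the
smallest sizes at which each property is cleanly measurable.

## Known limitations

* No window deformation in PIV: velocity gradients within a window
  bias estimates in shear layers and near walls.
* The stenotic field is kinematic; it cannot validate sensitivity to
  turbulence, jet breakdown, or cycle-to-cycle variability.
* TAWSS from PIV-resolution fields inherits the near-wall resolution
  limit; the weighted-fit choice affects absolute values.
* The clutter-rank detector is a stand-in with the same interface as
  published similarity-matrix methods, not a reimplementation of any
  specific one.
* DUS emulation reduces Doppler physics to centerline sampling with an
  optional bias factor; spectral broadening and sample-volume effects
  are not modeled.
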