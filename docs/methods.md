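# Methods

## The measurement problem

AFM tapping-mode imaging of fixed neutrophils yields height maps: grids of
surface heights (nm) at a lateral sampling of roughly 10–60 nm/pixel
depending on scan size (5 × 5 µm membrane patches at 512 points per line up
to 100 × 100 µm overview scans). During activation by PMA (a protein kinase
C activator) or the calcium ionophore A23187, neutrophils spread, lose
nuclear segmentation, shed a halo of sub-micron membrane fragments, and
finally rupture and release NETs — meshworks built from ~30–50 nm granules.
The package quantifies those changes from topography alone.

## Spatial spectrum convention

For a profile h_n (n = 0..N−1, spacing Δx) the spectrum is one-sided
amplitude-squared:

    S_k = |(2/N) Σ_n h_n exp(−2πi k n / N)|²,  ν_k = k / (N Δx),

for k = 1 .. ⌈N/2⌉−1. A cosine of amplitude A at an on-grid frequency gives
S = A² in its bin, so S reads directly as the squared roughness amplitude at
that period. DC is excluded (profiles are detrended first: least-squares
line in 1-D, plane in 2-D) and the Nyquist bin is excluded as well because
the one-sided doubling is wrong for it; Parseval then takes the form
Σ S_k / 2 = var(h) exactly for odd N, and var(h) minus the Nyquist power for
even N. No taper window is applied: the synthetic validation works at
on-grid frequencies where leakage vanishes, and real patches are large
relative to the periods of interest. Patch spectra average the per-row
spectra of a 5 × 5 µm patch centred on the cell apex, which stabilises
S_max; single-profile spectra remain available for figure-style output.

Two period windows, first order 600–1200 nm and second order 50–300 nm,
define the readout triple (S_max, ν_max, L_max = 1/ν_max) per window. Window
edges are inclusive; ties break toward the lowest frequency (largest
period). The 2-D band-pass reconstruction keeps coefficients with *radial*
frequency inside the window — roughness is treated as isotropic since no
orientation information is available.

## Synthetic scenes and their ground truth

The generator emulates the study conditions; every default is a study-level
number, not a tuning knob:

- **Cell body**: super-Gaussian cap h(r) = H·exp(−β(2r/D)^(2p)) with
  β = ln(H/20 nm), so the basal contour at the 20 nm contact height has
  exactly diameter D. Exponent p = 3 spans tall control cells through
  flat-topped spread cells. Control preset: H = 1200 nm, D = 9800 nm;
  spread presets: 638 nm and 300 nm at D = 16 500 nm (≈1.7× control);
  disrupted remnant: 100 nm. Nuclear lobes are Gaussian bumps (default
  200 nm tall, σ = 700 nm) on a ring at 0.35·D/2; the textured surface is
  rescaled so its maximum equals H exactly, and the effective roughness
  amplitudes recorded in the ground truth shrink by the same factor.
- **Roughness**: seeded white noise band-limited to a one-sided annulus
  [ν₀, 1.3ν₀] with ν₀ = 1/period, rescaled so the dominant peak of the
  row-averaged profile spectrum equals amplitude². The annulus is one-sided
  because the 1-D marginal of an isotropic ring peaks at the ring's lowest
  frequency; anchoring the ring at ν₀ makes the recovered L_max equal the
  nominal period. Within a cell scene the roughness rides on a membrane
  skirt (cap ≥ 2 nm), slightly beyond the basal contour, so that rim
  fluctuations are symmetric about the segmentation threshold. Control
  amplitudes 40 nm (S = 1600 nm²) and 2.3 nm (S ≈ 5.3 nm²) for the two
  bands.
- **Fragments**: paraboloid bumps with equivalent diameters drawn from a
  Gaussian mixture truncated below 150 nm (the observed lower end of halo
  structures), placed by rejection sampling with at most 10·n attempts;
  failure raises an error reporting the placed count, never a silent
  truncation, so ground-truth counts stay exact. A separation factor < 1
  optionally lets dense late-time halos partially overlap — emulating the
  observed fusion of fragments into larger structures — at the cost of
  merged detections. Presets: 26 fragments of 0.33 ± 0.15 µm (30 min),
  40 of 0.40 ± 0.19 µm (60 min), 58 with modes 0.25/0.81 µm (120 min);
  heights 16 ± 4 nm rising to 61 ± 13 nm.
- **NET meshwork**: chains of paraboloid granule beads (size ~ N(50, 20) nm
  for A23187, N(30, 10) nm for PMA) along random-walk paths at ≤ 3 nm/pixel.
  Beads are laid bead-to-bead with a 15% gap so each granule remains an
  individually resolvable connected component; chains avoid each other and
  their own earlier beads by bounded-retry rerouting.
- **Substrate noise**: 1 nm SD Gaussian (a free choice; the instrument
  noise floor is not reported). One integer seed feeds one named RNG stream
  per component (noise, cell, band1, band2, fragments, mesh), so scenes are
  bit-reproducible and components individually regenerable.

What the generator does **not** emulate: tip convolution, scan-line
artefacts and drift, sample tilt beyond a linear plane, spatially
correlated instrument noise, partially adherent or overlapping cells, and
NET fibre connectivity (granule chains are geometric, not mechanical).
Passing round-trip tests therefore demonstrates estimator correctness under
clean imaging assumptions, not robustness to every instrumental artefact.

## Morphometry

Background: the lowest quartile of heights is taken as pure substrate
(assumes ≥ 25% substrate pixels); its median and MAD are corrected with the
exact Gaussian lower-tail constants (median of the tail = µ − 1.15035σ,
MAD of the tail = 0.302193σ) to give the substrate level and noise SD.
Segmentation threshold: level + max(3σ, 20 nm); the 20 nm floor prevents
noise-driven masks on clean substrates and coincides with the generator's
contact height, making diameters comparable. The cell is the largest
connected component above threshold, holes filled; h_max is the mask
maximum above the level; diameter is equivalent-circle from mask area
(rotation-stable, unlike profile widths, which remain available from
`extract_profile`).

Lobe counting smooths with a Gaussian of 800 nm FWHM and counts h-maxima
with prominence above max(5σ_noise, 10% of h_max). The kernel width is a
documented knob: it must attenuate the first-order spongiform roughness
(period ~1000 nm, which at 250 nm smoothing would itself be counted as
maxima) while preserving micrometre-wide lobe bumps; 800 nm reduces a
1000 nm corrugation by ~10× but a σ = 700 nm lobe by only ~20%.

Typing rules, in order: type 4 if the mask is fragmented (solidity < 0.5),
a NET mesh was detected, or the cell is nearly flat (h_max < 150 nm) amid
off-mask particle cover (> 0.2% of substrate pixels above threshold);
type 1 if h_max ≥ 900 nm and diameter ≤ 12 µm; type 2 if h_max < 900 nm
with ≥ 2 lobes; type 3 if h_max < 900 nm with ≤ 1 lobe; otherwise "other"
(label 5). The thresholds are calibrated to the printed control/spread
heights and diameters; the generator assigns ground-truth labels from the
same table applied to the generating parameters, so classifier recovery
tests measure estimation error, not rule agreement.

## Particles and modality

Fragments and granules share one detection path: connected components above
level + max(3σ, floor) outside the cell mask, with floor 10 nm (fragments)
or 2 nm (granules), discarding components under 4 pixels. "Size" is the
equivalent-circle diameter of the component; area and maximum height are
carried alongside. Touching particles merge (no watershed splitting — a
deliberate limitation, exercised by a fixture). A paraboloid of height h
thresholded at t has footprint diameter D√(1 − t/h); the tests use that
closed form as the oracle for detected sizes.

Modality: 1- and 2-component Gaussian mixtures are fitted (5 restarts,
fixed seed); two modes are declared when the BIC improves by more than 2.
The decision is scale-invariant because rescaling shifts both models'
log-likelihoods equally. Mixtures truncated at zero are approximated by
untruncated fits, adequate at the observed size/SD ratios (≥ 2σ from zero).
At least 8 observations are required.

## Statistics

The regression is OLS of S_max (nm²) on h_max (nm) — the slope b has units
nm, fixing the direction of the fit — pooled over time points within one
activator arm and spectral order. Slope ratios between arms and
control/activated fold-changes use exact rational arithmetic with a single
terminal rounding (ratios to 2 decimals, fold-changes to 2 significant
figures). Mann–Whitney comparisons are two-sided, exact (no ties, smaller
sample ≤ 8) or normal-approximated with tie correction, starred at
p < 0.05/0.01/0.001. No multiple-testing correction is applied across
panels. Where the study reports two control intensities per order without
distinguishing them, the pipeline simply reports per-sample values and does
not attempt to resolve the ambiguity; likewise L = 1/ν is applied strictly
even where reported period ranges and frequency ranges are not exact
reciprocals.

## Time-course simulation sizes

`simulate_time_course` defaults to 10 cells per time point per arm, 3
fragment sections and 2 mesh scans; the test suite and the acceptance
script run 2–6 cells per time point, 20-seed spectral round trips, 50-seed
particle/modality checks, 120–200 classifier scenes and 100–200 regression
cohorts. These sizes keep full runs to a couple of minutes while leaving
Monte-Carlo rates (≥ 90% thresholds) far from their pass boundaries.

## Known limitations

- Component-based particle detection undercounts fused halos and reads
  thresholded (slightly shrunken) footprint diameters; both effects are
  systematic and documented rather than corrected.
- Lobe counting sees apex topography only; cells whose nuclear lobes do not
  deform the membrane are typed by height and diameter alone.
- The spectral window for the second order spans bins whose marginal ring
  energy is broad; recovered L_max for broad high-frequency bands can sit
  anywhere within the generated annulus (up to ~20% above the nominal
  period) even when S_max is recovered tightly.
- The classifier thresholds are specific to neutrophil-scale cells
  (heights 0.1–2 µm, diameters 6–20 µm) and would need recalibration for
  other cell types.
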