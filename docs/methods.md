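# Methods

## Spectral phasor transform

For a pixel spectrum *I(k)* over *N* frames in ascending-wavenumber order,
the phasor coordinates at harmonic *n* are

    G = Σₖ I(k) cos(2πnk/N) / Σₖ I(k)
    S = Σₖ I(k) sin(2πnk/N) / Σₖ I(k)

The transform is linear in intensity, scale-invariant (brightness cancels),
and bounded (G² + S² ≤ 1; asserted with a 10⁻⁹ absolute slack for
double-precision accumulation). The harmonic defaults to *n* = 1, the
standard choice: it gives the widest phasor spread for single broad
features. The test suite checks the transform against an independent
per-pixel loop oracle at 10⁻¹² relative tolerance and checks linearity via
the intensity-weighted mixture law.

**Multi-window stacks.** Acquisitions that cover several disjoint windows
(the C–H window plus two cell-silent windows) are concatenated frame-wise
and transformed with the *frame index*, not the physical wavenumber, as the
Fourier coordinate — windows are abutted, no gap handling or resampling.
This is deterministic and mirrors running the analysis on combined image
stacks; the alternative (physical-wavenumber coordinate with gaps) would
make the phasor depend on an arbitrary gap-filling convention. Window
subsets can be selected before the transform, so silent-region-only
analyses use the same code path.

**Frame order.** Stacks store frames in acquisition order — descending
wavenumber within each window, matching pump-laser tuning from short to
long wavelength — and every spectral operation sorts ascending internally.
A 0.4 nm pump step maps to 10⁷·Δλ/λ² ≈ 7 cm⁻¹ near 756 nm; the step is
carried as metadata only, never used to derive the axis (absolute pump and
Stokes wavelengths are instrument-specific and not modelled).

**Validity mask.** Pixels whose summed intensity falls below a threshold
have a noise-dominated, undefined phasor; they carry (0, 0) and an explicit
invalid flag, and are excluded from histograms and segmentation (avoids NaN
propagation). `phasor_transform` defaults the threshold to 1% of the
maximum per-pixel total. The pipeline instead defaults to Otsu's criterion
on the *log* total-intensity image: SRS total-intensity histograms are
strongly right-skewed (a large dim background plus a long bright
foreground tail), and log-Otsu puts the split at the
background/foreground valley for both the 115-frame and the
silent-windows-only analyses, whereas a fixed fraction of the maximum
admits the background for bright scenes. Both modes and a numeric override
are config-exposed.

## Segmentation

Gates are simple polygons in (G, S) space. Point-in-polygon tests are
boundary-inclusive; overlaps resolve by unique gate priority (higher wins),
mirroring layered manual gating deterministically. Automated gating runs
k-means (k-means++ initialization, fixed seed, 10 restarts) on the
valid-pixel phasor cloud and returns each cluster's convex hull as a gate.
Priorities are assigned by descending member count so the *smallest*
cluster has the highest priority: where hulls of adjacent clusters overlap,
compact minority populations are not swallowed by large ones. Degenerate
(collinear) clusters fall back to a padded bounding box. k defaults to 9,
the number of regions of interest in the headline triplex experiment
(six compartments + three probe channels).

Recovered segments are scored against ground truth by the full IoU matrix
and an optimal one-to-one assignment (Hungarian algorithm, maximizing total
IoU); a class counts as recovered at IoU ≥ 0.5, the standard detection
convention. Empty segments are reported with pixel count 0 and flagged
(NaN) spectra rather than dropped, so gating errors stay visible.

## Reference library and RIE

Each component is a sum of Gaussian (σ = fwhm / (2√(2 ln 2))) and
Lorentzian (γ = fwhm/2) peaks. The RIE of a band is the ratio of
baseline-corrected band maxima (or, optionally, trapezoid band areas)
between the sample band and the EdU alkyne band fixed at 2090–2150 cm⁻¹.
The baseline is the straight line through the band's endpoint samples —
the simplest reproducible correction; it makes the RIE exactly invariant
to constant offsets and equivariant under intensity scaling (both are
property-tested). Height, not area, is the default because tag brightness
is conventionally quoted as band intensity; the area method is offered but
its values are not calibrated.

Peak shapes in `references.json` are nominal. At load time every component
with a published RIE is rescaled so its baseline-corrected band height on a
1 cm⁻¹ grid equals RIE × EdU's band height: metallacarborane 3, bis-alkyne
butadiynes 12 (the 4-fold ratio), EdU 1 by definition. The split B–H
envelope is modelled as three overlapping Gaussians spanning
2480–2650 cm⁻¹; the sub-peak positions and widths are free parameters (the
underlying band tables are not public), as are the ortho-carborane (2.0,
kept below the metallacarborane) and stearic-d35 (0.8) values, which
preserve the published orderings without claiming measured numbers.
Fingerprint modes (B–B–M bend ~635 cm⁻¹, cage rocking ~250 cm⁻¹,
whole-molecule ~205 cm⁻¹) are included for completeness but lie outside
every default scan window. The CoSAN-D₂ C–D doublet is placed at its
measured 2260.4/2273.4 cm⁻¹ positions with uncalibrated amplitudes.

## Synthetic scenes

The generator emulates a single-plane, single-cell triplex experiment:

- **Geometry** (256 × 256 default): cell and nucleus ellipses; nucleoli,
  lipid droplets (plain and probe-labelled) and probe pockets placed
  uniformly at random inside their parent compartment by rejection
  sampling (retry budget 1000 per object, then a placement error naming
  the compartment); LD periphery and cell boundary are morphological
  dilation/erosion bands. All placements derive from the scene seed;
  identical (spec, plan, seed) gives bit-identical masks and stacks.
- **Spectra.** Each of the nine classes is a weighted sum of library
  references. Relative compartment amplitudes are not published anywhere,
  so the weights are plausibility choices fixed in the preset; they were
  chosen so the class spectra differ in *shape* (the phasor ignores
  brightness): protein:lipid ratio separates the label-free compartments,
  probe fraction separates the probe channels. Nuclear metallacarborane
  weight is 0.3× the cytoplasmic weight ("weak nuclear association"); the
  co-localized droplet class carries both the fatty-acid CD₂ and the
  alkyne band; alkyne-only pockets carry the alkyne alone. The preset
  satisfies, by construction, the separability precondition under which
  segmentation acceptance is meaningful: pairwise analytic class-phasor
  distances exceed 4× the noise-induced within-class spread (asserted by a
  dedicated test; minimum distance ≈ 0.10 vs spread ≈ 0.02).
- **Noise.** Shot noise is Poisson with `poisson_scale` counts per
  intensity unit; read noise is additive Gaussian over an optional
  constant offset; negatives are clipped (SRS intensity is physically
  non-negative). Defaults resolve against the scene: Gaussian SD = 2% of
  the peak compartment amplitude, and `poisson_scale` = 400/peak so the
  shot-noise SNR at the brightest band is ≈ 20 — visibly noisy but
  comfortably separable phasor clusters. Both are config-exposed;
  the background-noise SD is validated against the model on ≥ 10⁴
  background pixels to 5%.
- **Presets.** `triplex_crsan` (headline, 9 classes, 115 frames),
  `singleplex_fesan` (7 classes, C–H + B–H windows, probe in cytoplasm
  pockets and nucleolus) and `triplex_imidazole` (pan-cellular bis-alkyne
  that also enters the nuclei).

What the generator does *not* emulate: optical blur and spatial
correlations of real microscopes, out-of-focus background, water/solvent
bands, probe pharmacokinetics, z-structure, or spatially varying
compartment spectra. Passing tests therefore demonstrate the correctness
and internal consistency of the unmixing machinery under the stated noise
model, not performance on real cell data, where cluster overlap and
spatial artifacts can be substantially worse.

## Pipeline and determinism

`run_pipeline` executes simulate/load → concatenate → phasor → segment →
segment spectra → composite → evaluate, timing each stage, and writes every
intermediate artifact (window TIFFs + JSON axis sidecars, gates JSON, label
TIFF + name map, spectra CSV, composite TIFF, report JSON, resolved config
YAML). One config seed drives all stochastic stages through fixed offsets
(scene = seed, k-means = seed + 1), so a report is reproducible from its
config; `run_report_compare` refuses to diff reports with different config
hashes and otherwise compares metrics byte-level (timings excluded). Stage
isolation is tested: re-running from the on-disk window stacks reproduces
the segmentation exactly.

Problem sizes used in the shipped analyses: the full 256 × 256 scene with
the 40 + 35 + 40 frame plan for the headline runs, and a 64 × 64, 34-frame
scene with the same class structure for unit tests. The silent-region
evaluation scores against probe-level ground truth (B–H-bearing classes;
CD₂ + alkyne co-localized; alkyne-only), since compartments without probes
are dark there by construction.

## Known limitations

- Index-based window abutment means phasor coordinates change if the scan
  plan (frame counts per window) changes; gates are only transferable
  between identically planned acquisitions.
- Convex-hull gates from k-means can overlap for adjacent clusters; the
  priority rule resolves this deterministically but can shave boundary
  pixels from large clusters.
- The area-method RIE values are not calibrated (height is the calibrated
  convention) and differ from the height values for broad bands.
- No median filtering or intensity weighting of the phasor plane is
  implemented; gating operates on the raw per-pixel phasor.
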