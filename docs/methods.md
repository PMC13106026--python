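# Methods

This note documents the physical models, numerical choices and defaults of
the `decbct` package, and what its simulations do and do not establish about
real scanner data.

## Materials and attenuation

Elemental mass attenuation coefficients (total, with coherent scattering) for
H, C, N, O, F, Al, Ar and Ca are embedded on the standard 11-node grid from
10 to 200 keV. Compound and mixture coefficients follow the mixture rule
μ/ρ = Σᵢ wᵢ (μ/ρ)ᵢ over elemental mass fractions; interpolation between
nodes is log-log, which is exact at the nodes and accurate to well under 1%
between them in the diagnostic range. No embedded material has a K-edge
above 20 keV, so linear attenuation is monotone non-increasing over
40–150 keV — a property the test suite asserts for every material.

The phantom materials are the classic sensitometry set: air, PMP, LDPE,
polystyrene, acrylic/PMMA, Delrin (POM), Teflon (PTFE), and two
bone-equivalent materials at densities 1.14 and 1.40 g/cm³ with
literature-style H/C/N/O/Ca compositions. The module background is a
water-like epoxy (≈ +45 HU at 60 keV). Theoretical HU at energy E is
1000·(μ_m(E) − μ_w(E))/μ_w(E) from the same tables that drive the
simulation, so HU-accuracy metrics isolate pipeline error rather than
cross-database disagreement.

## X-ray spectra

Tube spectra are analytic: a Kramers bremsstrahlung continuum
N(E) ∝ (kVp − E)/E hardened through an Al-equivalent filtration thickness
(default 2.5 mm), plus the four tungsten K fluorescence lines (58.0, 59.3,
67.2, 69.1 keV) carrying 7% of the filtered continuum fluence when the tube
potential exceeds the K-edge. Spectra are relative (unit-sum) fluences on a
1 keV grid from 20 to 150 keV; absolute scale enters through mAs and the
fluence parameter below. Externally tabulated spectra can be loaded from CSV
(`Spectrum.from_csv`) and used everywhere a generated spectrum is accepted.
With the default filtration the fluence-weighted mean energies are ≈ 42 keV
(80 kVp) and ≈ 56 keV (140 kVp); the corresponding Al/PMMA
monoenergetic-equivalent matrix has condition number ≈ 27, comfortably
below the 10⁶ guard at which a spectrum pair is rejected as degenerate.

## Acquisition model

The default geometry is a centred flat-detector fan beam: source–axis
1000 mm, source–detector 1500 mm, 256 columns of 1.6 mm (≈ 273 mm field of
view at isocenter). A cone-beam (multi-row) mode and a laterally offset
(half-fan) detector with smooth redundancy weighting are available but are
not part of the default pipeline. Ray tracing is analytic — chord lengths of
source-to-element rays through the circular phantom and inserts — so the
forward model has no discretization error of its own.

The detector is energy-integrating: bin weights w(E) = E. Noise is a single
Poisson draw per element on the energy-integrated expected signal, scaled by
`fluence_scale` — the expected open-beam signal per detector element per mAs
— with default 10⁵. Electronic noise, scatter, detector lag and glare are
not modelled. Photon-starved elements are floored at half a count to keep
the log finite. Protocol arithmetic (pulses = framerate × 60 s, cumulative
mAs = mA × ms × pulses) reproduces the embedded eight-protocol table to
±1 mAs; the rotation time of 60 s is fixed because that table is internally
consistent only with that value.

Both energy scans of a DE acquisition share one trajectory (identical
angles, no inter-scan motion).

## Decomposition

The two-material forward model maps thicknesses (t_Al, t_PMMA) to
polyenergetic log attenuations through each spectrum. Inversion is a damped
Newton iteration: initialization (0, L₁₄₀/μ_PMMA(ē₁₄₀)); analytic Jacobian
(effective μ of the hardened beam); per-element step halving (up to 8×) when
the residual grows; convergence at max-residual < 10⁻⁹ log units (≈ 10⁻⁸ cm
in thickness). Negative thicknesses are permitted by default — clamping
would bias the noise statistics of the basis images; a clamped display mode
exists. Round-trip accuracy is < 10⁻⁵ cm over t_Al ∈ [0, 4] × t_PMMA ∈
[0, 30] cm. A least-squares 2D-polynomial inverse (default order 4) fitted
on a synthetic step-wedge grid provides a fast alternative solver, agreeing
with Newton to < 0.1 cm over the calibration range.

## Reconstruction

Weighted-filter-backproject with a flat detector: cosine weighting, ramp
(Ram-Lak) filtering built from the exact sampled real-space kernel (correct
DC response) with optional Hann apodization at Nyquist cutoff, then
distance-weighted backprojection with linear interpolation, pixel-centre
sampling, 0-based row-major indices with y increasing downward. Only full
360° circular trajectories are supported; the global redundancy factor ½
pairs with half-fan weights that sum to 2 over conjugate rays. The chain is
linear in the sinogram to double precision (asserted at 10⁻¹⁰ relative) —
the property underwriting fast VMI synthesis. On the noiseless water
cylinder the centre of the reconstruction matches μ_w to < 0.1%.

The default reconstruction grid is 128×128 at 1.75 mm (224 mm field of
view); the default filter in the pipeline is Hann (noise suppression), while
oracle-equivalence and normalization tests use the pure ramp.

## VMI synthesis and the energy sweep

Basis-weight volumes are combined per energy and HU-mapped against water at
the same energy, so water is 0 HU and vacuum −1000 HU at every synthesized
energy (energy-consistent HU; the alternative of a fixed reference energy
would make theoretical and measured HU drift apart across the sweep). The
sweep metric is the mean of |CNR| over the sensitometry inserts: the insert
set contains materials both denser and lighter than the background, so a
signed mean would cancel. Ties in the argmax resolve to the lowest energy.
Denoising (Gaussian, σ in voxels) exists but defaults to off and is never
applied before equivalence or HU-accuracy evaluations.

## Quality metrics

ROI statistics use population standard deviation (divide by n) and
centre-in-disk voxel membership — both fixed for exact reproducibility.
Insert ROIs are centred on the inserts at 60% of the insert radius;
the background ROI sits on the insert ring at a 20° angular gap; the
uniformity module has a central ROI plus four peripheral ROIs
(top/bottom/left/right) at 70% of the phantom radius, radius 8 mm. Mean
rCNR averages over all nine sensitometry inserts (inserts with zero
reference CNR are excluded with a warning).

## Dosimetry

K_air-vs-mAs models are ordinary least-squares fits per tube potential on
the embedded seven-protocol calibration table; estimates outside the fitted
mAs range are returned with an extrapolation flag rather than refused (the
80 kVp DE protocols sit above the fitted range; the flag records that).
CBDIw uses the universal weighted-index convention ⅓ centre + ⅔ mean
periphery. Chamber temperature–pressure corrections reference 22 °C and
101.325 kPa. The 32 cm→16 cm phantom conversion factor is 2.34. Percent
differences are signed and reported to one decimal; validation summaries are
mean ± population sd of the signed values. Combined DE dose is the sum of
the two per-potential estimates, reported also as an integer percentage of
the reference-protocol estimate.

## Default study conditions

The default pipeline run mirrors the matched-dose study design: DE pair
80 kVp/4046 mAs + 140 kVp/833 mAs at 15 frames/s against a single-energy
140 kVp/1688 mAs reference, both at 2D 128² scale with 900 views; the
acceptance script adds an 11 frames/s matched-dose run and repeats the sweep
over five seeds, reporting the median CNR-optimal energy. At these
conditions the simulation places the optimum near 55–60 keV, yields mean
rCNR ≈ 2 for the 60 keV VMI at matched dose, keeps per-insert HU deviations
within a few HU of theory, and shows the reference scan cupping by an order
of magnitude more than the VMI.

## What the simulation does and does not show

The generator reproduces the mechanisms that drive the study's trends —
beam hardening (hence cupping and its removal in VMIs), dose-dependent
Poisson noise, view aliasing at low framerate, and the anti-correlated basis
noise that shapes the VMI noise-vs-energy curve. It omits scatter, bowtie
filtration, detector lag/glare, electronic noise, gantry flex and inter-scan
motion, and its beam model is analytic rather than a measured tube spectrum.
Absolute metric values (rCNR magnitudes, the exact argmax energy, HU noise
levels) therefore characterize this simulation, not any particular scanner;
it is the directions and orderings — VMI ≥ reference CNR at matched dose,
degradation at 3 frames/s, cupping reduction, dose linearity — that carry
over.

## Known limitations

* Short-scan (< 360°) reconstruction is unsupported by design.
* The half-fan redundancy weighting is accurate to a few percent when the
  detector overlap is narrow; the default pipeline uses a centred detector.
* The bone-insert compositions are representative rather than vendor-exact;
  their theoretical HU is self-consistent with the simulation but should not
  be compared against vendor datasheets.
* Dose models are relative (K_air surrogate), not organ dose; low-mAs
  extrapolation inherits the calibration table's mild non-linearity at the
  lowest tube output.
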