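# Methods

## The measurement being modeled

Hyperpolarized [1-¹³C]pyruvate MRI observes, over ~60 s, the injected
pyruvate bolus arriving in brain tissue and converting to lactate
(via LDH; elevated in tumor by the Warburg effect) and to bicarbonate
(via PDH; a proxy for oxidative flux). Each metabolite is excited
independently at every timepoint with a constant flip angle
(α<sub>pyr</sub>/α<sub>lac</sub>/α<sub>bic</sub> = 20°/30°/30°, 20
timepoints, dt = 3 s, 16×16×8 voxels at 1.5 cm isotropic). The
longitudinal magnetizations evolve as a linear three-pool system

    dP/dt = −(1/T1P + kPL + kPB)·P + g(t)
    dL/dt = kPL·P − L/T1L
    dB/dt = kPB·P − B/T1B

with measured signal Mz·sin α and post-excitation depletion cos α per
pool. Conversion is modeled unidirectionally (back-conversion is not
identifiable at these SNRs and timescales) and T1s are fixed model
constants, not fitted.

## Inputless kinetic fit

The fit treats the measured pyruvate magnetization as the known drive,
so the unknown arterial input function never appears. For each product
pool with decay rate r = 1/T1:

    L[m+1] = L[m]·cos α·e^(−r·dt) + k · I[m]
    I[m]   = ∫₀^dt P(s) e^(−r(dt−s)) ds

Between samples, pyruvate is interpolated exponentially from its
post-flip value P[m]·cos α<sub>pyr</sub> to the next measurement P[m+1]
— exact whenever no inflow occurs within the interval — giving the
closed form I[m] = (P[m+1] − P[m]·cos α<sub>pyr</sub>·e^(−r·dt))/(ρ + r)
with ρ the inter-sample log-slope. When noise drives an endpoint
nonpositive, a linear interpolation of the clipped endpoints is used
instead (also closed form). A plain trapezoid of the drive was rejected
because it ignores within-interval T1 decay of newly converted label
(~6% per 3-s step at T1 = 25 s), which biases the fit and breaks
agreement with a fine-step ODE oracle; the exponential form refits the
true rate to machine precision in the decay-only regime and to <1% with
bolus inflow.

The prediction is affine in the rate, L̂ = H + k·G, so the nonnegative
least-squares estimate, its standard error (from the linearized residual
covariance with T−2 degrees of freedom) and hence the "modeling error"
(relative standard error of the estimate) are closed form. The two
channels (lactate → kPL, bicarbonate → kPB) are fitted independently
given the shared pyruvate drive. Rates are bounded to [0, 1] s⁻¹;
voxels whose relative standard error exceeds 30% (kPL) or 50% (kPB) are
filtered from rate maps. Voxels failing the pyruvate aSNR ≥ 5 mask are
excluded from fitting in the pipeline.

Estimator properties (established by the test suite): noiseless
forward–inverse recovery within 5% over kPL ∈ {0.005, 0.02, 0.05} s⁻¹ ×
kPB ∈ {0.002, 0.01} s⁻¹; scaling invariance (signal units cancel);
with every curve at aSNR ≈ 20 the median |kPL| error over 200 replicates
is ≈ 4–5%. The estimator is ordinary least squares on a linear model
with Gaussian noise, i.e. at the information limit for this
parameterization; the residual variance is dominated by lactate-channel
noise, not by the noisy pyruvate regressor.

## Parametric maps

- **AUC**: voxel-wise temporal sum.
- **Noise sd**: sample sd of all non-brain voxel samples pooled across
  timepoints (≥100 background voxels required).
- **aSNR** = AUC/(σ√T): under i.i.d. noise the temporal sum of T points
  has sd σ√T, so aSNR is the AUC in units of its own noise sd. The
  aSNR < 5 filter removes a voxel; exactly 5 is kept.
- **Ratios** (Lac/Pyr, Bic/Pyr, Bic/Lac) are computed from AUC maps only
  where both constituents pass their SNR masks; invalid voxels are NaN,
  never zero, so ROI medians are unaffected.
- **Percentile rank maps** (Pyr%, Lac%, Bic%): average-rank (tied)
  ranking of brain-voxel AUCs, normalized by the brain voxel count (no
  SNR filtering) and scaled to (0, 100]. Non-brain voxels are NaN, not
  zero. Percentiles are invariant under any strictly monotone intensity
  transform, which is what makes them comparable across patients and
  scan days.

## ROI geometry

NEL = T2L ∧ ¬CEL and NAWM = WM ∧ ¬T2L at ¹H resolution. Downsampling to
the ¹³C grid requires the ¹H grid to be an exact integer block
refinement; per ¹³C voxel, overlap fractions are exact block means. The
mutually exclusive labeling is: T2L if ≥30% of the voxel's volume is
T2L (fraction-of-voxel reading — a per-voxel criterion; a
fraction-of-lesion reading would make labels depend on total lesion
size); among remaining voxels, NAWM if ≥50% NAWM overlap. Both
thresholds are inclusive. Affine/oblique resampling of real data is out
of scope; the phantom guarantees the supported geometry. Lesion-level
¹³C analysis uses T2L only (CEL volumes are too small for reliable
serial comparison at 1.5-cm resolution).

## Longitudinal summaries

Per scan and ROI, each of the eight parameters (Pyr%, Lac%, Bic%,
Lac/Pyr, Bic/Pyr, Bic/Lac, kPL, kPB) is summarized by the median over
valid voxels. Lesion medians are normalized by the same patient's and
scan's NAWM median — an internal reference that cancels
polarization/scale differences between exams (normalization is exactly
invariant to multiplying all map values by a constant). Treatment groups
are assigned with priority bevacizumab > everolimus > multi-agent
alkylating > single-agent TMZ/CCNU control; progressor class comes from
the PFS6 flag (1 = progression within 6 months = early). Group
trajectories bin scans to integer months (first scan per patient per
bin), and report mean, SD (ddof = 1) and SE = SD/√N, with SD/SE omitted
at N = 1. Paired voxel-wise comparison selects voxels classified in the
ROI and carrying finite, nonzero values at both timepoints (a
scan-order-symmetric set) and reports per-voxel and mean percent change
100·(b − a)/a.

## Synthetic phantom: the stated world

Defaults emulate the clinical acquisition: 16×16×8 ¹³C grid at 1.5 cm,
¹H grid = 8× block refinement (1.875 mm), 20 timepoints at 3 s, flips
20/30/30.

Choices the acquisition papers do not pin down, declared once:

- **T1**: 30/25/25 s (pyr/lac/bic) — standard field values at 3 T;
  configurable.
- **Bolus**: gamma-variate inflow g(t) = A·((t−d)/β)^α·e^(−(t−d)/β)
  into the pyruvate pool with α = 2, β = 4 s, d = 3 s, A = 100 a.u. —
  bolus peak ~11 s after acquisition start, consistent with an injection
  beginning shortly before imaging.
- **Rates**: background (healthy brain) kPL = 0.012 s⁻¹,
  kPB = 0.008 s⁻¹; lesion kPL = 0.024 s⁻¹ (2× Warburg elevation),
  kPB = 0.006 s⁻¹ (mildly reduced oxidative flux).
- **Noise**: additive i.i.d. Gaussian, σ = 4 a.u., estimated exactly the
  way the pipeline estimates it (from non-brain voxels). σ and the
  lesion kPB were calibrated once while constructing the world so that
  all three metabolites are quantifiable (aSNR ≥ 5) in brain and lesion
  — the regime in which lesion Bic ratios are reportable at all — giving
  pyruvate aSNR ≈ 50–90, lactate ≈ 12–25, bicarbonate ≈ 6–8.
- **Anatomy**: nested ellipsoids (brain ⊃ WM, brain ⊃ T2L ⊃ CEL)
  rasterized at ¹H voxel centers, so lesion borders carry partial volume
  and exercise the 30%/50% downsampling thresholds. The ¹³C tissue
  support is the majority (≥50%) ¹H-brain block overlap — identical to
  the analysis-side brain mask — so background voxels are pure noise and
  the background σ estimate is unbiased.

Dynamics are stepped exactly per dt with the matrix exponential of the
three-pool system, treating inflow as constant within each
inter-excitation interval; a single clean curve per tissue class is
broadcast to its voxels before noise is added in fixed raster order from
one seed, making studies bit-reproducible.

What the phantom does **not** emulate: k-space/EPI artifacts, coil
sensitivity, B1 inhomogeneity, perfusion/vascular compartments,
intra-class rate heterogeneity, oblique ¹H↔¹³C geometry, and spatially
correlated (denoising-induced) noise. A green test on the phantom
therefore establishes algorithmic correctness (recovery, masking,
geometry, normalization arithmetic) — not robustness to real-data
artifacts.

## Numerical choices and degenerate inputs

- aSNR noise propagation uses σ√T; exactly-threshold voxels are kept.
- Empty fit masks warn and return all-NaN maps; unfit voxels are NaN.
- An all-zero pyruvate curve raises a no-signal error per voxel and is
  silently skipped in map fitting.
- Zero or missing NAWM medians make normalized values missing, never
  infinite; zero baseline volumes make percent change missing.
- kPL = 0 estimates get infinite relative error and thus never pass the
  error masks.
- Flip = 0 is representable in the forward model (unmeasured metabolite,
  downstream pools still evolve) but rejected at fit time.
- Month binning rounds to the nearest integer month; first scan per
  patient per bin enters group statistics.

## Known limitations

- The fit's inflow-interval drive interpolation leaves a ~0.6% bias at
  default bolus settings (bounded by the 5% recovery tolerance).
- T1 misspecification maps directly into rate bias; T1s are assumed, as
  in the inputless convention, not estimated.
- Single-σ background noise per metabolite image; no spatial noise
  variation.
- The clinical-table parser expects the packaged CSV schema; month
  tokens must be of the form "Nm".
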