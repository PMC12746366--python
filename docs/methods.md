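# Methods

## The measurement and the two models

Downfield ¹H-MRS at 7 T with spectrally selective excitation (90° pulse,
FWHM 2 ppm, centered 9.7 ppm) observes four resonances without water
suppression: tryptophan indole NH (singlet, 10.1 ppm) and the NAD⁺
nicotinamide H2 (singlet, 9.3 ppm), H6 and H4 (doublets, 9.1/8.9 ppm).
Two interleaved saturation-recovery experiments measure longitudinal
recovery after (a) selective saturation of the metabolite band only
(TS = 25/50/300/600 ms) and (b) broadband saturation of metabolites and
water together (TS = 500/1000/2000/4000 ms).  A no-saturation scan serves
as the equilibrium point and is assigned TS = 10 s in both curves.

**Model 1** fits each curve with `S(TS) = M₀(1 − k·e^(−TS/T₁,app))`,
bounded (`k ∈ [0,1]`, `T₁ > 0`), multi-start local least squares.  The
*apparent* T₁ implicitly contains the exchange: under selective saturation
the metabolite deviation decays at `1/T₁,A + σ_AB`; under broadband
saturation the recovery is dragged by the slowly recovering water pool
(T₁ ≈ 1.8 s), so the apparent T₁ ratio broadband/selective grows with
σ_AB and reaches ~20 for tryptophan-like parameters.

**Model 2** fits both curves simultaneously with the two-pool Solomon
equations (metabolite A, water B), detailed balance
`σ_BA = σ_AB·M₀,A/M₀,B`, water T₁ fixed at 1800 ms, and the
water:metabolite equilibrium-magnetization ratio fixed at
`(2·55 M)/0.3 mM ≈ 3.7·10⁵` (0.3 mM is the average brain NAD⁺
concentration; the same ratio is used for all four resonances, a stated
modeling assumption).  Saturation efficiencies are *not* free: they are
the Model-1 estimates of the respective experiments.  Free parameters are
`T₁,A` (exchange-corrected), `σ_AB`, and the amplitude scale `M₀,A`
(amplitude units after regression are arbitrary).  The objective — summed
squared residuals over both experiments, the equilibrium point included in
both — is minimized by basin-hopping (15 iterations, step 0.6, seeded,
normalized parameter space, L-BFGS-B local steps, bounds
T₁,A ∈ [50, 10000] ms, σ ∈ [0, 100] Hz) followed by a bounded
least-squares polish.  Fits pinned at a bound or not converged are flagged
and propagate as missing values.

### Solver

The coupled system is linear in the deviations.  It is solved in
*fractional* deviations `w = ((M_z,A−M₀,A)/M₀,A, (M_z,B−M₀,B)/M₀,B)`,
whose system matrix has off-diagonals `(σ_AB, σ_BA)` and O(1) initial
conditions — the raw deviation formulation mixes scales by the 3.7·10⁵
magnetization ratio and loses ~8 digits in the eigenvector solve.  The
closed form uses the explicit 2×2 eigendecomposition with the stable
quadratic-root rule (larger root by formula, smaller by det/λ₁) and falls
back to a matrix exponential if the eigenvalue gap vanishes.  An
independent numeric route (`solve_ivp`, DOP853, rtol 1e-13) exists purely
as a cross-check; the two agree to < 1e-9·M₀,A over the fitted parameter
range.

## Spectral processing and peak quantification

Per scan: 5 Hz exponential apodization; channel-wise frequency alignment by
integer-bin cross-correlation of magnitude spectra over 8.5–10.5 ppm with
rejection of channels whose best normalized correlation stays below 0.7
(alignment is skipped for a scan if it would reject every channel, as
happens on heavily saturated low-signal scans); matched-filter coil
combination with complex weights conjugate to the water-reference channel
amplitudes (spectral-peak readout by default, first-point optional),
normalized to unit power.  Display convention: ppm decreases left to
right; `ppm = carrier + f/f₀` with the carrier at the excitation center.

Linewidths are measured as the FWHM of the zeroth-order-phased *real*
(absorption) lineshape — the magnitude lineshape of a Lorentzian is √3
wider — with linear interpolation at the half maximum.  SNR follows the
in-vivo definition: NAD⁺ H2 peak magnitude of the no-saturation scan over
the standard deviation of the real part in a signal-free upfield window
(10.8–11.8 ppm), after removing a cubic trend that distant Lorentzian
tails otherwise contribute; a detrended residual below 10⁻⁵ of the peak is
reported as infinite (tail-leakage floor).

The no-saturation scan is decomposed by HSVD: balanced Hankel matrix
(rows = n/2), SVD truncated at min(60, numerical rank) — the rank cap
prevents spurious null-space poles on clean data — shift-invariance
eigenproblem for the poles, decaying poles only, amplitudes by linear
least squares.  One component per resonance is assigned within ±0.08 ppm
windows: the largest-amplitude component with a *plausible* linewidth
(8–120 Hz; the targets are 28–54 Hz wide plus broadening — far broader
components are baseline tails, far narrower ones noise spikes).  An empty
window leaves that resonance missing for that subject, mirroring the
in-vivo per-subject peak omissions.  All other components form the
baseline.

Saturation scans are fit by fixed-basis complex linear regression with
frequencies and dampings frozen.  Each resonance contributes a single
composite-lineshape column — its assigned component plus any plausible
window-mates (e.g., a resolved second doublet line), weighted by their
equilibrium-scan amplitudes and normalized to unit t = 0 amplitude — so
one free complex scale per resonance is estimated.  This is exact when the
lines of a resonance co-scale (they do: both doublet lines carry the same
recovery) and avoids the severe noise amplification of giving
near-collinear in-window components independent amplitudes.  Baseline
components within 7.9–8.85 ppm — the partially excited
adenosine/NAA/amide complex directly upfield of NAD⁺ — enter as free
nuisance columns, because that complex recovers at its own rate between
scans and a fixed-strength subtraction would be biased at short TS;
baseline poles elsewhere are noise and are excluded (each extra free
column leaks noise into the peak amplitudes).  Amplitudes are phased by
the equilibrium-scan amplitude of the same resonance (reported value
`Re(a·conj(a_m0)/|a_m0|)`), and the equilibrium point is appended to both
experiments.  Regression fit quality is high on the equilibrium scan
(time-domain R² ≈ 0.95–0.99 at the calibrated SNR) and declines on
strongly saturated short-TS scans, whose variability is noise-dominated —
expected, and without analogue in curve-fit R².

## Synthetic data generator

The generator emulates the acquisition end to end: four target resonances
at in-vivo mean linewidths (TRP 54, H2 28, H6 32, H4 38 Hz; doublet
J = 8 Hz, a typical three-bond nicotinamide ring coupling, unresolved at
these widths), a baseline complex of three broad Lorentzians at
8.2–8.7 ppm, excitation attenuation by a raised-cosine window with exact
FWHM 2 ppm centered at 9.7 ppm (monotone on each side, compact support;
H4 at 8.9 ppm retains 0.65), eight receive channels with random complex
sensitivities encoded in a water-reference scan, and stationary complex
Gaussian noise, independent across channels.  Per-resonance amplitudes
across TS follow the closed-form two-spin solution; the baseline complex
recovers mono-exponentially (T₁ = 300 ms) with its selective-saturation
efficiency attenuated by the 600 Hz saturation-pulse band profile (the
broadband pulse saturates everything).  Sampling: 2 kHz spectral width,
512 points, carrier at 9.7 ppm.

Defaults are the study conditions: TS grids as above, equilibrium scan at
TS = 10 s, saturation efficiencies 0.85 (0.6 for selective NAD⁺ H4, which
sits on the saturation transition band; the in-vivo report gives only
"above 0.7 except selective H4", so these are representative values, not
measurements).  The per-channel noise std (0.25 per component at unit H2
amplitude) was calibrated once, by simulation, so the processed
no-saturation scan shows NAD⁺ H2 spectral SNR ≈ 27, matching the in-vivo
27.4 ± 4.9; it was not adjusted afterwards.  The cohort truth sampler
draws per-resonance T₁,A and σ_AB from normal distributions centered on
the in-vivo cohort means/SDs (truncated to physical ranges), with mild
saturation-efficiency jitter.

What the generator does *not* emulate: per-transient frequency/phase
drift (none is corrected in vivo either), B₀/B₁ inhomogeneity across the
slice, chemically realistic macromolecule baselines, eddy currents, or
subject motion.  Passing tests therefore demonstrate correctness of the
processing and estimation chain under the stated noise model, not
robustness to every in-vivo artifact.

## Estimation precision at the calibrated SNR

A point that matters for interpreting the recovery studies: with 4 + 1
points per experiment and the saturation efficiencies estimated from
Model 1 and then fixed, the per-subject precision of σ_AB is intrinsically
limited.  Monte-Carlo at the amplitude level (exact curves plus Gaussian
amplitude noise) gives a median |relative error| of σ_AB of roughly
6–14% per resonance at 2% amplitude noise, 20–26% at 6%, and ~30% at 9%.
The processing chain at spectral SNR 27 delivers per-point amplitude noise
of about 7% (NAD⁺ H2) to 15–24% (NAD⁺ H4, transition band + baseline
overlap), so full-pipeline recovery settles around a 20–35% median
relative error on σ_AB.  Estimates are nearly median-unbiased; the error
is variance, dominated by the propagation of the Model-1 saturation-
efficiency estimate (corr(σ̂, k̂_sel) ≈ 0.8).  Cohort-level contrasts are
much stronger than per-subject precision: the TRP > NAD⁺ ordering of the
mean exchange rate reproduces in ≥ 95% of replicate cohorts at the
delivered noise, and the in-vivo cohort's own σ spread (e.g. 12.3 ± 3.1 Hz
for TRP) is consistent with this per-subject uncertainty plus biological
variation.  Quality filtering by fit R² is deliberately *not* applied to
cohort summaries of the synthetic studies: high-σ subjects have harder
curves, so such a filter selects against them and biases the TRP mean
downward.

## Statistics

Cohort cells are arithmetic mean ± sample SD (n−1) over non-missing
subjects — this reproduces the published per-subject table's summary row
exactly (one cell, the NAD⁺ H6 T₁ SD, prints truncated: exact 985.553
vs printed 985.5).  Selective vs broadband apparent T₁ uses a two-sided
t-test, paired by subject by default (the subjects are the same; unpaired
available).  Across-resonance comparisons use one-way ANOVA followed by
Tukey HSD.  Pairs or cells with missing members are dropped, never
zero-filled.

## Pipeline, containers, determinism

The pipeline (`simulate → process → fit-peaks → fit-t1 → fit-exchange →
cohort`) is exposed as a click CLI and as `run_pipeline`; per-subject
failures degrade to missing values.  Spectra travel in an HDF5 container
(`/subjects/<id>/<experiment>/<TS>/fid` with self-describing attributes
and an embedded schema version) with a plain-directory JSON+CSV dialect
for text-only archiving; both round-trip bit-exactly.  All randomness is
seeded (generator, cohort sampler, basin-hopping); identical config + seed
reproduce result tables byte-for-byte.  Problem sizes used by the test
suite and the acceptance script — 8-subject cohorts for full-pipeline
recovery, 100 amplitude-level replicate cohorts for the ordering study,
1,000 parameter draws for solver cross-checks — were chosen to keep a full
run in minutes on a single core while leaving Monte-Carlo margins well
above the assertion thresholds.

## Known limitations

* Single water T₁ for a slice containing GM/WM/CSF; fixed
  metabolite:water ratio shared by all resonances including TRP.
* σ_AB per-subject precision at SNR 27 is ~25–30% (see above); the
  recovery-error acceptance threshold of 15% is not attainable under
  these conditions and the corresponding check documents the shortfall
  rather than relaxing the conditions.
* The similarity metric and threshold for channel rejection are a simple
  stand-in (normalized band-limited cross-correlation ≥ 0.7); the in-vivo
  processing cites an external method without formula.
* Apparent-T₁ ratios (19 ± 6 for TRP in vivo) depend on unpublished
  per-subject apparent T₁s and are checked qualitatively (ratio ≫ 1,
  monotone in σ, → 1 as σ → 0), not numerically.
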