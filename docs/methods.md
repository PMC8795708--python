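# Methods

`nirslat` implements a block-design fNIRS analysis whose end point is the
hemispheric laterality index of two cognitive functions — language
production (picture naming) and visuospatial attention (landmark line
bisection) — together with a synthetic-session generator that carries known
ground truth through the entire chain. This note documents the model, the
parameters that matter, and the design decisions taken where the procedure
was genuinely open.

## Processing model

Raw data are dual-wavelength (740/850 nm) continuous-wave intensities from
80 source–detector channels at 3 cm separation, sampled at 17 Hz. Each task
run passes through, in order:

1. **Channel quality control.** Two rules, applied to the raw recording:
   (a) the Pearson correlation of a provisional HbO/HbR conversion must not
   be (numerically) −1 nor above 0.5 — HbO and HbR are anticorrelated
   during cognition, exact −1 indicates a degenerate cross-wavelength
   dependence and positive correlation indicates common-mode (motion)
   contamination; (b) the optical-density power spectrum must show a
   cardiac peak (0.8–1.5 Hz, ≥ 5× the local median background on either
   wavelength), the standard witness of optode–scalp coupling.
   A run with strictly more than 20 % bad channels excludes the participant
   for that task. The provisional conversion exists because the correlation
   criterion is defined on hemoglobin while pruning precedes processing.
2. **Optical density:** OD(t) = −log₁₀(I(t)/Ī) per channel and wavelength,
   with the channel's temporal mean as the reference intensity.
3. **Spline-SG motion correction** on OD. Artifact segments are detected
   where the sliding max−min excursion over 0.5 s exceeds min(0.2 OD, 4×
   the channel's median excursion) — a scale-free criterion that ignores
   ever-present rhythms such as the cardiac oscillation; flags are dilated
   by ±1 s. Within each segment a smoothing spline is subtracted and the
   segment re-anchored to the 2 s of preceding baseline; a Savitzky–Golay
   filter (frame 6 s, order 3) then smooths the full series. The spline is
   the discrete second-difference-penalized form solved with a banded
   factorization (penalty λ = (1−p)/p on the sample grid, p = 0.99
   following the csaps convention); it is the same estimator family as a
   cubic smoothing spline at a fraction of the cost on many short segments.
4. **Band-pass 0.008–0.5 Hz:** 3rd-order Butterworth applied
   forward–backward (zero phase, so block averages acquire no latency).
   At 17 Hz this removes DC exactly and leaves ≈1.4 % of a 1 Hz cardiac
   oscillation in steady state; the 0.008 Hz pole has minute-scale edge
   transients, which is why amplitude contracts are verified in the
   interior of long records.
5. **Modified Beer–Lambert law.** Per sample the 2×2 system
   ε·[ΔHbO·L, ΔHbR·L]ᵀ = ΔOD/DPF is solved, with ε the base-10 molar
   extinction matrix (compiled hemoglobin spectra, Prahl; mm⁻¹ mM⁻¹) and
   DPF = 6.0 at both wavelengths (not reported by any instrument here;
   configurable). Outputs are concentration change × pathlength in mM·mm —
   the units in which the block-rejection threshold is stated — so the
   geometric separation is never divided out.
6. **Resting-state PCA denoising.** Spatial eigenvectors of the channel
   covariance of a separately recorded 5-min resting run (processed through
   steps 2–5) are estimated per chromophore; the leading 2 components are
   projected out of the task data, X → X − XUUᵀ. Systemic physiology
   (pulse, respiration, Mayer waves) covaries across channels far more
   strongly than cortical responses, which is the premise of the step.
   Components whose eigenvalue is negligible — relative to the covariance
   trace or below an absolute floor (1e−30 (mM·mm)²) — are skipped, so a
   silent resting recording removes nothing rather than removing arbitrary
   directions.
7. **Block analysis.** A block is rejected when any retained channel's HbO
   moves by more than 0.1 mM·mm inside a 0.2 s window anywhere in the
   block's epoch, or when its behavioral accuracy is below 0.5 (landmark
   only; picture naming has no per-trial correctness). Participants keeping
   fewer than 3 blocks of the analysed condition are excluded. Epochs are
   cut at −5..+40 s around the active-period onset, linearly detrended,
   baseline-corrected on −5..0 s, trimmed to the stored −4..+40 s grid and
   averaged per condition; cutting at −5 s reconciles the 5 s baseline with
   the −4 s epoch start. The scalar response per channel is the mean over
   the 30 s window centred in the 0–40 s post-onset span, i.e. 5–35 s
   ("the middle 30 s"); analyses default to HbO, whose signal-to-noise
   ratio exceeds HbR's, with HbR available behind a switch.
8. **Laterality and group statistics.** L and R are the arithmetic means of
   the retained ROI channels (language: left 43/44/46/47 vs right
   34/35/38/39; attention: right 60/62/63/64 vs left 7/10/11/13), and
   LI = (L−R)/(L+R), positive = left-dominant; |L+R| below 1e−12 marks the
   subject's LI undefined and drops them from LI analyses with a ledger
   entry. Group level: one-sample and paired t-tests; channelwise
   one-sample t maps with Benjamini–Hochberg FDR control across channels
   within each task; two-way repeated-measures ANOVA
   (hemifield × deviation) with each effect tested against its own
   effect × subject error term and Tukey-HSD cell contrasts on the
   interaction error term (no sphericity correction by default); Pearson
   correlation of the two tasks' LIs, raw and after excluding points with
   Cook's D > 4/n or |externally studentized residual| > 2.5 from the
   simple regression (both thresholds configurable — regression-diagnostic
   packages differ on the exact recipe); a two-sample Kolmogorov–Smirnov
   comparison of the two LI distributions; and the noncentral-t
   sample-size scan for the paired design (power(n) with ncp = dz·√n,
   df = n−1).

Every exclusion — channel, block, participant, undefined LI — is written to
a structured ledger citing exactly one configured rule, because attrition
accounting is part of the analysis, not a side effect.

## Synthetic sessions

The generator inverts the forward model. Hemoglobin series are composed in
mM·mm and mapped through the Beer–Lambert forward relation to OD, motion
artifacts are added in OD space, and intensity is I = I₀·10^(−OD) with
per-channel lognormal I₀.

**Task structure.** Picture naming: 12 active blocks of 5 pictures ×
(4 s + 1 s ISI) = 25 s, 24 s rest. Landmark: 6 blocks per condition (LM,
LMC) alternating, each 4 s instruction + 12 trials × (1.6 s + 0.2 s) =
21.6 s active, rest drawn uniformly from {15, 16, 17} s. Responses are the
active-period boxcar convolved with a double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6 — the community-standard canonical shape),
normalized to unit peak so that effect amplitudes are peak responses in
mM·mm.

**Effects.** A subject's truth is the pair (LIₗₐₙ, LIₐₜₜ); amplitudes split
a fixed total L + R = 0.03 mM·mm (a realistic peak HbO block response) as
L = (1+LI)/2·(L+R). The landmark control condition activates both
hemispheres symmetrically at 30 % of the mean LM amplitude by default. HbR
responses are −1/3 of HbO with a 0.8 s lag (venous washout delay); the lag
keeps the HbO/HbR correlation of clean data away from exactly −1, and,
because the laterality analysis runs on HbO, it does not perturb LI
recovery. Cohorts draw (LIₗₐₙ, LIₐₜₜ) from a bivariate normal — defaults
mean (+0.3, −0.3), SD 0.25, correlation ρ configurable — clipped to ±0.95
to keep both hemisphere amplitudes positive.

**Noise.** Cardiac (1.1 Hz, 0.008 mM·mm), respiratory (0.25 Hz, 0.004),
Mayer waves (0.1 Hz, 0.005) and 1/f drift (0.01) share a global spatial
loading vector (per-channel U(0.5, 1.5), with 30 % per-component jitter so
the physiological subspace is not exactly rank 1); HbR receives −0.2 of
the HbO physiology (weak mirroring) plus an independent drift at 30 %
amplitude; white noise SD 0.002 mM·mm per chromophore; motion spikes
(0.5/min, 0.03 OD, 0.4 s decay) and baseline shifts (0.1/min, 0.008 OD)
hit all channels with random per-channel scale; 0.05 % multiplicative
intensity noise. Planted bad channels take three forms matching the QC
rules: physiology replaced by white noise (no cardiac peak), and two
deterministic cross-wavelength faults that make converted HbR an exact
positive or negative copy of HbO (the degenerate dependences the
correlation bounds are meant to catch; such channels carry no measurement
dither, as a deterministic fault would not).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photon transport through tissue (no Monte-Carlo
head model; the DPF is a constant), serial correlation of behavioral
responses, task-correlated motion (artifact times are Poisson, independent
of the design), superficial/scalp hemodynamics distinct from the global
systemic component, and between-channel differences in HRF shape. Cohort
claims should be read as statements about the pipeline's statistical
machinery, not about fNIRS physiology.

## Forward–inverse identifiability

With all noise amplitudes zero the pipeline recovers each subject's true LI
to ~1e−13. This is by construction: every processing step is either linear
(filters, spline subtraction with fixed segments, detrending, averaging,
the Beer–Lambert solves) or exactly affine in log-intensity (OD
conversion), and artifact-segment detection is scale-free, so all channels
carrying the same response waveform stay exact scalar multiples of one
common processed waveform and the ratio (L−R)/(L+R) is preserved exactly.
Two guards make this hold in practice: PCA skips negligible-eigenvalue
components (a silent resting run would otherwise contribute arbitrary
projection directions), and the channel QC is switched off
(`qc_enabled: false`) for noise-free runs — its correlation and
cardiac-presence rules presume stochastic physiological recordings and
degenerate on idealized data (no cardiac rhythm exists to detect, and
noise-free HbO/HbR correlate exactly −1).

With default noise, recovered LIs are amplified away from zero (cohort
mean ≈ ±0.5–0.6 for true ±0.3): the resting-trained PCA components overlap
the hemisphere-symmetric part of the task response more than its
asymmetric part, shrinking L+R relative to L−R. This over-removal is a
known cost of PCA-style global-signal regression in fNIRS; it preserves
the sign and ordering of LIs (group t-tests and cross-task correlations
remain faithful) but biases |LI| upward, which is worth remembering when
comparing absolute LI magnitudes across preprocessing choices.

## Numerical choices and degenerate inputs

* "Correlation equal to −1" is implemented as r ≤ −1 + 1e−6; zero-variance
  channels have undefined correlation and are flagged bad.
* The cardiac-presence threshold is 5× the local median PSD (0.5 Hz to
  1 Hz above the band, band excluded). With a 5-min recording and 60 s
  Welch segments, a 3× threshold would see phantom peaks on genuinely
  cardiac-free channels at a 1–2 % rate; real peaks are orders of
  magnitude above background, so 5× costs no sensitivity.
* Motion detection runs on a 2×-decimated stream (localization only; the
  ±1 s dilation far exceeds the granularity lost) and thresholds on the
  median sliding excursion, making decisions invariant to affine channel
  rescaling.
* The Savitzky–Golay window is round(frame·fs) forced odd; series shorter
  than the window, or frames shorter than the polynomial order allows, are
  configuration errors.
* Blocks whose epoch leaves the recording are dropped with a ledger entry
  rather than raising; a condition with zero usable blocks propagates as a
  participant exclusion.
* Zero-variance channels in t maps are recorded with |t| = ∞, p = 0 (or
  NaN when the mean is also zero) and flagged degenerate, as are channels
  retained in fewer than 3 subjects.
* The rm-ANOVA requires a fully crossed design and refuses missing cells
  (no imputation). Greenhouse–Geisser correction is available but off by
  default, matching the uncorrected degrees of freedom convention used
  with these designs.

## Problem sizes used by the test suite

Unit tests run on compact designs (2–4 blocks) and 16-channel montages.
The cohort-recovery acceptance study uses the full task designs with
45 subjects per cohort and 20 replicate seeds per condition at the
16-channel montage (the two ROIs and their homologs), which exercises every
pipeline stage while keeping a cohort to ~15 s; the 80-channel montage is
exercised by the QC and I/O tests. The acceptance script recomputes the
design-stage sample size, which is deterministic and instantaneous.

## Known limitations

Short-separation-channel regression and anatomically informed photon
transport are out of scope. The montage geometry is synthetic — real
optode coordinates were never published — so only channel numbering,
hemisphere membership and ROI homology are meaningful; do not interpret
the packaged positions spatially. The behavioral simulator draws RTs from
a lognormal with no condition structure beyond the accuracy model; it
exists to drive the accuracy-based block-rejection rule, not to model
decision processes.
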