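# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices behind them, and what the synthetic phantoms do and do
not demonstrate.

## Acquisition model

All MR stages share one SPGR steady-state signal model,
S = M₀ sin α (1−E1)/(1−E1 cos α) with E1 = exp(−TR/T1). The default
acquisition constants encode the 7 T small-animal protocol the pipeline
targets: flip-angle calibration at nominal 145/180/215° with TR = 460 ms;
VFA at 10/20/50° with TR = 144 ms; dynamic imaging at 25°, TR = 9 ms,
15.6 s per frame, 20 pre-contrast + 150 post-contrast frames. Times are
milliseconds (frame interval: seconds), angles degrees.

## Flip-angle (B1) mapping

A surface transmit coil scales the realized flip angle by a smooth field
κ(x) (actual = κ × nominal). The three long-TR calibration signals are
modeled as A·|sin(κ α_nom)|, which nulls where κ α_nom crosses 180°; κ and A
are obtained per voxel by least squares over the three angles. Choices:

* **T1 weighting of the calibration scans is ignored.** At TR = 460 ms the
  (1−E1)/(1−E1 cos α) factor varies little across the three high angles; the
  amplitude A absorbs its mean. The residual bias is second-order and covered
  by the Monte-Carlo tolerance (κ bias < 1 % at signal SNR 50 in the tests).
  The synthetic generator produces calibration scans from the same |sin|
  model, so closure tests isolate the fitting machinery.
* **Optimization**: the amplitude is projected out analytically, leaving a
  1-D problem in κ solved by a dense grid over [0.5, 1.5] plus vectorized
  golden-section refinement. Derivative-free on purpose — |sin| has a kink
  wherever κ α crosses a multiple of 180°, so Newton steps are unsafe there.
* **Fallback**: voxels with all-zero or non-finite signals are flagged and
  assigned κ = 1, degrading gracefully to the uncorrected VFA fit.

## VFA T1 mapping

With corrected angles α = κ α_nom, the three SPGR signals are linearized as
S/sin α = E1 · S/tan α + M₀(1−E1): an ordinary least-squares line per voxel
gives E1 (slope) and M₀. The linearized form is exact for noiseless data and
closed-form testable; nonlinear refinement is deliberately out of scope.
Voxels whose slope falls outside (0, 1) have no physical T1 and are flagged
(t1 = NaN, fit_ok = False); flagged voxels propagate as invalid
concentrations, never as silent NaNs.

## Signal → concentration

Per voxel, the baseline signal (mean of the 20 pre-contrast frames) and the
native T1 fix M₀ sin α; each frame's signal is inverted for
E1(t) = (M₀ sin α − S)/(M₀ sin α − S cos α), R1(t) = −ln E1 / TR, and
C(t) = (R1(t) − R1(0)) / r₁, assuming fast water exchange and linearity
between concentration and relaxation rate. Frames outside the invertible
domain (E1 ∉ (0,1)) invalidate the voxel. The relaxivity default
r₁ = 3.9 s⁻¹mM⁻¹ (gadodiamide near 7 T) only scales concentrations; all
recovery tests run the forward and inverse chain with the same r₁, so the
value does not affect correctness claims, and it is config-overridable.

## Extended Kety model and the AIF

Tissue concentration follows
C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ with
k_ep = K^trans/v_e. The AIF is an explicit, swappable bi-exponential
C_p(t) = D(a₁e^(−m₁t') + a₂e^(−m₂t')) with the classic plasma-clearance
parameters (a₁ = 3.99, a₂ = 4.78 kg/L; m₁ = 0.144, m₂ = 0.0111 min⁻¹)
scaled by the protocol dose D = 0.3 mmol/kg; any measured population AIF can
be substituted through config. Because the AIF is bi-exponential, the
convolution is evaluated exactly: each term contributes
a_i(e^(−m_i t) − e^(−k_ep t))/(k_ep − m_i), switching to the confluent limit
t·e^(−m t) when |k_ep − m| underflows a relative guard of 1e-9. No Riemann
sums appear in the model path; the quadrature lives only in the test oracle.

**Onset.** Bolus arrival is a property of the AIF (`onset_time`, seconds).
The generator and the default pipeline place it exactly at the end of the
pre-contrast block (312 s); when analyzing external data the onset can be
estimated as the first frame whose tumor-mean concentration exceeds 3 SD of
the pre-contrast frames (`estimate_onset`), or set explicitly.

## Voxelwise fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
with K^trans ∈ [0, 5] min⁻¹, v_e ∈ [1e-3, 1], v_p ∈ [0, 1], from a grid of
starts (K^trans ∈ {0.02, 0.1, 0.3, 1.0} × v_e ∈ {0.2, 0.5}, v_p start 0.02).
The multi-start loop stops early once a start reaches a numerically perfect
fit (rss below (1e-8 × signal scale)² per frame), which makes noiseless
closure runs cheap. Flag rules:

* K^trans or v_e pinned within 1e-6 of a bound → not identified, flagged.
  v_p = 0 is *not* flagged: zero plasma volume is a legitimate interior
  answer and appears in the recovery sweeps.
* v_e + v_p > 1 → unphysical, flagged.
* "Viable" (mapped) tissue for summary statistics = fit_ok AND peak
  concentration > 3× the pre-contrast noise SD of that voxel. With zero
  noise any enhancement qualifies; an all-zero voxel never does. The
  multiple is configurable.

Median K^trans is reported per tumor over viable voxels only, matching the
practice of excluding unmapped (non-enhancing) areas; cohorts then average
the per-tumor medians.

At the 15.6 s frame interval v_p is weakly identified — bolus-passage
information is mostly gone. The test suite pins this as a property: at
concentration SNR 20 the median relative error of v_p exceeds that of
K^trans (measured ≈ 5.8 % for K^trans, ≈ 2.2 % for v_e, and a median
absolute v_p error ≈ 0.006 at v_p ~ 0.05 in the acceptance run).

## Erosion shells and the periphery/core split

Iterated binary erosion with a 6-connected (face-neighbor) structuring
element; shell k is the set removed at step k, so shell index equals the
city-block distance to the nearest outside voxel (verified against
exhaustive search). 18/26-connectivity are available in config. Voxel
anisotropy (0.3×0.3×1 mm) is ignored — erosion is lattice-based, matching
the standard morphological formulation; a Euclidean-distance variant would
be a different (out-of-scope) definition. The periphery accumulates whole
shells outermost-first until they first hold ≥ N/3 of the in-mask voxels;
shells are the natural unit, so no fractional-shell splitting is invented.
Tiny tumors whose first shell exhausts the mask return an undefined core
rather than a number.

## Section metrics

Channels are aligned by integer-pixel translation maximizing normalized
cross-correlation within a bounded window (default ±8 px); a peak is
accepted only if its correlation exceeds 0.2 and beats the best
correlation outside its 3×3 neighborhood by a 1.02 ratio — otherwise the
channel is left unshifted with a warning. Rotation/scale are out of scope
(same-section re-imaging drifts translationally). Positivity uses fixed
per-channel thresholds from config (deterministic), falling back to Otsu
within the viable mask. The viable mask is tumor − necrosis − artifacts;
necrosis is an input mask (drawn manually against H&E in practice), not an
algorithm. Vessel distance is the exact Euclidean distance transform scaled
by pixel size, averaged over viable pixels; whether necrotic pixels join the
average is a switch (`vessel_distance_includes_necrosis`, default off).

## PET and calipers

The manually-drawn avid ROI is replaced by a reproducible surrogate: voxels
above 40 % of the volume maximum (configurable), largest 26-connected
component. Activity density = ROI activity sum / ROI volume. No decay or
partial-volume correction; the scan delay is stored for provenance only.
Caliper volume is (π/6)·a·b², rejecting a < b.

## Statistics

Mean ± SE (SD/√n; undefined for n = 1, never reported as 0). One-way ANOVA
is computed from between/within sums of squares and cross-checked to 1e-10
against independent references. Newman–Keuls processes spans widest-first:
a pair spanning r ordered means is tested at q = |Δmean|/√(MSE/n_h) against
the studentized range with (r, df_within); n_h is the harmonic mean of the
two compared group sizes (group sizes in such cohorts run 2–11); any pair
nested in a non-significant span is blocked (containment rule), which keeps
the family-wise error of a null cohort at the nominal α (measured 0.044 at
α = 0.05 over 2000 replicates). Studentized-range probabilities come from
numerical integration of the range distribution
(`scipy.stats.studentized_range`), validated against printed q tables. No
multiplicity correction is applied across metrics/days beyond SNK itself,
matching the study design; strata (metric × line × day) are tested
independently.

## Synthetic phantoms — what they emulate, and what they don't

**DCE phantom.** An ellipsoidal tumor (semi-axes 0.35× the grid extent)
with an enhancing rim (outer `rim_fraction` = 0.4 of the normalized radius,
K^trans 0.3 min⁻¹) and a poorly-perfused core (0.1 min⁻¹); uniform
v_e = 0.3, v_p = 0.05, T1 = 1500 ms; a linear transmit-field gradient
κ ∈ [0.9, 1.1] along one axis. The dynamic, VFA and calibration signals are
generated by the exact forward chain the pipeline inverts, so at zero noise
the full chain must close voxelwise (it does, to ~1e-9). Note the volume
arithmetic: the outer 40 % of the radius holds ~78 % of the voxels, so the
erosion-defined "inner two-thirds" core deliberately mixes rim and core
kinetics — a real feature of shell-based splits on thick-rimmed tumors.
Noise is additive Gaussian on the magnitude signal; the default is
noiseless, and the protocol's own noise level is unreported, so SNR is a
free config choice (Rician statistics at low SNR are a known omission).
No motion, B0 inhomogeneity, or partial-volume effects are simulated:
passing tests certify the inverse chain, not robustness to artifacts.

**Section phantom.** A rectangular tumor on a 200×200 grid at 5 µm/px
(a downsampled whole-section mosaic; 1×1 mm field), contiguous necrosis
painted to the requested fraction in raster order, single-pixel vessels
sampled uniformly from viable tissue with a perfused (Hoechst⁺) subset, and
EF5 positivity painted wherever the distance to the nearest perfused vessel
exceeds 120 µm — the classic 100–150 µm oxygen-diffusion band. Ki67/TUNEL
positives are painted to exact counts. Every metric therefore has a
ground-truth value reproduced to one-pixel quantization; this certifies the
counting/distance machinery, not segmentation of real stains (intensities
are bimodal by construction; real channels are not).

**Cohort generator.** Per-tumor metrics are log-normal,
value = baseline × effect(arm) × exp(σZ), σ = 0.4 (~40 % CV, typical
inter-tumor spread), n = 8 per arm. Default effects encode the PaCa13
day-7 pattern: metronomic arm — volume ×0.1, median K^trans ×5, hypoxia
×0.25, vessel distance ×0.7, FDG ×0.6; antiangiogenic arm — volume ×0.8,
K^trans ×1.0, hypoxia ×1.2, vessel distance ×1.8, FDG ×1.2. Under these
conditions the report reproduces the expected decision pattern (metronomic
volume and K^trans vs vehicle significant, antiangiogenic K^trans not) in
100/100 seeded replicates.

## Numerical/engineering notes

* All randomness flows through integer seeds; identical spec + seed is
  byte-identical output, and the pipeline writes a provenance JSON (package
  version, seed, config SHA-256) beside every run.
* Degenerate inputs raise typed errors: undefined metrics
  (`UndefinedResultError`: e.g. zero CD31 pixels, no viable voxels) are
  distinct from precondition violations (`InvalidInputError`) and from
  untestable statistics (`DegenerateDataError`: zero variance everywhere).
* Problem sizes in the shipped analyses (24³ phantom, 200² sections,
  500-voxel recovery sweeps, 2000-replicate null Monte Carlo) were chosen so
  the full suite and the acceptance script each run in minutes on one CPU
  while keeping Monte-Carlo confidence intervals tight enough for the
  stated tolerances.

## Known limitations

* The study's own population AIF is not published; absolute K^trans values
  are therefore not comparable to the study's figures — all correctness
  claims are self-consistent (forward/inverse) by design.
* No Rician noise, no motion/B0 artifacts, no DICOM ingestion, no
  reconstruction (PET starts from reconstructed volumes).
* Channel alignment is translation-only and integer-pixel.
* Shell construction ignores voxel anisotropy (see above).
* v_p at 15.6 s sampling is reported but should be interpreted as weakly
  identified.
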