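# Methods

## Scope and model

`scrkit` estimates radiation-induced secondary cancer risk (SCR) for organs
at risk in breast radiotherapy from dose–volume histograms (DVHs), and
compares treatment techniques at cohort level. The chain is

1. DVH (differential or cumulative, volume fractions over Gy dose bins) →
2. organ equivalent dose (OED) under a dose–response model →
3. excess absolute risk EAR = EAR₀ · OED with age-dependent baseline
   coefficients →
4. per-patient cumulative EAR over the organs at risk →
5. cohort summaries, technique ratios, paired t tests, ΔEAR age analysis.

Assumptions inherited from the OED/EAR formalism: risk is proportional to
OED; EAR₀ transfers A-bomb-survivor incidence data to the radiotherapy
cohort; the attained age is fixed at 70 years (other attained ages are
rejected unless the user supplies extended coefficient entries); proton
doses are already RBE-weighted with a constant factor 1.1 and are treated
as Gy throughout; no fractionation/dose-rate correction, neutron dose,
imaging dose, or variable-RBE effect is modelled.

## Dose–response models and parameters

For volume fractions `v_i` at bin-centre doses `D_i`:

| model | OED | parameter | default | interpretation |
|---|---|---|---|---|
| linear | Σ v_i·D_i | — | — | no cell kill; equals the mean dose; overestimates above a few Gy, reported for reference only |
| linear-exponential | Σ v_i·D_i·e^(−αD_i) | α (Gy⁻¹) | 0.044 | full cell kill, no repair/repopulation; "bell-shaped"; maximal response at 1/α ≈ 22.7 Gy |
| linear-plateau | Σ v_i·(1−e^(−δD_i))/δ | δ (Gy⁻¹) | 0.139 | full repair/repopulation; bounded by 1/δ ≈ 7.19 Gy |

α and δ come from a combined fit to A-bomb and Hodgkin-lymphoma survivor
data. Baseline coefficients (cases per 10,000 persons per year per Gy,
females, attained age 70): lung 7.5 (95% CI 5.1–10.0) and breast 9.2
(6.8–12.0) for exposure at 30; lung 7.8 (4.6–12) and breast 3.7 (2.1–5.9)
for exposure at 50. Both lungs use the lung coefficients, the
contralateral breast the breast coefficients; no laterality adjustment
exists for EAR₀. CI bounds propagate multiplicatively (EAR_low =
CI_low·OED) with no added distributional assumption — the sources report
coefficient CIs but no combined interval, so propagation is kept
transparent and optional.

## DVH conventions and numerics

* Volumes are fractions of the organ volume; absolute cm³ is optional
  metadata (the OED sums use the 1/V_T-normalised form).
* The representative dose of a bin is its centre — unbiased for dose
  piecewise-uniform within bins; the source analysis leaves the TPS
  export binning unstated, and the bin-refinement invariance tests bound
  the resulting uncertainty (mean dose stable to half a bin width).
* Differential↔cumulative conversion is an exact finite-difference /
  tail-sum pair; the round trip is the identity to 1e-12.
* Validation reports violations (normalisation 1e-9, monotonicity, edge
  ordering) rather than repairing silently.
* A uniform-dose organ is represented as a single near-degenerate bin
  (width 1e-12 Gy) centred on the dose, so closed-form checks hold to
  1e-12; an exactly zero-dose organ is the same spike at the origin, whose
  residual mean (5e-13 Gy) is numerically zero.
* Rebinning treats each bin's mass as located at its centre and reassigns
  it to the containing new bin: exactly volume-conserving, moves the mean
  by at most half the coarser bin width, and keeps a uniform-dose spike a
  spike on finer grids (an overlap-proportional scheme would smear it).
* EARs are kept at full precision internally and in CSV output; printed
  tables round to integers the way the clinical presentation does.

## Synthetic cohorts

The study's per-patient DVHs are not published; only arm-level mean doses
(with SEM, n = 5) and qualitative DVH shapes are. The generator therefore
emulates, per organ and arm:

* **shape** — a two-component mixture: a scaled Beta over (0, 50 Gy]
  (fraction `f_h`, concentration κ = 3) for the target-adjacent high-dose
  region, plus an exponential low-dose bath truncated at the prescription.
  Ipsilateral lungs use `f_h` = 0.20 (protons, bath scale 0.3 Gy) or 0.35
  (photons, bath 2.0 Gy); contralateral organs are bath-only — near-zero
  scale for protons (sub-0.1 Gy means), extended bath for photons (5–7 Gy
  means). These shape values are free parameters chosen once to mimic the
  published cumulative-DVH forms (proton: near-step with little
  out-of-field dose; photon: long low-/intermediate-dose tail);
* **level** — each patient's organ mean dose is a lognormal draw
  (positivity-preserving) around the published arm mean with CV =
  SEM·√5 / mean from the published dispersion. The free mixture parameter
  (Beta mean, or bath scale for bath-only organs) is then solved by Brent
  root-finding (tolerance 1e-10) so the *binned* DVH mean equals the draw
  exactly. If the required Beta mean exceeds its feasible range the
  high-dose fraction grows instead (mean stays exact); draws whose mean is
  bath-dominated fall back to bath-only. For nearly unirradiated organs
  (mean below ten bin widths) the grid refines to a tenth of the mean and
  truncates where the bath vanishes, mirroring the fine low-dose
  resolution of TPS exports; the default grid is otherwise 0.05 Gy over
  0–50 Gy (≤0.1% discretisation effect on OED at prescription-level
  doses);
* **cohort draws** — `generate_cohort` samples one lognormal quantile per
  probability stratum (strata shuffled across patients), so a five-patient
  cohort is representative of the inter-patient distribution and cohort
  means converge to the configured arm means much faster than i.i.d.
  sampling; `generate_patient_dvh` keeps plain i.i.d. draws for
  independent-patient use. Seeding: one master seed, per-organ substreams
  spawned deterministically; outputs are byte-reproducible per seed.

What passing tests do and do not show: quantities driven by arm mean doses
(linear-model OED/EAR, cumulative linear EAR, linear risk ratios, ΔEAR
ratios) reproduce the clinical analysis because the generator is calibrated
to exactly those means. Quantities driven by the full DVH shape (the
nonlinear-model OEDs) land in the right range and preserve every published
ordering (photon > proton per organ and model; the more complex nodal
target > the simpler one for protons), but their absolute values depend on
the invented mixture shapes and are not asserted against the clinical
tables. Real anatomical correlations between organs, setup uncertainties
and plan-specific DVH structure are not emulated.

Two of the published arm dispersions imply inter-patient CVs near or above
1 (e.g. contralateral lung 0.08 ± 0.10 Gy → CV ≈ 2.8, an SD exceeding the
mean). For such organs the n = 200 sample mean intrinsically fluctuates by
more than 1% across seeds, so the calibration test asserts a 1% match for
moderately dispersed organs (CV ≤ 0.5) and unbiasedness (across-seed
average of n = 200 means, within 1.5% ≈ 2.6 standard errors of that
average) for the heavy-tailed ones; the generator itself is not altered
for either check. Per-patient draws are clipped to the representable range
[1e-6 Gy, 98.5% of prescription]; the clipping probability under the
defaults is negligible (<1e-5 of the mean).

## Statistics

* Cohort dispersion: SD (ddof 1) and SEM = SD/√n are both computed — the
  clinical tables mix the two conventions — and the reporting convention
  is configurable (default SD for EAR tables).
* Relative factors: both the ratio of cohort cumulative means (headline;
  reproduces the printed 2.1/3.5/5.2 arithmetic) and the mean ± SEM of
  per-patient ratios are emitted, since the published "factor ± error"
  convention is ambiguous. Neither is asserted as "the" published method.
* Paired comparisons: two-tail paired Student t (scipy), significance at
  p < 0.05, run on cumulative and per-organ EARs. Zero-variance
  differences (identical synthetic patients) return p = 1 with a
  degenerate flag instead of raising. No multiple-testing correction is
  applied (none is described for the source analysis); reports state the
  number of tests performed.

## Problem sizes in the shipped checks

Unit and property tests run on DVHs up to 80 bins (hypothesis strategies,
derandomised) and a 10,000-voxel brute-force oracle; the pipeline checks
use the study-sized five-patient cohorts, a 100-seed power study of the
VMAT-vs-proton paired t test, and n = 200 cohorts for mean-dose
calibration — sizes chosen so the full suite completes in well under a
minute per module on a single CPU while leaving Monte-Carlo tolerances
comfortably non-marginal.

## Known limitations

* The EAR formalism itself carries large systematic uncertainty (EAR₀
  transfer, model choice); relative technique comparisons are the robust
  output, absolute incidences are indicative.
* Only three organs at risk are modelled; heart, oesophagus and thyroid
  contributions are out of scope, as are NTCP, survival conversion,
  DICOM ingestion and treatment planning.
* Config-file coverage is deliberately small: model selection, α, δ,
  EAR₀ overrides, exposure ages, dispersion convention, and the synthetic
  arm parameters.
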