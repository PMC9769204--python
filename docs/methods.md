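# Methods notes

This note records the modelling conventions, parameter choices and known
limitations behind `petrad`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Imaging conventions

Volumes are 3-D scalar grids in (x, y, z) axis order; physical position of
voxel *(i, j, k)* is `origin + index · spacing` with spacing in mm.
NIfTI-1 is the only on-disk image format — it keeps I/O testable without
vendor DICOM dialects; masks share the exact grid of their volume, and no
resampling happens at I/O time.

SUV is body-weight SUV with tissue density 1 g/mL:
`SUV = c / (A_inj · 10⁶ / (w · 10³))` for concentration *c* (Bq/mL),
injected activity *A_inj* (MBq) and weight *w* (kg). The injected dose is
assumed decay-corrected to scan start; callers who track injection-time
dose instead can pass `decay_minutes`, which decays the dose with the ¹⁸F
half-life (109.77 min). The flag exists because clinical software differs
silently on this point; it is off by default and documented rather than
guessed.

## Segmentation

The fixed-threshold rule is 40 % of the maximum SUV *inside the
operator's seed region* — the standard fixed-fraction method for cervical
lesions. The comparison is inclusive (≥) so a single-voxel lesion retains
its own maximum. Only the 26-connected component containing the hottest
voxel is kept (ties broken toward the lowest linear index), which
discards satellite nodal uptake caught in the seed box. The threshold is
applied inside the seed only; the VOI never grows past the region the
operator drew.

## Resampling and discretization

Texture features are computed on a 4 mm isotropic grid resampled from the
native reconstruction grid (typically 4.07 × 4.07 × 5.0 mm): trilinear
for intensities, nearest-neighbour for the mask. The resampled grid
shares the native origin, so data already on the target grid pass through
unchanged.

Discretization is absolute fixed-bin-width: level = ⌊(SUV − 0)/0.25⌋ + 1,
no upper clamp by default. The alternative reading of "0.25 fixed ... 
width" as a bin-*count* scheme is deliberately not the default; relative
binning destroys the cross-patient comparability of low-grey-level
emphasis features, which is exactly where the prognostic signal of
interest lives. `DiscretizationConfig` exposes `bin_width`,
`lower_bound` and `max_levels` for users who need other conventions.

Conventional SUV metrics (SUVmax/mean/peak/quartiles, MTV, TLG) are
computed *before* resampling, on the native grid; histogram, shape and
texture features after. SUVpeak uses a 1 mL sphere (radius 6.2035 mm),
voxel-centre membership, centred on VOI voxels only; the sphere may
extend beyond the VOI but is clipped at the image border (logged).

## Texture matrices and features

All four matrix families treat out-of-VOI voxels as absent: they never
pair, never extend runs, never join zones.

* **GLCM** — level pairs at the 13 unique offsets of the 26-neighbourhood
  (distance 1), symmetrized and *merged into a single matrix* (not
  per-direction feature averaging), then normalized. Merging matches the
  convention of the clinical texture software this pipeline mirrors.
* **GLRLM** — maximal equal-level runs along the 13 directions, merged.
  Run percentage is `N_runs / (13 · N_voxels)` so it stays in (0, 1]
  after merging.
* **NGLDM** — the stored matrix counts, for each voxel, its same-level
  26-neighbours (tolerance 0) — a dependence matrix with columns 0..26.
  The three scalar features (coarseness, contrast, busyness) are the
  classical neighbourhood-*difference* quantities of Amadasun &
  King, computed from per-level sums `s_i` of |level − mean neighbour
  level| kept alongside the matrix. Both structures are exposed; the
  dependence matrix carries the testable counting invariants, the
  difference summary carries the standard feature definitions.
* **GLZLM** — 26-connected iso-level zones counted by (level, size); the
  emphasis features reuse the GLRLM algebra with zone size in place of
  run length.

Degenerate single-grey-level VOIs are well-defined throughout: entropy
and contrast are 0, GLCM correlation is 0 by convention (logged),
skewness/kurtosis of a constant histogram are 0, and NGLDM coarseness is
capped at 10⁶ when the difference sum vanishes.

Shape features use the voxelized mask: surface area by face counting,
sphericity `(36π V²)^{1/3} / A`, compacity `V / (√π · A^{3/2})` with V in
mm³ and A in mm². Mesh-based surface area would give systematically
smaller values; face counting was chosen because it is exactly testable
(a 4 mm voxel has A = 96 mm²) and its bias is monotone and documented.

The registry exports 52 named features in a stable order. The named set
covers every feature the workflow's downstream selection can act on;
features reported by specific clinical packages but absent here (e.g.
wavelet-filtered variants) are out of scope.

## Selection

Mann–Whitney U is two-sided, exact when n₁·n₂ ≤ 400 with no ties,
otherwise normal with tie and continuity corrections. Inclusion is
strict (p < α, default 0.05) with *no* multiple-testing correction —
deliberate for an exploratory screen at n = 47, and stated rather than
hidden. `auc_equivalent = U/(n₁n₂)` is the probability that a deceased
patient's value exceeds a survivor's (ties half), identical to the ROC
AUC; the cross-module identity is tested to 1e-12.

Redundancy pruning is greedy keep-best-p: features visited by ascending
screening p (name as tie-break), kept iff |ρ| < 0.85 strictly against
everything kept so far; each drop records the blocking partner and ρ. The
absolute value is used — a ρ = −0.89 pair is just as redundant as +0.89.
Greediness makes the output deterministic and auditable; it does not
claim optimality.

## Survival analysis

DeLong's structural-component variance is implemented directly from the
placement values; the test suite checks it against a literal delete-one
jackknife, to which it is algebraically identical. The CI is
`AUC ± 1.96·SE` truncated to [0, 1].

The operating cut-off maximizes Youden's J over observed score values
with the rule "positive iff score ≥ t" (≤ for features depressed in the
deceased; the direction is chosen so AUC ≥ 0.5). Ties in J break toward
higher specificity, then the smaller cut-off — fixed and documented
because J landscapes on small cohorts are full of exact ties.

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines`; Greenwood variance and the O/E risk ratio are computed
in-module from the event table. Where Ŝ has reached 0 the Greenwood
product is reported as 0. "Risk ratio" here always means the log-rank
observed/expected hazard ratio (labelled `risk_ratio_oe`), the estimator
classic KM software prints — not a Cox model coefficient. With zero
observed or expected events in a stratum the ratio is degenerate and is
reported with an infinite CI and a warning rather than an exception.

## Synthetic data

Phantoms: an ellipsoidal lesion (default semi-axes 22 × 18 × 16 mm) on a
48 × 48 × 40 grid at 4.07 × 4.07 × 5.0 mm, background SUV 1.0 with
Gaussian noise (σ 0.05), lesion peak SUV 12 with a radial Gaussian
falloff (σ 0.5 in normalized ellipsoid radius), plus an optional
correlated Gaussian random field inside the lesion (correlation length
8 mm, σ 1.0, clipped at 0) and an optional necrotic core. The correlated
field is the simplest heterogeneity model whose effect on run-length and
co-occurrence features is predictably monotone in the correlation length
— a property the tests verify. The lesion centre snaps to a voxel centre
so the analytic 40 %-of-peak super-level set in the truth record is
exactly the sampled one. These phantoms deliberately omit PET physics
(PSF, Poisson sinogram noise, reconstruction artefacts): passing tests
demonstrate correctness of the measurement chain, not robustness to
scanner effects.

Cohorts: 47 patients, 36 survivors / 11 deaths, 730-day horizon — the
two-group structure this pipeline is designed around. The designated
prognostic feature (default SUVpeak, scale 10.9 + 2.2·z) separates the
outcome groups under a binormal model at a designed AUC of 0.74 (mean
shift √2·Φ⁻¹(AUC)); a 13-feature texture block (pairwise |ρ| > 0.85,
deceased lower, positive 10⁻³-scale values via a monotone exponential
transform), two correlated SUV companions, and 10 independent null
features complete the table. Deaths receive truncated-exponential times
(mean 400 days before truncation); survivors are administratively
censored at the horizon. An alternative `exponential` survival model
(hazard λ₀·exp(β·z)) exists for null calibration (β = 0) and
hazard-ratio recovery experiments. FIGO stages follow the emulated
composition 2/4/21/20.

A deliberate consequence of these study conditions: at designed AUC 0.74
and n = 36/11 the two-sided Mann–Whitney screen has power ≈ 0.7, so no
single synthetic replicate reliably "rediscovers" the prognostic feature
— only the calibration of the *mean* empirical AUC is tight. The
recovery property tests therefore use a clearly prognostic designed
effect (AUC 0.85), where screening-plus-stratification succeeds in ≥95 %
of seeds.

## Problem sizes in the test suite

Oracle equivalence runs on 200 random 5³ VOIs; AUC calibration on
300–500 cohort replicates; null calibration on ~1000 feature tests and
500 log-rank replicates; hazard-ratio recovery on 150 replicates. These
sizes put Monte-Carlo error comfortably inside the asserted tolerances
while keeping the default suite fast on a single CPU.

## Known limitations

* No DICOM series reading, no scanner harmonization (ComBat), no wavelet
  or 2-D slice-wise features, no IBSI certification paperwork.
* The exact feature list of any particular clinical package cannot be
  reproduced bit-for-bit; formulas here follow the published standard
  definitions and are frozen by the oracle tests.
* No Cox regression, time-dependent ROC or competing risks — the survival
  layer mirrors the univariate KM workflow only.
* Median-survival CIs come from the log-log transform via `lifelines`;
  on tiny strata they are wide and may be undefined (reported as such).
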