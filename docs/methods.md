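# Methods

## Scope and design

`msquant` measures per-region quantitative MRI values in MS patients:
lesion evolution classes from structural contrast, apparent diffusion
coefficients, and relative DSC perfusion parameters. Every numerical stage
is validated against a built-in digital phantom whose ground truth is known
exactly; the phantom is first-class, tested code, not a fixture.

## Lesion segmentation and classification

Lesions are delineated semi-automatically on FLAIR: from an operator seed,
the ROI is the 26-connected component of voxels with intensity at least
`local_factor` × the peak intensity in the seed's 3×3×3 neighbourhood
(default `local_factor = 0.5`). The growing is deterministic, always
includes the seed, and flags (rather than rejects) regions touching the
grid boundary. How the original interactive tool parameterises its local
threshold is not public; this fraction-of-local-peak rule is our documented
choice.

Classification thresholds are per modality:
`Thre_High/Low = Ī ± Mf·SD(I_NAWM)` with Ī, SD the mean and sample standard
deviation (n−1) of a NAWM reference ROI, and `Mf` a multiplier, default 2.0
(configurable; no canonical value exists). A lesion is enhancing iff its
Gd-T1 summary statistic strictly exceeds the Gd-T1 Thre_High and
hypointense iff its T1 statistic falls strictly below the T1 Thre_Low;
equality counts as isointense / non-enhancing. The summary statistic is the
mean over ROI voxels (median available as a config option). T1-hyperintense
lesions have no class in this scheme and are mapped to isointense with a
warning. Because lesion statistics and thresholds are both affine in the
intensities, classification is invariant under any global rescaling
`a·I + b, a > 0`.

The classified inventory round-trips through a small line-oriented text
dialect (one header line per ROI — id, class, colour, quoted label —
followed by `x y z` voxel lines) so an operator can revise class codes in a
text editor and the pipeline can reload the file and continue.

## Diffusion

Two-point Stejskal–Tanner inversion per axis: `ADC = ln(S0/S_b)/b` inside
the brain mask where both signals are positive; negative coefficients
(S_b > S0, possible under noise) are clamped to zero and counted. The
isotropic map is the voxelwise arithmetic mean of the three axis maps,
valid only where all three axes are. Clamped/invalid voxels are excluded
from region statistics via an explicit validity mask instead of polluting
them as zeros. Units are mm²/s; reporting layers may display ×10⁻³ mm²/s.

## Perfusion

*Arrival.* On the brain-mean intensity curve, the threshold is
`fraction × (max − min)` of the whole curve (default fraction 0.1), and the
baseline at step k is the cumulative mean of volumes 0..k−1; arrival is the
first k whose absolute departure from baseline exceeds the threshold. The
absolute difference makes the detector agnostic to signal drop vs rise; a
flat curve raises an explicit no-arrival error.

*Concentration.* `C(t) = −ln(S(t)/S0)/TE`, with S0 the mean of baseline
volumes `skip..arrival−1` (default skip = 1 non-steady-state volume).

*AIF.* Candidate voxels are ranked by the sum of percentile ranks of high
peak concentration, early time-to-peak and narrow FWHM; the AIF is the mean
curve of the top 10 voxels, which are reported for visual verification. The
scoring is our stand-in for an unpublished commercial criterion; a manual
ROI override bypasses it.

*Deconvolution.* Standard (non-circulant) truncated SVD of the
lower-triangular Toeplitz system `C = A·k`, `A[i,j] = TR·AIF[i−j]`.
Singular values below `svd_threshold × s_max` are zeroed; numerically-zero
singular values are always dropped (the matrix is rank-deficient whenever
the AIF starts with zeros), so threshold 0 means the plain pseudoinverse.
The default threshold is 0.2 for noise robustness; parameter-recovery
studies on noiseless phantoms use 0.05, where truncation bias is smaller.
`CBF = max_t k(t)`, `CBV = ∫C/∫AIF` (trapezoidal), `MTT = CBV/CBF` where
CBF > ε. Negative estimates are clamped to zero. Maps are relative — no
hematocrit or density constants — and delay/dispersion correction and
leakage modelling are out of scope.

## Registration

A deliberately simple, pluggable 6-DOF rigid estimator: multi-resolution
(×4, ×2, ×1) Powell search over a 32-bin normalized-mutual-information
metric, centre-of-mass translation seeding, rotations about the fixed-volume
centre. World coordinates in mm, RAS; voxel indices 0-based. Labels and
masks are always resampled nearest-neighbour (preserves the value set),
quantitative maps linearly; out-of-field voxels become 0. The search keeps
its incoming parameters when a level fails to improve on them, so a
perfectly aligned pair returns the exact identity. The pipeline snaps
estimated transforms whose maximum corner displacement is under 0.1 mm to
the identity instead of resampling: such transforms sit below estimator
resolution and resampling through them only adds interpolation blur. The
FLAIR–T1 transform is reused unchanged to carry lesion masks between spaces;
masks are never re-registered.

On the default phantom the estimator recovers a 3-voxel translation to
~0.02 voxel and a 5° in-plane rotation to ~0.01°.

## Tissue masks and volumes

NAGM/NAWM are set subtractions: `gm ∧ ¬lesion`, `wm ∧ ¬lesion`. Deep grey
structures (caudate, putamen, globus pallidus, thalamus; left/right) are
accepted as label inputs with a JSON code table. When no external
segmentation exists, a fallback 3-class k-means on standardized T1
intensities inside the brain mask stands in, classes ordered by mean and
mapped CSF < GM < WM (T1 contrast); it is deterministic given its seed and
invariant to positive affine rescaling. Skull-size volume normalization is
a plain multiplication by a supplied scaling factor (default 1.0); its
estimation from anatomy is out of scope.

## Region statistics and provenance

Statistics (n voxels, volume = n × voxel volume, normalized volume, mean,
SD, median, IQR, min/max) are computed in FLAIR space per region × map,
excluding upstream-invalid voxels (clamped ADC, zero-CBF for CBF/MTT).
Empty regions report missing markers, never fabricated zeros. The CSV has a
stable column order and round-trips losslessly.

The provenance log is append-only JSON-lines: per step, parameters, content
hashes of inputs/outputs, software version, timestamps. Step inputs are
snapshot-copied into a fresh versioned directory before the step may touch
anything, and reruns never overwrite earlier outputs. A verification pass
re-hashes recorded outputs and reports tampering.

## DICOM intake

De-identification follows a conservative configurable profile: direct
identifiers (names, birth date, dates, institution, physician/operator
tags) blanked, a replace map for pseudonyms, and study/series/SOP UIDs
re-hashed deterministically under a per-run salt into a recognizable org
root, making re-anonymization a header-level no-op (idempotent). Pixel data
are untouched; the identity↔pseudonym mapping is written only to a separate
permission-restricted file. Inventory checking flags patients missing any
required sequence, writes a per-patient missing-sequence checklist and
excludes them from the run list; layout normalization copies (never moves)
files to canonical vendor-independent names, routing unmapped extras to
`extra/`.

## The phantom

Geometry: an anisotropic ellipsoid brain (narrower left–right than
anterior–posterior — as real heads are, and making in-plane rotation
identifiable), a cortical GM shell, central CSF ventricles, eight deep-grey
spheres, a small arterial region, and spherical white-matter lesions (two
per class C1–C4 by default) that the generator requires to be disjoint and
inside the grid. Default grid 48×48×24 at 1 mm; DSC series 60 volumes at
TR = 1 s, TE = 0.03 s.

Forward models: structural = tissue mean + lesion offset + additive
Gaussian noise (default noise 0 — the phantom is a validation object with
exact truth; tests add noise explicitly); DWI `S_b = S0·exp(−b·ADC)` with
isotropic ADC truth (CSF/GM/WM/lesion = 3.0/0.9/0.7/1.0 ×10⁻³ mm²/s); DSC
`S(t) = S0·exp(−TE·C(t))` with `C = CBF·(AIF ⊛ e^{−t/MTT})` computed as the
continuous convolution integral on a 20×-finer grid and sampled at TR, so
MTT is the exact exponential time constant and CBV = CBF·MTT holds as an
integral identity independent of the deconvolution stage's quadrature.
Perfusion truth: WM (CBF 0.01 /s, CBV 0.04, MTT 4 s), GM (0.02, 0.08, 4 s).
The gamma-variate bolus (t0 = 9.5 s, α = 1, β = 1.5 s, amplitude 4) is
sharp enough that the first post-onset sample carries ~30 % of the total
signal drop, which is what makes exact arrival-index recovery by a
threshold detector a well-posed requirement; arterial voxels carry the AIF
itself at ~13× tissue peak concentration.

What the phantom does *not* emulate: realistic anatomy, partial-volume
mixing, Rician noise statistics, motion, signal drift, contrast leakage.
Passing tests therefore demonstrate correctness of the numerics and the
pipeline contracts, not clinical performance on patient data.

## Numerical choices and degenerate inputs

- Strict threshold comparisons; ties are isointense/non-enhancing.
- Noiseless NAWM gives SD = 0 and a degenerate (zero-width) window; this is
  well-defined under strict comparisons and exercised by tests.
- `signal_to_concentration` returns 0 wherever signals are non-positive.
- Sample SD uses the n−1 denominator everywhere; single-voxel regions
  report SD = 0 in region statistics but are rejected as NAWM references.
- Problem sizes in the validation suite (48×48×24 and 32³ grids, 60
  timepoints, 20–25 Monte-Carlo seeds) were chosen as the smallest at which
  the discretisation and sampling effects under study are clearly resolved.

## Known limitations

- The rigid estimator assumes a decent initial overlap (centre-of-mass
  seeding); it is not a general-purpose registration tool.
- SVD truncation biases CBF downward as the threshold grows; with the 0.2
  default on clean data expect ~20–30 % underestimation, which is the
  standard robustness/accuracy trade-off of the method.
- Lesion-level perfusion statistics inherit all DSC caveats (no leakage
  correction — enhancing lesions violate the intact-barrier assumption).
- The four-class scheme has no T1-hyperintense class; such lesions are
  flagged, not classified separately.
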