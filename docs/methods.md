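# Methods

`dosepaint` implements a voxel-wise "dose painting by numbers" workflow for
newly diagnosed glioblastoma: multiparametric MRI (apparent diffusion
coefficient, ADC, and relative cerebral blood flow, rCBF) is converted into
a per-voxel probability of tumour infiltration, the probability into a
heterogeneous dose prescription, the prescription into a deliverable dose
distribution via a surrogate optimizer, and the resulting plans are scored
against a standard uniform 60 Gy plan. This note records the models, the
defaults and why they were chosen, and the limits of what the synthetic
phantoms can demonstrate.

## Infiltration model

The probability of tumour presence at voxel *i* is driven by the linear
combination

    L_i = 1.64 + 1.80 · ADC_i + 1.43 · rCBF_i

of the *standardized* (z-scored) parametric maps. The three coefficients
come from a biologically validated logistic-regression model of glioma
infiltration fitted elsewhere against biopsy ground truth; this package
treats them as fixed constants and does not refit them.

The printed combination is unbounded, but it is used as a probability and
its coefficients have logistic provenance, so a link function is required.
Two are provided and recorded in the map's provenance:

* `logistic` (default): `p_i = 1 / (1 + exp(−L_i))`, consistent with how
  the coefficients were estimated;
* `clamped-linear`: `p_i = clamp(L_i, 0, 1)`, a literal reading of the
  formula.

Overrides, applied after the link: every GTV voxel gets `p = 1` (residual
tumour by definition), every CSF voxel `p = 0` (the model is not validated
in CSF). The map is masked to the CTV and is NaN outside it. CTV voxels
outside the perfusion field of view carry no model output; they receive
`p = 0` (hence the safe 60 Gy base dose) and a logged warning.

## Prescription

Dose painting assumes a linear relationship between infiltration
probability and required dose:

    D_rx,i = Dmin + (Dmax − Dmin) · p_i

with `Dmin = 60 Gy` (standard-of-care adjuvant dose) and `Dmax = 80 Gy`
(maximum tolerated dose in dose-escalation trials). The PTV ring outside
the CTV is prescribed the uniform 60 Gy base dose. The inverse prescription
`Dinv,i = Dmax − D_rx,i` is emitted for compatibility with commercial
optimizers driven through a pretreated mock plan; the surrogate optimizer
here does not need it. Fractionation (30 fractions) is metadata only — all
doses are total physical dose, which is also how the TCP model is
calibrated.

## Target volumes

CTV = GTV expanded isotropically by 15 mm, PTV = CTV expanded by 3 mm.
Expansion uses a Euclidean distance transform in physical millimetres
(anisotropy-aware, voxel-centre convention) thresholded at the margin.
Anatomical-barrier clipping is applied *after* expansion (post-hoc clip,
not geodesic), matching common treatment-planning-system behaviour; the
brain mask is the default barrier for the CTV. The PTV is not clipped to
the brain because the set-up margin is physical, not anatomical.

Two discretization facts matter for validation. First, a rasterized margin
is accurate to about half a voxel in equivalent-sphere radius (on a 0.5 mm
grid the 15 mm and 3 mm margins measure 14.93 mm and 2.93 mm). Second,
composing two expansions is a *subset* of one expansion by the summed
margin on a grid — the continuous-geometry equality only survives up to one
voxel diagonal of slack — because intermediate distances are forced through
voxel centres; the tests check the discrete property.

## Surrogate planning

The clinical workflow this package models runs its plans through a
commercial VMAT system. That machine model is deliberately replaced by a
transparent surrogate — this is the package's single largest
simplification. The deliverable dose is a Gaussian point-spread-function
blur (default FWHM 5 mm, mirroring the 5 mm MLC leaf width of the delivery
system the surrogate stands in for) of a non-negative latent intensity
field. The field is fitted by projected gradient descent (projection onto
the non-negative orthant; step halving on objective increase, so the
objective trace is non-increasing by construction) on a weighted sum of
one-sided quadratic penalties:

| term | default weight |
|---|---|
| squared deviation from the prescription on the PTV | 1.0 |
| under-dose vs GTV 76.8 / CTV 61.2 / PTV 60.6 Gy minima | 10.0 |
| over-dose vs the 77.5 Gy PTV maximum | 10.0 |
| OAR limits (Dmax; Dmean for whole brain) | 100.0 |
| quadratic falloff outside the PTV beyond 10 mm | 0.01 |

The weight ordering mirrors treatment-planning priorities: organ limits are
hard-ish, coverage targets firm, conformity soft. OAR limits follow
EORTC-style constraints: brain Dmean < 45 Gy (reports of this limit vary
between 45 and 50 Gy; 45 is the default and the value is configurable),
brainstem/chiasm/optic nerves Dmax < 54 Gy, lenses < 10 Gy, retinas
< 50 Gy. Voxels where an OAR overlaps the PTV are exempted from the OAR
penalty (target coverage outranks the overlapping organ), but
`check_constraints` always reports the full organ.

In `standard` mode the fit target is the uniform 60 Gy prescription and the
GTV/CTV boost minima are replaced by the PTV minimum: a uniform plan has no
boost targets, and retaining them would manufacture a boost the standard
arm must not have (its V76Gy must be 0).

Numerical choices: the latent field is initialized to the prescription
(zero outside the PTV); the optimizer works on a crop box around
brain + targets + organs padded by 3 PSF sigmas plus the falloff margin;
iteration stops on relative objective change < 1e-6 or at 300 iterations,
in which case `converged=False` is returned rather than raising. With the
PSF width set to zero and only the fit term active the optimum is the
prescription itself, which the tests use as an exact limiting case.

Because the optimum trades the 80 Gy prescription peak against the 77.5 Gy
PTV maximum (the weighted equilibrium sits near 77.7 Gy), the surrogate's
GTV quality factor lands around 97% on default phantoms — above the 95%
planning goal, with the same "conformity loss concentrated at the GTV–CTV
transition" signature the clinical system shows.

## Evaluation

* **Quality factor.** `QF = 100 − (100/n)·Σ |D_plan,i − D_rx,i| / D_rx,i`.
  The factor 100 on the deviation term expresses the mean absolute relative
  deviation in percent, consistent with "an ideal plan scores 100%" and
  with the QF literature.
* **DVH and dose metrics.** Cumulative DVH on a uniform dose grid (default
  0.1 Gy bins); `Dx%` is the (100−x)th percentile of voxel doses with
  linear interpolation between order statistics (numpy's default, type 7 —
  the nearest-voxel alternative differs by under a bin width and is not
  exposed); `VxGy` is the percent of voxels at or above x Gy. All are
  oracle-tested against sort-based brute force.
* **TCP.** `TCP = exp(−C · Σ_i p_i · exp(−α·D_i))` with `α = 0.12 Gy⁻¹`.
  `D_i` is the *planned* (delivered) dose when scoring plans — the model
  "converts a dose distribution into a TCP" — though the same routine
  accepts a prescription, since prescriptions are also scored. `C` is not
  universal: it absorbs the voxel volume and cohort anatomy, and is
  calibrated per cohort by bisection on log C so that the mean CTV TCP of
  the standard uniform plans equals the 27% 1-year progression-free
  survival of standard care (monotonicity in C makes the root unique;
  tolerance 1e-6 on TCP).
* **Statistics.** Paired standard-vs-DP comparisons use the Wilcoxon
  matched-pairs signed-rank test (exact null up to 25 non-zero differences,
  normal approximation with tie correction above; zero differences dropped;
  all-zero input flagged degenerate with p = 1). No multiple-testing
  correction is applied; p-values are reported raw.

## Synthetic phantoms

Each phantom emulates one co-registered, 1.2 mm isotropic post-operative
study on a 96³ grid: a brain ellipsoid (semi-axes 45/52/42 mm — a
deliberately desk-scale brain), two ellipsoidal lateral ventricles labelled
CSF, a 10 mm spherical GTV offset from the midline, geometric OARs
(brainstem cylinder, chiasm box, optic-nerve cylinders, lens/retina
spheres; pairwise disjoint by construction), and an axial FOV slab covering
the GTV ± 30 mm, mimicking limited perfusion coverage.

Ground-truth infiltration decays exponentially with Euclidean distance *d*
from the GTV surface, `p_true = clamp(exp(−d/λ)·(1+η), 0, 1)` with
λ = 10 mm, modulated by a smooth perturbation η (Gaussian-filtered white
noise, kernel sd 6 mm, amplitude 0.15) so prescriptions are spatially
non-trivial without destroying the monotone decay. ADC and rCBF are
constructed by *inverting* the infiltration model: the noiseless predictor
`L = link⁻¹(p_true)` (probabilities clipped to [1e-7, 1−1e-7] so the logit
stays finite) is split between the maps by a mixing fraction (default 0.5),
then independent Gaussian voxel noise (sd 0.1 in standardized units) is
added. Zero-noise phantoms therefore make the probability stage exactly
invertible — the pipeline's strongest internal consistency check.

Cohorts jitter GTV radius (±20%) and centre (±6 mm per axis) using
per-case sub-seeds spawned deterministically from the cohort seed
(`numpy.random.SeedSequence(seed, spawn_key=(index,))`), so cohorts are
reproducible and order-independent.

What the phantoms do **not** emulate: MR physics (bias fields, distortion,
partial volume), registration error, DSC time-series and leakage effects,
realistic neuroanatomy (falx/tentorium barriers — "anatomical boundaries"
reduce to the brain mask), or inter-patient biological variability beyond
geometric jitter. Passing tests therefore demonstrate that the *pipeline*
is correct and self-consistent, not that the infiltration model is accurate
on real patients — its clinical validity rests on the cited biopsy
validation, and cohort-level clinical results cannot be reproduced from
synthetic cases.

Phantom maps are emitted already in standardized units, so the pipeline
applies only the FOV-restriction step to them. The full raw-map chain —
resampling to 1.2 mm, normalization to a contralateral reference region,
edge-preserving bilateral smoothing (defaults: spatial sd 2 mm, range sd
0.5 in normalized units — light smoothing at the working resolution),
z-scoring with the population sd over brain voxels — targets real data and
is exercised directly by its unit tests. The standardization population
is an explicit mask argument (brain ∩ FOV ∖ CSF is the recommended
choice), since published practice varies on which voxels define the
z-scoring population. The chain is invariant to a global positive rescaling of the raw
input (normalization divides it out), which the tests verify.

## Problem sizes

Defaults were chosen to keep a full case interactive on one CPU: 96³ voxels
at 1.2 mm, ≈ 50 k-voxel PTVs, 300 optimizer iterations (≈ 30 s per plan),
5-case calibration cohorts. The test suite uses a reduced 64×64×56 phantom
with the same anatomy. All stages scale linearly in voxel count except the
optimizer's convolutions (n log n).

## Known limitations

* The surrogate optimizer shares the clinical problem's structure, not its
  physics: no beam geometry, no depth dose, no deliverability guarantees.
  Quantities that depend on the machine model (e.g. absolute OAR doses) are
  indicative only.
* The calibrated C is cohort-specific; the shipped default (0.032) is the
  literature value and should be recalibrated for any new cohort geometry.
* Margin expansion is non-geodesic; a barrier that separates tissue
  compartments can still be "jumped" by the post-hoc clip if the Euclidean
  path crosses it.
* The Wilcoxon exact method requires no ties in |differences|; with heavy
  ties scipy's exact enumeration still applies but conservative behaviour
  is not guaranteed.
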