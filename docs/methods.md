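# Methods

This note documents the models and numerical choices behind `cordpop`:
what each stage computes, which parameters matter and why their defaults
are what they are, what the surrogate does and does not emulate, and the
known limitations.

## 1. Digital population

A subject is defined by four transverse diameters at the cervical (C5)
epicenter: cord mediolateral SCOW and anterior-posterior SCOD, canal SCW
and SCD, all in mm. Defaults are the NHP population statistics
SCW = 11.6 ± 0.9, SCOW = 9.8 ± 0.7, SCD = 8.1 ± 0.4, SCOD = 6.3 ± 0.4 mm.
Cord and canal cross-sections are concentric ellipses; every derived
morphometric (areas SCO and SC, CSF area = SC − SCO, diametral CSF gaps,
occlusion ratios SCO/SC, SCOW/SCW, SCOD/SCD) follows in closed form.

**Sampling distribution.** The source statistics give only means and SDs,
so a distribution had to be chosen. Each diameter is drawn independently
from a normal truncated at ±2.5 SD; subjects violating the hard anatomical
constraint cord-strictly-inside-canal (SCOW < SCW and SCOD < SCD) are
rejected and redrawn. Two corrections and one caveat:

* Symmetric ±2.5 SD truncation alone would shrink the realized SD by
  ~4.5%, so the pre-truncation σ is inflated (solved numerically) so the
  *truncated* marginal SD equals the requested SD.
* The constraint rejection (~6% of draws at the defaults) necessarily
  biases the mediolateral marginals: it shifts the SCW mean up by ~0.09 mm
  and the SCOW mean down by ~0.05 mm (each < 1%), and shrinks their SDs
  by ~5–7%. This is an intrinsic property of the declared generative
  process, not a bug; tests compare against a Monte-Carlo oracle of the
  same declared distribution.
* No covariance between diameters is imposed (none is published). Real
  cords likely correlate with their canals; as a result the synthetic
  population slightly over-represents extreme occlusions.

Subject ids follow the `S1…Sn` convention. Identical seeds give identical
populations; per-subject random streams are keyed by (seed, subject id)
so results are independent of processing order.

## 2. Epicenter geometry

Coordinates: x mediolateral (positive = ipsilateral, i.e. the impactor
side), y anterior-posterior (positive = dorsal), origin at the canal
center. The epicenter cross-section is extruded into a 1-mm slab
(`slab_thickness`) so each element carries a volume EVOL; damage is scored
on this slab only, matching an epicenter-only damage metric. Whether the
reference analysis scored one element layer or a thicker slab is not
published; the thickness is configurable and sparing percentages are
volume ratios, so they are insensitive to it.

Regions, constructed with shapely:

* **Gray matter** — a fixed butterfly template (central commissure band,
  two ventral and two slimmer dorsal horns, built from ellipse unions,
  exactly x-symmetric). Its published shape is undefined; the default is a
  stylized primate cervical gray matter rescaled to 22% of the mean cord
  area (within the 20–30% range of primate cervical sections). The
  template has fixed absolute size for every subject: morphological
  variation lives in the white matter, the gray geometry is constant.
* **White matter** — cord ellipse minus the gray template.
* **Pia** — a 150-µm band outward of the cord, clipped to the canal.
* **Dura** — a 350-µm band inward of the canal, minus any overlap with
  the pia band.
* **CSF** — what remains between pia and dura. For tight-fitting subjects
  this annulus may pinch to nothing locally (or entirely, with a warning);
  that is intended — the band bookkeeping keeps all regions disjoint
  without forbidding near-contact anatomy, which the sampled population
  produces regularly.
* **Laminectomy** — a dorsal angular window (default 60° of arc centered
  20° ipsilateral of the dorsal midline). No dimensions are published;
  these values are a documented guess and the window is carried as
  metadata only (vertebrae are not modeled).

**Voxelization** labels square elements of side `voxel_size` (default
0.1 mm) by a centroid-in-region test with priority gray > white > pia >
CSF > dura; EVOL = voxel² × slab. The grid is symmetric about both axes,
so mirroring the subject mirrors the mesh exactly. At the default
resolution per-tissue volumes agree with the analytic areas to < 2%, and
halving the voxel changes them by < 2% (verified in tests). A voxel
larger than a shell thickness triggers a warning (that band may be
empty).

**Impactor footprint.** The 5-mm impactor center sits 0.5 mm ipsilateral
of the cord midline; the footprint is its mediolateral interval clipped to
the cord width. If the impactor edge extends past the lateral cord edge,
the overhang fraction quantifies "inadequate tissue at the impactor
edge", which feeds the surrogate's slippage term. The impactor bevel is
ignored in this planar analysis.

## 3. Tissue material models

`cordpop.materials` implements the constitutive parameter sets as
closed-form uniaxial, incompressible response functions — for
verification, reference curves and documentation, not as a 3-D FE
constitutive update.

* Gray matter: one-term Ogden, μ1 = 34.7 kPa, α = 7.61. **Convention
  note:** Ogden conventions differ by constant factors between codes. The
  form used here is W = (μ1/α)(λ1^α + λ2^α + λ3^α − 3) with uniaxial
  Cauchy stress σ = μ1(λ^α − λ^(−α/2)) and small-strain shear modulus
  μ1·α/2 (= 132.0 kPa for gray matter).
* White matter: Mooney–Rivlin QLV, C10 = 3270, C01 = 910 kPa;
  σ = 2(λ² − λ⁻¹)(C10 + C01/λ). The tabulated D = 239.3 kPa and
  γ = 6172 kPa are stored verbatim but deliberately unused: their role in
  the source QLV formulation is ambiguous, and guessing an interpretation
  would be worse than flagging it. Stored Poisson ratios are metadata for
  the same reason (the 1-D operators assume incompressibility).
* Viscoelasticity: Prony reduced relaxation g(t) = 1 − Σ gᵢ(1 − e^(−t/τᵢ))
  per tissue; relaxation times are taken as seconds (units unpublished;
  configurable). Long-term moduli implied by the tables: white 0.0261,
  gray 0.2352, dura 0.3546.
* QLV hereditary integral σ(t) = ∫ g(t−s) dσₑ(s): recursive
  per-exponential update, exact for σₑ piecewise-linear between samples;
  the caller chooses the time grid. Verified against direct quadrature
  (< 0.5% on a ramp) and the Prony limits (step response).
* CSF: Mie–Grüneisen with linear Us–Up Hugoniot,
  p = ρ0c0²η(1 − Γ0η/2)/(1 − sη)² + Γ0ρ0eₘ, guarded at the pole η = 1/s;
  small-compression slope equals the bulk modulus ρ0c0² ≈ 1.92 GPa.

## 4. Impact surrogate

The surrogate replaces an explicit dynamic FE solve. Its contract is
distributional: reproduce the population moments, correlation signs and
spatial damage gradients of the reference analysis under declared effect
sizes and noise. It makes no claim of predictive mechanics — no contact,
no fluid dynamics, no wave propagation — and must not be read as one.

**Peak force.** F = β0 + β_occ·(SCO/SC) + β_csf·CSF_area + ε,
ε ~ N(0, σ²), floored at 1 N. The mechanism this encodes: a
tighter-fitting cord engages more tissue under the impactor and sees more
force; CSF lets the cord translate away and is protective.
`calibrate_effects` keeps the relative weights of the two morphology terms
and rescales them so the morphology-driven part contributes a declared
fraction (default 0.75) of the target variance (default 24.3 ± 3.8 N),
with the remainder as noise; the intercept centers the mean. In the
noise-free limit the realized moments match the targets exactly on the
calibration population.

**Force–time curve.** Preload plateau at 0.75 N, then a raised-cosine
rise over the 8-ms impact phase (4 mm at 500 mm/s) peaking at full
displacement, then a half-length release. One pulse shape for all
subjects (the published curves are described as similar in shape across
subjects); impulse is the trapezoidal integral over the impact phase and
is therefore monotone in peak force.

**Strain field.** Compressive min LEP on gray/white elements only,
as max of two lobes, times a small multiplicative log-normal noise:

1. *Primary lobe* under the impactor: amplitude
   A = a0·(F/24.3)·engagement with a0 = 1.35 (the protocol compresses
   4 mm of a ~6 mm cord, |ln(1 − 4/6.3)| ≈ 1.0, plus dynamic overshoot);
   flat between the engagement center and the ipsilateral footprint edge;
   Gaussian decay beyond the edge with length 1.3 mm scaled by
   1 + 3·(SCOW/SCW − 0.845) (a tight cord cannot slip aside, so strain
   reaches the lateral rim); fast Gaussian decay (0.55 mm) on the
   contralateral side of the engagement center (the cord rolls away);
   mild depth decay (5 mm) below the dorsal surface. Engagement drops by
   0.5 × overhang fraction when the impactor overhangs the cord
   (slippage).
2. *Contralateral-ventral lobe* representing the cord pinched against the
   far canal wall: isotropic Gaussian (1.6 mm) at (−0.6·rx, −0.7·ry),
   amplitude ramping from zero below SCOW/SCW = 0.78 to 1.2·(F/24.3) at
   0.90.

The kernel constants were fixed in one calibration pass so that the
default population lands in the reported damage regime — gray/white
sparing means near 42%/56% with both thresholds straddled, lateral
extension of the white-matter lesion in a minority (~7/40) of
tight-fitting subjects, contralateral dorsal horn spared while
contralateral ventral damage appears in low-CSF subjects — and have been
frozen since. They are configuration, not fitted parameters.

**What passing tests do and do not show.** Tests demonstrate that the
pipeline recovers the statistical structure it generates (parameter
recovery, correlation signs, calibrated moments) and that the damage
arithmetic is exact on constructed fields. They cannot validate tissue
mechanics against experiments: agreement of the correlation family with
the published analysis shows the surrogate's declared structure matches
the published covariance pattern, not that a new morphology's strain
field would be predicted correctly.

## 5. Damage scoring

Thresholds on min LEP: gray −0.44, white −0.77 (50%-damage-probability
levels used as hard cutoffs, as in the reference analysis). "Exceeds the
threshold" is interpreted as strictly more negative; boundary equality is
spared (configurable via `strict`). Sparing is the volume-weighted
complement of the injured fraction per tissue over the epicenter slab.
Lateral extension is flagged when an injured white element lies within
one voxel of the ipsilateral-most white matter. Anatomical regions
partition gray+white by the cord midline and the horizontal through the
canal center, with a ±0.6-mm midline band split out (gray: central
canal/commissure zone; white: median septum/fissure zone) so that
near-midline damage — present in essentially every subject — is not
misattributed to contralateral horns or columns. The published analysis
names horns and columns without defining boundaries; this quadrant
partition is the package's own convention.

## 6. Population statistics

Pearson correlations only, pairwise deletion, no multiple-testing
correction (raw coefficients are reported, matching how this correlation
structure is conventionally presented; a documented limitation).
Zero-variance columns yield missing (not zero) correlations. Peak forces
are binned in half-open 5-N bins anchored at 0; normality is reported
descriptively via Shapiro–Wilk. Sample SDs use n−1 (the n-denominator
variant is also reported, since the convention behind the published
values is unstated). Outliers are subjects beyond mean ± 2 SD. The
lateral-extension group comparison is Welch's independent-samples t-test:
the groups are independent subject sets of unequal size, so a paired test
is not applicable; the output carries a note to that effect rather than
silently relabeling.

## 7. Determinism and problem sizes

One global seed drives the population sampler and all surrogate noise;
per-subject streams are keyed by subject id. Re-running a config is
bit-identical. The default analysis (40 subjects, 0.1-mm voxels, ~7000
cord elements per subject) runs in well under a minute on one core; tests
use the same sizes except where coarser voxels (0.15–0.2 mm) suffice for
the property under test.

## 8. Known limitations

* The surrogate is statistical; individual strain fields are stylized
  kernels, not mechanics. Only population-level structure is meaningful.
* 2.5-D epicenter slab: no rostral-caudal variation, no vertebrae, no
  CSF flow, no contact surfaces.
* Concentric cord/canal placement; the preload-phase ventral entrapment
  is not modeled geometrically (its main published consequence — the
  weak influence of anterior-posterior morphology — is instead reflected
  in the surrogate's effect structure).
* Independent diameter sampling (no published covariance).
* Gray-matter template shape, laminectomy window and midline-band width
  are package conventions, configurable but unvalidated.
* White-matter D and γ parameters are stored but uninterpreted.
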