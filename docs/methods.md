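# Methods

This note documents the models and numerical choices behind `otoquant`:
what the synthetic embryo generator simulates, how its parameters were
set, how the quantification operations are defined, and what the
synthetic validation does and does not demonstrate about real data.

## Coordinate and time conventions

Simulation time is minutes from the scenario's `t_start_hpf` (default
12 hpf); hours post fertilisation (hpf) appear only in configuration
fields.  Coordinates are right-handed micrometres centred on the
vesicle: x increases anterior→posterior, y medial→lateral, z
dorsal→ventral.  Voxel indices are 0-based; voxel and region boxes are
half-open (lower-inclusive), so a nucleus exactly on an octant midplane
belongs to the upper (posterior/lateral/ventral) half — a deterministic
tie-break for a measure-zero case.

## The vesicle model

The otic epithelium is abstracted as a static ellipsoidal shell
(semi-axes 42 x 36 x 32 µm) around a small lumen (8% of the ellipsoid
volume), giving a tissue volume of ≈186,000 µm³ and per-octant volumes
of ≈23,300 µm³.  The relative apicobasal *depth* of a point is 0 at the
lumen (apical) surface and 1 at the outer (basal) surface.  Morphogenesis
(placode folding, lumen expansion) is not modelled mechanically; the
anterior fold time enters only as the deadline after which ingression is
impossible.  With the printed nuclear densities (2.16 and 1.60
nuclei/10³ µm³) these volumes imply ≈50 neurogenic-octant cells out of
≈311 total at 19 hpf, which is self-consistent with the published counts.

Nuclei are placed by octant: per-octant initial counts are Poisson
(means 35.5 neurogenic / 35.8 other, calibrated so that counts at
19 hpf, after divisions and ingression, recover the published totals),
directions uniform within the octant, depths uniform in a band
(0.50–0.70 for the neurogenic octant — its progenitors sit basally,
which is also what "positioned to delaminate" keys on — 0.25–0.75
elsewhere).

## Cell behaviours

**Pioneers and ingression.**  Eight pioneer cells start anterior of the
placode, inside the standard photoconversion ROI, expressing reporter
since 11 hpf with per-cell rates drawn from 0.22–0.31 a.u./min.  The
pool behaves as a stream with a fated subpopulation: `ceil(8 x 0.59) = 5`
cells carry ingression competence and each succeeds with probability
0.59 x 8 / 5, making the expected ingression count exactly 4.72 while
keeping embryo-to-embryo dispersion near the stream's structure.  (A
per-cell coin flip would be amplified by the instruction coupling into
vesicle-level variance far beyond what the cohort statistics show; the
cost is that the generator under-represents the inter-embryo spread of
ingression counts seen in real cohorts.)  Ingression times are uniform
on 13.75–15.5 hpf and must precede the anterior fold (16 hpf in the
wild type); ingressed pioneers take a neurogenic-octant position and
delaminate 30–90 min later.  Non-ingressing pool members stay anterior,
along with ~50 passive anterior-field nuclei that make the standard
10⁵ µm³ ROI contain ≈58 nuclei at 13 hpf.

**Local specification.**  Resident neurogenic-octant cells acquire
reporter expression by an inhomogeneous-hazard process (the onset-time
distribution is a modelling choice — nothing in the data constrains its
shape — flagged here and in the config): hazard
`λ(t) = λ0 · g_h^(P(t) − P_ref)` from 13.5 hpf, where `P(t)` is the
number of ingressed pioneers present, `g_h` the instruction gain and
`P_ref = 4.7` the typical wild-type complement.  Expressing cells ramp
linearly at per-cell rates drawn uniformly from 0.15–0.54 a.u./min
(the observed wild-type range), additionally scaled by
`g_a^(P(t0) − P_ref)`.  Writing the coupling relative to `P_ref` keeps
the configured ranges equal to the wild-type *observed* ones; with both
gains at 1 the modulation is identically 1 and ablation has no
non-autonomous effect (a property test asserts this).  Hazard and
amplitude carry separate gains because the published effect sizes are
very different: ablation reduces the number of positive cells by ~58%
but their mean level by only ~27%; a single knob cannot produce both.

**Delamination.**  Each expressing resident draws a delamination level
uniformly from 45.5–52.5 a.u. (the printed interval, treated as exact
bounds of observed values) and delaminates when its ramp crosses it.
The event is logged at the continuous crossing time and the track gets
an extra sample inserted exactly there, so the reporter level at
delamination equals the drawn level exactly and track-based detection
reproduces the event log bit-for-bit on noiseless data.  Delaminated
cells drift basally (0.004 relative-depth/min, capped at 1.10) but stay
within the vesicle cuboid and keep expressing: specification summaries
at 18.5–20 hpf therefore include recently delaminated neuroblasts, which
is what makes F̄_cell exceed the delamination window, as in the data.

**Divisions.**  Each resident divides at most once, with probability
0.24 (neurogenic octant) or 0.0475 (other octants) at a uniform time in
14–18.5 hpf, giving ≈41% of all mitoses in the neurogenic octant.
Anaphase happens at an apical surface — the central lumen or, for 40% of
neurogenic divisions, the peripheral apical scaffold — with the spindle
axis perpendicular to the local apical normal, so cleavage planes are
perpendicular to the apical surface.  Daughters inherit the mother's
reporter *level* (F_cell reads mean cytosolic intensity, i.e.
concentration, which cytokinesis preserves), her ramp rate, and her
octant; a daughter born already above its own delamination level
delaminates rapidly (10 min).  Daughters of mothers that divide before
onset draw their own onset from the remaining hazard.  Divisions in the
neurogenic octant are symmetric by construction: both daughters either
delaminate within the window or remain basally positioned.

**Perturbations.**  *Ablation*: 3 pulses at 12.5 hpf, each destroying
2–3 of the pioneers nearest the placode (tracks terminated but kept in
the log) — the published pooled cohort mixed 1–3-pulse embryos, and the
size of the specification deficit requires essentially the whole stream
to be removed.  *FGF blockade*: anterior folding advanced to the
posterior fold time (13 hpf), before the ingression window opens, hence
zero ingressions; the specification deficit then follows entirely from
the lost instruction.  *Proliferation block (aphidicolin/hydroxyurea)*:
division probabilities zero; because the drug acts from hours before the
simulated window, the resident pool entering it is scaled to 0.6 and the
pioneer pool (itself partly a product of pre-window proliferation) to 7.

## Calibration

Quantities printed in the source observations enter verbatim: 311 cells
at 19 hpf, the 0.15–0.54 a.u./min ramp range, the 45.5–52.5 a.u.
delamination window, 2–3 cells per ablation pulse at 12.5 hpf, the
10⁵ µm³ ROI 25 µm anterior of the placode, ≈58 labelled nuclei, the
4.7-cell mean ingression count.  The free parameters — onset hazard
λ0 = 0.0026 min⁻¹, instruction gains g_h = 1.24 and g_a = 1.10 per
pioneer, the pioneer ramp range, and the proliferation-block pool
scales — were fitted once with `scripts/calibrate_coupling.py` against
the published cohort statistics (the four ablated/contralateral
specification metrics and the proliferation-block fold changes) and
frozen as scenario defaults.  At these values 100-pair cohorts give
contralateral N⁺ ≈ 23.4 / global ≈ 1470 / F̄ ≈ 63 / N⁺ʰⁱ ≈ 5.3 and
ablated ≈ 9.8 / 425 / 43.4 / 0.5, with proliferation-block folds
≈ 50% (N⁺) and ≈ 109% (F̄).

## Quantification definitions

* `F_cell` is the mean of three cytosolic readings at fixed angular
  offsets (0°, 120°, 240°) midway between nucleus and membrane on three
  distinct z slices, each background-subtracted; negative subtracted
  readings are clamped at 0 and flagged.
* Positivity and the high-expresser rule use strict inequalities
  (`F > threshold`, `F > 1.5 F̄_control`): deterministic at boundaries,
  which are measure-zero on real intensities.  The default threshold on
  noiseless synthetic data is 10 a.u. (recorded in every output); for
  rendered/noisy data a helper defines it as 5 background SDs.
* Delamination detection uses the ground-truth compartment transition
  when tracks carry one, otherwise ≥3 consecutive frames with the cell
  body deeper than 70% of the local epithelial thickness (robust to
  single-frame jitter; both the fraction and the run length are
  arguments).  Onset is the first reporter-positive sample.
* The level-versus-timer statistic normalises each cell's reporter level
  at delamination and elapsed time since onset by the group means, then
  compares dispersions (CV); the p value comes from a seeded per-cell
  label-swap permutation test (default 10,000 permutations).  It is
  invariant to rescaling all intensities by a common factor.
* Cleavage-plane orientation: the angle between the cleavage plane
  (normal = spindle axis) and the local apical surface (normal = radial
  direction), mapped to [0°, 90°]; ≥75° counts as perpendicular — the
  observations report a binary judgement without a tolerance, so the
  tolerance is explicit and configurable.
* Division fate: symmetric iff both daughters delaminate within the
  window or sit in the basal half at its end ("positioned to
  delaminate").
* t statistics are computed from their textbook formulas (pooled-variance
  Student t for unpaired comparisons, matching common practice in the
  field's statistics software); only the t distribution function comes
  from scipy.  Two-sided p values; no multiple-testing correction by
  default (a Holm option exists).  Where a report could be paired or
  unpaired by design, both are reported.

## Rendering

Cells are drawn as spherical membrane shells (radius 4.5 µm) with
nuclear blobs (2.5 µm); the reporter channel holds background + F_true
in the cytosolic annulus (identity calibration), stored as float32 so
TIFF round-trips are lossless and the noiseless oracle `F_cell ==
F_true` holds exactly.  The Poisson–Gaussian noise model
(`Poisson(gain·I)/gain + N(0, σ_read)`) is unbiased, so measured F_cell
equals the ground truth in expectation — verified by a Monte-Carlo test.
Optics are deliberately naive (no PSF); the renderer exists to validate
the measurement pipeline, not to benchmark segmentation.

## Problem sizes and limitations

Default cohorts mirror the study design: 11 embryos for morphometry, 11
cells for expression dynamics, 27 pooled divisions, 6 ablation pairs, 6
photoconversion embryos, 12 + 14 proliferation-block runs; one embryo is
~350 tracks at 2-min resolution, so a full cohort simulates in seconds.
With ~20 division events per embryo, cohort-level fractions such as the
neurogenic mitosis share carry a binomial standard error of ~3 points,
and 6-embryo means of vesicle summaries carry standard errors comparable
to the published SEMs — individual synthetic cohorts scatter around the
published values exactly as real cohorts would.

Passing the synthetic validation shows the *quantification* is correct
and that the generative model with published parameters reproduces the
published statistics; it does not validate segmentation or tracking on
real microscopy (tracks are inputs here), photobleaching handling,
mechanical morphogenesis, or the true inter-embryo variance structure
(the fated-pool ingression model deliberately under-disperses ingression
counts, and onset times use an assumed uniform-hazard form).
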