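# Methods

`prioplan` is a desk-scale implementation of wishlist-driven prioritized
(lexicographic) multicriteria planning for advanced-stage lung-cancer
radiotherapy. This note documents the model, its assumptions, the numerical
choices, and what the synthetic study conditions can and cannot show.

## The planning model

A treatment plan is a nonnegative beamlet fluence vector `x`. A sparse
dose-influence matrix `D` maps fluence to voxel dose, `d = D x` (Gy). Planning
is governed by a *wishlist*: hard constraints that every plan must satisfy and
objectives optimized strictly in priority order. The packaged NSCLC wishlist
has six hard constraints (patient/CTV/cord-spared-PTV maxima at 107% of the
prescription, cord+3 mm max 47 Gy, plexus max 63 Gy, mean lung-minus-GTV
19 Gy) and thirteen prioritized objectives: LTCP coverage of CTV (goal 1) and
PTV (goal 0.5) at sensitivity α = 0.8 Gy⁻¹, a 60%-of-prescription cap beyond
4 cm from the PTV, mean-lung reduction (15 then 5 Gy), two dose-falloff shells
(90% / 80% of prescription at 1 / 3 cm), esophagus gEUD (44 Gy, k = 8) and
mean, heart mean, a 42 Gy cord level, unspecified-tissue max, and plexus mean.

Cost functions:

- `LTCP(d) = mean_i exp(-α (d_i − D_p))` — a convex surrogate that penalizes
  target underdosage exponentially; 1 at a uniform prescription dose.
- `gEUD_k(d) = (mean_i d_i^k)^(1/k)` — the power mean; `k = 1` is the mean,
  large `k` approaches the maximum.

When the 5 mm-expanded spinal cord touches or overlaps the PTV, the PTV
coverage objective is applied to `PTV − (cord + 5 mm)` instead, deliberately
locating the protocol-accepted underdosage next to the cord.

## The two-phase lexicographic procedure

Phase 1 walks objectives by priority. For each objective the solver first
tests whether the *goal* is achievable under the hard constraints and all
previously fixed bounds; if so, the bound is fixed at the goal itself — not at
the (possibly far better) unconstrained optimum — so that lower priorities can
spend the slack. If the goal is unachievable, the objective is minimized and
the achieved value is fixed with a bit of slack (multiplicative 3%, additive
floor 10⁻³) as a constraint for all later stages. Phase 2 revisits every
objective in the same order and re-minimizes it to its fullest extent under
all other bounds, tightening its own bound to the new achieved value. The
number of phase-2 sweeps is configurable (default 1). A final pass selects the
minimum-total-fluence solution within all bounds; because that pass is a
linear program solved by a deterministic simplex, it doubles as the tie-break
among equally optimal fluences. (A least-squares minimum-norm tie-break would
need a quadratic program; the total-fluence LP achieves the same determinism
within the LP-only solver and is the package's choice.)

### Stage solves

Every stage is a convex program. It is solved by sequential linearization
over sparse HiGHS linear programs:

- max-dose terms are per-voxel linear rows (epigraph form as objectives);
  mean terms are linear;
- LTCP and gEUD are *separable* sums of scalar convex functions of voxel
  dose. Each gets one auxiliary variable per voxel supported by tangent
  lines, refined adaptively at the realized per-voxel doses. Tangents
  underestimate a convex function, so the LP is always a relaxation: an
  infeasible LP certifies an infeasible stage, and iteration stops when the
  true constraint violation and the objective gap fall below `tol_rel`
  (10⁻⁴ relative by default; 10⁻³ in the fast profile used for cohort runs).
- Each bound implies a per-voxel dose floor (LTCP) or cap (gEUD) which is
  added as explicit rows; this both tightens the relaxation and keeps the
  exponential/power coefficients in the LP moderate.
- LTCP bounds are imposed in the log domain (a logsumexp of affine terms,
  convex and overflow-free); reported values are always on the natural scale.

Hard max-dose rows that no admissible fluence can activate (given the
per-beamlet bounds implied by the constraint set) are dropped before each
stage, which roughly halves the LP without changing its solution.

Infeasible hard constraints are reported, never auto-relaxed: clinically the
response is a lower prescription, which is what the escalation ladder
implements.

## Dose engine

A deliberately simple pencil-beam-like engine: parallel (source-at-infinity)
beams in the axial plane, beamlets on a grid covering the PTV projection plus
one beamlet margin per angle. A beamlet deposits
`exp(-μ · radiological_depth) · exp(-lateral² / 2σ²)` Gy per unit fluence at
each patient voxel, with the radiological depth accumulated by ray marching
through a density map (water-equivalent patient, scalar reduced density 0.26
in lung, solid tumor). Defaults: μ = 0.005 mm⁻¹, σ = 3 mm, beamlet 6 mm,
23 equi-angular beams (more beams cost computation without measurable plan
quality gain), influence entries below 10⁻⁴ of a beamlet's maximum pruned.
There is no scatter modeling, beam divergence, or Monte Carlo transport;
fidelity beyond a smooth attenuated pencil is out of scope, and the engine
parameters are package defaults, not claims about any clinical system.

## Synthetic phantoms and study conditions

Phantoms are schematic axial thorax slices: elliptical patient contour
(220 × 170 mm), two lung ellipses, heart, esophagus, spinal cord and brachial
plexus, with a spherical GTV expanded by the clinical margins (GTV + 5 mm →
CTV, CTV + 10 mm laterally/ventro-dorsally and 10–12 mm cranio-caudally →
PTV; the grid is planar by default, so the cranio-caudal margin matters only
in 3-D mode). The default grid is 40 × 34 voxels at 6 mm. Margin expansion is
exact scaled-Euclidean expansion of voxel centers, so a brute-force distance
oracle reproduces it voxel for voxel.

Problem sizes were chosen once as the package's desk-scale conditions: the
default phantom with 15–23 beams solves in tens of seconds; cohort runs use
15 beams for the wishlist arm and 7 beams for the comparator.

A planar slice under-dilutes lung dose relative to real 3-D anatomy (every
lung voxel lies in the beam plane), so organ sizes were set so that the
default chest-wall-adjacent tumor (9 mm GTV) is plannable at the intended
66 Gy under all binding protocol rules. Two constructed geometries anchor the
escalation paths:

- the default phantom, acceptable at 66 Gy — used to demonstrate upward
  escalation from 60 Gy;
- a mediastinal tumor whose PTV overlaps the expanded cord by about one
  voxel. The cord maximum (47/46.3 Gy) caps that voxel, so the 99%-coverage
  rule (`V90 ≥ 99%`) fails whenever `0.9 · D_p` exceeds the cap — at 66 and
  55 Gy — but passes at 45 Gy (40.5 Gy requirement vs the 42 Gy cord
  objective level). This is the clinically canonical reason prescriptions
  are reduced, and the cohort generator verifies the overlap explicitly when
  constructing its "difficult" members (16/41 of a full-size cohort).

What passing tests on these phantoms do *not* show: absolute dosimetric
realism (planar geometry inflates V20-like bath metrics and admits sharper
in-plane gradients than 3-D delivery), population realism of the cohort, or
anything about deliverability (arc sequencing, apertures, monitor units are
out of scope).

## Plan evaluation and acceptability

All reported V/D indices use exact order statistics on unbinned dose vectors
(`D_x%` = the dose at rank `ceil(x·N/100)` of the descending sort); binned
cumulative DVHs exist for plotting only. Conformity `R50` counts patient
voxels at ≥ 50% of prescription over PTV voxels; homogeneity
`HI = (D2% − D98%) / D50%`. Binding acceptability rules: PTV V95 ≥ 95%,
CTV V95 ≥ 99%, PTV V90 ≥ 99%, mean lung dose < 20 Gy, lung V20 < 35%, cord
and plexus maxima within the fractionation tolerance (46.3/56.6 Gy at
3 Gy/fraction, 49.3/60 at 2.75, 50/66 at 2). Lung V5 < 60% and esophagus
V45 < 25% are advisory: they flag a plan but never fail it. Comparisons
happen at the 0.1 reporting precision, with strict inequality for the
protocol's "below" thresholds.

The prescription ladder is 30, 39, 45 Gy (3 Gy/fraction), 55 Gy (2.75),
60 Gy (2), 60.5 Gy (2.75), 66 Gy (2); upward steps are 45→55, 55→60.5,
60/60.5→66, and the 66→60-or-60.5 downward fork follows the patient's
fractionation. Escalation replans at each step and keeps the highest
prescription whose plan passes every binding rule; intermediate dose levels
are never returned.

## Cohort comparison

The comparator arm of a clinical validation (human-made plans) cannot be
reproduced, so the cohort study pits the full wishlist arm against a
documented degraded baseline: 7 fixed equi-angular beams and a single
coverage-only solve (target LTCP terms under the hard constraints, no
organ-sparing objectives, no priority structure) — a caricature of a
minimal-effort plan. Consequently only the *direction* of cohort differences
is meaningful, never their magnitude. Differences are oriented so that
positive favors the wishlist arm (`B − A` for coverage metrics, `A − B` for
organ doses, R50 and HI), and the summary reports both the patient-wise mean
of differences and the difference of arm means, since the two disagree after
rounding in general.

The Wilcoxon signed-rank test drops zero differences (a `pratt` variant is
available behind a flag), midranks ties, uses the exact null distribution for
up to 25 nonzero pairs (computed by subset-sum convolution over doubled
midranks, which is exactly the 2ⁿ sign-assignment enumeration without listing
it), and the normal approximation with continuity and tie corrections above
that. Five concordant pairs give the familiar two-tailed p = 0.0625 floor.

## Known limitations

- Planar (single-slice) geometry by default; the code paths are 3-D capable
  but all packaged study conditions are 2-D.
- The pencil-beam engine has no scatter or divergence; absolute dose scale is
  set by the optimizer, not by calibration.
- The degraded comparator arm is a construction, not an emulation of human
  planners; cohort-level numbers describe this package's synthetic conditions
  only.
- `check_acceptability` measures coverage on the full PTV even when the
  optimizer deliberately spares the cord-overlap region, so cord-overlapping
  targets can be unacceptable at every prescription level whose coverage
  requirement exceeds the cord cap; this mirrors the strict protocol reading
  of the V-based rules.
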