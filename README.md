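# prioplan

Wishlist-driven prioritized multicriteria optimization of radiotherapy
fluence maps, at desk scale.

Automated treatment planning for advanced-stage lung cancer replaces the
manual trial-and-error tuning of an optimizer with a *wishlist*: a short list
of hard constraints that a plan must never violate, and objectives ranked by
clinical priority and optimized one at a time. Once an objective reaches its
goal — or cannot improve further — its achieved value is fixed (with a bit of
slack) as a constraint and the optimizer moves to the next priority; a final
phase then pushes every objective to its fullest extent. The result is a
Pareto-consistent plan with clinically intended trade-offs, produced without
a human in the loop.

`prioplan` implements that method end to end on synthetic data, for people
who want to study, teach or extend prioritized planning without a clinical
treatment-planning system: seeded voxel thorax phantoms, a pencil-beam-like
beamlet dose engine, the NSCLC wishlist (6 hard constraints, 13 prioritized
objectives), a two-phase lexicographic solver built on sparse linear
programming, DVH-based plan-quality metrics and protocol acceptability, the
clinical dose-escalation ladder, and paired two-arm cohort comparisons with
exact Wilcoxon signed-rank statistics.

## The model in brief

A plan is a nonnegative beamlet fluence vector `x`; dose is `d = D x` with a
sparse influence matrix `D`. Target coverage is driven by the logarithmic
tumor-control surrogate

    LTCP(d) = (1/N) Σᵢ exp(−α (dᵢ − D_p)),   α = 0.8 Gy⁻¹,

which equals 1 at a uniform prescription dose `D_p` and explodes on
underdosage, and organ sparing by mean dose, maximum dose and the
generalized equivalent uniform dose

    gEUD_k(d) = ((1/N) Σᵢ dᵢᵏ)^(1/k),

the power mean (k = 1 is the mean; large k approaches the max). Objectives
are minimized lexicographically: priority 1 is CTV coverage (LTCP goal 1),
priority 2 PTV coverage (goal 0.5, applied to the cord-spared PTV when the
spinal cord abuts the target), then conformity, lung, falloff shells,
esophagus, heart, cord, unspecified tissue and plexus. Every stage is a
convex program solved by sequential linearization over HiGHS LPs. See
`docs/methods.md` for the full model, numerical choices and limitations.

## Worked example

```python
import prioplan as pp

ss  = pp.build_phantom(pp.PhantomConfig())          # synthetic thorax
bs  = pp.make_beamset(ss, n_beams=15)               # equi-angular beams
dij = pp.compute_dose_influence(ss, bs)             # sparse Gy-per-fluence
rx  = pp.ladder_prescription(66.0)                  # 66 Gy in 2 Gy fractions
wl  = pp.nsclc_wishlist()                           # 6 constraints, 13 objectives

plan, report = pp.prioritized_optimize(dij, wl, ss, rx)
for s in report.phase1():
    print(f"p{s.priority:2d} {s.volume:20s} {s.cost:5s} "
          f"achieved={s.achieved:8.3f} goal={s.goal:6.2f} clamped={s.clamped_at_goal}")

metrics = pp.compute_metric_report(plan.dose, ss, rx)
print(f"PTV V95 {metrics.ptv_v95_pct:.1f}%  MLD {metrics.mean_lung_dose_gy:.1f} Gy "
      f"V20 {metrics.lungs_v20_pct:.1f}%  R50 {metrics.r50:.2f}  HI {metrics.hi:.3f}")
print("acceptable:", pp.check_acceptability(metrics, rx).acceptable)
```

prints (default phantom, 15 beams):

```
p 1 ctv                  ltcp  achieved=   1.000 goal=  1.00 clamped=True
p 2 ptv                  ltcp  achieved=   0.500 goal=  0.50 clamped=True
p 3 patient_minus_ptv4   max   achieved=  28.644 goal= 39.60 clamped=True
p 4 lungs_minus_gtv      mean  achieved=  13.702 goal= 15.00 clamped=True
p 5 shell_ptv_1cm        max   achieved=  59.400 goal= 59.40 clamped=True
p 6 shell_ptv_3cm        max   achieved=  52.800 goal= 52.80 clamped=True
p 7 esophagus            eud   achieved=  12.470 goal= 44.00 clamped=True
p 8 esophagus            mean  achieved=  11.167 goal= 15.00 clamped=True
p 9 lungs_minus_gtv      mean  achieved=  12.595 goal=  5.00 clamped=False
p10 heart                mean  achieved=   4.752 goal= 15.00 clamped=True
p11 cord_plus_3mm        max   achieved=   9.934 goal= 42.00 clamped=True
p12 unspecified_tissue   max   achieved=  39.991 goal= 40.00 clamped=True
p13 plexus               mean  achieved=   3.483 goal= 20.00 clamped=True
PTV V95 100.0%  MLD 13.0 Gy V20 26.0%  R50 3.04  HI 0.051
acceptable: True
```

Twelve of the thirteen stages stop exactly at their goals (only the 5 Gy
aspirational lung-mean goal of priority 9 is out of reach, fixed at
12.6 Gy), and the plan passes every binding protocol rule at the intended
66 Gy.

The same pipeline is scriptable from the shell:

```
prioplan phantom --out ph.h5
prioplan solve --phantom ph.h5 --dose 66 --out plan.h5
prioplan evaluate --plan plan.h5 --phantom ph.h5 --out metrics.json
prioplan escalate --phantom ph.h5 --start-dose 60 --out trail.json
prioplan cohort --n-patients 10 --out report/
prioplan wishlist validate my_wishlist.yaml
```

## Layout

| path | contents |
| --- | --- |
| `src/prioplan/` | library: grid/structures/phantom, beams/influence, costs, wishlist, optimizer, evaluation, cohort, HDF5 I/O, CLI |
| `src/prioplan/data/` | packaged NSCLC wishlist (YAML) and its JSON schema |
| `tests/` | pytest suite with brute-force oracles (`tests/oracles.py`) |
| `docs/methods.md` | model, solver and study-condition documentation |
| `scripts/acceptance.py` | end-to-end reproduction script |
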