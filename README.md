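# fnti — femoral neck thickness index morphometry

Radiographic widening of the femoral neck is an early sign of bone
modeling in canine hip dysplasia (CHD): osteophytes and exostoses
progressively thicken the neck until it merges with the head in severe
disease. On a ventrodorsal hip-extended view this can be quantified by the
**femoral neck thickness index**

    FNTi = FNT / FHd

where FNT is the minimal neck thickness (shortest chord joining the two
closest points between the proximal and distal neck margins) and FHd is
the diameter of a circle fitted to the femoral head margin. The ratio is
unit-free, so it needs no pixel calibration and compares across breeds and
body sizes. FNTi rises with disease severity across the FCI
(Fédération Cynologique Internationale) grades A (normal) to E (severe).

This package is for veterinary imaging researchers who want to reproduce
or extend that analysis chain. It provides:

* **Landmark geometry** (`fnti.geometry`): Kåsa least-squares circle fit,
  exact polyline-to-polyline minimal distance with the realizing chord,
  the Norberg angle, and `measure_hip` composing them; all outputs are
  invariant under rigid motion and uniform scaling.
* **Rule-assisted FCI grading** (`fnti.grading`): the published A–E
  criteria (Norberg-angle thresholds plus congruency / osteoarthritis /
  subluxation flags), worst-criterion-wins, fully configurable.
* **Agreement statistics** (`fnti.agreement`): paired t, Bland–Altman
  limits of agreement d̄ ± 1.96·SD, Cohen's d (two variants), and
  ICC(2,1)/(3,1) with F-based confidence intervals and the conventional
  reliability bands.
* **Grade-group comparison** (`fnti.compare`): Shapiro–Wilk and Levene
  screening, Welch's heteroscedastic ANOVA, Games–Howell post hoc tests
  (studentized-range), and a compact letter display (groups share a
  letter iff not significantly different).
* **Synthetic data** (`fnti.synthetic`): seeded generators for (a) FNTi
  cohorts with the study's per-grade moments, sizes and examiner error
  structure, and (b) landmark scenes with exactly known ground-truth FHd,
  FNT and Norberg angle.
* **A CLI** (`fnti`): `measure`, `agreement`, `compare`, `simulate`,
  `report` subcommands orchestrating the above on annotation JSON/CSV and
  measurement CSV files.

## Worked example

A synthetic scene built with the geometry of the study's illustrated case
— a 31.5 mm head circle and a 28.7 mm neck chord:

```python
from fnti import SceneConfig, generate_scene, measure_hip

ann, truth = generate_scene(SceneConfig(fhd=31.5, fnt=28.7, na=105.0, jitter_sd=0.0))
m = measure_hip(ann, examiner="E1", session="S1")
print(f"FHd = {m.fhd:.1f}  FNT = {m.fnt:.1f}  FNTi = {m.fnti:.2f}  NA = {m.na:.1f}")
```

```
FHd = 31.5  FNT = 28.7  FNTi = 0.91  NA = 105.0
```

An index of 0.91 means the neck's minimal width is 91% of the head
diameter — a heavily modeled neck (normal hips centre around 0.81).

The full pipeline on a synthetic 106-hip cohort (three measurement series:
examiner 1 twice, examiner 2 once):

```python
from fnti import PipelineConfig, run_full

rep = run_full(PipelineConfig(seed=1))
for r in rep.agreement:
    print(f"{r.label}: d = {r.mean_diff:+.3f} +/- {r.sd_diff:.3f}, "
          f"LA ({r.loa_lower:.3f}, {r.loa_upper:.3f}), ICC = {r.icc:.2f} "
          f"[{r.icc_ci[0]:.2f}, {r.icc_ci[1]:.2f}] ({r.icc_band})")
print(rep.comparison.descriptives[["n", "mean", "sd", "letters"]].round(3))
w = rep.comparison.welch
print(f"Welch F({w.df1:.0f}, {w.df2:.1f}) = {w.f_stat:.1f}, p = {w.p_value:.2e}")
```

```
E1:S1-E1:S2: d = +0.000 +/- 0.020, LA (-0.038, 0.039), ICC = 0.93 [0.91, 0.96] (excellent)
E1:S1-E2:S1: d = -0.006 +/- 0.019, LA (-0.044, 0.032), ICC = 0.93 [0.90, 0.96] (good)
        n   mean     sd letters
group
A      19  0.802  0.024       a
B      23  0.834  0.038       b
C      24  0.859  0.020      bc
D      24  0.913  0.033       d
E      16  0.903  0.064      cd
Welch F(4, 46.0) = 43.9, p = 3.93e-15
```

The agreement rows mirror a repeatability/reproducibility table: bias near
zero, narrow limits of agreement, intraclass correlation ≈ 0.93. The
comparison table shows mean FNTi rising with grade; groups sharing a
superscript letter are not significantly different under Games–Howell at
α = 0.05, and the Welch omnibus test rejects equality of grade means
decisively. (Letter patterns vary between seeds at n = 106 — adjacent
grades overlap substantially.)

The same run from the shell:

```sh
fnti report --out-dir out/ --seed 1
fnti simulate --seed 1 --out-dir sim/ --scenes 10
fnti measure --annotations sim/scenes.json --out sim/measured.csv
```

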