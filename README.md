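# tmsfocal

Coil-placement optimization for transcranial magnetic stimulation (TMS).

Given a multi-shell head model, a figure-8 coil and a cortical target
point **T** on the gray-matter surface, `tmsfocal` finds the 6-DOF coil
pose (three coordinates, pitch α / roll β / yaw φ) that focuses the
induced electric field around the target on an intracortical observation
surface, and quantifies how much better that pose is than the standard
sulcus-aligned projection placement used in motor mapping.

The intended users are researchers modelling TMS targeting accuracy —
the kind of question asked in neuronavigated motor-mapping studies:
*how tight can the stimulated "hot spot" be made, how robust is the
optimum to coil-holder inaccuracy, and does a tighter spot also separate
neighbouring targets better?*

## The model

**Cost function.** The focality metric is the average absolute deviation

AAD = mean‖**T** − **T**ᵢ‖  [mm],

over all observation nodes **T**ᵢ whose field magnitude ‖**E**‖ is at or
above a threshold fraction (70/80/90%) of the field's own maximum — an
effective radius of the suprathreshold focal spot.

**Forward solver.** Quasistatic surface-charge boundary-element method:
the induced charge density (stored as g = ρ/ε₀) on each conductivity
interface solves a collocation integral equation; the operator is
assembled densely and LU-factorized once per head, so each coil pose
costs a single right-hand-side solve. The coil is a magnetic-dipole
cloud (CCD convention); its primary field is the time derivative of the
dipole vector potential. The solver is validated against the closed-form
induced field inside a spherically symmetric conductor, which is
independent of the radial conductivity profile.

**Inverse search.** Sequential coordinate descent over (φ, α, β, x, y, z)
with fixed steps (2 mm, 0.1 rad) from the sulcus-aligned initial pose,
under a hard ≥10 mm coil–scalp clearance constraint; validated against
an exhaustive grid search. A solution is accepted only if its
defocalization factor

DF = mean₍ₙ₌₀…₁₂₎ AADₙ / AAD_final < 1.25,

where AADₙ are the costs at ±1.5 mm / ±0.1 rad single-variable pose
perturbations (the accuracy envelope of a robotized coil holder);
unstable solutions are reverted update by update. The headline number is
the corrected focality improvement
1 − (DF_final·AAD_final)/(DF_initial·AAD_initial), plus the somatotopy
metric ARD = 1 − mean(‖**E**_Tn‖/‖**E**_T‖) over neighbouring targets,
the target field loss, and the distance of the 99-percentile field peak
from the target.

Everything runs on synthetic phantoms generated by the package: nested
sphere heads (skin, skull, CSF, GM, WM) and a gyrus variant whose GM/WM
shells carry a smooth crown flanked by two Gaussian-profile sulcal
trenches, with analytic wall normals.

## Worked example

```python
from tmsfocal.pipeline import build_case, run_case

case = build_case(seed=7)            # gyrus phantom + coil + factorized BEM
report = run_case(case, 4)           # optimize the 5th crown target
print(f"AAD  {report.aad_initial:.2f} -> {report.aad_final:.2f} mm")
print(f"DF   {report.df_initial:.3f} -> {report.df_final:.3f}")
print(f"improvement {100 * report.improvement:.1f} %")
print(f"field loss {report.field_loss:.1f} %")
```

prints (seed 7, 80% threshold, mid-surface):

```
AAD  5.04 -> 4.57 mm
DF   1.046 -> 1.038
improvement 10.0 %
field loss 5.2 %
```

meaning: the sulcus-aligned start already produced a 5.0 mm-radius
suprathreshold spot; the descent tightened it to 4.6 mm, the solution is
stable (DF well below the 1.25 bound), the defocalization-corrected
focality improved by 10%, and the field at the target dropped ~5% (the
usual price of a tighter spot — the stimulator output would be rescaled
accordingly). On these idealized smooth phantoms the sulcus-aligned
projection is often already near-optimal, so per-target improvements
range from 0% to ~10% — consistent with its reputation as an excellent
initial guess.

The same pipeline is scriptable from the shell:

```bash
tmsfocal phantom --kind gyrus --seed 7 --out head.msh --targets-out targets.csv
tmsfocal coil --preset small --out coil.ccd
tmsfocal optimize --head head.msh --coil coil.ccd --targets targets.csv \
                  --target-index 1 --threshold 0.8 --out report.json
tmsfocal report --in report.json --format md
```

Head models are Gmsh MSH v2 ASCII files with one surface physical group
per shell; the physical name encodes `name:sigma_in:sigma_out` (S/m), so
a model round-trips with its conductivities. STL/PLY per-shell I/O and
CCD coil files are also supported.

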