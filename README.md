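# guidefit

In-silico analysis of the positioning error of 3D-printed patient-specific
surgical guides on the radius.

Patient-specific guides are printed molds whose inner surface is the
negative of a patch of the patient's bone; in corrective osteotomy of the
radius they steer drills and saw blades to the preoperatively planned
trajectories. When the surgeon seats the guide slightly off its planned
location, that error propagates directly into the surgical action. This
package reproduces, entirely in software, a laboratory methodology for
quantifying that positioning error and how it depends on the **fitting
location** (distal, mid-shaft, proximal — thirds of the bone length) and
the **guide design** (a *standard* volar mold versus an *extended* mold
with a lateral wall reaching the coronal mid-plane of the bone).

It is aimed at researchers in computer-assisted orthopedic surgery who want
to study guide designs, registration-based error measurement, or the
statistics of factorial placement experiments without printing and
CT-scanning physical models.

## What it computes

For each simulated guide placement the bone and the guide are registered
rigidly to a CT-like *pose image* by maximizing the Pearson correlation
between gray values sampled from the reference image along a
*double-contour* point set (paired points one voxel inside/outside the
object surface) and the gray values the pose image takes at the transformed
point positions (Nelder–Mead over three displacements and three rotations).
With M_R the bone registration and M_G a guide registration, the error
matrix

    E = M_R⁻¹ · M_G

takes the guide from planned to actual position. E is factored about the
guide centroid c as

    E = T(c + Δ) · R_z R_x R_y · T(−c)

giving translation errors (Δx, Δy, Δz) in mm and rotation errors
(Δφx, Δφy, Δφz) in degrees in an anatomic frame (z = principal inertia
axis of the bone, x toward the styloid process), summarized as
ΔT = ‖Δ‖, ΔR = ‖Δφ‖ and the mean target registration error

    mTRE = (1/n) Σᵢ ‖pᵢ − E·pᵢ‖

over the clipped guide contour points. Three generalized linear models
(normal, identity link) with Wald chi-square tests and stepwise reduction
relate mTRE, ΔT and ΔR to Location, Extension, their interaction, Operator
and Geometry.

Everything upstream is synthetic: radius-like phantom meshes (tapered
shaft, widened distal end, styloid-like protrusion, surface-anchor bumps),
an automated implementation of the projection/erosion/extrusion guide-CAD
workflow, 0.33 mm isotropic CT simulation with partial-volume rendering,
Gaussian blur and seeded noise, and a per-(location, design) stochastic
placement-error model standing in for the human operators.

## Worked example

```python
from guidefit.pipeline import RunConfig, run_experiment

result = run_experiment(RunConfig(seed=5, measurement="analytic",
                                  make_figures=False))
print(result.trials.groupby("location")["mTRE"].mean().round(3))
final = result.glm_traces["mTRE"][-1]
print(final.effect_tests.to_string(index=False))
```

prints (full 4 operators × 6 bones × 3 locations × 2 designs factorial,
144 trials):

```
location
distal       0.908
mid-shaft    2.026
proximal     1.686
Name: mTRE, dtype: float64
   effect      chi2  df            p
Extension 83.005552   1 8.182325e-20
 Location 68.629778   2 1.250930e-15
```

Distal guides fit most accurately and mid-shaft guides worst, extended
guides beat standard ones on mTRE, and the stepwise reduction retains
Location and Extension as the significant predictors — the qualitative
structure the physical experiment reported. Swap
`measurement="registration"` to push every trial through the full
rendering → segmentation → registration chain instead of the analytic
shortcut (slower; the measured columns then carry the method's ~0.01 mm
noise floor next to the ground-truth columns).

The same machinery is available from the shell:

```bash
guidefit run --config experiment.yaml --out results/
guidefit design --bone bone.stl --landmarks lm.json \
    --location distal --design extended --out guide.stl
guidefit analyze results/trials.csv --response mTRE
```

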