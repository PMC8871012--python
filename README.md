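# cobbmeter

Automated Cobb-angle measurement for adolescent idiopathic scoliosis, from
the corner landmarks of the vertebrae in an anterior–posterior spine
radiograph.

The Cobb angle (CA) is the clinical standard for grading a scoliotic curve:
the angle between the superior endplate of the most-tilted vertebra above
the curve apex and the inferior endplate of the most-tilted vertebra below
it. Manual measurement with protractor or PACS tools is slow and carries
inter-observer variation of several degrees. `cobbmeter` takes the output
of a vertebra landmark detector — up to 17 thoracic and lumbar vertebrae,
each located by four corner points and a detection score — and measures the
angle automatically:

1. **score filtering** — boxes with detection score ≤ 0.5 are dropped;
2. **outlier rejection** — a box whose x-center lies more than half a box
   width from the mean x-center of its vertical neighbours is anatomically
   implausible and is rejected (worst first, re-checking the rest);
3. **imputation** — up to two rejected boxes are rebuilt from a local cubic
   fit of the remaining centers, with size and endplate tilt interpolated
   from the nearest good neighbours;
4. **apex detection** — the apex is the vertebral center with maximum
   perpendicular distance from the chord joining the first and last
   centers; the convex side comes from the left/right inter-vertebral gap
   profile (corner-to-corner distances of adjacent boxes);
5. **end-vertebra selection and angle** — the superior end maximizes
   |top-endplate tilt| at or above the apex, the inferior end maximizes
   |bottom-endplate tilt| at or below it, and
   CA = |tilt_sup − tilt_inf|.

The package also ships the surrounding pipeline stages that need no trained
network: LBP + boosted-cascade torso cropping of raw radiographs, the
keypoint-heatmap support math (penalty-reduced focal loss, mean landmark
error, center/corner offset-map encoding and decoding), a synthetic spine
phantom generator with analytically known ground truth, and the
observer-agreement statistics over a packaged 70-image measurement set
(specialist reference observer, second observer, automated method).

## Worked example

Generate a synthetic spine with a known 40° curve and 1 px landmark jitter,
then measure it:

```
$ cobbmeter simulate --cobb 40 --noise 1 --seed 7 --out phantom.json
true Cobb 40.0 deg, apex index 8, wrote phantom.json
$ cobbmeter measure phantom.json
{
 ...
 "log": [
  "read 17 boxes from phantom.json",
  "angle 40.3 deg (apex 8, ends 0-16, right-convex)"
 ],
 "result": {
  "angle_deg": 40.3,
  "angle_deg_rounded": 40,
  "apex_index": 8,
  "direction": "right-convex",
  "inferior_index": 16,
  "superior_index": 0,
  "tilt_inf_deg": 20.1,
  "tilt_sup_deg": -20.1,
  "zero_curve": false
 },
 ...
}
```

The measured 40.3° differs from the analytic 40.0° only by the injected
corner noise; apex index 8 is the constructed apex vertebra, and the end
vertebrae (0 and 16) carry endplate tilts of ∓20.1°, whose difference is
the angle.

Agreement statistics over the packaged 70-image measurement set:

```
$ cobbmeter evaluate --fixture
--- stratum: all (n=70) ---
 auto vs obs1: median accuracy 93.6% (IQR 90.0 to 97.6), median diff +0.0 deg, within ±5 deg 69/70 (98.6%)
 obs2 vs obs1: median accuracy 85.4% (IQR 77.7 to 94.5), median diff -3.0 deg, within ±5 deg 38/70 (54.3%)
...
--- reliability (all images) ---
 obs1-obs2: ICC(2,1) 0.917  ICC(2,k) 0.957  PCC 0.948
 obs1-auto: ICC(2,1) 0.991  ICC(2,k) 0.995  PCC 0.991
 obs2-auto: ICC(2,1) 0.912  ICC(2,k) 0.954  PCC 0.939
```

Per-image accuracy is `100 − 100·|ref − test| / ref` with the specialist
observer (`obs1`) as reference; the automated method agrees with the
reference within the clinically accepted ±5° band on 69 of 70 images, where
the second human observer manages 38 of 70.

## Scope

Single major curves only; multiple or minor curves, sagittal-plane angles
and vertebral level naming (T1–L5) are out of scope, as is any trained
detection network — the pipeline consumes landmarks from files or from the
phantom generator. See `docs/methods.md` for the model details, parameter
defaults and limitations.
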