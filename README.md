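# avleak

3D analysis of blood–brain-barrier leakage, perfused vessel density and
vessel-type-resolved hemodynamics in intravital two-photon z-stacks, after
experimental (photothrombotic) stroke — exercised entirely on synthetic 3D
vascular phantoms with known ground truth.

## The problem

After occlusion of a cortical artery, fluorescent tracer (70 kDa
FITC/TRITC-dextran) that is normally confined to the vessel lumen leaks
into the brain parenchyma. Quantifying that breach in 3D requires
separating *intraluminal* from *extraluminal* signal in anisotropic
z-stacks (0.58 × 0.58 × 1 µm voxels), attributing each parenchymal tracer
accumulation to the vessel it escaped from, and resolving everything along
the arteriovenous (AV) axis: artery (A) → arteriole (Ae) → capillary (C) →
venule (Ve) → vein (V). This package reimplements that analysis chain as a
tested library plus CLI:

- **tracing** — Gaussian pre-smoothing (σ = 1 px), seed-guided minimum-cost
  centerline tracing on the 26-connected voxel graph (edge cost: physical
  step length × mean of `1 + κ / max(I, floor)` at the endpoints), and
  intensity-constrained lumen filling from the traced path (accept voxels ≥
  a fraction of the path-median intensity, geodesic reach ≤ 3 × local
  radius).
- **leakage** — voxel-exact signal splitting, the normalised leakage ratio
  `extraluminal / luminal` (dimensionless; invariant to tracer dose and
  detector gain), parenchyma vs subarachnoid compartments from per-plane
  ROI polygons, and perfused vessel density (centerline µm per µm³).
- **avaxis** — AV classification from printed diameter bands
  (A > 45 µm, Ae 10–45, C < 10, Ve 10–50, V > 50) with morphology/topology
  flags resolving the overlaps; FWHM diameter from in-plane perpendicular
  profiles (3 adjacent stations averaged); nearest-wall leak attribution
  with an "equally close" tie rule; spreading distance as the mean over
  1–2 µm stations of the maximal wall-to-continuous-signal distance; and
  post/pre diameter dynamics.
- **infarct** — the serial-section formula
  `V_%stroke = (Σ infarct area / Σ ipsilateral hemisphere area) × 100`.
- **phantom** — the forward model: vascular trees with class-consistent
  diameters, intraluminal tracer, half-Gaussian leak halos calibrated so
  the detectable extent equals the planned spreading distance, two-photon
  PSF, Poisson + Gaussian noise, occlusion, constriction and two-timepoint
  leak progression. Every downstream stage is validated against this
  ground truth.

## Worked example

Simulate a leaky, partially occluded scene, trace the vessels visible in
the tracer channel, fill their lumina and quantify leakage and perfusion:

```python
import numpy as np
from avleak import phantom, tracing, leakage

spec = phantom.PhantomSpec(seed=42, occluded_fraction=0.25)
truth = phantom.generate_tree(spec)
rng = np.random.default_rng(42)
truth.leak_sites.extend(phantom.plan_leaks(
    truth, 4, rng, class_shares={"Ae": 0.25, "C": 0.5, "Ve": 0.25}))
stack = phantom.render(truth, spec)

smoothed = tracing.smooth(stack, sigma_px=1.0)
masks, paths = [], []
for p in truth.paths:
    if not truth.perfused[p.vessel_id]:
        continue                      # occluded vessels are dark: not traceable
    seeds = np.array([p.point_at(2.0), p.point_at(p.length_um - 2.0)])
    traced = tracing.trace(smoothed, seeds, vessel_id=p.vessel_id)
    masks.append(tracing.fill_lumen(smoothed, traced, threshold_fraction=0.3))
    paths.append(traced)
lumen = tracing.merge_lumen_masks(masks, paths)

luminal, extraluminal = leakage.split_signal(stack, lumen)
result = leakage.leakage_ratio(luminal, extraluminal, lumen_mask=lumen)
flags = {p.vessel_id: leakage.is_perfused(luminal, p) for p in paths}
density = leakage.perfused_density(paths, flags, stack.volume_um3)
print(f"leakage ratio (extraluminal/luminal): {result.ratio_total:.3f}")
print(f"perfused vessel density: {density*1e3:.3f} x 10^-3 um/um^3")
print(f"ground-truth density:    {truth.perfused_length_um/stack.volume_um3*1e3:.3f} x 10^-3 um/um^3")
```

Output:

```
leakage ratio (extraluminal/luminal): 0.395
perfused vessel density: 0.321 x 10^-3 um/um^3
ground-truth density:    0.327 x 10^-3 um/um^3
```

The ratio is well above the noise floor because four leak halos were
planted; the recovered density matches the planted perfused centerline
length within 2%.

The same stages are available from the shell:

```sh
avleak simulate --out phantom/ --seed 42 --leaks 4
avleak trace --stack phantom/tracer.tif --seeds seeds.json --out paths.swc
avleak fill --stack phantom/tracer.tif --paths paths.swc --out lumen.tif
avleak leakage --stack phantom/tracer.tif --mask lumen.tif
avleak classify --diameter 47 --morphology elongated   # -> A
avleak run-all --config config.json
```

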