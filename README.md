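# xpct

Desk-scale propagation-based X-ray phase-contrast tomography (XPCT) of the
spinal cord: a synthetic neurovascular phantom with exhaustive ground
truth, a physical forward model of the scan, phase retrieval, tomographic
reconstruction, and the vessel/neuron quantification used to compare
healthy, EAE-affected and stem-cell-treated groups.

## Who this is for

Synchrotron XPCT studies of neurovascular damage — here, experimental
autoimmune encephalomyelitis (EAE), the mouse model of multiple sclerosis —
rest on a long computational chain: in-line free-space propagation turns
refraction into measurable contrast, single- or multi-distance phase
retrieval recovers the projected phase, filtered back projection builds a
volume proportional to electron density, and segmentation/skeleton analysis
turns volumes into branch and cell counts compared across treatment groups.
`xpct` implements that whole chain against a seeded synthetic spinal-cord
phantom whose vessel tree, capillaries and motor neurons are known exactly,
so every stage can be validated quantitatively without beamline data.

## The model in brief

With refractive index `n = 1 − δ + iβ`, a projection acquires phase
`φ = −(2π/λ)∫δ dl` and attenuation `B = (2π/λ)∫β dl`; the detector at
distance `D` records `|𝔉⁻¹[𝔉[e^{−B+iφ}]·e^{−iπλD(u²+v²)}]|²`. Retrieval
inverts this with the single-distance homogeneous-object filter
`T = −(1/μ)ln 𝔉⁻¹[𝔉[I]/(1+πλD(δ/β)q²)]` (micro, 30 keV, D = 2.3 m,
3.5 µm pixel) or a multi-distance contrast-transfer-function least squares
(nano holotomography: cone beam at 17 keV mapped by the Fresnel scaling
theorem to a 130 nm effective pixel, magnification ≈ 23×). 360°
half-acquisition scans are stitched into 180° sinograms and reconstructed
by Ram-Lak FBP. Quantification: histogram-thresholded vessel masks →
topological thinning → pruned skeleton graph → branch count; motor neurons
as bright, round, soma-sized blobs in the ventral-horn mask; groups
summarised as mean ± SD over n = 3 replicates.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from xpct import (PhantomSpec, DiseaseModel, MaterialTable, generate_phantom,
                  contrast_grids)
from xpct.pipeline import RunConfig, reconstruct_sample, quantify_sample

spec = PhantomSpec.micro_default(shape=(96, 96, 96), seed=7)
phantom = generate_phantom(spec, DiseaseModel.preset("eae", timepoint_dpo=1, seed=7))
print(f"ground truth: {phantom.branch_count} branches, {phantom.neuron_count} neurons")

cfg = RunConfig(grid=(96, 96, 96), n_angles=160, photon_count=0)
vol = reconstruct_sample(phantom, cfg)          # scan -> Paganin -> stitch -> FBP
print(quantify_sample(vol, phantom, cfg))
```

prints

```
ground truth: 7 branches, 16 neurons
{'branch_count': 5, 'neuron_count': 16, 'vessel_volume_fraction': 0.0198,
 'gt_branch_count': 7, 'gt_neuron_count': 16}
```

i.e. after simulating the full half-acquisition scan of an EAE-onset
phantom (vessel dropout 0.35, reduced vessel contrast, 20% neuron loss) and
reconstructing it, the quantification recovers all 16 remaining motor
neurons and 5 of the 7 remaining vessel branches — the attenuated vascular
contrast of the EAE condition costs two faint branches, exactly the
phenomenology the study design probes. The vessel volume fraction is the
segmented lumen volume inside the cord region of interest.

The group experiment of the study design (naive / EAE / EAE+MSC at 1 and
5 days post onset, n = 3 each) runs with

```sh
xpct run --out results/run1 --seed 1
```

and writes `quant_report.csv` with one row per sample and per group
(mean ± SD). Individual stages are exposed as `xpct phantom / acquire /
retrieve / recon / quantify`.

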