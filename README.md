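# hermiteflow

Steered-Hermite-transform optical flow for 2D images and 3D+t volumes.

Dense motion estimation in volumetric medical sequences — the motivating
case is cardiac CT, where the left ventricle contracts and dilates over
the acquisition cycle and clinicians need per-voxel displacement fields
to characterize wall motion.  `hermiteflow` implements a bio-inspired
differential estimator: volumes are decomposed with a discrete Hermite
transform (a Gaussian-derivative filter bank modeling receptive fields of
early vision), coefficients are steered to the local orientation of
maximum energy, and a multiresolution Horn–Schunck-family functional
augmented with the high-order coefficients is minimized:

    E = ∫ (L₀(x,t) − L₀(x+w+dw,t+1))²
        + γ Σₙ (lₙ(x,t) − lₙ(x+w+dw,t+1))²
        + α |∇(w+dw)|²  dx

with `L₀` the order-0 (Gaussian-average) coefficient, `lₙ` the high-order
coefficient channels, `α` the smoothness weight and `γ` the high-order
weight.  Large displacements are handled coarse-to-fine by warping the
second volume with the current flow at each pyramid level.  Validation
follows the interpolation-error protocol: warp the volume at time t
forward with the estimated flow and measure the RMS difference (IE) and
gradient-normalized RMS difference (NE) against the true t+1 volume.

The package also provides synthetic phantoms with analytic ground truth
(translations, rotations, and a "beating" ellipsoidal shell emulating a
ventricle over a 10-phase cycle), IE/NE metrics with optional masks
(e.g. a segmented left ventricle), and I/O for NIfTI, multi-page TIFF,
DICOM series (read-only), Middlebury `.flo` flows and legacy-VTK vector
fields for glyph rendering.

## Worked example

```python
import numpy as np
import hermiteflow as hf

# a 48^3 beating-ellipsoid sequence, 10 phases, known ground-truth flow
spec = hf.PhantomSpec(seed=1)
volumes, gt_flows = hf.generate(spec)

# estimate flow for the highest-motion transition (10% -> 20% of cycle)
flow = hf.estimate_flow(volumes[1], volumes[2])          # HOF3D, defaults
base = hf.estimate_flow(volumes[1], volumes[2],
                        hf.FlowParams(baseline_mode=True))  # Horn-Schunck

peak = max(float(np.abs(v).max()) for v in volumes)
rep_h = hf.evaluate_pair(volumes[1], volumes[2], flow, intensity_scale=peak)
rep_b = hf.evaluate_pair(volumes[1], volumes[2], base, intensity_scale=peak)
print(f"HOF3D     IE={rep_h.ie:.4f}  NE={rep_h.ne:.4f}")
print(f"baseline  IE={rep_b.ie:.4f}  NE={rep_b.ne:.4f}")
```

prints

```
HOF3D     IE=0.0137  NE=0.0135
baseline  IE=0.0159  NE=0.0156
```

IE/NE are reported on the unit intensity scale (volumes divided by the
sequence peak): the high-order data term lowers the reconstruction error
relative to the plain multiresolution Horn–Schunck baseline on this
transition — as it does on every transition of the cycle — and the NE is
comfortably inside the tuned regime's quality bar (NE < 0.1).  Flow fields are in voxel units;
`hf.endpoint_error(flow, gt_flows[1])` compares against the analytic
ground truth.

The same workflows are available from the shell:

```sh
hermiteflow synth --kind beating_ellipsoid --out-dir phantom/
hermiteflow estimate phantom/phase_000.nii.gz phantom/phase_001.nii.gz --out-dir flows/
hermiteflow evaluate phantom/phase_*.nii.gz --out-dir eval/   # IE/NE table
hermiteflow benchmark --data-dir middlebury/other-data/       # 2D pairs + .flo
```

Every run writes its effective configuration (YAML) next to its outputs.

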