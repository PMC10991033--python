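# envmra

Quantitative-ultrasound envelope statistics for the **simultaneous
quantification of liver steatosis and fibrosis**: multi-Rayleigh mixture
modelling of the echo amplitude envelope with moment-space component-count
testing, detection of coherent (lipid-aggregate) signal components, and a
healthy-liver structure filter (HLSF) that converts fibrosis parameters into
a non-healthy area fraction.

It is written for QUS researchers who have 2-D envelope-amplitude rasters
(with physical pixel spacing) and want per-ROI tissue classification,
parametric maps, and frame-level steatosis/fibrosis indices — plus a
synthetic speckle-phantom generator with ground truth for method studies.

## The model

The envelope `x` of fully developed speckle follows a Rayleigh distribution

```
p_RA(x) = (2x / σ²) exp(−x² / σ²),
```

with echo power `σ² = E[x²]`. Diseased parenchyma mixes scatterer
populations, and the envelope is modelled as a three-component
multi-Rayleigh (MRA) mixture

```
p_MRA(x) = α_L p_L(x) + α_M p_M(x) + α_H p_H(x),     σ²_L < σ²_M < σ²_H,
```

where L/M/H stand for hypoechoic nodules, normal parenchyma, and
hyperechoic fibrotic tissue. The envelope is normalized so that
`E[x²] = 1`, hence `α_L σ²_L + α_M σ²_M + α_H σ²_H = 1`.

Per ROI (5.7 × 7.2 mm, three by three resolution cells), the number of
components is chosen by squared Mahalanobis distances in the space of raw
moments of orders (1, 3, 4, 5):

1. `D₁` against the Rayleigh theoretical moments; `D₁ ≤ 9.49`
   (upper-5% point of χ²₄) accepts one component;
2. otherwise `D₂` against the fitted two-component mixture; `D₂ ≤ 4.53`
   accepts two components, whose tissue combination (L+M vs M+H) is
   assigned by comparing the fitted powers with the normal-tissue power
   `σ²_M` of the ROI neighbourhood;
3. otherwise the three-component fit is used — unless it collapses back to
   a single Rayleigh (`α_L = α_H = 0`) while `m₁` lies **above** and `m₃`
   **below** the Rayleigh values: that is the signature of a coherent
   signal component attributed to aggregated lipid droplets (no Rayleigh
   mixture can produce it), and the ROI is labelled **non-MRA**. The
   non-MRA fraction of a frame is its steatosis index.

The fibrosis parameters `α_H` (fibrotic-tissue mixture rate) and
`σ²_H/σ²_M` (fibrosis-to-parenchyma power ratio) are mapped to polar
coordinates `θ = 2π α_H`, `r = σ²_H/σ²_M − 1`. The HLSF is the set of
0.5 × 0.5 cells in that plane covering the top 90% of the probability mass
of a healthy-liver reference; the share of an examination's points falling
outside it, `Frac_non-healthy = N_outside / N_total` (points in sample
cells of density < 0.001 excluded), is its fibrosis index.

## Worked example

```python
from envmra import (TissuePhantomSpec, simulate_frame, analyze_frame,
                    build_hlsf, frame_points)

# healthy-liver reference -> structure filter
reference = []
for seed in range(6):
    results, _ = analyze_frame(simulate_frame(TissuePhantomSpec.healthy(), seed))
    reference.extend(frame_points(results))
hlsf = build_hlsf(reference)

# a phantom with hyperechoic fibrotic strands (power ratio 6)
frame = simulate_frame(TissuePhantomSpec.fibrotic(), seed=41)
results, metrics = analyze_frame(frame, hlsf_filter=hlsf)
print(f"ROIs analyzed:        {metrics.n_rois}")
print(f"labels:               {metrics.label_counts}")
print(f"non-MRA fraction:     {metrics.non_mra_fraction:.3f}")
print(f"non-healthy fraction: {metrics.non_healthy_fraction:.3f}")
```

prints

```
ROIs analyzed:        90
labels:               {'RAYLEIGH': 79, 'MRA2_MH': 8, 'MRA2_LM': 3}
non-MRA fraction:     0.000
non-healthy fraction: 0.089
```

Most ROIs of the strand phantom still read as homogeneous speckle; eleven
contain enough strand tissue to reject the one-component model, eight of
which are assigned the normal+fibrosis combination. None shows the
coherent fat signature (non-MRA 0), and 8.9% of the fibrosis-parameter
points fall outside the healthy filter — against ≈ 1% for a healthy
phantom, reproducing the expected healthy-vs-fibrotic ordering.

The same pipeline is scriptable from the shell:

```
envmra simulate --spec phantom.yaml --seed 3 --out simdir
envmra build-hlsf --frames 'simdir/frame_*.json' --out hlsf.json
envmra analyze --frame simdir/frame_3.json --hlsf hlsf.json --out outdir
envmra metrics --results outdir
```

`analyze` writes a per-ROI results table (CSV), frame metrics (JSON), and
parametric maps of `α_H` (scale 0–1), `σ²_H/σ²_M` (scale 1–10) and the
decision label as CSV + PNG.

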