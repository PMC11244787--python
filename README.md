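# ssefuse

Multimodal grayscale image fusion for co-registered pairs (e.g. CT/MRI),
built from four stages plus a metrics suite:

1. **preprocess** — normalization to [0, 1] and an adaptive local Wiener
   filter (`k = var / (var + lambda)` shrinkage toward the window mean).
2. **swift** — contrast enhancement: log compression, sample-std and
   `u**lam / lam!` adjustment factors, a nonlinear exponential tone map,
   and min-max dynamic-range restoration.
3. **sse** — salient structure extraction: forward-difference gradient
   magnitudes of the two processed images are compared, mean-filtered
   and binarized into a per-pixel source-selection map.
4. **ncfilter** — edge-aware smoothing of the selection map by
   normalized convolution over a guidance-derived domain transform
   (iterated O(N) box filtering; the `sigma_r = inf` limit converges to
   a Gaussian blur).
5. **fuse** — the weighted-sum rule `F = w*A + (1-w)*B` with the
   smoothed map as the weight, orchestrating the whole pipeline.
6. **metrics** — twelve fusion-quality measures (API, SD, AG, H, MI,
   FS, CC, SF and the gradient-preservation family Q/L/N/Nm with
   `Q + L + Nm = 1`).
7. **phantoms_io** — PNG/TIFF I/O plus a synthetic co-registered
   CT-like/MRI-like phantom generator, so everything is testable with
   no external data.

## CLI

```bash
# generate a synthetic pair
ssefuse phantom --size 256 --seed 7 --noise 0.02 --out-ct ct.png --out-mri mri.png

# fuse it (optional YAML config, intermediates dump, metric report)
ssefuse fuse --a ct.png --b mri.png --out fused.png \
    --config cfg.yaml --dump-intermediates inter/ --report report.json

# metrics for an existing triple
ssefuse metrics --a ct.png --b mri.png --f fused.png --out report.json

# parameter sweep (CSV: one row of twelve metrics per value)
ssefuse sweep --a ct.png --b mri.png --parameter lambda --values 0,0.01,0.1 --out sweep.csv
```

The YAML config mirrors the defaults (absent keys keep them):

```yaml
wiener:  {radius: 3, lambda: 0.01}
swift:   {lambda_tune: 3, gamma: 1.0, parse_mode: fraction}
sse:     {window: 7, gradient_mode: paper, use_swift: true}
nc:      {sigma_s: 30.0, sigma_r: 0.25, iterations: 3}   # sigma_r: inf allowed
fuse:    {use_enhanced_sources: false, guidance: a, output_range: raw8}
```

## Library use

```python
from ssefuse import PhantomSpec, generate_phantom_pair, fuse_pipeline, metric_report

ct, mri = generate_phantom_pair(PhantomSpec(size=(256, 256), seed=7))
result = fuse_pipeline(ct, mri)
report = metric_report(ct, mri, result.fused)
```
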