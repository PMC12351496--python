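# organoid-quant

Quantification pipelines for fluorescence microscopy and expression data
from 3D cortical-organoid models of neurodegeneration — the kind of study
where a *MAPT*-mutant line is compared against an isogenic control across
immunostained sections, live calcium imaging and targeted expression
panels. The package turns those raw readouts into numbers:

* **2D marker coverage** — mean z-projection, median filter → background
  removal → H-minima transform (H = 0.05) → CLAHE, Otsu binarization, then
  the fraction of area covered by the signal and its integrated density;
  plus mask colocalization (e.g. VGluT1/PSD95 synaptic puncta) and
  count/length statistics of objects (mitochondria) inside a neurite path
  mask.
* **3D neurite morphometry** — Gaussian smoothing, local background
  subtraction and a single-scale Frangi vesselness filter (r = 10 px)
  enhance tube-like cytoskeleton in z-stacks; Otsu binarization and 3D
  thinning yield a skeleton whose **number of separated fragments** and
  **mean fragment length (µm)** quantify cytoskeletal fragmentation.
* **Calcium activity** — automatic cell detection from a Fourier-filtered
  cumulative frame-difference map, ΔF/F₀ traces, transient detection with
  a 2% amplitude threshold, exponential rise/decay fitting, fast-vs-slow
  classification at τ* = 1.5 s (slow signals are non-neuronal and are
  excluded), and network metrics: amplitude, frequency, fraction of active
  cells, synchrony (relative number of simultaneous events).
* **Expression statistics** — nCounter-style normalization by the geometric
  mean of housekeeping genes with average count > 450; per-gene t-tests
  with fold-change cutoffs ≥ 1.5 / ≤ 0.66 for up/down calls; hierarchical
  clustering (average linkage, Pearson distance); qPCR 2^−ΔCt relative
  expression against ATP5O, including the 4R/3R tau isoform ratio.
* **Synthetic data** — generators for every input (tube phantoms, puncta
  fields, calcium movies, count matrices, Ct tables) with exact ground
  truth, so every pipeline is testable end-to-end without raw data.

The scientific core in symbols: coverage = |mask|/|FOV| with
ISD = Σ_mask I_raw; fragment length = Σ adjacent-voxel steps
√((dz·vz)²+(dy·vy)²+(dx·vx)²); ΔF/F₀ = (F − F₀)/F₀ with F₀ a running 10th
percentile; transients fit A·(1−e^−(t−t₀)/τ_r)·e^−(t−t₀)/τ_d; cells are
neuronal iff median τ_r < 1.5 s; normalization scales sample s by
(grand geomean of HK geomeans)/(HK geomean of s); DE calls require
p ≤ 0.05 and FC ≥ 1.5 (up) or ≤ 0.66 (down); rel_expr = 2^−(Ct_g − Ct_ref).

## Worked example

Simulate a spontaneous-activity recording (20 cells, 5 min at 4 Hz,
2 events/min, SNR 5) and run the full calcium pipeline:

```python
from organoid_quant.synthetic import gen_calcium_movie
from organoid_quant.calcium_activity import analyze_movie

movie, truth = gen_calcium_movie(n_cells=20, rate_per_min=2.0, snr=5.0, seed=0)
rois, traces, cells, m = analyze_movie(movie)
print(f"detected {m.n_cells_total} cells ({m.n_active_fast} active fast)")
print(f"active fraction   {m.active_fraction:.2f}")
print(f"event frequency   {m.mean_frequency_per_min:.2f} events/min")
print(f"mean amplitude    {m.mean_amplitude:.3f} dF/F0")
print(f"synchrony         {m.synchrony:.2f}")
```

```
detected 20 cells (20 active fast)
active fraction   1.00
event frequency   1.91 events/min
mean amplitude    0.139 dF/F0
synchrony         0.15
```

All 20 planted cells are found and classified neuronal; the measured
1.91 events/min matches the planted trains (1.98 events/min on this
realization); the low synchrony reflects independent event trains
(`shared_event_fraction=1.0` would drive it to 1.0). Measured amplitudes
sit ~30% below the planted intrinsic ΔF/F₀ because the ROI disk averages
in non-cell background — a dilution inherent to disk ROIs that cancels in
group comparisons.

The same pattern works for the morphometry:

```python
from organoid_quant.synthetic import gen_tube_phantom
from organoid_quant.neurite_morph3d import analyze_stack

stack, truth = gen_tube_phantom(n_fragments=8, snr=10.0, seed=0)
stats, skeleton = analyze_stack(stack)
# -> fragments 8 (planted 8); mean length 7.30 um (planted 7.50)
```

## Command line

Each pipeline is also a subcommand of `organoid-quant`:

```bash
organoid-quant markers2d  --input field.tif --out coverage.csv
organoid-quant neurite3d  --input stack.tif --voxel-size 0.2 0.133 0.133
organoid-quant calcium    --movie rec.tif --rate 4 --edits curation.json
organoid-quant nanostring-de --counts counts.csv --housekeeping AARS,LARS,TADA2B
organoid-quant qpcr       --ct ct.csv --ref ATP5O --ratio 4R:3R
organoid-quant --seed 7 simulate tubes
```

Global flags `--config` (YAML with every tunable), `--seed`, `--out-dir`,
`--log-level`.

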