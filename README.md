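# holoquant

Quantification pipelines for **label-free holo-tomographic microscopy (HTM)**
— time-lapse 3D maps of the absolute refractive index (RI) of living cells —
together with a synthetic RI-phantom generator that provides exact ground
truth for validating every pipeline stage.

HTM reports, for each voxel, the absolute refractive index n ≈ 1.33–1.42.
Because dense, lipid-rich organelles (lipid droplets, mitochondria,
drug-induced late endosomes) raise the local RI well above the cytoplasm,
they can be detected and measured without any fluorescent label, and the RI
excess converts linearly into **dry mass** through the specific refractive
increment α:

```
ρ = (n − n_m) / α          ρ: dry-mass density [pg/µm³]
                           n_m: medium RI (1.33)
                           α: specific refractive increment (0.19 mL/g ≡ 0.19 µm³/pg)
```

The package implements four analysis pipelines, for users of tomographic
microscopes who want quantitative, reproducible readouts from float-TIFF RI
exports:

| pipeline | what it measures |
|---|---|
| `organelles` + `drymass` | lipid-droplet / late-endosome counts, per-object dry mass and dry-mass flux (pg/min) from maximum-intensity projections with a fixed RI threshold (1.354 for LDs, 1.347 for endosomes) and equivalent-diameter gating |
| `cellseg3d` | whole-cell segmentation by seeded propagation on rescaled (1.32–1.34 → 0–1) projections, slice-wise 3D extension with per-cell RI-range gating, and IoU tracking through division |
| `rotation` | intracellular (nuclear/organellar) rotation from SIFT feature matching, Lowe-ratio acceptance, RANSAC homography fitting and angle extraction |
| `coloc` | validation of RI signatures against fluorescence: bootstrapped Kolmogorov–Smirnov mask tests, Pearson correlation, object-overlap fractions |

The `phantom` module generates the synthetic study conditions (HeLa-like
cells on a 1.33-RI background, organelle birth/growth schedules, a
growth–rounding–division mitosis, rigid in-plane rotation) with analytic
ground truth, so that all headline statistics become parameter-recovery
tests.

## Worked example

Simulate a 3-hour oleic-acid lipid-droplet loading experiment (one RI
volume per minute, 128×128×32 voxels at 0.18/0.4 µm spacing), run the LD
pipeline on the projections, and report the population statistics:

```bash
holoquant run --scenario oa_loading --out oa_run --seed 0
```

prints

```json
{
  "count_final": 48,
  "count_fold_change": 16.0,
  "count_initial": 3,
  "flux_zero_crossing_min": 23.590821227056544,
  "steady_flux_per_object_pg_per_min": 0.0001019160264547651,
  "total_mass_final_pg": 1.0160956309778864
}
```

Reading the numbers: detected LDs rise from 3 to 48 (a **16-fold**
increase); the per-LD dry-mass flux starts negative (pre-existing LDs shed
material while new ones nucleate), crosses zero near minute **24** and
settles at ≈ **1×10⁻⁴ pg·min⁻¹ per LD** — the fingerprint of early LD
biogenesis under fatty-acid loading.  `oa_run/` also receives the
per-object CSV, the per-frame mass series, the flux table and a trace
figure.

The same entry point runs the other scenarios
(`u18666a`, `mitosis`, `rotation`, `static`), and the subcommands
`organelles`, `drymass`, `cells`, `rotation`, `coloc` operate on
directories of `frame_####.tiff` float-TIFF volumes from a real
instrument export.

From Python:

```python
from holoquant import phantom as ph
from holoquant.pipeline import analyze_organelle_timelapse

spec = ph.oa_loading_spec(seed=0)
records, series, flux, summary = analyze_organelle_timelapse(spec)
```

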