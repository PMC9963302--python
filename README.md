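# synquant

Quantitative image analysis of the immunological synapse (IS) — the
bull's-eye-shaped contact a T cell forms on an antigen-presenting surface,
with receptor microclusters streaming centripetally into a central cSMAC
surrounded by an adhesion (pSMAC) ring. `synquant` implements the full
measurement chain used to characterise this structure and its endocytic
machinery from fluorescence microscopy:

- **Segmentation & background** — per-cell masks from a bright-field-like
  reference channel (Otsu threshold, hole filling, size and border filters)
  and rolling-ball background subtraction (default radius 50 px).
- **MFI & colocalization** — mean fluorescence intensity per channel and the
  Pearson correlation coefficient (PCC) between channel pairs over the cell
  mask, `r = Σ(aᵢ−ā)(bᵢ−b̄) / √(Σ(aᵢ−ā)² Σ(bᵢ−b̄)²) ∈ [−1, 1]`, with
  median ± IQR aggregation and per-experiment means (superplots).
- **Radial averaging** — the positional average of each channel obtained by
  averaging 360 copies of the image rotated in 1° steps about the synapse
  centre (with a fast, equivalent polar-resampling path), plus 1D radial
  profiles and cohort averages with SEM.
- **Microcluster tracking** — scale-normalised Laplacian-of-Gaussian spot
  detection with subpixel refinement, globally optimal frame-to-frame
  linking (Hungarian algorithm with a displacement gate and gap closing),
  and secondary-channel intensity traces along tracks.
- **3D vesicle quantification** — a cell mask from the membrane channel of a
  confocal z-stack (anisotropic voxels, default z step 0.25 µm), then counts,
  physical volumes, and summed intensities of cargo-positive vesicles
  strictly inside (trans-endocytosed) or outside (released) the mask.
- **Bead-transfer statistic** — for bead-supported-lipid-bilayer assays,
  `f = MFI_bead / (MFI_bead + MFI_cell)` per experiment with SEM, and an
  extra-sum-of-squares F test comparing dose–response curves between
  conditions: `F = [(SS_shared − SS_separate)/Δdf] / [SS_separate/df_sep]`.
- **Statistics** — unpaired two-tailed Mann–Whitney U (exact enumeration
  with mid-rank ties for small samples, Edgeworth-corrected normal
  approximation otherwise), significance stars, optional Holm correction.
- **Synthetic ground truth** — a first-class generator that renders synapse
  images, microcluster movies, 3D cell stacks with vesicles, and transfer
  event tables with exact per-object ground-truth records, so every stage is
  validated against known truth without external data.

## Worked example

```python
import numpy as np
from synquant.synthetic import SynapseSpec, render_synapse
from synquant.segmentation2d import segment_cells, subtract_background
from synquant.coloc import mfi, pcc
from synquant.radial import radial_average_image, radial_profile

spec = SynapseSpec(coloc_mixing=0.7, gaussian_noise_sd=1.0, seed=1)
img, truth = render_synapse(spec)

cells = segment_cells(img["brightfield"], min_area_um2=20.0,
                      pixel_size_um=spec.pixel_size_um)
cell = cells[0]
rec = subtract_background(img["receptor"], 50)
ada = subtract_background(img["adaptor"], 50)
print(f"receptor MFI: {mfi(rec, cell.mask):.3f}")
print(f"PCC(receptor, adaptor): {pcc(rec, ada, cell.mask):.3f}")

avg = radial_average_image(img["adhesion"], cell.centroid_xy)
prof = radial_profile(avg, cell.centroid_xy, spec.pixel_size_um, 0.25,
                      channel="adhesion")
peak = prof.radii_um[np.argmax(prof.means["adhesion"])]
print(f"adhesion-ring radial peak: {peak:.3f} um")
```

prints

```
receptor MFI: 6.271
PCC(receptor, adaptor): 0.932
adhesion-ring radial peak: 3.625 um
```

One synapse is segmented (58.2 µm², centroid at the image centre); the
background-corrected receptor MFI is 6.27 a.u.; the receptor–adaptor PCC of
0.93 reflects the generator's mixing parameter of 0.7 plus the shared
punctate structure; and the radial profile of the adhesion channel peaks at
3.6 µm, recovering the generated pSMAC ring radius of 3.5 µm to within one
bin width.

The same flow is available from the shell:

```bash
synquant synthetic demo-2d --seed 1 --out demo.ome.tiff
synquant segment demo.ome.tiff --out-prefix demo
synquant run-2d --seed 1 --out results_2d     # full 2D pipeline
synquant run-3d --seed 1 --out results_3d     # full 3D pipeline
```

Every pipeline run writes per-cell and per-object CSVs plus a JSON manifest
of the inputs, parameters, seed, and software version; identical config and
seed reproduce byte-identical CSVs.

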