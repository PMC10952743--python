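# srsphasor

Spectral phasor unmixing of hyperspectral stimulated Raman scattering (SRS)
image stacks, built for multiplexed imaging of bioorthogonal Raman tags in
the cell-silent spectral region.

## The problem

SRS microscopy images one vibrational frequency at a time; scanning the pump
laser in small steps (0.4 nm ≈ 7 cm⁻¹) yields a hyperspectral stack with a
full Raman spectrum at every pixel. Bioorthogonal tags — alkynes (C≡C,
~2220 cm⁻¹), carbon–deuterium bonds (CD₂, 2102 cm⁻¹) and the boron–hydride
stretch of metallacarboranes (B–H, 2480–2650 cm⁻¹) — vibrate in the
cell-silent window where no endogenous bands interfere, but their bands
overlap each other and must be unmixed. This package implements the analysis
chain that does so:

1. **Spectral phasor transform.** Each pixel's spectrum *I(k)*,
   *k* = 0…*N*−1 over the (concatenated) frame axis, is mapped to normalized
   first-harmonic Fourier coefficients

   G = Σₖ I(k)·cos(2πnk/N) / Σₖ I(k),  S = Σₖ I(k)·sin(2πnk/N) / Σₖ I(k).

   (G, S) depends only on spectral shape, not brightness, so chemically
   similar pixels cluster in the phasor plane.
2. **Phasor-space segmentation.** Clusters are gated — by explicit polygons
   or by seeded k-means with convex-hull gates — and gated pixels are mapped
   back to a labelled image; per-segment mean spectra (min–max normalized to
   [0, 1]) identify each region.
3. **RIE quantification.** Tag brightness is reported as the relative
   intensity to EdU (RIE): the baseline-corrected height of the tag's
   reporter band over that of the EdU alkyne band at 2120 cm⁻¹
   (2090–2150 cm⁻¹).

Because measured cell stacks are not redistributable, the package ships a
synthetic scene generator with pixel-level ground truth that emulates a
triplex labelling experiment (metallacarborane + bis-alkyne + deuterated
fatty acid over six cellular compartments) on the three-window scan
3050–2800 (40 frames), 2650–2450 (35) and 2250–2000 cm⁻¹ (40 frames). The
ground-truth masks make segmentation quality measurable as
intersection-over-union (IoU) with optimal one-to-one class assignment.

## Worked example

```python
from srsphasor import (PipelineConfig, run_pipeline)

report = run_pipeline(PipelineConfig(preset="triplex_crsan", k=9, seed=1,
                                     out_dir="results/demo"))
print(report["classes_matched"], report["per_class_iou"]["lipid_droplets"])
```

Running the bundled analysis scripts from the repository root:

```
$ python analysis/01_simulate_scene.py
window 0: 40 frames, 2800-3050 cm^-1
window 1: 35 frames, 2450-2650 cm^-1
window 2: 40 frames, 2000-2250 cm^-1
9 ground-truth classes (pixels): {'nucleus': 3689, 'nucleolus': 788, ...}

$ python analysis/03_segment_unmix.py
nine-segment run: 9/9 classes matched at IoU >= 0.5
silent-region run: 3/3 probe channels matched

$ python analysis/04_rie_quantification.py
                     rie_height  rie_area
edu                         1.0     1.000
metallacarborane            3.0    20.306
...
metallacarborane RIE (height) = 3.00; butadiyne/metallacarborane ratio = 4.00
```

The nine-segment run means the full pipeline (simulate → concatenate →
phasor → k-means gating → back-mapping) recovered every ground-truth class —
nucleus, nucleolus, cytoplasm, lipid droplets, LD periphery, cell boundary,
and the three probe channels — each with IoU ≥ 0.5 against the masks the
scene was built from. The silent-region run shows the three Raman tags alone
can be unmixed from the two cell-silent windows. The RIE table reproduces
the packaged library's calibration: metallacarborane 3× EdU, bis-alkynes
4-fold above that.

There is also a CLI (`srsphasor simulate|phasor|run|rie|evaluate`) mirroring
these stages.

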