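# cytocorr

Correlative multi-modal fluorescence microscopy at desk scale: image
cytometry over thousands of cells, gate-driven physical retrieval of
selected cells on the microscope stage, single-molecule localization
(SMLM/dSTORM) reconstruction with fiducial drift correction,
cross-modality registration in physical coordinates, and dual-channel
colocalization by image cross-correlation spectroscopy (ICCS) and
object-based cluster matching.

## Who this is for

Labs that combine a fast widefield pass (to measure and classify
thousands of cells) with targeted high- and super-resolution follow-up
(confocal, TIRF, dSTORM) on selected cells. The package reimplements the
computational spine of such a pipeline as an open, scriptable toolchain:

1. **Cytometry** — flat-field and rolling-ball preprocessing, nuclear
   segmentation on the DNA channel, per-cell geometry (area,
   circularity = 4πA/P²) and per-channel mean/integrated intensity into a
   tab-delimited single-cell repository; intracellular spots measured as
   sub-compartments.
2. **Gating** — histograms, rectangle/polygon/boolean gates, population
   statistics, and a cell-cycle classifier: S phase from EdU
   incorporation (or from DNA content alone), G1/G2 windows
   `[g_lo, g_hi]·P` and `[2g_lo, 2g_hi]·P` around the G1 peak *P* of the
   kernel-smoothed DNA-integral distribution, and a mitosis overlay from
   chromatin condensation (high DNA mean), reduced area, high
   circularity, or a bright mitotic marker.
3. **Retrieval** — exact pixel↔stage coordinate conversion
   (`stage = tile_offset + swap(sign·(px + ½)·pixel_size)`) and position
   lists the microscope can re-visit.
4. **SMLM** — detection + weighted least-squares 2D Gaussian fitting,
   Thompson precision `σ²_loc = (s² + a²/12)/N + 8πs⁴b²/(a²N²)`,
   drift correction from fiducial markers imaged once every K frames
   (piecewise-linear between anchors), inter-channel shift correction,
   and Gaussian rendering (photon-weighted or unit-weight).
5. **Registration** — translation/rigid/similarity transforms in
   nanometers so 65 nm and 160 nm sampled images overlay correctly;
   phase-correlation shift estimation and closed-form (Procrustes)
   landmark fits.
6. **Colocalization** — ICCS
   (`G_ab(ξ,η) = ⟨δI_a δI_b⟩/(⟨I_a⟩⟨I_b⟩)`, fractions
   `f1 = Gcc(0)/G22(0)`, `f2 = Gcc(0)/G11(0)` from fitted zero-lag
   amplitudes) and object-based matching of 50 nm single-linkage
   clusters under an inclusive adjacency distance (50 nm for dSTORM,
   ~250 nm for TIRF), with confocal-derived compartment masks and
   nearest-neighbor distance distributions.
7. **Phantom** — a first-class synthetic-data generator producing every
   input above with ground truth (cell-cycle structure, mitotic
   morphology, nuclear foci, blinking SMLM movies with drift and
   fiducials, two-channel point patterns with a controlled colocalized
   fraction), so the whole pipeline is testable without any microscope.

## Worked example

Generate a 500-cell phantom, measure it, and classify the cell cycle:

```python
from cytocorr import phantom, cytometry, gating
from cytocorr.io_formats import ImageStack

cfg = phantom.PhantomConfig(n_cells=500)
stack, truth = phantom.generate_population(cfg, seed=1)

planes = {ch: cytometry.subtract_background(stack.plane(ch), 50)
          for ch in stack.channel_names}
labels = cytometry.segment_nuclei(planes["DNA"],
                                  cytometry.SegmentationParams(min_area_px=100))
cells = cytometry.measure_cells(
    labels, ImageStack(list(planes.values()), channel_names=list(planes)))
phases = gating.classify_cell_cycle(cells, mode="dna")
print(len(cells), "cells segmented")
print(phases["phase"].value_counts().to_dict())
```

prints

```
500 cells segmented
{'G1': 291, 'S': 132, 'G2': 50, 'M': 18, 'unclassified': 9}
```

— all 500 synthetic nuclei are recovered, and the DNA-content windows
split them into the generated 60/25/15 G1:S:G2M structure with the
mitotic overlay picking out the condensed, small, round, bright nuclei.

The same stages are available from the shell (`cytocorr --help`):

```bash
cytocorr phantom population --seed 1 --out pop/
cytocorr cytometry run --images pop/ --out cells.tsv
cytocorr gating run --cells cells.tsv --phase-mode dna --out labels.tsv
cytocorr retrieve --cells cells.tsv --select labels.tsv --phase M \
    --calib calib.yaml --out positions.csv
```

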