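# nanocol

Quantification of **trans-synaptic nanocolumn alignment** in ~8×-expanded
fluorescence images.

Chemical synapses organize presynaptic release-site proteins (RIM, Munc13-1,
Bassoon) and postsynaptic receptors/scaffolds (GluA1, PSD95, Homer1) into
*nanocolumns* — nanoscale clusters aligned across the synaptic cleft. With
~8-fold expansion microscopy (TREx) and Airyscan imaging (41.2 nm pixels in
expanded dimensions, i.e. ~5 nm biological), this alignment becomes visible in
ordinary multichannel images. `nanocol` implements the quantitative side of
that experiment for image analysts and microscopists:

- **Synapse ROI detection** — Otsu thresholding, connected-component labeling,
  and a two-stage shape rule: the largest region must have area ≥ 300 px and
  moment-ellipse axis ratio major/minor ≥ 2; failing that, the union of the
  three largest clusters is re-tested; failing that, the synapse is discarded
  (with a QC plot in every case).
- **Constrained affine alignment** of the presynaptic channel onto the
  postsynaptic one: translation → rotation → shear released in stages, scale
  hard-locked at 1, optimizing the Pearson correlation coefficient (PCC)
  inside the synapse ROI. A high post-alignment PCC over the synaptic domain
  indicates a nanocolumn arrangement.
- **Orientation–shift check** — the cosine between the synapse major axis and
  the recovered shift vector; a value near zero means the pre→post shift
  points straight across the cleft, as a trans-synaptic pairing requires.
- **Colocalization** of a trans-synaptic channel (e.g. LGI1) with its pre- and
  postsynaptic partners: per-channel Otsu overlap map plus an anchored PCC,
  computed on unmoved channels.
- **Expansion factors** — macroscopic (gel-diameter ratio) and structural
  (similarity + affine registration of pre-/post-expansion image pairs, with a
  distortion vector map of non-uniform expansion).
- **Group statistics** — box-plot summaries with single-pass 1.5 × SD outlier
  exclusion, Shapiro–Wilk normality checks and two-sample *t*-tests.
- **A synthetic-image generator** with full ground truth (nanodomain
  positions, cleft offset, applied misalignment, expansion scale), so every
  stage is testable without microscopy data.

## Worked example

`examples/simulate_and_align.py` simulates one synapse — six Gaussian
nanodomains along a bar, mirrored at a 318 nm (expanded) perpendicular cleft
offset, Poisson noise — displaces the postsynaptic channel by (−120, 90) nm
plus a 3° rotation, and runs the full analysis:

```
accepted:            True (stage: primary_region)
PCC before alignment: -0.179
PCC after alignment:  0.943
recovered shift:      (-6.87, 8.85) px
recovered rotation:   3.03 deg (applied: 3.00 deg)
orientation-shift cosine: -0.109
```

The aligned PCC near 1 says the two channels share one nanodomain layout; the
recovered rotation matches the applied one to 0.03°; the shift is the cleft
vector plus the applied misalignment; and the small cosine says it points
essentially perpendicular to the synapse axis. The other examples cover the
expansion factor (macroscopic 8.3× from a 12 mm → 100 mm gel; structural
8.00× recovered from a simulated 8× pair under a 100 nm distortion field),
the jitter sweep (aligned PCC falls monotonically from 0.95 to 0.76 as
per-domain jitter grows to 200 nm), and trans-channel colocalization.

## Command line

A thin CLI wraps the library:

```sh
nanocol simulate synapse --n 20 --seed 1 --out sims/
nanocol align 'sims/*.tif' --out aligned/      # writes data.txt, overlays, quivers
nanocol coloc 'sims/*.tif' --out coloc/
nanocol exfactor --pre-diameter 12 --post-diameter 100
nanocol summarize aligned/data.txt
```

`data.txt` is tab-separated with columns `filename, pcc, channel_pre,
channel_post` plus `pcc_before, shift_dx, shift_dy, orientation_dot, accepted,
stage`; one row per input image, discards included.

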