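# Methods

## Scope and data model

All three analyses operate on a single carrier, a calibrated `ImageStack`:
a T×Z×Y×X array of non-negative intensities with mandatory physical
metadata (µm per pixel, µm per z-step, minutes per frame, acquisition start
offset). Physical calibration is never defaulted silently — every reported
quantity is in µm and minutes. Multi-page TIFF page order is declared in a
JSON sidecar (`axes_order: TZYX`, page count = T×Z), never guessed from
TIFF tags. Coordinates are 0-based pixel indices with pixel centers at
index × pixel size; x is the column axis, y the row axis.

## Root-hair kinetics

Per frame (after maximum-intensity projection over Z):

1. **Segmentation.** Global Otsu threshold; the split is accepted only if
   the above-threshold class clears the background class median by 5 robust
   SDs (1.4826 × MAD), otherwise the frame is declared empty — Otsu on a
   unimodal frame otherwise bisects the noise. Objects under 20 µm² are
   removed. The root body is the largest connected component, of a
   morphological opening of the foreground, that touches the designated
   image edge; the opening (square structuring element, 7 µm half-width,
   implemented with separable min/max filters) erases tube-like hairs so
   that hairs attached to the root do not merge into it. Hairs are the
   remaining foreground.
2. **Tip detection.** Each hair component is skeletonized; skeleton pixels
   within 4 px of the root body seed a Dijkstra pass over the skeleton
   (8-connectivity, diagonal cost √2), and the tip is the skeleton endpoint
   with maximal geodesic distance. Components without endpoints (rings) are
   skipped and counted in QC; components with more than one distal endpoint
   (touching hairs) are flagged ambiguous and their records carry
   `qc = ambiguous`. Tip localization is pixel-precision by design: at the
   assay calibration (0.92 µm/px, 8-min frames) one frame of growth is
   6–9 px, so sub-pixel fitting would not change any read-out.
3. **Linking.** Greedy nearest-neighbour frame-to-frame linking under a
   speed gate (default 3 µm min⁻¹, ~2.6× the faster regime's mean rate);
   unmatched tips start new tracks; a track tolerates 2 consecutive missed
   frames. Hairs are laterally near-stationary, so global assignment would
   add cost without changing links; the test suite quantifies the residual
   risk by Hungarian matching against ground-truth trajectories.
4. **Growth curves.** Length(t) is the cumulative path length of tip
   displacements — exact for straight tubes, robust for curved hairs,
   monotone by construction — anchored at 0 at the first sample. The hair
   length already present at first detection (a hair must protrude ~3 µm
   before it survives despeckling) is measured as the skeleton geodesic
   length at that frame and carried as `initial_length_um`; final lengths
   add it back. Without this term, mean final length is biased low by about
   half a frame of growth (≈5 %), purely an artifact of late emergence.
5. **Kinetics.** The instantaneous rate is the central difference of the
   curve; growth runs from the first time the 3-frame sliding-mean rate
   reaches the rate floor (default 0.2 µm min⁻¹, ~4× below the slower
   regime's mean rate) until it first drops back below it. Growth rate is
   the least-squares slope over that interval; duration its length; final
   length the mean curve value over the first ≤3 samples at/after
   termination ("plateau length") plus the initial length. Taking the
   plateau at termination rather than at record end matters because tip
   jitter accumulates |Δ| > 0 on the plateau, so end-of-record means would
   drift with record length. A curve still rising at the last frame is
   flagged `truncated`; truncated and QC-flagged records are excluded from
   all condition summaries (completed growth only). Records with no
   interval above the rate floor get `qc = non_growing` and duration 0.

Condition summaries report mean, SE (= SD/√n) and n per metric, and fold
changes against a reference condition. Group comparison is Kruskal–Wallis
followed by Dunn pairwise z-tests on mean ranks with tie correction and
Holm adjustment, summarized as a compact letter display at α = 0.01
(insert-and-absorb construction; groups ordered by median).

## Puncta dynamics

Detection runs on maximum-intensity projections (the assay's own
convention; 3-D detection is out of scope). The detector is a
difference of Gaussians at σ = scale/√2 and 1.6σ (default scale 1 µm);
candidates are 3×3 local maxima of the band-pass image, deduplicated over
exact-tie plateaus, and accepted when the response exceeds k_sigma × robust
noise (1.4826 × MAD of the band-pass, floored at 10⁻⁶ of its dynamic range
so a noise-free frame lets nothing through). Because the threshold is
MAD-relative, detection decisions are invariant to positive rescaling of
the frame. The default k_sigma = 5 holds the false-positive rate on blank
noise frames below 0.1 per frame while recall at the assay's
signal-to-noise (~100) stays ≥ 0.98 for separated spots.

Each punctum is assigned the region label at its centroid pixel (label 0 →
excluded); per region and frame the pipeline reports raw counts, densities
(per area by default, per 1000 µm³ when the region set carries volumes —
mirroring the full-volume analysis — and per cell when cell counts are
given). Punctum intensities are the mean raw intensity in a disc of radius
`scale`; the reported intensity series subtracts the background-ROI mean of
the same frame and normalizes to the first time point (first point ≡ 1; a
non-positive first point is an error, not a silent NaN). Frames are
aggregated into [k·15, (k+1)·15) min bins: each region is first averaged
over its frames in the bin, then mean and SE are taken across regions per
class; a bin with a single region reports a missing SE, not 0.

Known limitation: on 2-D projections, puncta closer than roughly the DoG
resolution (~2σ) merge into one detection, so crowded cell files are
undercounted. At the contrast-study regime this depresses the recovered
non-hair/hair ratios by ~10 % relative to the generated 12-fold density and
8-fold per-cell contrast — visible in the study output, which reports the
measured and ground-truth ratios side by side.

## Diffusion quantification

ROI means use pixel-center membership (a pixel belongs to a circle iff its
center lies inside), which makes the brute-force enumeration oracle exact.
Background correction subtracts the background ROI frame-by-frame, floored
at 0. Arrival is the first time the corrected signal exceeds the baseline
mean (first 3 frames) by max(3 baseline SDs, 0.5 grey levels) and stays
above for 2 consecutive frames; the half-grey floor exists because on
integer-quantized data a smaller rise is not measurable, and it is what
keeps the rule's output on rendered stacks within one frame of the same
rule applied to the analytic curve. Equilibration is the first time the
signal reaches 95 % of the plateau (mean of the last 3 frames). These
thresholds are declared defaults: empirical arrival/equilibration times in
the source assays were read off curves without a stated rule. The optional
mechanistic summary fits amplitude × slab solution over (D_eff, amplitude)
by least squares, initialized from the empirical half-rise time via the
t ∝ 1/D scaling.

## Synthetic generator

The generator renders what the analyses need to be falsifiable, not
optical realism (no PSF convolution, photobleaching, chromatic channels,
wavy or branching hairs, or root growth during the record).

* **Hairs.** Root as a 120-µm bright band at the left edge; hairs as
  straight soft-edged capsules (diameter 9 µm) anchored on its flank at
  40-µm spacing, with per-hair truncated-normal rate and duration
  (control: 0.75 ± 0.15 µm min⁻¹, 132 ± 30 min; sucrose: 1.14 ± 0.15,
  210 ± 30), initiation uniform in [0, 240] min, and emergence angles
  uniform in 85–95° from the root axis. The spread ±5° keeps tubes from
  crossing at this packing and hair length (near-parallel hairs, as in the
  assay's imagery) while still denying the tracker any
  perpendicularity assumption. Ground truth stores every draw;
  final length = rate × duration exactly, and a hair whose final tip would
  leave the field is flagged `truncated`, not an error. 16-bit rendering at
  0.92 µm/px, 8-min frames, background 100, signal 3000, Gaussian read
  noise SD 30 — an SNR at which detection failures indicate algorithm bugs
  rather than noise. Records last 720 min so that essentially every hair
  terminates within the record.
* **Puncta.** Alternating 20-µm hair / non-hair cell files, 150 µm long;
  per frame and file an independent Poisson count with mean
  λ_class × volume/1000 × profile(t), positions uniform in the file
  footprint and class depth, rendered as 3-D Gaussians (σ_xy 1 µm,
  σ_z 2.5 µm) into a z-stack (2.5-µm steps) at 0.29 µm/px, 15-min frames.
  The contrast preset uses λ_non-hair/λ_hair = 12 with depths 30 vs 20 µm
  (volume ratio 1.5), which forces a per-cell count ratio of 8; the
  absolute scale (λ_hair = 8 puncta per hair-file volume at plateau) keeps
  files countable rather than saturated. Accumulation profiles encode the
  qualitative kinetics: the hair class rises to plateau at 5 h, the
  non-hair class lags 4 h and plateaus at 10 h. The decay preset holds
  rates flat and decays every punctum peak with a 240-min half-life. A
  15-µm puncta-free margin strip provides the background ROI.
* **Diffusion.** Bottom-plane intensity = background + source ×
  C(0,t)/C₀ from the eigenfunction series (terms truncated below 10⁻⁹),
  with D_eff = 400 µm²/s through a 4-mm slab — an order-of-magnitude value
  for small dyes in ~1 % agar, used for oracle tests only, not presented
  as a measured constant.

Identical parameters and seed give bit-identical stacks and ground truth;
all randomness flows from one `numpy` generator per simulation.

## What the synthetic benchmarks do and do not show

Passing recovery tests shows the pipeline is unbiased and correctly
calibrated on data whose generative process matches its assumptions:
straight hairs, clean backgrounds, Gaussian spots, a stationary root. They
do not certify performance on real recordings with curved or crossing
hairs, uneven illumination, drift, or autofluorescence; the QC flags
(ambiguous, non-growing, truncated, skipped-ring counts) are the intended
first diagnostic on real data. Study sizes used by the recovery scripts —
200 hairs per condition over ten fields of view, ten fields of two cell
files per class — match the scale of the original assays while keeping a
full run in the minutes range on one CPU.
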