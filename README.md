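# rootlapse

Quantitative analysis of long-term fluorescence time-lapses of *Arabidopsis*
roots, for three assays that are usually quantified by hand-tuned macros:

1. **Root-hair growth kinetics** — track every hair tip through a multi-hour
   record and extract, per hair, the final length *L*, the elongation rate
   *v* (µm min⁻¹) and the growth duration *T* (h), with condition-level
   means ± SE, fold changes and a Kruskal–Wallis + Dunn group comparison
   (compact letter display, α = 0.01). Root hairs elongate by tip growth at
   roughly 1 µm min⁻¹, so *L ≈ v·T* and all three read-outs respond to
   treatments such as sucrose.
2. **Autophagosome puncta dynamics per cell type** — detect
   diffraction-limited ATG8-reporter puncta on maximum-intensity
   projections with a deterministic difference-of-Gaussians (DoG) detector,
   assign them to hair / non-hair epidermal cell files, and report
   time-binned counts, per-volume densities, per-cell counts and
   background-corrected intensities normalized to the first time point.
3. **Chemical-diffusion quantification** — measure fixed ROIs (12-µm
   circles, 10-µm full-width strips) through a record of a fluorescent dye
   diffusing down an agar slab, extract arrival and equilibration times,
   and optionally fit the 1-D fixed-source slab-diffusion solution
   C(0,t)/C₀ = 1 − (4/π) Σₙ (−1)ⁿ/(2n+1) · exp(−D λₙ² t), λₙ = (2n+1)π/2H,
   for an effective diffusivity D.

Because live-plant image data cannot be regenerated at will, the package
ships a first-class **synthetic time-lapse generator** (`rootlapse.simulate`)
that renders all three assays with exact per-object ground truth: elongating
tubular hairs (truncated-normal rates and durations), cell files
accumulating Poisson-distributed 3-D Gaussian puncta at class-specific
per-volume rates, and an analytic diffusion front. Every analysis stage is
verified by parameter recovery against that ground truth.

## Worked example

Simulate 20 hairs per condition in the control regime (mean rate
0.75 µm min⁻¹, mean duration 2.2 h) and the sucrose regime (1.14 µm min⁻¹,
3.5 h), track them, and compare:

```sh
python analysis/01_hair_growth_kinetics.py --seed 1 --n-hairs 20
```

prints

```
39 usable kinetics records (1 truncated/flagged excluded)
  control  final_length_um            105.99 +/-  7.03 (n=20)  fold 1.00
  control  growth_rate_um_per_min       0.74 +/-  0.03 (n=20)  fold 1.00
  control  duration_h                   2.33 +/-  0.12 (n=20)  fold 1.00
  sucrose  final_length_um            240.95 +/- 11.39 (n=19)  fold 2.27
  sucrose  growth_rate_um_per_min       1.17 +/-  0.03 (n=19)  fold 1.57
  sucrose  duration_h                   3.43 +/-  0.13 (n=19)  fold 1.47
  Dunn letters for final_length_um: {'control': 'a', 'sucrose': 'b'} (Kruskal-Wallis p=9.37e-08)
```

Each line is the pipeline-recovered mean ± SE over non-truncated,
QC-passing hairs; `fold` is the ratio to the control mean; distinct Dunn
letters mean the conditions differ at p < 0.01. One hair was still growing
when the record ended and is excluded (`truncated`). The other two assays
have matching drivers:

```sh
python analysis/02_autophagosome_dynamics.py --seed 1   # puncta ratios + decay
python analysis/03_fluorescein_diffusion.py  --seed 1   # arrival/equilibration + D fit
```

The same steps are available as a CLI for real data
(`rootlapse simulate|track-hairs|count-puncta|diffusion|report`); stacks
travel as multi-page TIFF plus a JSON sidecar carrying the mandatory
physical calibration (µm per pixel, minutes per frame).

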