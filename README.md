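# aggscreen

Image-autocorrelation analysis of nuclear protein clustering for
high-content compound screens.

Many DNA-damage-response proteins (53BP1 being the canonical example)
redistribute into nuclear foci when cells are stressed, but in live-cell or
plain immunofluorescence images the foci often sit on a high diffuse
background and never resolve into countable spots. Spatial image
correlation spectroscopy (ICS) sidesteps spot detection entirely: the
amplitude of the spatial autocorrelation of intensity fluctuations within a
nucleus measures how many *independent* fluorescent particles occupy one
point-spread-function (PSF) area, regardless of whether they are visually
resolvable. `aggscreen` packages that measurement, the screen-level
statistics around it, and a fully synthetic image generator with analytic
ground truth, so the whole chain is testable without any external data.

## The measurement

For each segmented nucleus with mean protein intensity ⟨i⟩, the normalized
fluctuation autocorrelation over pixel lags (ξ, η)

    r(ξ, η) = ⟨ i(x, y) · i(x+ξ, y+η) ⟩ / ⟨i⟩² − 1

is computed by FFT on the mean-padded nucleus crop, and the peak is fit
with the 2-D Gaussian

    r(ξ, η) ≈ a · exp( −((ξ−x₀)² + (η−y₀)²) / c² ) + b .

The amplitude `a` estimates `1/N_PSF`, the inverse mean number of
independent particles per beam area, and the **degree of aggregation**

    DA = ⟨i⟩ · a = ⟨i⟩ / N_PSF

rises when fluorophores cluster into fewer, brighter particles. Per
compound and cell line, condition-mean DA is regressed on log₁₀
concentration (the DMSO vehicle enters three decades below the lowest
dose); a significantly non-zero slope (two-sided t-test, α = 0.05) calls
the compound active, with Benjamini–Hochberg adjusted p-values reported
alongside. Mechanism-of-action (MoA) classes with ≥ 5 compounds get the
signed activity score `Σ direction / n_compounds ∈ [−1, 1]`. Nuclei are
additionally classified into G1/S/G2 from integrated (background-
subtracted) DNA-stain intensity so dose responses can be stratified by
cell-cycle phase.

## Worked example

Simulate a 3-compound toy screen (one compound designed to increase
clustering with dose) and run the full pipeline:

```bash
aggscreen simulate --out-dir screen --n-compounds 3 --n-fields 3 \
    --active-fraction 0.34 --seed 11
aggscreen run-all screen/metadata.csv --out-dir results
```

which prints, for this seed:

```
wrote 3 compounds x 5 conditions to screen
INFO aggscreen: analyzed 45 fields: 537 nuclei segmented, 0 filtered out, 44 QC-failed
INFO aggscreen: wrote 6 tables to results (config 08cc5388de2476ee)
537 nuclei, 3 compound fits, 1 active -> results
```

`results/dose_response.csv` then contains one row per compound:

```
compound  slope       slope_se    p_value      active  direction
cmpd000   1.004923833 0.273104557 0.0347661758 True    1
cmpd001   0.057769915 0.027833197 0.1295492326 False   0
cmpd002   0.026421848 0.036685583 0.5234308779 False   0
```

`cmpd000` is the designed-active compound: its DA climbs ≈ 1.0 ADU per
decade of concentration (p ≈ 0.035), while the two null compounds show
flat responses. The other tables (`nuclei.csv`, `condition_summaries.csv`,
`volcano.csv`, `moa_scores.csv`, `phase_dose_response.csv`) hold the
per-nucleus measurements, pooled condition statistics, volcano-plot
coordinates, MoA scores and per-phase regressions; every CSV carries the
hash of the resolved configuration, which is serialized next to them.

The same stages are importable as functions (`simulate_field`,
`segment_nuclei`, `measure_nucleus`, `dose_response`, `classify_phases`,
`run_pipeline`, …) for notebook use.

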