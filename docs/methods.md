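# Methods

## The model

A fluorescence image of a nucleus is modelled as a set of point emitters
convolved with a Gaussian point-spread function (PSF)
`h(r) = exp(−r²/2σ²)`. If the emitters form a spatial Poisson process of
density ρ (particles per pixel²), the normalized fluctuation
autocorrelation of the image,

    r(ξ) = ⟨δi(x) δi(x+ξ)⟩ / ⟨i⟩² ,

is itself Gaussian with e⁻¹ radius `c = 2σ` and zero-lag amplitude

    a = 1 / (ρ · π (2σ)²) = 1 / N_PSF ,

i.e. the inverse mean number of independent particles per beam area
`π w²`, where `w = 2σ` is the e⁻² radius of the PSF intensity profile and
simultaneously the e⁻¹ radius of the correlation peak. (The correlation of
a Gaussian with itself is √2 wider than the Gaussian; a convention that
identifies the beam radius with the PSF's own e⁻¹ radius `σ√2` would make
`a` equal `1/(2·N_PSF)` instead, so the e⁻² convention is the one under
which the fitted amplitude reads directly as inverse particles per beam
area. The simulator's ground truth and the amplitude-recovery tests use
this convention throughout.)

When k monomers co-locate into one cluster with total brightness k·B, the
particle count drops by k while mean intensity is unchanged, so the
**degree of aggregation** `DA = ⟨i⟩·a = ⟨i⟩/N_PSF` scales with k. That is
the quantity pooled per condition and regressed on log dose.

## Per-nucleus measurement chain

1. **Segmentation** of the DNA-stain channel. The default backend is
   classical: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole
   filling → distance-transform watershed → labeling. Any callable
   returning a label mask can be plugged in instead (e.g. a pretrained
   star-convex model); all downstream code sees only the label mask.
   Nuclei outside a size window (default 200 px … 20× the median object
   area — deliberately loose, overridable per dataset) and nuclei whose
   bounding box touches the image border are removed and the mask is
   relabeled contiguously.
2. **Interior sampling.** The analysis mask is eroded by `erode_margin`
   (default 2 px). Pixels within ~2σ of the mask boundary receive only
   part of the PSF mass of the surrounding fluorophores; including that
   rim inflates the fitted amplitude by roughly `2σ/r̄` (r̄ the nucleus
   radius), a 20–30 % effect for small nuclei. Interior pixels are
   statistically homogeneous and leave no measurable bias. Masks that
   would fall below 50 px after erosion are analysed un-eroded.
3. **Mean padding.** The bounding box (+ 8 px margin) is cropped and every
   pixel outside the analysis mask is set to the nuclear mean ⟨i⟩, so the
   circular FFT correlation sees zero fluctuation outside the nucleus and
   no wrap-around edge artefacts.
4. **Autocorrelation.** `r = Re{IFFT(FFT(i)·conj(FFT(i)))}/(M⟨i⟩²) − 1`
   over the padded crop. Two normalizations are available:
   - *plain* (`mask=None`): divide by the full pixel count M. Because
     mean-padded pixels contribute no fluctuation but are counted in M,
     this dilutes the amplitude by the mask fill fraction — fine for
     rectangular regions, biased for arbitrary masks.
   - *mask-aware* (default in the pipeline): divide each lag by the number
     of pixel pairs that both fall inside the mask, obtained by
     autocorrelating the mask indicator with the same FFT. This is the
     standard estimator for irregular regions of interest; it makes the
     amplitude independent of mask shape (verified: equal-area ellipse vs
     rectangle agree within a few %). Lags supported by fewer than 16
     pairs are dropped (NaN).
5. **Peak fit.** Nonlinear least squares of
   `a·exp(−((ξ−x₀)²+(η−y₀)²)/c²) + b` over lags ‖(ξ,η)‖ ≤ `fit_radius`
   (default 16 px, clipped to half the crop for small nuclei). The (0,0)
   sample is excluded by default: shot and read noise are pixel-
   uncorrelated and appear only there as a delta spike, so excluding it
   removes the white-noise term without modelling it. Initialization:
   amplitude from the largest lag-1 neighbour, offset from the window
   boundary median, c₀ = 2 px, peak position at the argmax (refinable
   ±1 px). Bounds: a ∈ (0, 10], c ∈ (0.5, fit_radius], b ∈ [−0.1, 1].
6. **QC.** A nucleus is excluded from pooling when the fit fails to
   converge, a ≤ 0, c ≥ fit_radius, or the fitted peak centre lies outside
   the fit window (the signature of a featureless surface). Exclusions are
   counted and logged.

`DA·N_PSF = ⟨i⟩` holds exactly by construction. DA uses the raw
(non-background-subtracted) mean intensity over the analysis mask; a
uniform camera offset therefore dilutes `a` by `(signal/(signal+offset))²`
and enters DA multiplicatively — identical across the conditions of a
compound, hence harmless to slope-based activity calls, but documented:
the amplitude-recovery validation is specified at zero offset.

## Screen statistics

Per condition (compound × cell line × concentration), DA of QC-passing
nuclei is pooled into mean ± SD with n. Per compound, an unweighted OLS of
condition means on log₁₀ molar concentration is fit, with the DMSO vehicle
assigned (lowest dose)/1000 so it anchors the regression three decades
below the dose series. Significance is the two-sided t-test of slope = 0
with n−2 df; activity is raw p < α (default 0.05), with BH-adjusted
p-values computed across all compounds of a run and reported alongside (a
flag switches the calls to the adjusted values). Unweighted means were
chosen as the simplest model consistent with pooling; condition SDs are
carried in the outputs so a weighted variant can be added without schema
changes. A per-cell regression (all nuclei as observations) is not the
default because condition means are what the pooling stage defines.

MoA score: `Σ direction / n_compounds` per MoA (direction = sign of slope
for active compounds, else 0), only for MoAs with ≥ 5 compounds; scored
within each cell line when several are present, since fits are per cell
line.

## Cell-cycle classification

Integrated DNA-stain intensity is background-subtracted (median of
non-nucleus pixels × area removed) so it scales with DNA content rather
than nucleus area. The G1 reference is the mode of a Gaussian-KDE over all
nuclei of a batch (a cell line/plate — never a single condition, so
treatment-induced arrest cannot move the reference). Labels: G1 within
[0.75, 1.25]× the peak, G2 within [1.75, 2.5]×, S strictly between,
otherwise unclassified; batches under 50 nuclei or with degenerate
intensities are left unclassified entirely. The multiplicative windows
make classification scale-invariant. These window defaults are declared
package defaults, configurable per dataset. Phase-stratified dose
responses simply re-run the pooling + regression on phase-restricted
nuclei.

## The synthetic-data generator

The generator emulates the screen inputs end to end: elliptical,
non-overlapping nuclei (rejection-sampled placement with bounded retries);
per-nucleus DNA content drawn from a G1/S/G2 mixture (1×, uniform 1.05–
1.95×, 2× with 3 % jitter; default weights 0.60/0.15/0.25) rendered so
integrated DNA intensity is area-independent; protein emitters placed
uniformly in each nucleus as free monomers plus zero-extent clusters of k
monomers; Gaussian PSF blur; Poisson shot noise on signal + offset, then
Gaussian read noise, then optional sum-pooled pixel binning, clipping and
16-bit quantization. One seed fans out into geometry, camera and
per-nucleus emitter streams, so fields differing only in clustering
parameters share geometry and monomer counts nucleus-for-nucleus, and
identical specs are bit-identical.

Zero-extent clusters are the one deliberate idealization: they keep the
ICS identity `a = 1/N_PSF` exact so the simulator doubles as an analytic
oracle. Real foci have finite size, which widens the correlation peak and
lowers the amplitude; chromatin texture, out-of-focus light, illumination
gradients and cell crowding are likewise not modelled. Passing tests
therefore demonstrate correctness of the measurement chain under the
model's assumptions, not robustness to every real-microscopy artefact.

Default conditions (chosen once for realistic signal-to-noise at
screen-like magnification): 256² px fields, pixel size 1 μm, nuclei radius
12–16 px, monomer density 0.6 μm⁻², brightness 150 ADU, σ_PSF = 1.5 px,
offset 100 ADU, read noise 2 ADU. The dose series used by the screen
experiments is 10 nM–10 μM in decades plus vehicle, mirroring a four-dose
screen layout; designed-active compounds ramp the clustered fraction to
0.8 at top dose (k = 4), i.e. a ≈ 2.5× DA increase over vehicle.

## Validation experiments and problem sizes

All validation quantities are recomputed by `scripts/acceptance.py` and
asserted in `tests/test_acceptance.py`:

- FFT autocorrelation vs a direct circular-shift reference on 50 random
  images ≤ 64² (agreement to < 10⁻⁸; measured ~10⁻¹⁵).
- Amplitude recovery on 100 pure-monomer, zero-offset nuclei of radius
  18–24 px (the identity assumes beam area ≪ region area; small regions
  inflate the estimate).
- DA cluster scaling, k = 4 vs k = 1 at fixed monomers, 100 nuclei/arm
  (ratio expected in [3, 5], analytically 4).
- Mask-shape robustness, 40 homogeneous fields, equal-area ellipse vs
  rectangle.
- Binning sensitivity: the standardized k = 4 vs k = 1 separation shrinks
  under 2× binning (σ_PSF falls below a pixel).
- Regression vs closed-form OLS + t-CDF (10⁻¹⁰), and the DMSO axis
  placement.
- Null screen: 500 compound fits with flat designed clustering, one field
  per condition; the active-call rate must land in the binomial 99 % CI
  around α.
- Power: 50 replicate screens with one designed-active compound each
  (alternating sign), four fields per condition (~30 nuclei/condition —
  far below a production screen's hundreds, enough for the means to
  resolve the trend); ≥ 90 % must be called active with the correct sign.
- Cell-cycle: phase agreement on a two-population (G1/G2) DNA-content
  mixture, and per-phase slopes within 2 SE of the overall slope for a
  phase-independent effect, as a fraction over 8 replicate screens
  (each per-phase slope is itself a noisy estimate, so the check is a
  fraction, not a single draw).

These sizes keep the full suite and the reproduction script to a few
minutes each on a single CPU.

## Known limitations

- The amplitude estimate retains a small positive bias for very small
  nuclei (beam area not ≪ region area) even with interior sampling.
- A uniform background offset biases absolute DA (documented above); only
  relative, within-compound comparisons are offset-invariant.
- Finite-size clusters, spatially varying background and segmentation
  errors propagate into DA in ways the zero-extent-cluster model does not
  capture.
- The KDE-mode G1 reference assumes G1 is the most common phase in a
  batch; heavily arrested populations would need an external reference
  window.
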