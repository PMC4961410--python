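# Methods

## Scope and model

`ctcgate` re-implements, as a reusable and testable pipeline, an
immunofluorescence image-cytometry analysis in which circulating tumor
cells (CTCs) are identified from antibody-captured blood samples and
evaluated for PD-L1. The central claim the pipeline operationalizes: the
standard CTC definition (pCK⁺CD45⁻) admits CD11b⁺CD45^lo myeloid cells
whose intracellular staining is non-specific, and excluding them (the
*strict* criterion, CD11b⁻pCK⁺CD45⁻) changes both CTC counts and the
PD-L1 readout. No raw patient data exist for this analysis, so a
synthetic-data generator plants known truths and every stage is validated
by parameter recovery.

## Synthetic samples

Each scenario draws `n_cells` population memberships multinomially and
per-marker intensities log-normally, parameterized by median *m* and
geometric SD *g*: `X = m·exp(ln(g)·Z)`, `Z ~ N(0,1)`. The log-normal is
the standard right-skewed, strictly positive model for fluorescence
intensities; `g = 1` degenerates to a point mass, which the tests use for
exact-value checks. Arithmetic means follow `m·exp(ln(g)²/2)`, so planted
fold-changes of means equal median ratios whenever the compared classes
share `g` — the presets exploit this to plant exact fold-changes.

Class phenotypes (defaults, arbitrary units): WBC CD45 ~3000; MYELOID
CD45 ~80 ("CD45-low"), CD11b ~1200, pCK ~150, isotype ~100, PD-L1 ~800,
radius ~11 px (granulocyte-like size); CTC pCK ~400, capture antigen
~500, PD-L1 per scenario; OTHER is the CD11b⁻CD45⁻pCK⁻ comparison class.
Medians were chosen so each gated channel separates its positive and
negative classes by at least one decade, mirroring the clearly separated
clusters of real gating plots; geometric SDs of 1.4–1.8 match typical
decade-wide fluorescence spread.

Preset planted vectors encode the published summary statistics. Where
only endpoints and means are printed, the middle values are constrained
choices (flagged here, documented nowhere else as data): pCK fold-changes
{8, 9, 22} (mean 13) paired in sorted order with isotype fold-changes
{12, 19, 38} (mean 23); capture-antibody CD11b⁺ fractions 22/27/47%
(EpCAM/MUC1/Vim) in the single-patient comparison; five-patient
fractions with means 18/20/41% and overall range 3–66%; EpCAM
contamination of the standard CTC pool {33, 71, 100, 100}% (mean 76%) and
MUC1 {33, 63, 100, 100}% (mean 74%); surface-marker identification
false-positive fractions {10, 12, 10, 20}% (mean 13%). The PD-L1 preset
plants per-patient CTC PD-L1 medians spanning 50–1200 AU against a
myeloid class fixed at 800 AU, so CD11b exclusion shifts the readout by a
patient-dependent amount.

Image mode renders each cell as a filled nuclear disc (Hoechst, planted
radius) plus a cytoplasmic disc dilated 4 px (all other markers), on a
constant background of 500 AU with Gaussian read noise of SD 50 AU,
clipped to the 16-bit range; 5% of cells are deliberately placed touching
a neighbour; the field is cut into a 2×2 tile grid with 10% linear
overlap. One seeded generator per sample is split into substreams for
intensities versus placement/noise, so event-mode and image-mode samples
share identical planted intensities. What the simulator does **not**
model: optics (PSF, defocus), illumination gradients, spectral
bleed-through, bleaching, debris, and textured (non-uniform) staining.
Passing recovery tests therefore demonstrate correctness of the pipeline
arithmetic and gating logic under a clean imaging model, not robustness
to every real-microscope artifact.

## Image pipeline

Stitching trusts the layout sidecar (registration is configured, not
estimated) and averages overlapping pixels. "Average background" is
estimated per channel by the median of all pixels — robust while cells
cover a minority of the field (≲20%); a mean-outside-mask estimator is
available by configuration. Subtraction clips at zero; a consequence is
that channels whose true level sits near zero acquire a small positive
bias from rectified noise, which is why cross-mode consistency is
asserted only for channels well above the noise floor. Segmentation
binarizes the Hoechst channel at a user-set threshold (default 800 AU
above background, suited to the simulator's ~3000 AU nuclei), takes
8-connected components, drops those below 20 px, and splits components
holding ≥2 distance-transform maxima ≥7 px apart by watershed — the
"separate touching cells by their individual nuclei" rule. The
measurement region is the nucleus dilated by 3 px (pixels claimed by a
nearer label excluded), approximating whole-cell intensity; MFI is the
arithmetic pixel mean. Coordinates are 0-based (row, col); area and
centroid come from the undilated nucleus.

## Gating

Cutoffs are derived from the *representative* sample (first of the batch
unless named in configuration) and applied verbatim across the batch;
per-sample re-derivation exists but is never the default. The derivation
automates the "gate through the density valley between clusters"
rationale: Gaussian KDE with Silverman bandwidth on log10(x+1)
intensities, cutoff at the density minimum between the two
highest-density modes. Two numerical guards reject spurious splits: modes
closer than 0.25 decades, or a candidate mode below 5% of the dominant
mode's density (sampling wiggles in a long tail), yield a "no valley"
status instead of a cutoff — a real subpopulation at a few percent
frequency sits far above both guards. Boundary values belong to the
positive side everywhere; CD45-low and CD45-negative are deliberately not
distinguished (both fall below the CD45 cutoff, as in a two-sided CD45
gate). The PD-L1 positivity cutoff is derived the same way as the other
channels. Polygon gates count boundary points as inside (`shapely`
covers-semantics); watershed ties resolve by flood order on descending
distance.

## Biomarker quantities

The false-positive fraction is `n_MYELOID_FP / n_CTC_standard`; by
construction the strict CTC set is a subset of the standard set and the
two differ exactly by the false-positives, which yields the exact
decomposition `MFI_standard·n_standard = MFI_strict·n_strict +
MFI_FP·n_FP` used as an invariant test. "Average PD-L1 MFI" is the
arithmetic mean of per-cell MFIs (the plausible reading; medians would
change numbers, not conclusions). Ratios with empty denominators are
flagged `None`, never coerced to zero, so batch means skip undefined
samples instead of absorbing them.

## Statistics

Group comparisons use Student's t: paired tests on per-patient
differences (`df = n−1`), unpaired tests in the Welch unequal-variance
form with Welch–Satterthwaite degrees of freedom (the safer default when
only "unpaired" is specified). One-tailed tests require a direction; the
report orients each pair by descending group mean. Significance is called
at α = 0.05 and starred; no multiple-testing correction is applied, but
reports state the number of tests performed.

## Problem sizes

Recovery workflows use 5,000 events per simulated patient for
fold-changes, 2,000 for fraction recoveries (4,000 for the
surface-identification scenario whose positive pool is small), and 1,200
rendered cells on a 2048×2048 field for the image-mode capture
comparison — sizes at which binomial sampling error is comfortably inside
each quantity's tolerance while a full run stays in the minutes range on
one CPU.

## Known limitations

* The event-mode tables emulate a flow-cytometry readout statistically;
  no FCS parsing, compensation or scatter-based gating is provided.
* The valley-based threshold automates what is a manual step in practice;
  manual cutoffs can be injected through configuration but no
  mixture-model (EM) gating is implemented.
* Cell "size" axes are in pixels (area) — no physical calibration.
* Touching-cell separation relies on distance-transform maxima; heavily
  overlapping nuclei (centroid distance ≪ radius sum) can merge, which
  the simulator's 5% touching rate keeps rare.
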