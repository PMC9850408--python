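# Methods

This note documents the models, numerical choices, and open design
decisions behind `picamsi`, and what the synthetic tests do and do not
demonstrate about real data.

## Data model and preprocessing

An `MSIDataset` is a dense pixels × features matrix with 1-based grid
coordinates in acquisition order and a strictly ascending feature m/z axis.
Both continuous-mode imzML (shared axis) and processed-mode imzML
(per-pixel centroids) are read; processed mode is aligned onto a common
axis by **single-linkage clustering with a gap threshold**: pooled centroid
m/z values are sorted and split wherever consecutive values differ by more
than `bin_tol` (default 0.003 Da, matching the ±0.003 Da ion-image bin).
Each cluster's representative m/z is the intensity-weighted mean of its
members. This is a deliberately transparent stand-in for a full
preprocessing suite — no baseline correction, resampling, or profile-mode
support — chosen because the rule is exactly testable against a
hierarchical-clustering oracle.

**TIC normalization** scales each pixel so its total ion current equals the
mean TIC of nonzero pixels (or a fixed target). Zero-TIC pixels are kept as
zeros rather than dropped so that acquisition-order indexing, and therefore
every-nth-pixel subsampling, stays stable. The operation is idempotent and
preserves within-pixel intensity ratios, which is why it commutes with the
pixel-wise proportionality that colocalization exploits.

**Peak picking** runs on the mean spectrum: local maxima are retained when
height / σ̂ ≥ `snr_min` (default 6), with σ̂ = 1.4826 × MAD of the mean
spectrum. MAD is used because the mean spectrum is mostly baseline; the
1.4826 factor makes it a consistent Gaussian σ estimate.

**Recalibration** matches known reference m/z values to the nearest axis
feature within a window (default 0.01 Da) and fits observed → true: an
offset for one reference, a least-squares linear map (slope + offset) for
two or more. A linear map in m/z is sufficient for the small post-alignment
shifts it targets; residuals at the references are recorded in metadata.

## Colocalization

The Pearson correlation between the bait's ion image and every feature
column is computed over **all retained pixels, zeros included**. Shared
absence is genuine evidence of colocalization in imaging data; excluding
zeros would erase the on/off spatial structure that drives the statistic.
The bait image is the ±`tol` binned window (default 0.003 Da), not a single
column, mirroring how single-ion images are rendered; the bait's own
feature therefore scores exactly 1.

Zero-variance columns (detected exactly, as max = min, rather than through
a centered-norm threshold that floating-point cancellation can defeat) have
no correlation coefficient: they are flagged undefined, excluded from the
ranking, and counted in metadata. Ranking is deterministic — PCC
descending, ties broken by ascending feature m/z — and truncated at
`top_n` (default 100). Band edges default to high ≥ 0.9 and moderate
[0.6, 0.9), inclusive on the lower edge; both are per-analysis choices
exposed as configuration, since appropriate cutoffs vary with how strongly
isomers and shared fragments disturb a given dataset.

The three computation-reduction strategies:

- **Feature reduction** keeps features with m/z ≤ cutoff (inclusive). The
  default cutoff helper is bait m/z + 40 Da: singly charged fragments
  cannot exceed the precursor m/z, while the +40 Da margin keeps K⁺
  adducts (+37.956 Da above [M+H]⁺) in range. Column selection never
  changes the PCC of surviving features.
- **Pixel subsampling** keeps acquisition-order positions 1, 1+n, 1+2n, …
  (inclusive start, so the retained count is ⌈n_pixels/n⌉).
- **ROI filtering** accepts a boundary-inclusive rectangle, a polygon
  (boundary-inclusive point-in-polygon via `shapely.covers`, equivalent to
  the even-odd rule for simple polygons), or an explicit pixel-index list.

When combined (as in the CLI), they apply in the fixed order features →
pixels → ROI and each step is logged.

## Pseudo-MS/MS spectra

Every ranked feature with PCC ≥ threshold (default 0.9) becomes a peak
whose intensity is the arithmetic mean of that feature over **the same
pixel set used for the correlation** — enforced via a provenance check —
so reduction strategies propagate consistently. Whether means should run
over all pixels or only tissue pixels is genuinely open; all-pixels is the
default because it needs no segmentation and matches the correlation's
pixel set. Isotope satellites are retained as peaks rather than collapsed:
they are part of the evidence the spectrum carries. Export formats are
MSP, MGF (via pyteomics), and CSV; the CSV round-trip is bit-exact
(17-significant-digit output, round-trip float parsing).

## Exact-mass chemistry

Monoisotopic masses use CODATA-style isotope masses for C, H, N, O, P, S,
Na, K; ion m/z is (k·M + Δm − z·mₑ)/|z|, with electrons subtracted per
positive charge. Radical cations (e.g. anthocyanidins, [M]⁺) are the
adduct rule with zero added atoms and charge +1.

**Relation annotation** is a greedy, deterministic pass in ascending peak
m/z with priority isotope → adduct → multimer → neutral loss, each within
a ppm tolerance (default 5 ppm, appropriate for FT-grade data):

1. isotope: Δ = k × 1.0033548 Da (k ≤ 3) above any already-assigned peak —
   ascending order guarantees parents precede satellites;
2. adduct: Na−H (+21.981944) or K−H (+37.955881) relative to the bait;
3. multimer: k·M + H/Na/K (k ≤ 3) from the bait's neutral mass;
4. neutral loss: bait m/z − peak m/z against an editable loss table
   (water, CO, CO₂, deoxyhexose, hexose, pentose, rutinose, trimethylamine,
   the phosphoethanolamine head group).

Priority order and greediness replace the by-inspection assignment a mass
spectrometrist would make; ties are resolved by the fixed priority, so
results are reproducible. Unmatched peaks are reported unassigned, never
as errors.

**Formula enumeration** exhaustively scans per-element count ranges
(capped; vectorized over the last element) for ion formulas within a ppm
window (default 2 ppm), filtered by RDBE ≥ 0 and 0.2 ≤ H/C ≤ 3.1
(both toggleable), sorted by |ppm error|. **Isotope patterns** are
nominal-mass aggregates: per element, the single-atom heavy-isotope
distribution is raised to the n-th convolution power
(exponentiation-by-squaring) and element distributions convolved, A ≡ 1.
Fine structure is not resolved — sufficient for confirming elemental
compositions by A+1/A+2 ratios, not for ultrahigh-resolution work.

## Synthetic scenes and what they show

The generator builds a fruit-section-on-slide scene: nested regions by
distance from the grid border — bare **slide** (margin 4 px), tissue
**skin** band (4 px), **flesh** interior — on a default 40 × 40 grid. Each
metabolite gets a smooth log-Gaussian abundance field (white noise,
Gaussian-smoothed at σ = 3 px, standardized, exponentiated at log-scale
amplitude 1.0 ≈ one decade of dynamic range at ±2σ) masked to its region.
Every derived ion is a fixed fraction of that abundance — fragments at
their yields, adducts and multimers at their fractions, isotope satellites
from the shared isotope-pattern model — so the whole family is pixel-wise
proportional to the precursor by construction. Fragment isotope envelopes
use a carbon count scaled from the parent by the mass ratio, since only
the neutral-loss mass (not the fragment composition) is specified;
adequate because A+1 is carbon-dominated for CHO metabolites.

Matrix-cluster ions (a DHB-like k-mer series sharing one field) are
concentrated on the slide and *depleted, not absent*, over tissue
(fraction 0.25), reflecting absorption of the matrix coat by porous
tissue; they therefore anticorrelate with tissue metabolites. Eight
unstructured background metabolites span the whole tissue so that no
single metabolite dominates the pixel TIC — real peak-picked MALDI
datasets contain tens of thousands of features, and a near-empty scene
would make TIC normalization pathologically flatten the bait's own image.
One artifact feature is constant (500 a.u.) on the skin mask: perfect
co-occurrence with the bait, deliberately poor correlation.

Noise is multiplicative log-normal per pixel per feature (default
σ = 0.2), chosen over additive Gaussian because MALDI pixel-to-pixel
variation is scale-dependent and multiplicative noise keeps intensities
non-negative. The additive floor defaults to 0: the dataset models
peak-picked, S/N-thresholded intensities, where sub-noise signal is
already zeroed; the floor knob exists for emulating raw-like data. At
σ = 0 every derived ion correlates with its precursor at exactly 1 (to
float precision); recovery and band behavior at σ = 0.2 are checked over
20 seeds in the test suite.

What passing these tests does **not** show: robustness to isomeric
interference (two metabolites sharing a fragment m/z), nonlinear detector
saturation, spot-to-spot matrix crystallization effects, profile-mode
data, or spatial chromatic aberrations of real instruments. The scene's
regions are crisp rectangles of a small grid; real tissue boundaries are
soft and convoluted. Problem sizes in the suite (40 × 40 grids, ≤ 30
features, 20 replicate seeds; one 62,978-pixel single-feature grid for
subsampling arithmetic) were chosen so the whole suite exercises every
pipeline stage at desk scale.

## Degenerate inputs and numeric edges

- `pcc` on vectors shorter than 2, or of unequal length: error; zero
  variance: NaN flag, never an exception.
- Colocalization with no feature within bait ± tol: error naming the
  nearest feature. An all-constant bait window: every PCC undefined.
- Empty ion-image windows return zero images with a warning (not errors),
  since scanning a bait list should not abort on one absent ion.
- imzML round-trips preserve coordinates and the m/z axis losslessly
  (float64) and intensities to ≤ 1e-4 relative (float32 storage).
- Exact m/z collisions in the generator are merged (the axis must stay
  strictly ascending); near-collisions (< 1 mDa) only warn, since
  collision testing is a legitimate use.
- Recalibration with a single reference fits an offset only — a slope
  through one point would be unconstrained.
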