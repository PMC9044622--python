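# Methods

## Scope and model

`lminseg` segments one stained white blood cell (WBC) per image into
nucleus, whole cell and cytoplasm, using only the gray-level
distribution. The model assumption is an intensity ordering

    nucleus < cytoplasm < red blood cells ≤ background,

which holds for common stains (hematoxylin/eosin and rapid WBC
reagents) imaged on a bright field. Everything downstream follows from
that ordering; the package makes no shape or texture assumptions beyond
connectivity, so it generalizes across WBC types (lobed granulocyte
nuclei are handled by seeding from the largest nucleus component and by
hole filling).

## Nucleus threshold estimation

Images are converted to gray with BT.601 luminance weights and
normalized by the *dtype maximum* (255 or 65535), not min–max
stretched. The normalization choice matters: the initial value

    T_nc0 = Max(A)/n1 + Min(A)/n2,    n1, n2 ≥ 1 integers, default 3

is defined on the per-image extremes, and stretching would pin
Min(A) = 0, Max(A) = 1 on every image and erase the per-image
adaptation. With n1 = n2 = 3 and a near-zero minimum, T_nc0 sits near
1/3, which for bright-background smears lands between the nucleus and
cytoplasm intensity classes.

The histogram (default 256 bins over [0, 1]; counts always sum to the
pixel total) is searched for its first peak/valley pair:

1. Take the leading half of the bins and drop the maximal leading run
   of *flat* bins (counts ≤ 0 by default; dark stains leave an exactly
   empty tail below the nucleus class). A relative flatness tolerance
   is exposed as configuration.
2. Smooth the remaining counts with a Savitzky–Golay filter
   (window 11, polynomial order 3). These values are not stated by the
   threshold construction itself; they were chosen once to preserve the
   two-mode structure of 256-bin histograms, and the window shrinks
   automatically (with a warning) on short segments.
3. Scan the smoothed values in increasing knot order for the first
   local maximum x_c followed by the first local minimum x_{c+1}.
   Turning points are detected by neighbor comparison on the smoothed
   bin values, which equals sampling the cubic interpolating spline at
   its knots — the resolution thresholds are reported at — while being
   immune to spline ringing next to sharp count jumps; plateaus resolve
   to their smallest index. `interpolate_segment` exposes the dense
   cubic spline for plotting the fitted curve.
4. If no pair exists in the current segment, the segment end grows by
   ⌈0.1 · nbins⌉ bins and the search restarts, until the full histogram
   is exhausted.

The threshold ε_t is then placed by the branch rule with margin Er
(default 0.07, intensity units):

- validity (a): x_c < T_nc0 — the threshold must lie after the first
  peak. Pairs failing (a) are skipped in knot order; if none passes,
  ε_t falls back to T_nc0 (branch `"fallback"`, also used for images
  with no bimodal structure at all, e.g. constant images).
- (b) |T_nc0 − x_{c+1}| ≤ Er → ε_t = (T_nc0 + x_{c+1})/2.
- (c) |T_nc0 − x_{c+1}| > Er, T_nc0 > x_{c+1} → ε_t = (T_nc0 + x_{c+1} + Er)/2.
- (d) |T_nc0 − x_{c+1}| > Er, T_nc0 < x_{c+1} → ε_t = (T_nc0 + x_{c+1} − Er)/2.

Exact equality |T_nc0 − x_{c+1}| = Er is folded into (b); the three
formulas coincide there, so the tie-break is value-neutral. In every
branch ε_t lies within [min(T_nc0, x_{c+1}) − Er/2,
max(T_nc0, x_{c+1}) + Er/2].

Binarization takes f ≤ ε_t as nucleus; post-processing removes
8-connected components smaller than 0.5% of the image area (a size the
construction leaves open; 0.5% is small against any plausible nucleus)
and fills enclosed holes unconditionally, since pale chromatin gaps
inside lobes are still nucleus.

## Whole-cell segmentation (averaged multi-threshold reconstruction)

The cell interior is textured, so a single cut fragments it. Instead,
n thresholds (default n = 10)

    T_wbc_i = (Max(A) + T_nc0)/2 + er_i,
    er_i = a_l + i·Δh,  a_l = Min(A),  a_u = Max(A)/3,
    Δh = (a_u − a_l)/(n − 1),  i = 0 … n−1

produce floor-thresholded copies A_j (f ≤ T → T, else f); their mean
A_wbc equals mean_i max(f, T_i) per pixel, dominates the input
pointwise, and maps the whole cell to nearly the constant mean of the
thresholds while background pixels keep part of their spread. The step
values run *inclusively* from a_l to a_u — the endpoint-inclusive
Δh = (a_u − a_l)/(n−1) convention is the one that realizes the ordering
a_l = er_0 < … < er_{n−1} = a_u. Thresholds exceeding Max(A) (possible
whenever T_nc0 > Max(A)/3) are clipped with a warning; the clipped
copies saturate harmlessly and the family may then tie at Max(A).

A_wbc is binarized with Otsu's method — implemented as the exact
between-class-variance maximizer over a 256-bin histogram, dark class =
cell — then cleaned: a binary opening with a 2-px disk, small-object
removal, hole filling. The opening is the separation step: isolated
dark background pixels adjacent to the cell would otherwise be
8-connected to it and ride along with the seeded component; a 2-px disk
detaches those bridges while moving the true boundary by at most its
radius. The seed is the floored centroid of the largest nucleus
component (snapped to the nearest mask pixel for concave, multi-lobed
nuclei); the seeded 8-connected component is the WBC, and
cytoplasm = WBC ∧ ¬nucleus. Nucleus pixels outside the WBC indicate an
inconsistent mask pair and are clipped with a warning.

The Otsu threshold applied to A_wbc is reported per image and averaged
in batch summaries as "the WBC threshold". That reading of the batch
quantity is an interpretation — the averaging construction itself only
consumes the threshold — so cross-study comparisons of this number
should be made loosely.

## Touching cells

When an RBC touches the cell, the Otsu dark class merges them and the
seeded component overruns. Two standard fallbacks (delegated to
scikit-image; the bespoke parts are marker construction and retention)
cut the contact:

- **Watershed**: Otsu-binarize the gray image, fill holes, take the
  Euclidean distance transform, place markers at its local maxima with
  minimum separation max(distance)/2 — an automatic choice that scales
  with object size and needs no user-supplied count — and run
  marker-controlled watershed. The union of basins overlapping the
  nucleus is kept, so over-segmentation *of the cell* is harmless; only
  the basin boundary at the contact line matters.
- **SLIC**: superpixels (default n_segments = 100) on the color image
  when available, else on gray. Compactness defaults adapt to the
  input: 10 on the Lab-converted color path (lightness scale 0–100)
  and 1 on [0, 1] gray — scikit-image does not rescale gray input, and
  a fixed 10 there degenerates the superpixels to a rigid grid with no
  boundary adherence. A superpixel is retained if its pixel majority
  lies in the nucleus dilated by 3 px, or if its mean gray intensity is
  at most the cytoplasm estimate + 0.08, where the estimate is the mean
  intensity of a 10-px ring around the nucleus. Under-segmentation of
  the background is acceptable; the nucleus-seeded connected component
  of the retained union is the cell.

Both fallbacks guarantee a connected mask containing the nucleus seed.

## Synthetic data

`lminseg.synthfix` renders the study conditions: a 120 × 120 canvas
(the single-cell crop size of public WBC benchmarks; a 360 × 363 preset
mirrors the larger-field regime), a nucleus of 1–3 overlapping ellipses
near the center, a cytoplasm blob formed by dilating the nucleus hull
by ~11% of the image side, and annular RBC disks with pale centers.
Class means default to nucleus 0.20, cytoplasm 0.55, RBC 0.70,
background 0.90 — chosen so that T_nc0 ≈ 1/3 falls inside the
nucleus–cytoplasm valley, the regime reported for real stained smears —
with additive Gaussian noise of σ = 0.03 (constrained below half the
smallest inter-class gap) clipped to [0, 1]. Two regimes control RBC
placement: `separated` keeps ≥ 3 px clearance to the cell; `touching`
overlaps one RBC with the cytoplasm rim by ~2 px. A matching RGB
rendering (purple/pink/red) is generated with per-class colors scaled
so their BT.601 luminance equals the class gray mean, which makes the
color and gray paths consistent. All geometry and noise derive from one
integer seed; identical specs give bit-identical images.

What the generator does **not** emulate: chromatin and granule texture,
staining gradients, illumination falloff, defocus, JPEG artifacts,
overlapping multiple WBCs, and RBC color variability. Passing the
synthetic recovery tests therefore demonstrates the pipeline's logic —
threshold placement between classes, seeded extraction, contact
cutting — not robustness to optical nuisance on real smears; parameters
(Er, n1, n2, bins) are exposed precisely because real data may need
retuning.

## Evaluation

Pixel confusion counts take the ground truth as reference. Jaccard
JI = TP/(TP+FP+FN), Dice DSC = 2TP/(2TP+FP+FN) (so DSC = 2JI/(1+JI)),
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP).
Conventions: two empty masks score JI = DSC = 1 (with a warning);
ratios with zero denominators are *undefined* and excluded from batch
means with the exclusion count reported — zero-filling would bias
averages downward. The nucleus is scored against tri-level label 255,
the whole cell against 255 ∪ 128. Region contrast is reported as the
absolute difference of mean intensities over the nucleus and cytoplasm
masks.

## Numerical choices and degenerate inputs

- Problem sizes: the bundled verification suites use 50 separated and
  20 touching 120 × 120 images — large enough for stable medians while
  keeping the whole verification run in seconds.
- Histogram bins: 256, matching 8-bit sources; conservation
  Σcounts = M·N holds exactly.
- Constant images: no histogram structure → branch `"fallback"`,
  ε_t = T_nc0, with warnings; Otsu and the threshold family refuse
  constant images as degenerate.
- All-foreground/all-background binarizations warn rather than fail.
- Mask I/O is lossless PNG ({0, 255} for binary, {0, 128, 255}
  tri-level); tri-level reading snaps values to the nearest code and
  rejects files where any pixel is > 40 gray levels from every code.
- Determinism: the pipeline contains no unseeded randomness; SLIC and
  watershed as configured are deterministic, and the fixture generator
  is seeded end to end.

## Known limitations

- One WBC per image is assumed; a second (partial) cell in frame will
  be segmented too if it is the seeded component's neighbor, and size
  sanity warnings are the only guard.
- The averaging strategy needs the cell well separated from RBCs; the
  fallbacks need the cytoplasm distinguishable from RBC intensity (gray
  path) or color (SLIC path).
- Very low cytoplasm/background contrast defeats whole-cell
  segmentation while nucleus segmentation still succeeds.
- The branch rule presumes the first valley is the nucleus/cytoplasm
  boundary; heavily skewed histograms whose first valley is spurious
  are handled only by the validity check (a) and the fallback.
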