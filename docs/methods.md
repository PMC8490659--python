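# Methods

## Problem setting

A restraint team of three staff (role one controls the head, roles two
and three the patient's sides) restrains a patient dosed with UV
fluorescent dyes; a fourth participant per team plays the patient. Three
teams wear three different PPE sets; the scrubs-only team needs no
donning photograph, so it has three photo points instead of four. One
additional participant records physical observations on a dosed patient
and serves as the low-contact control. Full-body visible/UV photograph
pairs are taken at each photo point. The analysis question is where and
how much dye transferred, and how restraint compares with routine
observation contact.

All areas are raw pixel counts. The camera system is uncalibrated, so
units are arbitrary; counts are comparable between subjects only because
the imaging protocol (distance, pose, lighting) is fixed.

## Synthetic scene generator

No photographs from such evaluations are deposited, so the package
generates the study synthetically with per-pixel ground truth. The
generator's defaults encode the study layout: 12 participants in 3 teams
of 4, green dye sourced from the patient's hands/arms, blue from face and
upper torso, red delivered by two spray events at 150 mm and 300 mm
during the restraint episode (4.5 min), one control subject, photo stages
`pre_don / post_don / post_pi / post_doff` (three stages for the
scrubs-only team C).

**Bodies.** Each subject is the textured atlas silhouette under a smooth
random pose warp: a global shift (±1% of height) and scale (0.97–1.03)
plus a low-frequency random displacement field with ≈8 px amplitude at
the default 1024x512 raster. One pose per subject is reused across all
stages (a single frontal view per photo point); this keeps ground-truth
counts exactly additive between stages. Pose variation across stages of
one subject is therefore *not* emulated.

**Transfer.** Role-specific kernels place pixel-budgeted fuzzy blobs in
destination zones: role one receives the spit dye around the head plus
the face/torso dye on hands and arms; roles two and three receive the
hand/arm dye in hands, arms (axilla) and lower-torso zones; role two
additionally catches a small amount of spit. Spray distance scales the
droplet spread linearly (the far 300 mm event is wider and sparser); the
spray geometry itself is a modelling choice, as only the distances are
given. A faint blue pre-donning baseline (25 px at reference scale) on
the hands emulates the fluorescence of cleansing wipes. Contamination
accumulates by union across the episode; at `post_doff` each pixel
survives with probability `1 − efficiency(zone)`, with cleansing
efficiency 0.95 for PPE-covered zones but 0.70 for hands and 0.85 for
arms, where cleansing is observed to be hardest. Dye masks are kept
pairwise disjoint (dyes claim pixels in design order) so per-dye counts
are exact. The control subject receives a small hands-only transfer
(84 px at reference scale) sized so the ground-truth
staff-mean-to-control ratio sits near 23, the regime of interest.

**Rendering and artefacts.** The UV frame paints each dye mask in its
nominal sRGB colour on a dark booth background and faint body tone. The
default artefact model renders 10% of contaminated pixels near-white
(overexposure), adds glove/goggle confounder patches whose colour is
deliberately within the blue dye's ΔE tolerance, and Gaussian sensor
noise (σ = 3 intensity units). Confounder patches are also emitted as the
exclusion mask a human analyst would draw. Deliberately not emulated:
specular highlights, garment folds, shadows, JPEG artefacts and
illumination gradients — so passing tests show the algorithmic chain is
correct on its stated model, not that it is robust to every property of
real photographs.

Randomness is split per subject via `SeedSequence([seed, subject_index])`
(render streams add stage indices), so regenerating one photograph never
shifts another.

## Registration

Subjects are registered to a common template (template-based rather than
pairwise-across-stages registration; the alternative would difference
consecutive stages directly but cannot produce atlas-space maps). The
estimate composes (1) a diagonal affine from silhouette moments
(centroid and per-axis standard deviation) with (2) TV-L1 optical flow
computed at half resolution and upsampled — a coarse-to-fine variational
method standing in for the commercial deformable-registration tool such
studies use. The template carries a fixed smooth intensity texture so
flow is constrained inside the silhouette, not only at its edge.

Conventions: 0-based (row, col) coordinates, origin top-left. The stored
field is sampled on the subject grid with
`template_location = x − d(x)`; forward landmark transfer solves this by
fixed-point iteration. Registration residual (mean squared intensity
error on [0,1] images over the union of foregrounds, bound 0.01 by
default) above the bound flags the field with a `UserWarning` — never
silently. Zones are propagated by warping the combined label raster with
nearest-neighbour interpolation, which preserves disjointness by
construction. The four thorax zones split the thorax block at the
vertical midline and a configurable horizontal fraction (default 0.5);
the split geometry is a package choice, as the nine-region list does not
define it.

On the default synthetic study the propagated zones reach mean Dice
≈ 0.985 against the true warped zones; the acceptance floor is 0.9.

## Segmentation

sRGB → CIE L\*a\*b\* under D65; distances are Euclidean ΔE (CIE76) — the
simplest defensible metric once the colour space is fixed. Dominant
colours come from k-means (k-means++ seeding, fixed seed, 10 restarts)
over the reference photograph's L\*a\*b\* pixels, with k = number of
dyes + 2 background clusters; clusters are matched to dye names by
nearest nominal colour, remaining clusters become background references.
Because the spit dye only appears during the episode, the dye-reference
frame is the patient's first-stage render plus a red spray swatch, so all
three dye colours are measurable from one photograph. Explicit dye
references can be supplied instead (`extract_references=False` uses the
design's nominal colours), which is also the path for scenes with no
visible contamination to cluster.

Assignment rules, in priority order: excluded (label 254) >
overexposed, L\* > 97 (label 255) > nearest centroid, where a dye wins
only when strictly nearer than every background centroid and within its
tolerance (default ΔE = 25). Ties between a dye and a background
centroid resolve to background (the lower class index); ties among dyes
to the lower dye index. Overexposed pixels are never assigned to the
blue dye, which they otherwise resemble; they are reported as a separate
ambiguous class. All thresholds are config-exposed; the defaults are
package choices, as no assignment thresholds are inherited.

## Quantification

Zonal areas are dye-pixel counts within each propagated zone; ambiguous
and excluded pixels are tabulated separately in the QC table.
Accumulation series order stages per design; the residual flag marks
subjects whose post-doffing total exceeds 10% of their post-restraint
total (the persistence observation is qualitative, so the threshold is a
package default, config-exposed). The per-zone residual summary
additionally requires a 20 px floor (at the reference raster, scaled
with image area) so that Bernoulli cleansing noise on near-empty zones
cannot flag. Team maps sum staff areas per (team, zone) and divide by
the per-dye maximum over all teams and zones; role maps aggregate
post-restraint areas across teams per (role, zone) with the same per-dye
normalisation — each contamination type is treated separately, and an
all-zero dye maps to all zeros rather than dividing by zero. Patient
rows are excluded from both maps (the source would dominate the scale).

The contamination ratio divides the staff post-restraint mean by the
control subject's post-procedure total; a zero control total returns an
explicit `undefined` status. For the totals behind the ratio the
pipeline includes ambiguous/overexposed pixels as contamination of
unknown dye (config `count_overexposed_in_totals`, on by default):
saturated pixels are contaminated — only their dye identity is uncertain
— and omitting them would bias every total low, with the small control
subject hit hardest by the binomial noise. Baseline subtraction of the
pre-donning wipe fluorescence from accumulation series is available but
off by default, since whether the original accumulation graphs subtract
it is not stated.

## Problem sizes and numerical choices

The default raster is 1024x512 (portrait, head up); deposit budgets and
length scales are defined at that raster and scale with image area and
its square root respectively, so reduced-size runs are geometrically
similar. Unit tests run the study at 256x128; the acceptance checks run
the full default raster (about a minute end to end on one CPU, most of
it optical flow). Degenerate inputs are handled explicitly: empty
foregrounds and non-finite deformation fields raise, unreadable
photographs fail only their subject (the run continues and the manifest
records the failure), and k-means on an image with fewer distinct
colours than k warns about duplicate centroids.

## Known limitations

- Single frontal view; no back/side atlas, no multi-view fusion.
- Schematic bodies and additive colour rendering; robustness to
  photographic nuisance (shadows, folds, highlights) is untested by
  design.
- CIE76 ΔE underweights perceptual differences near saturation compared
  with CIEDE2000; with the well-separated dye colours used here the
  choice is immaterial, but borderline dyes would warrant the better
  metric.
- Registration accuracy is validated for smooth pose warps up to ~8 px
  plus modest affine; gross pose changes (raised arms) are out of scope.
- Areas are 2-D projections in pixels; no surface-area or volume
  interpretation is valid.
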