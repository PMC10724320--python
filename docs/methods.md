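# Methods

## Scope and model

The package quantifies nuclear HIF immunoreactivity in epithelium: the
fraction of counted epithelial nuclei whose chromogen-granule staining
falls in categories 2–4, compared across three specimen groups (primary
pterygium, recurrent pterygium, healthy conjunctiva) for two markers
(HIF1α, HIF2α).  A second, independent pipeline measures vessel-pixel
fraction in color photographs.  Both pipelines are exercised end to end
on synthetic images whose ground truth is known exactly.

## Synthetic data generator

The generator emulates AEC-stained, hematoxylin-counterstained
conjunctival epithelium at 0.25 µm/pixel (≈400× magnification),
configurable:

- **Cohort structure.** Defaults mirror the study arms: HIF1α 55/6/20
  specimens (primary/recurrent/control) with group positivity means
  (11, 18, 46)% and dispersions (20, 36, 30)%; HIF2α 84/28/20 with
  means (38, 21, 66)% and dispersions (31, 27, 31)%.  One field per
  specimen by default (the field count per specimen is not fixed by the
  protocol; it is configurable).
- **Per-specimen positivity** is drawn from a truncated normal on
  [0, 100].  The location parameter is solved numerically so that the
  *mean of the truncated law* equals the requested group mean: plain
  truncation of N(11, 20²) at zero would shift the mean to ≈21 and make
  every group systematically miss its target.  Dispersion is the scale
  of the underlying normal, so the realized SD is somewhat smaller than
  nominal near the boundaries — a conservative choice for
  standard-error bounds.
- **Fields.** 384×384 px (96 µm), 22–32 non-overlapping nuclei of radius
  3.8–5.0 µm, goblet fraction 0.1.  Each non-goblet nucleus is positive
  with probability equal to the specimen's drawn positivity; negatives
  get pattern 5 or 1, positives pattern 2, 3 or 4 (uniform).  "Few"
  counts are 1–4, "numerous" 5–8 small or 5–7 large (packing-limited).
  Granule diameters are uniform over [1.2, 1.6] µm (small) and
  (1.6, 2.2] µm (large).  The stored per-specimen truth is the
  *realized* count ratio, so the bookkeeping identity
  `positivity = 100·n_positive/n_non_goblet` holds exactly.  If a
  sampled granule set cannot be packed, the nucleus grows by 8% steps;
  if a nucleus cannot be placed the field keeps fewer nuclei (truth
  always reflects the rendered scene).
- **Rendering.** Anti-aliased disks over a pale background; the
  counterstain is blue-dominant, the chromogen red-dominant, goblet
  cells are a pale mucin blob with faint cytoplasmic tint and **no**
  counterstained nucleus — so counterstain-based detection never counts
  them, mirroring the manual exclusion rule.  Each granule is sharp in
  exactly one focal plane (3 by default) and Gaussian-blurred elsewhere
  (σ = 2 px per plane of defocus).  Additive Gaussian noise, SD 2/255.
- **Vessel photographs.** Smooth random-walk strokes of width 3 px in
  red over a pale background; strokes are added until the binary mask
  fraction within the ROI reaches the target (each stroke adds ≈1%, so
  the realized fraction is within ±2 points of the target or an error
  is raised).  Determinism: all draws derive from
  `SeedSequence([seed, specimen_index])`.

What the generator does **not** emulate: stromal tissue, section and
staining artifacts, uneven illumination, nucleus shape irregularity,
chromatin texture, overlapping nuclei in depth, and out-of-plane
nuclei.  Passing tests therefore demonstrate correctness of the
measurement chain under its stated assumptions, not robustness to the
full variability of real histology.

## Focus fusion

Per-pixel *selection* of the plane maximizing the variance of the
Laplacian in a 9×9 window (ties → lowest plane index).  Selection, not
blending, guarantees every fused pixel exists in some input plane and
preserves granule contrast for counting.  Planes are assumed aligned.

## Granule scoring

- **Nuclei**: blueness (B − R) > 25, hole filling, distance-transform
  watershed (peak separation 3 µm), area filter 15–250 µm².
- **Granules**: redness (R − B) > 30 within the nucleus mask (midway
  between counterstain and chromogen levels; faint cytoplasmic wash
  stays well below).  Component areas are measured **sub-pixel**: since
  chromogen coverage is linear in redness, each component's area is the
  sum of the normalized redness ramp over the component plus a 2 px
  ring (labels expanded without overlap), with the baseline taken from
  granule-free nucleus pixels.  This keeps equivalent-diameter errors
  near ±0.03 µm, which matters because the small/large boundary at
  1.6 µm decides positivity for pattern-1 vs pattern-3 nuclei.
- **Equivalent circular diameter** `2·√(area/π)·µm/px` is used for size
  classification (the protocol does not state whether diameters are
  longest-axis or equivalent; equivalent diameter is the standard
  image-analysis reading and is recorded here as an interpretation).
- **Boundaries**: [1.2, 1.6] µm → small; (1.6, 2.2] µm → large
  (1.6 exactly is small); < 1.2 µm ignored as noise; > 2.2 µm flagged
  `over_range` and ignored by default (strict reading of the defined
  intervals) with a config switch conceptually available via the size
  thresholds.
- **Few vs numerous**: the taxonomy does not quantify "few"; the
  default cut is `few_max = 4` (≤4 = few), exposed in the config.
- **Mixed nuclei**: any large granule dominates (the taxonomy defines
  pure patterns only; dominance by the stronger signal is the least
  surprising completion).
- **Positivity**: category ≥ 2; goblet-flagged nuclei excluded from
  numerator and denominator; a field with zero countable nuclei is an
  error (undefined percentage).

## Vessel density

Pipeline: green-channel extraction with polarity inversion (red vessels
absorb green, so inversion renders them bright) → high-pass (image minus
a σ = 20 px Gaussian background estimated by *normalized convolution
restricted to the ROI*, so pixels outside the ROI can never influence
the result) → linear stretch clipped at ROI percentiles 1/98 → h-dome →
min–max stretch → Otsu threshold within the ROI → fraction.

`hdome(f, h) = f − R^δ_f(f − h)` with 8-connectivity; outputs lie in
[0, h] and are invariant to intensity offsets.  Note that a constant
image is a single global plateau, so its dome is uniformly *h* (the
defining formula, verified against an iterative geodesic-dilation
fixpoint to machine precision).

Default `h = 0.5` of the stretched dynamic range.  This was chosen
because after high-pass filtering, vessel brightness varies along each
connected vessel by an amount comparable to the vessel/background
contrast; reconstruction swallows every vessel segment more than *h*
below its connected ridge maximum, so a small *h* (e.g. 0.2) retains
only the crests and underestimates density several-fold.  With h = 0.5
and the percentile-clipped stretch, recovered fractions on synthetic
images match truth to < 0.01 across densities 0.10–0.30.  Both the
blur scale and *h* are exposed parameters.

A noise floor (99.9th ROI percentile of the high-pass residual < 0.05)
declares a field vessel-free before any stretch, because stretching a
noise-only residual to full range would hand the threshold pure noise.

## Statistics

- Group summaries: mean and sample SD (n − 1).
- Tamhane T2: pairwise Welch t, Welch–Satterthwaite df, two-sided p,
  Šidák family adjustment `1 − (1 − p)^m` over all m pairs (Šidák, not
  Bonferroni — that is what distinguishes T2), significance strictly
  `p_adj < α`.  Degenerate pairs with zero pooled variance: p = 1 when
  means are equal, p floored at 1e−300 otherwise.
- Null behavior was simulated (2,000 cohorts, normal data, equal means,
  n = 55/6/20, SDs 20/36/30): family-wise error ≈ 3–4% at α = 0.05 —
  conservative, as expected for a Šidák-based all-pairs procedure on
  positively correlated contrasts.  Normal draws are used for this
  check because the procedure's error rate is defined under normality;
  power and recovery simulations use the cohort (truncated) model.
- Report arithmetic: positive-specimen percentages round half-up to
  integers; ratios and summary numbers round half-up to two significant
  figures, matching the reporting convention of the summary tables.
- Correlations (Pearson + Spearman) are provided for marker-vs-marker
  and marker-vs-vessel-density analyses; no particular method is
  canonical for these, so both are reported.

## Problem sizes

The shipped simulations use: 384×384 px fields with 22–32 nuclei
(one field per specimen); full cohorts of 81 (HIF1α) and 132 (HIF2α)
specimens for end-to-end recovery; 2,000 replicates for the null
family-wise error rate and 500 for power; 50 random 32×32 images for
the h-dome oracle; 384×384 vessel photographs at true fractions
0.10–0.30.  These sizes give stable estimates (binomial SE ≈ 0.5% at
2,000 replicates) while keeping a full run to minutes on one CPU.

## Known limitations

- Nucleus and goblet geometry is circular; real epithelial nuclei are
  elliptical and crowded, and goblet identification in real images
  would need either annotation (supported via CSV override) or a
  dedicated detector.
- The fusion equivalence to the original focus-stacking software is
  functional ("granules from all focus levels appear in one image"),
  not algorithmic — that software's internals are not documented.
- The group means/SDs used by the generator describe distributions;
  individual real specimens are not reproducible, so cohort-level
  checks are parameter-recovery checks, not re-analyses of tissue.
- Sub-pixel area measurement assumes chromogen response is linear in
  coverage, which holds for the renderer and approximately for real
  stain at low optical density.
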