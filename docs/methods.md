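# Methods

`myoagg` re-implements, as importable and tested code, an image-based
quantification of huntingtin (HTT) aggregation in skeletal muscle together
with the morphometry and group statistics that surround it. Because no
imaging data for this workflow are publicly available, the package ships a
synthetic-section generator with exact ground truth; every claim the test
suite makes is a claim about recovery of known truth or agreement with an
independent oracle.

## Aggregation quantification (roiquant)

The quantification follows fixed-threshold particle analysis as practised
in ImageJ:

* **Thresholds.** DAPI at intensity 90, S830 (aggregated-HTT antibody) at
  50, on 8-bit images. The rule is "pixels below the threshold are
  excluded", which we read as *keep intensity ≥ threshold*: a pixel at
  exactly 90 is nuclear. Boundary tests pin this semantics.
* **Objects.** Connected components of the thresholded mask,
  8-neighbour adjacency by default (the particle-analysis convention);
  4-neighbour is available in `QuantConfig`.
* **Debris.** DAPI objects with fewer than 25 pixels are debris, not
  nuclei; "fewer than" is strict, so a 25-pixel object is kept. No minimum
  is imposed on S830 objects by default (`s830_min_pixels = 1`,
  configurable and echoed in run manifests).
* **Compartment partition.** The debris-filtered DAPI mask partitions
  S830 foreground pixels into intra- and extra-nuclear counts; the two
  always sum to the S830 foreground total (a property asserted on every
  input in the suite).
* **Object-level assignment.** Pixel counting does not dictate what to do
  with an S830 *object* that straddles a nucleus border. Two rules are
  implemented: `pixel-partition` (default) cuts the object at the border
  and re-labels each side, conserving pixel totals; `majority` assigns the
  whole object to the side holding ≥ 50 % of its pixels (ties → nuclear,
  logged). Both are exercised in tests; on simulated data without
  straddling objects they agree exactly.
* **Per-ROI statistics.** Nucleus count and mean size, inclusion count and
  mean size, % S830 signal co-localized with DAPI, % inclusions nuclear,
  nuclear-inclusion count and mean size, and % nuclei containing an
  inclusion (a nucleus counts if ≥ 1 nuclear-inclusion pixel falls in its
  pixel set — an automated stand-in for what was originally a manual
  count). Statistics whose denominator is zero are emitted as missing
  (NaN), never as 0, so they drop out of per-mouse means instead of
  biasing them.
* **Sampling.** A deterministic 3×3 grid of equal boxes centred in the
  tissue bounding box provides nine ROIs per section; two sections per
  mouse give 18 ROIs, averaged per mouse before any group test.

## Fibre morphometry (morpho)

The original analysis used a proprietary rule set; this module
standardises on a conventional, fully reproducible surrogate:

1. Otsu threshold (or fixed) extracts the laminin-positive boundary band.
2. Fibre interiors are the complement, smoothed by morphological opening
   (radius `smoothing_radius_px`, default 1).
3. Watershed on the interior distance transform separates merged fibres.
   Markers are per-component distance *cores* (`distance >
   split_core_ratio × max`, default 0.6): superlevel sets of the concave
   distance function are connected on convex regions, so convex fibres
   are never split, while dumbbell-shaped merges produce two cores.
4. Each label is then expanded by `band_halfwidth_px` (default 2);
   expansion stops at the midline between neighbours, so adjacent fibres
   share the boundary band and sizes are not biased low by it.
5. Acceptance rules: area in [300, 30000] px, circularity ≥ 0.4, solidity
   ≥ 0.85, no image-edge contact (judged on the pre-expansion support).
   Rejected fibres are kept in the output with a reason, never dropped.

**Lesser diameter** is the minimum Feret (caliper) width, the standard
myopathology size measure because it is robust to oblique sectioning. The
implementation scans convex-hull edge normals, which is exact: the
minimum width of a convex polygon is attained with a caliper jaw flush
against a hull edge. Tests compare it against an exhaustive
projection-width sweep and assert rigid-motion invariance. On noiseless
synthetic tessellations, segmentation followed by `min_feret` recovers
interior-fibre true diameters within 2 px for ≥ 95 % of fibres; absolute
fibre counts per section are deliberately not a reproduction target, only
distributional properties are.

## The dilution model (dilution)

Per-mass assays (ligand-capture ELISA) and per-nucleus image statistics
can disagree when treatment changes the amount of tissue per nucleus. The
model is

    per_mass_signal = nuclei_per_mg / h × (1 − satellite_fraction)
                      × load_per_nucleus

with hypertrophy factor `h` (fibre-diameter multiplier; at constant
myonuclei per fibre the nuclear density per unit area falls as `1/h²`)
and `satellite_fraction` the aggregate-free satellite-cell share of
nuclei. Per-nucleus load is mapped from image statistics as
`mean_nuclear_inclusion_px × pct_nuclei_with_inclusions / 100`, using
only the two per-nucleus panel quantities. `reconcile` classifies a
treated/vehicle experiment from the per-mass and per-nucleus ratios:
both below `1 − tol` → disease-modifying; per-mass below but per-nucleus
not → dilution; otherwise mixed. `tol` defaults to 0.1 — a design choice,
exposed in the interface, reflecting that ~10 % shifts are within the
noise of both readouts at these sample sizes. Whether ELISA capture is
linear in inclusion volume is an assumption of the model, not something
the package can test.

## Group statistics (stats)

* **Two-way ANOVA** (genotype × treatment or treatment × age), Type-II
  sums of squares with the interaction included — the common convention
  for factorial designs without an interaction focus; balanced designs
  partition the total SS exactly and are checked against the textbook
  closed form. Model fitting is statsmodels OLS; the module owns cell
  validation (≥ 2 observations per cell, empty cells named in errors) and
  the degenerate case of zero residual variance (F = 0, p = 1).
* **Bonferroni** post-hoc adjustment, `min(1, m·p)`.
* **Grubbs screening**, iterative two-sided, one removal per pass,
  `G = max|x − x̄|/s` against the t-based critical value. Intended use is
  per genotype × treatment cell, so genotype effects cannot masquerade as
  outliers. Two same-side planted outliers are found iteratively;
  symmetric pairs can mask each other — an inherent property of the test,
  not a defect.
* **Kaplan–Meier / log-rank** via lifelines, using the hypergeometric
  variance without continuity correction (the Mantel-Cox convention).
  Fixtures are checked against a hand-tabulated observed-minus-expected
  event table and a brute-force product-limit estimator; the null
  rejection rate is calibrated (≈ 0.05) over 1000 simulated cohorts.
* **Gene-retention filter**: keep genes with count ≥ 2 in ≥ 10 samples
  (of 79 in the original design). Idempotent; retained count monotone
  non-increasing in both parameters. Downstream differential expression
  and network analysis are out of scope (established packages exist).
* **qPCR normalization**: per-sample target copies divided by the
  geometric mean of three housekeeping genes; group fold change relative
  to a reference group.

## The synthetic-section generator (simgen)

What it emulates, and how:

* **Fibres** are convex cells of a Voronoi tessellation seeded from a
  jittered square lattice (spacing = fibre diameter, jitter = diameter
  CV). The laminin channel draws a bright boundary band of fixed width;
  ground truth stores each cell polygon and its true minimum caliper
  width. The per-pixel fibre raster is the exact digital Voronoi of the
  cell seeds.
* **Nuclei** are non-overlapping discs placed within 2 px of fibre
  boundaries (sarcolemmal myonuclei; uniform placement is a switch). The
  expected count ties to the analytic fibre density
  (`image area / spacing²`) at a configured rate per 100 fibres, so a
  hypertrophy factor `h` scales nuclear density by exactly `1/h²`.
* **Inclusions** are discs with lognormal radii (compartment-specific
  medians, common log-sd). Each is nuclear with probability
  `nuclear_inclusion_prob` (placed wholly inside one nucleus) or
  cytoplasmic (intersecting no nucleus). A radius is drawn once per
  inclusion and only positions are retried, so placement rejection cannot
  truncate the size distribution. The per-ROI inclusion mean is tied to
  the realized nucleus count relative to the h = 1 baseline — marginally
  `inclusion_count_mean / h²`, but with the per-nucleus rate held exactly
  constant ROI by ROI, so a sparse-nuclei draw never demands an
  infeasible number of nuclear inclusions. This fixed per-nucleus process
  under `1/h²` nuclear thinning is precisely the "dilution without
  disease modification" condition.
* **Separability.** All objects are kept mutually non-adjacent under
  8-connectivity and foreground intensities (default 200/180) strictly
  exceed the quantification thresholds while background noise (uniform
  integers, default ≤ 40) stays strictly below them. Thresholding
  therefore recovers ground-truth masks *exactly*, which is what makes
  count, size and partition recovery tests exact rather than
  approximate. An optional Gaussian blur (default off) breaks this
  separability when harder images are wanted.
* **Count draws** are Poisson, truncated at +6σ (a vanishing share of
  the distribution) to keep freak draws out of the disc-packing regime;
  genuinely infeasible requests raise an overcrowding error rather than
  silently degrade.
* **Survival cohorts** are exponential with per-group hazards and
  administrative censoring; **count matrices** mix negative-binomial
  expressed genes (mean ≥ 5) with strictly-0/1 unexpressed genes so the
  retention filter's truth set is known by construction.

What it does **not** emulate: point-spread functions, uneven
illumination, autofluorescence, section folds, fibre-type heterogeneity,
3-D structure, or correlated noise. Passing tests therefore demonstrate
correctness of the measurement code and the internal consistency of the
dilution argument on idealized tissue — not robustness to real
microscopy artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run on 160×160 px fields at 0.5 µm/px
with ~20 µm fibres (a few dozen nuclei and inclusions per ROI), chosen so
that per-nucleus statistics match a full-size field at a fraction of the
cost; the full-size default (1024×1024 at 0.31 µm/px) is a configurable
placeholder, since the original acquisition geometry is not recoverable.
The demo cohort uses 8 mice and 6 ROIs per arm, hypertrophy h = 1.3.
Monte-Carlo checks use 50–1000 seeds depending on the quantity; per-ROI
seeds are spawned from the run seed via `numpy` seed sequences and stay
below 2³¹. The "unchanged-or-larger" inclusion-size check in the demo
report uses the same 10 % tolerance as the verdict rule, since the size
ratio is a noisy estimate whose expectation is exactly 1 under pure
hypertrophy.

## Known limitations

* The fibre-morphometry rule set is a reproducible surrogate for an
  unrecoverable proprietary pipeline; absolute counts will differ from
  the original instrument.
* The per-nucleus load proxy ignores cytoplasmic aggregate and treats
  inclusion pixel area as proportional to aggregate content.
* The ANOVA on longitudinal measures reproduces the stated
  between-subject design; it does not add a repeated-measures correction.
* Grubbs screening is vulnerable to masking by symmetric outlier pairs.
* The gene-filter check against the deposited RNA-seq matrix requires
  downloading that matrix (see `tests/test_acceptance.py`); it cannot run
  self-contained.
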