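# Methods

## Model

All analyses operate on a catalogue of co-registered binary expression
domains: one boolean volume per gene (per family, per stage) on a
shared voxel grid, plus an embryo foreground mask and an optional
anatomy label volume. The grid is indexed `(plane, row, column)` with
origin 0; two grids are interchangeable iff their shapes and voxel
sizes agree elementwise. Anisotropic voxels are supported; every
volume statistic is available both as a voxel count and in µm³
(count × product of voxel edge lengths).

The statistics are pure set algebra over these voxel sets:

- **Occupancy**: `occ(v) = Σ_g mask_g(v)`, the number of family
  members expressed at voxel v. Conservation,
  `Σ_v occ(v) = Σ_g |domain_g|`, holds exactly and is asserted in the
  tests.
- **ROHOs**: connected components of `{v : occ(v) ≥ t}`. The
  published thresholds ship as defaults (Wnt: 5 at E9.5, 4 at E10.5,
  5 at E11.5; Fzd: 4 at all stages; occupancy peaks at Wnt ≥ 7,
  Fzd ≥ 6) and are plain configuration.
- **Gene set of a region**: every gene whose domain intersects at
  least one voxel of the region (intersect-any-voxel rule), with the
  per-gene overlap voxel count retained.
- **Unique / zero territories**: `unique_g = domain_g ∩ {occ = 1}`;
  `zero = embryo ∩ {occ = 0}`. With domains clipped to the embryo,
  `|zero| + |occ=1| + |occ≥2| = |embryo|` exactly.
- **Jaccard index**: `JI = |A∩B| / |A∪B|`. Intersection tables can be
  row-normalised (`|i∩j|/|i|`) or column-normalised (`|i∩j|/|j|`);
  per-label total volumes are written into every exported table so
  absolute values are recoverable.
- **Networks**: nodes are genes, edges are pairs with `JI ≥ τ`.

## Numerical and design choices

**Connectivity.** ROHO components use 26-connectivity by default (6 and
18 available). The source analyses treated high-occupancy territories
as visually contiguous across serial sections without stating a
connectivity; 26 is the most inclusive standard choice, and the choice
is recorded in the result objects.

**Minimum region size.** Components smaller than `min_voxels = 5` are
discarded by default. Subtraction-derived territories are sensitive to
per-gene binarization noise, so single-voxel components are more likely
noise than biology; the floor is configurable and logged.

**Region labelling.** Components are numbered 1..n by decreasing voxel
count, ties broken by lexicographic bounding-box origin. The original
inventories (W1–W36, F1–F39) were numbered anatomically by hand; a
deterministic rule replaces that, and anatomical naming is left to the
user. Automated matching against the hand-curated inventory is out of
scope.

**Top-k network threshold.** "The k genes most similar to other genes"
is operationalised as: score each gene by its maximum off-diagonal JI,
and return the k-th largest score. A gene keeps an edge at threshold τ
iff its score ≥ τ, so this is precisely the largest threshold retaining
≥ k connected genes; ties keep every tied gene (the retained count is
recorded). Alternatives (mean JI, degree at fixed τ) were considered;
max-JI is the only one that makes the returned threshold exact rather
than approximate, but reproductions of published network topologies
remain approximate because the original criterion was not specified.

**Empty-domain conventions.** JI of two empty domains is defined as 0
(not NaN) so tables stay finite — undetected genes (zero-volume
domains) are legal catalogue members. Row/column normalisation by a
zero volume likewise yields 0. The fraction-outside statistic
(`coverage_outside`) and region profiles are *errors* on an empty
numerator-defining mask, since 0/0 there would silently mean "nothing
to report".

**Full-grid vs embryo-masked statistics.** Pairwise statistics are
computed over the full grid; mapped domains lie inside the embryo by
construction, so the two conventions coincide on clean data. A
`restrict_to_embryo` mode first intersects every mask with the
foreground and logs any change — a nonzero change flags stray voxels.

**Binarization.** Input volumes are binarized strictly as
`value > 0`. Thresholding of continuous signal into expressed /
not-detected is upstream of this package and is where the noise
sensitivity of subtraction-based territories originates; we document
it, we do not model it beyond the speckle option below.

## The synthetic embryo generator

The generator emulates the *statistical* structure the analysis
assumes, not embryo anatomy:

- **Embryo mask**: one filled ellipsoid with semi-axes drawn uniformly
  from 85–95% of each half-extent and a ≤ 2% centre jitter, giving a
  foreground fraction of roughly 0.32–0.45 (contract: 0.20–0.60) on
  any grid with ≥ 4 voxels per axis. Connected by construction.
- **Hotspots**: K centres rejection-sampled inside the mask at a
  minimum pairwise separation (budget 1000 tries per centre; failure
  is an error reporting how many were placed, never silent
  degradation). Each family with at least `genes_per_hotspot` members
  contributes exactly that many genes (drawn without replacement) to
  each hotspot; all assigned genes share the same sphere, so the
  hotspot is an occupancy plateau at the planted level.
- **Per-gene domains**: union of assigned hotspot spheres, private
  spheres, and optional speckle (independent per-voxel true-flips
  inside the embryo at `speckle_rate`, default 0 — a stand-in for
  binarization/mapping noise, not a claim about real data), all
  clipped to the embryo mask. Spheres are Euclidean balls in voxel
  units; anisotropy is ignored during generation.
- **Strict-recovery geometry**: requires
  `min_separation > 2 (r_hotspot + r_private)` and additionally keeps
  private spheres clear of hotspot spheres and of each other. Under
  these conditions thresholding at `t = genes_per_hotspot` provably
  yields exactly K components with the planted gene sets and peak
  occupancy — the generator's reason to exist.
- **Paralogue pairs**: core and private voxel *sets* drawn without
  replacement from embryo voxels (scattered, not blobs), making
  `JI = core/(core + p_a + p_b)` exact by integer arithmetic.
- **Reporter**: union of selected hotspot spheres, optionally dilated
  (6-connected structuring element, one iteration per voxel of
  dilation), clipped to the embryo — a read-out concentrated on
  co-expression hotspots.
- **Determinism**: one seed sequence per catalogue; hotspot placement
  and gene assignment use the parent stream, per-gene streams are
  spawned in label order. Identical configuration ⇒ bitwise-identical
  catalogues.

Default composition mirrors the real catalogue's scale: 19 Wnt-like
and 10 Fzd-like genes, five hotspots of five genes each, two private
spheres per gene, no speckle.

What the phantom does **not** emulate: realistic embryo geometry,
registration error fields, stage-to-stage pattern dynamics, or the
spatial autocorrelation of real expression boundaries. Passing
recovery tests therefore demonstrates correctness of the set-algebra
machinery, not robustness to real imaging artefacts.

## Verification strategy and problem sizes

Every statistic is verified against independent per-voxel brute-force
Python loops on 8³ grids (100 random catalogues of 5–10 genes in the
test suite; comparisons are exact, tolerance 0 — all arithmetic is
integer ratios). Conservation/partition identities are asserted on
random and phantom catalogues. Hotspot recovery runs K ∈ {1, 3, 5}
across 20 seeds each on 36×48×36 grids with 8 genes — small enough to
keep the whole suite around a few seconds while exercising every code
path at realistic occupancy levels; a speckle-robustness variant checks
that the default 5-voxel region floor absorbs 0.1% noise. Network
threshold selection is checked against an exhaustive scan over all
distinct JI values on 50 random 10-gene tables.

`scripts/acceptance.py` re-measures all of the above from scratch at a
caller-supplied seed and additionally runs the full pipeline on a
three-hotspot, 29-gene phantom, reporting the detected region count,
maximum occupancy, zero-expression fraction and selected network
threshold.

## Known limitations

- Published whole-embryo statistics (per-gene occupancy percentages,
  paralogue JI tables) were computed on deposited mapped volumes in
  Woolz format; reproducing them requires downloading and converting
  that data, which this package supports (NIfTI/TIFF ingestion) but
  does not bundle.
- The occupancy/ROHO machinery is exact set algebra; any disagreement
  with published region counts would stem from the unstated
  connectivity, minimum-size and delimitation conventions of the
  original manual analysis, not from voxel counting.
- GraphML export carries JI weights at full precision; layout and
  visual grouping of network nodes are deliberately left to external
  viewers.
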