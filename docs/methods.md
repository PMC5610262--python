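# Methods

`isletq` quantifies multicolor lineage-tracing experiments in the zebrafish
primary islet: which beta-cells belong to one clone, how many beta-cells an
islet holds, which cells respond to glucose, and how all of this is polarized
along the anterior–posterior (A/P) axis. This note records the models behind
each stage, the parameters that matter, and the choices made where the design
was genuinely open.

## Clonal analysis of color barcodes

A multicassette Cre-lox transgene gives every beta-cell a heritable RGB
signature: each cassette independently stays red or recombines to green or
blue, and the per-cassette expression mix is fixed in the founder and
inherited by its descendants. The analysis receives, per cell, the ROI mean
and standard deviation of each channel plus the ROI pixel count `n`.

Processing steps, in order:

1. **Background subtraction.** The green and blue means of ≥ 3 unlabeled
   reference cells are averaged and subtracted (clamped at zero) from every
   labeled cell. *The red channel is deliberately not subtracted* — it is the
   default, always-on channel of the transgene and its background reference
   is not part of the acquisition design. This asymmetry is intentional and
   preserved.
2. **Normalization.** `C_norm = C_mean / (R_mean + G_mean + B_mean) × 100`
   per channel; the three percentages sum to 100 and define the cell's color
   signature (a point on the 2-simplex; ternary plots render it in the unit
   equilateral triangle with red at the origin, green at (1, 0), blue at the
   apex).
3. **Triple-positivity.** A cell enters clonal analysis only if
   `C_mean − 2.58·C_sd > 0` (strict) in *all three* channels; 2.58 is the
   two-sided standard-normal critical distance for p = 0.01. Because the
   criterion compares the mean against the per-pixel sd (not the standard
   error), its false-positive rate on a truly empty channel is far below the
   nominal 1% for any realistic ROI size — it is a conservative gate.
4. **Pairwise equivalence (TOST).** Two cells are "the same color" when, for
   every channel, two one-sided Welch t-tests reject that their normalized
   means differ by more than ± `margin_pct` at level `alpha`. Channel sds are
   recorded on the raw scale, so they are propagated to the percentage scale
   by the delta method on `C/(R+G+B)` (analytic gradient, channels treated as
   independent), with Welch–Satterthwaite degrees of freedom built from each
   cell's `n − 1`. If both propagated variances vanish the test degenerates to
   `|Δ| < margin`. The equivalence margin is **not a measured constant**: the
   original procedure reports only "p < 0.05". It is therefore a mandatory,
   always-reported parameter, default `margin_pct = 10`, `alpha = 0.05`. No
   multiple-testing correction is applied across pairs (each pair is tested
   at its own alpha, matching the source procedure); a Bonferroni option
   exists but is off by default.
5. **Clustering.** Clones are the connected components of the equivalence
   graph: if A~B and B~C, then {A, B, C} is one clone even when A~C fails.
   This transitive-union rule is the defining convention of the procedure and
   is implemented with union–find; tests check it against an independent
   graph-library oracle.

Clonality is summarized as the percentage of clones that stayed single cells
vs. grew multicellular, with the number of clones (tracked recombination
events) as denominator, and compared across stages by a two-sided Fisher
exact test. An all-zero 2×2 table returns p = 1 by convention.

### Margin geometry, and what clone recovery can show

Signatures live on a 2-simplex, so only a handful of barcodes can be mutually
separated by large margins: at L∞ separation 40 percentage points the simplex
interior holds ~3–4 trichromatic barcodes, at separation 20 roughly 5–10.
The clone-recovery benchmark therefore runs at `margin_pct = 5` with
generator-enforced 20-point inter-clone separation and sparse trichromatic
founders — the regime the method is designed for, since trichromatic cells
(requiring ≥ 2 independent recombination events) are rare by construction.
Under these conditions the adjusted Rand index between recovered and true
clones averages ≥ 0.9 over 20 simulated islets (observed: 1.0). Crowded
islets whose barcodes sit closer than the margin will be merged by design;
the procedure cannot distinguish clones it was not given the color
resolution to separate.

## Volumetry and cell-number estimation

Stacks are min–max converted to 8-bit and thresholded (Otsu by default — the
source pipeline converts to 8-bit but never names its threshold rule; any
numeric cutoff can be supplied), then labeled as 3D connected components
under 26-connectivity (6 available), with volumes `voxel_count × voxel
volume` and deterministic raster-order labels.

Beta-cell number is estimated as

    N = V_total / V̄_single

where `V_total` sums all objects of the all-channel composite and
`V̄_single` is the mean volume of *isolated* single cells taken from the
green+blue composite, where sparse recombined cells stand apart from their
unlabeled neighbors. Isolation is a volume window. The fixed default
[50, 500] µm³ reflects the ~185 µm³ beta-cell scale, but at that scale it
admits fused *pairs* (~340–370 µm³), which inflate `V̄_single` and bias N
low by >10%. The end-to-end pipeline therefore defaults to a
self-calibrating window: `[0.5, 1.5] ×` the **volume-weighted median** of
G+B object volumes. The weighted median is used because sub-resolution noise
speckles can outnumber real cells among labeled objects in small islets
while holding negligible total volume; an unweighted median can collapse
onto them, the weighted one cannot. On the benchmark (10 simulated islets,
30–300 cells, Gaussian intensity noise, 1 µm voxels) the estimator's mean
relative error is 4–8% depending on seed, consistent with the <10%
validation the estimator is expected to meet.

Leaky (background) recombination arithmetic: with `k` spontaneous events
observed over `m` islets of `n` cells, `p_single = k/(n·m)`, and the chance
of a spontaneous *trichromatic* cell (two independent events) is the square.
By reporting convention `p_single` is rounded to one significant figure
before squaring (4 events / 10 islets × 820 cells → 0.0005 → 2.5×10⁻⁷); the
unrounded product is reported alongside.

## Calcium responder classification

Protocols are ordered phase lists — one basal (5 mM glucose) phase first, any
glucose steps, one KCl phase last. Per cell:

* `F0` = mean raw fluorescence over the basal phase (≥ 3 samples required);
  traces are reported as `(F − F0)/(F_max − F0)` with `F_max` the global
  maximum, so already-normalized traces are a fixed point. A trace whose
  maximum does not exceed `F0` is flagged flat, not an error.
* **KCl QC:** a viable beta-cell must depolarize under KCl; cells whose
  KCl-phase mean does not exceed `F0 + k_sd·sd_basal` (default `k_sd = 3`,
  raw scale) are excluded from all quantification.
* **Responder call:** a QC-passed cell is a glucose responder if its raw
  trace exceeds `F0 + k_sd·sd_basal` for at least `dwell_fraction = 0.10` of
  the samples of some glucose phase (default `k_sd = 3`), and is not already
  active at basal glucose. Basal activity is judged against its own fixed
  multiplier (`basal_k_sd = 3`) rather than the responder `k_sd`, so the
  responder call is monotone in `k_sd` (at `k_sd → ∞` nothing responds; at
  `k_sd = 0` every noisy QC-passed cell does) and lowering the sensitivity
  dial cannot disqualify cells through their own baseline noise. All
  thresholds are computed from basal statistics of the raw trace, making
  calls invariant to detector gain/offset. The numeric criterion is a design
  choice: the source analysis reports responder fractions without stating an
  amplitude threshold, and oscillation-based definitions reduce to this
  dwell-above-threshold form at the temporal resolution considered.
* Histone-retention (H2B) status: a cell is label-negative when its mean
  intensity is ≤ background mean + 2 background sds ("similar to
  background").

Regional statistics aggregate per islet: responder percentages per A/P half
(QC-passed denominator), posterior/anterior ratio (flagged infinite and
excluded from aggregation when the anterior half has no responders), mean ±
SEM across islets, Kruskal–Wallis across stages followed by pairwise
two-sided rank-sum tests.

## A/P partition

The A/P segment joins the anterior and posterior tips on the (x, y)
projection; the divider is the perpendicular through its midpoint; a cell is
anterior iff its signed projection onto the tip axis is ≥ 0, so cells exactly
on the divider count as anterior (fixed tie-break). Tips are user-supplied
or estimated as the most distant centroid pair (convex hull), with the
larger-x tip taken as anterior — supply tips explicitly when the acquisition
is not oriented. The partition is invariant under rigid motions and
anti-symmetric under tip exchange. The labeling ratio sums green+blue
intensity (per-cell mean × ROI pixels) per half; the original workflow
outlined the two half-areas manually before integrating intensity, so
cell-level aggregation can differ from it at islet-boundary pixels.

## The synthetic islet generator

The generator produces the statistical structure the analyses assume, with
full ground truth; it is the package's test bed, not an optics simulator.

* **Recombination:** each of 3 cassettes (configurable) independently
  recombines with `p_recomb = 0.25` under induction (`p_leaky = 5×10⁻⁴`
  without), switching to green or blue with equal odds. Trichromatic iff the
  expressed set is exactly {R, G, B} — hence ≥ 2 independent events.
* **Barcodes:** per-founder cassette expression is lognormal
  (σ = 0.35 around a 120 a.u. base) and clone-heritable, giving continuous
  signatures rather than the ~10 discrete 3-cassette compositions —
  expression variegation, the property that makes color clustering
  informative at all.
* **Growth:** founders are quiescent with probability 0.5; proliferative
  cells divide with probability 0.5 per stage interval (discrete-generation
  branching over stages 3.5 → 15 → 30 dpf); daughters inherit cassette
  states exactly. Per-islet cell-count trajectories are free parameters —
  defaults were chosen to give a few-hundred-cell juvenile islet.
* **Geometry:** positions are dart-thrown into a prolate ellipsoid
  (axis ratio 2.5:1:1, long axis = A/P) sized so cells fill ~8% of it, with
  a minimum separation of ~1.9 cell radii (relaxed geometrically if packing
  fails). Post-embryonic (neogenesis, Poisson rate 8/interval, unlabeled)
  cells prefer the anterior half and embryonic cells the posterior with
  probability `ap_bias = 0.9` — the age polarity of the islet.
* **Function:** responder probability 0.34 anterior / 0.67 posterior (the
  juvenile-islet asymmetry regime); histone retention marks cells that never
  divided.
* **Measurements:** ROI pixel counts are uniform on [30, 80]; per-pixel
  channel intensities are Gaussian (sd 6 a.u.) around true level +
  background (12/10/10 a.u.); recorded mean/sd are the empirical ROI
  statistics (exact values when sd = 0, avoiding float drift between
  sisters).
* **Rendering:** each cell becomes the `round(volume/voxel³)` voxels nearest
  its centroid (volume correct to one voxel), channel intensity = true
  level, plus background and Gaussian noise, 16-bit; overlap beyond 5% of
  foreground warns.
* **Calcium:** piecewise-constant traces — baseline ~N(100, 8) a.u.,
  glucose phases at `base × (1 + 0.02 × mM)` for responders, KCl at
  `2.5 × base` for all but a configurable QC-fail fraction (rendered flat),
  Gaussian noise on top. Phenomenological only: no oscillations, no
  biophysics, no photobleaching.

What passing tests do **not** show about real data: no point-spread-function
or optical sectioning effects, no manual-ROI selection bias, no dichromatic
lineage calling, no motion or bleaching artifacts, and calcium dynamics
without oscillatory structure. Recovery results bound what the statistics
can do under the stated noise model, not under microscope reality.

## Determinism and numerics

Every stochastic routine takes an integer seed and flows through one
`numpy.random.Generator`; identical config + seed reproduces tables
byte-for-byte. Ties: divider cells → anterior; voxel blobs break distance
ties in raster order; clone sets are sorted by member id. Degenerate inputs
are defined, not crashed: zero channel sum → error naming the cells; flat
calcium trace → flagged; all-background stack → empty table; all-zero
contingency table → p = 1.

## Problem sizes

Test-suite and benchmark sizes are chosen for tight feedback loops:
clustering oracles up to 50 cells, labeling oracles up to 20³ voxels,
responder cohorts of 200 cells, and 10 rendered islets of 30–300 cells for
the volumetric benchmark. All scale linearly (labeling) or quadratically
(pairwise TOST) if larger runs are needed.
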