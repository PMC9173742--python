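# Methods

`vtatrace` quantifies monosynaptic rabies-virus (RABV) input maps to ventral
tegmental area dopamine (VTA^DA) neurons. The experimental design it models
uses a Cre-dependent, attenuated TVA receptor (TC66T, an mCherry fusion) plus
rabies glycoprotein in DAT-Cre mice, followed by EnvA-pseudotyped RABV-GFP.
Starter cells are GFP+/TC66T+ neurons in the ventral midbrain; input cells
are GFP+/TC66T− neurons anywhere in the brain. Because TC66T suppresses
leak-mediated local infection, inputs *local* to the injection site (within
~1 mm, plus the posterior ventral midbrain) can be quantified alongside
long-range inputs.

## Region catalog

Counts are binned into 57 regions: 22 long-range and 35 local, shipped as a
versioned CSV. The published record does not print the long-range membership
as a single table; the shipped list is reconstructed from the figure
narratives and the prior whole-brain mapping studies the analysis is anchored
to, and should be treated as configuration — edits belong in the CSV. The
midline raphe nuclei (DR/B7, RMg/B3, MnR/B8) are flagged `midline` and are
never split by hemisphere. Serotonergic group labels B5 ("pons") and B9
("pontine tegmentum") are given region anchors (PnO, SPTg) as the closest
catalog entries; this mapping is likewise a reconstruction. PAG is classed
as local.

## Counting statistics

* **Fraction matrix** — per brain, input counts per region divided by the
  brain's total inputs (starters excluded from numerator and denominator).
  Rows sum to 1 by construction.
* **Convergence index** — long-range inputs / starter cells. Only long-range
  inputs enter the numerator so the index is comparable across receptor
  variants with different local background.
* **Per-10,000 normalization** — `count / total_inputs × 10,000`, the common
  denominator used for sparse co-labeled populations.
* **Starter summaries** — subnucleus composition over {PBP, PN, IF, SNc,
  Rli, other} and a center-of-mass ellipse with per-axis sample-SD (ddof=1)
  radii. Sample SD is used throughout, including SEM.
* **Group comparison** — two-sided unpaired Student t-test with pooled
  variance and a 95% CI of the mean difference; Welch's correction is an
  option (`welch=True`).

## Co-label maps

Rules are require/exclude sets over marker flags: GABAergic = GFP+, GAD1/2+,
TC66T−; dopaminergic = GFP+, TH+, mCherry(TC66T)−; serotonergic = GFP+,
Tph2+. GABAergic composition is computed per brain and then averaged (mean ±
SEM), matching the way such percentages are conventionally reported; a pooled
mode is available. For DA–DA connectivity the denominator excludes cells
inside the sphere of TVA spread (default radius 500 µm around the recorded
injection coordinate; the published radius is not printed, so this is an
assumed, configurable value). The published regions of interest are
qualitative (anterior / posterior-medial / posterior-lateral VTA, RRF);
because cell records carry only medial–lateral and dorsal–ventral
coordinates, the default ROI predicates partition the VTA subnuclei on the
ML axis (<250 µm, 250–500 µm, ≥500 µm) plus RRF. Regions with no eligible
denominator cells yield missing values, not zeros, and are excluded from
cross-brain means.

## Ensemble embedding and clustering

Fractional counts are z-scored per region across brains (sample SD; constant
regions become all-zero rows with a warning) so regions with different count
magnitudes are comparable. Because a single nonlinear embedding depends on
its seed, region geometry is summarized over an ensemble: 20 seeded UMAP
runs (n_neighbors=10, min_dist=0.1, Euclidean; all configurable — the
published parameters were tuned by hand and are not recoverable), each
reduced to a pairwise Euclidean distance matrix normalized by that
embedding's maximum distance, then averaged element-wise. The aggregated
matrix is symmetric, zero-diagonal and bounded by 1, and is asserted so on
every run. Regions are grouped by agglomerative clustering with average
linkage on the aggregated distances (Ward would require embedding-space
coordinates); by default the number of clusters is selected from k∈{2..6}
by maximum silhouette, so a three-cluster outcome is a result rather than an
input. Fixed k is available.

Cross-dataset comparability ("do two cohorts mix or segregate?") is
formalized as a nearest-neighbor mixing score: brains are embedded as points
over a region subset (fractions renormalized within the subset, jointly
z-scored), and the score is the mean fraction of each brain's k=5 nearest
neighbors sharing its cohort label, reported with the analytic chance level
and a label-permutation p-value. The published judgment was visual; this
statistic is this package's formalization.

## Innervation profiles

A band of configurable thickness (default 100 px, the line-tool semantics of
common image software) is sampled from the midline to the lateral end of the
medial lemniscus: bilinear interpolation at unit arc-length steps along the
line, averaging `thickness` samples at unit spacing perpendicular to it.
The raw profile is resampled to exactly 100 bins (partition means when the
raw vector is longer; linear interpolation when shorter), normalized to the
per-image maximum (so image-level profiles peak at exactly 1), then averaged
hierarchically: images → brain, brains → region, regions → cluster. Images
are converted to float in [0, 1] regardless of bit depth. Bin 1 is the
midline, bin 100 the lateral terminus.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions under
which the pipeline is exercised.

Per brain: starter count uniform on [900, 2,400], distributed 58/27/5/8/2%
over PBP/PN/IF/SNc/Rli; long-range input total Poisson(8 × starters); local
total Poisson sized so the expected local share is 0.46 — at these defaults
a brain carries roughly 23,000–32,000 inputs. Region counts are multinomial
within the long-range and local blocks separately, around a default
composition with these anchors: VTA subnuclei 10% of total inputs, SN 6%,
RPC+IPN 4%, VTA+RRF 11.5%, DR 12.5% (so a 0.30 Tph2 rate reproduces the
published ~376-per-10,000 serotonergic scale).

Between-brain covariance is planted through a per-brain Dirichlet(2,2,2)
mixture over three projection archetypes (lateral / uniform / medial); each
region loads one-hot on an archetype following the published cluster
narrative, and its weight is modulated by
`1 + archetype_strength·(3·w_a − 1)` (default strength 0.8) times a
lognormal jitter of scale `noise_scale` (default 0.1). This gives the
embedding stage a recoverable planted partition. Note that ratio statistics
(e.g. GABAergic shares) computed under full covariance sit 1–2 points off
their nominal anchors, as expected for ratios of correlated sums; recovery
tests that use binomial/multinomial tolerances therefore run with
`archetype_strength=0, noise_scale=0`.

Marker flags are drawn per cell from a mutually exclusive categorical with
marginal rates: GAD rates derived from the published composition of local
inhibition (rate ∝ share/composition, scale K=0.08 keeping all draws
feasible), TH 0.40 in VTA subnuclei and RRF, Tph2 0.25–0.31 in the
B-group regions. Hemisphere is ipsilateral with probability 0.75 (injection
in the right hemisphere); midline-region cells are labeled `midline`.
Coordinates (ML, DV, µm) are generated for starters and local inputs only.

Control brains: Cre-negative conditions draw a Poisson cell count (mean 2.67
for TC66T, 3,183 for wild-type TC-B, 0 without AAV) placed uniformly over
local regions — only the means of these backgrounds are published, so a
homogeneous Poisson model is used.

Two-dataset scenarios share one composition (`shared=True`) or resample the
second cohort's local composition (seeded permutation plus lognormal
perturbation), which makes local-region subsets segregate in the mixing
diagnostic while long-range structure stays comparable.

What the generator does *not* emulate: spatial point-process structure,
atlas geometry, anterior–posterior coordinates, imaging noise statistics, or
correlated marker expression. Passing tests therefore demonstrate that the
pipeline recovers known parameters under the stated sampling model, not that
it is robust to every artifact of real histology.

## Problem sizes and numerical choices

Monte-Carlo recovery tests use 50-brain cohorts (rate recovery) and a
200-brain cohort (convergence-index recovery, tolerance ±0.25); the
cluster-stability check uses 20 replicate 8-brain cohorts at
`noise_scale=0.05` — 8 brains, rather than the default 4, because
standardized archetype profiles over very few brains can coincide by chance,
and the stability analysis is about the method rather than the minimal
dataset. Silhouette selection searches k∈{2..6}. Fraction-row sums are
checked to 1e-9; aggregated-distance invariants to 1e-12. Degenerate inputs
(zero starters, zero inputs, all-zero profiles, coincident embedding points,
k_nn ≥ group size) raise explicit errors rather than returning silently
wrong numbers. All randomness flows through `numpy.random.default_rng`
seeds; UMAP runs with a fixed `random_state` per ensemble member, making
every pipeline stage bit-reproducible given its seed list.

## Known limitations

* The long-range catalog membership and the B5/B9 region anchors are
  reconstructions; users with atlas-registered data should supply their own
  catalog CSV.
* The default composition and co-label rates are anchored to printed summary
  values, not to a deposited per-region count table.
* The mixing score is a k-NN purity statistic; with very few brains its
  permutation null is coarse.
* Innervation profiles assume the band stays inside the image; there is no
  automatic midline or lemniscus detection.
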