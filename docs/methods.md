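# Methods

`ribohet` quantifies the conformational heterogeneity of immature large
ribosomal subunits (pre-50S particles) from the outputs of a heterogeneous
cryo-EM reconstruction, and quantifies sucrose-gradient profiles of the
strains that produce them. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data do and do
not emulate.

## Block occupancy

The unit of analysis is a *block*: a named set of inclusive residue ranges
of a reference atomic model (e.g. a mature 50S split into ~114 segments —
helices, protein chains, coarse regions). The occupancy of block *b* in
volume *v* is

```
occ(v, b) = |{ atoms a in b : z_v(x_a) >= τ }| / |b|
```

where `z_v` is the volume's density field after per-volume z-normalization
(zero mean, unit sd over all voxels) and `z_v(x_a)` is the trilinear
interpolation at the atom position. Atoms outside the grid count as
unoccupied and are tallied.

Choices and rationale:

* **Threshold τ = 1.5 sd** (configurable). Densities well above the
  solvent/noise distribution mark ordered structure; 1.5 sd separates
  rendered signal from background in the synthetic fixtures and is
  deliberately conservative. Occupancy is monotone non-increasing in τ.
* **Per-volume normalization**, not joint: decoder-generated volumes carry
  arbitrary absolute scale, and per-volume z-scoring makes the threshold
  portable across them.
* **No B-factor or element weighting**: every heavy atom counts equally.
  Hydrogens are dropped at parse time; they carry no density at the
  relevant resolutions.
* Occupancies are exact fractions in [0, 1]; an empty block selection is a
  flagged warning, not a silent zero.

## Volume partitioning and classification

Per-particle latent encodings (d = 8 by default) are partitioned by seeded
k-means++ into K volume clusters (K = 500 at study scale, so each volume
averages enough particles); each cluster's representative is the member
nearest its centroid in Euclidean distance, ties broken by lowest particle
id for determinism.

Volumes — not particles — are then classified: ward-linkage agglomerative
clustering (Euclidean metric) on the volumes' occupancy rows. Ward merges
the pair of clusters minimizing the increase in within-cluster variance;
merge heights are non-decreasing, and on small instances the linkage equals
an exhaustive greedy agglomeration by variance increase (tested).

**Choosing the class count.** With heights `h_1 <= ... <= h_{n-1}`,
cutting just below `h_{n-k+1}` yields k classes, supported by the relative
gap `r(k) = h_{n-k+1} / h_{n-k}`. A hierarchical ensemble shows large gaps
at several granularities — at the coarse maturation-stage level as well as
at the class level — so taking the single largest gap collapses to the
coarse structure on a fraction of replicates. The rule used here keeps the
**finest strongly supported cut**: the largest k (capped at 50) whose
excess gap `r(k) − 1` is at least half the maximal excess gap. On planted
ensembles with template separation ≥ 6× the row noise sd this recovers the
planted class count in ≥ 95% of seeded replicates; an explicit class count
can always be forced.

Class labels are renumbered 1..k along the dendrogram leaf order, so the
ordered similarity heatmap reads left-to-right in label order and reruns
are bitwise stable.

## Maturation-state taxonomy

Each class mean occupancy vector (particle-count-weighted mean of member
volumes) is mapped onto a two-axis state:

* **PTC stage (1-4)** — folding of the peptidyl transferase center,
  climbing CP → H73/H90-93 → H89 against a folded threshold θ:
  1. CP below θ (only the core folded);
  2. CP folded but H73 or H90-93 below θ;
  3. H73 and H90-93 folded, H89 still below θ;
  4. all of them folded — mature PTC.
* **H68/69 letter (A-D)** — the H68/69 category occupancy binned at
  0.25 / 0.5 / 0.75, from undocked (A) to fully docked (D).

θ defaults to 0.5: folding is described qualitatively in the source data
("good" vs "weak" density), so the symmetric midpoint is the default and
both θ and the bin edges are configuration. The assignment is monotone:
raising any category occupancy never lowers either axis. Category
occupancies are means over the blocks mapped to the category; the mapping
is derived from the block library (category tags for core/CP/H68-69,
block names for the individual PTC helices).

State fractions are particle-weighted: each volume contributes its particle
count to its class's state. Fractions sum to 1; between-dataset deltas sum
to 0 and are refused when the two runs used different taxonomy parameters.

## Gradient profiles

A260-vs-position traces are baseline-corrected by a morphological opening:
a rolling minimum followed by a rolling maximum, both over a window of 20%
of the trace length, applied to a median-filtered copy (window 5% of the
trace). The erosion finds the under-peak floor; the dilation restores it
to the drift line (a plain rolling minimum undershoots a tilted baseline
by half a window); the median prefilter keeps noise minima from dragging
the floor down. The corrected trace is clipped at zero.

Each named sedimentation window (30S, (pre)50S, 70S, polysome) yields the
peak position and height (window maximum) and the baseline-subtracted
trapezoidal area. The headline statistic is the **(pre)50S / 30S area
ratio** — areas rather than heights, because areas are robust to peak-width
differences between samples; heights are reported alongside. In mutant
strains the "50S" window captures the accumulated pre-50S peak, which
sediments near 50S.

**Validity envelope.** The opening baseline is accurate when each peak's
base width (≈ ±4σ for a Gaussian) fits inside the rolling window and drift
is gentle: the residual bias grows roughly as (drift slope) × (peak
support)². Peaks wider than the window are partially absorbed into the
baseline. The default windows match the synthetic generator's geometry
(span 0-10, 30S at 3, 50S at 5); real instruments need their own window
configuration.

## Synthetic data

The generator replaces the study's raw particle stacks, which are not
redistributable at desk scale. It emulates:

* **Phantom model + library** — disjoint atom clusters on a lattice
  (inter-block spacing ≥ 3 voxels; intra-block atoms on a sub-lattice of
  voxel centers ~3 voxels apart so each atom carries a well-sampled
  density peak). Landmark blocks are named core, CP, H38, L1_stalk,
  H68/H69, H71/H73/H89/H90-93, uL16/bL33/bL35/bL36.
* **Rendered volumes** — a block at occupancy q contributes Gaussians
  (default width 1 Å, amplitude 1) at a seeded random subset of
  round(q·n) of its atoms, plus white noise. Realizing occupancy as the
  fraction of atoms sitting in density is what makes q recoverable by the
  atoms-above-threshold scorer and mirrors how partially ordered regions
  present in averaged maps; scaling all atoms' amplitude by q instead
  would make the score a step function of q.
* **Particle ensembles** — particles draw a state template by weight;
  latent encodings are template centers (pairwise separation 8× the latent
  noise sd, inside the ≥ 6× regime where partition recovery is guaranteed)
  plus isotropic noise; occupancy rows are the template vector plus
  per-block noise sd 0.05, clipped to [0, 1]. Two fidelity tiers: fast
  row-level simulation for ensemble-scale tests, rendered volumes for
  closed-loop tests at small scale.
* **State templates** — one per volume class: 11 classes spanning 8 states
  (1A, 2A, 2C, 2D, 3B, 3D, 4C, 4D) for the factor-deletion ensemble with
  stage weights 14/56/20/10%, and 10 classes spanning 6 states for the
  N-loop-deletion ensemble with stage weights 13/27/52/8%. Classes sharing
  a state differ in non-taxonomy blocks (L1-stalk mobility, protein
  presence). The stage-2/stage-3 weights are the reported values; the
  stage-1/stage-4 weights are filled to sum to 100% and kept similar
  across the two ensembles, as described for the source data.
* **Gradient traces** — sums of Gaussians with specified analytic areas
  (default σ 0.20 / 0.22 for the 30S and 50S peaks) on a linear drift
  (slope 0.005 per position unit, intercept 0.1) with white noise at 1% of
  the tallest peak.

What the synthetic data do **not** emulate: projection images, CTF,
per-particle alignment error, B-factor falloff, correlated (non-white)
map noise, residue-level flexibility gradients within a block, and
instrument-specific gradient artifacts beyond linear drift. Passing the
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under its stated operating regime, not the performance
of the upstream reconstruction on real micrographs.

## Problem sizes and determinism

Ensemble-scale experiments use 500 volumes and 200 000 particles with
K = 500 (the study's scale); k-means at that size uses a single k-means++
initialization, smaller problems default to 10 restarts. Every stochastic
step takes an explicit seed; reruns with the same configuration are
checksum-identical on all tabular outputs, and each pipeline run writes a
JSON manifest (seeds, parameters, versions, output hashes) sufficient to
reproduce it.

## Known limitations

* Block boundaries are user configuration; the shipped 50S template has
  placeholder ranges and must be populated against a real reference model.
* The occupancy statistic ignores local resolution; a uniformly weak but
  complete region can score like a partially ordered one.
* The auto class-count rule assumes the planted granularity is the finest
  strongly supported gap; genuinely nested heterogeneity at several scales
  may warrant forcing the count.
* The letter-axis bin edges (0.25/0.5/0.75) are a declared convention; the
  quantitative boundary between adjacent docking grades is not defined by
  the source data.
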