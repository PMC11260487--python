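# ribohet

Quantitative heterogeneity analysis of pre-50S ribosome assembly
intermediates.

When an assembly factor of the bacterial large ribosomal subunit is
deleted, immature pre-50S particles accumulate — not as one structure but
as an ensemble of intermediates differing in which rRNA helices and late
proteins are ordered. Heterogeneous cryo-EM reconstruction turns such a
sample into hundreds of density volumes plus per-particle latent
encodings; `ribohet` turns those into interpretable biology:

1. **Block occupancy** — the reference model (e.g. a mature 50S) is split
   into named blocks; the occupancy of block *b* in volume *v* is the
   fraction of its atoms whose z-normalized, trilinearly interpolated
   density reaches a threshold τ (default 1.5 sd):
   `occ(v,b) = |{a ∈ b : z_v(x_a) ≥ τ}| / |b|`.
2. **Classification** — ward-linkage hierarchical clustering (Euclidean
   distance) of the volumes × blocks occupancy matrix groups volumes into
   conformational classes; the dendrogram is cut at the finest strongly
   supported merge-height gap, or at a forced class count.
3. **Maturation states** — each class is named `<stage><letter>`: the
   stage (1–4) tracks peptidyl-transferase-center folding (CP, then
   H73/H90–93, then H89 against a folded threshold θ = 0.5) and the
   letter (A–D) bins the H68/69 docking occupancy. State fractions are
   particle-weighted and comparable between datasets.
4. **Gradient profiles** — sucrose-gradient A260 traces are
   baseline-corrected (morphological opening) and integrated in named
   windows; the (pre)50S/30S area ratio quantifies pre-50S accumulation
   and ranks mutants.

A synthetic-data module generates every input the pipeline needs — phantom
models with block libraries, rendered noisy volumes, mixture particle
ensembles, multi-peak traces — with full ground-truth bookkeeping, so the
whole chain is validated by parameter recovery.

## Worked example

Simulate a 500-volume ensemble from the 11 planted class templates of the
factor-deletion dataset, classify it, and assign states:

```bash
ribohet simulate --dataset delta_yjga --n-volumes 500 --seed 1 --out sim/
ribohet states --matrix sim/occupancy_matrix.tsv --blocks sim/blocks.yaml \
               --classes auto --out sim/state_summary.tsv
```

The second command prints the particle-weighted state distribution:

```
       fraction  particle_count
state
1A        0.138            69.0
2A        0.098            49.0
2C        0.126            63.0
2D        0.350           175.0
3B        0.072            36.0
3D        0.118            59.0
4C        0.030            15.0
4D        0.068            34.0
```

Eleven classes are found by the auto cut and map onto eight states; state
2 (CP folded, PTC helices not yet) dominates with 2A + 2C + 2D ≈ 57% of
particles in this 500-volume draw, converging to the planted 56% at full
particle scale (see `analysis/03_state_fractions.py`). Quantifying a
synthetic two-peak gradient trace recovers its planted 50S/30S area ratio:

```bash
ribohet gradient --trace trace.csv --out quant.tsv
```

The numbered scripts under `analysis/` run the full study-scale
experiments and write their tables to `results/`: ensemble simulation
(`01`), class-count recovery — 11 and 10 classes for the two datasets
(`02`), 200 000-particle state-fraction recovery — state 2 at 56% vs 27%,
state 3 at 20% vs 52% (`03`), and the mutant gradient-ratio series from
0.34 (full-length) to 1.92 (`04`).

## Layout

```
src/ribohet/      library: io_formats, blocks, occupancy, clustering,
                  taxonomy, gradients, synthetic, pipeline, acceptance, cli
analysis/         numbered study-scale drivers (write to results/)
examples/         phantom block library + 50S template to populate
tests/            unit, property and recovery suites
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
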