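# smlmpatterns

Point-pattern analysis for two-color single-molecule localization
microscopy (SMLM/dSTORM) of cell–cell interfaces. The package quantifies
how a membrane receptor nanoclusters and how strongly it mixes with — or
segregates from — a second labelled species (the motivating system is a
chimeric antigen receptor, CAR, versus the bulky phosphatase CD45 at
CAR-T/target-cell contacts, where receptor–phosphatase segregation is a
signature of productive triggering under the kinetic-segregation model).

It is aimed at microscopists and analysts who have localization tables
(e.g. ThunderSTORM CSV exports) rather than raw camera frames, and at
method developers who need a fully synthetic ground truth to validate
every stage of such a pipeline.

## What it computes

* **Blinking correction** — a fluorophore blinks, so one molecule yields
  several localizations. Localizations within a distance threshold and a
  temporal gap (defaults 20 nm, 50 ms) are linked; connected components
  collapse to single molecules at their intensity-weighted mean position.
* **Pair correlation function (PCF)** — g(r) is the density of point
  pairs at separation r relative to complete spatial randomness (CSR):
  g = 1 for CSR, > 1 for clustering. Cross-channel g₁₂(r) = 1 for
  independent channels. Toroidal (periodic) edge correction by default,
  border exclusion for real ROIs.
* **Extent of mixing (EOM)** — the normalized bivariate PCF

  EOM(r) = (g₁₂(r) − 1) / (g_pool(r) − 1),

  where g_pool is the PCF of the pooled two-channel pattern. EOM = 0
  for independent channels ("no interaction"), EOM = 1 when channel
  identities are a random labelling of one pattern (full mixing).
  Segregation is 1 − EOM; standard readout radii are 20 nm (molecular
  overlap) and 200 nm (overlap of larger membrane features).
* **Nanocluster sizing** — DBSCAN with ε = 45 nm and minpts = 2
  classifies molecules into monomers, dimers and clusters of ≥ 3, with
  cumulative cluster-size distributions.
* **Axial separation** — per-channel mean z and a two-sided
  Mann–Whitney U (or Welch) test of the channel height difference.
* **Cohort statistics** — per-cell summaries aggregated per condition
  (mean ± SEM, tests against an off-target reference), excess killing,
  max-normalized parameter matrices and their Pearson correlations.
* **Synthetic ground truth** — seeded CSR and Thomas (clustered) pattern
  generators with independent / random-labelling / co-clustered /
  displaced-cluster channel coupling, plus geometric blinking emulation,
  so every stage can be tested against known truth.

## Worked example

```python
import numpy as np
from smlmpatterns import *

roi = ROI(0, 4000, 0, 4000)                      # 4 µm × 4 µm window, nm units
cfg = SyntheticConfig(window=roi, process="thomas",
                      coupling="random_label", seed=11)
rng = np.random.default_rng(11)
sample = simulate_two_color(cfg, rng)

table  = emulate_blinking(sample.points1, cfg, channel=1, rng=rng)
merged = merge_localizations(table, 60.0, 50.0)  # radius ~4× the 15 nm jitter

g     = pcf(sample.points1, roi)
curve = eom_curve(sample.points1, sample.points2, roi)
vals  = eom_at(curve, (20.0, 200.0))
dist  = size_distribution(dbscan_clusters(sample.points1, 45.0, 2))
```

prints, via the obvious `print` statements:

```
channel 1: 332 molecules, channel 2: 322 molecules
blinking: 1321 localizations -> 348 merged molecules
self-clustering g(20 nm) = 18.35
EOM(20 nm)  = 0.975   segregation = 0.025
EOM(200 nm) = 1.092   segregation = -0.092
clusters: 69, monomer/dimer/3+ molecule fractions = 0.13/0.16/0.71
```

Read: the channel-1 pattern is strongly clustered (g(20 nm) ≈ 18 ≫ 1);
because the two channels are a random labelling of one clustered
pattern, EOM sits at ≈ 1 (full mixing, segregation ≈ 0 up to noise);
the blinking correction recovers ≈ 348 molecules from 1321 raw
localizations against a ground truth of 332.

A command-line surface wraps the same stages:

```bash
smlmpatterns simulate --out sim --coupling random_label --seed 3
smlmpatterns eom sim/channel1.csv sim/channel2.csv eom.csv
smlmpatterns pipeline config.yaml --seed 1
```

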